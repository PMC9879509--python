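"""Hierarchical clustering of amino-acid repeat units.

Units are tripled before comparison (so short units align over a full
window), distances are global-alignment identity distances, clustering is
average-linkage with a flat cut, groups of >= 3 members become clusters,
and cluster names list the pooled residues with >= 10% frequency in
descending order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import average, fcluster, to_tree
from scipy.spatial.distance import squareform

NO_CLUSTER = "n.c."


@dataclass(frozen=True)
class ClusterAssignment:
    unit_id: str
    unit: str
    cluster_id: Optional[int]
    cluster_name: str


def triple_units(units: Sequence[str]) -> list[str]:
    """Concatenate each unit three times."""
    if not units:
        raise ValueError("units must be non-empty")
    return [u * 3 for u in units]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


def pairwise_distance(a: str, b: str) -> float:
    """Identity distance 1 - 2 * M / (|a| + |b|) where M is the maximal
    number of matched positions in a global alignment scoring match = 1
    and mismatch/gap = 0 (M equals the longest common subsequence).

    Symmetric, in [0, 1], zero iff a == b, and 1 when the alphabets are
    disjoint.
    """
    if not a or not b:
        raise ValueError("strings must be non-empty")
    if a == b:
        return 0.0
    matches = _aligner().score(a, b)
    return 1.0 - 2.0 * matches / (len(a) + len(b))


def distance_matrix(units: Sequence[str]) -> np.ndarray:
    tripled = triple_units(units)
    n = len(tripled)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pairwise_distance(tripled[i], tripled[j])
    return dist


def cluster_units(distances: np.ndarray, units: Sequence[str],
                  unit_ids: Optional[Sequence[str]] = None,
                  cutoff: float = 0.6,
                  min_size: int = 3) -> list[ClusterAssignment]:
    """Average-linkage clustering cut at ``cutoff``; flat groups with
    >= min_size members become named clusters, the rest are labeled n.c.

    Cluster ids are assigned by the sorted member-unit multisets, so the
    result is invariant to input permutation.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    distances = np.asarray(distances, float)
    if distances.shape[0] != len(units):
        raise ValueError("distance matrix does not match units")
    if unit_ids is None:
        unit_ids = [f"unit_{i}" for i in range(len(units))]
    if len(units) == 1:
        return [ClusterAssignment(unit_ids[0], units[0], None, NO_CLUSTER)]
    linkage = average(squareform(distances, checks=False))
    flat = fcluster(linkage, t=cutoff, criterion="distance")
    groups: dict[int, list[int]] = {}
    for idx, label in enumerate(flat):
        groups.setdefault(int(label), []).append(idx)
    kept = [members for members in groups.values() if len(members) >= min_size]
    kept.sort(key=lambda members: sorted(units[i] for i in members))
    assignment: dict[int, tuple[int, str]] = {}
    for cid, members in enumerate(kept, start=1):
        name = name_cluster([units[i] for i in members])
        for i in members:
            assignment[i] = (cid, name)
    return [
        ClusterAssignment(
            unit_id=unit_ids[i], unit=units[i],
            cluster_id=assignment[i][0] if i in assignment else None,
            cluster_name=assignment[i][1] if i in assignment else NO_CLUSTER,
        )
        for i in range(len(units))
    ]


def name_cluster(member_units: Sequence[str]) -> str:
    """Residues with pooled frequency >= 10% across the member units, in
    descending frequency (ties alphabetical)."""
    if not member_units:
        raise ValueError("need at least one member")
    counts = Counter("".join(member_units))
    total = sum(counts.values())
    named = [(aa, c) for aa, c in counts.items() if c / total >= 0.10]
    named.sort(key=lambda item: (-item[1], item[0]))
    return "".join(aa for aa, _ in named)


def dendrogram_newick(distances: np.ndarray,
                      labels: Sequence[str]) -> str:
    """Average-linkage dendrogram as a Newick string."""
    linkage = average(squareform(np.asarray(distances, float), checks=False))
    tree = to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = render(node.left), render(node.right)
        return (f"({left}:{node.dist - node.left.dist:.5f},"
                f"{right}:{node.dist - node.right.dist:.5f})")

    return render(tree) + ";"
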