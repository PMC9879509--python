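"""Independent brute-force reference implementations used only by tests.

Each oracle states the contract directly as quantified string comparisons
and stays free of the production code paths it checks.
"""

from __future__ import annotations


def primitive_root_by_divisors(unit: str) -> str:
    """Try every divisor length in increasing order."""
    n = len(unit)
    for p in range(1, n + 1):
        if n % p == 0 and unit[:p] * (n // p) == unit:
            return unit[:p]
    raise AssertionError("unreachable")


def brute_force_tandem_arrays(seq: str, *, min_region_len: int, min_copies: int,
                              min_unit_len: int = 1, min_distinct: int = 1,
                              excluded: str = "N",
                              max_unit_len: int | None = None,
                              ) -> set[tuple[int, int, str, int]]:
    """All maximal primitive tandem arrays at their leftmost placement.

    A tuple (i, e, unit, c) qualifies iff
      * unit = seq[i:i+m] is primitive, contains no excluded character,
        and has >= min_distinct distinct characters;
      * c is the greedy copy count from i and c >= min_copies,
        c*m >= min_region_len;
      * the window cannot be slid left: i == 0 or seq[i-1] != seq[i+m-1].

    ``max_unit_len`` bounds the period search (speed only); the cheap
    copy-count check runs first so infeasible (i, m) pairs exit fast.
    """
    n = len(seq)
    out: set[tuple[int, int, str, int]] = set()
    for i in range(n):
        max_m = (n - i) // min_copies
        if max_unit_len is not None:
            max_m = min(max_m, max_unit_len)
        for m in range(min_unit_len, max_m + 1):
            unit = seq[i : i + m]
            c = 1
            while seq[i + c * m : i + (c + 1) * m] == unit:
                c += 1
            if c < min_copies or c * m < min_region_len:
                continue
            if any(ch in excluded for ch in unit):
                continue
            if len(set(unit)) < min_distinct:
                continue
            if primitive_root_by_divisors(unit) != unit:
                continue
            if i > 0 and seq[i - 1] == seq[i + m - 1]:
                continue
            out.add((i, i + c * m, unit, c))
    return out


def flank_scan_oracle(seq: str, start: int, end: int, unit: str) -> tuple[int, int]:
    """Maximal-k linear scan for partial flanks, by direct comparison."""
    m = len(unit)
    a = 0
    for k in range(1, m):
        if start - k >= 0 and seq[start - k : start] == unit[m - k :]:
            a = k
    b = 0
    for k in range(1, m):
        if end + k <= len(seq) and seq[end : end + k] == unit[:k]:
            b = k
    return a, b


def terminal_inverted_repeat_oracle(seq: str, min_len: int) -> int | None:
    """Quadratic prefix/suffix reverse-complement scan."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    best = 0
    for k in range(1, len(seq) // 2 + 1):
        prefix = seq[:k]
        suffix_rc = "".join(comp[ch] for ch in reversed(seq[-k:]))
        if prefix == suffix_rc:
            best = k
    return best if best >= min_len else None


def lcs_length(a: str, b: str) -> int:
    """Classic O(len(a)*len(b)) longest-common-subsequence DP."""
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if ca == cb else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def kruskal_wallis_by_formula(g1, g2) -> float:
    """H from first principles: midranks by sorting, explicit tie factor."""
    pooled = sorted((v, 0, i) for i, v in enumerate(g1)) + \
             sorted((v, 1, i) for i, v in enumerate(g2))
    pooled.sort(key=lambda t: t[0])
    n = len(pooled)
    ranks: dict[tuple[int, int], float] = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        midrank = (i + 1 + j) / 2
        for k in range(i, j):
            ranks[(pooled[k][1], pooled[k][2])] = midrank
        i = j
    r1 = sum(ranks[(0, i)] for i in range(len(g1)))
    r2 = sum(ranks[(1, i)] for i in range(len(g2)))
    h = 12 / (n * (n + 1)) * (r1**2 / len(g1) + r2**2 / len(g2)) - 3 * (n + 1)
    values = sorted(v for v, _, _ in pooled)
    tie = 0
    i = 0
    while i < n:
        j = i
        while j < n and values[j] == values[i]:
            j += 1
        t = j - i
        tie += t**3 - t
        i = j
    denom = 1 - tie / (n**3 - n)
    return 0.0 if denom == 0 else h / denom
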