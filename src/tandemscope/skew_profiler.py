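"""GC skew, cumulative skew, replichore prediction, and the local GC/AT
symmetry profile around tandem repeat regions."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core_io import GenomeRecord
from .repeat_finder import TRRegion


@dataclass(frozen=True)
class SkewProfile:
    positions: np.ndarray      # window centers
    skew: np.ndarray           # (G - C) / (G + C), 0 where G + C == 0
    cumulative: np.ndarray     # running sum of skew
    window: int
    step: int
    predicted_origin: Optional[int]
    predicted_terminus: Optional[int]

    def __len__(self) -> int:
        return len(self.positions)


def _window_counts(seq: str, base: str, window: int, step: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord(base)
    csum = np.concatenate(([0], np.cumsum(arr)))
    starts = np.arange(0, len(seq) - window + 1, step)
    return csum[starts + window] - csum[starts]


def gc_skew(genome: GenomeRecord, window: int = 1000,
            step: int = 10) -> SkewProfile:
    """Windowed GC skew (G - C)/(G + C) with its cumulative sum.

    Windows with G + C == 0 are assigned skew 0 so the cumulative sum
    stays defined on A/T-rich stretches.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window > len(genome):
        raise ValueError("window exceeds genome length")
    seq = genome.sequence
    g = _window_counts(seq, "G", window, step).astype(float)
    c = _window_counts(seq, "C", window, step).astype(float)
    total = g + c
    skew = np.where(total > 0, (g - c) / np.where(total > 0, total, 1), 0.0)
    cumulative = np.cumsum(skew)
    starts = np.arange(0, len(seq) - window + 1, step)
    positions = starts + window // 2
    if np.all(skew == 0):
        origin = terminus = None
    else:
        origin = int(positions[int(np.argmin(cumulative))])
        terminus = int(positions[int(np.argmax(cumulative))])
    return SkewProfile(positions=positions, skew=skew, cumulative=cumulative,
                       window=window, step=step, predicted_origin=origin,
                       predicted_terminus=terminus)


def predict_replichores(profile: SkewProfile) -> Optional[tuple[int, int]]:
    """(origin, terminus) = positions of the global cumulative minimum and
    maximum (ties -> leftmost); None when the skew is identically zero."""
    if profile.predicted_origin is None:
        return None
    return profile.predicted_origin, profile.predicted_terminus


def symmetry_profile(genome: GenomeRecord, region: TRRegion) -> list[float]:
    """Sliding GC fraction over a repeat region plus one unit of flank on
    each side, window = half the unit length, step 1.  Over the repeat
    body the profile is exactly unit-length periodic."""
    m = region.unit_len
    if m < 2:
        raise ValueError("unit length must be >= 2 for a symmetry profile")
    window = m // 2
    lo = max(0, region.start - m)
    hi = min(len(genome), region.end + m)
    seq = genome.sequence[lo:hi]
    counts = _window_counts(seq, "G", window, 1) + _window_counts(seq, "C", window, 1)
    return (counts / window).tolist()


def write_profile_tsv(profile: SkewProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tskew\tcumulative\n")
        for p, s, c in zip(profile.positions, profile.skew, profile.cumulative):
            fh.write(f"{p}\t{s:.6f}\t{c:.6f}\n")


def plot_profile(profile: SkewProfile, path: str | Path) -> None:
    """Two-panel skew / cumulative-skew plot (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax1.plot(profile.positions, profile.skew, lw=0.5, color="grey")
    ax1.set_ylabel("GC skew")
    ax2.plot(profile.positions, profile.cumulative, color="green")
    ax2.set_ylabel("cumulative GC skew")
    ax2.set_xlabel("position (bp)")
    if profile.predicted_origin is not None:
        ax2.axvline(profile.predicted_origin, color="red", ls="--", lw=0.8)
        ax2.axvline(profile.predicted_terminus, color="blue", ls="--", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
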