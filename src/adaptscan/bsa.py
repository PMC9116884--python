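"""Bulk-segregant analysis: pool allele frequencies, sliding-window scan, peak calling.

The scan mirrors the classic extreme-pool mapping design: F2 individuals with
an extreme phenotype are pooled and sequenced, and the frequency of one
parent's allele is tracked along the genome. Away from causal loci the pool
is an unbiased draw from the cross and the frequency hovers around 0.5;
around a causal locus the selected pool is (nearly) fixed, so the windowed
median rises above ``high`` or falls below ``low``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PoolCounts",
    "pool_frequency",
    "window_scan",
    "call_peaks",
    "DEFAULT_WINDOW_BP",
    "DEFAULT_STEP_BP",
    "DEFAULT_HIGH",
    "DEFAULT_LOW",
    "DEFAULT_MIN_DEPTH",
]

DEFAULT_WINDOW_BP = 200_000
DEFAULT_STEP_BP = 5_000
DEFAULT_HIGH = 0.99
DEFAULT_LOW = 0.01
#: coherent with the DP > 3 site filter used upstream
DEFAULT_MIN_DEPTH = 4


@dataclass
class PoolCounts:
    """Per-marker read counts for a phenotype-selected sequencing pool.

    ``count_a`` counts reads supporting the parent-A allele, ``count_b`` the
    parent-B allele. Positions are 1-based.
    """

    chrom: np.ndarray
    pos: np.ndarray
    count_a: np.ndarray
    count_b: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.count_a = np.asarray(self.count_a, dtype=np.int64)
        self.count_b = np.asarray(self.count_b, dtype=np.int64)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.count_a) == len(self.count_b) == n):
            raise ValueError("PoolCounts arrays must have equal length")
        if (self.count_a < 0).any() or (self.count_b < 0).any():
            raise ValueError("read counts must be non-negative")

    def __len__(self) -> int:
        return len(self.pos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "count_a": self.count_a,
                "count_b": self.count_b,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PoolCounts":
        return cls(
            df["chrom"].to_numpy(),
            df["pos"].to_numpy(),
            df["count_a"].to_numpy(),
            df["count_b"].to_numpy(),
        )


def pool_frequency(counts: PoolCounts, min_depth: int = DEFAULT_MIN_DEPTH) -> np.ndarray:
    """Per-marker parent-A allele frequency ``A / (A + B)``.

    Markers whose total depth is below ``min_depth`` are set to NaN.
    Raises if no marker is informative.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    total = counts.count_a + counts.count_b
    freq = np.full(len(counts), np.nan)
    ok = total >= min_depth
    freq[ok] = counts.count_a[ok] / total[ok]
    if not ok.any():
        raise ValueError("no informative markers: all totals below min_depth")
    return freq


def window_scan(
    freqs: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window median +- SD of marker frequencies.

    Windows are anchored at position 1 on each chromosome and advanced by
    ``step_bp``; every start ``s`` with ``s + window_bp - 1 <= L`` is emitted
    (a chromosome shorter than one window yields a single ``[1, L]`` window).
    Windows are half-open ``[start, end)`` in the output with 1-based starts,
    i.e. a window row covers bases ``start .. end - 1``.

    NaN frequencies (uninformative markers) are ignored inside a window;
    windows with zero informative markers carry a NaN statistic. SD is the
    population SD (ddof=0) of the marker frequencies in the window.
    """
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    freqs = np.asarray(freqs, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if chroms is None:
        chroms = np.zeros(len(positions), dtype=object)
        chroms[:] = "chr"
    chroms = np.asarray(chroms)

    rows: list[tuple] = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos_c = positions[sel]
        frq_c = freqs[sel]
        order = np.argsort(pos_c, kind="stable")
        pos_c = pos_c[order]
        frq_c = frq_c[order]
        if chrom_lengths and chrom in chrom_lengths:
            length = int(chrom_lengths[chrom])
        else:
            length = int(pos_c.max()) if len(pos_c) else window_bp
        if length >= window_bp:
            starts = np.arange(1, length - window_bp + 2, step_bp, dtype=np.int64)
            ends = starts + window_bp
        else:
            starts = np.array([1], dtype=np.int64)
            ends = np.array([length + 1], dtype=np.int64)
        lo = np.searchsorted(pos_c, starts, side="left")
        hi = np.searchsorted(pos_c, ends, side="left")
        for s, e, i0, i1 in zip(starts, ends, lo, hi):
            vals = frq_c[i0:i1]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                rows.append((chrom, s, e, float(np.median(vals)), float(np.std(vals)), len(vals)))
            else:
                rows.append((chrom, s, e, np.nan, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "median_freq", "sd", "n_markers"]
    )


@dataclass
class PeakRegion:
    chrom: object
    start: int
    end: int
    direction: str  # "high" | "low"
    n_windows: int


def call_peaks(
    track: pd.DataFrame,
    high: float = DEFAULT_HIGH,
    low: float = DEFAULT_LOW,
) -> list[PeakRegion]:
    """Maximal merged runs of windows with median above ``high`` / below ``low``.

    Qualifying windows on the same chromosome whose coordinates overlap or
    touch are merged into a single region spanning their union.
    """
    if not (0 < low < high < 1):
        raise ValueError("need 0 < low < high < 1")
    regions: list[PeakRegion] = []
    for direction, mask in (
        ("high", track["median_freq"] > high),
        ("low", track["median_freq"] < low),
    ):
        qual = track[mask.fillna(False)]
        for chrom, grp in qual.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            cur_start = cur_end = None
            n = 0
            for _, row in grp.iterrows():
                if cur_start is None:
                    cur_start, cur_end, n = row["start"], row["end"], 1
                elif row["start"] <= cur_end:
                    cur_end = max(cur_end, row["end"])
                    n += 1
                else:
                    regions.append(PeakRegion(chrom, int(cur_start), int(cur_end), direction, n))
                    cur_start, cur_end, n = row["start"], row["end"], 1
            if cur_start is not None:
                regions.append(PeakRegion(chrom, int(cur_start), int(cur_end), direction, n))
    regions.sort(key=lambda r: (str(r.chrom), r.start, r.direction))
    return regions


def peaks_to_frame(regions: list[PeakRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.direction, r.n_windows) for r in regions],
        columns=["chrom", "start", "end", "direction", "n_windows"],
    )
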