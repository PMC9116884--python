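"""Copy-number estimation from read depth and mechanistic junction classification.

A tandem duplication (TD) between known breakpoints raises read depth inside
the duplicated interval in proportion to the number of copies carried. The
estimator slides fixed windows across the interval, normalizes each window's
mean depth to the pooled depth of the two flanking regions, and summarizes
with the median ratio; nearest-integer rounding of that median gives the
integer copy number. For a homozygous k-copy TD the expected ratio is k; for
a heterozygous TD it is (k + 1) / 2 because the two haplotypes contribute
additively to diploid depth.

Junction classification recovers the repair mechanism of a TD breakpoint
from the reference sequence and the observed junction: microhomology
(breakpoints ambiguous because the joined ends share an exact string),
templated insertion (novel bases copied from a nearby template), or blunt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoverageProfile",
    "CNEstimate",
    "JunctionCall",
    "normalized_coverage",
    "default_interval",
    "classify_junction",
    "DEFAULT_CN_WINDOW",
    "DEFAULT_CN_STEP",
    "DEFAULT_CN_FLANK",
    "FALLBACK_INTERVAL",
]

DEFAULT_CN_WINDOW = 800
DEFAULT_CN_STEP = 400
DEFAULT_CN_FLANK = 3_000

#: most extreme breakpoint pair observed for the duplicated locus, used when a
#: sample has no called breakpoints of its own (1-based half-open).
FALLBACK_INTERVAL = (30_363_708, 30_394_114)


@dataclass
class CoverageProfile:
    """Per-base read depth over a contiguous span.

    ``start`` is the 1-based position of ``depth[0]``; base i (1-based
    position ``start + i``) has depth ``depth[i]``.
    """

    chrom: str
    depth: np.ndarray
    start: int = 1

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        """1-based half-open end of the covered span."""
        return self.start + len(self.depth)

    def slice_mean(self, lo: int, hi: int) -> float:
        """Mean depth over 1-based half-open [lo, hi)."""
        if lo < self.start or hi > self.end:
            raise ValueError(f"[{lo}, {hi}) outside covered span [{self.start}, {self.end})")
        return float(self.depth[lo - self.start : hi - self.start].mean())


@dataclass
class CNEstimate:
    window_ratios: list[tuple[int, int, float]]
    median_ratio: float
    integer_cn: int
    flank_mean: float


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def normalized_coverage(
    profile: CoverageProfile,
    interval: tuple[int, int],
    window: int = DEFAULT_CN_WINDOW,
    step: int = DEFAULT_CN_STEP,
    flank: int = DEFAULT_CN_FLANK,
) -> CNEstimate:
    """Window/flank-normalized depth ratios over ``interval`` (1-based half-open).

    Each in-interval window's mean depth is divided by the flank mean: the
    unweighted average of the mean depths of the ``flank``-bp regions
    immediately upstream of ``interval[0]`` and downstream of ``interval[1]``.
    Windows are anchored at the interval start and advanced by ``step``; a
    terminal partial window shorter than ``window / 2`` is dropped.
    ``integer_cn`` is the half-up rounding of the median ratio, clamped to >= 1.
    """
    start, end = int(interval[0]), int(interval[1])
    if end - start < window:
        raise ValueError("interval shorter than one window")
    if start - flank < profile.start or end + flank > profile.end:
        raise ValueError("flank regions fall outside the coverage profile")

    up = profile.slice_mean(start - flank, start)
    down = profile.slice_mean(end, end + flank)
    flank_mean = 0.5 * (up + down)
    if flank_mean == 0:
        raise ValueError("uninformative flanks: flank mean depth is zero")

    ratios: list[tuple[int, int, float]] = []
    s = start
    while s < end:
        e = min(s + window, end)
        if e - s < window / 2:
            break
        ratios.append((s, e, profile.slice_mean(s, e) / flank_mean))
        s += step
    med = float(np.median([r for _, _, r in ratios]))
    return CNEstimate(
        window_ratios=ratios,
        median_ratio=med,
        integer_cn=max(1, _round_half_up(med)),
        flank_mean=flank_mean,
    )


def default_interval(override: tuple[int, int] | None = None) -> tuple[int, int]:
    """Fallback breakpoint interval used when no breakpoints are supplied."""
    if override is None:
        return FALLBACK_INTERVAL
    start, end = int(override[0]), int(override[1])
    if start >= end:
        raise ValueError("interval start must be < end")
    return (start, end)


@dataclass
class JunctionCall:
    mechanism: str  # "microhomology" | "templated" | "blunt"
    signature: str  # homology or insert string ("" for blunt)
    length: int
    breakpoints: tuple[int, int]  # 1-based (last base of left segment, first of right)

    def __post_init__(self) -> None:
        if self.length != len(self.signature):
            raise ValueError("length must equal len(signature)")
        if self.mechanism == "blunt" and self.length != 0:
            raise ValueError("blunt junction must have empty signature")


def _lcs_len(a: str, b: str) -> int:
    """Length of the longest common prefix of two strings."""
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _homology_at(reference: str, left_end: int, right_start: int) -> tuple[int, int]:
    """Breakpoint ambiguity (down-shift i, up-shift j) for adjacency left_end -> right_start.

    ``i`` is the largest k with ref[left_end-k:left_end] == ref[right_start-k:right_start]
    (the breakpoint pair can slide k bases left), ``j`` the largest k with
    ref[left_end:left_end+k] == ref[right_start:right_start+k] (slide right).
    """
    e, s = left_end, right_start
    i = 0
    while i < min(e, s) and reference[e - i - 1] == reference[s - i - 1]:
        i += 1
    j = _lcs_len(reference[e:], reference[s:])
    return i, j


def classify_junction(
    reference: str,
    left_end: int,
    right_start: int,
    observed_junction: str,
    max_probe: int = 25,
    template_search: int = 50,
) -> JunctionCall:
    """Classify the repair mechanism of a novel adjacency.

    ``left_end``/``right_start`` are 0-based half-open reference coordinates:
    the derived sequence joins ``reference[:left_end]`` to
    ``reference[right_start:]`` (for a tandem duplication of ``[s, e)``,
    ``left_end = e`` and ``right_start = s``). ``observed_junction`` must span
    the adjacency with at least ``max_probe`` bases of context on each side.

    Decision order: (i) any inserted bases absent from both breakpoint
    contexts are extracted by aligning the observed junction to the expected
    one; if an exact copy of the insert occurs within ``template_search`` bp
    of either breakpoint the call is ``templated``; an insert with no nearby
    template is unalignable. (ii) Otherwise the maximal exact string shared
    by the two joined ends (the breakpoint-ambiguity string) is computed from
    the reference: non-empty gives ``microhomology``, empty gives ``blunt``.
    """
    n = len(reference)
    if not (0 < left_end <= n and 0 <= right_start < n):
        raise ValueError("breakpoints outside reference")
    obs = observed_junction.upper()
    ref = reference.upper()

    # maximal prefix of obs matching a block ending at left_end, and maximal
    # suffix matching a block starting at right_start
    cl = 0
    for c in range(min(len(obs), left_end), -1, -1):
        if obs[:c] == ref[left_end - c : left_end]:
            cl = c
            break
    cr = 0
    for c in range(min(len(obs), n - right_start), -1, -1):
        if c == 0 or obs[len(obs) - c :] == ref[right_start : right_start + c]:
            cr = c
            break
    if cl < max_probe or cr < max_probe:
        raise ValueError("unalignable junction: insufficient matching context")

    insert = obs[cl : len(obs) - cr] if cl + cr < len(obs) else ""
    bkpts = (left_end, right_start + 1)  # 1-based annotation

    if insert:
        lo_l = max(0, left_end - template_search - len(insert))
        hi_l = min(n, left_end + template_search + len(insert))
        lo_r = max(0, right_start - template_search - len(insert))
        hi_r = min(n, right_start + template_search + len(insert))
        if insert in ref[lo_l:hi_l] or insert in ref[lo_r:hi_r]:
            return JunctionCall("templated", insert, len(insert), bkpts)
        raise ValueError("unalignable junction: inserted sequence has no nearby template")

    i, j = _homology_at(ref, left_end, right_start)
    if i + j > 0:
        sig = ref[left_end - i : left_end + j]
        return JunctionCall("microhomology", sig, i + j, bkpts)
    return JunctionCall("blunt", "", 0, bkpts)
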