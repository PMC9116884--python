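"""Population-genetic utilities: frequency spectra, sweep scan, selection fitting.

The sweep scan follows the composite-likelihood construction of classic
sweep-detection methods: the genome-wide (background) site frequency
spectrum plays the role of the neutral model, and near a sweep each sampled
lineage independently escapes the sweeping haplotype by recombination with
probability ``P_e = 1 - exp(-alpha * d)``, where ``alpha`` is the per-bp
sweep intensity and ``d`` the distance to the putative sweep site. Escaped
lineages sample the background spectrum; the non-escaped lineages coalesce
into a single ancestor. The composite likelihood ratio (CLR) compares the
maximized sweep model against the background at each point of a genomic grid.

Selection-coefficient estimation inverts the deterministic diploid
Wright-Fisher recursion: given a start and end frequency, the elapsed
generations and the dominance coefficient, bisection on ``s`` exploits the
monotonicity of the final frequency in ``s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpectrumSet",
    "BackgroundSpectrum",
    "CLRTrack",
    "TrajectoryFit",
    "wright_fisher_deterministic",
    "folded_jsfs",
    "sfs_from_counts",
    "watterson_theta",
    "sweep_spectrum",
    "clr_scan",
    "clr_regions",
    "estimate_s",
    "estimate_s_epochs",
    "corrected_mutation_rate",
    "scale_genetic_map",
    "BASE_MUTATION_RATE",
    "DADI_MUTATION_RATE",
    "DEFAULT_GRID_BP",
    "DEFAULT_SUBSAMPLE_FRACTION",
]

#: per-site per-generation spontaneous mutation rate used for the
#: missing-data correction of genealogy-based dating
BASE_MUTATION_RATE = 7e-9
#: mutation rate used for demographic (JSFS) model fitting; kept as a
#: separate named constant, never silently interchanged with the above
DADI_MUTATION_RATE = 7.1e-9

DEFAULT_GRID_BP = 100_000
DEFAULT_SUBSAMPLE_FRACTION = 0.9
DEFAULT_OUTCROSSING_RATE = 0.05


# ---------------------------------------------------------------------------
# Wright-Fisher recursion (deterministic core; the stochastic simulator in
# the synthetic-data module resamples around this recursion)
# ---------------------------------------------------------------------------

def wright_fisher_step(p: float, s: float, h: float) -> float:
    """One generation of the deterministic diploid selection recursion.

    Genotype fitnesses are ``1 + s`` (AA), ``1 + h*s`` (Aa), ``1`` (aa):
    ``p' = [p^2 (1+s) + p q (1+hs)] / w_bar``.
    """
    q = 1.0 - p
    w_aa = p * p * (1.0 + s)
    w_het = p * q * (1.0 + h * s)
    wbar = w_aa + 2.0 * w_het + q * q
    return (w_aa + w_het) / wbar


def wright_fisher_deterministic(
    p0: float, s: float, h: float, generations: int
) -> np.ndarray:
    """Deterministic allele-frequency trajectory, length ``generations + 1``."""
    traj = np.empty(generations + 1)
    traj[0] = p = float(p0)
    for t in range(1, generations + 1):
        p = wright_fisher_step(p, s, h)
        traj[t] = p
    return traj


# ---------------------------------------------------------------------------
# Frequency spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSet:
    """Folded or polarized 1-D SFS and/or folded 2-D JSFS with sample sizes."""

    sfs: np.ndarray | None = None
    jsfs: np.ndarray | None = None
    n1: int = 0
    n2: int = 0
    polarized: bool = False

    def __post_init__(self) -> None:
        if self.sfs is not None:
            self.sfs = np.asarray(self.sfs)
            if (self.sfs < 0).any():
                raise ValueError("spectrum counts must be non-negative")
        if self.jsfs is not None:
            self.jsfs = np.asarray(self.jsfs)
            if (self.jsfs < 0).any():
                raise ValueError("spectrum counts must be non-negative")


def sfs_from_counts(
    derived: np.ndarray, n: int, polarized: bool = True
) -> SpectrumSet:
    """1-D SFS from per-site derived (or alt) allele counts in a sample of n haploids.

    With ``polarized=False`` the spectrum is folded onto minor-allele counts
    0..n//2.
    """
    derived = np.asarray(derived, dtype=np.int64)
    if ((derived < 0) | (derived > n)).any():
        raise ValueError("derived counts must lie in [0, n]")
    if polarized:
        return SpectrumSet(sfs=np.bincount(derived, minlength=n + 1), n1=n, polarized=True)
    minor = np.minimum(derived, n - derived)
    return SpectrumSet(sfs=np.bincount(minor, minlength=n // 2 + 1), n1=n, polarized=False)


def folded_jsfs(
    geno1: np.ndarray,
    geno2: np.ndarray,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int | None = None,
    site_mask: np.ndarray | None = None,
) -> SpectrumSet:
    """Folded joint SFS from two haploid allele matrices (sites x haploids).

    Alleles are coded 0/1 with negative values meaning missing. Per site and
    per sample, ``ceil(subsample_fraction * n)`` haploids with a non-missing
    call are drawn at random; sites where either sample cannot supply that
    many calls are skipped, as are monomorphic sites (no minor allele in the
    joint subsample). ``site_mask`` marks sites to exclude (True = excluded);
    build it from BED interval tables with :func:`adaptscan.io.mask_from_bed`.

    Folding is joint: a configuration ``(c1, c2)`` with total count above
    half the joint subsample size is mapped to ``(m1 - c1, m2 - c2)``; exact
    ties are mapped to the lexicographically smaller of the two, which makes
    the spectrum invariant to a global ref/alt relabeling.
    """
    geno1 = np.asarray(geno1)
    geno2 = np.asarray(geno2)
    if geno1.shape[0] != geno2.shape[0]:
        raise ValueError("both samples must cover the same site set")
    rng = np.random.default_rng(seed)
    n1, n2 = geno1.shape[1], geno2.shape[1]
    m1 = math.ceil(subsample_fraction * n1)
    m2 = math.ceil(subsample_fraction * n2)
    jsfs = np.zeros((m1 + 1, m2 + 1), dtype=np.int64)
    total = m1 + m2
    for i in range(geno1.shape[0]):
        if site_mask is not None and site_mask[i]:
            continue
        ok1 = np.flatnonzero(geno1[i] >= 0)
        ok2 = np.flatnonzero(geno2[i] >= 0)
        if len(ok1) < m1 or len(ok2) < m2:
            continue
        pick1 = rng.choice(ok1, size=m1, replace=False)
        pick2 = rng.choice(ok2, size=m2, replace=False)
        c1 = int(geno1[i][pick1].sum())
        c2 = int(geno2[i][pick2].sum())
        t = c1 + c2
        if t == 0 or t == total:
            continue  # monomorphic in the joint subsample
        if 2 * t > total or (2 * t == total and (m1 - c1, m2 - c2) < (c1, c2)):
            c1, c2 = m1 - c1, m2 - c2
        jsfs[c1, c2] += 1
    if jsfs.sum() == 0:
        raise ValueError("no polymorphic sites after filtering")
    return SpectrumSet(jsfs=jsfs, n1=m1, n2=m2, polarized=False)


def watterson_theta(S: int, n: int, L: int) -> float:
    """Per-site Watterson estimator ``S / (L * sum_{i=1}^{n-1} 1/i)``."""
    if n < 2 or L < 1 or S < 0:
        raise ValueError("need n >= 2, L >= 1, S >= 0")
    a1 = sum(1.0 / i for i in range(1, n))
    return S / (L * a1)


# ---------------------------------------------------------------------------
# Sweep model and CLR scan
# ---------------------------------------------------------------------------

@dataclass
class BackgroundSpectrum:
    """Background probabilities over polymorphic derived-count classes 1..n-1."""

    probs: np.ndarray  # length n + 1; entries 0 and n are zero
    n: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != self.n + 1:
            raise ValueError("probs must have length n + 1")
        if self.probs[0] != 0 or self.probs[self.n] != 0:
            raise ValueError("background spectrum covers polymorphic classes only")
        if not math.isclose(self.probs.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("background probabilities must sum to 1")

    @classmethod
    def from_polymorphic(cls, p: np.ndarray) -> "BackgroundSpectrum":
        """From probabilities over classes 1..n-1 (length n - 1)."""
        p = np.asarray(p, dtype=float)
        full = np.zeros(len(p) + 2)
        full[1:-1] = p / p.sum()
        return cls(full, len(p) + 1)

    @classmethod
    def from_counts(cls, derived: np.ndarray, n: int) -> "BackgroundSpectrum":
        sfs = np.bincount(np.asarray(derived, dtype=np.int64), minlength=n + 1).astype(float)
        sfs[0] = sfs[n] = 0.0
        if sfs.sum() == 0:
            raise ValueError("no polymorphic sites")
        return cls(sfs / sfs.sum(), n)


def _downsample_matrix(bg: BackgroundSpectrum, m_max: int) -> list[np.ndarray]:
    """q[m][j]: background hypergeometrically downsampled to sample size m.

    ``q[m]`` has length m + 1; q[m][j] = sum_J p_J * Hypergeom(j; n, J, m).
    """
    n = bg.n
    qs: list[np.ndarray] = [np.zeros(1)]  # placeholder for m = 0
    Js = np.arange(n + 1)
    for m in range(1, m_max + 1):
        js = np.arange(m + 1)
        # pmf matrix: rows j, cols J
        pmf = stats.hypergeom.pmf(js[:, None], n, Js[None, :], m)
        qs.append(pmf @ bg.probs)
    return qs


def _sweep_mixing_matrix(bg: BackgroundSpectrum, n: int) -> np.ndarray:
    """M[e, b] = P(derived count b | e lineages escaped) for e = 0..n.

    For e < n the n - e swept lineages descend from one ancestor; the
    pre-sweep sample holds e + 1 lineages drawn from the (downsampled)
    background, of which j are derived. The sweeping ancestor is one of the
    e + 1 uniformly: if derived (prob j / (e+1)) all swept copies are
    derived, b = (n - e) + (j - 1); else b = j. With e = n no lineage was
    swept and the sample is a size-n draw from the background.
    """
    q = _downsample_matrix(bg, min(n + 1, bg.n))
    M = np.zeros((n + 1, n + 1))
    for e in range(n):
        m = e + 1
        qm = q[m]
        for j in range(m + 1):
            if qm[j] == 0:
                continue
            if j >= 1:
                b_swept = j - 1 + (n - e)
                M[e, b_swept] += qm[j] * (j / m)
            M[e, j] += qm[j] * ((m - j) / m)
    if n <= bg.n:
        M[n, : n + 1] = q[n]
    else:
        raise ValueError("sample size n exceeds background spectrum size")
    return M


def sweep_spectrum(
    bg: BackgroundSpectrum,
    alpha: float,
    d: float,
    n: int,
    condition_polymorphic: bool = False,
) -> np.ndarray:
    """Probability vector over derived counts 0..n under the sweep model.

    ``alpha`` is the per-bp sweep intensity and ``d`` the distance to the
    sweep site; each lineage escapes with ``P_e = 1 - exp(-alpha * d)``.
    ``alpha = inf`` (or ``alpha * d`` large) recovers the background model;
    ``alpha * d = 0`` puts all mass on the fixed classes (star-like sweep).
    With ``condition_polymorphic`` the vector is renormalized over classes
    1..n-1.
    """
    if alpha < 0 or d < 0:
        raise ValueError("alpha and d must be non-negative")
    p_esc = 1.0 if math.isinf(alpha) else -math.expm1(-alpha * d)
    M = _sweep_mixing_matrix(bg, n)
    w = stats.binom.pmf(np.arange(n + 1), n, p_esc)
    probs = w @ M
    if condition_polymorphic:
        mass = probs[1:n].sum()
        if mass == 0:
            raise ValueError("no polymorphic mass to condition on")
        probs = probs / mass
        probs[0] = probs[n] = 0.0
    return probs


@dataclass
class CLRTrack:
    grid: np.ndarray  # grid positions (bp)
    clr: np.ndarray
    alpha: np.ndarray  # maximizing alpha per grid point (inf = background limit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos": self.grid, "clr": self.clr, "alpha": self.alpha})


def _default_alpha_grid() -> np.ndarray:
    return np.logspace(-8, -2, 25)


def clr_scan(
    positions: np.ndarray,
    derived: np.ndarray,
    n: int,
    bg: BackgroundSpectrum,
    grid_bp: int = DEFAULT_GRID_BP,
    alpha_grid: np.ndarray | None = None,
    refine: bool = True,
) -> CLRTrack:
    """Composite-likelihood-ratio sweep scan on a regular genomic grid.

    At each grid point x, ``CLR(x) = 2 [max_alpha sum_i log P_sweep(b_i;
    alpha, |pos_i - x|) - sum_i log p_bg(b_i)]``, with the sweep model
    conditioned on polymorphism (the background holds polymorphic classes
    only). The maximization is over ``alpha_grid`` plus the background limit
    ``alpha = inf``, so CLR >= 0 by construction; a golden-section pass in
    log-alpha refines around the best grid value. All sites on the scanned
    stretch contribute at every grid point, with the sweep effect decaying
    with distance. The grid is anchored at the first site, which makes the
    scan translation-equivariant.
    """
    positions = np.asarray(positions, dtype=np.int64)
    derived = np.asarray(derived, dtype=np.int64)
    if len(positions) == 0:
        raise ValueError("no sites")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    if alpha_grid is None:
        alpha_grid = _default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if len(alpha_grid) == 0:
        raise ValueError("alpha_grid must be nonempty")

    p_bg = bg.probs[derived]
    if np.any(p_bg == 0):
        raise ValueError("background spectrum incomplete: observed class with zero probability")
    bg_loglik = float(np.log(p_bg).sum())

    M = _sweep_mixing_matrix(bg, n)
    e_classes = np.arange(n + 1)

    def sweep_loglik(x: float, alpha: float) -> float:
        d = np.abs(positions - x)
        p_esc = -np.expm1(-alpha * d)
        W = stats.binom.pmf(e_classes[None, :], n, p_esc[:, None])
        probs = W @ M  # sites x (n + 1)
        poly_mass = 1.0 - probs[:, 0] - probs[:, n]
        site_p = probs[np.arange(len(derived)), derived]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.log(site_p) - np.log(poly_mass)
        if not np.all(np.isfinite(ll)):
            return -np.inf
        return float(ll.sum())

    grid = np.arange(positions[0], positions[-1] + 1, grid_bp, dtype=np.int64)
    clr = np.empty(len(grid))
    best_alpha = np.empty(len(grid))
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    for k, x in enumerate(grid):
        lls = np.array([sweep_loglik(x, a) for a in alpha_grid])
        i_best = int(np.argmax(lls))
        ll_best, a_best = lls[i_best], alpha_grid[i_best]
        if refine and 0 < i_best < len(alpha_grid) - 1 and np.isfinite(ll_best):
            lo = math.log(alpha_grid[i_best - 1])
            hi = math.log(alpha_grid[i_best + 1])
            a, b = lo, hi
            c1 = b - phi * (b - a)
            c2 = a + phi * (b - a)
            f1 = sweep_loglik(x, math.exp(c1))
            f2 = sweep_loglik(x, math.exp(c2))
            for _ in range(20):
                if f1 < f2:
                    a, c1, f1 = c1, c2, f2
                    c2 = a + phi * (b - a)
                    f2 = sweep_loglik(x, math.exp(c2))
                else:
                    b, c2, f2 = c2, c1, f1
                    c1 = b - phi * (b - a)
                    f1 = sweep_loglik(x, math.exp(c1))
            ll_ref = max(f1, f2)
            if ll_ref > ll_best:
                ll_best = ll_ref
                a_best = math.exp(c1 if f1 >= f2 else c2)
        # background limit (all lineages escape): sweep model == background
        if bg_loglik >= ll_best:
            clr[k] = 0.0
            best_alpha[k] = math.inf
        else:
            clr[k] = 2.0 * (ll_best - bg_loglik)
            best_alpha[k] = a_best
    return CLRTrack(grid=grid, clr=clr, alpha=best_alpha)


def clr_regions(track: CLRTrack, percentile: float = 99.0, grid_bp: int | None = None) -> pd.DataFrame:
    """Merge contiguous grid points above the given CLR percentile into regions.

    Returns one row per region (chrom-less: the track covers one stretch)
    with the spanned coordinates and the peak CLR inside.
    """
    thr = float(np.percentile(track.clr, percentile))
    above = track.clr > thr
    if grid_bp is None:
        grid_bp = int(np.diff(track.grid).min()) if len(track.grid) > 1 else DEFAULT_GRID_BP
    rows = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            rows.append(
                (
                    int(track.grid[i]),
                    int(track.grid[j]) + grid_bp,
                    float(track.clr[seg].max()),
                    int(track.grid[seg][np.argmax(track.clr[seg])]),
                )
            )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(rows, columns=["start", "end", "peak_clr", "peak_pos"])


# ---------------------------------------------------------------------------
# Selection-coefficient estimation
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFit:
    s_hat: float
    h: float
    N: int | None
    generations: int
    bracket: tuple[float, float]
    converged: bool


def estimate_s(
    p0: float,
    pT: float,
    generations: int,
    h: float,
    tol: float = 1e-6,
    s_max: float = 10.0,
) -> TrajectoryFit:
    """Selection coefficient whose deterministic trajectory links p0 to pT.

    Bisection on ``s >= 0`` using the monotonicity of the final frequency of
    the deterministic diploid recursion in ``s``. Generation time is the
    caller's unit (1 year when converting from calendar spans).
    """
    if not (0.0 < p0 < 1.0 and 0.0 < pT < 1.0):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    if pT <= p0:
        raise ValueError("no positive-selection solution: pT must exceed p0")
    if generations < 1:
        raise ValueError("generations must be >= 1")

    def final(s: float) -> float:
        return wright_fisher_deterministic(p0, s, h, generations)[-1]

    lo, hi = 0.0, 0.01
    while final(hi) < pT:
        hi *= 2.0
        if hi > s_max:
            raise ValueError(f"target frequency unreachable with s <= {s_max}")
    converged = False
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if final(mid) < pT:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            converged = True
            break
    s_hat = 0.5 * (lo + hi)
    return TrajectoryFit(s_hat=s_hat, h=h, N=None, generations=generations,
                         bracket=(lo, hi), converged=converged)


def estimate_s_epochs(
    freq_points: list[tuple[int, float]],
    h: float,
    tol: float = 1e-6,
) -> list[TrajectoryFit]:
    """Piecewise-constant selection coefficients over user-supplied epochs.

    ``freq_points`` is a list of (generation, frequency) knots in increasing
    generation order; one fit is returned per adjacent pair.
    """
    if len(freq_points) < 2:
        raise ValueError("need at least two (generation, frequency) points")
    fits = []
    for (g0, f0), (g1, f1) in zip(freq_points[:-1], freq_points[1:]):
        if g1 <= g0:
            raise ValueError("generations must increase along epochs")
        fits.append(estimate_s(f0, f1, g1 - g0, h, tol=tol))
    return fits


# ---------------------------------------------------------------------------
# Rate and map corrections
# ---------------------------------------------------------------------------

def corrected_mutation_rate(missing: int, total: int, base_rate: float = BASE_MUTATION_RATE) -> float:
    """Missing-data-corrected mutation rate ``base_rate * (1 - missing / total)``."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= missing <= total):
        raise ValueError("need 0 <= missing <= total")
    return base_rate * (1.0 - missing / total)


def scale_genetic_map(
    genetic_map: pd.DataFrame,
    outcrossing_rate: float = DEFAULT_OUTCROSSING_RATE,
    position_col: str = "position",
    cm_col: str = "cM",
) -> pd.DataFrame:
    """Rescale crossover-based genetic distances for partial selfing.

    In a predominantly selfing population only the outcrossed fraction of
    matings realizes crossovers, so genetic distances are divided by
    ``1 / outcrossing_rate`` (20 at 5% outcrossing). Physical positions are
    unchanged; the input map must be monotone non-decreasing in both columns.
    """
    if not (0.0 < outcrossing_rate <= 1.0):
        raise ValueError("outcrossing_rate must lie in (0, 1]")
    pos = genetic_map[position_col].to_numpy()
    cm = genetic_map[cm_col].to_numpy(dtype=float)
    if np.any(np.diff(pos) < 0) or np.any(np.diff(cm) < 0):
        raise ValueError("genetic map must be monotone non-decreasing")
    out = genetic_map.copy()
    out[cm_col] = cm * outcrossing_rate
    return out
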