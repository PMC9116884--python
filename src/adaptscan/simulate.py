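"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure the downstream analyses
assume, so the whole repository builds and tests without any download:

* an F2 cross segregating a two-locus recessive-epistasis phenotype
  (roughly 1 in 16 individuals affected), with Haldane-map recombination
  within chromosomes and independent assortment across chromosomes;
* pooled short-read allele counts over a marker map (Poisson depth,
  binomial allele sampling with a symmetric error rate);
* Poisson per-base read depth over a region carrying a tandem duplication
  of known copy number and zygosity;
* derived duplication sequences with a controlled junction mechanism
  (microhomology, templated insertion, or blunt);
* Wright-Fisher allele-frequency trajectories under selection and
  dominance, deterministic or binomially resampled;
* two-population neutral split samples feeding the folded joint SFS.

Every stochastic operation takes an explicit seed; there is no global
random state, and outputs are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bsa import PoolCounts
from .cnv import CoverageProfile, JunctionCall
from .popgen import wright_fisher_deterministic, wright_fisher_step

__all__ = [
    "CrossConfig",
    "F2Cohort",
    "CoverageSimSpec",
    "JunctionSpec",
    "Microhomology",
    "Templated",
    "Blunt",
    "DuplicationResult",
    "WFParams",
    "Trajectory",
    "SplitSimConfig",
    "simulate_f2_cross",
    "select_extreme_pool",
    "simulate_pool_reads",
    "simulate_coverage",
    "make_duplication_junction",
    "simulate_wright_fisher",
    "conditioned_sweep_trajectory",
    "simulate_split_sample",
    "default_marker_map",
    "affected_threshold",
]

#: greenness-like phenotype means: healthy classes vs the doubly homozygous
#: affected class (chlorotic), on a green/red ratio scale
DEFAULT_HEALTHY_MEAN = 1.0
DEFAULT_AFFECTED_MEAN = 0.4
DEFAULT_NOISE_SD = 0.05
#: crossover density used when no explicit map distances are given
DEFAULT_CM_PER_MB = 4.0

_BASES = np.array(list("ACGT"))


@dataclass
class CrossConfig:
    """Configuration of a two-locus recessive-epistasis F2 cross.

    Parent A is the reference-genome parent; dosage counts parent-A alleles.
    An individual is affected when homozygous for the island (parent-B)
    allele at ``locus_a`` AND homozygous for the reference (parent-A) allele
    at ``locus_b`` - under independent assortment 1/16 of F2s.

    ``phenotype_means`` maps each of the nine (dosage_a, dosage_b) classes to
    a mean greenness; by default only the affected class is lowered.
    ``map_distances`` optionally gives centimorgans per adjacent marker pair
    (per chromosome); when absent, distances follow ``cm_per_mb`` within a
    chromosome, and chromosomes assort independently.
    """

    n_individuals: int
    locus_a: tuple[str, int]
    locus_b: tuple[str, int]
    marker_map: list[tuple[str, int]]
    map_distances: dict[str, np.ndarray] | None = None
    cm_per_mb: float = DEFAULT_CM_PER_MB
    phenotype_means: dict[tuple[int, int], float] | None = None
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.phenotype_means is None:
            self.phenotype_means = {
                (da, db): (DEFAULT_AFFECTED_MEAN if (da == 0 and db == 2) else DEFAULT_HEALTHY_MEAN)
                for da in (0, 1, 2)
                for db in (0, 1, 2)
            }


@dataclass
class F2Cohort:
    """Simulated F2 individuals: dosage of the parent-A allele at each marker."""

    genotypes: np.ndarray  # (n_individuals, n_markers) int8 in {0, 1, 2}
    phenotype: np.ndarray
    affected: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    locus_a_index: int
    locus_b_index: int


def default_marker_map(
    n_chromosomes: int = 5,
    chrom_length: int = 10_000_000,
    markers_per_chrom: int = 2_000,
) -> list[tuple[str, int]]:
    """Evenly spaced marker map over equally long chromosomes named '1'..'k'."""
    spacing = chrom_length // markers_per_chrom
    return [
        (str(c + 1), (i + 1) * spacing)
        for c in range(n_chromosomes)
        for i in range(markers_per_chrom)
    ]


def affected_threshold(config: CrossConfig) -> float:
    """Midpoint between the affected-class and healthy-class phenotype means."""
    means = config.phenotype_means
    affected = means[(0, 2)]
    healthy = [v for k, v in means.items() if k != (0, 2)]
    return 0.5 * (affected + float(np.mean(healthy)))


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction from map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _simulate_gametes(
    rng: np.random.Generator,
    n_gametes: int,
    r: np.ndarray,
) -> np.ndarray:
    """Gamete haplotypes along one chromosome: 1 = parent-A allele.

    ``r`` holds recombination fractions between adjacent markers. The first
    marker allele is a fair coin per gamete; crossover indicators flip the
    phase along the chromosome (parity of the cumulative crossover count).
    """
    m = len(r) + 1
    start = rng.integers(0, 2, size=(n_gametes, 1), dtype=np.int8)
    if m == 1:
        return start
    cross = rng.random((n_gametes, m - 1)) < r[None, :]
    parity = np.cumsum(cross, axis=1, dtype=np.int64) & 1
    hap = np.empty((n_gametes, m), dtype=np.int8)
    hap[:, :1] = start
    hap[:, 1:] = start ^ parity.astype(np.int8)
    return hap


def simulate_f2_cross(config: CrossConfig) -> F2Cohort:
    """Simulate an F2 cohort under the two-locus recessive-epistasis model."""
    chroms = np.array([c for c, _ in config.marker_map])
    positions = np.array([p for _, p in config.marker_map], dtype=np.int64)
    for name, locus in (("locus_a", config.locus_a), ("locus_b", config.locus_b)):
        if not np.any((chroms == locus[0]) & (positions == locus[1])):
            raise ValueError(f"{name} {locus} absent from marker_map")
    idx_a = int(np.flatnonzero((chroms == config.locus_a[0]) & (positions == config.locus_a[1]))[0])
    idx_b = int(np.flatnonzero((chroms == config.locus_b[0]) & (positions == config.locus_b[1]))[0])

    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    genotypes = np.empty((n, len(positions)), dtype=np.int8)
    for chrom in dict.fromkeys(chroms):  # preserve map order
        sel = np.flatnonzero(chroms == chrom)
        pos_c = positions[sel]
        order = np.argsort(pos_c, kind="stable")
        sel = sel[order]
        pos_c = pos_c[order]
        if config.map_distances is not None and chrom in config.map_distances:
            d_cm = np.asarray(config.map_distances[chrom], dtype=float)
            if len(d_cm) != len(pos_c) - 1:
                raise ValueError(f"map_distances for chromosome {chrom} must have one entry per adjacent pair")
        else:
            d_cm = np.diff(pos_c) / 1e6 * config.cm_per_mb
        r = _haldane_r(d_cm)
        hap1 = _simulate_gametes(rng, n, r)
        hap2 = _simulate_gametes(rng, n, r)
        genotypes[:, sel] = hap1 + hap2

    affected = (genotypes[:, idx_a] == 0) & (genotypes[:, idx_b] == 2)
    means = np.array(
        [config.phenotype_means[(da, db)] for da in (0, 1, 2) for db in (0, 1, 2)]
    ).reshape(3, 3)
    phenotype = means[genotypes[:, idx_a], genotypes[:, idx_b]]
    if config.noise_sd > 0:
        phenotype = phenotype + rng.normal(0.0, config.noise_sd, size=n)
    else:
        phenotype = phenotype.astype(float).copy()
    return F2Cohort(
        genotypes=genotypes,
        phenotype=phenotype,
        affected=affected,
        chroms=chroms,
        positions=positions,
        locus_a_index=idx_a,
        locus_b_index=idx_b,
    )


def select_extreme_pool(phenotype: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest phenotype values; ties broken by lowest index."""
    phenotype = np.asarray(phenotype, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(phenotype):
        raise ValueError("k exceeds the number of individuals")
    order = np.argsort(phenotype, kind="stable")
    return np.sort(order[:k])


def simulate_pool_reads(
    cohort: F2Cohort,
    pool: np.ndarray,
    mean_depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
) -> PoolCounts:
    """Pooled sequencing of selected individuals: Poisson depth, binomial counts.

    Per marker, the pooled parent-A allele frequency f is the mean dosage / 2
    over the pool; reads support parent A with probability
    ``f (1 - error_rate) + (1 - f) error_rate``. Read pairing and mapping
    bias are ignored: the scan statistic only consumes allele counts.
    """
    pool = np.asarray(pool, dtype=np.int64)
    if len(pool) == 0:
        raise ValueError("pool must be nonempty")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    f = cohort.genotypes[pool].mean(axis=0) / 2.0
    f_star = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    depth = rng.poisson(mean_depth, size=len(f))
    count_a = rng.binomial(depth, f_star)
    return PoolCounts(
        chrom=cohort.chroms,
        pos=cohort.positions,
        count_a=count_a,
        count_b=depth - count_a,
    )


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------

@dataclass
class CoverageSimSpec:
    """Poisson read-depth simulation over a region with copy-number tracks.

    ``base_depth`` is the mean depth of a normal diploid region (two copies).
    ``cn_track`` lists half-open intervals (1-based [start, end)) with copies
    per haplotype; ``zygosity`` states whether both haplotypes carry the
    duplication. Expected depth is ``base_depth * c(pos) / 2`` where c is the
    total copy count over both haplotypes (homozygous k-copy: c = 2k inside;
    heterozygous: c = k + 1).
    """

    region_length: int
    base_depth: float
    cn_track: list[tuple[int, int, int]] = field(default_factory=list)
    zygosity: str = "homozygous"
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length <= 0 or self.base_depth <= 0:
            raise ValueError("region_length and base_depth must be positive")
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise ValueError("zygosity must be 'homozygous' or 'heterozygous'")
        for start, end, copies in self.cn_track:
            if not (1 <= start < end <= self.region_length + 1):
                raise ValueError("cn_track interval outside region")
            if copies < 1:
                raise ValueError("copies per haplotype must be >= 1")


def simulate_coverage(spec: CoverageSimSpec) -> CoverageProfile:
    """Per-base Poisson depth with copy-number steps from ``spec.cn_track``."""
    rng = np.random.default_rng(spec.seed)
    c = np.full(spec.region_length, 2.0)
    for start, end, copies in spec.cn_track:
        if spec.zygosity == "homozygous":
            c[start - 1 : end - 1] = 2.0 * copies
        else:
            c[start - 1 : end - 1] = copies + 1.0
    depth = rng.poisson(spec.base_depth * c / 2.0)
    return CoverageProfile(chrom=spec.chrom, depth=depth, start=1)


# ---------------------------------------------------------------------------
# Duplication junctions
# ---------------------------------------------------------------------------

@dataclass
class Microhomology:
    seq: str


@dataclass
class Templated:
    insert: str
    #: 0-based half-open source interval in the reference; when None the
    #: template is placed a fixed offset upstream of the duplication start
    source: tuple[int, int] | None = None


@dataclass
class Blunt:
    pass


@dataclass
class JunctionSpec:
    """A tandem duplication of ``duplicated_interval`` (0-based half-open)
    with a controlled junction mechanism.

    The generator may adjust reference bases around the breakpoints so that
    the requested signature is exactly realized (and not accidentally
    extended); the adjusted reference is returned alongside the derived
    sequence.
    """

    reference: str
    duplicated_interval: tuple[int, int]
    mechanism: Microhomology | Templated | Blunt = field(default_factory=Blunt)

    def __post_init__(self) -> None:
        s, e = self.duplicated_interval
        if not (0 <= s < e <= len(self.reference)):
            raise ValueError("duplicated_interval outside reference")


@dataclass
class DuplicationResult:
    reference: str  # possibly adjusted
    derived: str
    annotation: JunctionCall


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return rng.choice(choices)


def make_duplication_junction(spec: JunctionSpec, seed: int = 0) -> DuplicationResult:
    """Derived sequence carrying ``duplicated_interval`` in tandem.

    The derived sequence is ``ref[:e] + insert + ref[s:e] + ref[e:]`` (insert
    empty unless templated). For microhomology the homologous string is
    written immediately upstream of both breakpoints, so the breakpoint pair
    is ambiguous by exactly ``len(seq)`` bases; for blunt and templated the
    bases adjacent to the breakpoints are forced to differ, removing any
    accidental ambiguity. The annotation records the mechanism, signature
    and the 1-based junction breakpoints in reference coordinates.
    """
    rng = np.random.default_rng(seed)
    ref = list(spec.reference.upper())
    s, e = spec.duplicated_interval
    mech = spec.mechanism

    if isinstance(mech, Microhomology):
        h = mech.seq.upper()
        k = len(h)
        if k == 0:
            raise ValueError("microhomology string must be nonempty")
        if s - k - 1 < 0 or e - s <= k:
            raise ValueError("interval leaves no room to place the microhomology")
        ref[e - k : e] = list(h)
        ref[s - k : s] = list(h)
        # block accidental extension on either side
        if ref[s - k - 1] == ref[e - k - 1]:
            ref[s - k - 1] = _other_base(rng, ref[e - k - 1])
        if e < len(ref) and ref[s] == ref[e]:
            ref[s] = _other_base(rng, ref[e])
        insert = ""
        signature, length, mechanism = h, k, "microhomology"
    else:
        # blunt and templated junctions must carry zero breakpoint ambiguity
        if s >= 1 and ref[s - 1] == ref[e - 1]:
            ref[s - 1] = _other_base(rng, ref[e - 1])
        if e < len(ref) and ref[s] == ref[e]:
            ref[s] = _other_base(rng, ref[e])
        if isinstance(mech, Blunt):
            insert = ""
            signature, length, mechanism = "", 0, "blunt"
        elif isinstance(mech, Templated):
            insert = mech.insert.upper()
            if not insert:
                raise ValueError("templated insert must be nonempty")
            if mech.source is None:
                t1 = s - 20
                t0 = t1 - len(insert)
            else:
                t0, t1 = mech.source
                if t1 - t0 != len(insert):
                    raise ValueError("template source interval must match insert length")
            if t0 < 0 or t1 > len(ref):
                raise ValueError("template source outside reference")
            ref[t0:t1] = list(insert)
            signature, length, mechanism = insert, len(insert), "templated"
        else:
            raise TypeError(f"unknown mechanism {mech!r}")

    ref_str = "".join(ref)
    derived = ref_str[:e] + insert + ref_str[s:e] + ref_str[e:]
    annotation = JunctionCall(
        mechanism=mechanism,
        signature=signature,
        length=length,
        breakpoints=(e, s + 1),
    )
    return DuplicationResult(reference=ref_str, derived=derived, annotation=annotation)


# ---------------------------------------------------------------------------
# Wright-Fisher trajectories
# ---------------------------------------------------------------------------

@dataclass
class WFParams:
    """Diploid Wright-Fisher model with selection ``s`` and dominance ``h``
    (0 = recessive, 0.5 = additive), starting frequency ``p0``."""

    N: int
    s: float
    h: float
    p0: float
    generations: int
    mode: str = "deterministic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("h must lie in [0, 1]")
        if self.s <= -1.0:
            raise ValueError("s must exceed -1")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError("mode must be 'deterministic' or 'stochastic'")


@dataclass
class Trajectory:
    freq: np.ndarray  # length generations + 1, freq[0] = p0
    params: WFParams


def simulate_wright_fisher(params: WFParams) -> Trajectory:
    """Allele-frequency trajectory under the diploid selection recursion.

    Deterministic mode applies the recursion exactly; stochastic mode
    additionally resamples 2N gametes binomially each generation.
    """
    if params.mode == "deterministic":
        freq = wright_fisher_deterministic(params.p0, params.s, params.h, params.generations)
        return Trajectory(freq=freq, params=params)
    rng = np.random.default_rng(params.seed)
    freq = np.empty(params.generations + 1)
    freq[0] = p = params.p0
    two_n = 2 * params.N
    for t in range(1, params.generations + 1):
        p_exp = wright_fisher_step(p, params.s, params.h)
        p = rng.binomial(two_n, p_exp) / two_n
        freq[t] = p
    return Trajectory(freq=freq, params=params)


def conditioned_sweep_trajectory(
    N: int,
    s: float,
    h: float,
    seed: int = 0,
    p0: float | None = None,
    fixation: float = 0.99,
    max_generations: int = 100_000,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Stochastic selected trajectory conditioned on (near-)fixation.

    New mutations are usually lost by drift even under selection, so runs
    are retried (fresh seeds derived from ``seed``) until the allele reaches
    ``fixation``; the trajectory is truncated there. ``p0`` defaults to a
    single copy, 1 / (2N).
    """
    if p0 is None:
        p0 = 1.0 / (2 * N)
    root = np.random.SeedSequence(seed)
    for child in root.spawn(max_tries):
        rng = np.random.default_rng(child)
        p = p0
        freqs = [p]
        two_n = 2 * N
        for _ in range(max_generations):
            p = rng.binomial(two_n, wright_fisher_step(p, s, h)) / two_n
            freqs.append(p)
            if p >= fixation:
                return np.array(freqs)
            if p == 0.0:
                break
    raise RuntimeError("no trajectory reached fixation; increase max_tries or s")


# ---------------------------------------------------------------------------
# Two-population split sampler
# ---------------------------------------------------------------------------

@dataclass
class SplitSimConfig:
    """Neutral split model: an ancestral population of size ``N_anc`` splits
    into daughters of sizes ``N_1`` and ``N_2`` that drift independently for
    ``T_split`` generations; ``n_1``/``n_2`` haploids are then sampled.

    Per-site starting frequencies are drawn from a neutral-like 1/x density
    on (1/(2 N_anc), 1 - 1/(2 N_anc)); ``anc_generations`` of ancestral
    drift precede the split (0 by default).
    """

    N_anc: int
    N_1: int
    N_2: int
    T_split: int
    n_1: int
    n_2: int
    n_sites: int
    anc_generations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("N_anc", "N_1", "N_2", "n_1", "n_2", "n_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.T_split < 0 or self.anc_generations < 0:
            raise ValueError("generation counts must be non-negative")
        if self.n_1 > 2 * self.N_1 or self.n_2 > 2 * self.N_2:
            raise ValueError("sample sizes cannot exceed population sizes")


def _drift(rng: np.random.Generator, freqs: np.ndarray, two_n: int, generations: int) -> np.ndarray:
    for _ in range(generations):
        freqs = rng.binomial(two_n, freqs) / two_n
    return freqs


def simulate_split_sample(config: SplitSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Haploid 0/1 allele matrices (n_sites x n_k) for the two daughters."""
    rng = np.random.default_rng(config.seed)
    lo = 1.0 / (2 * config.N_anc)
    u = rng.random(config.n_sites)
    # inverse-CDF draw from density proportional to 1/x on (lo, 1 - lo)
    freqs = lo * np.exp(u * np.log((1 - lo) / lo))
    freqs = _drift(rng, freqs, 2 * config.N_anc, config.anc_generations)
    f1 = _drift(rng, freqs.copy(), 2 * config.N_1, config.T_split)
    f2 = _drift(rng, freqs.copy(), 2 * config.N_2, config.T_split)
    geno1 = (rng.random((config.n_sites, config.n_1)) < f1[:, None]).astype(np.int8)
    geno2 = (rng.random((config.n_sites, config.n_2)) < f2[:, None]).astype(np.int8)
    return geno1, geno2
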