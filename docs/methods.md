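# Methods

This note documents the models, defaults and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
design decisions taken where more than one convention was defensible.

## Synthetic data

### F2 cross (`simulate.simulate_f2_cross`)

The cross models two diploid parents, A (reference) and B (island), and
draws F2 gametes marker-by-marker along each chromosome. The first marker
allele of a gamete is a fair coin; phase then flips between adjacent
markers with the Haldane recombination fraction
`r = (1 − exp(−2d/100))/2` for map distance `d` cM (no crossover
interference — the simplest standard map function; nothing downstream is
sensitive to interference). Chromosomes assort independently. When no
explicit map distances are supplied, distances follow a uniform
**4 cM/Mb** (a realistic genome-average crossover density for a small
selfing crucifer genome; the BSA design only requires that 200-kb windows
be tightly linked while chromosome arms decorrelate, which any value in
the 3–5 cM/Mb range provides).

Dosage counts parent-A alleles; an individual is *affected* iff dosage 0 at
locus A and dosage 2 at locus B, i.e. recessive epistasis with expected
affected fraction 1/16. Phenotype is the class mean of the 9-cell genotype
table plus Gaussian noise: by default healthy classes share mean 1.0, the
affected class mean is 0.4, and the noise SD is 0.05 (a greenness-like
scale on which the two classes are ~12 SD apart, matching the visibly
bimodal phenotype the design assumes — extreme-pool selection is then
essentially equivalent to selecting true affecteds). The affected flag is
computed from the causal genotypes, not the phenotype; a threshold helper
(`affected_threshold`) gives the midpoint rule used when classifying from
phenotype alone.

### Pool sequencing (`simulate_pool_reads`)

Per marker: depth ~ Poisson(mean depth); parent-A read count ~
Binomial(depth, f*) with `f* = f(1−e) + (1−f)e`, where `f` is the pooled
parent-A dosage frequency and `e` a symmetric error rate. Read pairing,
mapping bias and indel noise are deliberately not modeled: the scan
statistic consumes only allele counts, so these would add realism without
changing what passing tests demonstrate.

### Coverage (`simulate_coverage`)

Per-base depth ~ Poisson(base_depth × c(pos)/2), where c is the summed copy
number over both haplotypes (homozygous k-copy duplication: c = 2k inside
the interval; heterozygous: c = k + 1; background c = 2). GC bias,
mappability dips and dispersed repeats are not modeled, so the estimator's
near-perfect recovery on synthetic data bounds only its sampling error,
not its robustness to alignment artifacts.

### Duplication junctions (`make_duplication_junction`)

The derived sequence is `ref[:e] + insert + ref[s:e] + ref[e:]` for a
duplicated interval [s, e). Mechanism control works by local edits to the
reference, which is returned alongside the derived sequence:

* **microhomology** `h` (length k): `h` is written immediately upstream of
  both breakpoints (`ref[s−k:s] = ref[e−k:e] = h`), which makes the
  breakpoint pair ambiguous by exactly k bases; the bases flanking the
  placed homology are forced to differ so the ambiguity cannot extend;
* **templated** inserts are written at the junction and their template
  copied into the reference 20 bp upstream of the duplication start (or at
  a caller-supplied source interval);
* **blunt**: the bases adjacent to the breakpoints are forced to differ,
  guaranteeing zero ambiguity.

One published junction string is printed in its source as a "10-bp"
templated insert but has nine letters; the generator uses strings as given
and records their true length.

### Wright–Fisher (`simulate_wright_fisher`, `conditioned_sweep_trajectory`)

Deterministic mode iterates the diploid selection recursion
`p' = [p²(1+s) + pq(1+hs)] / [p²(1+s) + 2pq(1+hs) + q²]`; stochastic mode
additionally resamples 2N gametes binomially. `conditioned_sweep_trajectory`
retries stochastic runs from a single copy until one reaches near-fixation
(0.99), because unconditioned new mutations are usually lost even under
selection; the trajectory is truncated at fixation. This is the generative
source for "sampled post-fixation" sweep data.

### Two-population split (`simulate_split_sample`)

Per-site ancestral frequencies are drawn from a density ∝ 1/x on
(1/2N, 1 − 1/2N) — the shape of the standing neutral frequency spectrum —
then drift binomially in the ancestral population (0 generations by
default) and independently in the two daughters for T_split generations;
haploid samples are Bernoulli draws from the final frequencies. There is no
recombination graph and no migration: the sampler exists to give the folded
joint SFS its qualitative behavior (diagonal concentration at T_split = 0,
growing off-diagonal mass with divergence), not to fit demographic models.

## Variant filtering (`variants`)

Cell-level thresholds are strict inequalities (GQ > 25, DP > 3), matching
the quoted filter expressions; failing cells become missing. Site removal:
any missing/failed designated parent (when parent calls are required),
missing fraction above 0 (default — no missing calls tolerated), or minor
allele frequency below 5%. MAF uses called dosages only (missing cells are
excluded from the denominator — standard practice; the alternative of
counting missing as reference would bias MAF downward). A site at exactly
MAF = 0.05 is retained ("below 5%" removes, strictly).

LD pruning removes a marker whose squared Pearson dosage correlation with
any retained earlier in-window marker exceeds 0.1, scanning windows of
50 kb left to right. The window advance step is interpreted as **10
markers** by default: the printed step of "10 bp" against a 50-kb window is
ambiguous between units, and a bp-unit step is also supported
(`step_unit="bp"`); neither claim is asserted as the original intent.
Zero-variance markers cannot enter a correlation and are retained.

## Bulk segregant scan (`bsa`)

Markers with pooled depth below 4 (coherent with DP > 3) are masked.
Windows are anchored at position 1 per chromosome and advanced by the
step; all starts with a full window inside the chromosome are emitted (a
chromosome shorter than one window yields a single spanning window), so a
1-Mb chromosome under 200-kb/5-kb settings yields exactly
⌊(10⁶ − 2·10⁵)/5·10³⌋ + 1 = 161 windows. The window statistic is the
median marker frequency with its population SD; empty windows carry NaN.
Peak calling operates on the window median — the plotted statistic — with
strict thresholds (> 0.99, < 0.01), merging overlapping or touching
qualifying windows into maximal regions. Candidate-variant annotation is an
input contract: callers may join a marker→effect table onto peak regions;
effect prediction itself is out of scope.

## Copy number and junctions (`cnv`)

Window ratios use mean depth within a window (across-window summary is the
median ratio — "mean within, median across"); windows live entirely inside
the breakpoint interval, anchored at its start, and a terminal partial
window shorter than half a window is dropped. The two 3-kb flanks are
averaged with equal weight regardless of their own depths (symmetric
normalization). Integer copy number is the half-up rounding of the median
ratio, clamped to ≥ 1 — the least-assumptive map from a continuous ratio to
the integer copy numbers reported in practice. When a sample has no called
breakpoints, a configurable fallback interval (the most extreme breakpoint
pair observed for the locus, `(30363708, 30394114)`) is used.

Junction classification first aligns the observed junction to the expected
adjacency to extract any inserted bases (maximal context match on each
side; at least 25 matching bases per side are required, else the junction
is unalignable). An insert must have an exact template within ±50 bp of a
breakpoint to be called *templated*; an insert with no nearby template is
treated as unalignable rather than silently blunt. With no insert, the
breakpoint-ambiguity string is computed exactly from the reference (how far
the breakpoint pair can slide left or right leaving the derived sequence
unchanged); length ≥ 1 is *microhomology* — a single shared base counts,
since real junction homologies of 2–3 bp are typical — else *blunt*.
Mismatch-tolerant ("homeologous") homology is out of scope.

## Cross genetics (`cross_genetics`)

The segregation test is Pearson's chi-square against n×(expected ratio),
df = classes − 1, with optional Yates correction for two classes. For the
printed two-class cohort (24 affected of 454 against 1:15) the statistic
evaluates to ≈ 0.719 (0.56 with continuity correction); the value printed
in the source study (0.41) is not reproducible from those counts by either
formula and is treated as a documented discrepancy, not forced.

The two-locus fit is OLS on the full 3×3 factorial with sequential
(Type-I) sums of squares in the order A, B, A×B; on balanced designs this
coincides with Type-III and the components sum exactly to the total SS.
All nine cells must be occupied; empty cells are listed in the error. The
conditional-effect table reports, within each locus-A class, the mean
difference between extreme locus-B classes with a per-cell-variance
standard error — the recessive-epistasis signature is a B effect confined
to the A-homozygous stratum. The published ANOVA F statistic was computed
on real cross data and is not a reproduction target; the module reproduces
the procedure.

## Population genetics (`popgen`)

**Spectra.** Inbred accessions are treated as haploid for sample-size
accounting (standard for highly selfing populations). Polarization to the
reference genome (reference allele = ancestral) is the default for 1-D
spectra, with a folded mode. The folded JSFS draws, per site and per
population, ⌈0.9·n⌉ accessions without a missing call (sites that cannot
supply them are skipped), and folds jointly: configurations with total
minor count above half the joint sample size are reflected, exact ties
mapped to the lexicographically smaller configuration so the spectrum is
invariant to global allele relabeling. Site-exclusion masks (missingness,
CpG, repeats, pericentromere) enter as BED-derived boolean masks.

**Sweep model.** The background spectrum is the genome-wide distribution
over polymorphic derived-count classes 1..n−1. At distance d from a sweep
of intensity α, each of n lineages independently escapes with
`P_e = 1 − exp(−α·d)`; the non-escaped lineages coalesce into a single
ancestor, so the pre-sweep sample holds e + 1 lineages drawn from the
hypergeometrically downsampled background, of which the sweeping ancestor
is one uniformly at random. If the ancestor carries the derived allele
(probability j/(e+1) given j derived among e+1), the swept copies are all
derived. With e = n no lineage was swept and the model is an n-sized draw
from the background — this convention is forced by the required limit that
full escape (α·d → ∞) recovers the background exactly. Probabilities are
renormalized over polymorphic classes when conditioning on polymorphism
(always, inside the scan, since the background excludes fixed classes).

**CLR scan.** Grid points are spaced 100 kb starting at the first site
(making the scan translation-equivariant). All sites on the scanned
stretch contribute at every grid point with distance-decaying sweep
effect — the convention of the composite-likelihood scan family; no window
truncation is applied. α is maximized over a fixed log-spaced grid
(10⁻⁸..10⁻² per bp, 25 points) plus a golden-section refinement in log α
around the best grid value, and the background limit (α → ∞) is always
included, so CLR ≥ 0 by construction. Sweep-region extraction merges
contiguous grid points above a genome-wide CLR percentile (99% by
default); the threshold is always recomputed from the scanned data, never
imported from published values.

**Selection coefficients.** `estimate_s` inverts the deterministic diploid
recursion by bisection on s ≥ 0, exploiting the monotonicity of the final
frequency in s (verified as a property test); the bracket is doubled until
it contains the target, and convergence tolerance is 10⁻⁶ on s. Epoch-wise
estimation fits piecewise-constant s between user-supplied
(generation, frequency) knots. Generation time is the caller's unit — one
year when converting calendar spans. This deterministic fit is a clearly
labeled stand-in for genealogy-based trajectory inference: it does not use
coalescent information, so published selection coefficients and allele-age
estimates derived from genealogical importance sampling are context, not
reproduction targets.

**Rates and maps.** Two mutation-rate constants are kept separate and
never interchanged: 7×10⁻⁹ (base rate for the missing-data correction
`rate × (1 − missing/total)`) and 7.1×10⁻⁹ (demographic-model fitting).
Genetic-map rescaling divides distances by 1/outcrossing_rate (20 at 5%):
in a predominantly selfing population only outcrossed matings realize
crossovers, so effective map length shrinks by that factor; positions are
untouched and monotonicity is enforced.

## Ionome (`ionome`)

z-scores use population-level mean and SD (ddof = 1) computed per element
with all of a population's replicates pooled — population moments, not
per-batch moments, since batch structure is not part of the data contract.
A replicate is dropped if any element has |z| > 2 (strict); an element
with zero SD defines z = 0 and can drop nothing. Genotypes with fewer than
2 surviving replicates are excluded (including genotypes losing all
replicates). Ti/Cr-style contamination monitoring is available as hard
per-element ceilings, off by default. "Loading percentages" are reported
as squared-loading contributions (100 × loading² / column sum of squared
loadings) — the standard PCA-contribution convention; published loading
percentages from the real ionome data are not acceptance targets since
they require that data.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed and builds its own
`numpy` generator; no global state is used, and identical (config, seed)
pairs are bit-reproducible. The test suite exercises the designs at the
sizes the analyses assume — 454 F2s with a pool of 9 at 36× over
2,000-marker chromosomes (100 replicate crosses), copy numbers 1–7 at 40×
over a 15-kb interval (100 replicates each), 1,000 junction round-trips,
50 sweep localizations on 2-Mb stretches with 1,200 sites, and exhaustive
sweep-spectrum enumeration up to n = 6 — chosen so the full suite runs in
about two minutes on one core while keeping every rate estimate's Monte
Carlo error well below the margin it is tested against.

## Known limitations

* Read-level artifacts (mapping bias, duplicates, GC) are outside the
  generative model; estimator accuracies measured here are sampling-error
  bounds.
* The sweep scan assumes a single panmictic background spectrum;
  population structure inflates the null CLR.
* The split sampler has no recombination or migration and is not suitable
  for demographic inference, only for spectrum-shape tests.
* Junction classification requires exact homology/templates; diverged
  repeats are not recognized.
* The deterministic selection fit ignores drift and genealogical
  uncertainty; its estimates are point inversions, with the bisection
  bracket as the only reported interval.
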