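"""Biallelic SNP tables: VCF ingestion, quality/missingness/MAF filters, LD pruning.

Filter semantics follow the strict inequalities of the upstream command
syntax: a genotype cell passes only with GQ strictly above ``gq_min`` and
depth strictly above ``dp_min`` (so GQ 26+ and DP 4+ pass at the defaults).
A site is removed when a designated parent is missing or failed, when the
missing fraction among samples exceeds ``max_missing_fraction`` (0 by
default, i.e. no missing calls tolerated), or when the minor allele
frequency over called dosages falls below ``maf_min``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "FilterConfig",
    "load_biallelic_snps",
    "filter_sites",
    "ld_prune",
    "MISSING",
]

#: dosage code for a missing genotype call
MISSING = -1


@dataclass
class GenotypeTable:
    """Biallelic markers x samples with dosage, depth and genotype quality.

    ``dosage`` counts copies of the ALT allele (the parent-A allele when a
    synthetic cohort was written), ``MISSING`` (-1) for no-calls. ``roles``
    maps sample name -> "parent_A" | "parent_B" | "offspring" or a
    population label.
    """

    markers: pd.DataFrame  # columns chrom, pos, ref, alt
    samples: list[str]
    dosage: np.ndarray  # (n_markers, n_samples) int8
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.markers), len(self.samples)):
            raise ValueError("dosage shape must be (n_markers, n_samples)")
        bad = ~np.isin(self.dosage, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must lie in {0, 1, 2} or MISSING")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_indices(self, role: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if self.roles.get(s) == role])

    def subset_markers(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        return GenotypeTable(
            markers=self.markers.iloc[keep].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[keep],
            depth=None if self.depth is None else self.depth[keep],
            gq=None if self.gq is None else self.gq[keep],
            roles=dict(self.roles),
        )


@dataclass
class FilterConfig:
    gq_min: int = 25
    dp_min: int = 3
    require_parents_called: bool = True
    max_missing_fraction: float = 0.0
    maf_min: float = 0.05
    #: population label whose samples define the MAF; None = all samples
    maf_population: str | None = None

    def __post_init__(self) -> None:
        if self.gq_min < 0 or self.dp_min < 0 or self.max_missing_fraction < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")


def load_biallelic_snps(
    vcf_path: str,
    roles: dict[str, str] | None = None,
) -> GenotypeTable:
    """Read a VCF keeping only biallelic SNP records.

    Multiallelic and indel records are dropped and their counts logged.
    ``roles`` optionally tags samples (parent_A / parent_B / population).
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path, gts012=True)
    samples = list(vcf.samples)
    rows, dosages, depths, gqs = [], [], [], []
    n_multi = n_indel = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1 or rec.ALT[0] not in "ACGT":
            n_indel += 1
            continue
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        gt = rec.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        dosages.append(gt)
        try:
            depths.append(rec.format("DP")[:, 0])
        except (TypeError, KeyError):
            depths.append(np.full(len(samples), -1))
        try:
            gqs.append(rec.format("GQ")[:, 0])
        except (TypeError, KeyError):
            gqs.append(np.full(len(samples), -1))
    if n_multi or n_indel:
        logger.info("dropped %d multiallelic and %d non-SNP records", n_multi, n_indel)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    n = len(markers)
    return GenotypeTable(
        markers=markers,
        samples=samples,
        dosage=np.asarray(dosages, dtype=np.int8).reshape(n, len(samples)),
        depth=np.asarray(depths).reshape(n, len(samples)).astype(np.int32),
        gq=np.asarray(gqs).reshape(n, len(samples)).astype(np.int32),
        roles=dict(roles or {}),
    )


def filter_sites(table: GenotypeTable, cfg: FilterConfig | None = None) -> GenotypeTable:
    """Apply per-cell quality masking and site-level filters.

    Cells failing GQ/DP are set missing; sites are then removed on parent
    missingness, missing fraction, and MAF (computed from called dosages of
    the designated population). Site order and coordinates are preserved.
    """
    if table.n_markers == 0:
        raise ValueError("empty genotype table")
    cfg = cfg or FilterConfig()
    dosage = table.dosage.copy()
    missing = dosage == MISSING
    if table.gq is not None:
        missing |= table.gq <= cfg.gq_min
    if table.depth is not None:
        missing |= table.depth <= cfg.dp_min
    dosage[missing] = MISSING

    keep = np.ones(table.n_markers, dtype=bool)

    parent_cols = np.array(
        [i for i, s in enumerate(table.samples) if table.roles.get(s) in ("parent_A", "parent_B")]
    )
    if cfg.require_parents_called:
        if len(parent_cols) == 0:
            raise ValueError("require_parents_called set but no samples tagged as parents")
        keep &= ~missing[:, parent_cols].any(axis=1)

    keep &= missing.mean(axis=1) <= cfg.max_missing_fraction

    if cfg.maf_population is None:
        maf_cols = np.arange(len(table.samples))
    else:
        maf_cols = np.array(
            [i for i, s in enumerate(table.samples) if table.roles.get(s) == cfg.maf_population]
        )
        if len(maf_cols) == 0:
            raise ValueError(f"no samples labeled {cfg.maf_population!r}")
    sub = dosage[:, maf_cols].astype(float)
    called = sub >= 0
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, np.where(called, sub, 0).sum(axis=1) / (2 * n_called), np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep &= ~(maf < cfg.maf_min)  # NaN (all-missing) sites already dropped above

    out = table.subset_markers(np.flatnonzero(keep))
    out.dosage = dosage[keep]
    return out


def ld_prune(
    table: GenotypeTable,
    r2_max: float = 0.1,
    window_bp: int = 50_000,
    step: int = 10,
    step_unit: str = "markers",
) -> np.ndarray:
    """Prune markers in short-range linkage disequilibrium.

    Scanning windows of ``window_bp`` left to right (advanced by ``step``
    markers, or ``step`` bp with ``step_unit='bp'``), a marker is removed
    when its squared Pearson correlation of dosages with any retained
    earlier marker in-window exceeds ``r2_max``. Zero-variance markers are
    excluded from correlations (logged) but retained. Returns the kept
    marker indices in original order.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if step_unit not in ("markers", "bp"):
        raise ValueError("step_unit must be 'markers' or 'bp'")

    chroms = table.markers["chrom"].to_numpy()
    positions = table.markers["pos"].to_numpy()
    dosage = table.dosage.astype(float)
    dosage[dosage == MISSING] = np.nan

    removed = np.zeros(table.n_markers, dtype=bool)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(positions[idx], kind="stable")]
        pos_c = positions[idx]
        m = len(idx)
        w = 0
        while w < m:
            in_win = np.flatnonzero(
                (pos_c >= pos_c[w]) & (pos_c < pos_c[w] + window_bp)
            )
            in_win = in_win[in_win >= w]
            for a_i, i in enumerate(in_win):
                gi = idx[i]
                if removed[gi]:
                    continue
                xi = dosage[gi]
                if np.nanstd(xi) == 0:
                    logger.info("zero-variance marker at %s:%d excluded from LD correlations",
                                chrom, pos_c[i])
                    continue
                for j in in_win[:a_i]:
                    gj = idx[j]
                    if removed[gj]:
                        continue
                    xj = dosage[gj]
                    both = ~(np.isnan(xi) | np.isnan(xj))
                    if both.sum() < 2 or np.std(xj[both]) == 0 or np.std(xi[both]) == 0:
                        continue
                    r = np.corrcoef(xi[both], xj[both])[0, 1]
                    if r * r > r2_max:
                        removed[gi] = True
                        break
            if step_unit == "markers":
                w += step
            else:
                target = pos_c[w] + step
                nxt = np.searchsorted(pos_c, target, side="left")
                w = max(nxt, w + 1)
    return np.flatnonzero(~removed)
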