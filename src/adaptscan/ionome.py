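"""Leaf-ionome matrix cleaning and multivariate summary.

Replicate-level elemental concentrations (ug per g dry weight) are cleaned
with a per-population z-score rule: a replicate is dropped when any element
deviates more than ``z_max`` population standard deviations from the
population mean, and genotypes left with fewer than ``min_reps`` replicates
are excluded. Per-genotype medians of the surviving replicates feed a PCA
on the column-standardized matrix; "contribution" of an element to a
component is the squared loading expressed as a percentage of the
component's squared-loading total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["zscore_filter", "pca_summary", "PCASummary"]


def zscore_filter(
    matrix: pd.DataFrame,
    genotype_col: str = "genotype",
    population_col: str = "population",
    z_max: float = 2.0,
    min_reps: int = 2,
    contamination_max: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population outlier removal and per-genotype medians.

    All columns other than ``genotype_col`` and ``population_col`` are
    treated as element concentrations. z-scores use population-level mean
    and SD (ddof=1); an element with zero SD contributes z = 0 everywhere
    and can drop nothing. ``contamination_max`` optionally removes
    replicates whose named element exceeds a hard ceiling (e.g. a leaf-Ti
    threshold monitoring soil contamination); off by default.

    Returns ``(medians, drop_log)``: medians indexed by genotype with the
    population carried as a column, and one drop-log row per removed
    replicate or excluded genotype.
    """
    elements = [c for c in matrix.columns if c not in (genotype_col, population_col)]
    if not elements:
        raise ValueError("no element columns found")
    if matrix.groupby(genotype_col)[population_col].nunique().gt(1).any():
        raise ValueError("each genotype must map to a single population")

    drop_rows: list[tuple] = []
    keep_mask = pd.Series(True, index=matrix.index)

    if contamination_max:
        for col, ceiling in contamination_max.items():
            over = matrix[col] > ceiling
            for i in matrix.index[over]:
                drop_rows.append((matrix.loc[i, genotype_col], "replicate", f"{col} above {ceiling}"))
            keep_mask &= ~over

    for _, grp in matrix[keep_mask].groupby(population_col):
        vals = grp[elements].astype(float)
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        z = (vals - mean) / sd.replace(0.0, np.inf)  # zero-SD elements -> z = 0
        outlier = z.abs().gt(z_max).any(axis=1)
        for i in grp.index[outlier.to_numpy()]:
            worst = z.loc[i].abs().idxmax()
            drop_rows.append((matrix.loc[i, genotype_col], "replicate", f"|z({worst})| > {z_max}"))
        keep_mask.loc[grp.index[outlier.to_numpy()]] = False

    surviving = matrix[keep_mask]
    all_genotypes = matrix[genotype_col].unique()
    reps = surviving.groupby(genotype_col).size().reindex(all_genotypes, fill_value=0)
    ok_genotypes = reps[reps >= min_reps].index
    for g in reps[reps < min_reps].index:
        drop_rows.append((g, "genotype", f"fewer than {min_reps} surviving replicates"))

    kept = surviving[surviving[genotype_col].isin(ok_genotypes)]
    if kept.empty:
        raise ValueError("no genotypes survive filtering")
    medians = kept.groupby(genotype_col)[elements].median()
    medians[population_col] = kept.groupby(genotype_col)[population_col].first()
    drop_log = pd.DataFrame(drop_rows, columns=["genotype", "level", "reason"])
    return medians, drop_log


@dataclass
class PCASummary:
    scores: pd.DataFrame  # genotypes x components
    percent_variance: np.ndarray  # eigenvalue share per component, in %
    contributions: pd.DataFrame  # elements x components, columns sum to 100


def pca_summary(
    medians: pd.DataFrame,
    standardize: bool = True,
    population_col: str = "population",
) -> PCASummary:
    """PCA of the (column-standardized) genotype-median element matrix.

    Percent variance is the eigenvalue share; the percent contribution of
    element j to component k is ``100 * loading_jk^2 / sum_j loading_jk^2``.
    Both are invariant to the sign of a component.
    """
    data = medians.drop(columns=[population_col], errors="ignore").astype(float)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 genotypes and 2 elements")
    if data.isna().any().any():
        raise ValueError("median matrix contains missing cells")
    X = data.to_numpy()
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        const = np.flatnonzero(sd == 0)
        if len(const):
            names = ", ".join(data.columns[const])
            raise ValueError(f"constant element column(s) under standardization: {names}")
        X = X / sd
    u, svals, vt = np.linalg.svd(X, full_matrices=False)
    eig = svals**2
    percent_var = 100.0 * eig / eig.sum()
    loadings = vt.T  # elements x components
    contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    comps = [f"PC{i + 1}" for i in range(len(svals))]
    return PCASummary(
        scores=pd.DataFrame(u * svals, index=data.index, columns=comps),
        percent_variance=percent_var,
        contributions=pd.DataFrame(contrib, index=data.columns, columns=comps),
    )
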