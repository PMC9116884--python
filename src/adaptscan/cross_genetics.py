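"""Segregation-ratio tests and two-locus genotype-phenotype statistics for an F2.

The segregation test is a plain Pearson chi-square of observed class counts
against a Mendelian expectation (here typically 1:15 for a two-locus
recessive-epistasis trait), with an optional Yates continuity correction for
the two-class case. The two-locus fit is an ordinary least squares ANOVA on
the 3 x 3 factorial of genotype classes with sequential (Type-I) sums of
squares in the order locus A, locus B, interaction, plus a conditional-effect
table showing the effect of locus B within each locus-A stratum - the
signature of recessive epistasis is a B effect confined to one A class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SegregationTest", "EpistasisFit", "segregation_chisq", "two_locus_fit"]


@dataclass
class SegregationTest:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    continuity_corrected: bool


def segregation_chisq(
    observed: np.ndarray,
    expected_ratio: np.ndarray,
    continuity: bool = False,
) -> SegregationTest:
    """Pearson chi-square of observed counts against an expected ratio.

    ``expected_ratio`` holds proportions summing to 1; the Yates correction
    (subtract 0.5 from each absolute deviation) applies only with two
    classes. Degrees of freedom are classes - 1.
    """
    observed = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if len(observed) < 2 or len(observed) != len(ratio):
        raise ValueError("need >= 2 classes and matching expected proportions")
    if not np.isclose(ratio.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    n = observed.sum()
    expected = n * ratio
    if np.any(expected == 0):
        raise ValueError("expected count of zero in some class")
    dev = np.abs(observed - expected)
    if continuity and len(observed) == 2:
        dev = np.maximum(dev - 0.5, 0.0)
        corrected = True
    else:
        corrected = False
    chi2 = float((dev**2 / expected).sum())
    df = len(observed) - 1
    return SegregationTest(
        observed=observed,
        expected=expected,
        chi2=chi2,
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        continuity_corrected=corrected,
    )


@dataclass
class EpistasisFit:
    cell_means: pd.DataFrame  # 3 x 3, index = dosage A, columns = dosage B
    cell_counts: pd.DataFrame
    anova: pd.DataFrame  # rows locus_A, locus_B, interaction, residual
    conditional_effects: pd.DataFrame  # effect of B within each A class


def two_locus_fit(
    phenotype: np.ndarray,
    geno_a: np.ndarray,
    geno_b: np.ndarray,
) -> EpistasisFit:
    """OLS ANOVA on the 3 x 3 genotype factorial with Type-I sums of squares.

    Requires every one of the nine cells to be occupied (the full-interaction
    design is rank-deficient otherwise); the error message lists the empty
    cells. The conditional-effect table gives, within each locus-A class,
    the mean phenotype difference between the extreme locus-B classes with a
    standard error from the per-cell variances.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    phenotype = np.asarray(phenotype, dtype=float)
    geno_a = np.asarray(geno_a)
    geno_b = np.asarray(geno_b)
    if not (len(phenotype) == len(geno_a) == len(geno_b)):
        raise ValueError("phenotype and genotype vectors must have equal length")

    df = pd.DataFrame({"y": phenotype, "A": geno_a, "B": geno_b})
    counts = df.groupby(["A", "B"]).size()
    empty = [
        (a, b)
        for a in (0, 1, 2)
        for b in (0, 1, 2)
        if (a, b) not in counts.index
    ]
    if empty:
        raise ValueError(f"rank-deficient design: empty genotype cells {empty}")

    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    anova = anova.rename(
        index={"C(A)": "locus_A", "C(B)": "locus_B", "C(A):C(B)": "interaction", "Residual": "residual"}
    )

    cell_means = df.groupby(["A", "B"])["y"].mean().unstack()
    cell_counts = counts.unstack()
    cell_var = df.groupby(["A", "B"])["y"].var(ddof=1).unstack()

    rows = []
    for a in (0, 1, 2):
        m0, m2 = cell_means.loc[a, 0], cell_means.loc[a, 2]
        n0, n2 = cell_counts.loc[a, 0], cell_counts.loc[a, 2]
        v0 = 0.0 if pd.isna(cell_var.loc[a, 0]) else cell_var.loc[a, 0]
        v2 = 0.0 if pd.isna(cell_var.loc[a, 2]) else cell_var.loc[a, 2]
        rows.append((a, m2 - m0, np.sqrt(v0 / n0 + v2 / n2)))
    conditional = pd.DataFrame(rows, columns=["dosage_A", "effect_B", "se"]).set_index("dosage_A")

    return EpistasisFit(
        cell_means=cell_means,
        cell_counts=cell_counts,
        anova=anova,
        conditional_effects=conditional,
    )
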