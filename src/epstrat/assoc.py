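"""Association tests, one per (design x genetic model) cell.

Binary designs (EPS extremes, case-control) cross-classify group
status against genotype and use a Pearson chi-square (codominant),
Cochran-Armitage trend (additive) or pooled two-proportion z test
(recessive).  The random-sample design keeps the continuous phenotype
and uses one-way ANOVA (codominant, recessive) or linear regression
(additive).  The PC-correction experiments use a logistic-regression
likelihood ratio test with optional covariates.

No continuity corrections anywhere, which keeps the z^2 = chi-square
identity on 2x2 tables exact.  Degenerate inputs never raise during a
simulation run: they produce ``TestResult(valid=False)`` with a reason
code, and the experiment layer counts them as non-rejections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._tablestats import pearson_stat, trend_z, two_proportion_z
from .designs import DesignSample
from .mixture import GENETIC_MODELS

LOGISTIC_MAXITER = 100
LOGISTIC_TOL = 1e-8


@dataclass
class TestResult:
    test_name: str
    genetic_model: str | None
    statistic: float
    df: float | None
    p_value: float
    valid: bool = True
    reason: str | None = None

    def rejects(self, alpha: float) -> bool:
        """Rejection indicator; invalid results never reject (conservative)."""
        return bool(self.valid and self.p_value < alpha)


def _invalid(name: str, model: str | None, reason: str) -> TestResult:
    return TestResult(name, model, math.nan, None, math.nan, False, reason)


def build_table(sample: DesignSample, genetic_model: str) -> np.ndarray:
    """Cross-classify group status (rows) against genotype (columns).

    Row 0 is the upper extreme / case group.  Codominant and additive
    use the three genotype columns (AA, Aa, aa); recessive collapses to
    (AA+Aa, aa).
    """
    if genetic_model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {genetic_model!r}")
    if sample.group is None:
        raise ValueError("sample has no binary group labels")
    if sample.genotype is None:
        raise ValueError("sample has no genotypes")
    rows = [
        np.bincount(sample.genotype[sample.group == g], minlength=3)[:3]
        for g in (1, 0)
    ]
    table = np.asarray(rows)
    if genetic_model == "recessive":
        table = np.column_stack([table[:, 0] + table[:, 1], table[:, 2]])
    return table


def pearson_chisq(table) -> TestResult:
    """Pearson chi-square on a 2xC table; empty columns dropped, df reduced."""
    stat, df = pearson_stat(table)
    if not np.isfinite(stat):
        return _invalid("pearson_chisq", "codominant", "fewer than 2 nonempty columns")
    return TestResult(
        "pearson_chisq", "codominant", stat, df, float(stats.chi2.sf(stat, df))
    )


def cochran_armitage(table) -> TestResult:
    """Two-sided Cochran-Armitage trend test with scores (0, 1, 2).

    Score-test variance, so the squared statistic equals the score test
    of the additive term in a logistic regression of group on genotype.
    """
    z = trend_z(table)
    if not np.isfinite(z):
        return _invalid("cochran_armitage", "additive", "zero score variance")
    return TestResult(
        "cochran_armitage", "additive", z, 1, float(2.0 * stats.norm.sf(abs(z)))
    )


def two_proportion_test(table) -> TestResult:
    """Two-sided pooled-variance z test of equal aa-proportion (2x2 table)."""
    z = two_proportion_z(table)
    if not np.isfinite(z):
        return _invalid("two_proportion", "recessive", "pooled proportion is 0 or 1")
    return TestResult(
        "two_proportion", "recessive", z, 1, float(2.0 * stats.norm.sf(abs(z)))
    )


def anova_test(phenotype, genotype_category) -> TestResult:
    """One-way ANOVA F test of equal phenotype means across genotype classes."""
    phenotype = np.asarray(phenotype, dtype=float)
    category = np.asarray(genotype_category)
    groups = [phenotype[category == c] for c in np.unique(category)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return _invalid("anova", None, "fewer than 2 genotype classes present")
    if len(phenotype) - len(groups) < 1:
        return _invalid("anova", None, "no residual degrees of freedom")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):
        return _invalid("anova", None, "degenerate within-class variance")
    return TestResult("anova", None, float(f), len(groups) - 1, float(p))


def linear_trend_test(phenotype, genotype_additive) -> TestResult:
    """Two-sided t test on the slope of phenotype ~ additive genotype."""
    g = np.asarray(genotype_additive, dtype=float)
    if np.ptp(g) == 0.0:
        return _invalid("linear_regression", "additive", "constant genotype")
    res = stats.linregress(g, np.asarray(phenotype, dtype=float))
    t_stat = float(res.slope / res.stderr) if res.stderr > 0 else math.inf
    return TestResult("linear_regression", "additive", t_stat, None, float(res.pvalue))


def _genotype_columns(genotype: np.ndarray, genetic_model: str) -> np.ndarray:
    if genetic_model == "additive":
        return genotype.astype(float)[:, None]
    if genetic_model == "codominant":
        return np.column_stack(
            [(genotype == 1).astype(float), (genotype == 2).astype(float)]
        )
    if genetic_model == "recessive":
        return (genotype == 2).astype(float)[:, None]
    raise ValueError(f"unknown genetic model {genetic_model!r}")


def logistic_lrt(
    group,
    genotype,
    covariates=None,
    genetic_model: str = "additive",
) -> TestResult:
    """Likelihood ratio test for the candidate SNP in a logistic model.

    Compares group ~ covariates + genotype against group ~ covariates.
    The genotype enters as a numeric 0/1/2 variable (additive, 1 df) or
    as two indicator columns (codominant, 2 df).  Indicator columns for
    genotype classes absent from the sample are dropped and the df
    reduced; if no informative genotype column remains the result is
    invalid.  Non-convergence or separation also yields an invalid
    result rather than an exception.
    """
    name = "logistic_lrt"
    y = np.asarray(group, dtype=float)
    if len(np.unique(y)) < 2:
        return _invalid(name, genetic_model, "only one group present")
    gcols = _genotype_columns(np.asarray(genotype), genetic_model)
    keep = np.ptp(gcols, axis=0) > 0.0
    gcols = gcols[:, keep]
    df = gcols.shape[1]
    if df == 0:
        return _invalid(name, genetic_model, "genotype constant in sample")
    x_reduced = np.ones((len(y), 1))
    if covariates is not None:
        x_reduced = np.column_stack([x_reduced, np.asarray(covariates, dtype=float)])
    x_full = np.column_stack([x_reduced, gcols])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_kwargs = dict(maxiter=LOGISTIC_MAXITER, tol=LOGISTIC_TOL)
            full = sm.GLM(y, x_full, family=sm.families.Binomial()).fit(**fit_kwargs)
            reduced = sm.GLM(y, x_reduced, family=sm.families.Binomial()).fit(
                **fit_kwargs
            )
    except Exception as exc:  # separation / singular design / non-convergence
        return _invalid(name, genetic_model, f"fit failed: {type(exc).__name__}")
    lr = reduced.deviance - full.deviance
    if not np.isfinite(lr):
        return _invalid(name, genetic_model, "non-finite deviance")
    lr = max(lr, 0.0)
    return TestResult(name, genetic_model, float(lr), df, float(stats.chi2.sf(lr, df)))
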