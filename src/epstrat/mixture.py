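"""Closed-form mathematics of a two-subpopulation stratified cohort.

A cohort of size ``N`` is a mixture of two hidden subpopulations.  The
phenotype of an individual from population *i* is N(mu_i, sigma^2); a
candidate SNP with allele ``A`` at frequency ``p_i`` is in
Hardy-Weinberg equilibrium within each population.  Under the null
hypothesis of no causal effect, genotype and phenotype are independent
*conditional on population*, but marginally associated whenever both
the allele frequencies and the phenotype means differ between the
populations — the classic population-stratification confounder.

This module collects the closed-form pieces of that model:

* marginal genotype probabilities in the mixed cohort,
* the two-component normal mixture CDF of the phenotype and its
  numerical inverse,
* population membership probabilities and the phenotype distribution
  conditional on genotype (Bayes' rule on the mixture components),
* a large-sample approximation to the false positive rate of the
  standard association tests applied to the phenotype extremes
  (extreme phenotype sampling, EPS).

Genotypes are coded as the number of copies of the ``a`` allele:
AA = 0, Aa = 1, aa = 2, so ``P(g = 0) = p_i**2`` within population *i*.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2, ncx2, norm

from ._tablestats import pearson_stat, trend_z, two_proportion_z

GENOTYPE_LABELS = ("AA", "Aa", "aa")
GENETIC_MODELS = ("codominant", "additive", "recessive")


class ParameterError(ValueError):
    """A scenario parameter lies outside its domain."""


class DegenerateDistributionError(ValueError):
    """A conditional distribution is requested for a zero-probability class."""


@dataclass(frozen=True)
class ScenarioParams:
    """One simulation scenario for the two-population mixture.

    Parameters
    ----------
    omega1 : float
        Proportion of the cohort from population 1, in (0, 1).  The
        complement ``omega2`` is derived, never stored.
    mu1, mu2 : float
        Phenotype means per population.  ``mu2`` defaults to ``-mu1``,
        the symmetric convention used throughout the common-variant
        grid; presets with real-data means set it explicitly.
    p1, p2 : float
        Frequency of allele ``A`` in populations 1 and 2.
    sigma2 : float
        Common within-population phenotype variance (default 1).
    N : int
        Cohort size.
    tail_fraction : float
        Fraction genotyped per extreme (default 0.1, so each extreme
        group has ``n = round(0.1 * N)`` individuals).
    alpha : float
        Significance level for all association tests (default 0.05).
    """

    omega1: float
    mu1: float
    p1: float
    p2: float
    mu2: float | None = None
    sigma2: float = 1.0
    N: int = 5000
    tail_fraction: float = 0.1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.mu2 is None:
            object.__setattr__(self, "mu2", -self.mu1)
        if not 0.0 < self.omega1 < 1.0:
            raise ParameterError(f"omega1 must be in (0, 1), got {self.omega1}")
        for name in ("p1", "p2"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {value}")
        if not self.sigma2 > 0.0:
            raise ParameterError(f"sigma2 must be positive, got {self.sigma2}")
        if not 0.0 < self.tail_fraction <= 0.25:
            raise ParameterError(
                f"tail_fraction must be in (0, 0.25], got {self.tail_fraction}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if int(self.N) < 2:
            raise ParameterError(f"N must be at least 2, got {self.N}")
        object.__setattr__(self, "N", int(self.N))

    @property
    def omega2(self) -> float:
        return 1.0 - self.omega1

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)

    @property
    def n_extreme(self) -> int:
        """Individuals per extreme group: round(tail_fraction * N)."""
        return int(round(self.tail_fraction * self.N))

    @property
    def n_subsample(self) -> int:
        """Total retained under EPS (both extremes)."""
        return 2 * self.n_extreme

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_extreme"] = self.n_extreme
        return d


@dataclass(frozen=True)
class GenotypeDistribution:
    """Marginal genotype probabilities (AA, Aa, aa) in the mixed cohort."""

    pAA: float
    pAa: float
    paa: float

    def __post_init__(self) -> None:
        total = self.pAA + self.pAa + self.paa
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"genotype probabilities sum to {total}, not 1")
        if min(self.pAA, self.pAa, self.paa) < 0.0:
            raise ValueError("genotype probabilities must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.pAA, self.pAa, self.paa])


@dataclass(frozen=True)
class ConditionalMembership:
    """P(population 1 | genotype) for each genotype class (AA, Aa, aa)."""

    p_pop1_given_g: tuple[float, float, float]

    def as_array(self) -> np.ndarray:
        return np.array(self.p_pop1_given_g)


def _hwe(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([p * p, 2.0 * p * q, q * q])


def genotype_probabilities(params: ScenarioParams) -> GenotypeDistribution:
    """Marginal genotype probabilities in the mixture.

    HWE holds within each subpopulation by construction; the mixture
    itself is generally *out* of HWE (Wahlund effect) when p1 != p2.
    """
    probs = params.omega1 * _hwe(params.p1) + params.omega2 * _hwe(params.p2)
    return GenotypeDistribution(*probs)


def mixture_cdf(y, params: ScenarioParams):
    """Cohort-level phenotype CDF: a two-component normal mixture."""
    y = np.asarray(y, dtype=float)
    out = params.omega1 * norm.cdf((y - params.mu1) / params.sigma) + (
        params.omega2 * norm.cdf((y - params.mu2) / params.sigma)
    )
    return float(out) if out.ndim == 0 else out


def mixture_quantile(q: float, params: ScenarioParams) -> float:
    """Invert the mixture CDF by bracketed root finding.

    The mixture quantile always lies between the two component
    quantiles, which gives a cheap, guaranteed bracket for Brent's
    method.
    """
    if not 0.0 < q < 1.0:
        raise ParameterError(f"quantile level must be in (0, 1), got {q}")
    z = norm.ppf(q) * params.sigma
    lo = min(params.mu1, params.mu2) + z
    hi = max(params.mu1, params.mu2) + z
    if hi - lo < 1e-14:
        return lo
    return float(brentq(lambda y: mixture_cdf(y, params) - q, lo, hi, xtol=1e-12))


def population_given_genotype(params: ScenarioParams) -> ConditionalMembership:
    """P(population 1 | g) for g in (AA, Aa, aa), via Bayes' rule."""
    joint1 = params.omega1 * _hwe(params.p1)
    marginal = joint1 + params.omega2 * _hwe(params.p2)
    if np.any(marginal <= 0.0):
        bad = [GENOTYPE_LABELS[i] for i in np.flatnonzero(marginal <= 0.0)]
        raise DegenerateDistributionError(
            f"genotype class(es) {bad} have zero marginal probability"
        )
    return ConditionalMembership(tuple(joint1 / marginal))


def _genotype_index(g) -> int:
    if isinstance(g, str):
        try:
            return GENOTYPE_LABELS.index(g)
        except ValueError:
            raise ParameterError(f"unknown genotype class {g!r}") from None
    g = int(g)
    if g not in (0, 1, 2):
        raise ParameterError(f"genotype code must be 0, 1 or 2, got {g}")
    return g


def phenotype_cdf_given_genotype(y, g, params: ScenarioParams):
    """Phenotype CDF conditional on genotype class.

    A two-component mixture with weights P(population | g): the
    genotype shifts the mixture weights, never the component shapes —
    that is the entire mechanism of the confounding.
    """
    w1 = population_given_genotype(params).as_array()[_genotype_index(g)]
    y = np.asarray(y, dtype=float)
    out = w1 * norm.cdf((y - params.mu1) / params.sigma) + (1.0 - w1) * norm.cdf(
        (y - params.mu2) / params.sigma
    )
    return float(out) if out.ndim == 0 else out


def tail_genotype_distributions(
    params: ScenarioParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype distributions conditional on the lower / upper phenotype tail.

    With tail thresholds at the ``tail_fraction`` and
    ``1 - tail_fraction`` mixture quantiles,
    ``P(g | tail) = P(g) * P(Y in tail | g) / tail_fraction``.
    Returns ``(lower, upper)`` probability vectors over (AA, Aa, aa).
    """
    c = params.tail_fraction
    t_lo = mixture_quantile(c, params)
    t_hi = mixture_quantile(1.0 - c, params)
    probs = genotype_probabilities(params).as_array()
    w1 = population_given_genotype(params).as_array()
    cdf_lo = w1 * norm.cdf((t_lo - params.mu1) / params.sigma) + (1.0 - w1) * norm.cdf(
        (t_lo - params.mu2) / params.sigma
    )
    cdf_hi = w1 * norm.cdf((t_hi - params.mu1) / params.sigma) + (1.0 - w1) * norm.cdf(
        (t_hi - params.mu2) / params.sigma
    )
    lower = probs * cdf_lo / c
    upper = probs * (1.0 - cdf_hi) / c
    # The thresholds are exact mixture quantiles, so each vector sums to 1
    # up to floating point; renormalize to keep downstream tables exact.
    return lower / lower.sum(), upper / upper.sum()


def analytic_eps_fpr(params: ScenarioParams, genetic_model: str) -> float:
    """Large-sample false positive rate of the EPS design at level alpha.

    The construction: condition the genotype distribution on each
    phenotype tail, form the expected 2x3 table with ``n_extreme``
    individuals per tail, evaluate the relevant test statistic on that
    expected table to obtain the noncentrality parameter, and read the
    rejection probability off the noncentral chi-square distribution
    (1 df for the trend and two-proportion tests, 2 df for the
    codominant Pearson test, reduced when a genotype column is empty).

    Exact in the no-confounding limits: returns ``alpha`` whenever
    ``p1 == p2`` or ``mu1 == mu2``.
    """
    if genetic_model not in GENETIC_MODELS:
        raise ParameterError(f"unknown genetic model {genetic_model!r}")
    lower, upper = tail_genotype_distributions(params)
    n = params.n_extreme
    expected = n * np.vstack([upper, lower])
    if genetic_model == "codominant":
        ncp, df = pearson_stat(expected)
    elif genetic_model == "additive":
        z = trend_z(expected)
        ncp, df = z * z, 1
    else:
        collapsed = np.column_stack([expected[:, 0] + expected[:, 1], expected[:, 2]])
        z = two_proportion_z(collapsed)
        ncp, df = z * z, 1
    if not np.isfinite(ncp):
        raise DegenerateDistributionError(
            f"{genetic_model} statistic undefined: candidate SNP is "
            "(near-)monomorphic in the expected tail tables"
        )
    if ncp < 1e-12:
        return params.alpha
    crit = chi2.ppf(1.0 - params.alpha, df)
    return float(ncx2.sf(crit, df, ncp))
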