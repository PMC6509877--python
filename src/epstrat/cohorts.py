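"""Simulation of stratified cohorts under the null of no causal effect.

Phenotypes are drawn from the within-population normal distributions
and candidate-SNP genotypes from within-population HWE proportions,
*independently* of each other given the (hidden) population label — so
any marginal genotype-phenotype association in a simulated cohort is
pure confounding by stratification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import SeedLike, generator
from .mixture import ParameterError, ScenarioParams


@dataclass
class Cohort:
    """A simulated cohort.

    Attributes
    ----------
    phenotype : ndarray of float, shape (N,)
    genotype : ndarray of int, shape (N,), or None
        Candidate-SNP genotype as the count of ``a`` alleles (0/1/2).
        ``None`` for cohorts where the candidate SNP is supplied
        separately (four-population panel experiments).
    population : ndarray of int, shape (N,)
        Hidden population label, 1-based.
    """

    phenotype: np.ndarray
    genotype: np.ndarray | None
    population: np.ndarray

    def __post_init__(self) -> None:
        if len(self.phenotype) != len(self.population):
            raise ValueError("phenotype and population lengths differ")
        if self.genotype is not None and len(self.genotype) != len(self.phenotype):
            raise ValueError("genotype length differs from phenotype length")

    @property
    def N(self) -> int:
        return len(self.phenotype)

    def to_frame(self) -> pd.DataFrame:
        data = {"id": np.arange(self.N), "phenotype": self.phenotype}
        if self.genotype is not None:
            data["genotype"] = self.genotype
        data["population"] = self.population
        return pd.DataFrame(data)

    def dump_table(self, path: str | Path) -> None:
        """Debugging dump as a tab-delimited table."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def _population_counts(weights: np.ndarray, N: int) -> np.ndarray:
    """Deterministic per-population counts: rounded, largest-remainder fixup."""
    raw = weights * N
    counts = np.floor(raw + 0.5).astype(int)
    excess = counts.sum() - N
    if excess != 0:
        # adjust the populations whose rounding moved furthest
        order = np.argsort(raw - counts)
        idx = order[:excess] if excess > 0 else order[excess:]
        counts[idx] -= np.sign(excess)
    return counts


def simulate_stratified_cohort(
    weights,
    means,
    sigma2: float,
    N: int,
    counted_allele_freqs=None,
    seed: SeedLike = 0,
) -> Cohort:
    """Simulate a K-population cohort.

    Parameters
    ----------
    weights : sequence of float
        Mixing proportions (must sum to 1); population k receives a
        fixed ``round(weights[k] * N)`` individuals rather than a
        binomial draw, reducing Monte-Carlo variance without changing
        the estimand.
    means : sequence of float
        Phenotype mean per population; common variance ``sigma2``.
    counted_allele_freqs : sequence of float, optional
        Frequency of the counted (``a``) allele per population.  The
        candidate genotype is Binomial(2, freq) per individual (HWE).
        Omit for phenotype-only cohorts.
    """
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    if weights.shape != means.shape:
        raise ParameterError("weights and means must have equal length")
    if np.any(weights <= 0.0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ParameterError("weights must be positive and sum to 1")
    if sigma2 <= 0.0:
        raise ParameterError("sigma2 must be positive")
    rng = generator(seed)
    counts = _population_counts(weights, int(N))
    sigma = np.sqrt(sigma2)
    phenotype = np.empty(N)
    population = np.empty(N, dtype=np.int64)
    genotype = None if counted_allele_freqs is None else np.empty(N, dtype=np.int64)
    start = 0
    for k, nk in enumerate(counts):
        stop = start + nk
        phenotype[start:stop] = rng.normal(means[k], sigma, size=nk)
        population[start:stop] = k + 1
        if genotype is not None:
            q = float(counted_allele_freqs[k])
            if not 0.0 <= q <= 1.0:
                raise ParameterError(f"allele frequency {q} outside [0, 1]")
            genotype[start:stop] = rng.binomial(2, q, size=nk)
        start = stop
    return Cohort(phenotype, genotype, population)


def simulate_cohort(params: ScenarioParams, seed: SeedLike = 0) -> Cohort:
    """Simulate a two-population cohort for one scenario.

    Population 1 gets exactly ``round(omega1 * N)`` individuals.  The
    counted allele is ``a``, so its within-population frequency is
    ``1 - p_i``.
    """
    return simulate_stratified_cohort(
        weights=(params.omega1, params.omega2),
        means=(params.mu1, params.mu2),
        sigma2=params.sigma2,
        N=params.N,
        counted_allele_freqs=(1.0 - params.p1, 1.0 - params.p2),
        seed=seed,
    )


def preset_italy_france(omega_italy: float = 0.5) -> ScenarioParams:
    """Scenario with realistic European parameters.

    Lactase-persistence allele frequencies (0.286 Italy, 0.43 France)
    and female height as the phenotype (means 158.48 cm and 161.77 cm,
    common variance 6).  Population 1 is Italy.
    """
    return ScenarioParams(
        omega1=omega_italy,
        mu1=158.48,
        mu2=161.77,
        p1=0.286,
        p2=0.43,
        sigma2=6.0,
        N=5000,
        tail_fraction=0.1,
    )


def preset_rare_variant(
    maf1: float,
    maf2: float,
    omega1: float = 0.5,
    mu1: float = 0.1,
    N: int = 5000,
) -> ScenarioParams:
    """Scenario where the candidate SNP is rare in population 1.

    ``maf1``/``maf2`` are minor-allele frequencies; the counted ``a``
    allele is the minor allele, so the ``A`` frequency is ``1 - maf``.
    The study grid pairs maf1 = 0.01 with maf2 in {0.01, 0.05, 0.10}.
    """
    for name, maf in (("maf1", maf1), ("maf2", maf2)):
        if not 0.0 < maf <= 0.5:
            raise ParameterError(f"{name} must be in (0, 0.5], got {maf}")
    return ScenarioParams(omega1=omega1, mu1=mu1, p1=1.0 - maf1, p2=1.0 - maf2, N=N)
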