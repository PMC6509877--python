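"""The three subsampling designs compared by the study.

* ``eps``: genotype only the top-n and bottom-n individuals by
  phenotype and compare the two extreme groups as binary outcomes.
* ``random``: a simple random sample of the same total size, analyzed
  on the continuous phenotype.
* ``case_control``: the top-n extreme as "cases" (a quantitative trait
  dichotomized at a threshold), controls sampled from the remainder.

Selection is rank-based with exact group sizes, matching a study that
genotypes "the highest n and lowest n" individuals; ties (probability
zero for continuous phenotypes) are broken by stable original-index
order, with the first-indexed individuals preferred in each group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import SeedLike, generator
from .cohorts import Cohort

DESIGNS = ("eps", "random", "case_control")


class SampleSizeError(ValueError):
    """Requested subsample does not fit in the cohort."""


@dataclass
class DesignSample:
    """A subsample drawn from a cohort.

    ``group`` is 1 for the upper extreme / cases and 0 for the lower
    extreme / controls; ``None`` for the random design, which keeps the
    continuous phenotype instead.  ``indices`` are positions in the
    source cohort.
    """

    design: str
    genotype: np.ndarray | None
    group: np.ndarray | None
    phenotype: np.ndarray
    indices: np.ndarray

    @property
    def size(self) -> int:
        return len(self.indices)


def _take(cohort: Cohort, design: str, indices: np.ndarray, group) -> DesignSample:
    genotype = None if cohort.genotype is None else cohort.genotype[indices]
    return DesignSample(
        design=design,
        genotype=genotype,
        group=None if group is None else np.asarray(group, dtype=np.int64),
        phenotype=cohort.phenotype[indices],
        indices=indices,
    )


def _bottom_n(phenotype: np.ndarray, n: int) -> np.ndarray:
    return np.argsort(phenotype, kind="stable")[:n]


def _top_n(phenotype: np.ndarray, n: int) -> np.ndarray:
    # descending stable sort keeps the first-indexed tied individual first
    return np.argsort(-phenotype, kind="stable")[:n]


def eps_sample(cohort: Cohort, n: int) -> DesignSample:
    """Extreme phenotype sample: exactly n lowest plus n highest."""
    if 2 * n > cohort.N:
        raise SampleSizeError(f"2n = {2 * n} exceeds cohort size {cohort.N}")
    lower = _bottom_n(cohort.phenotype, n)
    upper = _top_n(cohort.phenotype, n)
    indices = np.concatenate([lower, upper])
    group = np.concatenate([np.zeros(n, dtype=np.int64), np.ones(n, dtype=np.int64)])
    return _take(cohort, "eps", indices, group)


def random_sample(cohort: Cohort, m: int, seed: SeedLike) -> DesignSample:
    """Simple random sample of m individuals without replacement."""
    if m > cohort.N:
        raise SampleSizeError(f"m = {m} exceeds cohort size {cohort.N}")
    indices = generator(seed).choice(cohort.N, size=m, replace=False)
    return _take(cohort, "random", indices, None)


def case_control_sample(cohort: Cohort, n: int, seed: SeedLike) -> DesignSample:
    """Top-n extremes as cases; n controls sampled from the remaining N - n."""
    if 2 * n > cohort.N:
        raise SampleSizeError(f"2n = {2 * n} exceeds cohort size {cohort.N}")
    cases = _top_n(cohort.phenotype, n)
    remaining = np.setdiff1d(np.arange(cohort.N), cases, assume_unique=True)
    controls = generator(seed).choice(remaining, size=n, replace=False)
    indices = np.concatenate([controls, cases])
    group = np.concatenate([np.zeros(n, dtype=np.int64), np.ones(n, dtype=np.int64)])
    return _take(cohort, "case_control", indices, group)
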