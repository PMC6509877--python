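"""Ancestry-SNP simulation, genotype standardization and principal components.

Two sources of per-population allele frequencies are provided:

* the Balding-Nichols model, where each SNP's subpopulation frequency
  is a beta draw around an ancestral frequency with variance governed
  by Fst, and
* a synthetic four-population European panel (TSI/IBS/GBR/FIN labels)
  with *heterogeneous* per-SNP differentiation — mostly near-identical
  frequencies with a minority of strongly differentiated SNPs — which
  emulates reference panels built from real European genotype data.

Genotype matrices simulated from a panel are standardized the
EIGENSTRAT way: center each SNP column and divide by
``sqrt(ptilde * (1 - ptilde))`` where ``ptilde = (1 + sum g) / (2 + 2n)``
is a pseudo-count allele-frequency estimate over the n retained
individuals; the pseudo-count keeps monomorphic columns finite.  Top
principal components of the standardized matrix serve as ancestry
covariates (component signs are arbitrary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.utils.extmath import randomized_svd

from ._rng import SeedLike, generator

EUROPEAN_LABELS = ("TSI", "IBS", "GBR", "FIN")
EUROPEAN_PHENOTYPE_MEANS = (0.3, 0.2, 0.0, -0.1)
EUROPEAN_RARE_CANDIDATE_MAFS = (0.01, 0.02, 0.05, 0.1)


class CandidateSelectionError(RuntimeError):
    """No SNP exceeds the confounding threshold; regenerate the panel."""


@dataclass(frozen=True)
class BaldingNicholsParams:
    """Balding-Nichols ancestry-SNP settings.

    ``fst`` controls the between-population frequency variance
    p(1-p)*Fst.  The beta shape parameters (``a_shape``, ``b_shape``)
    are derived per SNP as p(1-Fst)/Fst and (1-p)(1-Fst)/Fst.
    """

    n_snps: int = 5000
    fst: float = 0.01
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_freq_range
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")


def beta_shapes(p: float, fst: float) -> tuple[float, float]:
    """Beta shape parameters for the Balding-Nichols draw at ancestral freq p."""
    return p * (1.0 - fst) / fst, (1.0 - p) * (1.0 - fst) / fst


@dataclass
class FrequencyPanel:
    """Per-SNP, per-population frequencies of the counted ("1") allele."""

    pop_labels: tuple[str, ...]
    freqs: np.ndarray  # (n_snps, K)
    phenotype_means: np.ndarray | None = None
    candidate_mafs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(self.pop_labels):
            raise ValueError("freqs must be (n_snps, K) with K == len(pop_labels)")
        if len(self.pop_labels) < 2:
            raise ValueError("at least two populations required")
        if np.any((self.freqs < 0.0) | (self.freqs > 1.0)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        """Export as tab-delimited text (snp id + one column per population)."""
        frame = pd.DataFrame(self.freqs, columns=list(self.pop_labels))
        frame.insert(0, "snp", [f"snp{i}" for i in range(self.n_snps)])
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyPanel":
        frame = pd.read_csv(path, sep="\t")
        pops = tuple(c for c in frame.columns if c != "snp")
        return cls(pop_labels=pops, freqs=frame[list(pops)].to_numpy(float))


@dataclass
class AncestryPanel:
    """Simulated ancestry genotypes for a set of individuals.

    ``genotypes`` holds 0/1/2 counts of the "1" allele, individuals by
    SNPs.  ``est_freq``, ``standardized`` and ``pc_scores`` are filled
    by :func:`standardize_genotypes` / :func:`compute_pcs` via
    :func:`build_ancestry_panel`.
    """

    genotypes: np.ndarray
    subpop_freqs: FrequencyPanel
    populations: np.ndarray
    est_freq: np.ndarray | None = None
    standardized: np.ndarray | None = None
    pc_scores: np.ndarray | None = None


def balding_nichols_freqs(
    params: BaldingNicholsParams, n_pops: int, seed: SeedLike
) -> FrequencyPanel:
    """Draw a Balding-Nichols frequency panel for ``n_pops`` populations."""
    rng = generator(seed)
    lo, hi = params.ancestral_freq_range
    p = rng.uniform(lo, hi, size=params.n_snps)
    a, b = beta_shapes(p, params.fst)
    freqs = rng.beta(a[:, None], b[:, None], size=(params.n_snps, n_pops))
    labels = tuple(f"pop{k + 1}" for k in range(n_pops))
    return FrequencyPanel(pop_labels=labels, freqs=freqs)


def synthetic_european_panel(
    n_snps: int = 20000,
    seed: SeedLike = 0,
    fst_components: tuple[float, float] = (0.004, 0.05),
    high_fst_proportion: float = 0.05,
    rare_candidate: bool = False,
) -> FrequencyPanel:
    """Synthetic four-population European-like frequency panel.

    Emulates a reference panel of common SNPs from four closely related
    European populations: per-SNP Fst comes from a two-component
    mixture (most SNPs barely differentiated, a small minority strongly
    differentiated), and the retained SNPs satisfy the panel filters —
    panel-wide MAF > 0.05, the minor allele observed in every
    population, and a maximum per-population minor-allele frequency of
    at least 0.1.  Phenotype means per population are
    (0.3, 0.2, 0, -0.1) for (TSI, IBS, GBR, FIN); ``rare_candidate``
    attaches the rare-candidate MAF vector (0.01, 0.02, 0.05, 0.1).
    """
    rng = generator(seed)
    n_pops = len(EUROPEAN_LABELS)
    collected: list[np.ndarray] = []
    n_have = 0
    while n_have < n_snps:
        batch = max(2 * (n_snps - n_have), 1000)
        p = rng.uniform(0.05, 0.95, size=batch)
        high = rng.random(batch) < high_fst_proportion
        base = np.where(high, fst_components[1], fst_components[0])
        fst = base * rng.uniform(0.5, 1.5, size=batch)  # jitter within component
        a = p * (1.0 - fst) / fst
        b = (1.0 - p) * (1.0 - fst) / fst
        freqs = rng.beta(a[:, None], b[:, None], size=(batch, n_pops))
        minor = np.minimum(freqs, 1.0 - freqs)
        observed = np.all(minor > 1.0 / 180.0, axis=1)  # ~90 reference samples/pop
        panel_maf = np.minimum(freqs.mean(axis=1), 1.0 - freqs.mean(axis=1)) > 0.05
        max_freq = minor.max(axis=1) >= 0.1
        ok = observed & panel_maf & max_freq
        collected.append(freqs[ok])
        n_have += int(ok.sum())
    freqs = np.concatenate(collected)[:n_snps]
    return FrequencyPanel(
        pop_labels=EUROPEAN_LABELS,
        freqs=freqs,
        phenotype_means=np.asarray(EUROPEAN_PHENOTYPE_MEANS),
        candidate_mafs=(
            np.asarray(EUROPEAN_RARE_CANDIDATE_MAFS) if rare_candidate else None
        ),
    )


def simulate_panel_genotypes(
    panel: FrequencyPanel, pop_of_individual, seed: SeedLike
) -> AncestryPanel:
    """Draw HWE genotypes for each individual from its population's frequencies.

    ``pop_of_individual`` holds either population labels from the panel
    or 1-based population indices.  Each genotype is the sum of two
    independent Bernoulli(freq) allele draws, i.e. Binomial(2, freq).
    """
    pops = np.asarray(pop_of_individual)
    if pops.dtype.kind in "iu":
        col = pops - 1
        if np.any((col < 0) | (col >= len(panel.pop_labels))):
            raise ValueError("population index outside the panel")
    else:
        lookup = {label: k for k, label in enumerate(panel.pop_labels)}
        try:
            col = np.array([lookup[p] for p in pops])
        except KeyError as exc:
            raise ValueError(f"unknown population label {exc.args[0]!r}") from None
    rng = generator(seed)
    freq = panel.freqs[:, col].T  # (n_individuals, n_snps)
    u = rng.random((2, *freq.shape))
    genotypes = (u[0] < freq).view(np.int8) + (u[1] < freq).view(np.int8)
    return AncestryPanel(
        genotypes=genotypes, subpop_freqs=panel, populations=pops
    )


def standardize_genotypes(genotypes) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale a 0/1/2 genotype matrix the EIGENSTRAT way.

    Each SNP column is centered at its sample mean and divided by
    ``sqrt(ptilde * (1 - ptilde))`` with
    ``ptilde = (1 + sum_k g_k) / (2 + 2n)``; the pseudo-count keeps the
    scale strictly positive so monomorphic columns survive (as all-zero
    centered columns).  Returns ``(standardized, ptilde)``.
    """
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    ptilde = (1.0 + g.sum(axis=0)) / (2.0 + 2.0 * n)
    scale = np.sqrt(ptilde * (1.0 - ptilde))
    return (g - g.mean(axis=0)) / scale, ptilde


def compute_pcs(standardized, k: int = 5, random_state: int = 0) -> np.ndarray:
    """Scores of the top-k principal components of a standardized matrix.

    Small problems use an exact SVD; large ones a randomized truncated
    SVD (deterministic for a fixed ``random_state``).  Scores are
    ``U * S`` ordered by nonincreasing singular value; component signs
    are arbitrary.
    """
    z = np.asarray(standardized, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need a 2-d matrix with at least 2 individuals")
    if not 1 <= k <= min(z.shape):
        raise ValueError(f"k = {k} exceeds matrix dimensions {z.shape}")
    if min(z.shape) <= 200:
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        return u[:, :k] * s[:k]
    u, s, _ = randomized_svd(
        z, n_components=k, n_iter=7, random_state=random_state
    )
    return u * s


def build_ancestry_panel(
    panel: FrequencyPanel, pop_of_individual, seed: SeedLike, k: int = 5
) -> AncestryPanel:
    """Simulate genotypes, standardize, and attach top-k PC scores."""
    ap = simulate_panel_genotypes(panel, pop_of_individual, seed)
    ap.standardized, ap.est_freq = standardize_genotypes(ap.genotypes)
    ap.pc_scores = compute_pcs(ap.standardized, k=k)
    return ap


def _allele_count_tables(genotypes: np.ndarray, pops: np.ndarray):
    """Per-SNP 2xK allele-count tables, vectorized: (counts of allele 1, allele 0)."""
    labels = np.unique(pops)
    counts1 = np.stack(
        [genotypes[pops == lab].sum(axis=0) for lab in labels], axis=1
    ).astype(float)
    sizes = np.array([(pops == lab).sum() for lab in labels], dtype=float)
    counts0 = 2.0 * sizes[None, :] - counts1
    return counts1, counts0, sizes


def _chisq_neglog10_p(counts1: np.ndarray, counts0: np.ndarray) -> np.ndarray:
    """Vectorized chi-square -log10 p for per-SNP 2xK allele tables (screen)."""
    total1 = counts1.sum(axis=1, keepdims=True)
    total = counts1 + counts0
    grand = total.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = total * total1 / grand
        e0 = total - e1
        stat = np.nansum((counts1 - e1) ** 2 / e1 + (counts0 - e0) ** 2 / e0, axis=1)
    df = counts1.shape[1] - 1
    logsf = stats.chi2.logsf(stat, df)
    return -logsf / math.log(10.0)


def _fisher_neglog10_p(
    obs1: np.ndarray, obs0: np.ndarray, rng, mc_reps: int
) -> float:
    """Fisher exact -log10 p for one 2xK allele table.

    2x2 tables use the exact hypergeometric test; wider tables use a
    probability-ordering Monte Carlo over margin-preserving tables
    (``mc_reps`` samples, add-one estimator so the smallest reportable
    p is 1 / (mc_reps + 1)).
    """
    table = np.vstack([obs1, obs0]).astype(np.int64)
    if table.shape[1] == 2:
        p = stats.fisher_exact(table)[1]
        return -math.log10(max(p, 1e-300))
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    dist = stats.random_table(row, col)
    sampled = dist.rvs(mc_reps, random_state=rng)
    # conditional P(T) is proportional to 1 / prod(x_ij!), so order tables
    # by sum of log-factorials (larger sum = less probable)
    logprob_obs = -gammaln(table + 1.0).sum()
    logprob_sim = -gammaln(sampled + 1.0).sum(axis=(1, 2))
    hits = int(np.sum(logprob_sim <= logprob_obs + 1e-9))
    p = (1.0 + hits) / (1.0 + mc_reps)
    return -math.log10(p)


def select_confounded_candidate(
    genotypes,
    pop_labels,
    threshold: float = 4.0,
    seed: SeedLike = 0,
    mc_reps: int = 19999,
) -> int:
    """Pick a stratification-confounded SNP by Fisher exact test.

    Builds the per-SNP alleles x populations count table from the
    retained sample and returns a uniformly chosen SNP index among
    those whose Fisher exact test of equal allele frequencies has
    ``-log10 p > threshold``.  A vectorized chi-square screen (two
    orders of magnitude of slack) limits the exact computation to
    plausible candidates; candidates are then visited in uniformly
    random order and the first confirmed passer returned, which is a
    uniform draw from the passing set.

    Raises
    ------
    CandidateSelectionError
        If no SNP exceeds the threshold (regenerate the panel).
    """
    genotypes = np.asarray(genotypes)
    pops = np.asarray(pop_labels)
    if len(np.unique(pops)) < 2:
        raise ValueError("at least two populations must be present")
    rng = generator(seed)
    counts1, counts0, _ = _allele_count_tables(genotypes, pops)
    polymorphic = (counts1.sum(axis=1) > 0) & (counts0.sum(axis=1) > 0)
    screen = _chisq_neglog10_p(counts1, counts0) > threshold - 2.0
    candidates = np.flatnonzero(polymorphic & screen)
    if candidates.size == 0:
        raise CandidateSelectionError(
            f"no SNP passes the -log10 p > {threshold} screen"
        )
    for idx in rng.permutation(candidates):
        neglog = _fisher_neglog10_p(counts1[idx], counts0[idx], rng, mc_reps)
        if neglog > threshold:
            return int(idx)
    raise CandidateSelectionError(
        f"no SNP exceeds the Fisher -log10 p > {threshold} threshold"
    )
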