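# Methods

## The problem

Extreme phenotype sampling (EPS) genotypes only the individuals in the
top and bottom tails of a continuous phenotype measured on a large
cohort, then tests whether extreme-group membership is associated with
a candidate SNP.  The design buys power per genotyped sample, but any
confounder that shifts both the phenotype distribution and the allele
frequency — population stratification being the canonical example —
induces a *true* allele-frequency difference between the extreme
groups.  The tests then reject a null that is false for an
uninteresting reason, and the false positive rate climbs far above the
nominal level.  This package quantifies that inflation by simulation
and closed-form calculation, compares EPS against random-sample and
case-control-like designs, and verifies that adjusting a logistic
regression for the top principal components (PCs) of a genome-wide
genotype matrix restores the nominal type-1 error.

## The model

A cohort of N individuals is a two-component mixture: a fraction
omega_1 comes from population 1 and omega_2 = 1 - omega_1 from
population 2.  Within population i the phenotype is N(mu_i, sigma^2)
(default mu_2 = -mu_1, sigma^2 = 1) and the candidate SNP, with allele
A at frequency p_i, is in Hardy-Weinberg equilibrium.  Genotype and
phenotype are independent given population — the null of no causal
effect — so the marginal genotype probabilities are mixtures, e.g.
P(AA) = omega_1 p_1^2 + omega_2 p_2^2, the cohort phenotype CDF is
F(y) = omega_1 Phi((y - mu_1)/sigma) + omega_2 Phi((y - mu_2)/sigma),
and the phenotype CDF *conditional on genotype* is the same
two-component mixture with weights P(population | genotype) obtained
by Bayes' rule.  Genotypes are coded as counts of the a allele
(AA = 0, Aa = 1, aa = 2).

## Analytic EPS false positive rate

The rejection probability under EPS has a large-sample closed form,
built here from the conditional distributions above:

1. tail thresholds are the c and 1 - c mixture quantiles (c = tail
   fraction, default 0.1), found by bisection/Brent within the
   component-quantile bracket to ~1e-12;
2. the genotype distribution within each tail is
   P(g | tail) = P(g) P(Y in tail | g) / c;
3. the expected 2x3 extreme-group table has n = round(cN) individuals
   per tail;
4. the matching test statistic evaluated on that expected table is the
   noncentrality parameter, and the rejection probability is the upper
   tail of the noncentral chi-square at the nominal critical value —
   1 df for the trend and pooled two-proportion statistics, 2 df for
   the codominant Pearson statistic (reduced if a genotype column has
   zero probability).

This construction is exact in the no-confounding limits (it returns
alpha whenever p_1 = p_2 or mu_1 = mu_2) and is validated against the
Monte-Carlo pipeline (within 3 Monte-Carlo standard errors on an audit
grid; `analysis/05_analytic_vs_monte_carlo.py`).  It ignores the
multinomial fluctuation of the realized tail genotype counts around
their expectation and the rank-based (rather than fixed-threshold)
tail selection; both effects are O(1/sqrt(N)) and invisible at the
cohort sizes used.

## Simulation pipeline

* **Cohorts** (`epstrat.cohorts`): population sizes are fixed at
  round(omega_1 N), not binomial — the mixing proportion describes the
  cohort composition, and fixed counts reduce Monte-Carlo variance
  without changing the estimand.  Phenotypes and genotypes are drawn
  independently within population.
* **Designs** (`epstrat.designs`): EPS takes exactly the n highest and
  n lowest phenotypes (rank-based, stable tie order); the random
  design draws 2n without replacement and keeps the continuous
  phenotype; the case-control design takes the top n as cases and n
  controls from the remaining N - n.  The upper extreme is coded 1 in
  every binary analysis.
* **Tests** (`epstrat.assoc`): Pearson chi-square (codominant),
  Cochran-Armitage trend with scores 0/1/2 (additive) and pooled
  two-proportion z (recessive) for the binary designs; one-way ANOVA
  (codominant, recessive) and linear regression (additive) for the
  random design; logistic-regression likelihood ratio tests (additive:
  1 df numeric coding; codominant: 2 df indicator coding) for the PC
  experiments.  No continuity corrections anywhere, which keeps
  z^2 identical to the 2x2 Pearson statistic and the squared trend
  statistic identical to the logistic score test.  The trend statistic
  uses the score-test (total-n) variance.
* **Degenerate cells**: empty genotype columns are dropped with the df
  reduced; a test that is undefined (monomorphic SNP, empty group,
  non-converged or separated logistic fit — iteration cap 100,
  deviance tolerance 1e-8) returns an invalid result that counts as a
  non-rejection and is tallied in the output.  This is conservative;
  the tallies are reported so the choice is auditable.
* **Rates** (`epstrat.experiments`): each cell reports the rejection
  proportion at alpha = 0.05 with its binomial standard error
  sqrt(fpr (1 - fpr) / reps).  Within a replicate the same cohort is
  subsampled by all requested designs, sharpening design contrasts.

## Ancestry simulation and PC correction

Ancestry SNP frequencies come from the Balding-Nichols model: per SNP
an ancestral frequency p ~ U(0.1, 0.9), then one beta draw per
population with shapes p(1-Fst)/Fst and (1-p)(1-Fst)/Fst, so the
between-population frequency variance is p(1-p)Fst (default
Fst = 0.01, deliberately high for continental European populations to
make the correction problem hard).  Genotypes are simulated under HWE
*for the retained EPS subsample only*, since that is the sample whose
structure the PCs must capture (and the standardization formula sums
over the subsample).  Each SNP column is centered and scaled by
sqrt(ptilde (1 - ptilde)) with ptilde = (1 + sum g) / (2 + 2n); the
pseudo-count keeps monomorphic columns finite.  Top-5 PC scores come
from an exact SVD for small matrices and a seeded randomized truncated
SVD for large ones (scores U*S; signs arbitrary; orthogonality holds
to machine precision either way).

The four-population panel mode replaces Balding-Nichols with a fixed
synthetic European-like frequency panel (TSI/IBS/GBR/FIN labels,
phenotype means 0.3/0.2/0/-0.1).  Real reference panels mix
barely-differentiated SNPs with a strongly differentiated minority, so
per-SNP Fst is drawn from a two-component mixture (95% of mass near
0.004, 5% near 0.05, each jittered uniformly +/-50%) and SNPs are
filtered to panel-wide MAF > 0.05, minor allele present in every
population (frequency > 1/180, the resolution of a ~90-sample
reference population), and maximum per-population MAF >= 0.1.  The
confounded candidate SNP is the one a practitioner would pick: a
uniformly random SNP whose Fisher exact test of equal allele
frequencies across populations has -log10 p > 4.  For K > 2
populations no exact 2xK Fisher implementation is available in the
stack, so the p-value uses probability-ordering Monte Carlo over
margin-preserving tables (19,999 samples, add-one estimator; smallest
reportable p = 5e-5, comfortably below the threshold), behind a
vectorized chi-square prescreen with two orders of magnitude of slack.
Candidates are visited in uniformly random order and the first
confirmed passer returned, which is a uniform draw from the passing
set.

## What the generator does and does not emulate

The synthetic data reproduce the study conditions exactly as stated:
discrete subpopulations, independent SNPs, HWE within population, no
genotyping error, unrelated individuals, a single non-causal candidate
SNP.  Real cohorts add admixture (continuous ancestry), linkage
disequilibrium, relatedness and many weakly causal variants; passing
tests here show the designs' *relative* confounding behavior and the
PC correction's adequacy under clean stratification, not performance
on any particular real dataset.

## Problem sizes and reproducibility

Paper-scale runs (10,000 replicates for the design grids, 2,000-5,000
for the PC arms, 5,000 ancestry SNPs) are available through the
`--reps`/`--snps` flags and function arguments.  The package's
desk-scale defaults — used by `scripts/acceptance.py` and the test
suite — are 2,000-4,000 replicates for the design grids, 1,000-2,000
for the logistic arms, and 2,000 ancestry SNPs, sizes at which every
reproduced quantity's Monte-Carlo standard error is well inside the
comparison tolerance.  All randomness flows from one root seed through
`numpy.random.SeedSequence.spawn`, one child stream per replicate, so
any replicate is reproducible in isolation and extending a run leaves
its prefix unchanged.

## Known limitations

* The closed-form arm covers two subpopulations only; the K-population
  panel mode is simulation-only.
* The analytic rate is asymptotic in n; at very small tails (n below a
  few dozen) the discreteness of the tables matters and only the
  Monte-Carlo estimate should be used.
* The Italy/France preset uses the stated literature parameters
  verbatim; with a within-population variance of 6 the two height
  distributions are ~1.3 SD apart, which places every confounded rate
  near 1 (see the README's discussion of this scenario).
* Power under true genetic effects is out of scope; every simulation
  here runs under the null of no causal effect.
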