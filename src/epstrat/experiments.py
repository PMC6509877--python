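"""Scenario grids, false-positive-rate estimation, and result tables.

Each experiment simulates many independent cohorts under the null of
no causal effect, draws the subsamples, runs the matching association
test per genetic model, and reports the rejection proportion per
(scenario, design, genetic model) cell as the false-positive-rate
estimate with its binomial Monte-Carlo standard error.

Within a replicate the same cohort is subsampled by every requested
design, which sharpens design contrasts without biasing any single
cell.  Replicates use independently seeded child streams derived from
one root seed, so results are reproducible per replicate and the first
half of a doubled run is identical to the shorter run.  Invalid or
degenerate tests count as non-rejections and are tallied separately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.random import default_rng

from ._rng import SeedLike, seed_sequence
from .ancestry import (
    BaldingNicholsParams,
    CandidateSelectionError,
    FrequencyPanel,
    balding_nichols_freqs,
    build_ancestry_panel,
    select_confounded_candidate,
)
from .assoc import (
    anova_test,
    build_table,
    cochran_armitage,
    linear_trend_test,
    logistic_lrt,
    pearson_chisq,
    two_proportion_test,
)
from .cohorts import (
    preset_italy_france,
    simulate_cohort,
    simulate_stratified_cohort,
)
from .designs import (
    DESIGNS,
    DesignSample,
    case_control_sample,
    eps_sample,
    random_sample,
)
from .mixture import GENETIC_MODELS, ScenarioParams

ADJUSTMENTS = ("unadjusted", "pc_adjusted")

_BINARY_TEST = {
    "codominant": ("pearson_chisq", pearson_chisq),
    "additive": ("cochran_armitage", cochran_armitage),
    "recessive": ("two_proportion", two_proportion_test),
}
_RANDOM_TEST_NAME = {
    "codominant": "anova",
    "additive": "linear_regression",
    "recessive": "anova",
}


@dataclass
class FprEstimate:
    """Per-cell false-positive-rate estimate."""

    scenario: dict
    design: str
    genetic_model: str
    test: str
    n_reps: int
    n_rejections: int
    n_invalid: int

    def __post_init__(self) -> None:
        if self.n_rejections + self.n_invalid > self.n_reps:
            raise ValueError("rejections + invalid exceed replicate count")

    @property
    def fpr(self) -> float:
        return self.n_rejections / self.n_reps

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.fpr * (1.0 - self.fpr) / self.n_reps)

    def to_row(self) -> dict:
        row = dict(self.scenario)
        row.update(
            design=self.design,
            genetic_model=self.genetic_model,
            test=self.test,
            n_reps=self.n_reps,
            n_rejections=self.n_rejections,
            n_invalid=self.n_invalid,
            fpr=self.fpr,
            mc_se=self.mc_se,
        )
        return row


def _apply_test(sample: DesignSample, model: str):
    """Run the design-appropriate test for one genetic model."""
    if sample.design == "random":
        if model == "additive":
            return linear_trend_test(sample.phenotype, sample.genotype)
        category = sample.genotype if model == "codominant" else (
            (sample.genotype == 2).astype(int)
        )
        return anova_test(sample.phenotype, category)
    table = build_table(sample, model)
    return _BINARY_TEST[model][1](table)


def _test_name(design: str, model: str) -> str:
    if design == "random":
        return _RANDOM_TEST_NAME[model]
    return _BINARY_TEST[model][0]


def run_scenario(
    params: ScenarioParams,
    designs: Sequence[str] = DESIGNS,
    models: Sequence[str] = GENETIC_MODELS,
    n_reps: int = 10000,
    seed: SeedLike = 0,
) -> list[FprEstimate]:
    """Estimate the false positive rate for one scenario.

    Per replicate: simulate the cohort, draw every requested design's
    subsample from it, and test each genetic model at level
    ``params.alpha``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    for d in designs:
        if d not in DESIGNS:
            raise ValueError(f"unknown design {d!r}")
    for m in models:
        if m not in GENETIC_MODELS:
            raise ValueError(f"unknown genetic model {m!r}")
    n = params.n_extreme
    rejections = {(d, m): 0 for d in designs for m in models}
    invalid = {(d, m): 0 for d in designs for m in models}
    for child in seed_sequence(seed).spawn(n_reps):
        rng = default_rng(child)
        cohort = simulate_cohort(params, rng)
        for design in designs:
            if design == "eps":
                sample = eps_sample(cohort, n)
            elif design == "random":
                sample = random_sample(cohort, 2 * n, rng)
            else:
                sample = case_control_sample(cohort, n, rng)
            for model in models:
                result = _apply_test(sample, model)
                if result.rejects(params.alpha):
                    rejections[design, model] += 1
                elif not result.valid:
                    invalid[design, model] += 1
    scenario = params.to_dict()
    return [
        FprEstimate(
            scenario=scenario,
            design=d,
            genetic_model=m,
            test=_test_name(d, m),
            n_reps=n_reps,
            n_rejections=rejections[d, m],
            n_invalid=invalid[d, m],
        )
        for d in designs
        for m in models
    ]


def run_table1_grid(
    n_reps: int = 10000,
    seed: SeedLike = 0,
    omegas: Sequence[float] = (0.3, 0.4, 0.5, 0.6, 0.7),
    freqs: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    mus: Sequence[float] = (0.1, 0.2),
    designs: Sequence[str] = DESIGNS,
    models: Sequence[str] = GENETIC_MODELS,
    N: int = 5000,
) -> list[FprEstimate]:
    """Full cross of the common-variant parameter grid.

    One independent child seed per scenario; within a scenario the
    replicate streams are shared across designs and models.
    """
    scenarios = [
        ScenarioParams(omega1=w, mu1=mu, p1=p1, p2=p2, N=N)
        for w in omegas
        for mu in mus
        for p1 in freqs
        for p2 in freqs
    ]
    children = seed_sequence(seed).spawn(len(scenarios))
    out: list[FprEstimate] = []
    for params, child in zip(scenarios, children):
        out.extend(run_scenario(params, designs, models, n_reps, child))
    return out


def run_italy_france_grid(
    n_reps: int = 10000,
    seed: SeedLike = 0,
    omegas: Sequence[float] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    designs: Sequence[str] = ("eps", "random"),
    models: Sequence[str] = GENETIC_MODELS,
) -> list[FprEstimate]:
    """Realistic European scenario across population mixing proportions."""
    children = seed_sequence(seed).spawn(len(omegas))
    out: list[FprEstimate] = []
    for omega, child in zip(omegas, children):
        out.extend(
            run_scenario(preset_italy_france(omega), designs, models, n_reps, child)
        )
    return out


def run_sample_size_scaling(
    n_reps: int = 10000,
    seed: SeedLike = 0,
    cohort_sizes: Sequence[int] = (10000, 20000, 50000),
    designs: Sequence[str] = ("eps", "random"),
    models: Sequence[str] = GENETIC_MODELS,
) -> list[FprEstimate]:
    """Mild-stratification scenario across growing cohort sizes.

    omega1 = 0.1, mu1 = 0.1, p1 = 0.7, p2 = 0.6, 10% tails — the EPS
    subsample grows with the cohort (2,000 / 4,000 / 10,000 retained),
    and the inflation grows with it.
    """
    children = seed_sequence(seed).spawn(len(cohort_sizes))
    out: list[FprEstimate] = []
    for N, child in zip(cohort_sizes, children):
        params = ScenarioParams(omega1=0.1, mu1=0.1, p1=0.7, p2=0.6, N=int(N))
        out.extend(run_scenario(params, designs, models, n_reps, child))
    return out


def _pc_replicate_balding_nichols(
    params: ScenarioParams,
    rng,
    n_snps: int,
    fst: float,
    n_pcs: int,
    need_pcs: bool,
):
    cohort = simulate_cohort(params, rng)
    sample = eps_sample(cohort, params.n_extreme)
    pcs = None
    if need_pcs:
        bn = BaldingNicholsParams(n_snps=n_snps, fst=fst)
        panel = balding_nichols_freqs(bn, 2, rng)
        pops = cohort.population[sample.indices]
        ap = build_ancestry_panel(panel, pops, rng, k=n_pcs)
        pcs = ap.pc_scores
    return sample.group, sample.genotype, pcs


def _pc_replicate_panel(
    panel: FrequencyPanel,
    rng,
    N: int,
    tail_fraction: float,
    sigma2: float,
    n_pcs: int,
    fisher_threshold: float,
):
    K = len(panel.pop_labels)
    means = panel.phenotype_means
    if means is None:
        raise ValueError("panel mode requires phenotype_means on the panel")
    cohort = simulate_stratified_cohort(
        weights=np.full(K, 1.0 / K), means=means, sigma2=sigma2, N=N, seed=rng
    )
    n = int(round(tail_fraction * N))
    sample = eps_sample(cohort, n)
    pops = cohort.population[sample.indices]
    ap = build_ancestry_panel(panel, pops, rng, k=n_pcs)
    if panel.candidate_mafs is not None:
        mafs = np.asarray(panel.candidate_mafs, dtype=float)
        genotype = rng.binomial(2, mafs[pops - 1])
    else:
        idx = select_confounded_candidate(
            ap.genotypes, pops, threshold=fisher_threshold, seed=rng
        )
        genotype = np.asarray(ap.genotypes[:, idx], dtype=np.int64)
    return sample.group, genotype, ap.pc_scores


def run_pc_correction_experiment(
    mode: str = "balding_nichols",
    mu_grid: Sequence[float] = (0.1, 0.15, 0.175, 0.2),
    candidate_mafs: tuple[float, float] | None = None,
    n_reps: int = 2000,
    seed: SeedLike = 0,
    n_ancestry_snps: int = 5000,
    fst: float = 0.01,
    models: Sequence[str] = ("codominant", "additive"),
    adjustments: Sequence[str] = ADJUSTMENTS,
    n_pcs: int = 5,
    N: int = 5000,
    tail_fraction: float = 0.1,
    alpha: float = 0.05,
    panel: FrequencyPanel | None = None,
    fisher_threshold: float = 4.0,
) -> list[FprEstimate]:
    """Logistic-regression LRT false positive rates with/without PC covariates.

    ``balding_nichols`` mode: two equal subpopulations, candidate SNP
    "A" frequencies (0.5, 0.9) — or minor-allele frequencies
    ``candidate_mafs`` for the rare-variant arm — phenotype means
    ``(mu, -mu)`` per ``mu_grid`` entry.  Per replicate the EPS
    extremes are retained, ancestry SNPs are simulated *for the
    retained subsample only*, standardized, and the top ``n_pcs`` PC
    scores enter the adjusted model as fixed effects.

    ``panel`` mode: a fixed four-population frequency panel (see
    :func:`epstrat.ancestry.synthetic_european_panel`) supplies both
    the ancestry SNPs and, unless the panel carries rare-candidate
    MAFs, the Fisher-selected confounded candidate SNP; ``mu_grid`` is
    ignored in favor of the panel's phenotype means.
    """
    if mode not in ("balding_nichols", "panel"):
        raise ValueError(f"unknown mode {mode!r}")
    for adj in adjustments:
        if adj not in ADJUSTMENTS:
            raise ValueError(f"unknown adjustment {adj!r}")
    need_pcs = "pc_adjusted" in adjustments or mode == "panel"
    if mode == "panel":
        if panel is None:
            raise ValueError("panel mode requires a FrequencyPanel")
        scenarios: list[tuple[dict, ScenarioParams | None]] = [
            (
                {
                    "mode": "panel",
                    "pops": ",".join(panel.pop_labels),
                    "n_ancestry_snps": panel.n_snps,
                    "N": N,
                    "tail_fraction": tail_fraction,
                    "alpha": alpha,
                    "candidate": (
                        "rare_mafs"
                        if panel.candidate_mafs is not None
                        else "fisher_selected"
                    ),
                },
                None,
            )
        ]
    else:
        scenarios = []
        for mu in mu_grid:
            if candidate_mafs is None:
                p1, p2 = 0.5, 0.9
            else:
                p1, p2 = 1.0 - candidate_mafs[0], 1.0 - candidate_mafs[1]
            params = ScenarioParams(
                omega1=0.5, mu1=mu, p1=p1, p2=p2, N=N,
                tail_fraction=tail_fraction, alpha=alpha,
            )
            info = params.to_dict()
            info.update(mode=mode, n_ancestry_snps=n_ancestry_snps, fst=fst)
            scenarios.append((info, params))

    out: list[FprEstimate] = []
    scenario_seeds = seed_sequence(seed).spawn(len(scenarios))
    for (info, params), sseed in zip(scenarios, scenario_seeds):
        cells = {
            (adj, m): [0, 0] for adj in adjustments for m in models
        }  # [rejections, invalid]
        for child in sseed.spawn(n_reps):
            rng = default_rng(child)
            try:
                if mode == "balding_nichols":
                    group, genotype, pcs = _pc_replicate_balding_nichols(
                        params, rng, n_ancestry_snps, fst, n_pcs, need_pcs
                    )
                else:
                    group, genotype, pcs = _pc_replicate_panel(
                        panel, rng, N, tail_fraction, 1.0, n_pcs, fisher_threshold
                    )
            except CandidateSelectionError:
                for cell in cells.values():
                    cell[1] += 1
                continue
            for adj in adjustments:
                covariates = pcs if adj == "pc_adjusted" else None
                for m in models:
                    result = logistic_lrt(group, genotype, covariates, m)
                    if result.rejects(alpha):
                        cells[adj, m][0] += 1
                    elif not result.valid:
                        cells[adj, m][1] += 1
        for adj in adjustments:
            for m in models:
                rej, inv = cells[adj, m]
                out.append(
                    FprEstimate(
                        scenario=info,
                        design="eps",
                        genetic_model=m,
                        test=f"logistic_lrt_{adj}",
                        n_reps=n_reps,
                        n_rejections=rej,
                        n_invalid=inv,
                    )
                )
    return out


def estimates_to_frame(estimates: Iterable[FprEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.to_row() for e in estimates])


def wide_table(
    frame: pd.DataFrame,
    index: Sequence[str] = ("omega1",),
    columns: Sequence[str] = ("design", "genetic_model"),
    values: str = "fpr",
) -> pd.DataFrame:
    """Wide rendering of a long estimate table (one row per scenario)."""
    return frame.pivot_table(
        index=list(index), columns=list(columns), values=values
    )


def emit_tables(
    estimates: Sequence[FprEstimate],
    out_dir: str | Path,
    label: str = "results",
    seed: int | None = None,
    wide_index: Sequence[str] | None = ("omega1",),
) -> dict[str, Path]:
    """Write long CSV, wide CSV and a JSON run manifest; returns the paths."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to emit")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = estimates_to_frame(estimates)
    paths = {"long": out_dir / f"{label}_long.csv"}
    frame.to_csv(paths["long"], index=False)
    if wide_index is not None and all(c in frame.columns for c in wide_index):
        paths["wide"] = out_dir / f"{label}_wide.csv"
        wide_table(frame, index=wide_index).to_csv(paths["wide"])
    manifest = {
        "label": label,
        "root_seed": seed,
        "n_cells": len(estimates),
        "n_reps": sorted({e.n_reps for e in estimates}),
        "total_invalid": int(sum(e.n_invalid for e in estimates)),
    }
    paths["manifest"] = out_dir / f"{label}_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def load_scenario_config(path: str | Path) -> list[ScenarioParams]:
    """Read a scenario grid from a YAML/JSON config file.

    The file maps ScenarioParams field names to a value or a list of
    values; the grid is the full cross product.  Example::

        omega1: [0.3, 0.5]
        mu1: 0.1
        p1: [0.5, 0.7]
        p2: 0.7
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("scenario config must be a mapping")
    keys = list(raw)
    values = [v if isinstance(v, list) else [v] for v in raw.values()]
    grids: list[ScenarioParams] = []
    idx = [0] * len(keys)
    while True:
        grids.append(
            ScenarioParams(**{k: values[i][idx[i]] for i, k in enumerate(keys)})
        )
        for i in reversed(range(len(keys))):
            idx[i] += 1
            if idx[i] < len(values[i]):
                break
            idx[i] = 0
        else:
            break
    return grids
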