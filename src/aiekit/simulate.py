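"""Synthetic cohort generators and the coverage/bias/variance evaluation
harness.

Two generative designs are provided.  The null design samples outcome,
genotypes and covariates mutually independently, so every genetic estimand
is exactly zero.  The confounded design generates data by ancestral
sampling: principal components (and outcome-only covariates) first, then
genotypes from a per-variant two-stage binomial-logistic model given the
PCs, then the outcome from a declared mean function supporting per-copy or
per-genotype effects and k-way interaction terms.  Ground truth for the
confounded design is computed by Monte Carlo evaluation of the mean
function at the estimand vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .estimands import Contrast, EstimandSpec, estimand_vertices
from .nuisance import LearnerSpec
from .targeting import EmptySupportError, estimate

__all__ = [
    "NullScenario",
    "VariantModel",
    "OutcomeModel",
    "ConfoundedScenario",
    "simulate_null",
    "simulate_confounded",
    "monte_carlo_truth",
    "EvaluationGrid",
    "evaluate_cell",
    "evaluate_grid",
    "ate_spec",
    "aie_spec",
]


def ate_spec(
    outcome="Y", treatment="A1", baseline=0, target=1,
    confounders=(), covariates=(), family="gaussian",
) -> EstimandSpec:
    return EstimandSpec(
        kind="ate", outcome=outcome, treatments=(treatment,),
        contrast=Contrast(pairs=((baseline, target),)),
        confounders=tuple(confounders), covariates=tuple(covariates),
        outcome_family=family,
    )


def aie_spec(
    outcome="Y", treatments=("A1", "A2"), pairs=(((0, 1)), ((0, 1))),
    confounders=(), covariates=(), family="gaussian",
) -> EstimandSpec:
    return EstimandSpec(
        kind="aie", outcome=outcome, treatments=tuple(treatments),
        contrast=Contrast(pairs=tuple(tuple(p) for p in pairs)),
        confounders=tuple(confounders), covariates=tuple(covariates),
        outcome_family=family,
    )


@dataclass(frozen=True)
class NullScenario:
    """Outcome, genotypes and covariates mutually independent; all genetic
    effects are exactly zero by construction."""

    n: int
    mafs: Mapping[str, float] = field(default_factory=lambda: {"A1": 0.3})
    outcome: str = "gaussian"  # or "binomial"
    case_fraction: float = 0.1
    n_pcs: int = 2
    n_covariates: int = 0


def simulate_null(scenario: NullScenario, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n = scenario.n
    cols = {}
    for name, maf in scenario.mafs.items():
        cols[name] = rng.binomial(2, maf, size=n)
    if scenario.outcome == "binomial":
        cols["Y"] = rng.binomial(1, scenario.case_fraction, size=n)
    else:
        cols["Y"] = rng.standard_normal(n)
    for j in range(scenario.n_pcs):
        cols[f"PC{j + 1}"] = rng.standard_normal(n)
    for j in range(scenario.n_covariates):
        cols[f"C{j + 1}"] = rng.standard_normal(n)
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class VariantModel:
    """Two-stage binomial-logistic genotype model: allele probability is
    expit(intercept + PCs . pc_weights); dosage ~ Binomial(2, p)."""

    intercept: float
    pc_weights: tuple = ()


@dataclass(frozen=True)
class OutcomeModel:
    """Declared conditional mean of the outcome.

    main_effects maps a variant to either a per-copy slope (scalar) or a
    length-3 per-genotype effect vector (non-linear allelic effects).
    interactions lists (variant-name tuple, coefficient) terms multiplying
    the product of copy numbers.  Binary outcomes pass the mean through a
    logistic link.
    """

    intercept: float = 0.0
    main_effects: Mapping[str, object] = field(default_factory=dict)
    interactions: tuple = ()  # ((names...), coefficient)
    pc_effects: tuple = ()
    covariate_effects: tuple = ()
    noise_sd: float = 1.0
    binary: bool = False


@dataclass(frozen=True)
class ConfoundedScenario:
    n: int
    variants: Mapping[str, VariantModel]
    outcome: OutcomeModel
    n_pcs: int = 2
    n_covariates: int = 0


def _main_effect(effect, copies: np.ndarray) -> np.ndarray:
    effect_arr = np.asarray(effect, dtype=float)
    if effect_arr.ndim == 0:
        return float(effect_arr) * copies
    return effect_arr[copies.astype(int)]


def _mean_function(
    scenario: ConfoundedScenario,
    genotypes: Mapping[str, np.ndarray],
    pcs: np.ndarray,
    covs: np.ndarray,
) -> np.ndarray:
    om = scenario.outcome
    n = pcs.shape[0]
    mu = np.full(n, om.intercept, dtype=float)
    for name, eff in om.main_effects.items():
        mu += _main_effect(eff, np.asarray(genotypes[name], dtype=float))
    for names, coef in om.interactions:
        prod = np.ones(n)
        for name in names:
            prod = prod * np.asarray(genotypes[name], dtype=float)
        mu += coef * prod
    if om.pc_effects:
        mu += pcs[:, : len(om.pc_effects)] @ np.asarray(om.pc_effects, dtype=float)
    if om.covariate_effects:
        mu += covs[:, : len(om.covariate_effects)] @ np.asarray(
            om.covariate_effects, dtype=float
        )
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite outcome mean; check scenario coefficients")
    return mu


def _sample_background(scenario: ConfoundedScenario, n: int, rng):
    pcs = rng.standard_normal((n, scenario.n_pcs))
    covs = rng.standard_normal((n, scenario.n_covariates))
    return pcs, covs


def simulate_confounded(scenario: ConfoundedScenario, seed: int) -> pd.DataFrame:
    """Ancestral sampling: (PCs, C) -> A -> Y."""
    rng = np.random.default_rng(seed)
    n = scenario.n
    pcs, covs = _sample_background(scenario, n, rng)
    genotypes = {}
    for name, vm in scenario.variants.items():
        eta = np.full(n, vm.intercept, dtype=float)
        if vm.pc_weights:
            eta += pcs[:, : len(vm.pc_weights)] @ np.asarray(vm.pc_weights, dtype=float)
        genotypes[name] = rng.binomial(2, expit(eta))
    mu = _mean_function(scenario, genotypes, pcs, covs)
    if scenario.outcome.binary:
        y = rng.binomial(1, expit(mu))
    else:
        y = mu + scenario.outcome.noise_sd * rng.standard_normal(n)
    cols = {"Y": y}
    cols.update(genotypes)
    for j in range(scenario.n_pcs):
        cols[f"PC{j + 1}"] = pcs[:, j]
    for j in range(scenario.n_covariates):
        cols[f"C{j + 1}"] = covs[:, j]
    return pd.DataFrame(cols)


def monte_carlo_truth(
    scenario: ConfoundedScenario,
    spec: EstimandSpec,
    m_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """True estimand value under the scenario by Monte Carlo integration
    over the covariate distribution; returns (truth, MC standard error)."""
    rng = np.random.default_rng(seed)
    pcs, covs = _sample_background(scenario, m_draws, rng)
    # variants outside the estimand are integrated out by sampling them
    # from their genotype model given the PCs
    background = {}
    for name, vm in scenario.variants.items():
        if name in spec.treatments:
            continue
        eta = np.full(m_draws, vm.intercept, dtype=float)
        if vm.pc_weights:
            eta += pcs[:, : len(vm.pc_weights)] @ np.asarray(vm.pc_weights, dtype=float)
        background[name] = rng.binomial(2, expit(eta))
    vertices = estimand_vertices(spec)
    per_draw = np.zeros(m_draws)
    for v in vertices:
        genotypes = dict(background)
        genotypes.update(
            {
                name: np.full(m_draws, float(lvl))
                for name, lvl in zip(spec.treatments, v.assignment)
            }
        )
        mu = _mean_function(scenario, genotypes, pcs, covs)
        if scenario.outcome.binary:
            mu = expit(mu)
        per_draw += v.sign * mu
    return float(per_draw.mean()), float(per_draw.std(ddof=1) / np.sqrt(m_draws))


@dataclass(frozen=True)
class EvaluationGrid:
    """Cartesian grid of (scenario, estimand, estimator, n) cells, each
    replicated and scored for coverage / rejection / bias / variance."""

    scenarios: Mapping[str, object]
    specs: Mapping[str, EstimandSpec]
    estimators: tuple = ("wtmle",)
    sample_sizes: tuple = (5000,)
    n_replicates: int = 300
    alpha: float = 0.05
    base_seed: int = 0
    q_learner: LearnerSpec = LearnerSpec("glm")
    g_learner: LearnerSpec = LearnerSpec("glm")


def _simulate(scenario, n: int, seed: int) -> pd.DataFrame:
    scenario = replace(scenario, n=n)
    if isinstance(scenario, NullScenario):
        return simulate_null(scenario, seed)
    return simulate_confounded(scenario, seed)


def evaluate_cell(
    scenario,
    spec: EstimandSpec,
    estimator: str,
    n: int,
    n_replicates: int,
    truth: float = 0.0,
    alpha: float = 0.05,
    q_learner: LearnerSpec | None = None,
    g_learner: LearnerSpec | None = None,
    seed: int = 0,
) -> dict:
    """Replicate one grid cell: simulate, estimate, score.

    Coverage is the fraction of replicate CIs containing ``truth``;
    ``rejection_rate`` is the fraction with p < alpha (type-I error under
    a null truth, power otherwise).  Binomial MC standard errors included.
    """
    covered, rejected, estimates = [], [], []
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    for r in range(n_replicates):
        s = int(rep_seeds[r])
        data = _simulate(scenario, n, s)
        try:
            rec = estimate(
                data, spec, estimator=estimator,
                q_learner=q_learner, g_learner=g_learner,
                alpha=alpha, seed=s,
            )
        except EmptySupportError:
            continue
        covered.append(rec.ci[0] <= truth <= rec.ci[1])
        rejected.append(rec.pvalue < alpha)
        estimates.append(rec.psi)
    estimates = np.asarray(estimates)
    n_ok = len(estimates)
    coverage = float(np.mean(covered)) if n_ok else np.nan
    bias = float(estimates.mean() - truth) if n_ok else np.nan
    variance = float(estimates.var(ddof=1)) if n_ok > 1 else np.nan
    return {
        "n": n,
        "estimator": estimator,
        "n_replicates": n_ok,
        "coverage": coverage,
        "coverage_se": float(np.sqrt(coverage * (1 - coverage) / n_ok))
        if n_ok
        else np.nan,
        "rejection_rate": float(np.mean(rejected)) if n_ok else np.nan,
        "bias": bias,
        "variance": variance,
        "mse": float(np.mean((estimates - truth) ** 2)) if n_ok else np.nan,
        "truth": truth,
    }


def evaluate_grid(grid: EvaluationGrid, truths: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Run every cell of the grid; each cell is reproducible from
    (cell index, base_seed).  ``truths`` maps spec name -> true value
    (default 0, appropriate for null scenarios)."""
    rows = []
    cell = 0
    for scen_name, scenario in grid.scenarios.items():
        for spec_name, spec in grid.specs.items():
            truth = 0.0 if truths is None else truths.get(spec_name, 0.0)
            for estimator in grid.estimators:
                for n in grid.sample_sizes:
                    res = evaluate_cell(
                        scenario, spec, estimator, n,
                        n_replicates=grid.n_replicates, truth=truth,
                        alpha=grid.alpha, q_learner=grid.q_learner,
                        g_learner=grid.g_learner,
                        seed=grid.base_seed + 1_000_003 * cell,
                    )
                    res.update(scenario=scen_name, estimand=spec_name, cell=cell)
                    rows.append(res)
                    cell += 1
    return pd.DataFrame(rows)
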