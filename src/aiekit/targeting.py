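"""Efficient estimators built on nuisance fits: first-order bias, the
one-step (AIPW-generalizing) estimator, canonical and weighted TMLE, and
their cross-validated versions.

The TMLE fluctuation is an intercept-free one-parameter regression of the
outcome on the clever covariate with the initial fit as offset: identity
link for continuous outcomes (solved in closed form), logit link for
binary outcomes (one-dimensional Newton iteration).  Canonical mode puts
the inverse propensity in the covariate; weighted mode moves it into the
loss weights.  Both solve the empirical EIF score, driving the first-order
bias to zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import inference
from .estimands import (
    EstimandSpec,
    VertexWeight,
    estimand_vertices,
    plugin_estimate,
)
from .nuisance import (
    CrossFitPlan,
    LearnerSpec,
    NuisanceFits,
    adaptive_k_folds,
    fit_nuisances,
    make_plan,
)

__all__ = [
    "TargetedFit",
    "EstimateRecord",
    "first_order_bias",
    "one_step_estimate",
    "tmle_fluctuate",
    "estimate",
    "cv_estimate",
    "EmptySupportError",
    "ESTIMATORS",
]

ESTIMATORS = ("plugin", "ose", "tmle", "wtmle", "cv_ose", "cv_tmle", "cv_wtmle")
_MAX_ITER = 10

logger = logging.getLogger("aiekit")


def _analysis_sample(data: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Listwise deletion over the referenced columns, with the dropped
    count logged."""
    sub = data[list(columns)]
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    if n_dropped:
        logger.info(
            "dropped %d of %d rows with missing values", n_dropped, len(sub)
        )
    return kept.reset_index(drop=True)


class EmptySupportError(RuntimeError):
    """No individual matches any estimand vertex (after pruning)."""


@dataclass
class TargetedFit:
    epsilons: list
    qbar_obs: np.ndarray
    qbar_vertices: dict
    n_iter: int
    final_bias: float
    converged: bool


@dataclass
class EstimateRecord:
    """One estimated contrast component with its EIF-based inference."""

    estimand: str
    estimator: str
    psi: float
    eif: np.ndarray
    sigma2: float
    n: int
    ci: tuple
    pvalue: float
    alpha: float = 0.05
    notes: dict = field(default_factory=dict)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.sigma2 / self.n))


def first_order_bias(
    fits: NuisanceFits,
    vertices: Sequence[VertexWeight],
    qbar_obs: np.ndarray | None = None,
) -> float:
    """Empirical mean of the inverse-propensity-weighted residual term:
    ``(1/n) sum_i [sum_s sign_s 1{a_i=a(s)} / g(a_i, w_i)] (y_i - Qbar_i)``."""
    q_obs = fits.qbar_obs if qbar_obs is None else qbar_obs
    H = inference.clever_covariate(fits, vertices)
    return float(np.mean(H * (fits.y - q_obs)))


def _bias_tolerance(fits: NuisanceFits) -> float:
    if fits.family == "binomial":
        return 1e-8
    sd = float(np.std(fits.y))
    return 1e-8 * (sd if sd > 0 else 1.0)


def one_step_estimate(
    fits: NuisanceFits, vertices: Sequence[VertexWeight]
) -> tuple[float, np.ndarray]:
    """Plug-in plus first-order bias; returns (psi_hat, EIF values)."""
    plug = plugin_estimate(vertices, fits.qbar_vertices)
    psi = plug + first_order_bias(fits, vertices)
    eif = inference.eif_values(fits, vertices, psi)
    return psi, eif


def _vertex_covariates(
    fits: NuisanceFits, vertices: Sequence[VertexWeight], weighted: bool
) -> dict:
    """Clever covariate evaluated at each counterfactual vertex assignment."""
    out = {}
    for v in vertices:
        if weighted:
            out[v.assignment] = np.full(fits.n, float(v.sign))
        else:
            out[v.assignment] = v.sign / fits.g_vertices[v.assignment]
    return out


def _solve_logistic_epsilon(y, offset_logit, h, w, max_iter=50, tol=1e-12):
    """One-parameter logistic MLE with offset via damped Newton iteration.

    Solves ``sum_i w_i h_i (y_i - expit(offset_i + eps h_i)) = 0``.
    """
    eps = 0.0
    for _ in range(max_iter):
        mu = expit(offset_logit + eps * h)
        score = np.sum(w * h * (y - mu))
        info = np.sum(w * h * h * mu * (1 - mu))
        if info <= 0:
            break
        step = score / info
        # dampen absurd steps from near-degenerate curvature
        step = np.clip(step, -10.0, 10.0)
        eps += step
        if abs(step) < tol:
            break
    return eps


def tmle_fluctuate(
    fits: NuisanceFits,
    vertices: Sequence[VertexWeight],
    mode: str = "canonical",
    max_iter: int = _MAX_ITER,
    tol: float | None = None,
) -> TargetedFit:
    """Fluctuate the outcome regression until the first-order bias vanishes.

    mode="canonical": covariate H(g) with unit weights.  mode="weighted":
    covariate H' in {-1, 0, +1} with loss weights 1/g(A, W).  Continuous
    outcomes use an identity-link fluctuation solved in closed form (one
    step is exact); binary outcomes use a logit-link fluctuation.
    Non-convergence after ``max_iter`` sets ``converged=False`` rather than
    raising.
    """
    if mode not in ("canonical", "weighted"):
        raise ValueError(f"unknown fluctuation mode {mode!r}")
    weighted = mode == "weighted"
    tol = _bias_tolerance(fits) if tol is None else tol

    y = fits.y
    h_obs = inference.clever_covariate(fits, vertices, weighted=weighted)
    w = 1.0 / fits.g_obs if weighted else np.ones(fits.n)
    h_vertex = _vertex_covariates(fits, vertices, weighted)

    q_obs = fits.qbar_obs.copy()
    # restrict to this estimand's vertices (fits may carry a superset)
    q_vert = {v.assignment: fits.qbar_vertices[v.assignment].copy() for v in vertices}
    epsilons: list[float] = []
    bias = first_order_bias(fits, vertices, qbar_obs=q_obs)
    n_iter = 0
    while abs(bias) > tol and n_iter < max_iter:
        n_iter += 1
        if fits.family == "binomial":
            off = logit(q_obs)
            eps = _solve_logistic_epsilon(y, off, h_obs, w)
            q_obs = expit(off + eps * h_obs)
            for a in q_vert:
                q_vert[a] = expit(logit(q_vert[a]) + eps * h_vertex[a])
        else:
            denom = np.sum(w * h_obs**2)
            if denom == 0:
                break
            eps = float(np.sum(w * h_obs * (y - q_obs)) / denom)
            q_obs = q_obs + eps * h_obs
            for a in q_vert:
                q_vert[a] = q_vert[a] + eps * h_vertex[a]
        epsilons.append(eps)
        bias = first_order_bias(fits, vertices, qbar_obs=q_obs)

    converged = abs(bias) <= tol
    if not converged:
        warnings.warn(
            f"TMLE fluctuation did not converge: |B_n|={abs(bias):.3e} > {tol:.3e}",
            stacklevel=2,
        )
    return TargetedFit(
        epsilons=epsilons, qbar_obs=q_obs, qbar_vertices=q_vert,
        n_iter=n_iter, final_bias=bias, converged=converged,
    )


def _record(
    spec: EstimandSpec, estimator: str, psi: float, eif: np.ndarray,
    alpha: float, notes: dict,
) -> EstimateRecord:
    sigma2 = inference.iid_variance(eif)
    n = len(eif)
    ci, p = inference.wald_ci(psi, sigma2, n, alpha=alpha)
    return EstimateRecord(
        estimand=spec.label(), estimator=estimator, psi=psi, eif=eif,
        sigma2=sigma2, n=n, ci=ci, pvalue=p, alpha=alpha, notes=notes,
    )


def estimate_from_fits(
    fits: NuisanceFits,
    spec: EstimandSpec,
    estimator: str,
    alpha: float = 0.05,
    vertices: Sequence[VertexWeight] | None = None,
) -> EstimateRecord:
    """Compute an estimate from pre-computed nuisance fits.

    CV estimators share the canonical code path: the fits carry held-out
    predictions and a single pooled fluctuation (or pooled bias correction)
    is applied over all of them.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    vertices = estimand_vertices(spec) if vertices is None else vertices
    fits.validate(vertices)
    if not any(fits.indicators[v.assignment].any() for v in vertices):
        raise EmptySupportError(
            f"no individual at any vertex of {spec.label()} (empty-support)"
        )
    notes: dict = {"cross_fit": fits.fold_ids is not None}

    base = estimator.removeprefix("cv_")
    if base == "plugin":
        psi = plugin_estimate(vertices, fits.qbar_vertices)
        eif = inference.eif_values(fits, vertices, psi)
        notes["bias_uncorrected"] = first_order_bias(fits, vertices)
    elif base == "ose":
        psi, eif = one_step_estimate(fits, vertices)
    else:
        mode = "weighted" if base == "wtmle" else "canonical"
        tf = tmle_fluctuate(fits, vertices, mode=mode)
        psi = plugin_estimate(vertices, tf.qbar_vertices)
        eif = inference.eif_values(
            fits, vertices, psi, qbar_obs=tf.qbar_obs, qbar_vertices=tf.qbar_vertices
        )
        notes.update(
            epsilons=tf.epsilons, n_iter=tf.n_iter,
            final_bias=tf.final_bias, converged=tf.converged,
        )
    return _record(spec, estimator, psi, eif, alpha, notes)


def _default_plan(data: pd.DataFrame, spec: EstimandSpec, k_folds: int, seed):
    """Cross-fit plan for cv_* estimators.  Binary outcomes stratify on the
    outcome, with the fold count adapted to the rarest class
    (min(20, max(3, rare_count // 10))) when it exceeds the requested
    k_folds."""
    strata = None
    if spec.outcome_family == "binomial":
        y = np.asarray(data[spec.outcome])
        strata = y
        rare = int(min((y == 1).sum(), (y == 0).sum()))
        k_folds = max(k_folds, min(adaptive_k_folds(rare), rare))
    return make_plan(len(data), k_folds=k_folds, strata=strata, seed=seed)


def estimate(
    data: pd.DataFrame,
    spec: EstimandSpec,
    estimator: str = "wtmle",
    q_learner: LearnerSpec | None = None,
    g_learner: LearnerSpec | None = None,
    plan: CrossFitPlan | None = None,
    k_folds: int = 3,
    joint_propensity: bool = False,
    alpha: float = 0.05,
    seed: int | None = None,
) -> EstimateRecord:
    """Fit nuisances and estimate one contrast component end to end.

    ``cv_*`` estimators cross-fit the nuisances (a 3-fold plan is built
    when none is given); canonical estimators use full-sample fits unless
    an explicit plan is passed.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    data = _analysis_sample(data, spec.columns())
    q_learner = q_learner or LearnerSpec("glm")
    g_learner = g_learner or LearnerSpec("glm")
    if estimator.startswith("cv_") and plan is None:
        plan = _default_plan(data, spec, k_folds, seed)
    vertices = estimand_vertices(spec)
    fits = fit_nuisances(
        data, spec, vertices, q_learner, g_learner,
        plan=plan if (estimator.startswith("cv_") or plan is not None) else None,
        joint_propensity=joint_propensity, seed=seed,
    )
    return estimate_from_fits(fits, spec, estimator, alpha=alpha, vertices=vertices)


def estimate_components(
    data: pd.DataFrame,
    specs: Sequence[EstimandSpec],
    estimator: str = "wtmle",
    q_learner: LearnerSpec | None = None,
    g_learner: LearnerSpec | None = None,
    plan: CrossFitPlan | None = None,
    k_folds: int = 3,
    joint_propensity: bool = False,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[EstimateRecord]:
    """Estimate several contrast components sharing nuisance fits.

    All specs must share outcome, treatments, confounders and covariates
    (e.g. the 0->1 and 1->2 transitions of one variant).  Nuisances are fit
    once over the union of vertex assignments; each component then gets its
    own fluctuation (or bias correction) on the shared initial fit, and the
    per-individual EIFs are returned side by side for joint inference.
    """
    if not specs:
        return []
    head = specs[0]
    for s in specs[1:]:
        if (
            s.outcome != head.outcome
            or s.treatments != head.treatments
            or s.confounders != head.confounders
            or s.covariates != head.covariates
        ):
            raise ValueError("components must share outcome/treatment/covariate columns")
    data = _analysis_sample(data, head.columns())
    q_learner = q_learner or LearnerSpec("glm")
    g_learner = g_learner or LearnerSpec("glm")
    if estimator.startswith("cv_") and plan is None:
        plan = _default_plan(data, head, k_folds, seed)
    per_spec_vertices = {s.label(): estimand_vertices(s) for s in specs}
    union: dict[tuple, VertexWeight] = {}
    for verts in per_spec_vertices.values():
        for v in verts:
            union.setdefault(v.assignment, v)
    fits = fit_nuisances(
        data, head, list(union.values()), q_learner, g_learner,
        plan=plan, joint_propensity=joint_propensity, seed=seed,
    )
    return [
        estimate_from_fits(
            fits, s, estimator, alpha=alpha, vertices=per_spec_vertices[s.label()]
        )
        for s in specs
    ]


def cv_estimate(
    data: pd.DataFrame,
    spec: EstimandSpec,
    estimator: str = "cv_wtmle",
    q_learner: LearnerSpec | None = None,
    g_learner: LearnerSpec | None = None,
    plan: CrossFitPlan | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
) -> EstimateRecord:
    """Cross-validated estimation; estimator must be one of the cv_* names."""
    if not estimator.startswith("cv_"):
        raise ValueError("cv_estimate requires a cv_* estimator")
    return estimate(
        data, spec, estimator=estimator, q_learner=q_learner,
        g_learner=g_learner, plan=plan, alpha=alpha, seed=seed,
    )
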