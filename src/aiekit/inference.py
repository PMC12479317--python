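"""EIF-based inference: variance, Wald intervals, joint Hotelling tests,
delta-method functionals, positivity pruning and FDR adjustment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimands import EstimandSpec, VertexWeight
from .nuisance import NuisanceFits

__all__ = [
    "eif_values",
    "clever_covariate",
    "iid_variance",
    "wald_ci",
    "JointEstimate",
    "joint_test",
    "delta_method",
    "PruningReport",
    "positivity_prune",
    "bh_adjust",
]


def clever_covariate(
    fits: NuisanceFits, vertices: Sequence[VertexWeight], weighted: bool = False
) -> np.ndarray:
    """Per-individual clever covariate.

    Canonical form: ``sum_s sign_s 1{A_i = a(s)} / g(A_i, W_i)``.
    Weighted form drops the inverse propensity (values in {-1, 0, +1});
    the propensity moves into the fluctuation loss weights instead.
    """
    H = np.zeros(fits.n)
    for v in vertices:
        ind = fits.indicators[v.assignment]
        if weighted:
            H[ind] += v.sign
        else:
            H[ind] += v.sign / fits.g_vertices[v.assignment][ind]
    return H


def eif_values(
    fits: NuisanceFits,
    vertices: Sequence[VertexWeight],
    psi_hat: float,
    qbar_obs: np.ndarray | None = None,
    qbar_vertices: Mapping[tuple, np.ndarray] | None = None,
) -> np.ndarray:
    """Efficient influence function values at each observation.

    ``D*_i = sum_s sign_s [ 1{a_i=a(s)}/g(a_i,w_i) (y_i - Qbar(a_i,w_i))
    + Qbar(a(s), w_i) ] - psi_hat``.  Pass ``qbar_obs``/``qbar_vertices``
    to evaluate at targeted (fluctuated) fits.
    """
    q_obs = fits.qbar_obs if qbar_obs is None else qbar_obs
    q_vert = fits.qbar_vertices if qbar_vertices is None else qbar_vertices
    H = clever_covariate(fits, vertices)
    D = H * (fits.y - q_obs) - psi_hat
    for v in vertices:
        D = D + v.sign * q_vert[v.assignment]
    return D


def iid_variance(eif: np.ndarray) -> float:
    """Sample second moment of the EIF: ``(1/n) sum_i D*_i ** 2``."""
    eif = np.asarray(eif, dtype=float)
    return float(np.mean(eif**2))


def wald_ci(
    psi_hat: float, sigma2: float, n: int, alpha: float = 0.05
) -> tuple[tuple[float, float], float]:
    """Wald interval ``psi +- z_{1-a/2} sigma/sqrt(n)`` and two-sided
    normal p-value for H0: psi = 0.  Degenerate (sigma = 0) intervals
    collapse to the point estimate with p in {0, 1}."""
    if sigma2 < 0:
        raise ValueError("variance must be nonnegative")
    se = np.sqrt(sigma2 / n)
    if se == 0:
        warnings.warn("degenerate (zero-variance) interval", stacklevel=2)
        return (psi_hat, psi_hat), (1.0 if psi_hat == 0 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (psi_hat - z * se, psi_hat + z * se)
    p = 2 * stats.norm.sf(abs(psi_hat) / se)
    return ci, float(p)


@dataclass
class JointEstimate:
    """Joint inference over p estimand components sharing the sample."""

    psi: np.ndarray  # length p
    eif_matrix: np.ndarray  # p x n
    covariance: np.ndarray  # p x p, Sigma_hat
    n: int
    t2: float
    pvalue: float
    rank: int
    singular: bool = False


def joint_test(
    psi: Sequence[float], eif_matrix: np.ndarray, null: Sequence[float] | None = None
) -> JointEstimate:
    """Hotelling t-squared test of H0: psi0 = null (default 0).

    Sigma_hat_{jk} = (1/n) sum_i D_j(o_i) D_k(o_i); t2 = n (psi - null)
    Sigma^{-1} (psi - null)'; the reference distribution is
    ``p (n-1) / (n-p) F_{p, n-p}``.  A singular Sigma_hat falls back to the
    pseudo-inverse with reduced effective dimension.
    """
    psi = np.asarray(psi, dtype=float)
    eif_matrix = np.atleast_2d(np.asarray(eif_matrix, dtype=float))
    p, n = eif_matrix.shape
    if p != len(psi):
        raise ValueError("psi length must match EIF matrix rows")
    if p >= n:
        raise ValueError("joint test requires p < n")
    sigma = eif_matrix @ eif_matrix.T / n
    delta = psi if null is None else psi - np.asarray(null, dtype=float)
    rank = int(np.linalg.matrix_rank(sigma))
    singular = rank < p
    if singular:
        warnings.warn(
            "singular EIF covariance; using pseudo-inverse with reduced rank",
            stacklevel=2,
        )
        sigma_inv = np.linalg.pinv(sigma)
        p_eff = rank
    else:
        sigma_inv = np.linalg.inv(sigma)
        p_eff = p
    t2 = float(n * delta @ sigma_inv @ delta)
    if p_eff == 0:
        pvalue = 1.0
    else:
        f_stat = t2 * (n - p_eff) / (p_eff * (n - 1))
        pvalue = float(stats.f.sf(f_stat, p_eff, n - p_eff))
    return JointEstimate(
        psi=psi, eif_matrix=eif_matrix, covariance=sigma, n=n,
        t2=t2, pvalue=pvalue, rank=rank, singular=singular,
    )


def delta_method(
    psi: Sequence[float],
    eif_matrix: np.ndarray,
    func: Callable[[np.ndarray], float],
    gradient: Callable[[np.ndarray], np.ndarray] | Sequence[float],
    alpha: float = 0.05,
):
    """Inference for a differentiable function of component estimands.

    The new influence function is ``grad f(psi) . (component EIFs)``; for
    the difference ``f(x1, x2) = x2 - x1`` this yields the allelic-effect
    difference with variance Var D1 - 2 Cov(D1, D2) + Var D2.

    Returns ``(value, eif, sigma2, ci, pvalue)``.
    """
    psi = np.asarray(psi, dtype=float)
    eif_matrix = np.atleast_2d(np.asarray(eif_matrix, dtype=float))
    grad = np.asarray(gradient(psi) if callable(gradient) else gradient, dtype=float)
    if grad.shape[0] != eif_matrix.shape[0]:
        raise ValueError("gradient length must match number of components")
    value = float(func(psi))
    eif = grad @ eif_matrix
    sigma2 = iid_variance(eif)
    n = eif_matrix.shape[1]
    ci, p = wald_ci(value, sigma2, n, alpha=alpha)
    return value, eif, sigma2, ci, p


def allelic_difference(psi, eif_matrix, alpha: float = 0.05):
    """psi2 - psi1 contrast of two single-copy effects via the delta method."""
    return delta_method(
        psi, eif_matrix, func=lambda x: x[1] - x[0], gradient=(-1.0, 1.0), alpha=alpha
    )


@dataclass
class PruningReport:
    """Vertex-frequency screening decisions for a list of contrast components."""

    threshold: float
    frequencies: dict = field(default_factory=dict)  # label -> {assignment: freq}
    kept: list = field(default_factory=list)
    dropped: list = field(default_factory=list)


def vertex_frequencies(
    data: pd.DataFrame, treatments: Sequence[str], vertices: Sequence[VertexWeight]
) -> dict:
    """Unconditional joint frequency of each vertex level assignment."""
    n = len(data)
    obs = {t: np.asarray(data[t]) for t in treatments}
    out = {}
    for v in vertices:
        mask = np.ones(n, dtype=bool)
        for t, lvl in zip(treatments, v.assignment):
            mask &= obs[t] == lvl
        out[v.assignment] = float(mask.mean())
    return out


def positivity_prune(
    data: pd.DataFrame,
    components: Sequence[EstimandSpec],
    threshold: float,
    per_treatment: bool = False,
) -> tuple[PruningReport, list[EstimandSpec]]:
    """Drop contrast components whose required vertices are too rare.

    Frequencies are unconditional (marginal over confounders), computed on
    the analysis sample.  Only offending components are dropped — the rest
    of a multi-component estimand survives.  With ``per_treatment=True``
    the screen uses each treatment's marginal level frequency instead of
    the joint vertex frequency.
    """
    from .estimands import estimand_vertices

    report = PruningReport(threshold=threshold)
    kept_specs: list[EstimandSpec] = []
    for spec in components:
        vertices = estimand_vertices(spec)
        if per_treatment:
            freqs = {}
            for v in vertices:
                f = 1.0
                for t, lvl in zip(spec.treatments, v.assignment):
                    f = min(f, float((np.asarray(data[t]) == lvl).mean()))
                freqs[v.assignment] = f
        else:
            freqs = vertex_frequencies(data, spec.treatments, vertices)
        label = spec.label()
        report.frequencies[label] = freqs
        if all(f >= threshold for f in freqs.values()):
            report.kept.append(label)
            kept_specs.append(spec)
        else:
            report.dropped.append(label)
    return report, kept_specs


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0, 1)
    return out
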