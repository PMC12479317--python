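"""Nuisance estimation: outcome regression Qbar(A, W, C) and propensity
scores g(a(s) | W), with pluggable learners, optional cross-fitting, and a
stacked (super-learner style) ensemble.

Learners
--------
``constant``
    Training-sample mean / class frequencies; deliberately misspecified
    baseline, also useful as an ensemble floor.
``glm``
    Unpenalized linear / logistic / multinomial regression on an expanded
    design (treatment one-hot blocks, pairwise treatment interactions,
    linear confounder and covariate terms).
``glmnet``
    Ridge-penalized version of ``glm`` (hyperparameter ``alpha``).
``gbt``
    Histogram gradient-boosted trees on raw columns.
``stratified``
    Saturated cell-mean / cell-frequency fit keyed on the discrete values
    of its inputs; exact nonparametric fit for fully discrete problems.
``stacked``
    Convex (or winner-take-all) combination of base learners weighted by
    cross-validated loss.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold

from .estimands import EstimandSpec, TreatmentLevels, VertexWeight

__all__ = [
    "LearnerSpec",
    "CrossFitPlan",
    "NuisanceFits",
    "make_plan",
    "adaptive_k_folds",
    "make_learner",
    "fit_outcome_regression",
    "fit_propensity",
    "fit_nuisances",
    "StackedEnsemble",
    "stacked_ensemble_fit",
    "DegenerateFitError",
    "PositivityError",
    "EnsembleError",
]

DEFAULT_G_FLOOR = 1e-5
_Q_CLIP = 1e-6  # binary-outcome predictions kept inside (0, 1)


class DegenerateFitError(RuntimeError):
    pass


class PositivityError(RuntimeError):
    pass


class EnsembleError(RuntimeError):
    pass


@dataclass(frozen=True)
class LearnerSpec:
    """Name + hyperparameters of a learner; family set by the caller."""

    name: str
    params: Mapping = field(default_factory=dict)
    base_learners: tuple = ()  # for name == "stacked"
    selection: str = "convex"  # or "discrete" (stacked only)

    def __post_init__(self):
        if self.name == "stacked" and len(self.base_learners) < 2:
            raise ValueError("stacked ensemble requires >= 2 base learners")


@dataclass
class CrossFitPlan:
    """Fold assignment for cross-fitting; folds partition the sample."""

    k_folds: int
    fold_ids: np.ndarray

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("cross-fitting requires k_folds >= 2")
        present = np.unique(self.fold_ids)
        if not np.array_equal(present, np.arange(self.k_folds)):
            raise ValueError("fold ids must cover 0..k_folds-1")

    def splits(self):
        for f in range(self.k_folds):
            test = self.fold_ids == f
            yield f, ~test, test


def adaptive_k_folds(rare_count: int) -> int:
    """Fold count scaled to the rarest outcome class: min(20, max(3, c//10))."""
    return int(min(20, max(3, rare_count // 10)))


def make_plan(
    n: int,
    k_folds: int = 3,
    strata: np.ndarray | None = None,
    seed: int | None = None,
) -> CrossFitPlan:
    """Random (optionally stratified) fold assignment for ``n`` individuals."""
    fold_ids = np.empty(n, dtype=int)
    if strata is not None:
        strata = np.asarray(strata)
        if strata.ndim > 1:  # combine multiple stratification columns
            strata = pd.factorize(
                pd.MultiIndex.from_arrays([strata[:, j] for j in range(strata.shape[1])])
            )[0]
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        it = splitter.split(np.zeros(n), strata)
    else:
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        it = splitter.split(np.zeros(n))
    for f, (_, test_idx) in enumerate(it):
        fold_ids[test_idx] = f
    return CrossFitPlan(k_folds=k_folds, fold_ids=fold_ids)


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------


class _ConstantRegressor:
    def fit(self, X, y, sample_weight=None):
        self.mean_ = float(np.average(y, weights=sample_weight))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


class _ConstantClassifier:
    def fit(self, X, y, sample_weight=None):
        self.classes_, counts = np.unique(y, return_counts=True)
        self.proba_ = counts / counts.sum()
        return self

    def predict_proba(self, X):
        return np.tile(self.proba_, (len(X), 1))


def _as_key(key) -> tuple:
    # pandas groupby yields scalars for single-column keys; normalize
    return key if isinstance(key, tuple) else (key,)


class _CellMeanRegressor:
    """Saturated fit: mean of y within each distinct row of X."""

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        self.global_mean_ = float(y.mean())
        df = pd.DataFrame(X)
        self.table_ = {
            _as_key(key): grp.mean()
            for key, grp in pd.Series(y).groupby([df[c] for c in df.columns])
        }
        return self

    def predict(self, X):
        X = np.asarray(X)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            out[i] = self.table_.get(tuple(row), self.global_mean_)
        return out


class _CellFreqClassifier:
    """Saturated categorical fit: class frequencies within each X cell."""

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.global_ = np.array(
            [(y == c).mean() for c in self.classes_]
        )
        df = pd.DataFrame(X)
        self.table_ = {}
        for key, idx in pd.Series(np.arange(len(y))).groupby(
            [df[c] for c in df.columns]
        ).groups.items():
            yy = y[np.asarray(idx)]
            self.table_[_as_key(key)] = np.array(
                [(yy == c).mean() for c in self.classes_]
            )
        return self

    def predict_proba(self, X):
        X = np.asarray(X)
        out = np.empty((len(X), len(self.classes_)))
        for i, row in enumerate(X):
            out[i] = self.table_.get(tuple(row), self.global_)
        return out


def make_learner(spec: LearnerSpec, task: str, seed: int | None = None):
    """Instantiate an unfitted learner for ``task`` in {regression, classification}."""
    p = dict(spec.params)
    if spec.name == "constant":
        return _ConstantRegressor() if task == "regression" else _ConstantClassifier()
    if spec.name == "stratified":
        return _CellMeanRegressor() if task == "regression" else _CellFreqClassifier()
    if spec.name == "glm":
        if task == "regression":
            return LinearRegression()
        return LogisticRegression(C=p.get("C", 1e6), max_iter=p.get("max_iter", 1000))
    if spec.name == "glmnet":
        if task == "regression":
            return Ridge(alpha=p.get("alpha", 1.0))
        return LogisticRegression(
            C=1.0 / p.get("alpha", 1.0), max_iter=p.get("max_iter", 1000)
        )
    if spec.name == "gbt":
        kw = dict(
            max_iter=p.get("n_rounds", 100),
            max_depth=p.get("max_depth", None),
            learning_rate=p.get("learning_rate", 0.1),
            random_state=seed,
        )
        if task == "regression":
            return HistGradientBoostingRegressor(**kw)
        return HistGradientBoostingClassifier(**kw)
    if spec.name == "stacked":
        return StackedEnsemble(
            base_specs=spec.base_learners,
            task=task,
            selection=spec.selection,
            k_folds=p.get("k_folds", 3),
            seed=seed,
        )
    raise ValueError(f"unknown learner {spec.name!r}")


class StackedEnsemble:
    """Cross-validated convex (or discrete) combination of base learners.

    Weights minimize CV squared error (regression) or CV log-loss
    (classification) over held-out base-learner predictions, then every
    base learner is refit on the full data.
    """

    def __init__(self, base_specs, task, selection="convex", k_folds=3, seed=None):
        self.base_specs = tuple(base_specs)
        self.task = task
        self.selection = selection
        self.k_folds = k_folds
        self.seed = seed

    def _cv_predictions(self, X, y):
        n = len(y)
        if self.task == "classification":
            classes = np.unique(y)
            preds = np.full((n, len(self.base_specs), len(classes)), np.nan)
            splitter = StratifiedKFold(
                n_splits=self.k_folds, shuffle=True, random_state=self.seed
            )
            split_iter = splitter.split(X, y)
        else:
            classes = None
            preds = np.full((n, len(self.base_specs)), np.nan)
            splitter = KFold(n_splits=self.k_folds, shuffle=True, random_state=self.seed)
            split_iter = splitter.split(X)
        for train, test in split_iter:
            for j, bs in enumerate(self.base_specs):
                learner = make_learner(bs, self.task, seed=self.seed)
                learner.fit(X[train], y[train])
                if self.task == "classification":
                    proba = learner.predict_proba(X[test])
                    cols = {c: i for i, c in enumerate(learner.classes_)}
                    for ci, c in enumerate(classes):
                        preds[test, j, ci] = proba[:, cols[c]] if c in cols else 0.0
                else:
                    preds[test, j] = learner.predict(X[test])
        return preds, classes

    @staticmethod
    def _loss(task, pred, y, classes=None):
        if task == "regression":
            return float(np.mean((y - pred) ** 2))
        onehot = (np.asarray(y)[:, None] == classes[None, :]).astype(float)
        p = np.clip(pred, 1e-12, 1.0)
        return float(-np.mean(np.sum(onehot * np.log(p), axis=1)))

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X)
        y = np.asarray(y)
        preds, classes = self._cv_predictions(X, y)
        L = len(self.base_specs)
        self.cv_losses_ = np.array(
            [
                self._loss(self.task, preds[:, j] if self.task == "regression" else preds[:, j, :], y, classes)
                for j in range(L)
            ]
        )
        if self.selection == "discrete":
            w = np.zeros(L)
            w[int(np.argmin(self.cv_losses_))] = 1.0
        else:
            def objective(w):
                w = np.clip(w, 0, None)
                w = w / w.sum()
                mix = np.tensordot(preds, w, axes=([1], [0]))
                return self._loss(self.task, mix, y, classes)

            res = minimize(
                objective,
                np.full(L, 1.0 / L),
                method="SLSQP",
                bounds=[(0.0, 1.0)] * L,
                constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            )
            w = np.clip(res.x, 0, None)
            w = w / w.sum()
        self.weights_ = w
        mix = np.tensordot(preds, w, axes=([1], [0]))
        self.cv_loss_ = self._loss(self.task, mix, y, classes)

        self.models_, failures = [], []
        for bs in self.base_specs:
            try:
                m = make_learner(bs, self.task, seed=self.seed)
                m.fit(X, y)
                self.models_.append(m)
            except Exception as exc:  # noqa: BLE001 - aggregated below
                self.models_.append(None)
                failures.append(f"{bs.name}: {exc}")
        if all(m is None for m in self.models_):
            raise EnsembleError("all base learners failed: " + "; ".join(failures))
        if classes is not None:
            self.classes_ = classes
        return self

    def predict(self, X):
        X = np.asarray(X)
        out = np.zeros(len(X))
        for w, m in zip(self.weights_, self.models_):
            if w > 0 and m is not None:
                out += w * m.predict(X)
        return out

    def predict_proba(self, X):
        X = np.asarray(X)
        out = np.zeros((len(X), len(self.classes_)))
        for w, m in zip(self.weights_, self.models_):
            if w > 0 and m is not None:
                proba = m.predict_proba(X)
                cols = {c: i for i, c in enumerate(m.classes_)}
                for ci, c in enumerate(self.classes_):
                    if c in cols:
                        out[:, ci] += w * proba[:, cols[c]]
        return out


def stacked_ensemble_fit(
    base_learners: Sequence[LearnerSpec],
    X,
    y,
    family: str = "gaussian",
    plan: CrossFitPlan | None = None,
    selection: str = "convex",
    seed: int | None = None,
) -> StackedEnsemble:
    """Fit a stacked ensemble; returns the fitted object (weights in
    ``.weights_``, per-learner CV losses in ``.cv_losses_``)."""
    if len(base_learners) < 2:
        raise ValueError("stacked ensemble requires >= 2 base learners")
    task = "regression" if family == "gaussian" else "classification"
    k = plan.k_folds if plan is not None else 3
    ens = StackedEnsemble(
        base_specs=tuple(base_learners), task=task, selection=selection,
        k_folds=k, seed=seed,
    )
    ens.fit(np.asarray(X), np.asarray(y))
    return ens


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def resolve_levels(data: pd.DataFrame, spec: EstimandSpec) -> dict[str, TreatmentLevels]:
    """Level orderings for each treatment: declared if available, else the
    sorted observed values."""
    out = {}
    for name in spec.treatments:
        tl = spec.treatment_levels.get(name)
        if tl is None:
            tl = TreatmentLevels(name, tuple(sorted(pd.unique(data[name]))))
        out[name] = tl
    return out


def _treatment_codes(values: pd.Series, tl: TreatmentLevels) -> np.ndarray:
    idx = {lvl: i for i, lvl in enumerate(tl.levels)}
    try:
        return values.map(idx).to_numpy(dtype=float)
    except (ValueError, TypeError):
        raise PositivityError(
            f"observed level outside declared levels for {tl.name!r}"
        ) from None


def build_q_design(
    data: pd.DataFrame,
    spec: EstimandSpec,
    levels: Mapping[str, TreatmentLevels],
    expanded: bool,
    override: Mapping[str, object] | None = None,
) -> np.ndarray:
    """Design matrix for the outcome regression.

    expanded=True (glm/glmnet): per-treatment one-hot blocks (first level
    dropped), all pairwise products between treatment blocks, then linear
    confounder/covariate columns.  expanded=False (gbt/stratified/constant):
    raw treatment codes + raw confounder/covariate columns.

    ``override`` maps treatment name -> fixed level, used for vertex
    predictions.
    """
    n = len(data)
    cols: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    for name in spec.treatments:
        tl = levels[name]
        if override is not None and name in override:
            codes = np.full(n, tl.index_of(override[name]), dtype=float)
        else:
            codes = _treatment_codes(data[name], tl)
        if expanded:
            block = np.zeros((n, len(tl.levels) - 1))
            for j in range(1, len(tl.levels)):
                block[:, j - 1] = codes == j
            blocks.append(block)
        else:
            cols.append(codes)
    if expanded:
        cols.extend(blocks)
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                bi, bj = blocks[i], blocks[j]
                inter = (bi[:, :, None] * bj[:, None, :]).reshape(n, -1)
                cols.append(inter)
    for c in list(spec.confounders) + list(spec.covariates):
        cols.append(np.asarray(data[c], dtype=float))
    if not cols:
        return np.zeros((n, 0))
    return np.column_stack(cols)


def _confounder_matrix(data: pd.DataFrame, spec: EstimandSpec) -> np.ndarray:
    if not spec.confounders:
        return np.zeros((len(data), 0))
    return np.column_stack(
        [np.asarray(data[c], dtype=float) for c in spec.confounders]
    )


# ---------------------------------------------------------------------------
# nuisance fits
# ---------------------------------------------------------------------------


@dataclass
class NuisanceFits:
    """Per-individual nuisance predictions at the observed data and at
    every estimand vertex.

    All arrays have length n, aligned with the analysis sample.  Propensity
    values are clipped into ``[g_floor, 1 - g_floor]``; binary-outcome Qbar
    predictions live in the open unit interval.
    """

    y: np.ndarray
    family: str
    qbar_obs: np.ndarray | None = None
    qbar_vertices: dict = field(default_factory=dict)
    g_vertices: dict = field(default_factory=dict)
    g_obs: np.ndarray | None = None
    indicators: dict = field(default_factory=dict)
    fold_ids: np.ndarray | None = None
    g_floor: float = DEFAULT_G_FLOOR
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.y)

    def validate(self, vertices: Sequence[VertexWeight]):
        for v in vertices:
            if v.assignment not in self.qbar_vertices:
                raise ValueError(f"missing Qbar at vertex {v.assignment!r}")
            if v.assignment not in self.g_vertices:
                raise ValueError(f"missing g at vertex {v.assignment!r}")


def _clip_q(pred: np.ndarray, family: str) -> np.ndarray:
    if family == "binomial":
        return np.clip(pred, _Q_CLIP, 1 - _Q_CLIP)
    return pred


def _q_predict(model, X, family):
    if family == "binomial":
        proba = model.predict_proba(X)
        col = {c: i for i, c in enumerate(model.classes_)}.get(1)
        if col is None:
            raise DegenerateFitError("positive outcome class absent from training data")
        return _clip_q(proba[:, col], family)
    return model.predict(X)


def fit_outcome_regression(
    data: pd.DataFrame,
    spec: EstimandSpec,
    learner: LearnerSpec,
    vertices: Sequence[VertexWeight],
    plan: CrossFitPlan | None = None,
    seed: int | None = None,
    fits: NuisanceFits | None = None,
) -> NuisanceFits:
    """Fit Qbar and populate observed + vertex predictions.

    With a cross-fit ``plan``, each individual's predictions come from the
    model trained without that individual's fold.  Vertex predictions are
    obtained by overwriting the treatment columns with the vertex levels.
    """
    y = np.asarray(data[spec.outcome], dtype=float)
    family = spec.outcome_family
    task = "regression" if family == "gaussian" else "classification"
    y_fit = y.astype(int) if family == "binomial" else y
    levels = resolve_levels(data, spec)
    expanded = learner.name in ("glm", "glmnet")
    X_obs = build_q_design(data, spec, levels, expanded)
    X_vertices = {
        v.assignment: build_q_design(
            data, spec, levels, expanded,
            override=dict(zip(spec.treatments, v.assignment)),
        )
        for v in vertices
    }

    if fits is None:
        fits = NuisanceFits(y=y, family=family)
    fits.fold_ids = plan.fold_ids if plan is not None else None
    fits.provenance["q_learner"] = learner.name

    n = len(y)
    qbar_obs = np.empty(n)
    qbar_vertices = {a: np.empty(n) for a in X_vertices}
    if plan is None:
        model = make_learner(learner, task, seed=seed)
        if family == "binomial" and len(np.unique(y_fit)) < 2:
            raise DegenerateFitError("single-class binary outcome (full sample)")
        model.fit(X_obs, y_fit)
        qbar_obs[:] = _q_predict(model, X_obs, family)
        for a, Xv in X_vertices.items():
            qbar_vertices[a][:] = _q_predict(model, Xv, family)
    else:
        for f, train, test in plan.splits():
            if family == "binomial" and len(np.unique(y_fit[train])) < 2:
                raise DegenerateFitError(
                    f"single-class binary outcome in training data for fold {f}"
                )
            model = make_learner(learner, task, seed=seed)
            model.fit(X_obs[train], y_fit[train])
            qbar_obs[test] = _q_predict(model, X_obs[test], family)
            for a, Xv in X_vertices.items():
                qbar_vertices[a][test] = _q_predict(model, Xv[test], family)

    fits.qbar_obs = _clip_q(qbar_obs, family)
    fits.qbar_vertices = {a: _clip_q(v, family) for a, v in qbar_vertices.items()}
    return fits


def _classifier_proba(model, X, wanted_levels):
    """Probability columns for each wanted level; absent classes get 0."""
    proba = model.predict_proba(X)
    cols = {c: i for i, c in enumerate(model.classes_)}
    out = {}
    for lvl in wanted_levels:
        out[lvl] = proba[:, cols[lvl]] if lvl in cols else np.zeros(len(X))
    return out


def fit_propensity(
    data: pd.DataFrame,
    spec: EstimandSpec,
    learner: LearnerSpec,
    vertices: Sequence[VertexWeight],
    plan: CrossFitPlan | None = None,
    joint: bool = False,
    g_floor: float = DEFAULT_G_FLOOR,
    seed: int | None = None,
    fits: NuisanceFits | None = None,
) -> NuisanceFits:
    """Fit g and populate vertex propensities, observed propensities and
    vertex-match indicators.

    joint=False (default): one categorical model per treatment on the
    confounders; joint vertex probability is the product over treatments.
    joint=True: one model over the observed joint treatment categories.
    """
    levels = resolve_levels(data, spec)
    W = _confounder_matrix(data, spec)
    n = len(data)
    obs = {name: np.asarray(data[name]) for name in spec.treatments}

    # every vertex level must occur in the data
    for v in vertices:
        for name, lvl in zip(spec.treatments, v.assignment):
            if not np.any(obs[name] == lvl):
                raise PositivityError(
                    f"treatment level {lvl!r} of {name!r} absent from the data"
                )

    if fits is None:
        y = np.asarray(data[spec.outcome], dtype=float)
        fits = NuisanceFits(y=y, family=spec.outcome_family)
    fits.g_floor = g_floor
    fits.provenance["g_learner"] = learner.name
    fits.provenance["g_joint"] = joint

    wanted = {
        name: sorted(
            {v.assignment[i] for v in vertices} | set(pd.unique(data[name])),
            key=levels[name].index_of,
        )
        for i, name in enumerate(spec.treatments)
    }

    def _fit_models(train_idx):
        models = {}
        for name in spec.treatments:
            codes = np.array([levels[name].index_of(v) for v in obs[name]])
            m = make_learner(learner, "classification", seed=seed)
            m.fit(W[train_idx], codes[train_idx])
            models[name] = m
        return models

    def _per_treatment_probs(models, idx):
        out = {}
        for name in spec.treatments:
            wanted_codes = [levels[name].index_of(l) for l in wanted[name]]
            probs = _classifier_proba(models[name], W[idx], wanted_codes)
            out[name] = {
                lvl: probs[levels[name].index_of(lvl)] for lvl in wanted[name]
            }
        return out

    if joint:
        return _fit_joint_propensity(
            data, spec, learner, vertices, plan, g_floor, seed, fits, W, obs
        )

    g_vertices = {v.assignment: np.empty(n) for v in vertices}
    g_obs = np.empty(n)
    index_sets = (
        [(None, np.arange(n), np.arange(n))]
        if plan is None
        else [(f, np.where(tr)[0], np.where(te)[0]) for f, tr, te in plan.splits()]
    )
    for _, train_idx, test_idx in index_sets:
        models = _fit_models(train_idx)
        probs = _per_treatment_probs(models, test_idx)
        for v in vertices:
            gv = np.ones(len(test_idx))
            for name, lvl in zip(spec.treatments, v.assignment):
                gv = gv * probs[name][lvl]
            g_vertices[v.assignment][test_idx] = gv
        go = np.ones(len(test_idx))
        for name in spec.treatments:
            stacked = np.column_stack([probs[name][lvl] for lvl in wanted[name]])
            lvl_pos = {lvl: j for j, lvl in enumerate(wanted[name])}
            sel = np.array([lvl_pos[v] for v in obs[name][test_idx]])
            go = go * stacked[np.arange(len(test_idx)), sel]
        g_obs[test_idx] = go

    fits.g_vertices = {
        a: np.clip(gv, g_floor, 1 - g_floor) for a, gv in g_vertices.items()
    }
    fits.g_obs = np.clip(g_obs, g_floor, 1 - g_floor)
    fits.indicators = {}
    for v in vertices:
        ind = np.ones(n, dtype=bool)
        for name, lvl in zip(spec.treatments, v.assignment):
            ind &= obs[name] == lvl
        fits.indicators[v.assignment] = ind
    return fits


def _fit_joint_propensity(data, spec, learner, vertices, plan, g_floor, seed, fits, W, obs):
    """One categorical model over the joint treatment combinations."""
    n = len(data)
    joint_obs = list(zip(*(obs[t] for t in spec.treatments)))
    cats = sorted(set(joint_obs), key=lambda t: tuple(map(str, t)))
    cat_code = {c: i for i, c in enumerate(cats)}
    codes = np.array([cat_code[c] for c in joint_obs])
    for v in vertices:
        if v.assignment not in cat_code:
            raise PositivityError(
                f"joint treatment level {v.assignment!r} absent from the data"
            )

    g_vertices = {v.assignment: np.empty(n) for v in vertices}
    g_obs = np.empty(n)
    index_sets = (
        [(None, np.arange(n), np.arange(n))]
        if plan is None
        else [(f, np.where(tr)[0], np.where(te)[0]) for f, tr, te in plan.splits()]
    )
    for _, train_idx, test_idx in index_sets:
        m = make_learner(learner, "classification", seed=seed)
        m.fit(W[train_idx], codes[train_idx])
        probs = _classifier_proba(m, W[test_idx], list(range(len(cats))))
        for v in vertices:
            g_vertices[v.assignment][test_idx] = probs[cat_code[v.assignment]]
        stacked = np.column_stack([probs[i] for i in range(len(cats))])
        g_obs[test_idx] = stacked[np.arange(len(test_idx)), codes[test_idx]]

    fits.g_vertices = {
        a: np.clip(gv, g_floor, 1 - g_floor) for a, gv in g_vertices.items()
    }
    fits.g_obs = np.clip(g_obs, g_floor, 1 - g_floor)
    fits.indicators = {
        v.assignment: codes == cat_code[v.assignment] for v in vertices
    }
    return fits


def fit_nuisances(
    data: pd.DataFrame,
    spec: EstimandSpec,
    vertices: Sequence[VertexWeight],
    q_learner: LearnerSpec,
    g_learner: LearnerSpec,
    plan: CrossFitPlan | None = None,
    joint_propensity: bool = False,
    g_floor: float = DEFAULT_G_FLOOR,
    seed: int | None = None,
) -> NuisanceFits:
    """Convenience wrapper fitting both nuisances into one NuisanceFits."""
    fits = fit_outcome_regression(data, spec, q_learner, vertices, plan=plan, seed=seed)
    fit_propensity(
        data, spec, g_learner, vertices, plan=plan, joint=joint_propensity,
        g_floor=g_floor, seed=seed, fits=fits,
    )
    fits.validate(vertices)
    return fits
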