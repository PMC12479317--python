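import numpy as np
import pandas as pd
import pytest

from aiekit.estimands import Contrast, EstimandSpec, estimand_vertices
from aiekit.nuisance import (
    CrossFitPlan,
    DegenerateFitError,
    LearnerSpec,
    PositivityError,
    adaptive_k_folds,
    fit_nuisances,
    fit_outcome_regression,
    fit_propensity,
    make_plan,
    stacked_ensemble_fit,
)

from conftest import binary_ate_spec


def example1_data(rng, n=10_000, alpha=1.0, b1=0.5, b2=-0.3, gamma=0.7, sd=1.0):
    a1 = rng.binomial(1, 0.5, n)
    a2 = rng.binomial(1, 0.5, n)
    y = alpha + b1 * a1 + b2 * a2 + gamma * a1 * a2 + sd * rng.standard_normal(n)
    return pd.DataFrame({"Y": y, "A1": a1, "A2": a2})


def aie_spec_2():
    return EstimandSpec(
        kind="aie", outcome="Y", treatments=("A1", "A2"),
        contrast=Contrast(pairs=((0, 1), (0, 1))),
    )


class TestCrossFitPlan:
    def test_folds_partition_sample(self):
        plan = make_plan(101, k_folds=3, seed=0)
        assert np.bincount(plan.fold_ids).sum() == 101
        assert set(plan.fold_ids) == {0, 1, 2}

    def test_stratified_folds_balance_classes(self, rng):
        y = rng.binomial(1, 0.1, 600)
        plan = make_plan(600, k_folds=3, strata=y, seed=1)
        for f in range(3):
            frac = y[plan.fold_ids == f].mean()
            assert abs(frac - y.mean()) < 0.02

    def test_k_folds_lower_bound(self):
        with pytest.raises(ValueError):
            CrossFitPlan(k_folds=1, fold_ids=np.zeros(10, dtype=int))

    @pytest.mark.parametrize(
        "rare,expected", [(5, 3), (30, 3), (47, 4), (120, 12), (1000, 20)]
    )
    def test_adaptive_fold_count(self, rare, expected):
        assert adaptive_k_folds(rare) == expected


class TestOutcomeRegression:
    def test_constant_learner_predicts_sample_mean(self, toy_confounded):
        spec = binary_ate_spec()
        vws = estimand_vertices(spec)
        fits = fit_outcome_regression(
            toy_confounded, spec, LearnerSpec("constant"), vws
        )
        ybar = toy_confounded["Y"].mean()
        assert np.allclose(fits.qbar_obs, ybar)
        for v in vws:
            assert np.allclose(fits.qbar_vertices[v.assignment], ybar)

    def test_glm_recovers_example1_vertex_surface(self, rng):
        data = example1_data(rng)
        spec = aie_spec_2()
        vws = estimand_vertices(spec)
        fits = fit_outcome_regression(data, spec, LearnerSpec("glm"), vws)
        truth = {
            (a1, a2): 1.0 + 0.5 * a1 - 0.3 * a2 + 0.7 * a1 * a2
            for a1 in (0, 1) for a2 in (0, 1)
        }
        # coefficient SEs are ~ sd / sqrt(n/4) = 0.02; allow 4x
        for v in vws:
            pred = fits.qbar_vertices[v.assignment].mean()
            assert pred == pytest.approx(truth[v.assignment], abs=0.08)

    def test_cross_fit_bookkeeping(self, toy_confounded):
        spec = binary_ate_spec()
        vws = estimand_vertices(spec)
        plan = make_plan(len(toy_confounded), 3, seed=2)
        fits = fit_outcome_regression(
            toy_confounded, spec, LearnerSpec("glm"), vws, plan=plan
        )
        assert len(fits.qbar_obs) == len(toy_confounded)
        assert fits.fold_ids is not None
        # heterogeneous folds -> per-fold models differ
        v = vws[0].assignment
        fold_means = [
            fits.qbar_vertices[v][plan.fold_ids == f].mean() for f in range(3)
        ]
        assert len(set(np.round(fold_means, 12))) > 1

    def test_cross_fit_no_leakage(self, toy_confounded, rng):
        # permuting outcomes inside fold f leaves fold f's held-out
        # predictions unchanged (they come from models trained without f)
        spec = binary_ate_spec()
        vws = estimand_vertices(spec)
        plan = make_plan(len(toy_confounded), 3, seed=3)
        base = fit_outcome_regression(
            toy_confounded, spec, LearnerSpec("glm"), vws, plan=plan
        )
        perturbed = toy_confounded.copy()
        in_fold = plan.fold_ids == 0
        perturbed.loc[in_fold, "Y"] = rng.permutation(
            perturbed.loc[in_fold, "Y"].to_numpy()
        ) + rng.standard_normal(int(in_fold.sum()))
        new = fit_outcome_regression(
            perturbed, spec, LearnerSpec("glm"), vws, plan=plan
        )
        assert np.allclose(base.qbar_obs[in_fold], new.qbar_obs[in_fold])
        assert not np.allclose(base.qbar_obs[~in_fold], new.qbar_obs[~in_fold])

    def test_single_class_binary_fold_raises(self):
        n = 30
        data = pd.DataFrame(
            {"Y": np.zeros(n, dtype=int), "A": [0, 1] * 15, "W": np.arange(n)}
        )
        data.loc[0, "Y"] = 1
        spec = binary_ate_spec(family="binomial")
        vws = estimand_vertices(spec)
        plan = make_plan(n, 3, seed=0)
        with pytest.raises(DegenerateFitError, match="fold"):
            # the only case lands in one fold; the others are single-class
            fit_outcome_regression(data, spec, LearnerSpec("glm"), vws, plan=plan)

    def test_binary_predictions_in_open_unit_interval(self, rng):
        n = 500
        w = rng.standard_normal(n)
        a = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, 0.2 + 0.3 * a, n)
        data = pd.DataFrame({"Y": y, "A": a, "W": w})
        spec = binary_ate_spec(family="binomial")
        vws = estimand_vertices(spec)
        fits = fit_outcome_regression(data, spec, LearnerSpec("gbt"), vws, seed=0)
        assert np.all(fits.qbar_obs > 0) and np.all(fits.qbar_obs < 1)


class TestPropensity:
    def test_constant_learner_gives_marginal_frequencies(self, rng):
        n = 1000
        a = rng.binomial(1, 0.3, n)
        data = pd.DataFrame({"Y": rng.standard_normal(n), "A": a, "W": rng.standard_normal(n)})
        spec = binary_ate_spec()
        vws = estimand_vertices(spec)
        fits = fit_propensity(data, spec, LearnerSpec("constant"), vws)
        p1 = (a == 1).mean()
        assert np.allclose(fits.g_vertices[(1,)], p1)
        assert np.allclose(fits.g_vertices[(0,)], 1 - p1)

    def test_product_rule_for_independent_treatments(self, rng):
        n = 4000
        a1 = rng.binomial(1, 0.5, n)
        a2 = rng.binomial(1, 0.2, n)
        data = pd.DataFrame({"Y": rng.standard_normal(n), "A1": a1, "A2": a2})
        spec = aie_spec_2()
        vws = estimand_vertices(spec)
        fits = fit_propensity(data, spec, LearnerSpec("constant"), vws)
        expected = (a1 == 1).mean() * (a2 == 1).mean()
        assert np.allclose(fits.g_vertices[(1, 1)], expected)

    def test_joint_model_uses_empirical_joint_frequencies(self, rng):
        n = 4000
        a1 = rng.binomial(1, 0.5, n)
        a2 = np.where(rng.random(n) < 0.8, a1, rng.binomial(1, 0.5, n))  # correlated
        data = pd.DataFrame({"Y": rng.standard_normal(n), "A1": a1, "A2": a2})
        spec = aie_spec_2()
        vws = estimand_vertices(spec)
        fits = fit_propensity(data, spec, LearnerSpec("constant"), vws, joint=True)
        emp = ((a1 == 1) & (a2 == 1)).mean()
        assert np.allclose(fits.g_vertices[(1, 1)], emp)
        # product rule would be wrong here
        assert abs(emp - (a1 == 1).mean() * (a2 == 1).mean()) > 0.05

    def test_logistic_truth_recovered(self, rng):
        from scipy.special import expit

        n = 10_000
        w = rng.standard_normal(n)
        p = expit(-0.4 + 0.8 * w)
        a = rng.binomial(1, p)
        data = pd.DataFrame({"Y": rng.standard_normal(n), "A": a, "W": w})
        spec = binary_ate_spec()
        vws = estimand_vertices(spec)
        fits = fit_propensity(data, spec, LearnerSpec("glm"), vws)
        assert np.corrcoef(fits.g_vertices[(1,)], p)[0, 1] > 0.99
        assert np.abs(fits.g_vertices[(1,)] - p).mean() < 0.02

    def test_per_treatment_probabilities_sum_to_one(self, rng):
        n = 2000
        a = rng.binomial(2, 0.3, n)
        w = rng.standard_normal(n)
        data = pd.DataFrame({"Y": rng.standard_normal(n), "A": a, "W": w})
        spec = EstimandSpec(
            kind="ate", outcome="Y", treatments=("A",),
            contrast=Contrast(pairs=((0, 1),)), confounders=("W",),
        )
        from aiekit.estimands import VertexWeight

        all_levels = [
            VertexWeight(s=(1,), assignment=(lvl,), sign=1) for lvl in (0, 1, 2)
        ]
        fits = fit_propensity(data, spec, LearnerSpec("glm"), all_levels, g_floor=0.0)
        total = sum(fits.g_vertices[(lvl,)] for lvl in (0, 1, 2))
        assert np.allclose(total, 1.0, atol=1e-8)

    def test_absent_vertex_level_raises(self, rng):
        n = 100
        data = pd.DataFrame(
            {"Y": rng.standard_normal(n), "A": rng.binomial(1, 0.5, n), "W": rng.standard_normal(n)}
        )
        spec = EstimandSpec(
            kind="ate", outcome="Y", treatments=("A",),
            contrast=Contrast(pairs=((0, 2),)), confounders=("W",),
        )
        vws = estimand_vertices(spec)
        with pytest.raises(PositivityError, match="2"):
            fit_propensity(data, spec, LearnerSpec("constant"), vws)

    def test_clipping_floor(self, rng):
        n = 200
        a = np.zeros(n, dtype=int)
        a[:2] = 1
        data = pd.DataFrame({"Y": rng.standard_normal(n), "A": a, "W": np.zeros(n)})
        spec = binary_ate_spec()
        vws = estimand_vertices(spec)
        fits = fit_propensity(data, spec, LearnerSpec("constant"), vws, g_floor=0.05)
        assert fits.g_vertices[(1,)].min() >= 0.05


class TestStackedEnsemble:
    def test_weight_concentrates_on_correct_model(self, rng):
        n = 4000
        x = rng.standard_normal((n, 2))
        y = 1.0 + x @ np.array([0.8, -0.5]) + 0.5 * rng.standard_normal(n)
        ens = stacked_ensemble_fit(
            [LearnerSpec("constant"), LearnerSpec("glm")], x, y, seed=0
        )
        assert ens.weights_[1] > 0.9

    def test_discrete_selection_is_argmin(self, rng):
        n = 1000
        x = rng.standard_normal((n, 2))
        y = x[:, 0] + 0.3 * rng.standard_normal(n)
        ens = stacked_ensemble_fit(
            [LearnerSpec("constant"), LearnerSpec("glm")], x, y,
            selection="discrete", seed=0,
        )
        assert list(ens.weights_) == [0.0, 1.0]
        assert np.argmin(ens.cv_losses_) == 1

    def test_duplicated_learners_have_equal_losses(self, rng):
        n = 500
        x = rng.standard_normal((n, 1))
        y = x[:, 0] + rng.standard_normal(n)
        ens = stacked_ensemble_fit(
            [LearnerSpec("glm"), LearnerSpec("glm")], x, y, seed=0
        )
        assert ens.cv_losses_[0] == pytest.approx(ens.cv_losses_[1], rel=1e-10)

    def test_ensemble_cv_loss_not_worse_than_best_base(self, rng):
        n = 1500
        x = rng.standard_normal((n, 2))
        y = np.sin(x[:, 0]) + 0.4 * rng.standard_normal(n)
        ens = stacked_ensemble_fit(
            [LearnerSpec("constant"), LearnerSpec("glm"), LearnerSpec("gbt")],
            x, y, seed=0,
        )
        assert ens.cv_loss_ <= ens.cv_losses_.min() + 1e-6

    def test_requires_two_base_learners(self, rng):
        with pytest.raises(ValueError):
            stacked_ensemble_fit([LearnerSpec("glm")], np.zeros((10, 1)), np.zeros(10))

    def test_binary_classification_ensemble(self, rng):
        from scipy.special import expit

        n = 2000
        x = rng.standard_normal((n, 2))
        y = rng.binomial(1, expit(x[:, 0]))
        ens = stacked_ensemble_fit(
            [LearnerSpec("constant"), LearnerSpec("glm")], x, y,
            family="binomial", seed=0,
        )
        assert ens.weights_[1] > 0.8
        proba = ens.predict_proba(x)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_stacked_spec_requires_bases(self):
        with pytest.raises(ValueError):
            LearnerSpec("stacked")


class TestFitNuisancesIntegration:
    def test_stacked_learner_through_pipeline(self, toy_confounded):
        spec = binary_ate_spec()
        vws = estimand_vertices(spec)
        stacked = LearnerSpec(
            "stacked", base_learners=(LearnerSpec("constant"), LearnerSpec("glm"))
        )
        fits = fit_nuisances(
            toy_confounded, spec, vws, stacked, LearnerSpec("glm"), seed=0
        )
        assert fits.qbar_obs.shape == (len(toy_confounded),)
        assert set(fits.g_vertices) == {(0,), (1,)}
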