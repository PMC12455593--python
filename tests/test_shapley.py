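"""Shapley attribution: axioms, oracle equivalence, estimator convergence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from visionair import FunctionModel, beeswarm_export, exact_shap, mean_abs_shap, sampled_shap
from visionair.shapley import ShapExplanation

from oracles import brute_shapley


@pytest.fixture(scope="module")
def tree_model(default_spec):
    """Small forest on 4 noisy interacting features (module-scope oracle target)."""
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(300, 4)), columns=["a", "b", "c", "d"])
    y = X["a"] * X["b"] + np.sin(X["c"]) + 0.5 * X["d"] + rng.normal(0, 0.1, 300)
    rf = RandomForestRegressor(n_estimators=25, random_state=0).fit(X, y)
    return rf, X


class TestExact:
    def test_linear_closed_form(self):
        m = FunctionModel(lambda X: 2 * X["x1"] + 3 * X["x2"])
        bg = pd.DataFrame({"x1": [0.0], "x2": [0.0]})
        inst = pd.DataFrame({"x1": [1.0], "x2": [1.0]})
        e = exact_shap(m, inst, bg)
        assert e.phi.iloc[0].tolist() == pytest.approx([2.0, 3.0])
        assert e.phi0 == pytest.approx(0.0)

    def test_product_interaction_split_evenly(self):
        """f = x1*x2 at (1,1) from background (0,0): phi1 = phi2 = 1/2."""
        m = FunctionModel(lambda X: X["x1"] * X["x2"])
        bg = pd.DataFrame({"x1": [0.0], "x2": [0.0]})
        inst = pd.DataFrame({"x1": [1.0], "x2": [1.0]})
        e = exact_shap(m, inst, bg)
        assert e.phi.iloc[0].tolist() == pytest.approx([0.5, 0.5])

    def test_dummy_feature_zero(self):
        m = FunctionModel(lambda X: 5 * X["x1"])
        bg = pd.DataFrame({"x1": [0.0, 1.0], "x2": [3.0, -1.0]})
        inst = pd.DataFrame({"x1": [2.0], "x2": [9.0]})
        e = exact_shap(m, inst, bg)
        assert e.phi.iloc[0]["x2"] == 0.0

    def test_symmetry(self):
        m = FunctionModel(lambda X: X["x1"] + X["x2"] + X["x1"] * X["x2"])
        bg = pd.DataFrame({"x1": [0.0, 2.0], "x2": [0.0, 2.0]})
        inst = pd.DataFrame({"x1": [1.5], "x2": [1.5]})
        e = exact_shap(m, inst, bg)
        assert e.phi.iloc[0]["x1"] == pytest.approx(e.phi.iloc[0]["x2"])

    def test_matches_brute_oracle_and_additivity(self, tree_model):
        rf, X = tree_model
        bg, inst = X.iloc[:5], X.iloc[20:23]
        e = exact_shap(rf, inst, bg)
        for i in range(len(inst)):
            phi_b, phi0_b = brute_shapley(rf.predict, inst.iloc[i], bg)
            np.testing.assert_allclose(e.phi.iloc[i].to_numpy(), phi_b.to_numpy(), atol=1e-10)
            assert e.phi0 == pytest.approx(phi0_b)
        np.testing.assert_allclose(e.predictions.to_numpy(), rf.predict(inst), atol=1e-8)

    def test_cutoff_enforced(self, tree_model):
        rf, X = tree_model
        with pytest.raises(ValueError, match="sampled_shap"):
            exact_shap(rf, X.iloc[:1], X.iloc[:3], exact_cutoff=3)

    def test_empty_background_rejected(self, tree_model):
        rf, X = tree_model
        with pytest.raises(ValueError, match="background"):
            exact_shap(rf, X.iloc[:1], X.iloc[:0])


class TestSampled:
    def test_linear_model_single_background_exact(self):
        """Linear model, one background row: every ordering gives the same
        marginal contribution, so sampling is exact."""
        m = FunctionModel(lambda X: 2 * X["x1"] - X["x2"] + 0.5 * X["x3"])
        bg = pd.DataFrame([[0.5, -1.0, 2.0]], columns=["x1", "x2", "x3"])
        inst = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["x1", "x2", "x3"])
        s = sampled_shap(m, inst, bg, n_permutations=4, seed=1)
        e = exact_shap(m, inst, bg)
        np.testing.assert_allclose(s.phi.to_numpy(), e.phi.to_numpy(), atol=1e-10)

    def test_linear_model_matches_closed_form_within_mc_error(self):
        """With many background rows the only sampling noise is the
        background draw; the closed form beta*(x - mean(bg)) is recovered."""
        m = FunctionModel(lambda X: 2 * X["x1"] - X["x2"] + 0.5 * X["x3"])
        rng = np.random.default_rng(0)
        bg = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x1", "x2", "x3"])
        inst = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["x1", "x2", "x3"])
        s = sampled_shap(m, inst, bg, n_permutations=128, seed=1)
        closed = np.array([2.0, -1.0, 0.5]) * (inst.iloc[0] - bg.mean()).to_numpy()
        z = np.abs(s.phi.to_numpy()[0] - closed) / (s.mc_se.to_numpy()[0] + 1e-12)
        assert (z < 3.0).all()

    def test_additivity_exact_for_sampled(self, tree_model):
        rf, X = tree_model
        s = sampled_shap(rf, X.iloc[10:14], X.iloc[:30], n_permutations=8, seed=2)
        np.testing.assert_allclose(
            s.predictions.to_numpy(), rf.predict(X.iloc[10:14]), atol=1e-10
        )

    def test_converges_to_exact_within_mc_error(self, tree_model):
        rf, X = tree_model
        bg, inst = X.iloc[:10], X.iloc[30:35]
        e = exact_shap(rf, inst, bg)
        s = sampled_shap(rf, inst, bg, n_permutations=512, seed=0)
        z = ((s.phi - e.phi).abs() / (s.mc_se + 1e-12)).to_numpy()
        # 3-sigma per cell, allowing the expected Poisson-rate of exceedances
        assert (z > 3.0).sum() <= max(1, int(0.01 * z.size))
        assert z.max() < 5.0

    def test_dummy_feature_within_noise(self):
        m = FunctionModel(lambda X: X["x1"] ** 2)
        rng = np.random.default_rng(3)
        bg = pd.DataFrame(rng.normal(size=(15, 2)), columns=["x1", "x2"])
        inst = pd.DataFrame([[1.0, 5.0]], columns=["x1", "x2"])
        s = sampled_shap(m, inst, bg, n_permutations=64, seed=4)
        assert abs(s.phi.iloc[0]["x2"]) <= 3 * s.mc_se.iloc[0]["x2"] + 1e-12

    def test_error_shrinks_with_more_permutations(self, tree_model):
        """Mean |error| drops roughly 1/sqrt(2) when permutations double."""
        rf, X = tree_model
        bg, inst = X.iloc[:8], X.iloc[40:42]
        e = exact_shap(rf, inst, bg)
        errs = {}
        for k in (32, 64):
            errors = []
            for seed in range(20):
                s = sampled_shap(rf, inst, bg, n_permutations=k, seed=seed)
                errors.append((s.phi - e.phi).abs().to_numpy().mean())
            errs[k] = np.mean(errors)
        ratio = errs[64] / errs[32]
        assert 0.5 < ratio < 0.95

    def test_minimum_permutations(self, tree_model):
        rf, X = tree_model
        with pytest.raises(ValueError):
            sampled_shap(rf, X.iloc[:1], X.iloc[:3], n_permutations=1)


class TestGlobalImportance:
    def test_mean_abs_definition(self):
        exps = [
            ShapExplanation(i, 0.0, pd.Series({"f": v}), "exact")
            for i, v in enumerate([1.0, -1.0, 2.0])
        ]
        gi = mean_abs_shap(exps)
        assert gi.I["f"] == pytest.approx(4 / 3)
        assert gi.m == 3

    def test_zero_and_singleton(self):
        zero = [ShapExplanation(0, 0.0, pd.Series({"f": 0.0}), "exact")]
        assert mean_abs_shap(zero).I["f"] == 0.0
        single = [ShapExplanation(0, 0.0, pd.Series({"f": -0.7}), "exact")]
        assert mean_abs_shap(single).I["f"] == pytest.approx(0.7)

    def test_mismatched_features_rejected(self):
        exps = [
            ShapExplanation(0, 0.0, pd.Series({"f": 1.0}), "exact"),
            ShapExplanation(1, 0.0, pd.Series({"g": 1.0}), "exact"),
        ]
        with pytest.raises(ValueError, match="mismatched"):
            mean_abs_shap(exps)


class TestBeeswarm:
    def test_shape_colors_and_ordering(self, tree_model):
        rf, X = tree_model
        e = exact_shap(rf, X.iloc[:6], X.iloc[:10])
        fv = X.iloc[:6].copy()
        fv["a"] = [10.0, 30.0, 20.0, 15.0, 25.0, 12.0]
        fv["d"] = 7.0  # constant feature
        out = beeswarm_export(e, fv)
        assert len(out) == 6 * 4
        a_rows = out[out["feature"] == "a"].set_index("instance")
        assert a_rows.loc[X.index[2], "color"] == pytest.approx(0.5)  # midpoint of [10, 30]
        assert (out[out["feature"] == "d"]["color"] == 0.5).all()
        # features ordered by descending importance
        order = out.drop_duplicates("feature")["feature"].tolist()
        assert order == mean_abs_shap(e).ranking().index.tolist()
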