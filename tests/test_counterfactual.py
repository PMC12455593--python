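"""Donor-pool construction, counterfactual resampling, exposure gradient."""

import warnings

import numpy as np
import pandas as pd
import pytest

from visionair import (
    FunctionModel,
    GradientBoostedTrees,
    counterfactual_ucva,
    derive_labels,
    encode_features,
    exposure_gradient,
    exposure_subgroup,
    generate_cohort,
    scenario_report,
)
from visionair.counterfactual import stratum_mask
from visionair.synthetic import GenerativeSpec


@pytest.fixture()
def linear_setup():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(
        {"no2": rng.normal(36, 2, 60), "other": rng.normal(size=60)},
        index=[f"r{i}" for i in range(60)],
    )
    model = FunctionModel(lambda F: 4.6 - 0.01 * F["no2"] + 0.1 * F["other"], name="lin")
    return model, X


class TestDonorPool:
    def test_empirical_quantile_with_ties(self):
        t = pd.DataFrame({"no2": np.arange(1.0, 11.0)})
        pool = exposure_subgroup(t, ["no2"], 0.2)
        assert t.loc[pool, "no2"].tolist() == [1.0, 2.0]
        t_eq = pd.DataFrame({"no2": np.full(10, 5.0)})
        assert len(exposure_subgroup(t_eq, ["no2"], 0.2)) == 10  # ties included

    def test_pool_mean_below_cohort_mean(self, cohort_small):
        pool = exposure_subgroup(cohort_small, ["no2"], 0.2)
        assert cohort_small.loc[pool, "no2"].mean() < cohort_small["no2"].mean()

    def test_joint_pool_is_union_of_low_tails(self, cohort_small):
        pool_j = exposure_subgroup(cohort_small, ["no2", "pm25"], 0.2)
        pool_n = exposure_subgroup(cohort_small, ["no2"], 0.2)
        pool_p = exposure_subgroup(cohort_small, ["pm25"], 0.2)
        assert set(pool_j) == set(pool_n) | set(pool_p)

    def test_invalid_quantile(self, cohort_small):
        with pytest.raises(ValueError):
            exposure_subgroup(cohort_small, ["no2"], 1.5)


class TestCounterfactual:
    def test_unused_pollutant_identity(self, linear_setup):
        _, X = linear_setup
        model = FunctionModel(lambda F: 4.6 + 0.1 * F["other"], name="no-pollutant")
        with pytest.warns(UserWarning, match="not model features"):
            res = counterfactual_ucva(model, X.drop(columns=["no2"]), ["no2"], X.index[:5], t=3)
        pd.testing.assert_series_equal(
            res.counterfactual, res.baseline, check_names=False
        )

    def test_singleton_pool_deterministic(self, linear_setup):
        model, X = linear_setup
        pool = X.index[:1]
        r1 = counterfactual_ucva(model, X, ["no2"], pool, t=1, seed=0)
        r2 = counterfactual_ucva(model, X, ["no2"], pool, t=500, seed=99)
        pd.testing.assert_series_equal(r1.counterfactual, r2.counterfactual)
        fixed = X.copy()
        fixed["no2"] = X["no2"].iloc[0]
        np.testing.assert_allclose(r1.counterfactual, model.predict(fixed))

    def test_linear_donor_mean_convergence(self, linear_setup):
        """Cohort-mean counterfactual -> beta * donor mean within 3 MC SE."""
        model, X = linear_setup
        pool = exposure_subgroup(X, ["no2"], 0.2)
        t = 500
        res = counterfactual_ucva(model, X, ["no2"], pool, t=t, seed=4)
        donor = X.loc[pool, "no2"]
        expected = 4.6 - 0.01 * donor.mean() + 0.1 * X["other"]
        per_ind_se = 0.01 * donor.std(ddof=0) / np.sqrt(t)
        cohort_se = per_ind_se / np.sqrt(len(X))
        assert abs(res.counterfactual.mean() - expected.mean()) < 3 * cohort_se

    def test_determinism_and_row_order_stability(self, linear_setup):
        model, X = linear_setup
        pool = X.index[:12]
        r1 = counterfactual_ucva(model, X, ["no2"], pool, t=40, seed=7)
        r2 = counterfactual_ucva(model, X, ["no2"], pool, t=40, seed=7)
        pd.testing.assert_series_equal(r1.counterfactual, r2.counterfactual)
        shuffled = X.sample(frac=1.0, random_state=1)
        r3 = counterfactual_ucva(model, shuffled, ["no2"], pool, t=40, seed=7)
        pd.testing.assert_series_equal(
            r1.counterfactual.sort_index(), r3.counterfactual.sort_index()
        )

    def test_null_scenario_neutral_for_linear_model(self, linear_setup):
        """Resampling from the whole cohort leaves a linear model's mean fixed."""
        model, X = linear_setup
        res = counterfactual_ucva(model, X, ["no2"], X.index, t=400, seed=2)
        per_ind_se = 0.01 * X["no2"].std(ddof=0) / np.sqrt(400)
        cohort_se = per_ind_se / np.sqrt(len(X))
        assert abs(res.delta.mean()) < 3 * cohort_se

    def test_substituted_means_match_donor_pool(self, linear_setup):
        _, X = linear_setup
        probe = FunctionModel(lambda F: F["no2"], name="probe")
        pool = exposure_subgroup(X, ["no2"], 0.2)
        res = counterfactual_ucva(probe, X, ["no2"], pool, t=300, seed=5)
        donor_mean = X.loc[pool, "no2"].mean()
        assert res.counterfactual.mean() == pytest.approx(donor_mean, abs=0.05)
        assert res.donor_summary["pollutants"]["no2"]["donor_mean"] == pytest.approx(donor_mean)

    def test_mc_error_shrinks_like_sqrt_t(self, linear_setup):
        model, X = linear_setup
        Xs = X.iloc[:30]
        pool = exposure_subgroup(Xs, ["no2"], 0.3)
        sds = {}
        for t in (50, 200, 800):
            means = [
                counterfactual_ucva(model, Xs, ["no2"], pool, t=t, seed=s).counterfactual.to_numpy()
                for s in range(10)
            ]
            sds[t] = np.std(np.stack(means), axis=0).mean()
        assert 1.4 < sds[50] / sds[200] < 2.9
        assert 1.4 < sds[200] / sds[800] < 2.9

    def test_invalid_inputs(self, linear_setup):
        model, X = linear_setup
        with pytest.raises(ValueError):
            counterfactual_ucva(model, X, ["no2"], X.index[:0], t=5)
        with pytest.raises(ValueError):
            counterfactual_ucva(model, X, ["no2"], X.index[:3], t=0)


class TestScenarioReport:
    def test_stratum_means_and_unknown_stratum(self, linear_setup):
        model, X = linear_setup
        labels = pd.DataFrame(
            {
                "school_level": ["primary"] * 30 + ["senior"] * 30,
                "myopia_class": ["school"] * 60,
            },
            index=X.index,
        )
        res = counterfactual_ucva(model, X, ["no2"], X.index[:10], t=20, seed=0)
        rep = scenario_report(res, labels, strata=("all", "primary", "senior"))
        row = rep.summary.set_index("stratum")
        assert row.loc["all", "n"] == 60
        mask = labels["school_level"] == "primary"
        assert row.loc["primary", "mean_delta"] == pytest.approx(res.delta[mask].mean())
        with pytest.raises(KeyError):
            scenario_report(res, labels, strata=("all", "martians"))

    def test_histogram_counts_complete(self, linear_setup):
        model, X = linear_setup
        labels = pd.DataFrame(
            {"school_level": "primary", "myopia_class": "none"}, index=X.index
        )
        res = counterfactual_ucva(model, X, ["no2"], X.index[:5], t=10, seed=0)
        rep = scenario_report(res, labels, strata=("all",))
        assert rep.histograms["baseline_count"].sum() == len(X)


class TestExposureGradient:
    def test_flat_model_zero_slope(self, linear_setup):
        _, X = linear_setup
        flat = FunctionModel(lambda F: 0 * F["no2"] + 4.5, name="flat")
        labels = pd.DataFrame(
            {"school_level": "primary", "myopia_class": "none"}, index=X.index
        )
        grad, slopes = exposure_gradient(flat, X, "no2", labels, n_bins=5, strata=("all",), t=5)
        assert np.allclose(grad["mean_ucva"], 4.5)
        assert slopes["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_frequency_bins_and_reduction_warning(self, linear_setup):
        model, X = linear_setup
        labels = pd.DataFrame(
            {"school_level": "primary", "myopia_class": "none"}, index=X.index
        )
        grad, _ = exposure_gradient(model, X, "no2", labels, n_bins=6, strata=("all",), t=5)
        assert grad["bin"].nunique() == 6
        assert np.all(np.diff(grad["bin_mean_pollutant"]) > 0)
        small = X.iloc[:4]
        with pytest.warns(UserWarning, match="distinct"):
            exposure_gradient(
                model, small, "no2", labels.iloc[:4], n_bins=10, strata=("all",), t=2
            )

    def test_stratum_slope_ordering_recovered(self, default_spec, schema):
        """beta_primary >> beta_senior in the generator -> steeper primary slope."""
        payload = default_spec.model_dump()
        payload["pollutant_effects"] = {"no2": -0.005, "pm25": 0.0}
        payload["school_multiplier"] = {"primary": 4.0, "middle": 1.0, "high": 1.0}
        payload["missing_rates"] = {}
        spec = GenerativeSpec(**{**payload, "n": 3000})
        table = generate_cohort(spec, seed=13)
        table = table.set_index(pd.Index(table["id"]), drop=False)
        labels = derive_labels(table)
        fm = encode_features(table, schema=schema)
        model = GradientBoostedTrees(
            n_trees=150, depth=4, categorical_features=fm.categorical
        ).fit(fm.X, table["ucva"])
        _, slopes = exposure_gradient(
            model, fm.X, "no2", labels, n_bins=10, strata=("primary", "senior"), t=15, seed=1
        )
        s = slopes.set_index("stratum")["slope"]
        assert s["primary"] < 0
        assert abs(s["primary"]) > abs(s["senior"])
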