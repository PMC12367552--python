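import numpy as np
import pandas as pd
import pytest
from scipy import stats

from infraccess.health import (
    fit_health_model,
    group_comparisons,
    pearson_with_ci,
    predicted_health_change,
    rf_importance,
)
from infraccess.synthetic import DEFAULT_BETA, simulate_health_panel


class TestPearson:
    def test_perfect_linear_relation(self, rng):
        x = rng.random(50)
        r, lo, hi, p = pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_definition_oracle(self, rng):
        x, y = rng.random(200), rng.random(200)
        r, *_ = pearson_with_ci(x, y)
        oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_null_coverage(self):
        # independent x, y: the 95% CI should cover 0 about 95% of the time
        covered = 0
        reps = 300
        rng = np.random.default_rng(7)
        for _ in range(reps):
            x, y = rng.normal(size=60), rng.normal(size=60)
            _, lo, hi, _ = pearson_with_ci(x, y)
            covered += lo <= 0 <= hi
        assert 0.91 <= covered / reps <= 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci(np.ones(10), np.arange(10.0))


class TestHealthModel:
    def test_no_group_effect_degenerates_to_ols(self):
        # mirror the panel across groups so the between-group contrast is
        # exactly zero: the variance component sits on the boundary and the
        # mixed fit must coincide with plain least squares
        import statsmodels.api as sm

        df = simulate_health_panel(seed=5, gamma_north=0.0, gamma_south=0.0)
        swapped = df.copy()
        swapped["group"] = swapped["group"].map({"North": "South", "South": "North"})
        sym = pd.concat([df, swapped], ignore_index=True)
        res = fit_health_model(sym, "III", log_transform=False)
        X = sm.add_constant(
            sym[["LnPop", "LnGDP", "ExpEco", "ExpSoc", "GiniEco", "GiniSoc"]].to_numpy()
        )
        ols = sm.OLS(sym["Health"].to_numpy(), X).fit()
        np.testing.assert_allclose(
            res.summary["coef"].to_numpy(), ols.params, atol=1e-6
        )

    def test_sign_recovery_on_generated_data(self):
        # average over replicate fits: access effects positive, economic
        # inequality effect negative, as in the generating law
        coefs = []
        for rep in range(20):
            df = simulate_health_panel(seed=100 + rep)
            res = fit_health_model(df, "III", log_transform=False)
            coefs.append(res.summary.set_index("term")["coef"])
        mean_coef = pd.concat(coefs, axis=1).mean(axis=1)
        assert mean_coef["ExpEco"] > 0
        assert mean_coef["GiniEco"] < 0
        assert mean_coef["LnGDP"] > 0

    def test_model_terms_match_specification(self):
        df = simulate_health_panel(seed=2)
        for model_id, expected in {
            "I": {"const", "LnPop", "LnGDP", "ExpEco", "ExpSoc"},
            "II": {"const", "LnPop", "LnGDP", "GiniEco", "GiniSoc"},
            "III": {"const", "LnPop", "LnGDP", "ExpEco", "ExpSoc", "GiniEco", "GiniSoc"},
        }.items():
            res = fit_health_model(df, model_id, log_transform=False)
            assert set(res.summary["term"]) == expected

    def test_ci_brackets_coefficient(self):
        df = simulate_health_panel(seed=3)
        res = fit_health_model(df, "I", log_transform=False)
        s = res.summary
        assert ((s["ci_low"] <= s["coef"]) & (s["coef"] <= s["ci_high"])).all()

    def test_heteroscedastic_data_triggers_sandwich(self):
        flagged = 0
        for rep in range(10):
            df = simulate_health_panel(seed=400 + rep, heteroscedastic=True, resid_sd=2.0)
            res = fit_health_model(df, "III", log_transform=False)
            flagged += res.robust_se_used
        assert flagged >= 8  # Levene should reject for 2x variance ratio

    def test_homoscedastic_robust_and_model_se_agree(self):
        df = simulate_health_panel(seed=11, gamma_north=0.0, gamma_south=0.0)
        res_plain = fit_health_model(df, "III", log_transform=False)
        import statsmodels.api as sm

        X = sm.add_constant(
            df[["LnPop", "LnGDP", "ExpEco", "ExpSoc", "GiniEco", "GiniSoc"]].to_numpy()
        )
        ols = sm.OLS(df["Health"].to_numpy(), X).fit()
        hc1 = ols.get_robustcov_results("HC1")
        ratio = np.asarray(hc1.bse) / np.asarray(ols.bse)
        assert np.all(np.abs(ratio - 1) < 0.35)
        assert not res_plain.robust_se_used or res_plain.levene[1] < 0.05

    def test_log_transform_auto_on_skewed_response(self):
        df = simulate_health_panel(seed=21)
        df["Health"] = np.exp(df["Health"] / 10.0)  # strongly lognormal response
        res = fit_health_model(df, "I", log_transform="auto")
        assert res.log_transformed
        res_forced = fit_health_model(df, "I", log_transform=False)
        assert not res_forced.log_transformed

    def test_single_group_rejected(self):
        df = simulate_health_panel(seed=1)
        df["group"] = "North"
        with pytest.raises(ValueError, match="2 groups"):
            fit_health_model(df, "I")

    def test_group_as_fixed_fallback(self):
        df = simulate_health_panel(seed=9)
        res = fit_health_model(df, "III", log_transform=False, group_as_fixed=True)
        assert np.isnan(res.group_var)
        assert res.coef("GiniEco") < 0


class TestPredictedHealthChange:
    def test_worked_example(self):
        df = simulate_health_panel(seed=2)
        res = fit_health_model(df, "III", log_transform=False)
        res.summary.loc[res.summary["term"] == "GiniEco", "coef"] = -9.95
        assert predicted_health_change(res, "GiniEco", 0.10) == pytest.approx(-0.995)

    def test_zero_delta_and_linearity(self):
        df = simulate_health_panel(seed=2)
        res = fit_health_model(df, "III", log_transform=False)
        assert predicted_health_change(res, "ExpEco", 0.0) == 0.0
        one = predicted_health_change(res, "ExpEco", 0.1)
        two = predicted_health_change(res, "ExpEco", 0.2)
        assert two == pytest.approx(2 * one)

    def test_unknown_covariate_rejected(self):
        df = simulate_health_panel(seed=2)
        res = fit_health_model(df, "I", log_transform=False)
        with pytest.raises(KeyError):
            predicted_health_change(res, "GiniEco", 0.1)


class TestRandomForestImportance:
    @staticmethod
    def _planted_panel(seed=0, n=160):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({c: rng.normal(size=n) for c in
                           ["LnPop", "LnGDP", "ExpEco", "ExpSoc", "GiniEco", "GiniSoc"]})
        df["Health"] = 10.0 * df["GiniEco"] + rng.normal(scale=0.5, size=n)
        return df

    def test_planted_signal_ranks_first(self):
        df = self._planted_panel()
        table = rf_importance(df, n_runs=10, n_trees=100, seed=42)
        firsts = 0
        for _, run in table.groupby("run"):
            top = run.sort_values("inc_mse", ascending=False)["covariate"].iloc[0]
            firsts += top == "GiniEco"
        assert firsts >= 9

    def test_pure_noise_importances_overlap(self):
        df = self._planted_panel(seed=3)
        df["Health"] = np.random.default_rng(99).normal(size=len(df))
        table = rf_importance(df, n_runs=5, n_trees=100, seed=7)
        med = table.groupby("covariate")["inc_node_purity"].median()
        assert med.max() < 3 * max(med.min(), 1e-9)

    def test_reproducible_with_fixed_seed(self):
        df = self._planted_panel()
        a = rf_importance(df, n_runs=3, n_trees=50, seed=5)
        b = rf_importance(df, n_runs=3, n_trees=50, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestGroupComparisons:
    def test_identical_groups(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           "g": ["a"] * 3 + ["b"] * 3})
        out = group_comparisons(df, "v", "g")
        assert out["statistic"].iloc[0] == pytest.approx(0.0)
        assert out["effect_size"].iloc[0] == pytest.approx(0.0)

    def test_cohens_d_definition(self, rng):
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(1.0, 1.0, 100)
        df = pd.DataFrame({"v": np.r_[a, b], "g": ["a"] * 100 + ["b"] * 100})
        out = group_comparisons(df, "v", "g")
        assert abs(out["effect_size"].iloc[0]) == pytest.approx(1.0, abs=0.35)

    def test_anova_on_two_groups_equals_t_squared(self, rng):
        df = pd.DataFrame(
            {"v": rng.normal(size=40), "g": ["a"] * 20 + ["b"] * 20}
        )
        t_row = group_comparisons(df, "v", "g", test="t").iloc[0]
        f_row = group_comparisons(df, "v", "g", test="anova").iloc[0]
        assert f_row["statistic"] == pytest.approx(t_row["statistic"] ** 2, abs=1e-10)

    def test_three_group_anova_matches_scipy(self, rng):
        df = pd.DataFrame(
            {"v": rng.normal(size=60), "g": ["a"] * 20 + ["b"] * 20 + ["c"] * 20}
        )
        out = group_comparisons(df, "v", "g").iloc[0]
        F, p = stats.f_oneway(*[g["v"].to_numpy() for _, g in df.groupby("g")])
        assert out["statistic"] == pytest.approx(F)
        assert out["p"] == pytest.approx(p)
        assert out["effect_name"] == "cohens_f"

    def test_degenerate_groups_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0], "g": ["a", "a", "b"]})
        with pytest.raises(ValueError):
            group_comparisons(df, "v", "g")
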