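"""Statistical battery tests: screening, correlations, stepwise, RM-ANOVA."""
import numpy as np
import pandas as pd
import pytest
from conftest import exhaustive_stepwise, synthetic_summaries
from scipy import stats as sps

from gsforce.stats import (
    DATASETS,
    correlation_magnitude,
    effect_magnitude,
    pearson_with_ci,
    rm_anova_holm,
    run_stepped_model,
    screen_normality,
    stepwise_regression,
)


class TestNormalityScreen:
    def test_outlier_sample_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        x[0] += 10.0
        flags = screen_normality(pd.DataFrame({"v": x}))
        assert flags[0].flagged and flags[0].p < 0.05

    def test_typical_normal_sample_passes(self):
        rng = np.random.default_rng(42)
        flags = screen_normality(pd.DataFrame({"v": rng.normal(size=15)}))
        assert not flags[0].flagged

    def test_constant_vector_degenerate(self):
        flags = screen_normality(pd.DataFrame({"v": np.ones(15)}))
        assert flags[0].degenerate and flags[0].p is None

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            screen_normality(pd.DataFrame({"v": [1.0, 2.0]}))

    def test_type_one_error_rate_near_alpha(self):
        """Shapiro-Wilk on normal data rejects at ~5%."""
        rng = np.random.default_rng(1)
        hits = sum(
            screen_normality(pd.DataFrame({"v": rng.normal(size=15)}))[0].flagged
            for _ in range(400)
        )
        assert 0.02 < hits / 400 < 0.09


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_with_ci(x, x).r == pytest.approx(1.0)
        assert pearson_with_ci(x, -x).r == pytest.approx(-1.0)

    def test_magnitude_labels_at_thresholds(self):
        assert correlation_magnitude(0.05) == "trivial"
        assert correlation_magnitude(0.2) == "small"
        assert correlation_magnitude(0.4) == "moderate"
        assert correlation_magnitude(0.6) == "strong"
        assert correlation_magnitude(-0.9) == "very strong"

    def test_constant_input_degenerate(self):
        out = pearson_with_ci(np.ones(10), np.arange(10.0))
        assert out.degenerate and np.isnan(out.r)

    def test_ci_contains_r(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(size=15)
        out = pearson_with_ci(x, y)
        assert out.ci_low <= out.r <= out.ci_high

    def test_fisher_ci_coverage(self):
        """95% CI covers rho=0.5 in 95% +/- 2% of bivariate-normal draws."""
        rng = np.random.default_rng(11)
        rho, n, hits, n_rep = 0.5, 15, 0, 1000
        cov = np.array([[1.0, rho], [rho, 1.0]])
        for _ in range(n_rep):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            out = pearson_with_ci(xy[:, 0], xy[:, 1])
            hits += out.ci_low <= rho <= out.ci_high
        assert hits / n_rep == pytest.approx(0.95, abs=0.02)


class TestStepwise:
    def test_exact_predictor_enters_alone(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"a": rng.normal(size=12), "b": rng.normal(size=12)})
        res = stepwise_regression(x["a"].to_numpy(), x, response="y")
        assert res.entered == ["a"]
        assert res.std_beta["a"] == pytest.approx(1.0, abs=1e-10)
        assert res.model_r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = 0.8 * x + rng.normal(size=20) * 0.5
        res = stepwise_regression(y, pd.DataFrame({"x": x}))
        assert res.std_beta["x"] == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)

    def test_pure_noise_gives_empty_model(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=30)
        x = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        res = stepwise_regression(y, x)
        # "no clear model prediction": nothing need enter on pure noise
        assert res.empty or all(p <= 0.05 for p in res.p_values.values())

    def test_r2_changes_sum_to_model_r2(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        y = x["a"] * 2 - x["b"] + rng.normal(size=25) * 0.3
        res = stepwise_regression(y.to_numpy(), x)
        assert sum(res.r2_change.values()) == pytest.approx(res.model_r2, abs=1e-10)

    @pytest.mark.parametrize("n_pred", [1, 2, 3])
    def test_agrees_with_exhaustive_subset_oracle(self, n_pred):
        """Selection matches the all-subsets replay on random datasets."""
        rng = np.random.default_rng(100 + n_pred)
        for _ in range(30):
            n = int(rng.integers(8, 20))
            X = rng.normal(size=(n, n_pred))
            coef = rng.normal(size=n_pred) * rng.integers(0, 2, size=n_pred)
            y = X @ coef + rng.normal(size=n) * rng.uniform(0.2, 2.0)
            frame = pd.DataFrame(X, columns=[f"x{j}" for j in range(n_pred)])
            res = stepwise_regression(y, frame)
            oracle = exhaustive_stepwise(y, X)
            assert res.entered == [f"x{j}" for j in oracle]


class TestRmAnova:
    def test_identical_conditions_null_effect(self):
        data = pd.DataFrame(np.tile(np.arange(10.0)[:, None], (1, 3)),
                            columns=["a", "b", "c"])
        out = rm_anova_holm(data)
        assert out.f_stat == pytest.approx(0.0, abs=1e-9)
        assert (out.pairwise["d_pooled"] == 0).all()

    def test_two_conditions_equal_paired_t_squared(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=12)
        b = a + 0.4 + rng.normal(size=12) * 0.3
        out = rm_anova_holm(pd.DataFrame({"a": a, "b": b}))
        t = sps.ttest_rel(a, b)
        assert out.f_stat == pytest.approx(t.statistic**2, abs=1e-8)
        assert out.p == pytest.approx(t.pvalue, abs=1e-10)

    def test_effect_magnitude_labels(self):
        assert effect_magnitude(0.1) == "trivial"
        assert effect_magnitude(0.3) == "small"
        assert effect_magnitude(0.6) == "moderate"
        assert effect_magnitude(0.7) == "moderate"
        # with thresholds 0.2/0.5/0.8 the top bin is "strong"
        assert effect_magnitude(-1.2) == "strong"

    def test_holm_dominates_raw_p(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        data["b"] += 0.5
        out = rm_anova_holm(data)
        pw = out.pairwise.sort_values("p_raw")
        assert (pw["p_holm"] >= pw["p_raw"] - 1e-15).all()
        assert pw["p_holm"].is_monotonic_increasing

    def test_incomplete_design_rejected(self):
        data = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, np.nan]})
        with pytest.raises(ValueError, match="complete"):
            rm_anova_holm(data)


class TestSteppedModel:
    @staticmethod
    def _cohort_frame(n=15, seed=0):
        rng = np.random.default_rng(seed)
        rows = {}
        de = rng.uniform(-6.5, -5.0, size=n)
        rows["T"] = -4.0 * de + rng.normal(size=n) * 0.1
        for d in DATASETS:
            f_tot = rng.uniform(1.4, 1.9, size=n)
            rf = rng.uniform(0.6, 0.76, size=n)
            rows[f"de_mech_per_vin_{d}"] = de + rng.normal(size=n) * 0.05
            rows[f"length_{d}"] = rng.uniform(24, 27, size=n)
            rows[f"f_tot_{d}"] = f_tot
            rows[f"rf_{d}"] = rf
            rows[f"f_r_{d}"] = f_tot * rf * (1 + rng.normal(size=n) * 0.002)
            rows[f"f_out_{d}"] = f_tot * 2 / 3
            rows[f"f_diff_{d}"] = np.full(n, 1 / 3) + rng.normal(size=n) * 0.02
        return pd.DataFrame(rows)

    def test_exact_linear_course_time_selected_with_unit_r2(self):
        frame = self._cohort_frame()
        frame["T"] = -3.0 * frame["de_mech_per_vin_course"]
        report = run_stepped_model(synthetic_summaries(frame))
        l1 = report.level1["course"]
        assert l1.entered[0] == "de_mech_per_vin"
        assert l1.model_r2 == pytest.approx(1.0, abs=1e-9)

    def test_report_covers_all_datasets_and_levels(self):
        report = run_stepped_model(synthetic_summaries(self._cohort_frame()))
        for level in (report.level1, report.level2, report.level3, report.level4):
            assert set(level) == set(DATASETS)
        d = report.to_dict()
        assert set(d["level2"]["course"]) == {"T", "de_mech_per_vin"}

    def test_quasi_identity_level3(self):
        report = run_stepped_model(synthetic_summaries(self._cohort_frame()))
        for ds in DATASETS:
            assert report.level3[ds].model_r2 > 0.99

    def test_small_cohort_warns_every_model(self):
        frame = self._cohort_frame(n=3)
        report = run_stepped_model(synthetic_summaries(frame))
        assert any("underpowered" in w for w in report.warnings)
        assert all(any("underpowered" in w for w in r.warnings)
                   for r in report.level1.values() if not r.empty)

    def test_excluded_athletes_are_dropped(self):
        frame = self._cohort_frame()
        from gsforce.config import StatsConfig

        report = run_stepped_model(
            synthetic_summaries(frame), StatsConfig(exclude_athletes=(0, 1))
        )
        assert report.n_athletes == 13
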