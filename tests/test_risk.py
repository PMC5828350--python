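import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearcohort import risk
from wearcohort.synth import simulate_interaction_cohort


def _record(**kw):
    base = dict(gender="male", bmi=24.0, wc=85.0, sbp=120.0, dbp=75.0,
                totalchol=5.0, hdl=1.4, ldl=3.0, tg=1.2, fbg=5.2)
    base.update(kw)
    return pd.DataFrame([base])


class TestDichotomize:
    @pytest.mark.parametrize(
        "kw,flag,expected",
        [
            (dict(bmi=27.5), "high_bmi", False),   # strict inequality
            (dict(bmi=27.51), "high_bmi", True),
            (dict(gender="male", wc=101.0), "high_wc", True),
            (dict(gender="male", wc=95.0), "high_wc", False),
            (dict(gender="female", wc=95.0), "high_wc", True),
            (dict(hdl=0.99), "low_hdl", True),
            (dict(hdl=1.0), "low_hdl", False),
            (dict(sbp=140.0), "high_sbp", False),
            (dict(dbp=90.5), "high_dbp", True),
            (dict(totalchol=6.3), "high_totalchol", True),
            (dict(ldl=4.2), "high_ldl", True),
            (dict(tg=2.31), "high_tg", True),
            (dict(fbg=6.01), "high_fbg", True),
        ],
    )
    def test_threshold_boundaries(self, kw, flag, expected):
        flags = risk.dichotomize(_record(**kw))
        assert bool(flags.loc[0, flag]) is expected

    def test_missing_value_gives_missing_flag(self):
        rec = _record()
        rec.loc[0, "fbg"] = np.nan
        flags = risk.dichotomize(rec)
        assert pd.isna(flags.loc[0, "high_fbg"])

    @given(bmi=st.floats(15, 40), delta=st.floats(0, 10))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_in_underlying_value(self, bmi, delta):
        """Raising BMI can set but never clear the high-BMI flag."""
        lo = risk.dichotomize(_record(bmi=bmi)).loc[0, "high_bmi"]
        hi = risk.dichotomize(_record(bmi=bmi + delta)).loc[0, "high_bmi"]
        assert hi or not lo


class TestFitLogistic:
    def test_interaction_estimate_close_to_truth_at_large_n(self):
        rng = np.random.default_rng(0)
        data = simulate_interaction_cohort(20_000, 0.70, rng)
        res = risk.fit_logistic(data, "flag", "daily_steps", model="steps")
        assert res.converged
        term = risk.interaction_term(res)
        assert term["or_"] == pytest.approx(0.70, abs=0.05)
        assert term["ci_low"] < 0.70 < term["ci_high"]

    def test_null_metric_ci_covers_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        data = pd.DataFrame(
            {
                "flag": (rng.random(n) < 0.25).astype(float),
                "gender": np.where(rng.random(n) < 0.5, "male", "female"),
                "age": rng.uniform(21, 69, n),
                "resting_hr": rng.normal(70, 7, n),
            }
        )
        res = risk.fit_logistic(data, "flag", "resting_hr", model="hr")
        term = risk.metric_term(res)
        assert term["ci_low"] < 1.0 < term["ci_high"]

    def test_single_gender_interaction_is_flagged_inestimable(self):
        rng = np.random.default_rng(2)
        data = simulate_interaction_cohort(300, 0.7, rng)
        data["gender"] = "female"
        res = risk.fit_logistic(data, "flag", "daily_steps", model="steps")
        assert not res.converged

    def test_single_class_outcome_flagged(self):
        data = simulate_interaction_cohort(100, 1.0, np.random.default_rng(3))
        data["flag"] = 0.0
        res = risk.fit_logistic(data, "flag", "daily_steps", model="steps")
        assert not res.converged and "single class" in res.message


class TestFitLinear:
    def test_near_noiseless_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame({"x": x, "y": 2.0 * x + rng.normal(0, 1e-8, 200)})
        res = risk.fit_linear(df, "y ~ x")
        assert res.term("x")["estimate"] == pytest.approx(2.0, abs=1e-6)

    def test_active_effect_recovered(self):
        rng = np.random.default_rng(1)
        n = 1000
        active = rng.random(n) < 0.6
        age = rng.uniform(21, 69, n)
        y = 70 - 3.0 * active + 0.05 * (age - 46) + rng.normal(0, 5, n)
        df = pd.DataFrame({"y": y, "active": active.astype(float), "age": age})
        res = risk.fit_linear(df, "y ~ age + active")
        t = res.term("active")
        assert t["ci_low"] < -3.0 < t["ci_high"]

    def test_permuted_outcome_ci_covers_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 500)
        y = rng.permutation(2 * x)
        res = risk.fit_linear(pd.DataFrame({"x": x, "y": y}), "y ~ x")
        t = res.term("x")
        assert t["ci_low"] < 0.0 < t["ci_high"]


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.arange(10.0)
        assert risk.bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        x = np.arange(10.0)
        assert risk.bland_altman(x + 5, x) == (5.0, 5.0, 5.0)

    def test_limits_approach_196_sigma(self):
        rng = np.random.default_rng(0)
        y = rng.normal(70, 8, 200_000)
        x = y + rng.normal(0, 3.0, 200_000)
        mean_diff, lo, hi = risk.bland_altman(x, y)
        assert mean_diff == pytest.approx(0.0, abs=0.05)
        assert hi - lo == pytest.approx(2 * 1.96 * 3.0, rel=0.01)

    def test_limits_symmetric_about_mean(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 50), rng.normal(0.5, 1, 50)
        mean_diff, lo, hi = risk.bland_altman(x, y)
        assert (hi - mean_diff) == pytest.approx(mean_diff - lo, abs=1e-12)

    def test_single_pair_absent(self):
        assert risk.bland_altman([1.0], [2.0]) is None


# the published cross-tabulation of occupational activity x weekly exercise
# hours (cycling excluded), transcribed as an independent oracle
GPPAQ_ORACLE = {
    ("sedentary", 0): 0, ("sedentary", 1): 1, ("sedentary", 2): 2, ("sedentary", 3): 3,
    ("standing", 0): 1, ("standing", 1): 2, ("standing", 2): 3, ("standing", 3): 3,
    ("physical", 0): 2, ("physical", 1): 3, ("physical", 2): 3, ("physical", 3): 3,
    ("heavy_manual", 0): 3, ("heavy_manual", 1): 3, ("heavy_manual", 2): 3, ("heavy_manual", 3): 3,
}


class TestGppaq:
    @pytest.mark.parametrize("occ,band", list(GPPAQ_ORACLE))
    def test_full_matrix_against_oracle(self, occ, band):
        assert risk.gppaq_pai(occ, band) == GPPAQ_ORACLE[(occ, band)]

    def test_cycling_hours_ignored(self):
        assert risk.gppaq_pai("sedentary", 0, cycling_band=3) == 0

    def test_missing_occupation_absent(self):
        assert risk.gppaq_pai(None, 2) is None
        assert risk.gppaq_pai("sedentary", None) is None

    def test_unknown_occupation_rejected(self):
        with pytest.raises(ValueError, match="occupation"):
            risk.gppaq_pai("astronaut", 1)


class TestActiveFlag:
    @pytest.mark.parametrize("steps,expected", [(8000.0, False), (8001.0, True), (None, None)])
    def test_strict_threshold(self, steps, expected):
        assert risk.active_flag(steps) is expected


class TestCohortSummary:
    def test_known_2x2_chi_squared_statistic(self):
        # hand formula: chi2 = sum (O-E)^2/E for table [[20,10],[10,20]]
        table = np.array([[20, 10], [10, 20]])
        assert risk.chi2_statistic(table) == pytest.approx(6.6667, abs=1e-4)

    def test_constant_variable_has_no_test(self):
        df = pd.DataFrame({"gender": ["female"] * 5 + ["male"] * 5, "x": 1.0})
        out = risk.cohort_summary(df, continuous=["x"])
        assert np.isnan(out.loc[0, "p"])

    def test_group_means_and_t_test(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "gender": ["female"] * 60 + ["male"] * 60,
                "x": np.concatenate([rng.normal(0, 1, 60), rng.normal(1.5, 1, 60)]),
            }
        )
        out = risk.cohort_summary(df, continuous=["x"], categorical=[])
        assert out.loc[0, "p"] < 1e-6

    def test_null_p_values_not_systematically_small(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(100):
            df = pd.DataFrame({"gender": ["female"] * 40 + ["male"] * 40, "x": rng.normal(size=80)})
            ps.append(risk.cohort_summary(df, continuous=["x"]).loc[0, "p"])
        assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.12
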