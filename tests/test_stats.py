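"""Group statistics: ANOVA, normative limits, regressions, trends."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st_

import mfphnr as m
from mfphnr.stats import (anova_from_summary, anova_oneway, classify_abnormal,
                          format_p, morphofunctional_regression,
                          normative_limit_from_summary, pearson, trend_fit)


def _col(cohort, region_type, region, measure):
    sel = cohort[(cohort.region_type == region_type) & (cohort.region == region)
                 & (cohort.measure == measure)]
    return sel.sort_values("eye_id")["value"].to_numpy()


class TestGroupSummary:
    def test_patient_means_match_published_summaries(self, reference_cohort,
                                                     reference_summaries):
        summ = m.group_summary(reference_cohort)
        pub = reference_summaries[reference_summaries.group == "patient"]
        merged = summ.merge(pub, on=["group", "region_type", "region", "measure"],
                            suffixes=("_calc", "_pub"))
        assert len(merged) == 14
        assert (merged["mean_calc"].round(3) == merged["mean_pub"]).all()
        assert (merged["sd_calc"].round(3) == merged["sd_pub"]).all()

    def test_constant_column_sd_zero(self):
        df = pd.DataFrame({"group": "patient", "region_type": "ring",
                           "region": "R1", "measure": "mfPhNR_RAD",
                           "value": [5.0, 5.0, 5.0]})
        out = m.group_summary(df)
        assert out.loc[0, "sd"] == 0.0


class TestAnova:
    def test_summary_form_reproduces_published_f(self, reference_cohort):
        r1 = _col(reference_cohort, "ring", "R1", "mfPhNR_RAD")
        F, df, p = anova_from_summary(30.047, 4.616, 20,
                                      r1.mean(), r1.std(ddof=1), 21)
        assert df == (1, 39)
        # control summaries are printed at 3 dp, so the recomputed F can
        # differ from the published 84.49 in the second decimal
        assert F == pytest.approx(84.49, abs=0.05)
        assert p < 0.001

    def test_identical_groups_f_zero(self):
        F, _, p = anova_oneway([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_unequal_means_infinite(self):
        F, _, p = anova_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)
        assert math.isinf(F) and p == 0.0

    @given(st_.integers(0, 10_000))
    def test_summary_form_equals_raw_form(self, seed):
        """Self-consistency oracle: summary-statistics F from the sample
        moments equals the raw-data F exactly."""
        rng = np.random.default_rng(seed)
        a = rng.normal(10, 3, rng.integers(3, 30))
        b = rng.normal(12, 2, rng.integers(3, 30))
        F_raw, df_raw, p_raw = anova_oneway(a, b)
        F_sum, df_sum, p_sum = anova_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
        assert df_raw == df_sum
        assert F_sum == pytest.approx(F_raw, rel=1e-9)
        assert p_sum == pytest.approx(p_raw, rel=1e-6)


class TestNormativeLimits:
    def test_closed_form(self):
        # mean - t(0.975, 19) * sd / sqrt(20)
        limit = normative_limit_from_summary(5.041, 1.431, 20)
        assert limit == pytest.approx(
            5.041 - 2.093 * 1.431 / math.sqrt(20), abs=1e-3)
        assert limit == pytest.approx(4.371, abs=0.001)

    def test_zero_sd_limit_is_mean(self):
        assert normative_limit_from_summary(7.0, 0.0, 10) == 7.0

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            normative_limit_from_summary(5.0, 1.0, 1)

    def test_supplied_limits_echo_inputs(self):
        table = m.load_reference_limits()
        limits = m.supplied_normative_limits(table)
        assert limits.method == "supplied"
        assert limits.limit_for("area", "Area3", "GCL_T") == 23.27
        assert limits.limit_for("ring", "R1", "mfPhNR_RAD") == 26.92


class TestClassification:
    def test_published_abnormal_fractions(self, reference_cohort):
        area3 = _col(reference_cohort, "area", "Area3", "GCL_T")
        _, n_ab, pct = classify_abnormal(area3, 23.27)
        assert n_ab == 20 and round(pct, 1) == 95.2
        sn = _col(reference_cohort, "sector", "SN", "GCL_T")
        _, n_ab, pct = classify_abnormal(sn, 28.83)
        assert n_ab == 15 and round(pct, 1) == 71.4

    def test_value_at_limit_is_normal(self):
        flags, n_ab, _ = classify_abnormal([5.0, 4.9, 5.1], 5.0)
        assert list(flags) == [False, True, False] and n_ab == 1

    @given(st_.floats(0, 50), st_.floats(0, 50))
    def test_raising_limit_is_monotone(self, lim1, lim2):
        values = np.linspace(0, 50, 23)
        lo, hi = sorted((lim1, lim2))
        assert classify_abnormal(values, lo)[1] <= classify_abnormal(values, hi)[1]


class TestRegression:
    def test_published_slope_and_r2(self, reference_cohort):
        rad = _col(reference_cohort, "ring", "R1", "mfPhNR_RAD")
        gcl = _col(reference_cohort, "area", "Area1", "GCL_T")
        res = morphofunctional_regression(rad, gcl)
        assert round(res.slope, 2) == 0.75
        # the published R^2 (0.80) was computed from unrounded raw values;
        # recomputing from the 1-dp printed individuals gives 0.805
        assert res.r2 == pytest.approx(0.80, abs=0.015)
        assert res.p < 0.001
        assert res.ci_low == pytest.approx(0.57, abs=0.02)
        assert res.ci_high == pytest.approx(0.92, abs=0.02)

    def test_st_sector_r2(self, reference_cohort):
        rad = _col(reference_cohort, "sector", "ST", "mfPhNR_RAD")
        gcl = _col(reference_cohort, "sector", "ST", "GCL_T")
        res = morphofunctional_regression(rad, gcl)
        assert res.r2 == pytest.approx(0.53, abs=0.015)

    def test_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = morphofunctional_regression(2 * x, x)
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_slope_equals_r_times_sd_ratio(self):
        rng = np.random.default_rng(8)
        x = rng.normal(30, 5, 25)
        y = 0.5 * x + rng.normal(0, 2, 25)
        res = morphofunctional_regression(y, x)
        r, _, _ = pearson(y, x)
        assert res.slope == pytest.approx(r * y.std(ddof=1) / x.std(ddof=1),
                                          rel=1e-9)

    def test_zero_variance_regressor_rejected(self):
        with pytest.raises(ValueError):
            morphofunctional_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestPearson:
    def test_anticorrelated_pair(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, r2, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r, _, _ = pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        direct = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(direct, rel=1e-12)


class TestTrendFit:
    def test_published_eccentricity_slopes(self, reference_cohort):
        vals, idx = [], []
        for i, region in enumerate(["Area1", "Area2", "Area3"]):
            v = _col(reference_cohort, "area", region, "GCL_T")
            vals += v.tolist()
            idx += [i] * len(v)
        fits, _ = trend_fit(vals, idx, ["patient"] * len(vals))
        assert round(fits["patient"].slope, 2) == -3.32
        cm = [45.224, 33.150, 24.030]
        fits, _ = trend_fit(cm, [0, 1, 2], ["control"] * 3)
        assert round(fits["control"].slope, 2) == -10.60

    def test_individuals_equal_means_when_balanced(self):
        """Balanced complete design: slope on individuals equals slope on
        the level means (algebraic identity)."""
        rng = np.random.default_rng(10)
        means = [30.0, 25.0, 18.0]
        vals, idx = [], []
        for i, mu in enumerate(means):
            vals += (mu + rng.normal(0, 3, 12)).tolist()
            idx += [i] * 12
        fits_ind, _ = trend_fit(vals, idx, ["g"] * len(vals))
        level_means = [np.mean([v for v, j in zip(vals, idx) if j == i])
                       for i in range(3)]
        fits_mean, _ = trend_fit(level_means, [0, 1, 2], ["g"] * 3)
        assert fits_ind["g"].slope == pytest.approx(fits_mean["g"].slope,
                                                    abs=1e-9)

    def test_flat_means_slope_zero_and_interaction(self):
        vals = [5.0, 5.0, 5.0, 1.0, 3.0, 5.0] * 4
        idx = [0, 1, 2, 0, 1, 2] * 4
        grp = (["a"] * 3 + ["b"] * 3) * 4
        fits, p_int = trend_fit(vals, idx, grp)
        assert fits["a"].slope == pytest.approx(0.0, abs=1e-12)
        assert fits["b"].slope == pytest.approx(2.0)
        assert p_int < 0.01  # slopes genuinely differ

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            trend_fit([1.0, 2.0], [0, 0], ["a", "a"])


def test_p_value_formatting():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.0234) == "0.023"
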