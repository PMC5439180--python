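"""Distribution-shape descriptors, normality screen, and t comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neurofrac as nf

# published two-tailed Student-t critical values (alpha = 0.05)
T_TABLE_05 = {
    1: 12.706, 2: 4.303, 3: 3.182, 4: 2.776, 5: 2.571, 6: 2.447, 7: 2.365,
    8: 2.306, 9: 2.262, 10: 2.228, 12: 2.179, 15: 2.131, 20: 2.086,
    22: 2.074, 23: 2.069, 25: 2.060, 30: 2.042, 60: 2.000, 120: 1.980,
}


class TestMoments:
    def test_symmetric_sample_zero_skew(self):
        assert nf.skewness_a3([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_skewness_frozen_value(self):
        # m2 = 0.1875, m3 = 0.09375 -> a3 = 0.09375 / 0.1875**1.5
        assert nf.skewness_a3([0, 0, 0, 1]) == pytest.approx(1.1547, abs=1e-4)

    def test_two_point_excess(self):
        assert nf.excess_e([0, 1] * 8) == pytest.approx(-2.0, abs=1e-12)

    def test_excess_of_large_normal_sample_near_zero(self):
        x = np.random.default_rng(7).normal(size=100_000)
        assert nf.excess_e(x) == pytest.approx(0.0, abs=0.05)

    @given(
        a=st.floats(0.1, 10), b=st.floats(-100, 100),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_location_scale_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=20)
        assert nf.skewness_a3(a * x + b) == pytest.approx(nf.skewness_a3(x), abs=1e-8)
        assert nf.excess_e(a * x + b) == pytest.approx(nf.excess_e(x), abs=1e-8)

    def test_odd_symmetry_of_skewness(self):
        x = np.random.default_rng(3).normal(size=30)
        assert nf.skewness_a3(-x) == pytest.approx(-nf.skewness_a3(x), abs=1e-12)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            nf.skewness_a3([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            nf.excess_e([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            nf.skewness_a3([1.0, 2.0])


class TestStandardErrors:
    def test_sigma3_reference_values(self):
        assert nf.sigma3(24) == pytest.approx(0.452, abs=5e-4)
        assert nf.sigma3(9) == pytest.approx(np.sqrt(48 / 120), abs=1e-12)

    def test_sigma3_monotone_decreasing(self):
        vals = [nf.sigma3(n) for n in range(4, 60)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_sigma4_exact_and_published(self):
        assert nf.sigma4(24, source="exact") == pytest.approx(0.737, abs=5e-4)
        assert nf.sigma4(24, source="published") == 0.768
        # fallback when no published value exists
        assert nf.sigma4(20, source="published") == nf.sigma4(20, source="exact")

    def test_sigma4_monotone_decreasing_beyond_mode(self):
        # the exact excess SE rises from n=6 to a mode near n=15 before
        # its asymptotic sqrt(24/n) decay; monotone decrease holds after
        vals = [nf.sigma4(n) for n in range(15, 200)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_minimum_sample_sizes(self):
        with pytest.raises(ValueError):
            nf.sigma3(3)
        with pytest.raises(ValueError):
            nf.sigma4(5)


class TestNormalityScreen:
    def test_published_mode_reproduces_reference_row(self):
        # binary D_B under the standard schedule: a3 = -0.292, e = -1.352,
        # n = 24 -> ratios sigma3/a3 = 1.548, sigma4/e = 0.568, both <= 2
        r_skew = abs(nf.sigma3(24) / -0.292)
        r_exc = abs(nf.sigma4(24, "published") / -1.352)
        assert r_skew == pytest.approx(1.548, abs=2e-3)
        assert r_exc == pytest.approx(0.568, abs=2e-3)
        assert r_skew <= 2 and r_exc <= 2

    def test_modes_disagree_on_wide_excess(self):
        # a3 = 0.401, e = -1.930 at n = 24: published mode passes but the
        # conventional ratio |e|/sigma4 = 2.51 exceeds 2
        assert abs(nf.sigma3(24) / 0.401) <= 2
        assert abs(nf.sigma4(24, "published") / -1.930) <= 2
        assert abs(-1.930 / nf.sigma4(24, "published")) == pytest.approx(2.51, abs=0.01)

    def test_conventional_mode_passes_normal_samples(self):
        rng = np.random.default_rng(42)
        passed = sum(
            nf.normality_check(rng.normal(size=24), mode="conventional").normal
            for _ in range(100)
        )
        assert passed >= 90

    def test_published_mode_rejects_zero_statistics(self):
        sym = np.array([-2.0, -1.0, -1.0, 0.0, 1.0, 1.0, 2.0])  # a3 exactly 0
        with pytest.raises(ZeroDivisionError):
            nf.normality_check(sym, mode="published")
        res = nf.normality_check(sym, mode="conventional")
        assert res.ratio_skew == 0.0

    def test_result_truthiness(self):
        rng = np.random.default_rng(1)
        res = nf.normality_check(rng.normal(size=24), mode="conventional")
        assert bool(res) == res.normal


class TestTTests:
    def test_paired_frozen_example(self):
        res = nf.paired_t([1, 2, 3, 4], [0, 1, 2, 4])
        assert res.t_c == pytest.approx(3.0, abs=1e-12)
        assert res.df == 3
        assert res.kind == "paired"

    def test_paired_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            nf.paired_t([1, 2, 3], [1, 2, 3])

    def test_paired_antisymmetry(self):
        x = [1.1, 2.3, 3.1, 4.0]
        y = [0.9, 2.0, 3.3, 3.1]
        assert nf.paired_t(x, y).t_c == pytest.approx(-nf.paired_t(y, x).t_c)

    def test_two_sample_frozen_examples(self):
        assert nf.two_sample_t([1, 2, 3], [1, 2, 3]).t_c == 0.0
        res = nf.two_sample_t([0, 1], [2, 3])
        assert res.t_c == pytest.approx(-2.828, abs=5e-4)
        assert res.df == 2

    def test_region_cohort_sizes_give_df_22(self):
        rng = np.random.default_rng(0)
        res = nf.two_sample_t(rng.normal(size=15), rng.normal(size=9))
        assert res.df == 22
        assert res.t_critical[0.05] == pytest.approx(2.074, abs=5e-4)

    @given(a=st.floats(0.1, 5), b=st.floats(-10, 10), seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=8)
        t0 = nf.two_sample_t(x, y).t_c
        t1 = nf.two_sample_t(a * x + b, a * y + b).t_c
        assert t1 == pytest.approx(t0, abs=1e-8)

    def test_significance_levels_ordered(self):
        res = nf.two_sample_t([0.0, 0.1, 0.2], [5.0, 5.1, 5.2])
        crit = res.t_critical
        assert crit[0.05] < crit[0.01] < crit[0.001]
        assert res.significant_at == 0.001


class TestCriticalT:
    def test_against_published_table(self):
        for df, expected in T_TABLE_05.items():
            assert nf.critical_t(0.05, df) == pytest.approx(expected, abs=5e-4)

    def test_normal_limit(self):
        assert nf.critical_t(0.05, np.inf) == pytest.approx(1.960, abs=5e-4)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            nf.critical_t(0.0, 10)
        with pytest.raises(ValueError):
            nf.critical_t(0.05, 0)


class TestGroupSummary:
    def test_mean_and_se_frozen(self):
        gs = nf.group_summary([1, 2, 3, 4, 5, 6], normality_mode="conventional")
        assert gs.mean == pytest.approx(3.5)
        assert gs.SE == pytest.approx(0.7638, abs=5e-5)
        assert gs.n == 6

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            nf.group_summary([2.0] * 10)

    def test_summary_text(self):
        gs = nf.group_summary(
            np.random.default_rng(5).normal(size=24), normality_mode="conventional"
        )
        text = gs.summary()
        assert "mean" in text and "sigma3" in text


class TestPercentDifference:
    def test_reference_schedule_differences(self):
        ref = nf.stats.TYPE_III_REFERENCE_MEANS
        diffs = {
            rep: nf.percent_difference(v["standard"], v["modified"])
            for rep, v in ref.items()
        }
        assert round(diffs["binary"], 1) == 2.7
        assert round(diffs["outline"], 1) == 0.7
        assert round(diffs["skeleton"], 1) == 0.4
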