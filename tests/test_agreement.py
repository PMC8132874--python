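import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import thermoagree as ta
from thermoagree.agreement import bland_altman_plot_data
from conftest import dataset_from_diffs, icc_anova_oracle


class TestPairedTTest:
    def test_zero_mean_symmetric_set(self):
        t, p, n = ta.paired_t_test([0.0, 0.5, -0.5, 0.2, -0.2])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert n == 5

    def test_hand_computed_statistic(self):
        # mean 4/3, sd 1/sqrt(3): t = (4/3) / ((1/sqrt(3))/sqrt(3)) = 4
        t, p, n = ta.paired_t_test([1.0, 1.0, 2.0])
        assert t == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(4.0, df=2))

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            ta.paired_t_test([0.3])

    def test_zero_spread_rejected_even_with_zero_mean(self):
        for diffs in ([0.0, 0.0, 0.0], [0.4, 0.4, 0.4]):
            with pytest.raises(ValueError, match="zero-variance"):
                ta.paired_t_test(diffs)


class TestBlandAltman:
    def test_degenerate_all_zero(self):
        ba = ta.bland_altman([0.0, 0.0, 0.0])
        assert (ba.bias, ba.sd, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0, 0.0)

    def test_three_point_hand_case(self):
        ba = ta.bland_altman([-1.0, 0.0, 1.0])
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(-1.96)
        assert ba.loa_high == pytest.approx(1.96)

    def test_ci_formulas_match_direct_computation(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.1, 0.4, 80)
        ba = ta.bland_altman(d, alpha=0.05)
        n, sd = 80, d.std(ddof=1)
        tq = stats.t.ppf(0.975, 79)
        assert ba.bias_ci == pytest.approx(
            (d.mean() - tq * sd / math.sqrt(n), d.mean() + tq * sd / math.sqrt(n))
        )
        se_loa = sd * math.sqrt(1 / n + 1.96**2 / (2 * (n - 1)))
        assert ba.loa_high_ci == pytest.approx(
            (ba.loa_high - tq * se_loa, ba.loa_high + tq * se_loa)
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ta.bland_altman([0.1, 0.2])

    @given(
        st.lists(st.floats(-2, 2), min_size=3, max_size=60),
    )
    @settings(max_examples=200, derandomize=True)
    def test_loa_midpoint_and_width_identities(self, diffs):
        ba = ta.bland_altman(diffs)
        assert (ba.loa_low + ba.loa_high) / 2 == pytest.approx(ba.bias, abs=1e-9)
        assert ba.loa_high - ba.loa_low == pytest.approx(3.92 * ba.sd, abs=1e-9)


class TestIccConsistency:
    def test_identical_columns_give_unity(self):
        x = np.array([31.0, 33.0, 34.0, 35.5, 37.0])
        icc, ci = ta.icc_consistency(x, x)
        assert icc == 1.0
        assert ci == (1.0, 1.0)

    def test_constant_offset_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        icc, _ = ta.icc_consistency(x, x + 1.0)
        assert icc == pytest.approx(1.0, abs=1e-12)

    def test_all_equal_values_rejected(self):
        with pytest.raises(ValueError, match="no variance"):
            ta.icc_consistency(np.full(6, 34.0), np.full(6, 34.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n >= 5"):
            ta.icc_consistency([1.0, 2.0, 3.0, 4.0], [1.1, 2.1, 3.1, 4.1])

    @pytest.mark.parametrize("n", [5, 6, 12, 23, 50])
    def test_matches_elementwise_anova_oracle(self, n):
        rng = np.random.default_rng(n)
        s = rng.normal(34.0, 1.4, n)
        x = s + rng.normal(0, 0.4, n)
        y = s + rng.normal(0, 0.4, n)
        icc, _ = ta.icc_consistency(x, y)
        assert icc == pytest.approx(icc_anova_oracle(x, y), abs=1e-10)

    def test_matches_pingouin_point_and_interval(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        s = rng.normal(0, 1.5, 40)
        x = s + rng.normal(0, 0.5, 40)
        y = s + rng.normal(0, 0.5, 40)
        table = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": ["a", "b"] * 40,
                "rating": np.column_stack([x, y]).ravel(),
            }
        )
        res = pg.intraclass_corr(table, "subject", "rater", "rating").set_index("Type")
        for type_label, absolute in (("ICC(C,1)", False), ("ICC(A,1)", True)):
            icc, ci = ta.icc_consistency(x, y, absolute=absolute)
            row = res.loc[type_label]
            assert icc == pytest.approx(row["ICC"], abs=1e-9)
            # pingouin reports the interval rounded to 2 decimals
            assert ci == pytest.approx(tuple(row["CI95"]), abs=0.006)

    def test_large_sample_limit_is_variance_ratio(self):
        """ICC converges to sigma_b^2 / (sigma_b^2 + sigma_e^2)."""
        rng = np.random.default_rng(11)
        n = 10_000
        s = rng.normal(0, math.sqrt(0.9), n)
        x = s + rng.normal(0, math.sqrt(0.1), n)
        y = s + rng.normal(0, math.sqrt(0.1), n)
        icc, _ = ta.icc_consistency(x, y)
        assert icc == pytest.approx(0.9, abs=0.01)


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "icc, label",
        [
            (0.94, "excellent"),
            (0.75, "excellent"),
            (0.74, "good"),
            (0.60, "good"),
            (0.59, "moderate"),
            (0.40, "moderate"),
            (0.39, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_cutoffs(self, icc, label):
        assert ta.classify_icc(icc) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ta.classify_icc(float("nan"))


class TestPctWithinThreshold:
    @pytest.mark.parametrize(
        "diffs, expected",
        [
            ([0.0, 0.0, 0.0], 100.0),
            ([0.1, 0.6, -0.4], pytest.approx(200.0 / 3.0)),
            ([0.5], 100.0),  # boundary inclusive
        ],
    )
    def test_examples(self, diffs, expected):
        assert ta.pct_within_threshold(diffs, 0.5) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ta.pct_within_threshold([], 0.5)

    def test_gaussian_closed_form_limit(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.1, 0.5, 100_000)
        expected = 100.0 * (stats.norm.cdf(0.8) - stats.norm.cdf(-1.2))
        assert ta.pct_within_threshold(d, 0.5) == pytest.approx(expected, abs=0.5)


class TestTypeICalibration:
    def test_null_rejection_rate_near_alpha(self):
        """With zero injected bias the paired t-test rejects ~5 % of runs."""
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(1000):
            _, p, _ = ta.paired_t_test(rng.normal(0.0, 0.53, 50))
            rejections += p < 0.05
        assert rejections / 1000 == pytest.approx(0.05, abs=0.015)


class TestBuildReport:
    def test_report_invariants_on_simulated_cohort(self, cohort20):
        _, _, filtered = cohort20
        r = ta.build_report(filtered)
        assert r.n == filtered.n_retained
        assert r.n_candidate_pairs == filtered.n_total
        assert (r.loa_low + r.loa_high) / 2 == pytest.approx(r.bias, abs=1e-12)
        assert r.loa_high - r.loa_low == pytest.approx(3.92 * r.sd, abs=1e-9)
        assert r.icc_ci[0] <= r.icc <= r.icc_ci[1]
        assert 0.0 <= r.pct_within <= 100.0
        assert r.icc_class == ta.classify_icc(r.icc)

    def test_serialization_round_trip(self, cohort20):
        _, _, filtered = cohort20
        r = ta.build_report(filtered)
        assert ta.AgreementReport.from_json(r.to_json()) == r

    def test_degenerate_perfect_agreement(self):
        # varying level, identical methods: ICC is exactly 1, t undefined
        level = np.linspace(33.0, 37.0, 12)
        frame = pd.DataFrame(
            {
                "t": np.arange(12.0) * 1800,
                "ds_core": level,
                "ref": level,
                "diff": np.zeros(12),
                "artifact": False,
            }
        )
        r = ta.build_report(ta.PairedDataset(frame=frame, filtered=True))
        assert r.bias == 0.0
        assert r.icc == 1.0
        assert math.isnan(r.t_stat) and math.isnan(r.p_value)
        assert any("undefined" in note for note in r.notes)

    def test_unfiltered_dataset_rejected(self):
        with pytest.raises(ValueError, match="filtered"):
            ta.build_report(dataset_from_diffs([0.1, 0.2, 0.3]))

    def test_plot_data_matches_retained_pairs(self, cohort20):
        _, _, filtered = cohort20
        r = ta.build_report(filtered)
        points, lines = bland_altman_plot_data(filtered, r)
        assert len(points) == filtered.n_retained
        expected_mean = (filtered.retained["ds_core"] + filtered.retained["ref"]) / 2
        assert np.allclose(points["mean"], expected_mean)
        assert lines == {
            "bias": r.bias, "loa_low": r.loa_low, "loa_high": r.loa_high
        }
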