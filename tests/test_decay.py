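"""Decay-curve analysis: smoothing, baseline, YFP50, dist50 and averaging.

Expected values were computed with independent oracles: direct
convolution for the moving average, arithmetic by hand for baselines and
YFP50, and a dense-grid (0.001 µm) scan of the closed-form exponential
for dist50.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from colidecay import decay as dk
from colidecay import profiles as pf


def _dense_scan_dist50(fn, level, hi=2000.0, res=0.001):
    """Brute-force oracle: first d (on a 0.001-µm grid) where fn(d) < level."""
    d = np.arange(0.0, hi, res)
    below = np.flatnonzero(fn(d) < level)
    return d[below[0]]


class TestSmoothing:
    def test_constant_preserved(self):
        assert np.allclose(dk.smooth_profile(np.full(50, 3.5), 20), 3.5)

    def test_window_one_is_identity(self):
        y = np.random.default_rng(0).normal(size=30)
        np.testing.assert_array_equal(dk.smooth_profile(y, 1), y)

    def test_linear_ramp_unchanged_in_interior(self):
        y = np.arange(100.0)
        s = dk.smooth_profile(y, 20)
        np.testing.assert_allclose(s[10:-10], y[10:-10], atol=1e-9)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=60)
        s = dk.smooth_profile(y, 8)
        # oracle: brute-force symmetric truncated mean at each index
        h0 = 8 // 2
        expected = [
            y[i - min(h0, i, 59 - i): i + min(h0, i, 59 - i) + 1].mean()
            for i in range(60)
        ]
        np.testing.assert_allclose(s, expected, atol=1e-12)

    @given(arrays(float, st.integers(2, 80),
                  elements=st.floats(-1e3, 1e3)))
    @settings(max_examples=40, deadline=None)
    def test_never_extends_value_range(self, y):
        s = dk.smooth_profile(y, 20)
        assert s.min() >= y.min() - 1e-9 and s.max() <= y.max() + 1e-9

    def test_masked_smoothing_respects_gaps(self):
        y = np.concatenate([np.full(30, 10.0), np.full(10, 1e6), np.full(30, 20.0)])
        mask = np.ones(70, bool)
        mask[30:40] = False
        s = dk.smooth_masked(y, mask, 10)
        assert np.all(np.isnan(s[30:40]))
        assert np.allclose(s[:30], 10.0) and np.allclose(s[40:], 20.0)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            dk.smooth_profile(np.ones(5), 0)


class TestBaseline:
    def test_constant_vector(self):
        assert dk.estimate_baseline(np.full(40, 5.0)) == 5.0

    def test_tail_mean_of_last_20(self):
        y = np.concatenate([np.full(30, 99.0), np.arange(1.0, 21.0)])
        assert dk.estimate_baseline(y, n_tail=20) == pytest.approx(10.5)

    def test_length_exactly_n_tail_uses_whole_vector(self):
        y = np.arange(1.0, 21.0)
        assert dk.estimate_baseline(y, n_tail=20) == pytest.approx(10.5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            dk.estimate_baseline(np.ones(10), n_tail=20)

    def test_subtraction_zeroes_reestimated_baseline(self):
        rng = np.random.default_rng(4)
        y = 100.0 + rng.normal(size=80)
        b = dk.estimate_baseline(y)
        assert dk.estimate_baseline(dk.subtract_baseline(y, b)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_subtract_arithmetic(self):
        np.testing.assert_allclose(
            dk.subtract_baseline(np.array([10.0, 8.0, 6.0]), 6.0), [4.0, 2.0, 0.0]
        )


class TestYfp50:
    @pytest.mark.parametrize(
        "maximum,baseline,expected", [(100.0, 0.0, 50.0), (130.0, 30.0, 80.0)]
    )
    def test_halfway_value(self, maximum, baseline, expected):
        assert dk.compute_yfp50(maximum, baseline) == expected

    def test_max_below_baseline_rejected(self):
        with pytest.raises(ValueError):
            dk.compute_yfp50(10.0, 20.0)


class TestDist50:
    def test_linear_decay_midpoint(self):
        d = np.arange(0.0, 201.0)
        y = 100.0 * (1.0 - d / 200.0)
        assert dk.compute_dist50(d, y, 50.0).value == pytest.approx(100.0)

    def test_exponential_matches_dense_scan_oracle(self):
        d = np.arange(0.0, 1000.0, 1.0)
        y = 100.0 * np.exp(-d / 100.0)
        got = dk.compute_dist50(d, y, 50.0).value
        oracle = _dense_scan_dist50(lambda x: 100.0 * np.exp(-x / 100.0), 50.0)
        assert oracle == pytest.approx(100.0 * np.log(2), abs=0.002)
        assert got == pytest.approx(oracle, abs=0.5)

    def test_monotone_increase_flags_no_crossing(self):
        d = np.arange(0.0, 100.0)
        res = dk.compute_dist50(d, d.copy(), 50.0)
        assert res.value is None and res.flag == "no-crossing"

    def test_unaligned_profile_rejected(self):
        with pytest.raises(ValueError, match="not aligned"):
            dk.compute_dist50(np.arange(50.0, 150.0), np.linspace(100, 0, 100), 50.0)

    def test_affine_invariance(self, synthetic_decay_profile):
        prof = synthetic_decay_profile
        res = dk.analyze_contacting(prof)
        scaled = pf.CrossSectionProfile(
            distances=prof.distances,
            intensities={"YFP": 3.0 * prof.channel("YFP") + 50.0},
            mask=prof.mask,
        )
        res_scaled = dk.analyze_contacting(scaled)
        assert res.dist50 == pytest.approx(res_scaled.dist50, abs=1e-6)


class TestNoncontacting:
    def test_consistent_with_contacting_on_identical_profile(self):
        d = np.arange(0.0, 600.0)
        y = 1000.0 * np.exp(-d / 100.0)
        yfp50 = dk.compute_yfp50(float(y.max()), 0.0)
        a = dk.compute_dist50(d, y, yfp50).value
        b = dk.infer_dist50_noncontacting(d, y, yfp50).value
        assert a == pytest.approx(b, abs=1e-9)

    def test_gap_masked_exponential_matches_oracle(self):
        d = np.arange(0.0, 900.0, 1.0)
        y = 1000.0 * np.exp(-d / 100.0)
        mask = ~((d >= 0.0) & (d <= 50.0))
        res = dk.infer_dist50_noncontacting(d, y, 500.0, mask)
        assert res.value == pytest.approx(100.0 * np.log(2), abs=0.5)

    def test_crossing_inside_gap_flagged(self):
        d = np.arange(0.0, 900.0, 1.0)
        y = 1000.0 * np.exp(-d / 100.0)
        mask = ~((d >= 0.0) & (d <= 120.0))  # crossing at 69.3 falls in the gap
        res = dk.infer_dist50_noncontacting(d, y, 500.0, mask)
        assert res.value is None and res.flag == "crossing-in-gap"

    def test_reference_above_profile_flagged(self):
        d = np.arange(0.0, 300.0)
        y = 100.0 * np.exp(-d / 100.0)
        res = dk.infer_dist50_noncontacting(d, y, 1e4)
        assert res.value is None and res.flag == "reference-above-profile"


class TestPeakAndScaling:
    def test_constant_profile_tie_breaks_to_smallest_distance(self):
        v, d = dk.peak_signal(np.arange(10.0), np.full(10, 4.0))
        assert (v, d) == (4.0, 0.0)

    def test_single_spike_found(self):
        d = np.arange(0.0, 300.0)
        y = np.zeros(300)
        y[120] = 50.0
        assert dk.peak_signal(d, y) == (50.0, 120.0)

    def test_fully_masked_rejected(self):
        with pytest.raises(ValueError):
            dk.peak_signal(np.arange(5.0), np.ones(5), np.zeros(5, bool))

    def test_smoothed_noisy_exponential_peaks_near_origin(self):
        rng = np.random.default_rng(8)
        d = np.arange(0.0, 600.0)
        y = 1000.0 * np.exp(-d / 150.0) + rng.normal(0, 20, d.size)
        s = dk.smooth_profile(y, 20)
        _, peak_d = dk.peak_signal(d, s)
        assert peak_d <= 20.0

    def test_minmax_examples(self):
        np.testing.assert_allclose(
            dk.minmax_scale(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0]
        )
        y = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(dk.minmax_scale(y), y)

    def test_minmax_affine_identity(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=50)
        np.testing.assert_allclose(
            dk.minmax_scale(y), dk.minmax_scale(2.7 * y + 11.0), atol=1e-12
        )

    def test_minmax_constant_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            dk.minmax_scale(np.full(5, 2.0))


class TestAveraging:
    def test_identical_replicates_have_zero_sd(self):
        d = np.arange(0.0, 50.0)
        y = np.exp(-d / 10.0)
        out = dk.average_decays([(d, y, None)] * 4)
        assert np.allclose(out["sd"], 0.0)
        np.testing.assert_allclose(out["mean"], y, atol=1e-12)

    def test_single_profile_flags_undefined_sd(self):
        d = np.arange(0.0, 30.0)
        out = dk.average_decays([(d, d.copy(), None)], min_n=2)
        assert out["sd"].isna().all()
        assert out["low_n"].all()

    def test_two_profiles_hand_computed_sd(self):
        d = np.array([0.0, 1.0, 2.0])
        out = dk.average_decays(
            [(d, np.array([1.0, 2.0, 3.0]), None), (d, np.array([3.0, 2.0, 1.0]), None)],
            step=1.0,
        )
        np.testing.assert_allclose(out["mean"], [2.0, 2.0, 2.0])
        np.testing.assert_allclose(out["sd"], [np.sqrt(2.0), 0.0, np.sqrt(2.0)])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            dk.average_decays([])


class TestAnalyze:
    def test_no_response_flag_on_flat_profile(self):
        rng = np.random.default_rng(10)
        d = np.arange(0.0, 400.0)
        y = 100.0 + rng.normal(0, 10, d.size)
        prof = pf.CrossSectionProfile(
            distances=d, intensities={"YFP": y}, mask=np.ones(d.size, bool)
        )
        res = dk.analyze_contacting(prof)
        assert not res.valid and "no-response" in res.reasons
        assert res.dist50 is None

    def test_exponential_profile_recovers_lambda_ln2(self, synthetic_decay_profile):
        res = dk.analyze_contacting(synthetic_decay_profile)
        assert res.valid
        assert res.dist50 == pytest.approx(100.0 * np.log(2), abs=10.0)
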