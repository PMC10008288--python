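import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracle
from envregimes import RegimeConfig, ValidationError, compute_index_set
from envregimes.indices import (
    count_changes,
    count_pulses,
    ma1_mean,
    ma2_median,
    ma3_cv,
    ma4_skew,
    pulse_thresholds,
    rc_rate_of_change,
)

ONE_TO_TEN = np.arange(1.0, 11.0)

windows = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False, width=32),
    min_size=2,
    max_size=40,
).map(np.asarray)

# Integer-valued windows: shifting/scaling by an integer is then exact in
# float64, so count equalities probe the invariant, not rounding artifacts.
grid_windows = st.lists(
    st.integers(min_value=-10**6, max_value=10**6).map(float),
    min_size=2,
    max_size=40,
).map(np.asarray)


class TestMagnitude:
    @pytest.mark.parametrize(
        "values,expected",
        [(ONE_TO_TEN, 5.5), (np.full(5, 3.0), 3.0), ([2, 4, 9], 5.0)],
    )
    def test_mean(self, values, expected):
        assert ma1_mean(values) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "values,expected",
        [(ONE_TO_TEN, 5.5), ([1, 2, 100], 2.0), (np.full(4, 7.0), 7.0)],
    )
    def test_median(self, values, expected):
        assert ma2_median(values) == pytest.approx(expected)

    def test_cv_of_one_to_ten(self):
        # sd(1..10, ddof=1) = 3.02765..., /5.5 * 100
        expected = 100 * math.sqrt(sum((v - 5.5) ** 2 for v in ONE_TO_TEN) / 9) / 5.5
        assert ma3_cv(ONE_TO_TEN) == pytest.approx(expected, rel=1e-12)
        assert ma3_cv(ONE_TO_TEN) == pytest.approx(55.048188, rel=1e-6)

    def test_cv_constant_is_zero(self):
        assert ma3_cv(np.full(8, 4.2)) == 0.0

    def test_cv_zero_mean_missing(self):
        assert math.isnan(ma3_cv([-1.0, 1.0]))

    def test_cv_scale_invariant(self):
        assert ma3_cv(ONE_TO_TEN * 17.3) == pytest.approx(ma3_cv(ONE_TO_TEN), rel=1e-12)

    def test_skew_symmetric_is_zero(self):
        assert ma4_skew([1.0, 2.0, 3.0]) == pytest.approx(0.0, abs=1e-12)

    def test_skew_moment_matches_formula(self):
        # [1,1,1,7]: m2 = 6.75, m3 = 20.25, skew = 20.25 / 6.75**1.5 = 2/sqrt(3)
        assert ma4_skew([1, 1, 1, 7]) == pytest.approx(2 / math.sqrt(3), rel=1e-12)
        assert ma4_skew([1, 1, 1, 7]) == pytest.approx(1.1547, abs=1e-4)

    def test_skew_moment_matches_scipy(self):
        from scipy.stats import skew

        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.lognormal(size=int(rng.integers(3, 25)))
            assert ma4_skew(x) == pytest.approx(skew(x, bias=True), rel=1e-10)

    def test_skew_mean_over_median(self):
        assert ma4_skew([2, 4, 9], skew_kind="mean_over_median") == pytest.approx(1.25)

    def test_skew_degenerate_missing(self):
        assert math.isnan(ma4_skew([5.0, 5.0, 5.0]))  # zero variance
        assert math.isnan(ma4_skew([1.0, 2.0]))  # n < 3
        assert math.isnan(ma4_skew([-1.0, 0.0, 1.0], skew_kind="mean_over_median"))


class TestPulses:
    def test_thresholds_of_one_to_ten(self):
        ext_low, low, high, ext_high = pulse_thresholds(ONE_TO_TEN, RegimeConfig())
        assert (low, high) == (3.25, 7.75)
        assert (ext_low, ext_high) == (pytest.approx(1.9), pytest.approx(9.1))

    def test_thresholds_constant(self):
        assert pulse_thresholds(np.full(6, 2.0), RegimeConfig()) == (2.0,) * 4

    def test_thresholds_nondecreasing_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = pulse_thresholds(rng.normal(size=15), RegimeConfig())
            assert t[0] <= t[1] <= t[2] <= t[3]

    @pytest.mark.parametrize(
        "values,mode,expected",
        [
            ([1, 9, 1, 9, 1], "timepoints", 3),
            ([1, 9, 1, 9, 1], "runs", 3),
            ([1, 1, 9, 9, 1], "timepoints", 3),
            ([1, 1, 9, 9, 1], "runs", 2),
        ],
    )
    def test_below_counting(self, values, mode, expected):
        assert count_pulses(values, 5.0, "below", pulse_mode=mode) == expected

    def test_constant_window_strict_counts_zero(self):
        x = np.full(9, 4.0)
        for direction in ("below", "above"):
            assert count_pulses(x, 4.0, direction, strict_inequality=True) == 0

    def test_nonstrict_counts_ties(self):
        assert count_pulses([4.0, 4.0, 5.0], 4.0, "below", strict_inequality=False) == 2

    def test_missing_value_splits_a_run(self):
        x = [1.0, 1.0, math.nan, 1.0, 9.0]
        assert count_pulses(x, 5.0, "below", pulse_mode="runs") == 2
        assert count_pulses(x, 5.0, "below", pulse_mode="timepoints") == 3

    def test_empty_counts_zero(self):
        assert count_pulses([], 1.0, "below") == 0


class TestRateOfChange:
    def test_constant_is_zero(self):
        x = np.full(7, 2.5)
        assert rc_rate_of_change(x) == 0.0
        assert rc_rate_of_change(x, "abs_mean") == 0.0

    def test_signed_and_abs_means(self):
        # diffs of [1,3,2,5] are +2, -1, +3
        assert rc_rate_of_change([1, 3, 2, 5]) == pytest.approx(4 / 3)
        assert rc_rate_of_change([1, 3, 2, 5], "abs_mean") == pytest.approx(2.0)

    def test_pairs_spanning_missing_excluded(self):
        # valid pairs: (1,3) and (7,8) -> diffs +2, +1
        assert rc_rate_of_change([1, 3, math.nan, 7, 8]) == pytest.approx(1.5)

    def test_counts_of_changes(self):
        assert count_changes([1, 3, 2, 5], "rising") == 2
        assert count_changes([1, 3, 2, 5], "declining") == 1
        x = np.arange(12.0)
        assert count_changes(x, "rising") == 11
        assert count_changes(x, "declining") == 0

    def test_no_valid_pairs_is_missing(self):
        assert math.isnan(rc_rate_of_change([1.0]))
        assert math.isnan(count_changes([1.0, math.nan, 2.0], "rising"))


class TestComputeIndexSet:
    def test_constant_window(self):
        out = compute_index_set(np.full(10, 6.0))
        assert out["MA1"] == out["MA2"] == 6.0
        assert out["MA3"] == 0.0
        assert math.isnan(out["MA4"])
        for code in ("ML1", "MH1", "EL1", "EH1", "RH1", "RL1"):
            assert out[code] == 0
        assert out["RC"] == 0.0

    def test_single_value_window(self):
        out = compute_index_set([4.2])
        assert out["MA1"] == out["MA2"] == 4.2
        for code in ("MA3", "MA4", "ML1", "MH1", "EL1", "EH1", "RC", "RH1", "RL1"):
            assert math.isnan(out[code])
        assert out.n == 1

    def test_matches_single_purpose_kernels(self):
        cfg = RegimeConfig()
        out = compute_index_set(ONE_TO_TEN, cfg)
        ext_low, low, high, ext_high = pulse_thresholds(ONE_TO_TEN, cfg)
        assert out["MA1"] == ma1_mean(ONE_TO_TEN)
        assert out["MA2"] == ma2_median(ONE_TO_TEN)
        assert out["MA3"] == ma3_cv(ONE_TO_TEN)
        assert out["MA4"] == ma4_skew(ONE_TO_TEN)
        assert out["ML1"] == count_pulses(ONE_TO_TEN, low, "below")
        assert out["MH1"] == count_pulses(ONE_TO_TEN, high, "above")
        assert out["EL1"] == count_pulses(ONE_TO_TEN, ext_low, "below")
        assert out["EH1"] == count_pulses(ONE_TO_TEN, ext_high, "above")
        assert out["RC"] == rc_rate_of_change(ONE_TO_TEN)
        assert out["RH1"] == count_changes(ONE_TO_TEN, "rising")
        assert out["RL1"] == count_changes(ONE_TO_TEN, "declining")

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            RegimeConfig(low_p=0.8, high_p=0.75)
        with pytest.raises(ValidationError):
            RegimeConfig(min_n=1)
        with pytest.raises(ValidationError):
            RegimeConfig.from_mapping({"not_a_key": 1})


class TestProperties:
    @given(windows)
    @settings(max_examples=200, derandomize=True)
    def test_conservation_of_changes(self, x):
        """RH1 + RL1 + #zero-diffs = #valid pairs."""
        d = np.diff(x)
        rh1 = count_changes(x, "rising")
        rl1 = count_changes(x, "declining")
        assert rh1 + rl1 + int((d == 0).sum()) == len(d)

    @given(windows)
    @settings(max_examples=200, derandomize=True)
    def test_extreme_counts_nested_in_counts(self, x):
        """EL1 <= ML1 and EH1 <= MH1 in strict timepoints mode."""
        out = compute_index_set(x)
        assert out["EL1"] <= out["ML1"]
        assert out["EH1"] <= out["MH1"]

    @given(grid_windows, st.integers(min_value=-100, max_value=100).map(float))
    @settings(max_examples=100, derandomize=True)
    def test_shift_equivariance(self, x, k):
        base, shifted = compute_index_set(x), compute_index_set(x + k)
        assert shifted["MA1"] == pytest.approx(base["MA1"] + k, abs=1e-6)
        assert shifted["MA2"] == pytest.approx(base["MA2"] + k, abs=1e-6)
        for code in ("ML1", "MH1", "EL1", "EH1", "RH1", "RL1"):
            assert shifted[code] == base[code]
        assert shifted["RC"] == pytest.approx(base["RC"], abs=1e-6)

    @given(grid_windows, st.integers(min_value=1, max_value=100).map(float))
    @settings(max_examples=100, derandomize=True)
    def test_scale_equivariance(self, x, k):
        base, scaled = compute_index_set(x), compute_index_set(x * k)
        for code in ("MA1", "MA2", "RC"):
            assert scaled[code] == pytest.approx(base[code] * k, rel=1e-6, abs=1e-9)
        if not math.isnan(base["MA3"]):
            assert scaled["MA3"] == pytest.approx(base["MA3"], rel=1e-6)
        if not math.isnan(base["MA4"]):
            assert scaled["MA4"] == pytest.approx(base["MA4"], rel=1e-6, abs=1e-9)
        for code in ("ML1", "MH1", "EL1", "EH1", "RH1", "RL1"):
            assert scaled[code] == base[code]

    @given(windows, st.randoms(use_true_random=False))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_invariance_of_distributional_indices(self, x, rand):
        perm = list(x)
        rand.shuffle(perm)
        base, shuffled = compute_index_set(x), compute_index_set(np.asarray(perm))
        for code in ("MA1", "MA2", "MA3", "MA4", "ML1", "MH1", "EL1", "EH1"):
            a, b = base[code], shuffled[code]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, rel=1e-9)

    def test_order_sensitivity_of_rate_indices(self):
        """RC/RH1/RL1 depend on the sequence, not the multiset, of values."""
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]
        assert count_changes(x, "declining") != count_changes(y, "declining")
        assert rc_rate_of_change(x, "abs_mean") != rc_rate_of_change(y, "abs_mean")

    def test_signed_rc_telescopes_on_gapless_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(2, 30)))
            assert rc_rate_of_change(x) == pytest.approx(
                (x[-1] - x[0]) / (len(x) - 1), rel=1e-9, abs=1e-12
            )


class TestOracleEquivalence:
    def _assert_matches(self, x, cfg, expected):
        out = compute_index_set(x, cfg)
        for code, want in expected.items():
            got = out[code]
            if math.isnan(want):
                assert math.isnan(got), code
            else:
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12), code

    @pytest.mark.parametrize("pulse_mode", ["timepoints", "runs"])
    @pytest.mark.parametrize("rc_kind", ["signed_mean", "abs_mean"])
    def test_random_windows_match_bruteforce(self, pulse_mode, rc_kind):
        """Independent pure-Python re-derivation agrees on random windows."""
        from conftest import random_window

        cfg = RegimeConfig(pulse_mode=pulse_mode, rc_kind=rc_kind)
        rng = np.random.default_rng(2024)
        for i in range(250):
            x = random_window(rng, missing_prob=0.15 if i % 3 == 0 else 0.0)
            expected = _oracle.index_set(
                list(x), pulse_mode=pulse_mode, rc_kind=rc_kind
            )
            self._assert_matches(x, cfg, expected)

    def test_mean_over_median_skew_matches_bruteforce(self):
        from conftest import random_window

        cfg = RegimeConfig(skew_kind="mean_over_median")
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = random_window(rng)
            want = _oracle.skew_mean_over_median(list(x))
            assert compute_index_set(x, cfg)["MA4"] == pytest.approx(want, rel=1e-12)
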