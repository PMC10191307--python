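import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoseq import (RPeakTrain, accel_to_counts, align_by_crosscorr,
                      correct_intervals, epoch_hr_stats, intervals_from_rpeaks,
                      upsample_activity)


class TestIntervals:
    def test_uniform_train(self):
        np.testing.assert_allclose(intervals_from_rpeaks(np.array([0, 1, 2, 3.0])),
                                   [1, 1, 1])

    def test_irregular_train(self):
        np.testing.assert_allclose(intervals_from_rpeaks(np.array([0, 0.8, 1.0])),
                                   [0.8, 0.2])

    def test_short_train_is_empty(self):
        assert intervals_from_rpeaks(np.array([1.5])).size == 0
        assert intervals_from_rpeaks(np.array([])).size == 0

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            intervals_from_rpeaks(np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            RPeakTrain(np.array([0.0, 0.0, 1.0]))


class TestCorrectIntervals:
    def test_short_interval_replaced_by_midpoint(self):
        out, ep = correct_intervals(np.array([1.0, 0.2]), np.zeros(2, int))
        np.testing.assert_allclose(out, [1.0, 0.6])

    def test_long_interval_split_into_chunks(self):
        # T = 3.0, T_mean = 5/3 -> n = round(1.8) = 2 equal chunks of 1.5 s
        out, ep = correct_intervals(np.array([1.0, 1.0, 3.0]), np.zeros(3, int))
        np.testing.assert_allclose(out, [1.0, 1.0, 1.5, 1.5])
        np.testing.assert_array_equal(ep, [0, 0, 0, 0])

    def test_in_band_intervals_unchanged(self):
        iv = np.array([0.33, 0.7, 1.0, 1.33])
        out, ep = correct_intervals(iv, np.zeros(4, int))
        np.testing.assert_array_equal(out, iv)

    def test_first_interval_fallback_uses_epoch_mean(self):
        out, _ = correct_intervals(np.array([0.2, 1.0, 1.2]), np.zeros(3, int))
        np.testing.assert_allclose(out[0], np.mean([0.2, 1.0, 1.2]))

    def test_split_conserves_total_duration(self):
        rng = np.random.default_rng(0)
        iv = rng.uniform(0.4, 1.2, 50)
        iv[[7, 23]] = [2.4, 3.1]
        ep = np.repeat(np.arange(5), 10)
        # splitting only: replaced interval becomes equal parts of the
        # same span, so the total is conserved exactly
        out, _ = correct_intervals(iv, ep)
        assert out.sum() == pytest.approx(iv.sum(), abs=1e-9)

    def test_epoch_means_computed_per_epoch(self):
        # second epoch has short mean, so its long interval splits finer
        iv = np.array([1.0, 1.0, 0.5, 0.5, 2.0])
        ep = np.array([0, 0, 1, 1, 1])
        out, _ = correct_intervals(iv, ep)
        # epoch-1 T_mean = 1.0 -> n = 2 chunks of 1.0
        np.testing.assert_allclose(out, [1.0, 1.0, 0.5, 0.5, 1.0, 1.0])


class TestEpochHrStats:
    def test_constant_epoch(self):
        hrm, hrsd = epoch_hr_stats(np.full(30, 60.0))
        assert (hrm, hrsd) == (60.0, 0.0)

    def test_two_sd_outliers_discarded(self):
        # 28 x 60 plus {100, 20}: mean 60, SD ~10.50, band ~[39.0, 81.0]
        vals = np.concatenate([np.full(28, 60.0), [100.0, 20.0]])
        assert np.std(vals, ddof=1) == pytest.approx(10.50, abs=0.01)
        hrm, hrsd = epoch_hr_stats(vals)
        assert (hrm, hrsd) == (60.0, 0.0)

    def test_single_value(self):
        assert epoch_hr_stats(np.array([55.0])) == (55.0, 0.0)

    def test_empty_epoch_masked(self):
        hrm, hrsd = epoch_hr_stats(np.array([]))
        assert np.isnan(hrm) and np.isnan(hrsd)

    @given(st.lists(st.floats(40, 180), min_size=2, max_size=40),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        a = epoch_hr_stats(np.array(values))
        b = epoch_hr_stats(np.array(shuffled))
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-9)


class TestUpsample:
    def test_replication(self):
        np.testing.assert_array_equal(upsample_activity([5, 0]), [5, 5, 0, 0])

    def test_empty_and_singleton(self):
        assert upsample_activity([]).size == 0
        np.testing.assert_array_equal(upsample_activity([3.5]), [3.5, 3.5])

    @given(st.lists(st.floats(0, 1e4), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_total_doubles_and_order_preserved(self, counts):
        x = np.array(counts)
        y = upsample_activity(x)
        assert y.size == 2 * x.size
        assert y.sum() == pytest.approx(2 * x.sum(), rel=1e-12)
        np.testing.assert_array_equal(y[::2], x)
        np.testing.assert_array_equal(y[1::2], x)


class TestAccelToCounts:
    fs = 32.0

    def test_zero_signal_gives_zero_counts(self):
        counts = accel_to_counts(np.zeros(int(self.fs * 60)), self.fs)
        assert counts.shape == (4,)
        np.testing.assert_array_equal(counts, 0)

    def test_gravity_offset_rejected(self):
        t = np.arange(int(self.fs * 60)) / self.fs
        dc = accel_to_counts(np.full(t.size, 1.0), self.fs)
        sine = accel_to_counts(0.1 * np.sin(2 * np.pi * 2.0 * t), self.fs)
        assert dc.sum() < 0.01 * sine.sum()

    def test_counts_increase_with_amplitude(self):
        t = np.arange(int(self.fs * 60)) / self.fs
        base = 2 * np.pi * 2.0 * t
        c1 = accel_to_counts(0.1 * np.sin(base), self.fs).sum()
        c2 = accel_to_counts(0.2 * np.sin(base), self.fs).sum()
        assert c2 > c1 > 0

    def test_too_short_signal(self):
        assert accel_to_counts(np.zeros(10), self.fs).size == 0

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            accel_to_counts(np.zeros(1000), fs=6.0)


class TestAlign:
    def test_identical_series_lag_zero(self):
        x = np.random.default_rng(0).normal(size=200)
        lag, a, b = align_by_crosscorr(x, x, max_lag=10)
        assert lag == 0
        np.testing.assert_array_equal(a, b)

    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        shifted = np.roll(x, 3)  # hr lags activity by 3 epochs
        lag, a, b = align_by_crosscorr(x[10:-10], shifted[10:-10], max_lag=8)
        assert lag == 3
        assert a.size == b.size
        # after alignment the series correlate near-perfectly
        assert np.corrcoef(a, b)[0, 1] > 0.95

    def test_zero_variance_warns_lag_zero(self):
        with pytest.warns(UserWarning):
            lag, a, b = align_by_crosscorr(np.ones(100), np.ones(100), max_lag=5)
        assert lag == 0 and a.size == b.size

    def test_overlap_contract_on_noise(self):
        rng = np.random.default_rng(2)
        lag, a, b = align_by_crosscorr(rng.normal(size=100), -rng.normal(size=100),
                                       max_lag=5)
        assert abs(lag) <= 5
        assert a.size == b.size > 0
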