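import numpy as np
import pytest

from hopfec import (
    BoldTimeseries,
    ConnectivityMatrix,
    DegenerateSignalError,
    average_connectivity,
    bandpass_filter,
    estimate_intrinsic_frequencies,
    functional_connectivity,
    lagged_functional_connectivity,
)

from conftest import brute_pearson


def make_ts(data, tr=1.0, **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return BoldTimeseries(data=data, tr=tr, region_ids=[f"r{i}" for i in range(data.shape[0])], **kw)


def sinusoid(f, n=900, tr=1.0, amp=1.0, phase=0.0):
    t = np.arange(n) * tr
    return amp * np.sin(2 * np.pi * f * t + phase)


def spectral_amplitude(x, f, tr=1.0):
    """Amplitude of the spectral component nearest frequency f (the oracle)."""
    spec = np.abs(np.fft.rfft(x)) * 2.0 / len(x)
    freqs = np.fft.rfftfreq(len(x), d=tr)
    return spec[np.argmin(np.abs(freqs - f))]


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        x = sinusoid(0.03)
        out = bandpass_filter(make_ts(x), 0.008, 0.08)
        assert spectral_amplitude(out.data[0], 0.03) >= 0.9 * spectral_amplitude(x, 0.03)

    def test_out_of_band_rejected(self):
        x = sinusoid(0.2)
        out = bandpass_filter(make_ts(x), 0.008, 0.08)
        assert spectral_amplitude(out.data[0], 0.2) <= 0.1 * spectral_amplitude(x, 0.2)

    def test_constant_series_goes_to_zero(self):
        out = bandpass_filter(make_ts(np.full(900, 3.7)), 0.008, 0.08)
        assert np.max(np.abs(out.data)) < 1e-9

    def test_mean_removed(self, rng):
        out = bandpass_filter(make_ts(rng.normal(5, 1, 900)), 0.008, 0.08)
        assert abs(out.data[0].mean()) < 1e-12

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(make_ts(np.zeros(900)), 0.008, 0.6)  # above Nyquist
        with pytest.raises(ValueError):
            bandpass_filter(make_ts(np.zeros(900)), 0.08, 0.008)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass_filter(make_ts(np.zeros(100)), 0.008, 0.08)

    def test_idempotence_for_band_centre_content(self):
        # a 2nd-order Butterworth is only ~unity-gain near band centre, so
        # idempotence is asserted there; see the filter design note.
        ts = make_ts(sinusoid(0.03, n=2000))
        once = bandpass_filter(ts, 0.008, 0.08)
        twice = bandpass_filter(once, 0.008, 0.08)
        rms = np.sqrt(np.mean(once.data**2))
        assert np.sqrt(np.mean((twice.data - once.data) ** 2)) < 0.01 * rms

    def test_second_pass_changes_broadband_content_modestly(self, rng):
        ts = make_ts(rng.normal(0, 1, 2000))
        once = bandpass_filter(ts, 0.008, 0.08)
        twice = bandpass_filter(once, 0.008, 0.08)
        rms = np.sqrt(np.mean(once.data**2))
        assert np.sqrt(np.mean((twice.data - once.data) ** 2)) < 0.3 * rms


class TestIntrinsicFrequencies:
    BIN = 1.0 / 225.0  # welch bin width for 900 samples, nperseg = n // 4

    def test_pure_sinusoid(self):
        est = estimate_intrinsic_frequencies([make_ts(sinusoid(0.03))])
        assert abs(est[0] - 0.03) <= self.BIN

    def test_dominant_of_two_components(self):
        x = sinusoid(0.05, amp=2.0) + sinusoid(0.02, amp=1.0)
        est = estimate_intrinsic_frequencies([make_ts(x)])
        assert abs(est[0] - 0.05) <= self.BIN

    def test_average_across_sessions(self):
        est = estimate_intrinsic_frequencies(
            [make_ts(sinusoid(0.02)), make_ts(sinusoid(0.04))]
        )
        assert abs(est[0] - 0.03) <= self.BIN

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            estimate_intrinsic_frequencies([])

    def test_constant_region_flagged(self):
        data = np.vstack([sinusoid(0.03), np.zeros(900)])
        with pytest.raises(DegenerateSignalError) as err:
            estimate_intrinsic_frequencies([make_ts(data)])
        assert "r1" in err.value.regions

    def test_estimates_clamped_to_band(self):
        est = estimate_intrinsic_frequencies([make_ts(sinusoid(0.03))], band=(0.02, 0.04))
        assert 0.02 <= est[0] <= 0.04


class TestFunctionalConnectivity:
    def test_identical_regions_correlate_one(self, rng):
        x = rng.normal(0, 1, 500)
        fc = functional_connectivity(make_ts(np.vstack([x, x.copy()])))
        assert fc.values[0, 1] == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self, rng):
        x = rng.normal(0, 1, 500)
        fc = functional_connectivity(make_ts(np.vstack([x, -x])))
        assert fc.values[0, 1] == pytest.approx(-1.0)

    def test_white_noise_null(self):
        rng = np.random.default_rng(777)
        fc = functional_connectivity(make_ts(rng.normal(0, 1, (3, 1000))))
        off = fc.values[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_matches_brute_force(self, rng):
        data = rng.normal(0, 1, (4, 60))
        fc = functional_connectivity(make_ts(data))
        for i in range(4):
            for j in range(4):
                assert fc.values[i, j] == pytest.approx(brute_pearson(data[i], data[j]), abs=1e-10)

    def test_symmetry_and_unit_diagonal(self, rng):
        fc = functional_connectivity(make_ts(rng.normal(0, 1, (5, 200))))
        np.testing.assert_array_equal(fc.values, fc.values.T)
        np.testing.assert_array_equal(np.diag(fc.values), np.ones(5))

    def test_constant_region_reported(self):
        data = np.vstack([np.arange(100.0), np.full(100, 2.0)])
        with pytest.raises(DegenerateSignalError) as err:
            functional_connectivity(make_ts(data))
        assert "r1" in err.value.regions


class TestLaggedFunctionalConnectivity:
    def test_shifted_copy_is_one(self, rng):
        s = rng.normal(0, 1, 500)
        tau = 2
        target = np.roll(s, tau)  # target copies the source tau samples later
        m = lagged_functional_connectivity(make_ts(np.vstack([s, target])), float(tau))
        # row = target (later), column = source (earlier)
        assert m.values[1, 0] == pytest.approx(1.0, abs=1e-12)
        assert abs(m.values[0, 1]) < 0.2  # the reverse direction is just noise

    def test_independent_noise_null(self):
        rng = np.random.default_rng(42)
        m = lagged_functional_connectivity(make_ts(rng.normal(0, 1, (3, 2000))), 2.0)
        assert np.max(np.abs(m.values)) < 0.1

    def test_common_signal_without_delay_is_symmetric(self):
        t = np.arange(1200.0)
        common = np.sin(2 * np.pi * 0.03 * t)
        data = np.vstack([2.0 * common, 0.5 * common + 1.0, -1.5 * common])
        m = lagged_functional_connectivity(make_ts(data), 2.0)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-10)

    def test_zero_lag_equals_fc(self, rng):
        ts = make_ts(rng.normal(0, 1, (4, 300)))
        m0 = lagged_functional_connectivity(ts, 0.0)
        fc = functional_connectivity(ts)
        np.testing.assert_allclose(m0.values, fc.values, atol=1e-6)

    def test_non_multiple_tau_rejected(self, rng):
        with pytest.raises(ValueError, match="multiple"):
            lagged_functional_connectivity(make_ts(rng.normal(0, 1, (2, 100))), 1.5)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            lagged_functional_connectivity(make_ts(rng.normal(0, 1, (2, 4))), 2.0)

    def test_asymmetry_index_positive_for_directed_delay(self, rng):
        s = rng.normal(0, 1, 800)
        target = np.roll(s, 2)
        m = lagged_functional_connectivity(make_ts(np.vstack([s, target])), 2.0)
        assert np.linalg.norm(m.values - m.values.T) > 0.5


class TestAverageConnectivity:
    def _fc(self, val, ids=("a", "b")):
        v = np.array([[1.0, val], [val, 1.0]])
        return ConnectivityMatrix(v, kind="FC", region_ids=list(ids))

    def test_single_matrix_identity(self):
        m = self._fc(0.3)
        avg = average_connectivity([m])
        np.testing.assert_array_equal(avg.values, m.values)

    def test_cancellation(self):
        v = np.array([[0.0, 0.4], [-0.4, 0.0]])
        a = ConnectivityMatrix(v, kind="FC_tau", region_ids=["a", "b"], tau=2.0)
        b = ConnectivityMatrix(-v, kind="FC_tau", region_ids=["a", "b"], tau=2.0)
        avg = average_connectivity([a, b])
        np.testing.assert_array_equal(avg.values, np.zeros((2, 2)))

    def test_arithmetic_mean(self):
        mats = [self._fc(v) for v in (0.1, 0.2, 0.3, 0.4)]
        avg = average_connectivity(mats)
        assert avg.values[0, 1] == pytest.approx(0.25)

    def test_kind_mismatch_rejected(self):
        fc = self._fc(0.2)
        sc = ConnectivityMatrix(np.zeros((2, 2)), kind="SC", region_ids=["a", "b"])
        with pytest.raises(ValueError, match="kind"):
            average_connectivity([fc, sc])

    def test_ordering_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ordering"):
            average_connectivity([self._fc(0.2), self._fc(0.2, ids=("b", "a"))])
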