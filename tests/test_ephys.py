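"""Conduction-velocity chain: filtering, whitening, lags, velocities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neckconnective import ephys, synth
from neckconnective.probes import make_probe
from tests.conftest import simulate_and_estimate

FS = 30_000.0


def brute_force_xcorr(x_i, x_j):
    """O(n^2) oracle for c[l] = sum_t x_i[t+l] * x_j[t]."""
    n = len(x_i)
    half = n // 2
    lags = np.arange(-half, half + 1)
    c = np.zeros(lags.size)
    for idx, lag in enumerate(lags):
        for t in range(n):
            if 0 <= t + lag < n:
                c[idx] += x_i[t + lag] * x_j[t]
    return lags, c


def gaussian_pulse(n=121, center=60.0, sigma=6.0):
    t = np.arange(n)
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(int(FS)) / FS
        tone = np.sin(2 * np.pi * 1000 * t)
        out = ephys.bandpass(tone, FS)
        mid = slice(2000, -2000)
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_dc_removed(self):
        out = ephys.bandpass(np.full(30_000, 7.0), FS)
        assert abs(out.mean()) < 1e-6

    def test_hum_attenuated_20db(self):
        t = np.arange(int(FS)) / FS
        hum = np.sin(2 * np.pi * 50 * t)
        out = ephys.bandpass(hum, FS)
        assert np.abs(out[3000:-3000]).max() < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ephys.bandpass(np.zeros(100), fs=8000, hi=5000)


class TestZscore:
    def test_standardizes(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.0, (20_000, 2))
        z = ephys.zscore_channels(x)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)

    def test_already_standard_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (50_000, 1))
        x = (x - x.mean()) / x.std()
        assert np.allclose(ephys.zscore_channels(x), x, atol=1e-9)

    def test_constant_channel_named_in_error(self):
        x = np.ones((100, 3))
        x[:, 0] = np.arange(100)
        x[:, 2] = np.arange(100)
        with pytest.raises(ValueError, match=r"\[1\]"):
            ephys.zscore_channels(x)


class TestWhitening:
    def test_alpha_zero_diagonal_covariance_is_pure_zscore(self):
        spec = ephys.modified_whitening(np.diag([4.0, 9.0]), alpha=0.0)
        assert np.allclose(spec.w_new, np.diag([0.5, 1.0 / 3.0]))

    def test_alpha_one_whitens_exactly(self):
        cov = np.array([[2.0, 0.8], [0.8, 1.5]])
        spec = ephys.modified_whitening(cov, alpha=1.0)
        assert np.allclose(spec.w_new @ cov @ spec.w_new.T, np.eye(2), atol=1e-12)

    def test_blend_matches_eigendecomposition_oracle(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        vals, vecs = np.linalg.eigh(cov)
        w = vecs @ np.diag(vals**-0.5) @ vecs.T
        expected = 0.1 * w + 0.9 * np.diag(np.diag(w))
        spec = ephys.modified_whitening(cov, alpha=0.1)
        assert np.allclose(spec.w_new, expected)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            ephys.modified_whitening(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestRoundRobin:
    def make_set(self, waveforms):
        return ephys.MeanWaveformSet(
            waveforms=np.atleast_2d(waveforms),
            fs_hz=FS,
            positions_um=np.zeros(np.atleast_2d(waveforms).shape[0]),
            window_ms=4.0,
            time_offsets_s=np.zeros(np.atleast_2d(waveforms).shape[0]),
        )

    def test_slot_zero_unchanged(self):
        w = gaussian_pulse()
        out = ephys.correct_round_robin(self.make_set(w), [0])
        assert np.array_equal(out.waveforms[0], w)

    def test_effective_rate(self):
        assert 1.05e6 / 35 == FS

    def test_sinusoid_slot17_resampled_to_reference(self):
        """A band-limited tone sampled 17 slots late lands on frame times."""
        k = np.arange(121)
        adc = 1.05e6
        delta_s = 17 / adc
        recorded = np.sin(2 * np.pi * 1200 * (k / FS + delta_s))
        reference = np.sin(2 * np.pi * 1200 * k / FS)
        wfset = self.make_set(recorded)
        order = np.zeros(1, int)
        order[0] = 17
        out = ephys.correct_round_robin(wfset, order)
        resid = out.waveforms[0][8:-8] - reference[8:-8]
        assert np.sqrt((resid**2).mean()) / np.sqrt((reference**2).mean()) < 0.01

    def test_duplicate_slots_rejected(self):
        w = np.stack([gaussian_pulse()] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            ephys.correct_round_robin(self.make_set(w), [4, 4])


class TestExtractMeanWaveforms:
    def test_single_spike_equals_snippet(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(3000, 2))
        wf = ephys.extract_mean_waveforms(data, [1500], FS)
        half = wf.waveforms.shape[1] // 2
        assert np.array_equal(wf.waveforms[0], data[1500 - half:1500 + half + 1, 0])

    def test_averaging_shrinks_noise_as_sqrt_k(self):
        rng = np.random.default_rng(3)
        template = gaussian_pulse()
        n, k = 121, 64
        data = rng.normal(0, 1.0, size=(k * 400, 1))
        centers = np.arange(k) * 400 + 200
        for c in centers:
            data[c - 60:c + 61, 0] += template
        wf = ephys.extract_mean_waveforms(data, centers, FS)
        resid = wf.waveforms[0] - template
        assert resid.std() == pytest.approx(1.0 / np.sqrt(k), rel=0.25)

    def test_edge_spikes_dropped_and_counted(self):
        data = np.random.default_rng(4).normal(size=(1000, 1))
        wf = ephys.extract_mean_waveforms(data, [0, 500, 999], FS)
        assert wf.n_spikes_used == 1
        assert wf.n_spikes_dropped == 2

    def test_no_usable_spikes_errors(self):
        data = np.zeros((200, 1))
        with pytest.raises(ValueError):
            ephys.extract_mean_waveforms(data, [0], FS)


class TestPairLag:
    def test_identical_waveforms_zero_lag(self):
        """The 4-point quadratic can never be exactly symmetric around the
        peak, so 'zero' means well under a hundredth of a sample."""
        w = gaussian_pulse()
        assert ephys.pair_lag(w, w, FS).dt_s == pytest.approx(0.0, abs=0.01 / FS)

    def test_integer_shift_matches_brute_force(self):
        w = gaussian_pulse()
        shifted = np.roll(w, 3)
        lags, c = ephys.cross_correlation(w, shifted)
        lags_b, c_b = brute_force_xcorr(w, shifted)
        assert np.array_equal(lags, lags_b)
        assert np.allclose(c, c_b)
        est = ephys.pair_lag(w, shifted, FS)
        assert est.dt_s * FS == pytest.approx(3.0, abs=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=9999), st.integers(min_value=8, max_value=256))
    def test_xcorr_equals_brute_force_on_random_pairs(self, seed, n):
        """Exact agreement with the O(n^2) double loop, any length <= 256."""
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(size=n)
        lags, c = ephys.cross_correlation(x, y)
        lags_b, c_b = brute_force_xcorr(x, y)
        assert np.array_equal(lags, lags_b)
        assert np.allclose(c, c_b, rtol=1e-12, atol=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        w = gaussian_pulse() + 0.05 * rng.normal(size=121)
        shifted = np.roll(gaussian_pulse(), 2) + 0.05 * rng.normal(size=121)
        dt_ij = ephys.pair_lag(w, shifted, FS).dt_s
        dt_ji = ephys.pair_lag(shifted, w, FS).dt_s
        assert dt_ij == pytest.approx(-dt_ji, abs=0.3 / FS)

    def test_subsample_shift_within_quarter_sample(self):
        """Band-limited 2.5-sample shift recovered to <= 0.25 samples."""
        k = np.arange(121)
        base = np.exp(-0.5 * ((k - 60) / 6.0) ** 2)
        shifted = ephys._fractional_shift(base, 2.5)
        est = ephys.pair_lag(base, shifted, FS)
        assert est.dt_s * FS == pytest.approx(2.5, abs=0.25)

    def test_all_zero_waveform_errors(self):
        with pytest.raises(ValueError):
            ephys.pair_lag(np.zeros(50), gaussian_pulse(50, 25, 3), FS)


class TestEstimateVelocity:
    def test_recovers_simulated_2mps_within_5pct(self, est_2mps):
        assert est_2mps.v_mps == pytest.approx(2.0, rel=0.05)
        assert est_2mps.direction == "ascending"
        assert not est_2mps.flagged

    def test_reversed_unit_flips_sign_only(self, est_2mps, est_2mps_reversed):
        assert est_2mps_reversed.v_mps == pytest.approx(-2.0, rel=0.05)
        assert est_2mps_reversed.direction == "descending"
        assert abs(est_2mps_reversed.v_mps) == pytest.approx(
            abs(est_2mps.v_mps), rel=0.02
        )

    def test_same_shank_pairs_excluded(self, est_2mps):
        assert (est_2mps.pairs.dx_um != 0).all()

    def test_all_channels_below_threshold_errors(self):
        geom = make_probe()
        wfset = ephys.MeanWaveformSet(
            waveforms=np.full((16, 121), 0.5),
            fs_hz=FS,
            positions_um=geom.channel_positions_um,
            window_ms=4.0,
            time_offsets_s=np.zeros(16),
        )
        with pytest.raises(ValueError, match="eligible"):
            ephys.estimate_velocity(wfset, geom)

    def test_near_simultaneous_pairs_excluded_not_averaged(self):
        """Identical waveforms on all channels: velocity is unresolvable."""
        geom = make_probe()
        w = gaussian_pulse()
        wfset = ephys.MeanWaveformSet(
            waveforms=np.tile(w * 5, (16, 1)),
            fs_hz=FS,
            positions_um=geom.channel_positions_um,
            window_ms=4.0,
            time_offsets_s=np.zeros(16),
        )
        with pytest.raises(ValueError, match="near-simultaneous"):
            ephys.estimate_velocity(wfset, geom)


class TestBoundsAndLatency:
    def test_reference_probe_bounds(self):
        geom = make_probe(4, 4, 150)
        v_max, v_min = ephys.observational_bounds(geom, 30_000, 4.0)
        assert v_max == pytest.approx(13.5)
        assert v_min == pytest.approx(0.225)
        assert ephys.round_half_up(v_min, 2) == 0.23

    def test_doubling_fs_doubles_vmax_only(self):
        geom = make_probe()
        v_max1, v_min1 = ephys.observational_bounds(geom, 30_000)
        v_max2, v_min2 = ephys.observational_bounds(geom, 60_000)
        assert v_max2 == pytest.approx(2 * v_max1)
        assert v_min2 == pytest.approx(v_min1)

    def test_single_shank_has_no_bounds(self):
        with pytest.raises(ValueError):
            ephys.observational_bounds(make_probe(1, 4, 150), 30_000)

    @pytest.mark.parametrize(
        "v,length_m,expected_ms",
        [(10.0, 0.01, 1.0), (2.0, 220e-6, 0.11), (0.044, 220e-6, 5.0)],
    )
    def test_latency_conversions(self, v, length_m, expected_ms):
        assert ephys.to_latency(v, length_m) == pytest.approx(expected_ms)

    def test_zero_velocity_latency_undefined(self):
        with pytest.raises(ValueError):
            ephys.to_latency(0.0)

    def test_required_velocity_for_one_wingbeat(self):
        """Traversing 220 um within 5 ms takes only 0.044 m/s."""
        v = ephys.required_velocity(220e-6, 5e-3)
        assert v == pytest.approx(0.044)
        assert ephys.to_latency(v, 220e-6) == pytest.approx(5.0)


class TestCompareDirections:
    def test_identical_groups_ks_p_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        rep = ephys.compare_directions(v, -v)
        assert rep["ks_p_value"] == pytest.approx(1.0)

    def test_same_distribution_rarely_rejected(self):
        rng = np.random.default_rng(6)
        rejections = 0
        for _ in range(40):
            a = rng.normal(2.4, 1.2, 100)
            b = rng.normal(2.4, 1.2, 100)
            rejections += ephys.compare_directions(a, b)["ks_p_value"] < 0.05
        assert rejections <= 6  # ~alpha, generous margin

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(20):
            a = rng.normal(2.4, 1.0, 100)
            b = rng.normal(3.4, 1.0, 100)
            rejections += ephys.compare_directions(a, b)["ks_p_value"] < 0.05
        assert rejections >= 18

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ephys.compare_directions([1.0, 2.0], [1.0, 2.0, 3.0])


def test_velocity_recovery_across_speed_range():
    """|V| recovered within 5% for 0.33-5 m/s, with no sign trend in bias."""
    errors = []
    for v_true in (0.33, 1.0, 5.0):
        _, est = simulate_and_estimate(v_true)
        rel = (est.v_mps - v_true) / v_true
        errors.append(rel)
        assert abs(rel) <= 0.05
    assert not (all(e > 0 for e in errors) and min(errors) > 0.02)
    assert not (all(e < 0 for e in errors) and max(errors) < -0.02)
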