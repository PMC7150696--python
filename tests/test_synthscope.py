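"""Synthetic stack generator: determinism, degradation model, drift fields."""
import numpy as np
import pytest

import fastscan as fs
from fastscan.spectra import FrequencyProfile, amplitude_spectrum


class TestGroundTruth:
    def test_fixed_seed_is_bit_identical(self):
        a = fs.make_ground_truth(64, 96, seed=7)
        b = fs.make_ground_truth(64, 96, seed=7)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, fs.make_ground_truth(64, 96, seed=8).pixels)

    def test_values_in_unit_interval_with_variance(self):
        t = fs.make_ground_truth(64, 64, seed=1)
        assert t.pixels.min() >= 0 and t.pixels.max() <= 1
        assert t.pixels.std() > 0

    def test_constant_texture(self):
        t = fs.make_ground_truth(64, 64, {"kind": "constant", "level": 0.5}, seed=9)
        assert np.all(t.pixels == 0.5)

    def test_broadband_power_above_half_nyquist(self):
        # the spectrum must hold real power in the top-quartile frequency band
        t = fs.make_ground_truth(480, 640, seed=7)
        spec = amplitude_spectrum(t.pixels)
        rows, cols = spec.amplitudes.shape
        fy = (np.arange(rows) - rows // 2) / rows
        fx = (np.arange(cols) - cols // 2) / cols
        r = np.hypot(fy[:, None], fx[None, :])
        power = spec.amplitudes**2
        assert power[r > 0.25].sum() / power.sum() > 0.01

    def test_rejects_tiny_dimensions(self):
        with pytest.raises(ValueError):
            fs.make_ground_truth(16, 64)


class TestDetectorLowpass:
    def test_flat_profile_is_identity(self, truth_small):
        out = fs.detector_lowpass(truth_small.pixels, FrequencyProfile.flat())
        assert np.allclose(out, truth_small.pixels, atol=1e-12)

    def test_impulse_row_spectrum_equals_profile(self):
        f = np.linspace(0, 0.5, 65)
        prof = FrequencyProfile(f, 0.2 + 0.8 * (0.5 + 0.5 * np.cos(2 * np.pi * f)))
        img = np.zeros((4, 128))
        img[:, 13] = 1.0
        out = fs.detector_lowpass(img, prof)
        spec = np.abs(np.fft.rfft(out[0]))
        expected = prof.resample(np.fft.rfftfreq(128))
        assert np.allclose(spec, expected, atol=1e-10)

    def test_row_spectrum_ratio_matches_profile(self):
        # the filter acts purely multiplicatively on every row spectrum
        f = np.linspace(0, 0.5, 65)
        prof = FrequencyProfile(f, np.clip(0.5 + 0.5 * np.cos(2 * np.pi * f), 0, 1))
        rng = np.random.default_rng(0)
        img = rng.standard_normal((256, 256))
        out = fs.detector_lowpass(img, prof)
        sin = np.abs(np.fft.rfft(img, axis=1)).mean(axis=0)
        sout = np.abs(np.fft.rfft(out, axis=1)).mean(axis=0)
        expected = prof.resample(np.fft.rfftfreq(256))
        keep = expected > 0.05
        ratio = sout[keep] / sin[keep]
        assert np.sqrt(np.mean((ratio - expected[keep]) ** 2)) < 0.03

    def test_columns_untouched(self, truth_small):
        f = np.linspace(0, 0.5, 65)
        prof = FrequencyProfile(f, np.clip(0.5 + 0.5 * np.cos(2 * np.pi * f), 0, 1))
        out = fs.detector_lowpass(truth_small.pixels, prof)
        # column means equal row-filtered means: DC along rows preserved where
        # profile(0) == 1, so the column-mean profile is unchanged
        assert np.allclose(out.mean(axis=1), truth_small.pixels.mean(axis=1), atol=1e-9)


class TestSimulateStack:
    def test_no_degradation_copies_truth(self, truth_small):
        stack = fs.simulate_stack(truth_small, n_frames=3, seed=0)
        for frame in stack.frames:
            assert np.array_equal(frame, truth_small.pixels)

    def test_determinism(self, truth_small):
        kw = dict(
            drift=fs.DriftModel.constant_rate((0.3, -0.2), 4),
            noise=fs.NoiseModel(gaussian_sigma=0.1, seed=5),
            n_frames=4,
            seed=9,
        )
        a = fs.simulate_stack(truth_small, **kw)
        b = fs.simulate_stack(truth_small, **kw)
        assert np.array_equal(a.frames, b.frames)

    def test_known_shift_recovered_by_full_search(self, granular_small):
        stack = fs.simulate_stack(
            granular_small,
            fs.DriftModel.constant_rate((0.0, 1.0), 8),
            noise=fs.NoiseModel(gaussian_sigma=0.02, seed=1),
            n_frames=8,
            seed=1,
        )
        template = stack.frames[0][32:96, 40:104]
        m = 8
        window = stack.frames[4][32 - m : 96 + m, 40 - m : 104 + m]
        surf = fs.zncc_surface(template, window)
        py, px = np.unravel_index(surf.argmax(), surf.shape)
        assert (py - m, px - m) == (0, 4)

    def test_charging_applied_per_frame(self, truth_small):
        charging = fs.ChargingModel.exponential_decay(3, b0=0.2, tau=1.0, gain=1.5)
        stack = fs.simulate_stack(truth_small, charging=charging, n_frames=3, seed=0)
        for t in range(3):
            expected = 1.5 * truth_small.pixels + 0.2 * np.exp(-t)
            assert np.allclose(stack.frames[t], expected, atol=1e-12)

    def test_mean_converges_as_sqrt_n(self, truth_small):
        noise = fs.NoiseModel.for_target_snr(truth_small.pixels, 0.5, seed=2)
        stack = fs.simulate_stack(truth_small, None, None, noise, None, 64, seed=2)
        rmse = {
            n: np.sqrt(np.mean((stack.frames[:n].mean(0) - truth_small.pixels) ** 2))
            for n in (1, 4, 16, 64)
        }
        for n in (4, 16, 64):
            assert abs(rmse[n] * np.sqrt(n) / rmse[1] - 1) < 0.15

    def test_equal_anchors_degenerate_to_global(self, truth_small):
        traj = np.cumsum(np.full((4, 2), (0.3, -0.7)), axis=0)
        g = fs.simulate_stack(
            truth_small, fs.DriftModel("global", trajectory=traj), n_frames=4, seed=3
        )
        v = fs.simulate_stack(
            truth_small, fs.DriftModel.varying(traj, traj.copy()), n_frames=4, seed=3
        )
        assert np.array_equal(g.frames, v.frames)

    def test_varying_drift_shifts_edges_oppositely(self, granular_small):
        left = np.array([[0.0, -4.0]])
        right = np.array([[0.0, 4.0]])
        stack = fs.simulate_stack(
            granular_small, fs.DriftModel.varying(left, right), n_frames=1, seed=0
        )
        frame = stack.frames[0]
        truth = granular_small.pixels

        def local_shift(c0, c1):
            m = 6
            template = truth[30:90, c0:c1]
            window = frame[30 - m : 90 + m, c0 - m : c1 + m]
            return fs.match_pyramid(template, window, levels=1, origin=(m, m))

        left = local_shift(10, 42)
        right = local_shift(118, 150)
        # columns drift oppositely: content moved left on the left side, right
        # on the right side, by the column-interpolated displacement
        assert left.dy == 0 and right.dy == 0
        assert -4 <= left.dx <= -2
        assert 2 <= right.dx <= 4

    def test_short_trajectory_rejected(self, truth_small):
        with pytest.raises(ValueError, match="shorter"):
            fs.simulate_stack(
                truth_small, fs.DriftModel.constant_rate((0, 1), 3), n_frames=5
            )

    def test_snr_calibration_round_trip(self, truth_small):
        noise = fs.NoiseModel.for_target_snr(truth_small.pixels, 1.0, seed=4)
        stack = fs.simulate_stack(truth_small, None, None, noise, None, 2, seed=4)
        est = fs.covariance_stats(stack.frames[0], stack.frames[1])
        assert abs(est.snr_amp - 1.0) < 0.1

    def test_poisson_noise_path(self, truth_small):
        noise = fs.NoiseModel(gaussian_sigma=0.01, poisson_scale=200.0, seed=6)
        stack = fs.simulate_stack(truth_small, None, None, noise, None, 2, seed=6)
        assert not np.array_equal(stack.frames[0], stack.frames[1])
        assert abs(stack.frames.mean() - truth_small.pixels.mean()) < 0.01


class TestModelValidation:
    def test_charging_requires_positive_gain(self):
        with pytest.raises(ValueError):
            fs.ChargingModel(np.zeros(3), np.array([1.0, 0.0, 1.0]))

    def test_noise_rejects_negative(self):
        with pytest.raises(ValueError):
            fs.NoiseModel(gaussian_sigma=-1.0)

    def test_global_drift_requires_trajectory(self):
        with pytest.raises(ValueError):
            fs.DriftModel("global")
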