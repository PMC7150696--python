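"""ZNCC surface, pyramid matching, stack alignment."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.feature import match_template

import fastscan as fs
from fastscan.register import default_levels, placement_counts


def _brute_zncc(template, inspection):
    th, tw = template.shape
    out = np.zeros((inspection.shape[0] - th + 1, inspection.shape[1] - tw + 1))
    t0 = (template - template.mean()).ravel()
    tn = np.sqrt(t0 @ t0)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            p = inspection[i : i + th, j : j + tw]
            p0 = (p - p.mean()).ravel()
            out[i, j] = (t0 @ p0) / (tn * np.sqrt(p0 @ p0))
    return out


class TestZnccSurface:
    def test_perfect_match_scores_one(self):
        rng = np.random.default_rng(0)
        insp = rng.standard_normal((32, 32))
        template = insp[5:21, 7:23]
        surf = fs.zncc_surface(template, insp)
        assert surf[5, 7] == pytest.approx(1.0, abs=1e-9)

    def test_negated_template_scores_minus_one(self):
        rng = np.random.default_rng(1)
        insp = rng.standard_normal((32, 32))
        surf = fs.zncc_surface(-insp[5:21, 7:23], insp)
        assert surf[5, 7] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_brute_force_and_library_oracle(self):
        rng = np.random.default_rng(2)
        template = rng.standard_normal((16, 16))
        insp = rng.standard_normal((32, 32))
        surf = fs.zncc_surface(template, insp)
        assert np.abs(surf - _brute_zncc(template, insp)).max() < 1e-10
        assert np.abs(surf - match_template(insp, template)).max() < 1e-8

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.floats(0.1, 20), st.floats(-5, 5))
    def test_affine_template_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        template = rng.standard_normal((8, 8))
        insp = rng.standard_normal((16, 16))
        ref = fs.zncc_surface(template, insp)
        scaled = fs.zncc_surface(a * template + b, insp)
        assert np.allclose(ref, scaled, atol=1e-8)

    def test_symmetry_under_swap(self):
        # two circularly shifted views: the central crop of one matches the
        # other at s, and vice versa at -s
        rng = np.random.default_rng(3)
        base = rng.standard_normal((48, 48))
        shifted = np.roll(base, (3, -5), (0, 1))
        m = 8
        sa = fs.match_pyramid(base[m:-m, m:-m], shifted, levels=1, origin=(m, m))
        sb = fs.match_pyramid(shifted[m:-m, m:-m], base, levels=1, origin=(m, m))
        assert (sa.dy, sa.dx) == (3, -5)
        assert (sb.dy, sb.dx) == (-3, 5)

    def test_zero_variance_template_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fs.zncc_surface(np.ones((8, 8)), np.random.default_rng(0).standard_normal((16, 16)))

    def test_oversized_template_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            fs.zncc_surface(np.zeros((20, 20)), np.zeros((16, 16)))


class TestMatchPyramid:
    def test_exact_offset_noiseless(self):
        rng = np.random.default_rng(4)
        template = rng.standard_normal((32, 32))
        insp = rng.standard_normal((64, 64))
        insp[11:43, 17:49] = template
        sh = fs.match_pyramid(template, insp, levels=2)
        assert (sh.dy, sh.dx) == (11, 17)
        assert sh.score > 0.99

    def test_pyramid_equals_full_search_when_margin_clear(self, granular_small):
        truth = granular_small.pixels
        sigma = truth.std()  # snr 1
        same = 0
        checked = 0
        for k in range(25):
            rng = np.random.default_rng(10 + k)
            dy, dx = (int(v) for v in rng.integers(-6, 7, 2))
            f1 = truth + rng.normal(0, sigma, truth.shape)
            f2 = np.roll(truth, (dy, dx), (0, 1)) + rng.normal(0, sigma, truth.shape)
            template = f1[32:96, 40:104]
            m = 10
            window = f2[22:106, 30:114]
            surf = fs.zncc_surface(template, window)
            if fs.peak_margin(surf) <= 0.05:
                continue
            checked += 1
            py, px = np.unravel_index(surf.argmax(), surf.shape)
            sh = fs.match_pyramid(template, window, levels=2, origin=(m, m))
            same += (sh.dy + m, sh.dx + m) == (py, px)
        assert checked > 0 and same == checked

    def test_levels_one_is_full_search(self):
        rng = np.random.default_rng(5)
        template = rng.standard_normal((9, 9))
        insp = rng.standard_normal((21, 23))
        surf = fs.zncc_surface(template, insp)
        py, px = np.unravel_index(surf.argmax(), surf.shape)
        sh = fs.match_pyramid(template, insp, levels=1)
        assert (sh.dy, sh.dx) == (py, px)

    def test_collapsing_template_rejected(self):
        with pytest.raises(ValueError, match="pyramid"):
            fs.match_pyramid(np.zeros((16, 16)) + np.eye(16), np.zeros((32, 32)), levels=3)

    def test_default_levels_keep_coarse_side(self):
        assert default_levels((256, 256)) == 4  # 256 -> 128 -> 64 -> 32
        assert default_levels((40, 40)) == 1

    def test_pyramid_placement_budget(self):
        pyramid, full = placement_counts((256, 256), (480, 640), levels=3)
        assert pyramid < 0.1 * full


class TestAlignStack:
    def test_drift_free_noiseless_stack_gives_zero_shifts(self, granular_small):
        stack = fs.simulate_stack(granular_small, n_frames=4, seed=0)
        traj = fs.align_stack(stack, fs.ROI(32, 40, 96, 120), search_margin=8)
        assert np.all(traj.dy == 0) and np.all(traj.dx == 0)
        assert traj.shifts[0].score == 1.0

    def test_recovers_known_integer_drift(self, granular_small):
        drift = fs.DriftModel.constant_rate((0.0, 1.0), 12)
        noise = fs.NoiseModel.for_target_snr(granular_small.pixels, 1.0, seed=1)
        stack = fs.simulate_stack(granular_small, drift, None, noise, None, 12, seed=1)
        traj = fs.align_stack(stack, fs.ROI(32, 40, 96, 104), search_margin=14)
        expected = np.arange(12)
        assert np.mean(traj.dx == expected) >= 0.95
        assert np.all(traj.dy == 0)

    def test_tiny_roi_at_low_snr_flags_failures(self, granular_small):
        # a 16x16 template at SNR 0.25 cannot resolve the true (zero) shift:
        # matches wander and scores sit at the surface noise ceiling, below
        # the size-adaptive confidence threshold
        noise = fs.NoiseModel.for_target_snr(granular_small.pixels, 0.25, seed=2)
        stack = fs.simulate_stack(granular_small, None, None, noise, None, 24, seed=2)
        traj = fs.align_stack(
            stack, fs.ROI(56, 72, 72, 88), reference="first", search_margin=8
        )
        wrong = np.count_nonzero((traj.dy != 0) | (traj.dx != 0))
        assert wrong > 0
        assert len(traj.low_confidence()) > 0

    def test_roi_with_margin_must_fit(self, granular_small):
        stack = fs.simulate_stack(granular_small, n_frames=2, seed=0)
        with pytest.raises(ValueError, match="margin"):
            fs.align_stack(stack, fs.ROI(0, 0, 64, 64), search_margin=8)

    def test_first_reference_matches_running_mean_when_clean(self, granular_small):
        drift = fs.DriftModel.constant_rate((1.0, 0.0), 6)
        stack = fs.simulate_stack(granular_small, drift, n_frames=6, seed=3)
        roi = fs.ROI(32, 40, 96, 120)
        a = fs.align_stack(stack, roi, reference="first", search_margin=8)
        b = fs.align_stack(stack, roi, reference="running_mean", search_margin=8)
        assert np.array_equal(a.dy, b.dy) and np.array_equal(a.dx, b.dx)
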