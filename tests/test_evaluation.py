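"""Amplitude images, line profiles, PSNR/SSIM and rigid registration."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import samdenoise as sd
from samdenoise.errors import ParameterError, RegistrationError


def ssim_window_oracle(ref, test, peak):
    """Sliding 11x11 Gaussian-weighted SSIM computed window by window."""
    sigma = 1.5
    radius = 5
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    w = np.outer(g, g)
    w /= w.sum()
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    nx, ny = ref.shape
    vals = []
    for i in range(radius, nx - radius):
        for j in range(radius, ny - radius):
            a = ref[i - radius:i + radius + 1, j - radius:j + radius + 1]
            b = test[i - radius:i + radius + 1, j - radius:j + radius + 1]
            mua = np.sum(w * a)
            mub = np.sum(w * b)
            va = np.sum(w * (a - mua) ** 2)
            vb = np.sum(w * (b - mub) ** 2)
            cov = np.sum(w * (a - mua) * (b - mub))
            vals.append(
                ((2 * mua * mub + c1) * (2 * cov + c2))
                / ((mua**2 + mub**2 + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))


class TestAmplitudeImage:
    def test_zero_volume_gives_zero_image(self):
        img = sd.amplitude_image(sd.Volume(np.zeros((4, 4, 8))))
        assert not np.any(img.values)

    def test_forced_arithmetic_single_scan(self):
        v = sd.Volume(np.array([-1.0, 2.0, 0.0]).reshape(1, 1, 3))
        assert sd.amplitude_image(v, "max_abs").values[0, 0] == 2.0
        assert sd.amplitude_image(v, "peak_to_peak").values[0, 0] == 3.0

    def test_matches_per_pixel_loop_oracle(self, small_spec):
        v = sd.add_gaussian_noise(
            sd.simulate_clean_volume(small_spec), sd.NoiseModel(5.0), seed=1
        )
        img = sd.amplitude_image(v).values
        for i, j in [(0, 0), (7, 3), (19, 19)]:
            assert img[i, j] == pytest.approx(
                max(abs(float(x)) for x in v.data[i, j]), rel=1e-7
            )

    def test_unknown_reduction_rejected(self):
        with pytest.raises(ParameterError):
            sd.amplitude_image(sd.Volume(np.zeros((2, 2, 2))), "rms")


class TestLineProfile:
    def test_returns_requested_row(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(sd.line_profile(img, 2), img[:, 2])

    def test_profile_length_is_nx(self, clean_amplitude):
        assert len(sd.line_profile(clean_amplitude, 5)) == clean_amplitude.shape[0]

    def test_out_of_range_row_rejected(self):
        with pytest.raises(ParameterError):
            sd.line_profile(np.zeros((4, 4)), 4)


class TestPSNR:
    def test_identical_images_infinite(self):
        a = np.ones((8, 8))
        assert sd.psnr(a, a, peak=1.0) == np.inf

    def test_uniform_error_forced_arithmetic(self):
        ref = np.zeros((16, 16))
        test = np.full((16, 16), 5.0)
        assert sd.psnr(ref, test, peak=255.0) == pytest.approx(
            20.0 * np.log10(51.0), abs=1e-9
        )

    def test_matches_mse_formula_oracle(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(0, 1, (20, 20))
        test = ref + rng.normal(0, 0.3, (20, 20))
        mse = np.mean((ref - test) ** 2)
        assert sd.psnr(ref, test, 4.0) == pytest.approx(
            10 * np.log10(16.0 / mse), rel=1e-12
        )

    def test_monotone_in_noise_level(self, clean_amplitude):
        rng = np.random.default_rng(3)
        peak = np.ptp(clean_amplitude)
        values = []
        for s in (1.0, 3.0, 9.0):
            noisy = clean_amplitude + rng.normal(0, s, clean_amplitude.shape)
            values.append(sd.psnr(clean_amplitude, noisy, peak))
        assert values[0] > values[1] > values[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            sd.psnr(np.zeros((4, 4)), np.zeros((4, 5)), 1.0)


class TestSSIM:
    def test_identical_images_give_one(self, clean_amplitude):
        assert sd.ssim(clean_amplitude, clean_amplitude, 30.0) == 1.0

    def test_symmetry(self, clean_amplitude):
        rng = np.random.default_rng(4)
        other = clean_amplitude + rng.normal(0, 3, clean_amplitude.shape)
        assert sd.ssim(clean_amplitude, other, 30.0) == pytest.approx(
            sd.ssim(other, clean_amplitude, 30.0), rel=1e-12
        )

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(10, 3, (32, 32))
        test = ref + rng.normal(0, 1, (32, 32))
        peak = float(np.ptp(ref))
        assert sd.ssim(ref, test, peak) == pytest.approx(
            ssim_window_oracle(ref, test, peak), abs=1e-7
        )

    def test_bounded_above_by_one(self, clean_amplitude):
        rng = np.random.default_rng(6)
        noisy = clean_amplitude + rng.normal(0, 2, clean_amplitude.shape)
        assert sd.ssim(clean_amplitude, noisy, 30.0) < 1.0

    def test_too_small_image_rejected(self):
        with pytest.raises(ParameterError):
            sd.ssim(np.zeros((8, 8)), np.zeros((8, 8)), 1.0)


class TestRegistration:
    def test_identity_for_equal_images(self, clean_amplitude):
        r = sd.register_rigid(clean_amplitude, clean_amplitude)
        assert (r.dx, r.dy, r.theta) == (0.0, 0.0, 0.0)
        np.testing.assert_array_equal(r.registered, clean_amplitude)

    def test_known_shift_recovered(self, clean_amplitude):
        mov = ndi.shift(clean_amplitude, (3, -2), order=1, mode="nearest")
        r = sd.register_rigid(clean_amplitude, mov)
        assert r.dx == pytest.approx(-3.0, abs=0.2)
        assert r.dy == pytest.approx(2.0, abs=0.2)

    def test_known_rotation_recovered(self, clean_amplitude):
        mov = ndi.rotate(clean_amplitude, 2.5, reshape=False, order=1, mode="nearest")
        r = sd.register_rigid(clean_amplitude, mov)
        assert r.theta == pytest.approx(-2.5, abs=0.2)

    def test_constant_image_rejected(self):
        with pytest.raises(RegistrationError):
            sd.register_rigid(np.ones((16, 16)), np.ones((16, 16)))

    def test_self_consistency_after_registration(self, clean_amplitude):
        mov = ndi.shift(
            ndi.rotate(clean_amplitude, 2.0, reshape=False, order=1, mode="nearest"),
            (2, -1), order=1, mode="nearest",
        )
        first = sd.register_rigid(clean_amplitude, mov)
        second = sd.register_rigid(clean_amplitude, first.registered)
        assert abs(second.dx) < 0.05 and abs(second.dy) < 0.05
        assert abs(second.theta) < 0.05

    def test_aligned_noisy_pair_untouched(self, clean_amplitude, noisy10):
        noisy_img = sd.amplitude_image(noisy10).values
        r = sd.register_rigid(clean_amplitude, noisy_img)
        assert (r.dx, r.dy, r.theta) == (0.0, 0.0, 0.0)


class TestEvaluateFilters:
    def test_report_has_seven_labelled_rows(self, report10):
        assert set(report10) == set(sd.evaluation.FILTER_NAMES)
        assert len(report10) == 7

    def test_identity_pipeline_rows(self, small_spec):
        """With zero noise and zero thresholds the block-matching pipelines
        reproduce the reference exactly; the fixed-kernel baselines smooth
        the clean signal and stay below that bound."""
        clean = sd.simulate_clean_volume(small_spec)
        cfg = sd.EvalConfig(
            bm4d=sd.BM4DParams(sigma=0.0, lambda_4d=0.0),
            bm3d=sd.BM3DParams(sigma=0.0, lambda_3d=0.0),
        )
        rows = sd.evaluate_filters(clean, clean, cfg).as_dict()
        for name in ("unfiltered", "bm3d", "bm4d", "bm4d+bm3d"):
            # identity up to float64 transform round-trip dust
            assert rows[name][0] >= 150.0
            assert rows[name][1] == pytest.approx(1.0, abs=1e-9)
        for name in ("gaussian", "median", "wiener"):
            assert np.isfinite(rows[name][0])
            assert rows[name][0] < 150.0

    def test_shape_mismatch_rejected(self, small_spec):
        clean = sd.simulate_clean_volume(small_spec)
        other = sd.Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ParameterError):
            sd.evaluate_filters(clean, other)
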