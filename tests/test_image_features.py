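"""Spectral, saliency-sampled and structural orientation features."""

import math

import numpy as np
import pytest

from sacbias.circular_stats import rayleigh_test
from sacbias.image_features import (
    GreyImage,
    SaliencyMap,
    SpectralConfig,
    feature_horizontal_bias,
    preprocess_image,
    proxy_saliency_map,
    read_saliency_text,
    saliency_direction_samples,
    spectral_orientation_profile,
    structural_orientation_likelihood,
    write_saliency_text,
)
from sacbias.synthetic_data import gen_white_noise_image

DPP = 1.0 / 30.0  # 30 px/deg test scale
# At a 128-px desk scale the lowest DFT bins carry Hann-window leakage, so
# the low band floor sits above them (the dataset presets assume the much
# denser spectra of full-resolution corpora).
CFG = SpectralConfig(f_lo=0.8, f_hi=12.1)


def _grating(n=128, cpd=3.0, contour_deg=0.0):
    """Sinusoidal grating whose CONTOURS lie at ``contour_deg`` (y-up)."""
    x = (np.arange(n) + 0.5) * DPP
    y = ((n - np.arange(n) - 0.5) * DPP)[:, None]
    th = math.radians(contour_deg + 90.0)  # gradient direction
    phase = 2 * math.pi * cpd * (x * math.cos(th) + y * math.sin(th))
    return GreyImage(0.5 + 0.5 * np.sin(phase), DPP)


class TestPreprocess:
    def test_constant_image_zeroed(self):
        out = preprocess_image(GreyImage(np.full((32, 32), 0.7), DPP))
        assert np.allclose(out.pixels, 0.0, atol=1e-12)

    def test_zero_mean_and_zero_corners(self, rng):
        out = preprocess_image(GreyImage(rng.random((41, 33)), DPP))
        assert abs(out.pixels.mean()) < 1e-12
        # Hann endpoints are zero, so all corners equal minus the subtracted mean
        corners = out.pixels[[0, 0, -1, -1], [0, -1, 0, -1]]
        assert np.allclose(corners, corners[0], atol=1e-12)

    def test_degenerate_dimension_raises(self):
        with pytest.raises(ValueError, match="too small"):
            preprocess_image(GreyImage(np.zeros((2, 50)), DPP))


class TestSpectralProfile:
    @pytest.mark.parametrize("contour", [0.0, 45.0, 90.0, 135.0])
    def test_grating_argmax_at_contour_orientation(self, contour):
        p = spectral_orientation_profile(_grating(contour_deg=contour), CFG)
        peak = p.angle_deg[int(np.argmax(p.amplitude))]
        d = min(abs(peak - contour), 180 - abs(peak - contour))
        assert d <= 1.0

    def test_rotation_equivariance_quarter_turn(self, rng):
        img = GreyImage(rng.random((128, 128)), DPP)
        pa = spectral_orientation_profile(img, CFG)
        pb = spectral_orientation_profile(GreyImage(np.rot90(img.pixels), DPP), CFG)
        shift = int(
            np.argmax([np.dot(pa.amplitude, np.roll(pb.amplitude, -s)) for s in range(180)])
        )
        assert shift == 90

    def test_white_noise_profile_flat_in_aggregate(self):
        """Mean profile over many noise images is flat (max/min < 1.2)."""
        total = np.zeros(180)
        rng = np.random.default_rng(5)
        for _ in range(40):
            img = gen_white_noise_image(128, DPP, rng)
            total += spectral_orientation_profile(img, CFG).amplitude
        assert total.max() / total.min() < 1.2

    def test_band_outside_nyquist_raises(self):
        cfg = SpectralConfig(f_lo=0.8, f_hi=60.0)
        with pytest.raises(ValueError, match="band"):
            spectral_orientation_profile(_grating(), cfg)


class TestSaliencySampling:
    def test_horizontal_strip_gives_horizontal_directions(self):
        m = np.zeros((33, 65))
        m[16, :] = 1.0
        sal = SaliencyMap.from_unnormalized(m, 0.35)
        _, dirs = saliency_direction_samples(sal, 500, rng=0)
        folded = np.minimum(dirs % 180, 180 - (dirs % 180))
        # within atan(1 px jitter / typical horizontal distance), generously 45 deg
        assert np.quantile(folded, 0.9) < 45.0

    def test_isotropic_blob_uniform_directions(self):
        n = 129
        yy, xx = np.mgrid[0:n, 0:n]
        m = np.exp(-(((xx - 64) ** 2 + (yy - 64) ** 2) / (2 * 18.0**2)))
        sal = SaliencyMap.from_unnormalized(m, 0.2)
        hits = 0
        for seed in range(10):
            _, dirs = saliency_direction_samples(sal, 2000, rng=seed)
            _, p = rayleigh_test(np.deg2rad(dirs))
            hits += p > 0.05
        assert hits >= 9

    def test_two_blobs_bimodal(self):
        m = np.zeros((64, 64))
        m[32, 8] = m[32, 56] = 1.0
        sal = SaliencyMap.from_unnormalized(m, 0.35)
        _, dirs = saliency_direction_samples(sal, 1000, rng=1)
        moved = np.abs(np.cos(np.deg2rad(dirs))) > 0.9
        # half the pairs repeat a blob (any direction from jitter); the rest
        # travel horizontally between blobs
        assert moved.mean() > 0.45

    def test_mirrored_map_mirrors_directions(self):
        from sacbias.synthetic_data import gen_saliency_map

        sal = gen_saliency_map(64, 0.35, arrangement_orientation_deg=30.0, rng=2)
        mir = SaliencyMap(sal.prob[:, ::-1].copy(), 0.35)
        _, d1 = saliency_direction_samples(sal, 4000, rng=3)
        _, d2 = saliency_direction_samples(mir, 4000, rng=3)
        # mirroring about the vertical axis maps direction th -> 180 - th
        h1, _ = np.histogram((180.0 - d2) % 360.0, bins=36, range=(0, 360))
        h2, _ = np.histogram(d1, bins=36, range=(0, 360))
        assert np.abs(h1 - h2).sum() / h1.sum() < 0.25

    def test_single_pixel_map_raises(self):
        m = np.zeros((16, 16))
        m[8, 8] = 1.0
        with pytest.raises(ValueError, match="nonzero"):
            saliency_direction_samples(SaliencyMap.from_unnormalized(m, 0.35), 10, rng=0)


class TestStructuralLikelihood:
    def test_constant_image_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            vec = structural_orientation_likelihood(GreyImage(np.full((32, 32), 0.5), DPP))
        assert np.allclose(vec, 1 / 360)

    def test_horizontal_grating_peaks_at_vertical_gradient(self):
        vec = structural_orientation_likelihood(_grating(contour_deg=0.0))
        assert int(np.argmax(vec[:180])) in range(85, 96)
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_external_classifier_contract(self):
        img = _grating()
        vec = structural_orientation_likelihood(img, classifier=lambda im: np.ones(360))
        assert np.allclose(vec, 1 / 360)
        with pytest.raises(ValueError, match="360"):
            structural_orientation_likelihood(img, classifier=lambda im: np.ones(10))


class TestFeatureBias:
    def test_horizontal_samples_calibration(self):
        dirs = np.array([0.0] * 50 + [180.0] * 50)
        assert feature_horizontal_bias(samples_deg=dirs) == pytest.approx(2.0, abs=0.01)

    def test_uniform_likelihood_calibration(self):
        assert feature_horizontal_bias(likelihood=np.ones(360)) == pytest.approx(0.16, abs=0.005)

    def test_oriented_profile_beats_noise_profile(self):
        from sacbias.synthetic_data import gen_oriented_noise_image

        strong = spectral_orientation_profile(
            gen_oriented_noise_image(128, DPP, 1.0, 0.0, rng=0), CFG
        )
        noise = spectral_orientation_profile(gen_white_noise_image(128, DPP, 0), CFG)
        assert feature_horizontal_bias(profile=strong) > feature_horizontal_bias(profile=noise)

    def test_requires_exactly_one_input(self):
        with pytest.raises(ValueError, match="exactly one"):
            feature_horizontal_bias(samples_deg=np.array([0.0]), likelihood=np.ones(360))


class TestSaliencyIO:
    def test_text_round_trip(self, tmp_path):
        from sacbias.synthetic_data import gen_saliency_map

        sal = gen_saliency_map(32, 0.5, rng=0)
        path = tmp_path / "sal.txt"
        write_saliency_text(sal, path)
        back = read_saliency_text(path)
        assert back.deg_per_px == pytest.approx(0.5)
        np.testing.assert_allclose(back.prob, sal.prob, atol=1e-12)

    def test_proxy_map_is_valid(self, rng):
        sal = proxy_saliency_map(GreyImage(rng.random((48, 48)), DPP))
        assert sal.prob.sum() == pytest.approx(1.0, abs=1e-9)
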