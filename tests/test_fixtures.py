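import numpy as np
import pytest

from corticalmask.fixtures import (
    FixtureSpec,
    distort,
    estimate_e_star,
    generate_rated_set,
    generate_reference_images,
)
from corticalmask.frontend import FrontEndParams
from corticalmask.metric import evaluate_metric, perceptual_distance
from corticalmask.model import IdentityCascade
from corticalmask.stimuli import Stimulus


def _fitted_spectral_slope(img):
    """Log-log regression of the radially averaged amplitude spectrum."""
    F = np.abs(np.fft.fft2(img - img.mean()))
    M = img.shape[0]
    fy = np.fft.fftfreq(M)[:, None]
    fx = np.fft.fftfreq(M)[None, :]
    r = np.hypot(fx, fy).ravel()
    a = F.ravel()
    keep = (r > 1.5 / M) & (r < 0.4)
    bins = np.logspace(np.log10(2.0 / M), np.log10(0.4), 12)
    which = np.digitize(r[keep], bins)
    rs, amps = [], []
    for k in range(1, len(bins)):
        sel = which == k
        if sel.sum() > 4:
            rs.append(np.mean(r[keep][sel]))
            amps.append(np.mean(a[keep][sel]))
    slope = np.polyfit(np.log(rs), np.log(amps), 1)[0]
    return slope


class TestReferenceImages:
    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_spectral_slope_matches_request(self, alpha):
        spec = FixtureSpec(seed=11, n_references=6, alpha=alpha)
        imgs = generate_reference_images(spec)
        slopes = [_fitted_spectral_slope(im.pixels) for im in imgs]
        assert np.mean(slopes) == pytest.approx(-alpha, abs=0.1)

    def test_same_seed_is_bit_identical(self):
        spec = FixtureSpec(seed=3, n_references=2)
        a = generate_reference_images(spec)
        b = generate_reference_images(spec)
        for ia, ib in zip(a, b):
            assert np.array_equal(ia.pixels, ib.pixels)

    def test_mean_luminance_normalized(self):
        spec = FixtureSpec(seed=3, n_references=2)
        for im in generate_reference_images(spec):
            assert im.pixels.mean() == pytest.approx(50.0, rel=0.02)


class TestDistortions:
    @pytest.fixture()
    def ref(self):
        return generate_reference_images(FixtureSpec(seed=9, n_references=1))[0]

    @pytest.mark.parametrize(
        "kind", ["white_noise", "hf_noise", "blur", "block_dct", "masked_noise"]
    )
    def test_level_zero_is_identity(self, ref, kind, rng):
        out = distort(ref, kind, 0.0, rng)
        assert np.array_equal(out.pixels, ref.pixels)

    def test_unknown_kind_rejected(self, ref, rng):
        with pytest.raises(ValueError, match="unknown distortion"):
            distort(ref, "jpeg2000", 0.1, rng)

    def test_masked_noise_follows_local_contrast(self, ref, rng):
        # signal-dependent distortion: noise amplitude tracks the local
        # contrast map of the background
        from corticalmask.fixtures import _local_contrast_map

        from scipy import ndimage

        out = distort(ref, "masked_noise", 0.3, rng)
        envelope = ndimage.gaussian_filter(
            np.abs(out.pixels - ref.pixels), 2.0, mode="wrap"
        )
        cmap = _local_contrast_map(ref.pixels, ref.mean_luminance)
        r = np.corrcoef(envelope.ravel(), cmap.ravel())[0, 1]
        assert r > 0.3

    def test_levels_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            FixtureSpec(seed=1, distortions={"blur": (1.0, 0.5)})

    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            FixtureSpec(seed=None)


class TestRatedSet:
    def test_noiseless_identity_link_closes_the_loop(self):
        # MOS generated from the very metric under evaluation: rank
        # correlation is exactly 1
        spec = FixtureSpec(
            seed=21, n_references=2, size_px=32, samples_per_degree=32.0,
            observer_sigma=0.0, mos_link="identity",
            distortions={"white_noise": (0.05, 0.1, 0.2), "blur": (0.5, 1.0, 2.0)},
        )
        m = IdentityCascade()

        def oracle(a, b):
            return perceptual_distance(a, b, m)

        rated = generate_rated_set(spec, oracle)
        rep = evaluate_metric(m, rated)
        assert rep["spearman"] == 1.0

    def test_deterministic_under_seed(self):
        spec = FixtureSpec(seed=4, n_references=1, size_px=32,
                           samples_per_degree=32.0)

        def rmse(a, b):
            return float(np.sqrt(np.mean((a.pixels - b.pixels) ** 2)))

        r1 = generate_rated_set(spec, rmse)
        r2 = generate_rated_set(spec, rmse)
        assert np.array_equal(r1.mos, r2.mos)
        for a, b in zip(r1.items, r2.items):
            assert np.array_equal(a.distorted.pixels, b.distorted.pixels)

    def test_covers_both_distortion_taxonomies(self):
        spec = FixtureSpec(seed=4, n_references=1)
        kinds = set(spec.distortions)
        assert "white_noise" in kinds  # signal independent
        assert "masked_noise" in kinds  # signal dependent


class TestEStar:
    def test_constant_images_floored_positive(self, pyr16):
        ims = [Stimulus(np.full((16, 16), 50.0), 16.0, 50.0) for _ in range(3)]
        e = estimate_e_star(ims, FrontEndParams().bypass_all(), pyr16, 2.0)
        assert np.all(e > 0)

    def test_homogeneity_with_bypassed_front_end(self, pyr16):
        # doubling image contrast scales e* by 2^gamma when the front end
        # is linear
        gamma = 2.0
        fe = FrontEndParams().bypass_all()
        spec1 = FixtureSpec(seed=8, n_references=4, size_px=16,
                            samples_per_degree=16.0, rms_contrast=0.05)
        spec2 = FixtureSpec(seed=8, n_references=4, size_px=16,
                            samples_per_degree=16.0, rms_contrast=0.10)
        e1 = estimate_e_star(generate_reference_images(spec1), fe, pyr16, gamma)
        e2 = estimate_e_star(generate_reference_images(spec2), fe, pyr16, gamma)
        big = e1 > 1e3 * e1.max() * 1e-6  # ignore floored entries
        assert np.allclose(e2[big] / e1[big], 2.0**gamma, rtol=1e-6)

    def test_band_profile_decreases_fine_to_coarse(self, pyr64):
        # with the CSF enabled the reference energy is low-frequency
        # dominant: coarse oriented scales carry more than fine ones
        spec = FixtureSpec(seed=12, n_references=6)
        e = estimate_e_star(
            generate_reference_images(spec), FrontEndParams(), pyr64, 2.0
        )
        means = pyr64.index.band_means(e)
        per_scale = {}
        for b in pyr64.index.oriented_bands():
            per_scale.setdefault(b.scale, []).append(means[b.band_id])
        s = {k: np.mean(v) for k, v in per_scale.items()}
        assert s[3] > s[2] > s[1]

    def test_empty_set_rejected(self, pyr16):
        with pytest.raises(ValueError, match="empty"):
            estimate_e_star([], FrontEndParams(), pyr16, 2.0)
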