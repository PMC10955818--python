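"""PSNR / SSIM / MS-SSIM identities and the statistics harness."""

import math

import numpy as np
import pytest

from octasv.metrics import ms_ssim, one_way_anova, pairwise_ttests, psnr, ssim_map


class TestPSNR:
    def test_identical_images_infinite(self, rng):
        a = rng.random((16, 16))
        assert psnr(a, a) == math.inf

    def test_full_scale_error_is_zero_db(self):
        a = np.zeros((8, 8))
        b = np.full((8, 8), 255.0)
        assert psnr(a, b, 255.0) == pytest.approx(0.0)

    def test_known_mse_closed_form(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 5.0)  # MSE = 25
        assert psnr(a, b, 255.0) == pytest.approx(10 * math.log10(65025 / 25), abs=1e-9)
        assert psnr(a, b, 255.0) == pytest.approx(34.15, abs=0.01)

    def test_decreases_with_noise_level(self, rng):
        a = rng.random((32, 32)) * 255
        prev = math.inf
        for sigma in (1, 4, 16):
            val = psnr(a, a + rng.normal(0, sigma, a.shape), 255.0)
            assert val < prev
            prev = val

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            psnr(rng.random((4, 4)), rng.random((5, 5)))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        a = rng.random((32, 32)) * 255
        mean, smap = ssim_map(a, a)
        assert mean == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(smap, 1.0, atol=1e-12)

    def test_matches_reference_implementation(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.random((48, 64)) * 255
        b = np.clip(a + rng.normal(0, 20, a.shape), 0, 255)
        mine, _ = ssim_map(a, b, L=255.0)
        ref = structural_similarity(a, b, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False, data_range=255.0)
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_constant_images_luminance_bound(self):
        # closed form for constant a vs b: (2ab + C1)/(a^2 + b^2 + C1)
        a = np.zeros((16, 16))
        b = np.full((16, 16), 255.0)
        mean, _ = ssim_map(a, b, L=255.0)
        c1 = (0.01 * 255) ** 2
        assert mean == pytest.approx(c1 / (255.0**2 + c1), abs=1e-12)
        assert mean < 0.01

    def test_independent_noise_scores_low(self):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            vals.append(ssim_map(r.random((32, 32)) * 255, r.random((32, 32)) * 255)[0])
        assert np.mean(vals) < 0.1

    def test_symmetry(self, rng):
        a = rng.random((32, 32)) * 255
        b = rng.random((32, 32)) * 255
        assert ssim_map(a, b)[0] == pytest.approx(ssim_map(b, a)[0], abs=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ssim_map(np.zeros((8, 8)), np.zeros((8, 8)))


class TestMSSSIM:
    def test_self_similarity_is_one(self, rng):
        a = rng.random((64, 64)) * 255
        assert ms_ssim(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        a = rng.random((64, 64)) * 255
        b = rng.random((64, 64)) * 255
        assert ms_ssim(a, b) == pytest.approx(ms_ssim(b, a), abs=1e-12)

    def test_blur_preferred_over_equal_mse_noise(self):
        # On fine-textured images with mild blur, structural similarity
        # ranks the blurred copy above independent noise of equal MSE.
        # (The ordering is regime-dependent: heavy blur on smooth images
        # flips it, because the pyramid's coarse scales average noise away.)
        from scipy.ndimage import gaussian_filter

        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = r.random((64, 64)) * 255
            blurred = gaussian_filter(a, 0.5)
            mse = np.mean((a - blurred) ** 2)
            noisy = a + r.normal(0, np.sqrt(mse), a.shape)
            wins += ms_ssim(a, blurred) > ms_ssim(a, noisy)
        assert wins >= 8

    def test_scale_count_reduced_for_small_images(self, rng):
        # 32x32 supports only 2 dyadic scales with an 11-tap window
        a = rng.random((32, 32)) * 255
        b = np.clip(a + rng.normal(0, 10, a.shape), 0, 255)
        val = ms_ssim(a, b)
        assert 0 < val < 1


class TestStatistics:
    def test_identical_groups_f_zero(self):
        f, p = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_three_groups(self):
        # SSB = 3*((2-3)^2 + 0 + 1) = 6, SSW = 6, F = (6/2)/(6/6) = 3
        f, _ = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0, abs=1e-12)

    def test_two_group_f_equals_t_squared(self, rng):
        a = list(rng.normal(0, 1, 8))
        b = list(rng.normal(0.5, 1, 8))
        f, p_f = one_way_anova([a, b])
        tt = pairwise_ttests([a, b])
        assert f == pytest.approx(tt["t"][0] ** 2, rel=1e-10)
        assert p_f == pytest.approx(tt["p"][0], rel=1e-10)

    def test_group_vs_itself_p_one(self):
        out = pairwise_ttests([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert out["p"][0] == 1.0

    def test_separated_groups_tiny_p(self, rng):
        a = list(rng.normal(0, 1e-3, 4))
        b = list(1 + rng.normal(0, 1e-3, 4))
        assert pairwise_ttests([a, b])["p"][0] < 1e-3

    def test_matches_permutation_oracle(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.8, 1, 10)
        p_t = pairwise_ttests([list(a), list(b)])["p"][0]
        # permutation oracle on the mean difference
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += abs(pooled[:10].mean() - pooled[10:].mean()) >= obs
        assert p_t == pytest.approx(count / n_perm, abs=0.05)

    def test_bonferroni_column(self):
        out = pairwise_ttests([[1, 2, 3], [2, 3, 4], [5, 6, 7]])
        assert np.all(out["p_bonferroni"] >= out["p"])
        assert np.all(out["p_bonferroni"] <= 1.0)

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])
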