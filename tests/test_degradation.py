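"""Degradation simulator: noise model, blur/down-sampling, kernel PCA,
degradation maps, dataset builders, and the phantom generator."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad

import ctenhance as ce
from ctenhance.degradation import DegradationSpec, delta_kernel, gaussian_kernel


MID_GRAY = np.full((256, 256), 0.5)


class TestGaussianPdf:
    def test_closed_form_values(self):
        assert ce.gaussian_pdf(0.0, 1.0) == pytest.approx(1 / math.sqrt(2 * math.pi), abs=1e-9)
        for sigma in (0.5, 1.0, 7.0):
            assert ce.gaussian_pdf(sigma, sigma) == pytest.approx(
                math.exp(-0.5) / math.sqrt(2 * math.pi) / sigma, rel=1e-12
            )

    def test_even_symmetry_and_unit_integral(self):
        for a in (0.3, 1.7, 9.0):
            assert ce.gaussian_pdf(a, 2.5) == ce.gaussian_pdf(-a, 2.5)
        integral, _ = quad(lambda x: ce.gaussian_pdf(x, 3.0), -np.inf, np.inf)
        assert integral == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ce.gaussian_pdf(0.0, 0.0)
        with pytest.raises(ValueError):
            ce.gaussian_pdf(0.0, -1.0)


class TestAddGaussianNoise:
    def test_zero_sigma_is_identity(self):
        out = ce.add_gaussian_noise(MID_GRAY, 0.0, seed=3)
        assert np.array_equal(out, MID_GRAY)

    def test_sample_std_recovers_sigma(self):
        # clipping is negligible at mid-gray for sigma up to 18
        for sigma in range(2, 19, 2):
            out = ce.add_gaussian_noise(MID_GRAY, sigma, seed=sigma)
            measured = 255.0 * np.std(out - MID_GRAY)
            assert abs(measured - sigma) / sigma < 0.05

    def test_psnr_matches_closed_form(self):
        for sigma in (5.0, 10.0, 15.0):
            out = ce.add_gaussian_noise(MID_GRAY, sigma, seed=int(sigma))
            expected = 20.0 * math.log10(255.0 / sigma)
            assert ce.psnr(MID_GRAY, out) == pytest.approx(expected, abs=0.2)

    def test_reproducible_under_seed_and_negative_sigma_rejected(self):
        a = ce.add_gaussian_noise(MID_GRAY, 8.0, seed=11)
        b = ce.add_gaussian_noise(MID_GRAY, 8.0, seed=11)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            ce.add_gaussian_noise(MID_GRAY, -1.0, seed=0)


class TestDegrade:
    def test_identity_spec(self):
        img = ce.generate_phantom(64, seed=0)
        spec = DegradationSpec(sigma=0.0, scale_factor=1)
        assert np.array_equal(ce.degrade(img, spec, seed=0), img)

    def test_downsample_geometry_512_to_256(self):
        img = ce.generate_phantom(512, seed=1)
        out = ce.degrade(img, DegradationSpec(sigma=5.0, scale_factor=2), seed=0)
        assert out.shape == (256, 256)

    def test_constant_image_stays_constant(self):
        img = np.full((64, 64), 0.37)
        out = ce.degrade(img, DegradationSpec(sigma=0.0, scale_factor=2), seed=0)
        assert np.allclose(out, 0.37, atol=1e-9)

    def test_nondivisible_dimensions_error_names_divisibility(self):
        img = np.zeros((65, 64))
        with pytest.raises(ValueError, match="divisible"):
            ce.degrade(img, DegradationSpec(scale_factor=2), seed=0)

    def test_noise_before_downsample_order(self):
        img = ce.generate_phantom(64, seed=2)
        spec = DegradationSpec(sigma=10.0, scale_factor=2,
                               noise_order="before_downsample")
        out = ce.degrade(img, spec, seed=0)
        assert out.shape == (32, 32)
        # interpolation averages the pre-downsampling noise, so the
        # residual is weaker than the nominal sigma
        clean = ce.degrade(img, DegradationSpec(scale_factor=2), seed=0)
        assert 0 < 255 * np.std(out - clean) < 10.0


class TestDegradationSpecValidation:
    def test_kernel_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DegradationSpec(kernel=np.ones((3, 3)))

    def test_negative_sigma_and_bad_scale(self):
        with pytest.raises(ValueError):
            DegradationSpec(sigma=-2.0)
        with pytest.raises(ValueError):
            DegradationSpec(scale_factor=0)


class TestKernelProjector:
    @staticmethod
    def _family(n=20, side=15):
        return [gaussian_kernel(side, s) for s in np.linspace(0.2, 3.0, n)]

    def test_basis_is_orthonormal(self):
        proj = ce.fit_kernel_projector(self._family(), t=5)
        gram = proj.basis @ proj.basis.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_rank_one_family_recovers_kernel_direction(self):
        k = gaussian_kernel(7, 1.0)
        proj = ce.fit_kernel_projector([k, k, k], t=1)
        v = proj.basis[0]
        unit = k.ravel() / np.linalg.norm(k.ravel())
        assert np.allclose(np.abs(v @ unit), 1.0, atol=1e-10)

    def test_full_rank_round_trip_matches_svd_oracle(self):
        family = self._family(n=60, side=7)
        proj = ce.fit_kernel_projector(family, t=49)
        for k in family[::7]:
            recon = proj.back_project(proj.project(k))
            assert np.linalg.norm(recon - k) < 1e-6

    def test_truncated_reconstruction_error_equals_svd_oracle(self):
        family = self._family(n=30, side=7)
        t = 4
        proj = ce.fit_kernel_projector(family, t=t)
        mat = np.stack([k.ravel() for k in family])
        _, _, vt = np.linalg.svd(mat, full_matrices=False)
        oracle = mat @ vt[:t].T @ vt[:t]
        ours = np.stack([
            proj.back_project(proj.project(k)).ravel() for k in family
        ])
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_t_larger_than_dimensionality_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ce.fit_kernel_projector(self._family(60, side=7), t=50)


class TestDegradationMaps:
    def test_channel_count_and_spatial_uniformity(self):
        proj = ce.fit_kernel_projector(
            [gaussian_kernel(15, s) for s in np.linspace(0.2, 3, 20)], t=15
        )
        maps = ce.build_degradation_maps(gaussian_kernel(15, 1.2), 10.0, 40, 40, proj)
        assert maps.channels.shape == (16, 40, 40)
        assert np.all(np.ptp(maps.channels, axis=(1, 2)) == 0.0)
        assert np.allclose(maps.noise_channel, 10.0 / 255.0)

    def test_zero_sigma_gives_zero_noise_channel(self):
        proj = ce.fit_kernel_projector([delta_kernel(5)], t=1)
        maps = ce.build_degradation_maps(delta_kernel(5), 0.0, 8, 6, proj)
        assert maps.channels.shape == (2, 6, 8)
        assert np.all(maps.noise_channel == 0.0)

    def test_kernel_side_mismatch_rejected(self):
        proj = ce.fit_kernel_projector([delta_kernel(5)], t=1)
        with pytest.raises(ValueError, match="side"):
            ce.build_degradation_maps(delta_kernel(7), 0.0, 8, 8, proj)


class TestPatchDataset:
    def test_zero_patches_gives_empty_list(self):
        classes = ce.NoiseLevelClassSet()
        assert ce.make_noise_patch_dataset([np.zeros((8, 8))], 4, 0, classes) == []

    def test_counts_sizes_and_reproducibility(self, phantom_sources):
        classes = ce.NoiseLevelClassSet((0.0, 9.0, 18.0))
        a = ce.make_noise_patch_dataset(phantom_sources[:3], 16, 50, classes, seed=5)
        b = ce.make_noise_patch_dataset(phantom_sources[:3], 16, 50, classes, seed=5)
        assert len(a) == 50
        assert all(item.patch.shape == (16, 16) for item in a)
        assert all(np.array_equal(x.patch, y.patch) for x, y in zip(a, b))

    def test_class_balance_is_binomial(self):
        classes = ce.NoiseLevelClassSet()  # 10 classes
        patches = ce.make_noise_patch_dataset(
            [np.full((16, 16), 0.5)], 8, 10_000, classes, seed=0
        )
        counts = np.bincount([p.class_index for p in patches], minlength=10)
        assert all(800 <= c <= 1200 for c in counts)

    def test_too_small_source_is_named(self):
        classes = ce.NoiseLevelClassSet()
        with pytest.raises(ValueError, match="source image 1"):
            ce.make_noise_patch_dataset(
                [np.zeros((50, 50)), np.zeros((10, 10))], 32, 5, classes
            )


class TestSRPairs:
    def test_dimension_invariant_and_noiseless_identity(self, phantom_sources):
        pairs = ce.make_sr_pairs(phantom_sources[:4], [5, 10, 15], 2, seed=1)
        assert len(pairs) == 4
        for p in pairs:
            assert p.target.shape == tuple(2 * d for d in p.degraded.shape)
        clean = ce.make_sr_pairs(phantom_sources[:2], [0.0], 1, seed=1)
        for p in clean:
            assert np.array_equal(p.degraded, p.target)

    def test_empty_sigmas_rejected(self):
        with pytest.raises(ValueError, match="sigmas"):
            ce.make_sr_pairs([np.zeros((16, 16))], [], 2)


class TestPhantom:
    def test_deterministic_under_seed(self):
        a = ce.generate_phantom(96, seed=4)
        b = ce.generate_phantom(96, seed=4)
        assert np.array_equal(a, b)

    def test_range_size_and_edges(self):
        img = ce.generate_phantom(128, seed=9)
        assert img.shape == (128, 128)
        assert img.min() >= 0.0 and img.max() <= 1.0
        gy, gx = np.gradient(img)
        assert np.hypot(gy, gx).max() > 0.1

    def test_distinct_seeds_differ(self):
        a = ce.generate_phantom(96, seed=1)
        b = ce.generate_phantom(96, seed=2)
        assert np.mean(a != b) >= 0.01

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            ce.generate_phantom(32, seed=0)
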