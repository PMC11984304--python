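"""Cumulant engine: partition formula, auto/cross images, subsequences."""

import numpy as np
import pytest

from helpers import brute_force_joint_cumulant, fit_gaussian_fwhm_2d
from paintsofi.blink_sim import KineticParams, OpticsCamera, Phantom, DockingSite, render_movie
from paintsofi.cumulants import (
    CumulantImage,
    auto_cumulant_image,
    combine_subsequence_cumulants,
    cross_cumulant_image,
    estimate_block_shifts,
    joint_cumulant,
    split_subsequences,
    virtual_pixel_combination,
)


class TestJointCumulant:
    def test_order_two_equals_biased_covariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 500))
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        assert joint_cumulant([a, b]) == pytest.approx(cov, rel=1e-12)

    def test_constant_series_gives_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        for n in (2, 3, 4):
            assert joint_cumulant([np.full(50, 3.7)] + [x] * (n - 1)) == pytest.approx(0.0, abs=1e-12)

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(2)
        series = [rng.normal(size=60) for _ in range(5)]
        ref = joint_cumulant(series)
        perm = [series[i] for i in (3, 0, 4, 1, 2)]
        assert joint_cumulant(perm) == pytest.approx(ref, rel=1e-12)

    def test_multilinearity_in_one_slot(self):
        rng = np.random.default_rng(3)
        a, b, c, d = (rng.normal(size=40) for _ in range(4))
        lhs = joint_cumulant([2.0 * a + d, b, c])
        rhs = 2.0 * joint_cumulant([a, b, c]) + joint_cumulant([d, b, c])
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_cumulant([np.zeros(10), np.zeros(11)])

    @pytest.mark.parametrize("order", [2, 3, 4, 5, 6])
    def test_matches_brute_force_partition_enumeration(self, order):
        rng = np.random.default_rng(10 + order)
        for _ in range(3):
            series = [rng.normal(size=rng.integers(order, 51)) for _ in range(order)]
            n = min(len(s) for s in series)
            series = [s[:n] for s in series]
            ours = joint_cumulant(series)
            oracle = brute_force_joint_cumulant(series)
            scale = max(abs(oracle), 1e-6)
            assert abs(ours - oracle) / scale < 1e-10


class TestAutoCumulantImage:
    def test_pure_noise_third_order_averages_to_zero(self):
        rng = np.random.default_rng(4)
        movie = rng.normal(100.0, 3.0, size=(3000, 24, 24))
        img = auto_cumulant_image(movie, 3).values
        assert abs(img.mean()) < 3 * img.std() / np.sqrt(img.size)

    def test_single_emitter_order2_is_psf_squared(self, single_emitter_movie):
        img = auto_cumulant_image(single_emitter_movie, 2)
        fwhm = fit_gaussian_fwhm_2d(img.values)
        expected = single_emitter_movie.meta.psf_fwhm / single_emitter_movie.meta.pixel_size / np.sqrt(2)
        assert abs(fwhm - expected) / expected < 0.05

    def test_cumulant_images_add_for_independent_sources(self):
        rng = np.random.default_rng(5)
        kin = KineticParams(per_site_binding_rate=0.5, mean_bound_time=0.3)
        optics = OpticsCamera(
            n_frames=2000, psf_fwhm=300.0, photons_per_bound_imager_per_s=1e5,
            background_photons_per_pixel_per_frame=0.0, read_noise_sd=0.0, camera_offset=0.0, seed=14,
        )
        ph_a = Phantom([DockingSite((800.0, 800.0), kin)], (3200.0, 3200.0))
        ph_b = Phantom([DockingSite((2400.0, 2400.0), kin)], (3200.0, 3200.0))
        a = render_movie(ph_a, optics, noise=False).frames
        b = render_movie(ph_b, optics, acquisition=1, noise=False).frames
        k_sum = auto_cumulant_image(a + b, 2).values
        k_a = auto_cumulant_image(a, 2).values
        k_b = auto_cumulant_image(b, 2).values
        peak = max(np.abs(k_a).max(), np.abs(k_b).max())
        assert np.abs(k_sum - (k_a + k_b)).max() / peak < 0.02

    def test_order_out_of_range_rejected(self, single_emitter_movie):
        with pytest.raises(ValueError):
            auto_cumulant_image(single_emitter_movie, 7)


class TestCrossCumulantImage:
    def test_integer_lattice_points_equal_auto_cumulant(self, single_emitter_movie):
        auto = auto_cumulant_image(single_emitter_movie, 2)
        cross = cross_cumulant_image(single_emitter_movie, 2)
        assert np.allclose(cross.values[::2, ::2], auto.values)

    def test_flattened_single_emitter_has_no_lattice_parity_contrast(self, single_emitter_movie):
        from paintsofi.postproc import flatten

        flat = flatten(cross_cumulant_image(single_emitter_movie, 2))
        v = flat.values
        i0 = np.unravel_index(np.argmax(v), v.shape)
        win = v[i0[0] - 8 : i0[0] + 9, i0[1] - 8 : i0[1] + 9]
        odd = (win[0::2, 1::2].sum() + win[1::2, 0::2].sum()) / 2
        even = (win[0::2, 0::2].sum() + win[1::2, 1::2].sum()) / 2
        assert abs(odd / even - 1.0) < 0.05

    def test_combination_centroid_and_minimal_spread(self):
        for n in (2, 3, 4, 5, 6):
            for a in range(n):
                for b in range(n):
                    combo = np.array(virtual_pixel_combination(n, a, b), dtype=float)
                    assert combo[:, 0].sum() == a and combo[:, 1].sum() == b
                    # floor/ceil split: every offset is 0 or 1
                    assert set(np.unique(combo)) <= {0.0, 1.0}

    def test_movie_smaller_than_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            cross_cumulant_image(np.zeros((300, 2, 2)), 4, psf_sigma_px=1.3)


class TestSubsequences:
    @pytest.mark.parametrize(
        "T,expected_blocks,expected_dropped",
        [(5000, 5, 0), (500, 1, 0), (2500, 2, 500), (1000, 1, 0)],
    )
    def test_block_splitting_rules(self, T, expected_blocks, expected_dropped):
        plan = split_subsequences(T)
        assert len(plan.blocks) == expected_blocks
        assert plan.n_dropped == expected_dropped
        starts = [a for a, _ in plan.blocks]
        assert starts == sorted(starts)

    def test_identical_blocks_combine_to_identity(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(40, 40))
        imgs = [CumulantImage(2, base.copy(), 1) for _ in range(3)]
        out = combine_subsequence_cumulants(imgs)
        assert np.allclose(out.values, base, atol=1e-10)
        assert np.allclose(out.provenance["block_shifts"], 0.0)

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(7)
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(rng.normal(size=(64, 64)) ** 2, 2.0)
        shifted = np.roll(base, (3, -2), axis=(0, 1))
        shifts = estimate_block_shifts([base, shifted])
        # reported as the correction registering the block onto the first:
        # a block drifted by (3, -2) needs a (-3, 2) shift
        assert np.allclose(shifts[1], [-3.0, 2.0], atol=0.2)

    def test_single_block_passthrough(self):
        img = CumulantImage(3, np.ones((10, 10)), 1)
        out = combine_subsequence_cumulants([img])
        assert np.array_equal(out.values, img.values)
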