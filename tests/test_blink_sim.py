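"""Simulator: phantoms, hybridization kinetics, occupancy, camera model."""

import numpy as np
import pytest

from paintsofi.blink_sim import (
    BindingTrace,
    DockingSite,
    KineticParams,
    OpticsCamera,
    Phantom,
    binding_statistics,
    integrate_occupancy,
    make_filament_phantom,
    make_grid_phantom,
    make_point_pair_phantom,
    render_movie,
    simulate_binding_trace,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"per_site_binding_rate": 0.0, "mean_bound_time": 1.0},
        {"per_site_binding_rate": np.inf, "mean_bound_time": 1.0},
        {"per_site_binding_rate": 1.0, "mean_bound_time": -1.0},
        {"per_site_binding_rate": 1.0, "mean_bound_time": 1.0, "n_repeat_motifs": 0},
        {"per_site_binding_rate": 1.0, "mean_bound_time": 1.0, "destabilizer_on_time_factor": 0.0},
        {"per_site_binding_rate": 1.0, "mean_bound_time": 1.0, "destabilizer_on_time_factor": 1.5},
    ],
)
def test_kinetic_params_rejects_unphysical_values(kwargs):
    with pytest.raises(ValueError):
        KineticParams(**kwargs)


class TestPhantoms:
    def test_point_pair_separation_and_shared_kinetics(self, dense_kinetics):
        ph = make_point_pair_phantom(180.0, dense_kinetics)
        a, b = ph.positions
        assert np.linalg.norm(a - b) == pytest.approx(180.0)
        assert all(s.kinetics is dense_kinetics for s in ph.sites)

    def test_point_pair_zero_separation_collapses_to_center(self, dense_kinetics):
        ph = make_point_pair_phantom(0.0, dense_kinetics, extent=(2000.0, 2000.0))
        assert np.allclose(ph.positions, [[1000.0, 1000.0]] * 2)

    def test_filament_zero_filaments_gives_empty_phantom(self, dense_kinetics):
        ph = make_filament_phantom(0, (5000.0, 5000.0), 0.05, dense_kinetics, seed=1)
        assert ph.sites == []

    def test_filament_site_count_near_poisson_mean(self, dense_kinetics):
        density = 0.05
        ph = make_filament_phantom(3, (8000.0, 8000.0), density, dense_kinetics, seed=3)
        L = sum(c["arc_length_nm"] for c in ph.truth_geometry["curves"])
        expected = density * L
        assert abs(len(ph.sites) - expected) < 4 * np.sqrt(expected)

    def test_filament_same_seed_reproducible(self, dense_kinetics):
        a = make_filament_phantom(2, (6000.0, 6000.0), 0.04, dense_kinetics, seed=9)
        b = make_filament_phantom(2, (6000.0, 6000.0), 0.04, dense_kinetics, seed=9)
        assert np.array_equal(a.positions, b.positions)

    def test_filament_rejects_tiny_extent(self, dense_kinetics):
        with pytest.raises(ValueError, match="width"):
            make_filament_phantom(1, (0.0, 5000.0), 0.05, dense_kinetics)

    def test_sites_outside_extent_rejected(self, dense_kinetics):
        with pytest.raises(ValueError, match="outside extent"):
            Phantom([DockingSite((-5.0, 10.0), dense_kinetics)], (100.0, 100.0))


class TestBindingTrace:
    def test_vanishing_rate_produces_no_events(self):
        kin = KineticParams(per_site_binding_rate=1e-12, mean_bound_time=1.0)
        tr = simulate_binding_trace(kin, 10.0, seed=0)
        assert tr.n_events == 0

    def test_mean_bound_dwell_matches_configuration(self):
        kin = KineticParams(
            per_site_binding_rate=2.0, mean_bound_time=0.4, destabilizer_on_time_factor=0.5
        )
        tr = simulate_binding_trace(kin, 20000.0, seed=1)
        iv = tr.all_intervals()
        # drop the last interval (clipped at the movie end)
        on = (iv[:, 1] - iv[:, 0])[:-1]
        assert len(on) > 10_000
        se = on.std() / np.sqrt(len(on))
        assert abs(on.mean() - 0.2) < 3 * se

    def test_start_bound_begins_at_time_zero(self, dense_kinetics):
        tr = simulate_binding_trace(dense_kinetics, 5.0, seed=2, start_bound=True)
        assert tr.all_intervals()[0, 0] == 0.0

    def test_rejects_nonpositive_duration(self, dense_kinetics):
        with pytest.raises(ValueError):
            simulate_binding_trace(dense_kinetics, 0.0, seed=0)


class TestOccupancy:
    def test_interval_spanning_one_frame_exactly(self):
        trace = np.array([[0.03, 0.04]])  # exactly frame 3 at 10 ms
        occ = integrate_occupancy(trace, 0.01, 10)
        expected = np.zeros(10)
        expected[3] = 0.01
        assert np.allclose(occ, expected)

    def test_interval_straddling_boundary_splits_by_fraction(self):
        trace = np.array([[0.017, 0.025]])  # 3 ms in frame 1, 5 ms in frame 2
        occ = integrate_occupancy(trace, 0.01, 4)
        assert occ[1] == pytest.approx(0.003)
        assert occ[2] == pytest.approx(0.005)
        assert occ.sum() == pytest.approx(0.008)

    def test_occupancy_conserves_total_bound_time(self, dense_kinetics):
        tr = simulate_binding_trace(dense_kinetics, 50.0, seed=3)
        occ = integrate_occupancy(tr, 0.01, 5000)
        iv = tr.all_intervals()
        clipped = np.clip(iv, 0.0, 50.0)
        assert abs(occ.sum() - (clipped[:, 1] - clipped[:, 0]).sum()) < 1e-9

    def test_rejects_nonpositive_frame_time(self):
        with pytest.raises(ValueError):
            integrate_occupancy(np.zeros((0, 2)), 0.0, 10)


class TestRenderMovie:
    def test_background_only_counts_match_camera_model(self):
        optics = OpticsCamera(
            n_frames=2000,
            pixel_size=100.0,
            psf_fwhm=300.0,
            background_photons_per_pixel_per_frame=7.0,
            camera_gain=1.0,
            camera_offset=100.0,
            read_noise_sd=0.0,
            seed=4,
        )
        ph = Phantom([], (1600.0, 1600.0))
        mov = render_movie(ph, optics)
        per_pixel_mean = mov.frames.mean(axis=0)
        se = np.sqrt(7.0 / 2000)  # Poisson SE of the temporal mean
        assert np.abs(per_pixel_mean.mean() - 107.0) < 3 * se

    def test_photon_conservation_without_noise(self, dense_kinetics):
        optics = OpticsCamera(
            n_frames=200, background_photons_per_pixel_per_frame=3.0, seed=6
        )
        ph = make_filament_phantom(2, (3200.0, 3200.0), 0.03, dense_kinetics, seed=6)
        mov, occ = render_movie(ph, optics, noise=False, return_occupancy=True)
        from paintsofi.blink_sim import psf_kernel_matrix

        kernels = psf_kernel_matrix(ph.positions, optics, (32, 32))
        expected = occ.sum(axis=1) * 0.0  # placeholder shape
        expected = (occ * optics.photons_per_bound_imager_per_s) @ kernels.sum(axis=1)
        expected += 3.0 * 32 * 32
        total = mov.frames.reshape(200, -1).sum(axis=1)
        assert np.allclose(total, expected, rtol=1e-6)

    def test_same_seed_bit_identical(self, dense_kinetics):
        optics = OpticsCamera(n_frames=50, seed=8)
        ph = make_point_pair_phantom(200.0, dense_kinetics, extent=(1600.0, 1600.0))
        a = render_movie(ph, optics)
        b = render_movie(ph, optics)
        assert np.array_equal(a.frames, b.frames)

    def test_adding_a_site_does_not_perturb_existing_traces(self, dense_kinetics):
        optics = OpticsCamera(n_frames=100, background_photons_per_pixel_per_frame=0.0, seed=12)
        one = Phantom([DockingSite((400.0, 400.0), dense_kinetics)], (1600.0, 1600.0))
        two = Phantom(
            [DockingSite((400.0, 400.0), dense_kinetics), DockingSite((1200.0, 1200.0), dense_kinetics)],
            (1600.0, 1600.0),
        )
        m1, occ1 = render_movie(one, optics, noise=False, return_occupancy=True)
        m2, occ2 = render_movie(two, optics, noise=False, return_occupancy=True)
        assert np.array_equal(occ1[:, 0], occ2[:, 0])

    def test_site_outside_field_dropped_with_warning(self, dense_kinetics):
        optics = OpticsCamera(n_frames=20, seed=13)
        ph = Phantom(
            [DockingSite((10_000.0, 10_000.0), dense_kinetics)], (12_000.0, 12_000.0)
        )
        ph.extent = (1600.0, 1600.0)  # shrink the rendered field after the fact
        with pytest.warns(UserWarning, match="outside the field"):
            render_movie(ph, optics)


class TestBindingStatistics:
    def test_duty_cycle_single_interval(self, dense_kinetics):
        tr = BindingTrace([np.array([[2.0, 3.0]])], 10.0, dense_kinetics)
        stats = binding_statistics([tr])
        assert stats.duty_cycle == pytest.approx(0.1)
        assert stats.mean_on_time == pytest.approx(1.0)

    def test_empty_traces_flagged_undefined_not_nan(self, dense_kinetics):
        tr = BindingTrace([np.zeros((0, 2))], 10.0, dense_kinetics)
        stats = binding_statistics([tr])
        assert stats.n_events == 0
        assert not stats.defined
        assert stats.mean_on_time is None and stats.mean_off_time is None

    def test_grid_phantom_covers_extent(self, dense_kinetics):
        ph = make_grid_phantom(100.0, (800.0, 800.0), dense_kinetics)
        assert len(ph.sites) == 64
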