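"""SMLM branch: detection, integrated-Gaussian fitting, drift, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import erf

from paintsofi.localize import (
    LOCALIZATION_COLUMNS,
    detect_candidates,
    estimate_uncertainty,
    filter_and_drift_correct,
    fit_integrated_gaussian,
    localize_movie,
    read_localizations,
    render_ash,
    write_localizations,
    FitRecord,
)


def make_frame(x0, y0, sigma, N, bg, shape=(25, 25), rng=None):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    s = sigma * np.sqrt(2)
    gx = 0.5 * (erf((xx - x0 + 0.5) / s) - erf((xx - x0 - 0.5) / s))
    gy = 0.5 * (erf((yy - y0 + 0.5) / s) - erf((yy - y0 - 0.5) / s))
    expected = N * gx * gy + bg
    return rng.poisson(expected).astype(float) if rng is not None else expected


class TestDetection:
    def test_noise_only_false_positive_rate_follows_gaussian_tail(self):
        rng = np.random.default_rng(0)
        # one-sided Gaussian tail at 3 sigma is 0.135% of pixels; local-maximum
        # thinning keeps the observed rate at or below that bound
        n_fp = sum(len(detect_candidates(rng.normal(100, 3, (64, 64)), 3.0)) for _ in range(20))
        assert n_fp < 0.00135 * 20 * 64 * 64 * 1.5
        # a higher threshold suppresses false positives below 0.1% of pixels
        n_fp_high = sum(len(detect_candidates(rng.normal(100, 3, (64, 64)), 3.5)) for _ in range(20))
        assert n_fp_high < 0.001 * 20 * 64 * 64

    def test_bright_emitter_yields_one_candidate_near_truth(self):
        rng = np.random.default_rng(1)
        frame = make_frame(12.0, 10.0, 1.3, 5000, 10, rng=rng)
        cands = detect_candidates(frame, 3.0)
        assert len(cands) == 1
        assert abs(cands[0][0] - 10) <= 1 and abs(cands[0][1] - 12) <= 1

    def test_two_separated_emitters_yield_two_candidates(self):
        rng = np.random.default_rng(2)
        frame = make_frame(6.0, 12.0, 1.3, 5000, 10, rng=rng) + make_frame(16.0, 12.0, 1.3, 5000, 0)
        assert len(detect_candidates(frame, 3.0)) == 2


class TestFitting:
    def test_noiseless_position_recovery(self):
        frame = make_frame(10.30, 7.75, 1.3, 5000, 10)
        rec = fit_integrated_gaussian(frame, (8, 10))
        assert rec.x_px == pytest.approx(10.30, abs=0.01)
        assert rec.y_px == pytest.approx(7.75, abs=0.01)

    def test_initial_sigma_misconfiguration_tolerated(self):
        frame = make_frame(12.0, 12.0, 1.3, 8000, 5)
        a = fit_integrated_gaussian(frame, (12, 12), init_sigma=1.6)
        b = fit_integrated_gaussian(frame, (12, 12), init_sigma=3.2)
        assert a.sigma_px == pytest.approx(b.sigma_px, rel=0.01)

    def test_border_candidate_skipped(self):
        frame = make_frame(2.0, 2.0, 1.3, 5000, 10)
        assert fit_integrated_gaussian(frame, (2, 2), fit_radius=4) is None

    def test_empirical_precision_matches_thompson_formula(self):
        rng = np.random.default_rng(3)
        xs, ys, preds = [], [], []
        for _ in range(200):
            frame = make_frame(12.3, 12.2, 1.3, 5000, 10, rng=rng)
            rec = fit_integrated_gaussian(frame, (12, 12))
            if rec is None:
                continue
            xs.append(rec.x_px)
            ys.append(rec.y_px)
            preds.append(estimate_uncertainty(rec, 100.0))
        emp = np.sqrt(0.5 * (np.std(xs) ** 2 + np.std(ys) ** 2)) * 100.0
        assert abs(emp - np.mean(preds)) / np.mean(preds) < 0.25


class TestUncertainty:
    def test_quadrupling_photons_halves_uncertainty(self):
        # photon-limited regime (no background): pure 1/sqrt(N) scaling
        a = estimate_uncertainty(FitRecord(0, 0, 1.3, 2000, 0, True), 100.0)
        b = estimate_uncertainty(FitRecord(0, 0, 1.3, 8000, 0, True), 100.0)
        assert a / b == pytest.approx(2.0, rel=0.05)

    def test_background_strictly_increases_uncertainty(self):
        clean = estimate_uncertainty(FitRecord(0, 0, 1.3, 5000, 0, True), 100.0)
        noisy = estimate_uncertainty(FitRecord(0, 0, 1.3, 5000, 50, True), 100.0)
        assert noisy > clean

    def test_typical_event_single_digit_nanometers(self):
        unc = estimate_uncertainty(FitRecord(0, 0, 1.3, 5000, 10, True), 100.0)
        assert 0.5 < unc < 10.0

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            estimate_uncertainty(FitRecord(0, 0, 1.3, 0, 10, True), 100.0)


def _synthetic_table(rng, n=15000, n_frames=5000, drift_x=0.0, drift_y=0.0, noise_nm=10.0):
    frames = np.sort(rng.integers(0, n_frames, n))
    structure = rng.choice([0, 1], n)
    x0 = np.where(structure, rng.uniform(500, 5500, n), 3000 + rng.normal(0, 30, n))
    y0 = np.where(structure, 3000 + rng.normal(0, 30, n), rng.uniform(500, 5500, n))
    df = pd.DataFrame(
        {
            "frame": frames,
            "x [nm]": x0 + drift_x * frames + rng.normal(0, noise_nm, n),
            "y [nm]": y0 + drift_y * frames + rng.normal(0, noise_nm, n),
            "sigma [nm]": 130.0,
            "intensity [photon]": 5000.0,
            "offset [photon]": 10.0,
            "uncertainty [nm]": 5.0,
        }
    )[LOCALIZATION_COLUMNS]
    return df, x0, y0


class TestDriftCorrection:
    def test_all_records_above_threshold_filtered_out(self):
        rng = np.random.default_rng(4)
        df, _, _ = _synthetic_table(rng, n=100)
        df["uncertainty [nm]"] = 20.0
        out = filter_and_drift_correct(df, max_uncertainty_nm=15.0)
        assert len(out) == 0

    def test_linear_drift_removed(self):
        rng = np.random.default_rng(5)
        df, x0, y0 = _synthetic_table(rng, drift_x=0.2, drift_y=-0.1)
        out = filter_and_drift_correct(df, bin_frames=500)
        fr = out["frame"].to_numpy()
        resx = out["x [nm]"].to_numpy() - x0[out.index]
        bins = (fr // 250).astype(int)
        traj = np.array([resx[bins == b].mean() for b in np.unique(bins)])
        assert np.sqrt(np.mean((traj - traj.mean()) ** 2)) < 5.0

    def test_zero_drift_leaves_positions_nearly_unchanged(self):
        rng = np.random.default_rng(6)
        df, _, _ = _synthetic_table(rng, drift_x=0.0, drift_y=0.0)
        out = filter_and_drift_correct(df, bin_frames=500)
        shift = np.abs(out["x [nm]"].to_numpy() - df.loc[out.index, "x [nm]"].to_numpy())
        # registration precision at ~1500 localizations/block is a few nm
        assert shift.max() < 5.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            filter_and_drift_correct(pd.DataFrame(columns=LOCALIZATION_COLUMNS))


class TestRendering:
    def test_single_localization_unit_mass(self):
        df = pd.DataFrame(
            [[0, 512.0, 480.0, 130.0, 5000.0, 10.0, 5.0]], columns=LOCALIZATION_COLUMNS
        )
        ash = render_ash(df, magnification=5.0, camera_pixel_nm=100.0)
        assert ash.sum() == pytest.approx(1.0)

    def test_mass_conservation_many_records(self):
        rng = np.random.default_rng(7)
        df, _, _ = _synthetic_table(rng, n=10_000)
        ash = render_ash(df, 5.0, 100.0)
        assert ash.sum() == pytest.approx(len(df), rel=1e-3)

    def test_magnification_preserves_mass(self):
        rng = np.random.default_rng(8)
        df, _, _ = _synthetic_table(rng, n=2000)
        assert render_ash(df, 5.0, 100.0).sum() == pytest.approx(render_ash(df, 10.0, 100.0).sum())


class TestTableIO:
    def test_csv_round_trip_with_column_reordering(self, tmp_path):
        rng = np.random.default_rng(9)
        df, _, _ = _synthetic_table(rng, n=50)
        path = tmp_path / "locs.csv"
        write_localizations(df, path)
        shuffled = pd.read_csv(path)[list(reversed(LOCALIZATION_COLUMNS))]
        shuffled.to_csv(path, index=False)
        back = read_localizations(path)
        assert list(back.columns) == LOCALIZATION_COLUMNS
        assert np.allclose(back["x [nm]"], df["x [nm]"])

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"frame": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            read_localizations(path)


class TestLocalizeMovie:
    def test_sparse_movie_localizations_near_sites(self, sparse_kinetics):
        from paintsofi.blink_sim import OpticsCamera, Phantom, DockingSite, render_movie

        from paintsofi.blink_sim import KineticParams

        kin = KineticParams(per_site_binding_rate=0.05, mean_bound_time=0.5)
        optics = OpticsCamera(
            n_frames=400, frame_time=0.1, pixel_size=100.0, psf_fwhm=300.0,
            photons_per_bound_imager_per_s=5e4, background_photons_per_pixel_per_frame=5.0, seed=23,
        )
        sites = [DockingSite((800.0, 800.0), kin), DockingSite((2400.0, 2000.0), kin)]
        mov = render_movie(Phantom(sites, (3200.0, 3200.0)), optics)
        table = localize_movie(mov)
        table = table[table["uncertainty [nm]"] <= 15.0]  # the pipeline's filter
        assert len(table) > 5
        pos = table[["x [nm]", "y [nm]"]].to_numpy()
        truth = np.array([[800.0, 800.0], [2400.0, 2000.0]])
        d = np.min(np.linalg.norm(pos[:, None, :] - truth[None], axis=2), axis=1)
        assert np.median(d) < 50.0
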