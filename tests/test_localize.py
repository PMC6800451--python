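"""Detection, fitting, z assignment, drift, rendering and stitching."""

import numpy as np
import pandas as pd
import pytest

from bessellight import blink_sim as bs
from bessellight import localize as loc


def _spot_frame(cam, x_nm, y_nm, sx_nm, sy_nm, photons, baseline=None):
    """Noise-free frame with one pixel-integrated elliptical Gaussian."""
    from bessellight.blink_sim import _pixel_integrated_spot
    h, w = cam.frame_shape
    base = cam.baseline if baseline is None else baseline
    img = _pixel_integrated_spot((h, w), x_nm / cam.pixel_size,
                                 y_nm / cam.pixel_size,
                                 sx_nm / cam.pixel_size,
                                 sy_nm / cam.pixel_size, photons)
    return img / cam.gain + base


class TestDetectSpots:
    def test_blank_frame_no_candidates(self, cam):
        frame = np.full(cam.frame_shape, cam.baseline)
        assert len(loc.detect_spots(frame)) == 0

    def test_ten_separated_emitters_found(self, psf, cam):
        rng = np.random.default_rng(0)
        grid = np.stack(np.meshgrid([10, 20, 30, 40], [12, 36]), -1).reshape(-1, 2)
        pos = grid[:10] * cam.pixel_size + 50.0
        em = pd.DataFrame({"frame": 0, "emitter": np.arange(len(pos)),
                           "x": pos[:, 0].astype(float),
                           "y": pos[:, 1].astype(float),
                           "z": 0.0, "photons": 5000.0})
        stack = bs.render_frame_stack(em, psf, cam, seed=1, noise=True)
        cands = loc.detect_spots(stack.frames[0])
        assert len(cands) == len(pos)
        for x, y in pos:
            d = np.hypot(cands[:, 1] * cam.pixel_size - x,
                         cands[:, 0] * cam.pixel_size - y)
            assert d.min() <= 1.5 * cam.pixel_size

    def test_adjacent_emitters_merge(self, cam):
        frame = (_spot_frame(cam, 2400.0, 2400.0, 150, 150, 3000)
                 + _spot_frame(cam, 2500.0, 2400.0, 150, 150, 3000, baseline=0))
        cands = loc.detect_spots(frame)
        assert len(cands) == 1


class TestFitSpot:
    def test_subpixel_position_recovery(self, cam):
        # emitter 0.3 px off a pixel centre, noise-free: error < 1e-3 px
        x_true = (24 + 0.5 + 0.3) * cam.pixel_size
        y_true = (24 + 0.5) * cam.pixel_size
        frame = _spot_frame(cam, x_true, y_true, 150.0, 150.0, 5000.0)
        rec = loc.fit_spot(frame, (24, 24), cam)
        assert rec is not None
        assert abs(rec["x"] - x_true) < 1e-3 * cam.pixel_size
        assert abs(rec["y"] - y_true) < 1e-3 * cam.pixel_size

    def test_ellipticity_recovery(self, cam):
        frame = _spot_frame(cam, 2450.0, 2450.0, 1.4 * 150.0, 150.0, 8000.0)
        rec = loc.fit_spot(frame, (24, 24), cam)
        assert rec["ellipticity"] == pytest.approx(1.4, rel=0.02)

    def test_photon_and_background_recovery(self, cam):
        frame = _spot_frame(cam, 2450.0, 2450.0, 160.0, 160.0, 5000.0,
                            baseline=cam.baseline + 3.0)
        rec = loc.fit_spot(frame, (24, 24), cam)
        assert rec["photons"] == pytest.approx(5000.0, rel=0.01)
        assert rec["background"] == pytest.approx(3.0 * cam.gain, abs=0.2)

    def test_rmse_close_to_crlb(self, cam):
        # Poisson-only repeats: positional RMSE within 1.2x the CRLB computed
        # from the Fisher information of the pixel-integrated model
        from bessellight.blink_sim import _pixel_integrated_spot
        rng = np.random.default_rng(42)
        photons, sigma_nm, reps = 5000.0, 150.0, 400
        x_px, y_px = 24.5, 24.5
        s_px = sigma_nm / cam.pixel_size
        clean = _pixel_integrated_spot(cam.frame_shape, x_px, y_px, s_px, s_px,
                                       photons)
        # Fisher information for x under Poisson pixels: sum mu_x'^2 / mu
        eps = 1e-4
        dmu = (_pixel_integrated_spot(cam.frame_shape, x_px + eps, y_px, s_px,
                                      s_px, photons) - clean) / eps
        fisher = np.sum(dmu**2 / np.maximum(clean, 1e-12))
        crlb_px = 1.0 / np.sqrt(fisher)
        errs = []
        for _ in range(reps):
            noisy = rng.poisson(clean).astype(float) / cam.gain + cam.baseline
            rec = loc.fit_spot(noisy, (24, 24), cam)
            if rec is not None:
                errs.append(rec["x"] / cam.pixel_size - x_px)
        errs = np.asarray(errs)
        assert len(errs) > 0.95 * reps
        rmse = np.sqrt(np.mean(errs**2))
        assert rmse <= 1.2 * crlb_px

    def test_window_outside_frame_rejected(self, cam):
        frame = np.full(cam.frame_shape, cam.baseline)
        assert loc.fit_spot(frame, (1, 1), cam) is None


class TestAssignZ:
    def test_on_curve_record_gets_exact_z(self, psf):
        cal = loc.DefocusCalibration.from_model(psf)
        z_true = 150.0
        df = pd.DataFrame([{
            "frame": 0, "x": 0.0, "y": 0.0, "z": np.nan,
            "sigma_x": float(psf.sigma_x(z_true)),
            "sigma_y": float(psf.sigma_y(z_true)),
            "photons": 1000.0, "background": 0.0, "uncertainty_xy": 10.0,
            "ellipticity": 1.0, "keep": True}])
        out = loc.assign_z_and_filter(loc.LocalizationTable(df), cal)
        assert out.df["keep"].iloc[0]
        assert out.df["z"].iloc[0] == pytest.approx(z_true, abs=1.0)

    def test_inflated_symmetric_blob_rejected(self, psf):
        cal = loc.DefocusCalibration.from_model(psf)
        s = 3.0 * float(psf.sigma_x(0.0))
        df = pd.DataFrame([{
            "frame": 0, "x": 0.0, "y": 0.0, "z": np.nan,
            "sigma_x": s, "sigma_y": s, "photons": 1000.0, "background": 0.0,
            "uncertainty_xy": 10.0, "ellipticity": 1.0, "keep": True}])
        out = loc.assign_z_and_filter(loc.LocalizationTable(df), cal)
        assert not out.df["keep"].iloc[0]

    def test_filter_only_clears_flags(self, psf):
        cal = loc.DefocusCalibration.from_model(psf)
        rng = np.random.default_rng(1)
        n = 50
        df = pd.DataFrame({
            "frame": np.arange(n), "x": 0.0, "y": 0.0, "z": np.nan,
            "sigma_x": rng.uniform(100, 600, n),
            "sigma_y": rng.uniform(100, 600, n),
            "photons": 1000.0, "background": 0.0, "uncertainty_xy": 10.0,
            "ellipticity": 1.0, "keep": True})
        out = loc.assign_z_and_filter(loc.LocalizationTable(df), cal)
        assert len(out.df) == n
        assert out.df["keep"].sum() <= n

    def test_z_rmse_from_forward_simulation(self, psf, cam, random_spots_stack):
        stack, truth = random_spots_stack
        table = loc.localize_stack(stack)
        cal = loc.DefocusCalibration.from_model(psf)
        out = loc.assign_z_and_filter(table, cal)
        merged = out.df[out.df["keep"]].merge(truth, on="frame",
                                              suffixes=("", "_true"))
        close = np.hypot(merged["x"] - merged["x_true"],
                         merged["y"] - merged["y_true"]) < 100.0
        m = merged[close]
        assert len(m) > 100
        z_rmse = float(np.sqrt(np.mean((m["z"] - m["z_true"]) ** 2)))
        lat_rmse = float(np.sqrt(np.mean((m["x"] - m["x_true"]) ** 2)))
        # astigmatic z is a few-fold less precise than lateral, bounded by
        # the calibration slope scale factor
        cal_slope = np.median(np.abs(np.gradient(cal.sigma_x - cal.sigma_y,
                                                 cal.z)))
        assert z_rmse <= 2.0 * lat_rmse * np.sqrt(2) / cal_slope


def _drift_table(rng, n_frames=2000, rate=(0.2, 0.1), loc_sigma=10.0):
    drift_x = rate[0] * np.arange(n_frames)
    drift_y = rate[1] * np.arange(n_frames)
    parts = []
    for fx, fy in [(500.0, 500.0), (4500.0, 4500.0), (500.0, 4500.0)]:
        parts.append(pd.DataFrame({
            "frame": np.arange(n_frames),
            "x": fx + drift_x + rng.normal(0, loc_sigma, n_frames),
            "y": fy + drift_y + rng.normal(0, loc_sigma, n_frames)}))
    m = 4000
    fr = rng.integers(0, n_frames, m)
    parts.append(pd.DataFrame({
        "frame": fr,
        "x": rng.uniform(1500, 3500, m) + drift_x[fr] + rng.normal(0, 15, m),
        "y": rng.uniform(1500, 3500, m) + drift_y[fr] + rng.normal(0, 15, m)}))
    df = pd.concat(parts, ignore_index=True)
    df["keep"] = True
    df["uncertainty_xy"] = loc_sigma
    return loc.LocalizationTable(df), drift_x, drift_y


class TestDriftCorrect:
    def test_fiducial_recovers_linear_drift(self):
        rng = np.random.default_rng(3)
        table, dx_true, dy_true = _drift_table(rng)
        _, traj = loc.drift_correct(table, "fiducial")
        # residual drift below the 10 nm localization precision
        assert np.max(np.abs(traj.dx - dx_true)) < 10.0
        assert np.max(np.abs(traj.dy - dy_true)) < 10.0

    def test_xcorr_recovers_endpoint(self):
        rng = np.random.default_rng(4)
        table, dx_true, dy_true = _drift_table(rng)
        _, traj = loc.drift_correct(table, "xcorr", n_bins=8, bin_size=20.0)
        assert abs(traj.dx[-1] - dx_true[-1]) <= 20.0
        assert abs(traj.dy[-1] - dy_true[-1]) <= 20.0

    def test_zero_drift_null_trajectory(self):
        rng = np.random.default_rng(5)
        table, _, _ = _drift_table(rng, rate=(0.0, 0.0))
        _, traj = loc.drift_correct(table, "fiducial")
        assert np.max(np.abs(traj.dx)) < 5.0
        assert np.max(np.abs(traj.dy)) < 5.0

    def test_idempotence(self):
        rng = np.random.default_rng(6)
        table, _, _ = _drift_table(rng)
        corrected, _ = loc.drift_correct(table, "fiducial")
        _, second = loc.drift_correct(corrected, "fiducial")
        assert np.max(np.abs(second.dx)) < 5.0
        assert np.max(np.abs(second.dy)) < 5.0

    def test_no_fiducial_errors(self):
        df = pd.DataFrame({"frame": np.arange(100),
                           "x": np.random.default_rng(0).uniform(0, 1e4, 100),
                           "y": np.random.default_rng(1).uniform(0, 1e4, 100)})
        with pytest.raises(ValueError):
            loc.drift_correct(loc.LocalizationTable(df), "fiducial")


class TestRender:
    def _table(self, df):
        return loc.LocalizationTable(df)

    def test_single_record_single_count(self):
        df = pd.DataFrame({"frame": [0], "x": [55.0], "y": [25.0]})
        img = loc.render(self._table(df), 10.0)
        assert img.sum() == 1.0
        assert img.max() == 1.0

    def test_histogram_sum_equals_kept_count(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"frame": np.zeros(500, int),
                           "x": rng.uniform(0, 5000, 500),
                           "y": rng.uniform(0, 5000, 500),
                           "keep": rng.random(500) < 0.7})
        table = self._table(df)
        img = loc.render(table, 20.0)
        assert img.sum() == len(table.kept)

    def test_two_lines_at_60nm_resolved(self):
        rng = np.random.default_rng(8)
        n = 4000
        y = np.where(rng.random(n) < 0.5, -30.0, 30.0) + rng.normal(0, 8, n)
        df = pd.DataFrame({"frame": np.zeros(n, int),
                           "x": rng.uniform(0, 2000, n), "y": y + 500.0})
        img = loc.render(self._table(df), 10.0,
                         extent=((0.0, 2000.0), (400.0, 600.0)))
        profile = img.sum(axis=1)
        peaks = np.sort(np.argsort(profile)[-8:])
        ridge1 = profile[peaks[0]]
        valley = profile[(len(profile)) // 2]
        assert valley < 0.75 * ridge1

    def test_gaussian_mode_preserves_mass(self):
        df = pd.DataFrame({"frame": [0, 0], "x": [500.0, 700.0],
                           "y": [500.0, 700.0], "uncertainty_xy": [20.0, 20.0]})
        img = loc.render(self._table(df), 10.0, mode="gaussian",
                         extent=((0.0, 1200.0), (0.0, 1200.0)))
        assert img.sum() == pytest.approx(2.0, rel=1e-6)


class TestStitchTiles:
    def _tile(self, rng, n=300, x0=0.0, y0=0.0, extent=10000.0):
        df = pd.DataFrame({"frame": rng.integers(0, 50, n),
                           "x": rng.uniform(0, extent, n),
                           "y": rng.uniform(0, extent, n)})
        return loc.LocalizationTable(df)

    def test_single_tile_identity(self):
        rng = np.random.default_rng(0)
        t = self._tile(rng)
        merged = loc.stitch_tiles([t], [(0.0, 0.0)])
        assert len(merged) == len(t)
        np.testing.assert_allclose(np.sort(merged.df["x"]), np.sort(t.df["x"]))

    def test_2x2_layout_bounding_box(self):
        # four 250 x 175 um tiles in a 2 x 2 layout fit in 500 x 350 um
        rng = np.random.default_rng(1)
        w, h = 250e3, 175e3
        tiles, offsets = [], []
        for i in range(2):
            for j in range(2):
                df = pd.DataFrame({"frame": np.zeros(100, int),
                                   "x": rng.uniform(0, w, 100),
                                   "y": rng.uniform(0, h, 100)})
                tiles.append(loc.LocalizationTable(df))
                offsets.append((j * w, i * h))
        merged = loc.stitch_tiles(tiles, offsets)
        assert merged.df["x"].max() - merged.df["x"].min() <= 500e3
        assert merged.df["y"].max() - merged.df["y"].min() <= 350e3
        assert len(merged) == 400

    def test_registration_recovers_injected_misalignment(self):
        rng = np.random.default_rng(2)
        n = 3000
        base = pd.DataFrame({"frame": rng.integers(0, 50, n),
                             "x": rng.uniform(0, 20000, n),
                             "y": rng.uniform(0, 20000, n)})
        left = base[base["x"] < 12000].copy()
        right = base[base["x"] > 8000].copy()
        bin_size = 50.0
        shift = 150.0  # injected misalignment, nm
        right["x"] = right["x"] - shift
        merged = loc.stitch_tiles(
            [loc.LocalizationTable(left), loc.LocalizationTable(right)],
            [(0.0, 0.0), (0.0, 0.0)], overlap_registration=True,
            bin_size=bin_size)
        # overlap records should deduplicate once registration aligns them
        matched = merged.df["x"]
        assert len(merged) <= len(left) + len(right)
        assert len(merged) <= len(base) + 0.2 * min(len(left), len(right))

    def test_mismatched_offsets_raise(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            loc.stitch_tiles([self._tile(rng)], [(0, 0), (1, 1)])


class TestEndToEnd:
    def test_recall_and_precision_at_5000_photons(self, random_spots_stack, cam):
        stack, truth = random_spots_stack
        table = loc.localize_stack(stack)
        hits, ex, ey, uncs = 0, [], [], []
        for t, row in truth.iterrows():
            locs = table.df[table.df["frame"] == row["frame"]]
            if len(locs) == 0:
                continue
            d = np.hypot(locs["x"] - row["x"], locs["y"] - row["y"])
            i = d.idxmin()
            if d[i] <= 100.0:
                hits += 1
                ex.append(locs["x"][i] - row["x"])
                ey.append(locs["y"][i] - row["y"])
                uncs.append(locs["uncertainty_xy"][i])
        recall = hits / len(truth)
        assert recall >= 0.9
        rmse = np.sqrt(np.mean(np.asarray(ex) ** 2 + np.asarray(ey) ** 2) / 2)
        assert rmse <= 1.5 * np.mean(uncs)
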