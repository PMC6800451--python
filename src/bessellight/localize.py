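"""Single-molecule detection, fitting, 3D assignment and reconstruction.

The pipeline mirrors a standard localization-microscopy workflow: a
difference-of-Gaussians band-pass isolates spot-sized features, local maxima
above a threshold become candidates, each candidate is fit with a
pixel-integrated elliptical Gaussian plus constant background by least
squares (analytic Jacobian), the fitted widths are decoded into an axial
position through a width-vs-z astigmatism calibration, and events whose
(sigma_x, sigma_y) pair falls off the calibration curve — sidelobe blobs,
overlapping emitters — are rejected rather than mis-assigned.  Drift is
removed by fiducial tracking or by cross-correlation of time-binned
reconstructions, and tiled acquisitions are merged by offset (optionally
correlation-refined) stitching.

Coordinates are 0-based pixel indices; a localization at the centre of pixel
(i, j) has position ((j + 0.5) px, (i + 0.5) px) in nm.  z = 0 at the
astigmatic crossing, with sigma_x > sigma_y for z > 0.

Localization precision uses the Thompson-style variance

    var = (s^2 + a^2/12) / N  +  8 pi s^4 b^2 / (a^2 N^2)

with s the mean fitted width (nm), a the pixel size, N the fitted photons
and b the fitted background (photons per pixel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

from .blink_sim import AstigmaticPSFModel, CameraModel, FrameStack

__all__ = [
    "LocalizationTable",
    "DefocusCalibration",
    "DriftTrajectory",
    "detect_spots",
    "fit_spot",
    "localize_stack",
    "assign_z_and_filter",
    "drift_correct",
    "render",
    "stitch_tiles",
    "thompson_uncertainty",
]

RECORD_COLUMNS = [
    "frame", "x", "y", "z", "sigma_x", "sigma_y",
    "photons", "background", "uncertainty_xy", "ellipticity", "keep",
]


@dataclass
class LocalizationTable:
    """Ordered localization records plus acquisition metadata.

    ``df`` columns follow :data:`RECORD_COLUMNS`; positions in nm.
    """

    df: pd.DataFrame
    pixel_size: float = 100.0
    stack_id: str = ""
    tile_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        missing = [c for c in ("frame", "x", "y") if c not in self.df.columns]
        if missing:
            raise ValueError(f"localization table lacks columns {missing}")
        if "keep" not in self.df.columns:
            self.df = self.df.assign(keep=True)
        self.df = self.df.sort_values("frame", kind="stable").reset_index(drop=True)

    @property
    def kept(self) -> pd.DataFrame:
        return self.df[self.df["keep"]]

    def __len__(self) -> int:
        return len(self.df)


def thompson_uncertainty(
    s_nm: float | np.ndarray,
    photons: float | np.ndarray,
    pixel_nm: float,
    background: float | np.ndarray,
) -> float | np.ndarray:
    """Lateral localization precision (nm) from photon statistics."""
    s2 = np.asarray(s_nm, float) ** 2
    N = np.asarray(photons, float)
    b = np.asarray(background, float)
    a2 = pixel_nm**2
    var = (s2 + a2 / 12.0) / N + 8.0 * math.pi * s2**2 * b**2 / (a2 * N**2)
    return np.sqrt(var)


def detect_spots(
    frame: np.ndarray,
    band_pass: tuple[float, float] = (1.0, 2.5),
    threshold: float | None = None,
    min_distance: int = 3,
) -> np.ndarray:
    """Candidate spot positions (row, col) from a DoG band-pass + local maxima.

    ``band_pass`` gives the two Gaussian sigmas (px) of the difference
    filter; ``threshold`` is an absolute level on the filtered image
    (default: 3x the robust MAD noise scale of the filtered image).
    Candidates closer than ``min_distance`` px merge into the brighter one.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    lo, hi = band_pass
    filt = ndimage.gaussian_filter(frame, lo) - ndimage.gaussian_filter(frame, hi)
    if threshold is None:
        mad = np.median(np.abs(filt - np.median(filt)))
        threshold = 3.0 * 1.4826 * mad
    if threshold <= 0:
        threshold = 1e-9  # all-flat frame: nothing can exceed a zero floor
    peaks = peak_local_max(
        filt, min_distance=min_distance, threshold_abs=threshold, exclude_border=2
    )
    return peaks


def _spot_model_and_jac(
    params: np.ndarray, xe: np.ndarray, ye: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-integrated elliptical Gaussian and its Jacobian.

    params = (x0, y0, sx, sy, N, b) in pixel units / photons; xe, ye are the
    pixel edge coordinates of the fit window.
    """
    x0, y0, sx, sy, N, b = params
    rt2 = math.sqrt(2.0)
    ax = (xe - x0) / (rt2 * sx)
    ay = (ye - y0) / (rt2 * sy)
    Ex = 0.5 * (special.erf(ax[1:]) - special.erf(ax[:-1]))
    Ey = 0.5 * (special.erf(ay[1:]) - special.erf(ay[:-1]))
    model = b + N * np.outer(Ey, Ex)

    # d erf(a)/dx0 = 2/sqrt(pi) e^{-a^2} * (-1/(rt2 sx)); similarly for sigma
    dEx_dx0 = 0.5 * (2 / math.sqrt(math.pi)) * (
        np.exp(-ax[1:] ** 2) - np.exp(-ax[:-1] ** 2)
    ) * (-1.0 / (rt2 * sx))
    dEy_dy0 = 0.5 * (2 / math.sqrt(math.pi)) * (
        np.exp(-ay[1:] ** 2) - np.exp(-ay[:-1] ** 2)
    ) * (-1.0 / (rt2 * sy))
    dEx_dsx = 0.5 * (2 / math.sqrt(math.pi)) * (
        np.exp(-ax[1:] ** 2) * (-ax[1:]) - np.exp(-ax[:-1] ** 2) * (-ax[:-1])
    ) / sx
    dEy_dsy = 0.5 * (2 / math.sqrt(math.pi)) * (
        np.exp(-ay[1:] ** 2) * (-ay[1:]) - np.exp(-ay[:-1] ** 2) * (-ay[:-1])
    ) / sy

    n_pix = model.size
    J = np.empty((n_pix, 6))
    J[:, 0] = (N * np.outer(Ey, dEx_dx0)).ravel()
    J[:, 1] = (N * np.outer(dEy_dy0, Ex)).ravel()
    J[:, 2] = (N * np.outer(Ey, dEx_dsx)).ravel()
    J[:, 3] = (N * np.outer(dEy_dsy, Ex)).ravel()
    J[:, 4] = np.outer(Ey, Ex).ravel()
    J[:, 5] = 1.0
    return model, J


def fit_spot(
    frame: np.ndarray,
    candidate: tuple[int, int],
    cam: CameraModel,
    model: str = "elliptical",
    window: int = 9,
) -> dict | None:
    """Least-squares fit of one candidate spot; returns a record dict or
    ``None`` when the fit fails to converge or leaves the window.

    The frame is converted to photons with the camera's gain and baseline
    before fitting.  ``model='symmetric'`` constrains sigma_x = sigma_y.
    """
    row, col = int(candidate[0]), int(candidate[1])
    half = window // 2
    h, w = frame.shape
    if not (half <= row < h - half and half <= col < w - half):
        return None
    win = (np.asarray(frame[row - half: row + half + 1,
                            col - half: col + half + 1], float)
           - cam.baseline) * cam.gain
    xe = np.arange(window + 1, dtype=float)
    ye = np.arange(window + 1, dtype=float)
    tot = float(win.sum())
    bg0 = float(np.median(win))
    N0 = max(tot - bg0 * win.size, 10.0)
    p0 = np.array([half + 0.5, half + 0.5, 1.3, 1.3, N0, max(bg0, 0.0)])
    symmetric = model == "symmetric"

    def resid(p: np.ndarray) -> np.ndarray:
        q = p.copy()
        if symmetric:
            q[3] = q[2]
        m, _ = _spot_model_and_jac(q, xe, ye)
        return (m - win).ravel()

    def jac(p: np.ndarray) -> np.ndarray:
        q = p.copy()
        if symmetric:
            q[3] = q[2]
        _, J = _spot_model_and_jac(q, xe, ye)
        if symmetric:
            J[:, 2] = J[:, 2] + J[:, 3]
            J[:, 3] = 0.0
        return J

    lb = [0.0, 0.0, 0.3, 0.3, 1.0, 0.0]
    ub = [window, window, window, window, np.inf, np.inf]
    try:
        sol = optimize.least_squares(
            resid, p0, jac=jac, bounds=(lb, ub), method="trf",
            xtol=1e-10, ftol=1e-10, max_nfev=200,
        )
        if sol.success:
            # variance-weighted refinement: weights 1/sqrt(mu) from the first
            # pass approximate the Poisson maximum-likelihood estimator
            q = sol.x.copy()
            if symmetric:
                q[3] = q[2]
            mu0, _ = _spot_model_and_jac(q, xe, ye)
            wgt = 1.0 / np.sqrt(np.maximum(mu0, 1.0)).ravel()
            sol = optimize.least_squares(
                lambda p: resid(p) * wgt, sol.x,
                jac=lambda p: jac(p) * wgt[:, None],
                bounds=(lb, ub), method="trf",
                xtol=1e-10, ftol=1e-10, max_nfev=200,
            )
    except Exception:
        return None
    if not sol.success:
        return None
    x0, y0, sx, sy, N, b = sol.x
    if symmetric:
        sy = sx
    # reject fits pinned at the window edge or degenerate widths
    if not (0.5 < x0 < window - 0.5 and 0.5 < y0 < window - 0.5):
        return None
    if sx >= window / 2 or sy >= window / 2 or N <= 0:
        return None
    px = cam.pixel_size
    # window-local continuous coordinate -> frame nm (pixel centre convention)
    x_nm = (col - half + x0) * px
    y_nm = (row - half + y0) * px
    s_mean = 0.5 * (sx + sy) * px
    unc = float(thompson_uncertainty(s_mean, N, px, max(b, 1e-6)))
    return {
        "frame": 0,
        "x": x_nm,
        "y": y_nm,
        "z": np.nan,
        "sigma_x": sx * px,
        "sigma_y": sy * px,
        "photons": float(N),
        "background": float(b),
        "uncertainty_xy": unc,
        "ellipticity": float(sx / sy),
        "keep": True,
    }


def localize_stack(
    stack: FrameStack,
    cam: CameraModel | None = None,
    band_pass: tuple[float, float] = (1.0, 2.5),
    threshold: float | None = None,
    window: int = 9,
    model: str = "elliptical",
) -> LocalizationTable:
    """Run detection + fitting over every frame of a stack."""
    if cam is None:
        cam = CameraModel(pixel_size=stack.pixel_size,
                          frame_shape=stack.frames.shape[1:])
    records = []
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        for cand in detect_spots(frame, band_pass, threshold):
            rec = fit_spot(frame, cand, cam, model=model, window=window)
            if rec is not None:
                rec["frame"] = t
                records.append(rec)
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    return LocalizationTable(df, pixel_size=stack.pixel_size)


@dataclass
class DefocusCalibration:
    """Width-vs-z lookup for astigmatic 3D assignment.

    ``z`` is sampled on a uniform grid (default 20 nm step); ``sigma_x`` and
    ``sigma_y`` are the calibration curves (nm).  The width ratio must be
    monotone over the range so the curve is invertible.
    """

    z: np.ndarray
    sigma_x: np.ndarray
    sigma_y: np.ndarray

    def __post_init__(self) -> None:
        ratio = self.sigma_x / self.sigma_y
        d = np.diff(ratio)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("width ratio is not monotone: calibration not invertible")

    @classmethod
    def from_model(
        cls,
        psf: AstigmaticPSFModel,
        z_range: float | None = None,
        step: float | None = None,
    ) -> "DefocusCalibration":
        zr = psf.z_range if z_range is None else z_range
        st = psf.calibration_step if step is None else step
        z = np.arange(-zr, zr + st / 2.0, st)
        return cls(z=z, sigma_x=np.asarray(psf.sigma_x(z)),
                   sigma_y=np.asarray(psf.sigma_y(z)))

    @classmethod
    def from_bead_stack(
        cls, stack: FrameStack, cam: CameraModel | None = None, step: float = 20.0
    ) -> "DefocusCalibration":
        """Fit each plane of a bead z-scan and interpolate the width curves
        onto a uniform z grid of the given step (nm)."""
        z_planes = np.asarray(stack.exposure["z_values"], float)
        if cam is None:
            cam = CameraModel(pixel_size=stack.pixel_size,
                              frame_shape=stack.frames.shape[1:])
        zs, sxs, sys_ = [], [], []
        for t, z in enumerate(z_planes):
            cands = detect_spots(stack.frames[t])
            if len(cands) == 0:
                continue
            rec = fit_spot(stack.frames[t], cands[0], cam)
            if rec is None:
                continue
            zs.append(z)
            sxs.append(rec["sigma_x"])
            sys_.append(rec["sigma_y"])
        if len(zs) < 3:
            raise ValueError("too few usable calibration planes")
        zs = np.asarray(zs)
        grid = np.arange(zs.min(), zs.max() + step / 2.0, step)
        return cls(z=grid,
                   sigma_x=np.interp(grid, zs, np.asarray(sxs)),
                   sigma_y=np.interp(grid, zs, np.asarray(sys_)))


def assign_z_and_filter(
    table: LocalizationTable,
    cal: DefocusCalibration,
    asymmetry_tolerance: float = 0.2,
) -> LocalizationTable:
    """Assign z from the nearest point on the calibration curve; reject
    events lying off the curve.

    The distance of each record's (sigma_x, sigma_y) to the sampled curve is
    minimised on the calibration grid and refined by parabolic interpolation
    between neighbouring samples.  Records whose residual distance exceeds
    ``asymmetry_tolerance`` (relative to the curve's local width magnitude)
    — e.g. sidelobe blobs, symmetric-but-inflated spots — get keep = False,
    as do records outside the calibration range.  Filters only clear keep
    flags; no record is dropped.
    """
    df = table.df.copy()
    cx, cy = cal.sigma_x, cal.sigma_y
    sx = df["sigma_x"].to_numpy(float)
    sy = df["sigma_y"].to_numpy(float)
    d2 = (sx[:, None] - cx[None, :]) ** 2 + (sy[:, None] - cy[None, :]) ** 2
    i_min = np.argmin(d2, axis=1)
    z_out = cal.z[i_min].astype(float)
    d_min = d2[np.arange(len(df)), i_min]
    # parabolic refinement on interior minima
    interior = (i_min > 0) & (i_min < len(cal.z) - 1)
    ii = i_min[interior]
    dm1 = d2[np.nonzero(interior)[0], ii - 1]
    dp1 = d2[np.nonzero(interior)[0], ii + 1]
    d0 = d2[np.nonzero(interior)[0], ii]
    denom = dm1 - 2 * d0 + dp1
    shift = np.where(denom > 0, 0.5 * (dm1 - dp1) / np.maximum(denom, 1e-30), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = cal.z[1] - cal.z[0]
    z_out[interior] = cal.z[ii] + shift * step
    curve_mag = np.hypot(cx[i_min], cy[i_min])
    rel = np.sqrt(d_min) / curve_mag
    on_edge = (i_min == 0) | (i_min == len(cal.z) - 1)
    keep_new = (rel <= asymmetry_tolerance) & ~on_edge
    df["z"] = z_out
    df["keep"] = df["keep"].to_numpy(bool) & keep_new
    out = replace(table)
    out.df = df
    return out


@dataclass
class DriftTrajectory:
    """Per-frame lateral displacement (nm), anchored at (0, 0) for frame 0."""

    frames: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if abs(self.dx[0]) > 1e-9 or abs(self.dy[0]) > 1e-9:
            raise ValueError("trajectory must start at (0, 0)")


def _smooth(v: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return v
    kernel = np.ones(win) / win
    pad = np.pad(v, (win // 2, win - 1 - win // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def drift_correct(
    table: LocalizationTable,
    method: str = "fiducial",
    n_bins: int = 10,
    bin_size: float = 20.0,
    fiducial_radius: float = 500.0,
    min_occupancy: float = 0.5,
    smooth_window: int = 51,
) -> tuple[LocalizationTable, DriftTrajectory]:
    """Estimate and subtract lateral drift.

    ``fiducial``: emitters localized in at least ``min_occupancy`` of all
    frames within ``fiducial_radius`` (nm) are treated as fiducial markers;
    their per-frame displacement from their own mean, averaged over markers
    and smoothed, is the trajectory.  ``xcorr``: frames are split into
    ``n_bins`` time bins, each bin is rendered as a histogram image at
    ``bin_size`` nm, and bins are registered to the first by subpixel
    phase correlation; the per-frame trajectory is linearly interpolated
    between bin centres.
    """
    df = table.df
    n_frames = int(df["frame"].max()) + 1
    frames = np.arange(n_frames)
    if method == "fiducial":
        # candidate markers: occupancy peaks of a coarse 2D histogram, then
        # records within 1.5 radius of each peak centre (robust to drift of
        # up to ~ the radius itself)
        bx = np.arange(df["x"].min(), df["x"].max() + 2 * fiducial_radius,
                       fiducial_radius)
        by = np.arange(df["y"].min(), df["y"].max() + 2 * fiducial_radius,
                       fiducial_radius)
        occ, _, _ = np.histogram2d(df["y"], df["x"], bins=[by, bx])
        peaks = np.argwhere(occ >= min_occupancy * n_frames)
        traj_sum = np.zeros((n_frames, 2))
        traj_cnt = np.zeros(n_frames)
        n_fid = 0
        used = np.zeros(len(df), dtype=bool)
        for iy, ix in peaks:
            cx = bx[ix] + fiducial_radius / 2.0
            cy = by[iy] + fiducial_radius / 2.0
            sel = (np.hypot(df["x"] - cx, df["y"] - cy)
                   < 1.5 * fiducial_radius).to_numpy() & ~used
            g = df[sel]
            if g["frame"].nunique() < min_occupancy * n_frames:
                continue
            used |= sel
            n_fid += 1
            mx, my = g["x"].mean(), g["y"].mean()
            per = g.groupby("frame")[["x", "y"]].mean()
            idx = per.index.to_numpy(int)
            traj_sum[idx, 0] += per["x"].to_numpy() - mx
            traj_sum[idx, 1] += per["y"].to_numpy() - my
            traj_cnt[idx] += 1
        if n_fid == 0:
            raise ValueError("no fiducial markers found (occupancy too low)")
        have = traj_cnt > 0
        dx = np.interp(frames, frames[have], traj_sum[have, 0] / traj_cnt[have])
        dy = np.interp(frames, frames[have], traj_sum[have, 1] / traj_cnt[have])
        dx = _smooth(dx, smooth_window)
        dy = _smooth(dy, smooth_window)
    elif method == "xcorr":
        if n_frames < 2 or n_bins < 2:
            raise ValueError("cross-correlation drift needs >= 2 time bins")
        edges = np.linspace(0, n_frames, n_bins + 1)
        extent = (
            (df["x"].min(), df["x"].max() + bin_size),
            (df["y"].min(), df["y"].max() + bin_size),
        )
        imgs, centers = [], []
        for b in range(n_bins):
            sel = (df["frame"] >= edges[b]) & (df["frame"] < edges[b + 1])
            sub = df[sel]
            if len(sub) == 0:
                continue
            img, _, _ = np.histogram2d(
                sub["y"], sub["x"],
                bins=[
                    np.arange(extent[1][0], extent[1][1] + bin_size, bin_size),
                    np.arange(extent[0][0], extent[0][1] + bin_size, bin_size),
                ],
            )
            imgs.append(img)
            centers.append(0.5 * (edges[b] + edges[b + 1]))
        shifts = [(0.0, 0.0)]
        for img in imgs[1:]:
            sh, _, _ = phase_cross_correlation(imgs[0], img, upsample_factor=20)
            # shift of img relative to reference, (row, col) = (y, x), in bins
            shifts.append((-sh[1] * bin_size, -sh[0] * bin_size))
        shifts = np.asarray(shifts)
        centers = np.asarray(centers)

        def _interp_extrap(t: np.ndarray, tc: np.ndarray, v: np.ndarray) -> np.ndarray:
            out = np.interp(t, tc, v)
            if len(tc) >= 2:  # linear extrapolation beyond the bin centres
                s0 = (v[1] - v[0]) / (tc[1] - tc[0])
                s1 = (v[-1] - v[-2]) / (tc[-1] - tc[-2])
                out[t < tc[0]] = v[0] + s0 * (t[t < tc[0]] - tc[0])
                out[t > tc[-1]] = v[-1] + s1 * (t[t > tc[-1]] - tc[-1])
            return out

        dx = _interp_extrap(frames.astype(float), centers, shifts[:, 0])
        dy = _interp_extrap(frames.astype(float), centers, shifts[:, 1])
    else:
        raise ValueError(f"unknown drift method {method!r}")
    dx = dx - dx[0]
    dy = dy - dy[0]
    out_df = df.copy()
    out_df["x"] = df["x"] - dx[df["frame"].to_numpy(int)]
    out_df["y"] = df["y"] - dy[df["frame"].to_numpy(int)]
    out = replace(table)
    out.df = out_df
    return out, DriftTrajectory(frames=frames, dx=dx, dy=dy, method=method)


def render(
    table: LocalizationTable,
    bin_size: float = 10.0,
    mode: str = "histogram",
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> np.ndarray:
    """Render kept localizations into a 2D super-resolution image.

    ``histogram``: integer counts per bin; the image sum equals the kept
    record count (records outside an explicit ``extent`` excepted).
    ``gaussian``: each record splatted as a unit-integral Gaussian of width
    uncertainty_xy.  ``extent`` = ((x0, x1), (y0, y1)) in nm; default spans
    the data.  Returned array is indexed [y, x].
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    df = table.kept
    if extent is None:
        if len(df) == 0:
            raise ValueError("cannot infer extent from an empty table")
        extent = (
            (float(df["x"].min()), float(df["x"].max()) + bin_size),
            (float(df["y"].min()), float(df["y"].max()) + bin_size),
        )
    (x0, x1), (y0, y1) = extent
    xedges = np.arange(x0, x1 + bin_size / 2.0, bin_size)
    yedges = np.arange(y0, y1 + bin_size / 2.0, bin_size)
    if mode == "histogram":
        img, _, _ = np.histogram2d(df["y"], df["x"], bins=[yedges, xedges])
        return img
    if mode == "gaussian":
        ny, nx = len(yedges) - 1, len(xedges) - 1
        img = np.zeros((ny, nx))
        xs = df["x"].to_numpy(float)
        ys = df["y"].to_numpy(float)
        # fall back to the median precision when a record lacks one
        unc = df["uncertainty_xy"].to_numpy(float) if "uncertainty_xy" in df else None
        if unc is None or np.all(~np.isfinite(unc)):
            unc = np.full(len(df), bin_size)
        unc = np.where(np.isfinite(unc) & (unc > 0), unc, np.nanmedian(unc))
        for x, y, s in zip(xs, ys, unc):
            s_b = max(s / bin_size, 0.3)
            cx = (x - x0) / bin_size
            cy = (y - y0) / bin_size
            r = int(math.ceil(3 * s_b)) + 1
            i0, i1 = int(cy) - r, int(cy) + r + 1
            j0, j1 = int(cx) - r, int(cx) + r + 1
            i0c, i1c = max(i0, 0), min(i1, ny)
            j0c, j1c = max(j0, 0), min(j1, nx)
            if i0c >= i1c or j0c >= j1c:
                continue
            yy = np.arange(i0c, i1c) + 0.5
            xx = np.arange(j0c, j1c) + 0.5
            gy = np.exp(-0.5 * ((yy - cy) / s_b) ** 2)
            gx = np.exp(-0.5 * ((xx - cx) / s_b) ** 2)
            patch = np.outer(gy, gx)
            tot = patch.sum()
            if tot > 0:
                img[i0c:i1c, j0c:j1c] += patch / tot
        return img
    raise ValueError(f"unknown render mode {mode!r}")


def stitch_tiles(
    tables: Sequence[LocalizationTable],
    nominal_offsets: Sequence[tuple[float, float]],
    overlap_registration: bool = False,
    bin_size: float = 50.0,
    merge_radius: float | None = None,
) -> LocalizationTable:
    """Merge sub-volume tiles into one table.

    Each tile's coordinates are shifted by its nominal (x, y) offset (nm);
    with ``overlap_registration`` the offset of every tile after the first
    is refined by phase correlation of the rendered overlap with the running
    mosaic.  Duplicate records — same frame, within ``merge_radius`` (one
    rendering bin by default) — are removed once.
    """
    if len(tables) != len(nominal_offsets):
        raise ValueError("one offset per tile required")
    if merge_radius is None:
        merge_radius = bin_size
    shifted: list[pd.DataFrame] = []
    refined_offsets = [np.asarray(o, float) for o in nominal_offsets]
    for i, (tab, off) in enumerate(zip(tables, refined_offsets)):
        df = tab.df.copy()
        df["x"] = df["x"] + off[0]
        df["y"] = df["y"] + off[1]
        if overlap_registration and i > 0:
            mosaic = pd.concat(shifted, ignore_index=True)
            ox = (max(mosaic["x"].min(), df["x"].min()),
                  min(mosaic["x"].max(), df["x"].max()))
            oy = (max(mosaic["y"].min(), df["y"].min()),
                  min(mosaic["y"].max(), df["y"].max()))
            if ox[0] >= ox[1] or oy[0] >= oy[1]:
                raise ValueError(f"tile {i} shares no overlap for registration")
            ext = ((ox[0], ox[1]), (oy[0], oy[1]))
            ref = render(LocalizationTable(mosaic, pixel_size=tab.pixel_size),
                         bin_size, "histogram", extent=ext)
            mov = render(LocalizationTable(df, pixel_size=tab.pixel_size),
                         bin_size, "histogram", extent=ext)
            sh, _, _ = phase_cross_correlation(ref, mov, upsample_factor=10)
            df["x"] = df["x"] + sh[1] * bin_size
            df["y"] = df["y"] + sh[0] * bin_size
        df["tile"] = i
        shifted.append(df)
    merged = pd.concat(shifted, ignore_index=True)
    # deduplicate: same frame, within merge_radius -> keep the first-seen record
    gx = np.floor(merged["x"] / merge_radius).astype(int)
    gy = np.floor(merged["y"] / merge_radius).astype(int)
    dup_key = pd.DataFrame({"f": merged["frame"].astype(int), "gx": gx, "gy": gy})
    dup = dup_key.duplicated()
    merged = merged[~dup.to_numpy()].drop(columns="tile").reset_index(drop=True)
    return LocalizationTable(merged, pixel_size=tables[0].pixel_size)
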