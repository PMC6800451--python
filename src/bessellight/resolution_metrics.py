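"""Resolution analysis for localization data.

Three complementary resolution notions are computed:

* **Nyquist (labeling-density) resolution** — the structural limit imposed
  by a localization density rho in d dimensions, R_Nyq = 2 / rho^(1/d).
* **Overall theoretical resolution** — Nyquist combined in quadrature with
  the localization-precision FWHM 2.355 sigma:
  R = sqrt(R_Nyq^2 + (2.355 sigma)^2).  Quadrature is the conventional
  combination of two independent blurs; it recovers each ingredient in the
  limit where the other vanishes.
* **Fourier ring correlation (FRC)** — correlation of two half-dataset
  reconstructions on frequency rings; the first sustained drop below 1/7
  defines the cutoff frequency, and resolution = 1 / cutoff.

The density-vs-frames curve, with an optional saturating-exponential fit
D(N) = D_inf (1 - exp(-N / tau)), quantifies the photobleaching plateau; the
frame planner inverts the overall-resolution model to the smallest frame
count that reaches a target resolution under a linear density budget.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DensityCurve",
    "ResolutionEstimate",
    "FRCCurve",
    "density_vs_frames",
    "fit_saturation",
    "nyquist_resolution",
    "overall_resolution",
    "plan_frames",
    "frc_curve",
    "frc_resolution",
]

PRECISION_FWHM_FACTOR = 2.355  # FWHM of a Gaussian of unit sigma
FRC_THRESHOLD = 1.0 / 7.0


@dataclass
class DensityCurve:
    """Cumulative localization density vs frame count.

    ``density`` is localizations per um^2 (d=2) or um^3 (d=3) of the
    structure; non-decreasing by construction.
    """

    frames: np.ndarray
    density: np.ndarray
    structure_area: float
    d_inf: float | None = None
    tau: float | None = None
    fit_rms: float | None = None


@dataclass(frozen=True)
class ResolutionEstimate:
    nyquist: float
    precision_fwhm: float
    overall: float
    d: int


@dataclass
class FRCCurve:
    """FRC values on spatial-frequency rings (1/nm) with the 1/7 cutoff."""

    frequency: np.ndarray
    frc: np.ndarray
    cutoff_frequency: float | None
    resolution: float | None
    ring_counts: np.ndarray | None = None  # pixels per ring (noise-floor scale)


def density_vs_frames(
    df: pd.DataFrame,
    structure_area: float,
    frame_grid: np.ndarray | None = None,
    fit: bool = False,
) -> DensityCurve:
    """Cumulative kept-localization density at each frame count.

    ``df`` needs ``frame`` and (optionally) ``keep`` columns;
    ``structure_area`` in um^2 (or um^3 for volumetric densities).  With
    ``fit=True`` a saturating exponential D_inf (1 - e^(-N/tau)) is fit and
    its parameters and residual RMS attached.
    """
    if structure_area <= 0:
        raise ValueError("structure_area must be positive")
    kept = df[df["keep"]] if "keep" in df.columns else df
    frames = kept["frame"].to_numpy(int)
    if frame_grid is None:
        n_max = int(frames.max()) + 1 if len(frames) else 1
        frame_grid = np.unique(np.linspace(0, n_max, 51).astype(int))
    frame_grid = np.asarray(frame_grid, int)
    counts = np.searchsorted(np.sort(frames), frame_grid, side="left")
    density = counts / structure_area
    curve = DensityCurve(frames=frame_grid, density=density,
                         structure_area=structure_area)
    if fit:
        d_inf, tau, rms = fit_saturation(frame_grid, density)
        curve.d_inf, curve.tau, curve.fit_rms = d_inf, tau, rms
    return curve


def fit_saturation(
    frames: np.ndarray, density: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares fit of D(N) = D_inf (1 - exp(-N / tau)).

    Returns (D_inf, tau, residual RMS).  The fit is unconstrained beyond
    positivity; for genuinely linear data tau diverges and the residual test
    downstream should reject the saturating model.
    """
    frames = np.asarray(frames, float)
    density = np.asarray(density, float)
    d_max = density.max() if density.max() > 0 else 1.0
    p0 = (d_max * 1.2, max(frames.max() / 3.0, 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = optimize.curve_fit(
            lambda n, d_inf, tau: d_inf * (1.0 - np.exp(-n / tau)),
            frames, density, p0=p0,
            bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
    d_inf, tau = popt
    resid = density - d_inf * (1.0 - np.exp(-frames / tau))
    return float(d_inf), float(tau), float(np.sqrt(np.mean(resid**2)))


def nyquist_resolution(density: float, d: int = 2) -> float:
    """Nyquist structural resolution 2 / rho^(1/d), in nm for rho per um^d.

    ``density`` in localizations per um^2 (d=2) or um^3 (d=3); the result is
    converted to nm.  Zero density maps to infinity.
    """
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    if density < 0:
        raise ValueError("density must be non-negative")
    if density == 0:
        return math.inf
    return 2.0 / density ** (1.0 / d) * 1000.0


def overall_resolution(nyquist: float, precision_sigma: float, d: int = 2) -> ResolutionEstimate:
    """Quadrature combination of Nyquist and precision FWHM (both nm)."""
    if nyquist < 0 or precision_sigma < 0:
        raise ValueError("inputs must be non-negative")
    p_fwhm = PRECISION_FWHM_FACTOR * precision_sigma
    overall = math.hypot(nyquist, p_fwhm)
    return ResolutionEstimate(nyquist=nyquist, precision_fwhm=p_fwhm,
                              overall=overall, d=d)


def plan_frames(
    target_resolution: float,
    density_slope_per_frame: float,
    precision_sigma: float,
    d: int = 2,
) -> int:
    """Smallest frame count reaching a target overall resolution.

    Assumes a linear density budget rho(N) = slope * N (per um^d per frame)
    — the no-photobleaching limit.  Raises when the target is below the
    precision floor 2.355 sigma, which no amount of sampling can beat.
    """
    if density_slope_per_frame <= 0:
        raise ValueError("density slope must be positive")
    p_fwhm = PRECISION_FWHM_FACTOR * precision_sigma
    if target_resolution <= p_fwhm:
        raise ValueError(
            f"target {target_resolution} nm is at or below the precision floor "
            f"{p_fwhm:.1f} nm"
        )
    nyq_needed = math.sqrt(target_resolution**2 - p_fwhm**2)  # nm
    rho_needed = (2.0 * 1000.0 / nyq_needed) ** d  # per um^d
    n = max(1, math.ceil(rho_needed / density_slope_per_frame))
    # guard against ceil landing one high through float rounding
    while n > 1 and overall_resolution(
        nyquist_resolution((n - 1) * density_slope_per_frame, d), precision_sigma, d
    ).overall <= target_resolution:
        n -= 1
    return n


def _radial_ring_average(
    f1: np.ndarray, f2: np.ndarray, bin_nm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ny, nx = f1.shape
    fy = np.fft.fftfreq(ny, d=bin_nm)
    fx = np.fft.fftfreq(nx, d=bin_nm)
    fr = np.sqrt(fx[None, :] ** 2 + fy[:, None] ** 2)
    df = 1.0 / (min(nx, ny) * bin_nm)  # one frequency sample per ring
    ring = np.round(fr / df).astype(int)
    n_rings = ring.max() + 1
    num = np.bincount(ring.ravel(), weights=np.real(f1 * np.conj(f2)).ravel(),
                      minlength=n_rings)
    d1 = np.bincount(ring.ravel(), weights=np.abs(f1.ravel()) ** 2, minlength=n_rings)
    d2 = np.bincount(ring.ravel(), weights=np.abs(f2.ravel()) ** 2, minlength=n_rings)
    counts = np.bincount(ring.ravel(), minlength=n_rings)
    freq = np.arange(n_rings) * df
    return freq, num, np.sqrt(d1 * d2), counts


def frc_curve(img1: np.ndarray, img2: np.ndarray, bin_nm: float) -> FRCCurve:
    """FRC between two half-dataset images rendered at ``bin_nm`` nm bins.

    Rings are one frequency sample wide; the curve is smoothed with a 3-ring
    moving average before the threshold crossing is located (linear
    interpolation between rings).  No crossing within the band yields
    ``cutoff_frequency = None`` with a warning.
    """
    if img1.shape != img2.shape:
        raise ValueError("half-images must share a shape")
    F1 = np.fft.fft2(img1)
    F2 = np.fft.fft2(img2)
    freq, num, den, counts = _radial_ring_average(F1, F2, bin_nm)
    valid = (den > 0) & (counts > 0)
    frc = np.zeros_like(num)
    frc[valid] = num[valid] / den[valid]
    # restrict to rings inside the Nyquist disc
    f_max = 1.0 / (2.0 * bin_nm)
    keep = freq <= f_max
    freq, frc, counts = freq[keep], frc[keep], counts[keep]
    smooth = np.convolve(frc, np.ones(3) / 3.0, mode="same")
    smooth[0] = frc[0]  # the zero ring is exact, not averaged
    cutoff = None
    for i in range(1, len(smooth)):
        if smooth[i] < FRC_THRESHOLD:
            f0, f1_ = freq[i - 1], freq[i]
            v0, v1 = smooth[i - 1], smooth[i]
            cutoff = f0 + (v0 - FRC_THRESHOLD) * (f1_ - f0) / (v0 - v1)
            break
    if cutoff is None:
        warnings.warn("FRC never crosses 1/7 in band; resolution unresolved",
                      stacklevel=2)
        resolution = None
    else:
        resolution = 1.0 / cutoff
    return FRCCurve(frequency=freq, frc=frc, cutoff_frequency=cutoff,
                    resolution=resolution, ring_counts=counts)


def frc_resolution(
    df: pd.DataFrame,
    bin_size: float = 10.0,
    split_rule: str = "alternating_frames",
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
    seed: int = 0,
) -> FRCCurve:
    """FRC resolution of a localization table.

    The table is split into two statistically independent halves —
    ``alternating_frames`` (odd/even frame index) or ``random`` (seeded
    per-record coin flip) — and each half rendered as a histogram image on a
    common extent before ring correlation.
    """
    kept = df[df["keep"]] if "keep" in df.columns else df
    if len(kept) < 4:
        raise ValueError("too few localizations for an FRC split")
    if split_rule == "alternating_frames":
        sel = (kept["frame"].to_numpy(int) % 2) == 0
    elif split_rule == "random":
        rng = np.random.default_rng(seed)
        sel = rng.random(len(kept)) < 0.5
    else:
        raise ValueError(f"unknown split rule {split_rule!r}")
    if extent is None:
        extent = (
            (float(kept["x"].min()), float(kept["x"].max()) + bin_size),
            (float(kept["y"].min()), float(kept["y"].max()) + bin_size),
        )
    (x0, x1), (y0, y1) = extent
    xedges = np.arange(x0, x1 + bin_size / 2.0, bin_size)
    yedges = np.arange(y0, y1 + bin_size / 2.0, bin_size)
    h1, _, _ = np.histogram2d(kept["y"][sel], kept["x"][sel], bins=[yedges, xedges])
    h2, _, _ = np.histogram2d(kept["y"][~sel], kept["x"][~sel], bins=[yedges, xedges])
    return frc_curve(h1, h2, bin_size)
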