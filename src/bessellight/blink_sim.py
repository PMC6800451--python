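"""Synthetic spontaneously-blinking single-molecule data.

Forward model for sheet-illuminated localization microscopy with a
spontaneously blinking dye (HMSiR-like): ground-truth structures are
decorated with fluorophores, each fluorophore follows a two-state Markov
chain (dark <-> on) with an absorbing bleached state, excitation — and hence
both photon yield and bleach hazard — is weighted by the lightsheet's
intensity profile at the fluorophore's detection-axis position, and frames
are rendered through an astigmatic elliptical-Gaussian PSF onto a Poisson +
Gaussian-read-noise camera.

The three blinking parameters (p_on, mean_on_frames, p_bleach) are
assumptions: spontaneous-blinking rate constants in clearing media are not
tabulated, and these three reproduce the phenomena the downstream analysis
relies on — a small duty cycle, a linear cumulative-localization curve
without bleaching, and a saturating curve with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .beam_optics import SheetProfile

__all__ = [
    "GroundTruthStructure",
    "BlinkKinetics",
    "CameraModel",
    "AstigmaticPSFModel",
    "FrameStack",
    "generate_structure",
    "simulate_blink_traces",
    "render_frame_stack",
    "generate_calibration_stack",
]


@dataclass
class GroundTruthStructure:
    """Fluorophore positions (nm) with structure labels and a reference area.

    ``points`` is (N, 3) for (x, y, z) in nm; ``labels`` tags the geometric
    primitive each point belongs to; ``structure_area`` (um^2) normalises
    localization densities downstream.
    """

    points: np.ndarray
    labels: np.ndarray
    structure_area: float
    fov: tuple[float, float]  # (x, y) extent in nm
    rng_seed: int

    def __post_init__(self) -> None:
        if self.structure_area <= 0:
            raise ValueError("structure_area must be positive")
        if len(self.points) == 0:
            raise ValueError("structure has no fluorophores")


def generate_structure(kind: str, params: dict, seed: int) -> GroundTruthStructure:
    """Deterministic ground-truth point sets standing in for neurites.

    kinds
    -----
    ``lines``: parallel lines along x. params: n_lines, separation (nm),
        length (nm), density (fluorophores/um), z (nm, default 0).
    ``tubes``: cylinder surfaces along x. params: radius (nm), length (nm),
        n_tubes, separation (nm), density (/um of axis).
    ``shell``: spherical shell. params: radius (nm), n_points, thickness (nm).
    ``grid``: regular lattice. params: pitch (nm), nx, ny.
    """
    rng = np.random.default_rng(seed)
    p = dict(params)
    if kind == "lines":
        n_lines = int(p.get("n_lines", 2))
        sep = float(p.get("separation", 60.0))
        length = float(p.get("length", 5000.0))
        dens = float(p.get("density", 50.0))  # per um
        z0 = float(p.get("z", 0.0))
        n_per = max(1, int(round(dens * length / 1000.0)))
        pts, labels = [], []
        y_off = -(n_lines - 1) * sep / 2.0
        for i in range(n_lines):
            x = rng.uniform(0.0, length, n_per)
            y = np.full(n_per, y_off + i * sep)
            z = np.full(n_per, z0)
            pts.append(np.column_stack([x, y, z]))
            labels.append(np.full(n_per, i))
        points = np.concatenate(pts)
        # reference area: a band of one separation per line pair
        area = (length / 1000.0) * (max(sep * n_lines, 100.0) / 1000.0)
        fov = (length, max(sep * n_lines * 2, 1000.0))
    elif kind == "tubes":
        radius = float(p.get("radius", 100.0))
        length = float(p.get("length", 5000.0))
        n_tubes = int(p.get("n_tubes", 1))
        sep = float(p.get("separation", 500.0))
        dens = float(p.get("density", 100.0))
        n_per = max(1, int(round(dens * length / 1000.0)))
        pts, labels = [], []
        y_off = -(n_tubes - 1) * sep / 2.0
        for i in range(n_tubes):
            x = rng.uniform(0.0, length, n_per)
            phi = rng.uniform(0.0, 2 * math.pi, n_per)
            y = y_off + i * sep + radius * np.cos(phi)
            z = radius * np.sin(phi)
            pts.append(np.column_stack([x, y, z]))
            labels.append(np.full(n_per, i))
        points = np.concatenate(pts)
        area = (length / 1000.0) * (2 * radius * n_tubes / 1000.0)
        fov = (length, (sep * n_tubes + 2 * radius) * 2)
    elif kind == "shell":
        radius = float(p.get("radius", 2000.0))
        n_points = int(p.get("n_points", 1000))
        thick = float(p.get("thickness", 0.0))
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = radius + rng.uniform(-thick / 2.0, thick / 2.0, n_points)[:, None]
        points = v * r
        labels = np.zeros(n_points, dtype=int)
        area = 4 * math.pi * (radius / 1000.0) ** 2
        fov = (4 * radius, 4 * radius)
        return GroundTruthStructure(points, labels, area, fov, seed)
    elif kind == "grid":
        pitch = float(p.get("pitch", 500.0))
        nx = int(p.get("nx", 5))
        ny = int(p.get("ny", 5))
        xv, yv = np.meshgrid(np.arange(nx) * pitch, np.arange(ny) * pitch)
        points = np.column_stack([xv.ravel(), yv.ravel(), np.zeros(nx * ny)])
        labels = np.arange(nx * ny)
        area = (nx * pitch / 1000.0) * (ny * pitch / 1000.0)
        fov = (nx * pitch, ny * pitch)
        return GroundTruthStructure(points, labels, area, fov, seed)
    else:
        raise ValueError(f"unknown structure kind {kind!r}")
    return GroundTruthStructure(points, np.concatenate(labels), area, fov, seed)


@dataclass(frozen=True)
class BlinkKinetics:
    """Per-frame blinking parameters of a spontaneously blinking dye.

    p_on: probability a dark fluorophore switches on in one frame (at unit
    sheet weight); mean_on_frames: expected on-state duration in frames;
    photons_per_on_frame: mean detected photons at unit sheet weight;
    p_bleach: per-on-frame irreversible bleach probability (also scaled by
    the sheet weight).  Defaults are documented assumptions, not measured
    rate constants.
    """

    p_on: float = 1e-3
    mean_on_frames: float = 2.0
    photons_per_on_frame: float = 1000.0
    p_bleach: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.p_on <= 1 and 0 <= self.p_bleach <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_on_frames < 1:
            raise ValueError("mean_on_frames must be >= 1")
        if self.photons_per_on_frame <= 0:
            raise ValueError("photons_per_on_frame must be positive")

    @property
    def duty_cycle(self) -> float:
        x = self.p_on * self.mean_on_frames
        return x / (1.0 + x)


@dataclass(frozen=True)
class CameraModel:
    """sCMOS-like detection: object-space pixel pitch (nm), read noise (e- RMS),
    baseline offset (counts), gain (e- per count)."""

    pixel_size: float = 100.0
    read_noise: float = 1.6
    baseline: float = 100.0
    gain: float = 1.0
    frame_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.gain <= 0:
            raise ValueError("pixel_size and gain must be positive")


@dataclass(frozen=True)
class AstigmaticPSFModel:
    """Elliptical-Gaussian PSF with cylindrical-lens astigmatism.

    sigma_x(z) = sigma0 sqrt(1 + ((z + gamma)/d)^2),
    sigma_y(z) = sigma0 sqrt(1 + ((z - gamma)/d)^2)      (all nm),

    so the two width curves cross exactly once at z* = 0 and sigma_x >
    sigma_y for z > 0.  ``gamma`` is the focal-plane offset of each
    astigmatic axis, ``d`` the defocus depth scale, ``z_range`` the validity
    half-range, ``calibration_step`` the z sampling of the width lookup.
    """

    sigma0: float = 150.0
    gamma: float = 250.0
    d: float = 400.0
    z_range: float = 400.0  # keep below sqrt(gamma^2 + d^2), where the
    # width ratio turns over and the curve stops being invertible
    calibration_step: float = 20.0

    def sigma_x(self, z: np.ndarray | float) -> np.ndarray | float:
        return self.sigma0 * np.sqrt(1.0 + ((np.asarray(z, float) + self.gamma) / self.d) ** 2)

    def sigma_y(self, z: np.ndarray | float) -> np.ndarray | float:
        return self.sigma0 * np.sqrt(1.0 + ((np.asarray(z, float) - self.gamma) / self.d) ** 2)

    @property
    def crossing_z(self) -> float:
        return 0.0


@dataclass
class FrameStack:
    """T x H x W camera frames (counts) plus pixel size and ground truth.

    ``sidecar`` is the per-frame emitter table used to render the stack
    (frame, emitter id, x, y, z in nm, expected photons, clipped flag).
    """

    frames: np.ndarray
    pixel_size: float
    exposure: dict = field(default_factory=dict)
    sidecar: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if np.any(self.frames < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def simulate_blink_traces(
    structure: GroundTruthStructure,
    kinetics: BlinkKinetics,
    sheet: SheetProfile | None,
    n_frames: int,
    seed: int,
) -> pd.DataFrame:
    """Per-frame emitter lists from the two-state (+bleach) Markov model.

    Each fluorophore starts dark.  Per frame, a dark fluorophore switches on
    with probability p_on * w (w = sheet weight at its z, in [0, 1]); an on
    fluorophore emits Poisson-mean photons_per_on_frame * w, bleaches with
    probability p_bleach * w, otherwise returns to dark with probability
    1/mean_on_frames.  Sheet confinement therefore suppresses both
    activations and premature bleaching away from the focal plane.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(structure.points)
    z_um = structure.points[:, 2] / 1000.0
    if sheet is None:
        w = np.ones(n)
    else:
        w = np.asarray(sheet.weight(z_um), dtype=float)
    state = np.zeros(n, dtype=np.int8)  # 0 dark, 1 on, 2 bleached
    p_off = 1.0 / kinetics.mean_on_frames
    rows: list[np.ndarray] = []
    for t in range(n_frames):
        dark = state == 0
        turn_on = dark & (rng.random(n) < kinetics.p_on * w)
        state[turn_on] = 1
        on = np.nonzero(state == 1)[0]
        if on.size:
            photons = kinetics.photons_per_on_frame * w[on]
            rec = np.empty((on.size, 6))
            rec[:, 0] = t
            rec[:, 1] = on
            rec[:, 2:5] = structure.points[on]
            rec[:, 5] = photons
            rows.append(rec)
            u = rng.random(on.size)
            bleach = u < kinetics.p_bleach * w[on]
            go_dark = (~bleach) & (u < kinetics.p_bleach * w[on] + p_off)
            state[on[bleach]] = 2
            state[on[go_dark]] = 0
    if rows:
        data = np.concatenate(rows)
    else:
        data = np.empty((0, 6))
    return pd.DataFrame(
        data, columns=["frame", "emitter", "x", "y", "z", "photons"]
    ).astype({"frame": int, "emitter": int})


def _pixel_integrated_spot(
    shape: tuple[int, int],
    x_px: float,
    y_px: float,
    sx_px: float,
    sy_px: float,
    photons: float,
) -> np.ndarray:
    """Elliptical Gaussian integrated over pixels (erf model), photons units.

    Coordinates follow the package convention: continuous position u maps to
    pixel index u - 0.5, i.e. pixel (i, j) spans [j, j+1) x [i, i+1) in units
    of the pixel pitch with its centre at (j+0.5, i+0.5).
    """
    h, wdt = shape
    xe = np.arange(wdt + 1)
    ye = np.arange(h + 1)
    cx = 0.5 * (
        special.erf((xe[1:] - x_px) / (math.sqrt(2) * sx_px))
        - special.erf((xe[:-1] - x_px) / (math.sqrt(2) * sx_px))
    )
    cy = 0.5 * (
        special.erf((ye[1:] - y_px) / (math.sqrt(2) * sy_px))
        - special.erf((ye[:-1] - y_px) / (math.sqrt(2) * sy_px))
    )
    return photons * np.outer(cy, cx)


def render_frame_stack(
    emitters: pd.DataFrame,
    psf: AstigmaticPSFModel,
    cam: CameraModel,
    seed: int,
    n_frames: int | None = None,
    noise: bool = True,
) -> FrameStack:
    """Render per-frame emitter lists into a camera frame stack.

    Each emitter becomes an elliptical Gaussian with widths sigma_x(z),
    sigma_y(z), pixel-integrated, with integral = photons.  With
    ``noise=True``: Poisson shot noise on the signal electrons, Gaussian read
    noise, then gain and baseline.  Emitters falling off-frame are clipped
    and flagged in the sidecar.
    """
    rng = np.random.default_rng(seed)
    h, wdt = cam.frame_shape
    if n_frames is None:
        n_frames = int(emitters["frame"].max()) + 1 if len(emitters) else 1
    signal = np.zeros((n_frames, h, wdt))
    clipped = np.zeros(len(emitters), dtype=bool)
    px = cam.pixel_size
    for i, row in enumerate(emitters.itertuples(index=False)):
        t = int(row.frame)
        if t >= n_frames:
            clipped[i] = True
            continue
        x_px = row.x / px
        y_px = row.y / px
        if not (0 <= x_px < wdt and 0 <= y_px < h):
            clipped[i] = True
            continue
        sx = float(psf.sigma_x(row.z)) / px
        sy = float(psf.sigma_y(row.z)) / px
        signal[t] += _pixel_integrated_spot((h, wdt), x_px, y_px, sx, sy, row.photons)
    if noise:
        electrons = rng.poisson(signal).astype(float)
        electrons += rng.normal(0.0, cam.read_noise, size=electrons.shape)
        frames = np.maximum(electrons / cam.gain + cam.baseline, 0.0)
    else:
        frames = signal / cam.gain + cam.baseline
    sidecar = emitters.copy()
    sidecar["clipped"] = clipped
    return FrameStack(
        frames=frames,
        pixel_size=px,
        exposure={"seed": seed, "noise": noise},
        sidecar=sidecar,
    )


def generate_calibration_stack(
    psf: AstigmaticPSFModel,
    cam: CameraModel,
    z_range: tuple[float, float] = (-5000.0, 5000.0),
    z_step: float = 100.0,
    photons: float = 20000.0,
    noise: bool = False,
    seed: int = 0,
) -> FrameStack:
    """Bead z-scan for defocus calibration: one bright bead per plane.

    ``z_range`` in nm; plane count = range / step + 1 (a 10 um scan at
    100 nm steps gives 101 planes).  The bead sits at the frame centre;
    plane k is at z = z_range[0] + k * z_step.
    """
    z0, z1 = z_range
    if z_step <= 0 or z_step > (z1 - z0):
        raise ValueError("z_step must be positive and no larger than the range")
    z_values = np.arange(z0, z1 + z_step / 2.0, z_step)
    h, wdt = cam.frame_shape
    x_nm = (wdt / 2.0) * cam.pixel_size
    y_nm = (h / 2.0) * cam.pixel_size
    emitters = pd.DataFrame(
        {
            "frame": np.arange(len(z_values)),
            "emitter": 0,
            "x": x_nm,
            "y": y_nm,
            "z": z_values,
            "photons": photons,
        }
    )
    stack = render_frame_stack(emitters, psf, cam, seed=seed, noise=noise)
    stack.exposure["z_values"] = z_values
    return stack
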