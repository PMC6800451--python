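"""Fourier-optics simulation of the axicon-generated Bessel lightsheet.

The excitation path modelled here: a collimated Gaussian beam passes a
lens-axicon doublet, which adds the phase

    Phi(r) = -k0 [ r^2 / (2 F) + (n_axicon - 1) * alpha * r ],   r = sqrt(x^2+z^2)

and focuses into a bright ring of radius R0 = alpha (n_axicon - 1) q at the
image distance q given by the lens law 1/F = 1/R_F + 1/q.  The ring is
spatially filtered by an annular mask (expressed as an NA band), relayed to
the back pupil of the excitation objective, and interferes into a Bessel
beam whose axial extent is set by the annulus width:  for a thin annulus the
on-axis intensity follows sinc^2 with

    FWHM_axial ~= 1.772 * n * lambda0 / (NA_outer^2 - NA_inner^2).

Scanning the beam along x time-averages it into a virtual lightsheet.

Conventions: y is the illumination propagation axis, z the detection axis,
x the sheet-scan axis.  All lengths are micrometres internally; configuration
objects accept millimetres where noted.  NA includes the medium index
(NA = n sin(theta)); the pupil-radius <-> NA map is linear (sine condition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SamplingError",
    "OpticalConfig",
    "GaussianBeamSpec",
    "FieldGrid",
    "Annulus",
    "BeamProfile3D",
    "SheetProfile",
    "PowerDensityReport",
    "fwhm_to_waist",
    "waist_to_fwhm",
    "make_gaussian_field",
    "apply_axicon_lens_phase",
    "propagate",
    "image_distance_and_ring",
    "apply_annular_mask",
    "focus_annulus_to_bessel",
    "sweep_sheet",
    "power_density",
    "interp_fwhm",
    "gaussian_sheet",
]

_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


class SamplingError(ValueError):
    """A grid is too coarse to represent a phase or transfer function."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical-path parameters of the excitation arm.

    Parameters
    ----------
    lambda0 : vacuum wavelength (um); default 0.637 (red excitation line).
    n_medium : immersion refractive index (1.33 water, 1.38 clearing agent).
    n_axicon : axicon glass refractive index.
    alpha : axicon deflection angle (rad).
    F : focal length of the axicon's companion lens (mm).
    magnification : transverse relay magnification between mask and pupil.
    excitation_NA_max : numerical-aperture bound of the excitation objective.
    """

    lambda0: float = 0.637
    n_medium: float = 1.33
    n_axicon: float = 1.46
    alpha: float = 0.0175
    F: float = 200.0
    magnification: float = 1.6
    excitation_NA_max: float = 0.66

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.n_medium < 1.0:
            raise ValueError("n_medium must be >= 1")
        if not 0 <= self.alpha < math.pi / 2:
            raise ValueError("alpha must lie in [0, pi/2)")
        if self.F <= 0:
            raise ValueError("F must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    @property
    def k0(self) -> float:
        """Vacuum propagation constant, rad/um."""
        return 2.0 * math.pi / self.lambda0


@dataclass(frozen=True)
class GaussianBeamSpec:
    """Input Gaussian beam: 1/e^2 field radius ``w`` (mm) and wavefront
    curvature ``R_F`` (mm; ``inf`` for collimated)."""

    w: float
    R_F: float = math.inf

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("beam waist w must be positive")

    @property
    def FWHM_G(self) -> float:
        """Intensity FWHM, FWHM_G = sqrt(2 ln 2) * w."""
        return waist_to_fwhm(self.w)

    @classmethod
    def from_fwhm(cls, FWHM_G: float, R_F: float = math.inf) -> "GaussianBeamSpec":
        return cls(w=fwhm_to_waist(FWHM_G), R_F=R_F)


def fwhm_to_waist(FWHM_G: float) -> float:
    """Convert intensity FWHM to the 1/e^2 field radius: w = FWHM / sqrt(2 ln 2)."""
    if FWHM_G <= 0:
        raise ValueError("FWHM must be positive")
    return FWHM_G / _SQRT_2LN2


def waist_to_fwhm(w: float) -> float:
    """Inverse of :func:`fwhm_to_waist`."""
    if w <= 0:
        raise ValueError("waist must be positive")
    return w * _SQRT_2LN2


@dataclass
class FieldGrid:
    """Sampled complex optical amplitude on a transverse (x, z) plane.

    ``amplitude`` is indexed ``[z, x]``; ``dx``/``dz`` are sample spacings in
    micrometres; ``y`` is the axial position of the plane; the in-medium
    wavelength is ``lambda0 / n_medium``.
    """

    amplitude: np.ndarray
    dx: float
    dz: float
    lambda0: float
    n_medium: float = 1.0
    y: float = 0.0

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if self.amplitude.ndim != 2 or min(self.amplitude.shape) < 2:
            raise ValueError("amplitude must be 2-D with >= 2 samples per axis")
        if self.dx <= 0 or self.dz <= 0:
            raise ValueError("sample spacings must be positive")
        if not np.isfinite(self.energy()) or self.energy() < 0:
            raise ValueError("field energy must be finite and non-negative")

    @property
    def wavelength_in_medium(self) -> float:
        return self.lambda0 / self.n_medium

    @property
    def x(self) -> np.ndarray:
        n = self.amplitude.shape[1]
        return (np.arange(n) - n // 2) * self.dx

    @property
    def z(self) -> np.ndarray:
        n = self.amplitude.shape[0]
        return (np.arange(n) - n // 2) * self.dz

    def radius(self) -> np.ndarray:
        """Radial coordinate sqrt(x^2 + z^2) on the grid, um."""
        return np.hypot(self.x[None, :], self.z[:, None])

    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    def energy(self) -> float:
        """Total energy sum(|E|^2) dx dz."""
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.dx * self.dz)


@dataclass(frozen=True)
class Annulus:
    """NA band [NA_inner, NA_outer] transmitted by an annular pupil mask."""

    NA_inner: float
    NA_outer: float

    def __post_init__(self) -> None:
        if not 0 <= self.NA_inner < self.NA_outer:
            raise ValueError("require 0 <= NA_inner < NA_outer")

    @property
    def NA_mean(self) -> float:
        return 0.5 * (self.NA_inner + self.NA_outer)

    def area(self) -> float:
        """Annulus area in NA^2 units, pi (NA_out^2 - NA_in^2)."""
        return math.pi * (self.NA_outer**2 - self.NA_inner**2)


def make_gaussian_field(
    spec: GaussianBeamSpec,
    cfg: OpticalConfig,
    grid_shape: tuple[int, int] = (1024, 1024),
    extent: float | None = None,
) -> FieldGrid:
    """Sample the input Gaussian beam E = exp[(i k0 / 2R_F - 1/w^2) r^2].

    ``spec`` is in mm; the returned grid is in um.  ``extent`` (mm) is the
    full width of the square grid; it must be at least 4 w so the Gaussian
    tails are represented (default 6 w).
    """
    w_um = spec.w * 1000.0
    extent_um = (extent * 1000.0) if extent is not None else 6.0 * w_um
    if extent_um < 4.0 * w_um:
        raise SamplingError(
            f"grid extent {extent_um:.0f} um < 4 w = {4 * w_um:.0f} um; "
            "the Gaussian tails would be truncated"
        )
    nz, nx = grid_shape
    dz = extent_um / nz
    dx = extent_um / nx
    x = (np.arange(nx) - nx // 2) * dx
    z = (np.arange(nz) - nz // 2) * dz
    r2 = x[None, :] ** 2 + z[:, None] ** 2
    coeff = -1.0 / w_um**2
    if math.isfinite(spec.R_F):
        coeff = coeff + 1j * cfg.k0 / (2.0 * spec.R_F * 1000.0)
    amp = np.exp(coeff * r2)
    return FieldGrid(amp, dx=dx, dz=dz, lambda0=cfg.lambda0, n_medium=1.0)


def apply_axicon_lens_phase(fieldg: FieldGrid, cfg: OpticalConfig) -> FieldGrid:
    """Add the lens-axicon phase Phi = -k0 [r^2/2F + (n-1) alpha r].

    The amplitude modulus is untouched.  Raises :class:`SamplingError` when
    the phase changes by more than pi between adjacent samples anywhere the
    field carries energy (aliasing would silently corrupt the propagation).
    """
    k0 = cfg.k0
    F_um = cfg.F * 1000.0
    cone = (cfg.n_axicon - 1.0) * cfg.alpha
    r = fieldg.radius()
    # worst-case radial phase slope within the energy-bearing support
    inten = fieldg.intensity()
    support = inten > 1e-12 * inten.max()
    r_max = float(r[support].max()) if support.any() else 0.0
    slope = k0 * (r_max / F_um + cone)
    step = max(fieldg.dx, fieldg.dz)
    if slope * step >= math.pi:
        raise SamplingError(
            f"axicon-lens phase slope {slope:.3g} rad/um aliases at spacing "
            f"{step:.3g} um; refine the grid (need < {math.pi / slope:.3g} um)"
        )
    phi = -k0 * (r**2 / (2.0 * F_um) + cone * r)
    out = replace(fieldg)
    out.amplitude = fieldg.amplitude * np.exp(1j * phi)
    return out


def _transfer_function(
    shape: tuple[int, int], dx: float, dz: float, lambda0: float, n: float,
    distance: float, method: str,
) -> np.ndarray:
    fz = np.fft.fftfreq(shape[0], d=dz)
    fx = np.fft.fftfreq(shape[1], d=dx)
    f2 = fx[None, :] ** 2 + fz[:, None] ** 2
    k_med = n / lambda0  # spatial frequency of the carrier, 1/um
    if method == "angular_spectrum":
        arg = k_med**2 - f2
        kz = np.sqrt(np.maximum(arg, 0.0))
        H = np.exp(2j * math.pi * distance * kz)
        H[arg < 0] = 0.0  # evanescent components dropped (never amplified)
        return H
    if method == "fresnel":
        return np.exp(2j * math.pi * distance * k_med) * np.exp(
            -1j * math.pi * lambda0 * distance * f2 / n
        )
    raise ValueError(f"unknown propagation method {method!r}")


def propagate(
    fieldg: FieldGrid,
    distance: float,
    n: float | None = None,
    method: str = "angular_spectrum",
) -> FieldGrid:
    """Free-space propagate the field by ``distance`` (um; may be negative).

    Angular-spectrum transfer function by default; ``method='fresnel'``
    selects the paraxial approximation.  Energy is conserved (Parseval) for
    non-evanescent fields.
    """
    if distance == 0:
        return replace(fieldg)
    n_prop = fieldg.n_medium if n is None else n
    spec = np.fft.fft2(fieldg.amplitude)
    # wraparound guard: the sampled transfer function computes a cyclic
    # convolution, so energy walking further than the grid period corrupts
    # the result.  Band edge taken where the spectrum holds > 1e-4 of peak
    # power (weaker tails wrap with negligible energy).
    power = np.abs(spec) ** 2
    occupied = power > 1e-4 * power.max()
    fz = np.fft.fftfreq(fieldg.amplitude.shape[0], d=fieldg.dz)
    fx = np.fft.fftfreq(fieldg.amplitude.shape[1], d=fieldg.dx)
    fr = np.sqrt(fx[None, :] ** 2 + fz[:, None] ** 2)
    f_occ = float(fr[occupied].max())
    k_med = n_prop / fieldg.lambda0
    if 0 < f_occ < k_med:
        walk = abs(distance) * f_occ / math.sqrt(k_med**2 - f_occ**2)
        extent = min(fieldg.dx * fieldg.amplitude.shape[1],
                     fieldg.dz * fieldg.amplitude.shape[0])
        if walk >= extent:
            raise SamplingError(
                f"propagated energy walks {walk:.3g} um, beyond the grid "
                f"period {extent:.3g} um; enlarge the grid extent"
            )
    H = _transfer_function(
        fieldg.amplitude.shape, fieldg.dx, fieldg.dz, fieldg.lambda0, n_prop,
        distance, method,
    )
    out = replace(fieldg)
    out.amplitude = np.fft.ifft2(spec * H)
    out.y = fieldg.y + distance
    return out


def image_distance_and_ring(
    cfg: OpticalConfig, R_F: float = math.inf
) -> tuple[float, float]:
    """Lens-law image distance and ring radius of the axicon doublet.

    1/F = 1/R_F + 1/q gives q; the focused ring has radius
    R0 = alpha (n_axicon - 1) q.  Both returned in mm (``R_F`` in mm).
    """
    if math.isinf(R_F):
        q = cfg.F
    else:
        inv = 1.0 / cfg.F - 1.0 / R_F
        if inv == 0:
            raise ZeroDivisionError("R_F equals F: image distance diverges")
        q = 1.0 / inv
    R0 = cfg.alpha * (cfg.n_axicon - 1.0) * q
    return q, R0


def apply_annular_mask(
    fieldg: FieldGrid,
    mask: Annulus,
    pupil_mapping: Callable[[np.ndarray], np.ndarray] | float,
) -> tuple[FieldGrid, float]:
    """Zero the field outside the NA band of an annular mask.

    ``pupil_mapping`` converts grid radius (um) to NA — either a callable or
    a scalar NA-per-um factor.  Returns the masked field and the transmitted
    energy fraction.
    """
    r = fieldg.radius()
    na = pupil_mapping(r) if callable(pupil_mapping) else pupil_mapping * r
    keep = (na >= mask.NA_inner) & (na <= mask.NA_outer)
    e_in = fieldg.energy()
    if e_in == 0:
        raise ValueError("cannot mask a zero-energy field")
    out = replace(fieldg)
    out.amplitude = np.where(keep, fieldg.amplitude, 0.0)
    frac = out.energy() / e_in
    if frac == 0.0:
        raise ValueError("annular mask transmits no energy on this grid")
    return out, frac


def interp_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM of a sampled peak by linear interpolation of the half-max crossings.

    The peak is taken on the sampled grid (no sub-sample refinement).  Raises
    if either half-maximum crossing lies outside the sampled range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i_pk = int(np.argmax(y))
    half = y[i_pk] / 2.0

    def _cross(idx_range: np.ndarray) -> float:
        for i in idx_range:
            if y[i] < half:
                j = i + 1 if i < i_pk else i - 1  # neighbour toward the peak
                x0, x1, y0, y1 = x[i], x[j], y[i], y[j]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
        raise ValueError("half-maximum crossing not contained in the sampled range")

    left = _cross(np.arange(i_pk - 1, -1, -1))
    right = _cross(np.arange(i_pk + 1, len(y)))
    return abs(right - left)


@dataclass
class BeamProfile3D:
    """Bessel-beam focal region: on-axis intensity vs y plus the focal plane.

    The full I(x, z; y) cube is not materialised; planes at arbitrary y come
    from :meth:`plane`.  ``axial_fwhm`` is the FWHM of the on-axis intensity
    along y; ``lateral_fwhm`` the FWHM of the central lobe in z at focus.
    """

    y: np.ndarray
    on_axis: np.ndarray
    axial_fwhm: float
    lateral_fwhm: float
    focal_plane: FieldGrid
    _pupil: np.ndarray = field(repr=False, default=None)
    _kz: np.ndarray = field(repr=False, default=None)

    @property
    def y_peak(self) -> float:
        return float(self.y[int(np.argmax(self.on_axis))])

    def plane(self, y: float) -> FieldGrid:
        """Transverse field at propagation position ``y`` (um)."""
        amp = np.fft.ifft2(self._pupil * np.exp(1j * self._kz * y))
        out = replace(self.focal_plane)
        out.amplitude = np.fft.fftshift(amp)
        out.y = y
        return out


def focus_annulus_to_bessel(
    pupil: FieldGrid | Annulus,
    cfg: OpticalConfig,
    y_range: Sequence[float] | np.ndarray,
    grid_shape: tuple[int, int] = (1024, 1024),
    oversample: float = 2.0,
    na_per_um: float | None = None,
) -> BeamProfile3D:
    """Focus an annular pupil into a Bessel beam and profile it along y.

    The pupil is the angular spectrum of the focal field under the sine
    condition: a pupil point at NA maps to transverse spatial frequency
    NA / lambda0.  An :class:`Annulus` builds a uniform (top-hat) band; a
    :class:`FieldGrid` is reinterpreted on the frequency grid via the linear
    map NA = ``na_per_um`` * r.  Each y-plane is the inverse FFT of the pupil
    times the angular-spectrum defocus factor exp(i kz y) with
    kz = 2 pi sqrt((n/lambda0)^2 - f^2).

    ``y_range`` must straddle the on-axis peak; otherwise the axial FWHM is
    undefined and an error is raised.
    """
    lam = cfg.lambda0
    n = cfg.n_medium
    y = np.asarray(y_range, dtype=float)
    if y.size < 3:
        raise ValueError("y_range needs at least 3 samples")

    if isinstance(pupil, Annulus):
        if pupil.NA_outer > cfg.excitation_NA_max + 1e-12:
            raise ValueError(
                f"annulus NA_outer {pupil.NA_outer} exceeds the objective bound "
                f"{cfg.excitation_NA_max}"
            )
        nz, nx = grid_shape
        dx = lam / (2.0 * pupil.NA_outer * oversample)
        dz = dx
        fz = np.fft.fftfreq(nz, d=dz)
        fx = np.fft.fftfreq(nx, d=dx)
        fr = np.sqrt(fx[None, :] ** 2 + fz[:, None] ** 2)
        na_grid = lam * fr
        pupil_arr = ((na_grid >= pupil.NA_inner) & (na_grid <= pupil.NA_outer)).astype(
            complex
        )
        if not pupil_arr.any():
            raise ValueError("annulus falls between frequency samples; enlarge grid")
    else:
        if na_per_um is None:
            raise ValueError("na_per_um is required when pupil is a FieldGrid")
        # reinterpret the (centered) pupil samples as frequency samples:
        # sample at radius r carries frequency na_per_um * r / lambda
        nz, nx = pupil.amplitude.shape
        df = na_per_um * pupil.dx / lam
        dfz = na_per_um * pupil.dz / lam
        dx = 1.0 / (nx * df)
        dz = 1.0 / (nz * dfz)
        pupil_arr = np.fft.ifftshift(pupil.amplitude)
        fz = np.fft.fftfreq(nz, d=dz)
        fx = np.fft.fftfreq(nx, d=dx)
        fr = np.sqrt(fx[None, :] ** 2 + fz[:, None] ** 2)

    k_med = n / lam
    arg = k_med**2 - fr**2
    propagating = arg > 0
    pupil_arr = np.where(propagating, pupil_arr, 0.0)
    kz = 2.0 * math.pi * np.sqrt(np.maximum(arg, 0.0))

    # on-axis amplitude: the zero-frequency Fourier sum of the defocused pupil
    nzidx = np.nonzero(pupil_arr)
    vals = pupil_arr[nzidx]
    kz_vals = kz[nzidx]
    on_axis_amp = np.empty(len(y), dtype=complex)
    for i0 in range(0, len(y), 32):  # chunked to bound the phase-matrix size
        blk = y[i0:i0 + 32]
        on_axis_amp[i0:i0 + 32] = np.exp(1j * np.outer(blk, kz_vals)) @ vals
    on_axis = np.abs(on_axis_amp) ** 2
    peak = float(on_axis.max())
    if peak <= 0:
        raise ValueError("no on-axis intensity in the requested y range")
    if isinstance(pupil, Annulus):
        # a uniform real pupil attains its aligned-phasor bound exactly at
        # focus; a window peaking well below it only saw sidelobes
        bound = float(np.abs(vals).sum()) ** 2
        if peak < 0.5 * bound:
            raise ValueError(
                "y_range does not contain the focal peak (half-maximum not "
                "reached in window); extend it"
            )
    on_axis = on_axis / peak

    i_pk = int(np.argmax(on_axis))
    if i_pk in (0, len(y) - 1):
        raise ValueError("y_range does not contain the focal peak; extend it")
    axial_fwhm = interp_fwhm(y, on_axis)

    focal_amp = np.fft.fftshift(np.fft.ifft2(pupil_arr * np.exp(1j * kz * y[i_pk])))
    focal = FieldGrid(focal_amp, dx=dx, dz=dz, lambda0=lam, n_medium=n, y=y[i_pk])
    inten = focal.intensity()
    zi, xi = np.unravel_index(int(np.argmax(inten)), inten.shape)
    lateral_fwhm = interp_fwhm(focal.z, inten[:, xi])

    return BeamProfile3D(
        y=y,
        on_axis=on_axis,
        axial_fwhm=axial_fwhm,
        lateral_fwhm=lateral_fwhm,
        focal_plane=focal,
        _pupil=pupil_arr,
        _kz=kz,
    )


@dataclass
class SheetProfile:
    """Scan-averaged virtual lightsheet along the detection axis z.

    ``z`` and ``z_profile`` sample the x-averaged focal-plane intensity;
    ``thickness_fwhm`` is the FWHM of that profile (um); ``coverage_area`` is
    the product axial length x scan range (um^2).
    """

    z: np.ndarray
    z_profile: np.ndarray
    thickness_fwhm: float
    coverage_area: float

    def weight(self, z_um: np.ndarray | float) -> np.ndarray | float:
        """Relative excitation weight at detection-axis position z (um),
        normalised to 1 at the sheet peak; 0 outside the sampled range."""
        prof = self.z_profile / self.z_profile.max()
        return np.interp(z_um, self.z, prof, left=0.0, right=0.0)


def sweep_sheet(profile: BeamProfile3D, scan_range: float) -> SheetProfile:
    """Average the focal plane along the scan axis x into a sheet profile.

    ``coverage_area`` = axial FWHM of the beam x ``scan_range`` (um^2), the
    area the swept beam illuminates.
    """
    if scan_range <= 0:
        raise ValueError("scan_range must be positive")
    inten = profile.focal_plane.intensity()
    z_profile = inten.mean(axis=1)
    thickness = interp_fwhm(profile.focal_plane.z, z_profile)
    return SheetProfile(
        z=profile.focal_plane.z,
        z_profile=z_profile,
        thickness_fwhm=thickness,
        coverage_area=profile.axial_fwhm * scan_range,
    )


def gaussian_sheet(thickness_fwhm: float, z_extent: float = 10.0, n: int = 513) -> SheetProfile:
    """Analytic Gaussian sheet of a given FWHM (um), for simulations that do
    not need the full Bessel sidelobe structure."""
    if thickness_fwhm <= 0:
        raise ValueError("thickness_fwhm must be positive")
    z = np.linspace(-z_extent, z_extent, n)
    sigma = thickness_fwhm / (2.0 * _SQRT_2LN2)
    prof = np.exp(-0.5 * (z / sigma) ** 2)
    return SheetProfile(z=z, z_profile=prof, thickness_fwhm=thickness_fwhm,
                        coverage_area=float("nan"))


@dataclass(frozen=True)
class PowerDensityReport:
    """Excitation power budget: power (mW) over coverage area (um^2) in kW/cm^2."""

    power: float
    area: float
    density: float


def power_density(power_mw: float, area_um2: float) -> float:
    """Excitation power density in kW/cm^2 from power (mW) and area (um^2).

    1 mW / um^2 = 100 kW / cm^2 exactly.
    """
    if power_mw <= 0 or area_um2 <= 0:
        raise ValueError("power and area must be positive")
    return 100.0 * power_mw / area_um2


def power_density_report(power_mw: float, area_um2: float) -> PowerDensityReport:
    return PowerDensityReport(power=power_mw, area=area_um2,
                              density=power_density(power_mw, area_um2))
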