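# Methods

`bessellight` models the computational chain of single-wavelength Bessel
lightsheet localization microscopy in cleared tissue: beam shaping, blinking
single-molecule image formation, 3D localization, resolution estimation, and
labeled-volume quantification. This note records the models, the parameters
that matter, the numerical conventions, and the limits of what the synthetic
tests demonstrate.

## Coordinate and unit conventions

`y` is the illumination propagation axis, `z` the detection axis, `x` the
sheet-scan axis. All lengths are micrometres inside `beam_optics` (config
objects accept millimetres for bench-scale quantities such as focal lengths
and beam waists) and nanometres inside the localization chain. Numerical
aperture includes the medium index (NA = n sin θ), and the pupil-radius ↔ NA
map is linear (sine condition). Pixels are 0-based; a localization at the
centre of pixel (i, j) has position ((j + 0.5)·a, (i + 0.5)·a) with a the
pixel pitch. Voxels are half-open, `[i·s, (i+1)·s)` per axis, so a point
exactly on a boundary belongs to the upper voxel.

## Beam shaping (`beam_optics`)

The input Gaussian beam is E ∝ exp[(ik₀/2R_F − 1/w²)(x² + z²)] with
FWHM_G = √(2 ln 2)·w. The lens–axicon doublet adds the phase
Φ = −k₀[(x² + z²)/2F + (n_ax − 1)α√(x² + z²)]; by the lens law
1/F = 1/R_F + 1/q the beam focuses into a ring of radius
R₀ = α(n_ax − 1)q at the image distance q. The ring is filtered by a hard
binary annular mask (the physical mask's edge profile is not modelled) and
relayed to the excitation objective's pupil, where the NA band
[NA_in, NA_out] interferes into a Bessel beam.

**Propagator.** Free-space steps use the angular-spectrum transfer function
H(f) = exp(i2πd·√((n/λ₀)² − f²)), with a paraxial Fresnel option. The
angular-spectrum form is exact for scalar fields and reduces to Fresnel at
low NA; at NA 0.26 the paraxial error is no longer negligible, so angular
spectrum is the default. Evanescent components are dropped (never
amplified on back-propagation). Two guards raise `SamplingError` rather
than silently alias: the axicon/lens phase must change by < π between
adjacent samples within the energy-bearing support, and the propagated
energy must not walk beyond one grid period (the sampled transfer function
computes a cyclic convolution, so wrap-around is the real failure mode).

**Bessel focus.** The annular pupil *is* the angular spectrum of the focal
field: a pupil point at NA maps to transverse frequency NA/λ₀. Each
transverse plane at defocus y is the inverse FFT of the pupil times
exp(i·kz·y). The on-axis intensity is the plain phasor sum over the pupil,
evaluated in chunks; the full I(x, z; y) cube is never materialised
(profiles store the on-axis curve and the focal plane, with arbitrary
planes available lazily). For a thin annulus the on-axis profile is
sinc² with FWHM ≈ 1.772·n·λ₀/(NA_out² − NA_in²); the numerical
propagation matches this closed form to < 5% RMS and provides the finite-
width values: ≈ 44 µm for NA 0.185–0.26 in n = 1.33, ≈ 330 µm for
NA 0.174–0.187 in n = 1.38.

**FWHM convention.** Peaks are taken on the sampled grid; half-maximum
crossings are linearly interpolated (no sub-sample peak fit) —
deterministic and testable. "Axial FWHM of the beam" is the FWHM of
on-axis intensity vs y; "sheet thickness" is the FWHM of the scan-averaged
z-profile. These differ: scan-averaging folds the Bessel sidelobes into the
sheet, so the sheet is thicker than the central lobe. The sheet thickness
is reported as a metric, never asserted against a target — a thin-annulus
estimate at the published NA bands gives a central lobe wider than the
often-quoted sub-µm confinement, and the measurement definition behind such
numbers (e.g. main-lobe-only energy fraction) is not fixed here.

**Power budget.** Power density = power / (axial length × scan range),
converted exactly: 1 mW/µm² = 100 kW/cm². 20 mW over 20,000 µm² → 0.10
kW/cm²; 3 mW over 2,500 µm² → 0.12 kW/cm².

**Grid sizes.** The annulus-to-Bessel step defaults to 1024² pupils with
focal-plane sampling λ₀/(2·NA_out·oversample), oversample 2 (4 where the
central-lobe shape itself is measured). This resolves the annulus with
tens of frequency rings, which is what the axial profile accuracy depends
on; the thin-annulus oracle test pins the residual at < 2%. Axicon-plane
simulations size their grids from the phase-aliasing bound instead of a
fixed constant.

## Blinking simulation (`blink_sim`)

Each fluorophore is a three-state Markov chain per frame: dark → on with
probability p_on·w, on → bleached with probability p_bleach·w, on → dark
with probability 1/mean_on_frames; w ∈ [0, 1] is the lightsheet intensity
at the fluorophore's z position, normalised to the sheet peak. Photon
yield per on-frame is photons_per_on_frame·w. Coupling *both* the photon
yield and the bleach hazard to the local sheet intensity is what makes
sheet confinement protective: fluorophores away from the focal plane are
neither excited nor consumed.

Defaults (assumptions — spontaneous-blinking rate constants in clearing
media are not tabulated): p_on = 10⁻³, mean_on_frames = 2,
photons_per_on_frame = 1000, p_bleach = 0.01. These reproduce the three
phenomena the analysis relies on: a small duty cycle (sparse frames), a
linear cumulative-localization curve when p_bleach = 0, and a saturating
curve D(N) ≈ D∞(1 − e^(−N/τ)) with D∞ = N_fluor/p_bleach/area and
τ ≈ 1/(p_on·p_bleach) when bleaching is on.

The detection PSF is an elliptical Gaussian with hyperbolic defocus
curves, σ_x(z) = σ₀√(1 + ((z + γ)/d)²) and σ_y with −γ, crossing once at
z = 0 with σ_x > σ_y for z > 0. Defaults: σ₀ = 150 nm, γ = 250 nm,
d = 400 nm, validity ±400 nm — deliberately below √(γ² + d²) ≈ 472 nm,
where the width *ratio* turns over and the curve stops being invertible.
The exact defocusing model used on the real instrument is not public; the
interface is parametric so measured curves can be substituted. Spots are
rendered pixel-integrated (erf model); noise is Poisson shot noise on
signal electrons plus Gaussian read noise (1.6 e⁻ RMS default), gain
1 e⁻/count, baseline 100 counts, 100 nm object pixels. Bead calibration
stacks place one bright emitter per plane over a z-scan (10 µm at 100 nm
steps → 101 planes).

## Localization (`localize`)

Detection: difference-of-Gaussians band-pass (σ = 1.0/2.5 px), strict
local maxima above an absolute threshold (default 3× the robust MAD scale
of the filtered frame), minima separation 3 px — two emitters within one
PSF width merge into the brighter candidate, by design.

Fitting: pixel-integrated elliptical Gaussian + constant background,
least squares with analytic Jacobians, followed by a variance-weighted
refinement pass (weights 1/√μ from the first fit) that approximates the
Poisson maximum-likelihood estimator — plain unweighted least squares is
measurably inefficient (~1.3× CRLB; the weighted refinement tests at
≤ 1.2× CRLB against a Fisher-information oracle). Non-converged, edge-
pinned or degenerate fits are dropped, not returned.

Reported precision is the Thompson-style variance
σ² = (s² + a²/12)/N + 8π·s⁴·b²/(a²·N²), with s the mean fitted width, a
the pixel pitch, N the fitted photons, b the fitted background per pixel.

z assignment: nearest point on the width-vs-z calibration curve in
(σ_x, σ_y) space, on the 20 nm calibration grid with parabolic
refinement. The asymmetry filter clears the keep flag of any record whose
distance to the curve exceeds 20% (default) of the local curve magnitude
— this is what rejects Bessel-sidelobe blobs and overlapping emitters,
which are symmetric-but-inflated or off-curve. The threshold is ours; no
published value exists. Filters only clear flags; records are never
deleted, so counts are conserved through the pipeline.

Drift: fiducial mode finds occupancy peaks of a coarse spatial histogram
(markers present in ≥ 50% of frames), averages their per-frame
displacement and smooths with a 51-frame moving average; cross-correlation
mode registers time-binned histogram renderings by subpixel phase
correlation and interpolates (linearly extrapolating beyond the outermost
bin centres). Both anchor the trajectory at (0, 0) for frame 0.

Stitching shifts tiles by nominal offsets, optionally refines each tile
against the running mosaic by phase correlation of the rendered overlap,
and deduplicates same-frame records within one rendering bin (default).

## Resolution metrics (`resolution_metrics`)

Nyquist resolution 2/ρ^(1/d) (localization-density convention); precision
FWHM 2.355σ; overall resolution is their quadrature sum — the standard
combination of independent blurs, chosen because it recovers each
ingredient when the other vanishes. The frame planner inverts this model
under a linear density budget ρ(N) = slope·N and raises when the target is
below the precision floor. Densities count kept records only.

FRC splits the table into halves by alternating frames (or a seeded random
split), renders both on a common extent, correlates on rings one frequency
sample wide, smooths with a 3-ring moving average (the zero ring kept
exact), and takes the first interpolated crossing below 1/7. No crossing
in band returns an open-ended result with a warning rather than a number.

## Region quantification (`region_quant`)

Classification against a labeled voxel volume uses the floor/half-open
voxel rule; out-of-bounds records count as outside, and inside + outside
equals the kept total exactly. Region volume = voxel count × voxel volume
(exact up to float rounding); zero-voxel regions are flagged, not divided.
Intensity thresholding is inclusive (≥ lower bound, e.g. 78 on an 8-bit
scale) and idempotent on binarised volumes. Group comparison reports
mean ± SEM per region and a two-sided Welch t-test (unequal variances);
no multiple-testing correction is applied by default — with 15 sectors a
user comparing all of them should apply their own.

## What the synthetic data does and does not show

The generator reproduces sparse blinking, sheet confinement, astigmatic
image formation, camera noise, photobleaching saturation, drift, and
tiling — the mechanisms every downstream algorithm depends on. It does not
model depth-dependent aberrations, scattering residuals in cleared tissue,
fluorophore orientation effects, sCMOS fixed-pattern noise, or overlapping-
emitter ambiguity beyond simple merging. Passing tests therefore certify
the algorithms against their own forward model and against closed-form
oracles, not the absolute numbers attainable on tissue; tissue-scale
quantities (tens of millions of localizations, measured ~20 nm precision)
require the raw instrument data.

## Problem sizes

Default test and acceptance problem sizes: 1024² pupil grids (2048² only
for the axicon ring-radius check), 150–200 frames of 48² px for end-to-end
localization at 5000 photons/spot, 2000-frame drift runs, ≤ 64k-record FRC
tables, and ≤ 20³ voxel masks. These are the package's own choices for
desk-scale reproducibility; every physical conclusion above is grid-
converged at these sizes (halving the sampling changes the beam metrics by
well under the test tolerances).
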