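# Methods

This document records the physical models, numerical methods, unit and
coordinate conventions, and the deliberate simplifications behind
`stormsim`. It is written for someone validating or extending the
simulator.

## Units and coordinates

- Lengths in nanometres, times in seconds, rates per frame unless a
  name says otherwise.
- Sample-space coordinates have their origin at the field-of-view
  corner, x to the right along image columns, y down along image rows,
  z along the optical axis (z = 0 is the focal plane).
- Frames are 0-based internally; files (TIFF page order, ground-truth
  CSV, drift CSV) are 1-based.

## Ground-truth patterns (`patterns`)

- **Axon segments**: rings of radius r spaced by the pitch along the
  segment axis. Epitopes are Poisson-distributed along each ring with a
  linear density (labels/µm of ring circumference); each epitope carries
  a local orthonormal triad (radial, tangential, axial) for rigid dipole
  attachment.
- **Lines**: arbitrary 2D/3D polylines, Poisson-labelled per unit
  length.
- **Vesicles**: spherical shells, Poisson-labelled per unit area
  (uniform on the sphere).
- **Labelling**: a linker of configurable length displaces the
  fluorophore from its epitope, either rigidly along the local normal or
  re-sampled isotropically at each switching event ("flexible").
  Dipole modes: `free_rotating` (orientation averaged during emission),
  `fixed_random` (one isotropic draw per fluorophore), `fixed_custom`
  (given in the local triad).

## Photophysics (`photophysics`)

Per fluorophore, per frame: a two-state on/off Markov chain with
activation probability `on_rate × photoselection weight × excitation
efficiency`, geometric on-time (`off_rate`), and bleaching with fixed
probability per switching cycle. Photon budgets per event are
exponential with mean `mean_photons_per_event × photoselection weight ×
excitation efficiency`, so off-peak-excited (crosstalk) events are both
rarer and dimmer; photons are split across the frames an event overlaps
proportionally to overlap time. Photoselection is exactly cos² between
the absorption dipole and a linear excitation field (circular excitation
averages over the in-plane field direction; free rotors use the
isotropic average 1/3).

## Optics (`optics`)

Three interchangeable PSF models produce a radial/2D intensity profile
normalized to unit total energy in the image plane:

- **Gaussian**: width σ(z) = σ₀ √(1 + (z/z_R)²), with σ₀ = 0.21 λ/NA
  (Airy-matched) and z_R the Rayleigh range; exact normalization.
- **Scalar diffraction**: rotationally symmetric pupil integral
  I(r, z) = |∫ √cosθ J₀(k r n sinθ) e^{i k Φ(θ, z)} sinθ dθ|² with a
  defocus plus refractive-index-mismatch aberration phase Φ. The θ
  integral uses Gauss–Legendre quadrature (1024 nodes); every evaluation
  verifies internal convergence against the half-order rule at 1e-6
  relative tolerance and raises rather than returning an inaccurate
  profile. Because of the √cosθ apodization the focal profile reduces to
  the Airy pattern only in the paraxial limit; the equivalence test runs
  at NA 0.05 with matched indices.
- **Fixed dipole**: high-NA emission pattern of a fixed dipole,
  decomposed into in-plane and axial components; axial dipoles produce a
  doughnut with a central null, and their total collected energy is
  substantially lower than for in-plane dipoles (the kernel mass encodes
  the relative collection efficiency).

Events are rendered onto a sub-pixel photon canvas (8× oversampling by
default) over a truncated support, then binned to camera pixels with
exact photon conservation.

## Spectral model (`spectral`)

Dye absorption/emission spectra are bundled as synthetic CSV fixtures
(sum-of-Gaussians approximations resampled at 1 nm; see "Fixtures"
below). Excitation efficiency is the normalized absorption at the laser
line; detection efficiency integrates the emission spectrum through the
multiband filter (four passbands, out-of-band floor 1e-4). Crosstalk is
emergent: a far-red dye under 561 nm excitation gets ≈ 7.4 % of its
peak excitation efficiency, producing rare, dim events in the orange
channel. Sequential excitation is configured as a laser schedule of
(wavelength, frame-count) blocks.

## Structured fluorescence background (`camera`)

The SFB is a defocused copy of the fluorophore sum image, blurred with
the configured PSF at the SFB defocus (800 nm default), rescaled so its
peak equals `strength × single-molecule peak signal`, and added to the
per-frame background rate map (the ratio convention is
background/signal: "50 %" means the background peak is half the peak
pixel signal of one average in-focus molecule).

## Camera (`camera`)

Photon rate map → Poisson draw → (optional) EMCCD gain register drawn
as a gamma distribution (excess noise factor 2) → Gaussian read noise →
ADU conversion with baseline, quantization and uint16 saturation. The
mean/variance of the chain match the closed-form EMCCD expressions to
within Monte-Carlo error.

## Drift (`drift`)

Velocity follows a discretized Ornstein-Uhlenbeck process
dv = −k (v − v_mean) dt + σ √dt ξ; offsets integrate the velocity and
start at zero. Stationary velocity variance is σ²/(2k); the standard
error of the time-averaged velocity over duration T is
√(2 σ²/(2k) / (k T)). Drift shifts true emitter positions per frame;
the ground-truth table records both the nominal and drifted positions,
and the evaluation harness can subtract the known trajectory.

## Localization harness (`eval`)

A deliberately simple localizer, kept symmetric-Gaussian regardless of
the PSF that generated the data (the model mismatch is part of what the
simulator is for):

- **Background estimate**: per-pixel temporal median of the stack.
  Emitters blink sparsely in time, so everything static — baseline,
  uniform background, SFB of any spatial width — is captured exactly.
  (A spatial median filter provably fails here: an SFB ridge narrower
  than the filter window survives subtraction and floods the detector
  with false candidates.) Stacks shorter than 20 frames fall back to a
  spatial median filter.
- **Detection**: local maxima of the background-subtracted frame above
  5× the per-pixel camera-noise standard deviation predicted by the
  EMCCD model at the local background level (shot noise on a bright
  structured background is orders of magnitude larger than on the dark
  field, so a global threshold either floods or starves).
- **Fitting**: least-squares symmetric 2D Gaussian + constant offset per
  candidate window (Levenberg-Marquardt with analytic Jacobian);
  fits with non-physical width or centre outside the window are
  rejected.
- **Filtering**: fitted sigma window, normalized residual ceiling and
  photon floor; scenario runs calibrate sigma/residual windows from
  percentiles of the localization distribution.
- **Measurements**: axial ring periodicity (mean inter-peak spacing of
  the 5 nm projected histogram), transverse line separation
  (shared-width two-Gaussian mixture fit of the 10 nm histogram), and
  modal radial distance from the segment axis. The segment axis is the
  midpoint of the 2 %/98 % quantiles of the transverse coordinate: the
  tube projection has sharp, equal-density edges, so the quantile
  midpoint locates the midline far more accurately than the sample mean
  (which inherits the asymmetric angular-sampling bias).

## Reproducibility

One `master_seed` feeds a numpy `SeedSequence` tree (patterns,
switching, camera, drift), so identical configurations give
byte-identical outputs. The manifest stores the seed and a SHA-256 of
the canonicalized config.

## Fixtures

The bundled dye spectra are synthetic sum-of-Gaussians approximations
to the published band shapes, not vendor data; they are regenerable via
`stormsim make-fixtures` and are validated by shape properties
(normalization, red-shift of emission, ≈ 7.4 % far-red excitation at
561 nm) rather than point-by-point values.

## Deliberate simplifications

- No astigmatic/biplane 3D localization; the harness is 2D.
- Aberrations beyond defocus + index mismatch (coma, spherical from
  other sources) are out of scope.
- The EMCCD register is modelled by its gamma limit rather than
  per-stage binomial multiplication; clock-induced charge is omitted.
- Blind (image-based) drift correction is out of scope; drift is
  corrected from the known trajectory.
- Free-rotating dipoles are rendered with the isotropic-average PSF
  rather than time-resolved orientation sampling.
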