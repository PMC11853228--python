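# Methods

`mslsci` implements depth-resolved perfusion imaging with multi-spectral
laser speckle contrast imaging (MS-LSCI): raw speckle movies at several
laser wavelengths are reduced to visibility-ratio maps whose inverse square
peaks over subsurface flow, a sloped-channel calibration phantom converts
those responses into absolute depths, and differencing wavelength pairs
enhances depth-specific flow. Because no experimental raw data accompany
the technique, the package carries a physically motivated dynamic-speckle
simulator and a photon Monte Carlo that together make every stage testable
end to end. This note records the models, the parameter choices, and what
the synthetic studies do and do not establish.

## Statistics computed from raw stacks

**Speckle contrast.** `K = sigma / <I>` with the population (divide-by-N)
standard deviation, the speckle-statistics convention. Temporal contrast is
computed per pixel over frames; spatial contrast over a centered odd window
(default 7x7). Fully developed, polarized, static speckle has exponential
intensity statistics and K -> 1; motion blurs the pattern within the
exposure and lowers K.

**Visibility ratio.** `Vr = (<Imax> - <Imin>) / <I>_st` over a sliding 7x7
window: within every frame the window maximum and minimum are extracted,
`<Imax>` and `<Imin>` are their means over frames, and `<I>_st` is the mean
over the whole space-time block. The depth metric is `1/Vr^2`, regularized
as `1/max(Vr, eps)^2` with `eps = 1e-6` (clamped pixels are flagged).
Sliding windows use stride 1, results are assigned to the window center,
and borders where the window does not fit are masked invalid rather than
padded. All grids are row-major, 0-based, `(row, col)`.

The angle brackets on `Imax`/`Imin` admit a second reading — extremes of
the temporally averaged frame — implemented as
`visibility_ratio(..., extremes="extremes_of_mean")`. On raw
single-wavelength stacks the default per-frame-extremes reading preserves
the temporal speckle information and is preferred. On *difference* stacks
the situation reverses, for a reason worth recording: the difference of two
speckle intensity patterns retains unit-contrast spatial structure at every
amplitude, so the per-frame window range never drops over a vessel and the
per-frame-extremes reading is provably blind to differential flow. The
temporal *mean* of the difference, by contrast, is smooth wherever either
channel fluctuates, and its window extremes collapse exactly over vessels.
`mix_and_profile` therefore evaluates mixed stacks in the temporal-mean
mode by default.

## Depth profiling

Maps are reduced to line profiles by band averaging (masked pixels
excluded); a 5 px moving average (about one speckle grain) suppresses
sub-vessel noise before peak detection. Vessels are detected in two
stages: prominence-based candidates on the smoothed profile, classified by
their raw vessel-center elevation `(peak - baseline)/baseline` against a
floor of 0.6x the baseline (the profile median). The floor is a property
of the detector, placed midway between the deep-vessel responses of the
blue/green channels (elevation about 0.45 at 2 mm depth) and the red/NIR
channels (about 0.8-1.1) in the synthetic study, so that the
wavelength-dependent detectability dichotomy seen experimentally is
reproduced with roughly 4-sigma margins on both sides. Peak sharpness is
scored by FWHM with linear interpolation between samples; the baseline is
the median outside a 3x-FWHM-guess exclusion zone around the peak.

**Absolute depth assignment.** The calibration phantom provides, at every
position of known depth, the response a vessel of that depth would produce.
Two monotone statistics are tabulated along the channel and pooled over
repeated acquisitions (`build_calibration`):

* the **flow index** — shot-corrected temporal flow variance referenced to
  a pump-off acquisition, `mean(Var_t[I_on] - Var_t[I_off]) /
  (mean(<I_off>) * scale)`. The frozen speckle envelope enters the flow
  variance linearly, so the reference cancels it patchwise; the reference
  variance also supplies the shot-noise floor. This is the most precise
  statistic at moderate modulation but saturates where the modulated
  fraction approaches its maximum (it behaves as `2s(1-s) + gamma s^2` in
  the modulated fraction `s`);
* the **`1/Vr^2` elevation**, measured as the pixelwise flow-on/pump-off
  ratio over the channel core — exactly the statistic a vessel peak
  reports, steepest where the flow index saturates.

A detected vessel's two measurements are inverted on the two pooled curves
and fused by inverse-variance weighting, with per-position uncertainties
from the between-acquisition scatter and variances scaled by the local
slope of each curve; where one statistic saturates its weight vanishes.
Estimates whose two inversions disagree strongly, or whose measurements
fall outside the calibrated range, are flagged low-confidence.

The generic profile-level operation `estimate_depth` matches peak
elevations directly against a calibration profile, falling back to
normalized cross-correlation alignment for peak-free targets (a target that
is a verbatim segment of the calibration profile maps to its own center).
Pure shape correlation cannot assign depth to an isolated vessel peak over
a smooth calibration ramp — the amplitude carries the depth information —
which is why the calibrated two-statistic inversion above is the
production path.

**Calibration protocol.** Each calibration acquisition is a (flow-on,
pump-off) pair of the sloped channel; the sloped geometry offers only a
handful of independent speckle grains per depth bin, so the frozen pattern,
not photon noise, limits a single acquisition. Pooling six acquisitions
with independent speckle realizations (experimentally: translate the
phantom laterally and re-acquire, a standard calibration practice) and
enforcing monotonicity by isotonic regression brings the curve noise to a
few percent. Pump-off references are the other standard tool and cost one
extra acquisition.

## Wavelength mixing

`difference_stack` subtracts two co-registered stacks frame by frame after
matching their global means (an overall illumination/exposure correction);
the default is the absolute difference, keeping downstream statistics on
non-negative intensities. No registration is attempted — acquisition is
assumed fixed-rig. The enhancement mechanism is differential absorption:
blood absorbs strongly in the blue/green and weakly in the red/NIR, so a
vessel's shadow survives the subtraction with a wavelength-pair-specific
amplitude while common static structure cancels. Recommended pairs are
blue+green (450+515 nm) for shallow flow and red+green (658+515 nm) or
red+NIR (658+850 nm) for deep flow.

## Photon Monte Carlo

A weight-propagation random walk in a homogeneous semi-infinite slab under
the similarity approximation: isotropic scattering at the reduced
coefficient `mu_s'`, step lengths `~Exp(mu_a + mu_s')`, a fraction
`mu_a/mu_t` of the weight deposited per collision, Russian roulette below
weight 1e-4 with survival 0.1, and an index-matched top surface (Fresnel
mismatch is not modeled; the phantom optical-property table carries
`n = 1.4` for reference only). The fluence is accumulated on a
cylindrically collapsed (depth x radius) grid, 0.05 mm voxels, 20 mm deep.
Checks: the weight ledger (deposited + escaped + net roulette adjustment)
balances to launch weight up to float rounding on every run; in the
absorption-dominated limit the axial deposition follows Beer-Lambert; in
the far field the laterally integrated fluence decays at the
diffusion-theory rate `mu_eff = sqrt(3 mu_a (mu_a + mu_s'))` within 10%
for all four tabulated wavelength rows.

Two depth summaries are derived. The **penetration depth** is where the
laterally integrated fluence falls to `1/e^2` of its surface value (surface
extrapolated from the first two depth bins so the estimate is not offset by
half a voxel). The **sampling-depth curve** of diffuse reflectance — the
fraction of back-escaped photon weight whose path reached at least depth
`d` — is the fraction of a surface-detected signal that a moving scatterer
at that depth can modulate, and decays much faster than the fluence because
most detected photons only graze the superficial layers. The default runs
use 1e5 photons (a 1e6-photon run reproduces the same curves well within
the quoted tolerances at 10x the cost).

## Dynamic-speckle phantom simulator

The simulator renders 16-bit multi-frame stacks of two phantom geometries:
a two-layer phantom (1 mm-wide channels at 1 mm and 2 mm depth, 1 cm
apart) and a sloped calibration channel (0.5 to 2.5 mm by default), at
23 mm/s flow, 10 ms exposure, 55 frames/s, 200 frames.

* **Speckle formation.** Complex circular-Gaussian fields are synthesized
  by shaping white complex noise in the Fourier domain to a Gaussian
  bandwidth whose intensity autocorrelation FWHM equals the
  diffraction-limited grain `d_min / (camera pixel)`, with
  `d_min = 1.22 (1+M) (f/#) lambda` (M=8, f/#=1.6, 3.45 um pixels).
  Intensities `|field|^2` are exactly negative-exponential.
* **Flow.** Within a vessel footprint the field evolves as an AR(1) process
  with decorrelation time `tau_c = d_min / (M v)` (grain transit at the
  sensor-plane speed); intensity is averaged over up to `n_sub_max = 12`
  sub-exposure steps, reproducing within-exposure blurring. At 23 mm/s the
  field fully decorrelates within a sub-step, so the cap sets the residual
  contrast floor of the blurred component (1/sqrt(12) ~ 0.29).
* **Depth.** The vessel field is the coherent sum
  `sqrt(1-S) static + sqrt(S) dynamic`, where `S(lambda, depth)` is the
  Monte Carlo sampling-depth fraction at the vessel depth. This gives
  S(1 mm) = 0.38/0.40/0.52/0.58 and S(2 mm) = 0.18/0.20/0.30/0.36 at
  450/515/658/850 nm — the quantitative backbone of the wavelength
  dichotomy. A simple exponential in the diffusion attenuation coefficient
  was rejected: it decays far too slowly over the first 2 mm and would make
  the deep vessel visible at every wavelength.
* **Absorption shadows.** A fraction `kappa(lambda) * S` of the light that
  sampled a vessel is absorbed by the blood analog, with hemoglobin-like
  contrast `kappa = 0.60/0.45/0.08/0.12` at 450/515/658/850 nm. Shadows
  are spatially smooth, so they cancel in the ratio statistics (Vr, K) and
  matter only for wavelength differencing — which is exactly the
  absorption-difference mechanism the technique exploits.
* **Multi-wavelength sessions.** `generate_session` draws the static
  fields of all channels from an Ornstein-Uhlenbeck chain over wavenumber,
  giving pairwise field correlation `exp(-L |1/lambda_a - 1/lambda_b|)`
  with `L = 0.05 um` (cross-channel intensity correlation about 0.95);
  dynamic fields are channel-independent, since multiply scattered light
  from moving blood decorrelates across wavelengths far faster than the
  static surface speckle. The correlation scale is a model choice — no
  quantitative cross-spectral correlation is published for this system —
  set so that differencing suppresses common static structure strongly, the
  premise of the mixing technique.
* **Camera.** Gain places the static background mean at 10% of the 16-bit
  full scale, leaving headroom for the bright tail of exponential speckle
  (clipping at 4x the mean would visibly truncate the histogram). Shot
  noise uses a Gaussian approximation to Poisson, indistinguishable at
  thousands of counts per pixel. Fixed seeds give bit-identical stacks.

**Desk scale.** Defaults are 256x256 frames over a 20x20 mm field (the
experimental geometry is 700x700 over ~40 mm; the per-millimetre sampling
is comparable and 700x700 is available by setting `frame_px`). Calibration
stacks use 32 rows, enough for the channel core plus an unshadowed
background strip. The synthetic studies in the test suite use 20 seeds of
200-frame stacks at all four wavelengths.

## What the synthetic studies show — and what they do not

Passing tests establish that the analysis chain is internally consistent:
the statistics match their closed-form and brute-force oracles; the
wavelength-dependent detectability dichotomy, depth recovery to +-0.25 mm
(median over seeds; single-seed scatter is ~0.15 mm, frozen-speckle
limited), and the mixing improvements all follow from light-transport
physics injected through the Monte Carlo. They do not validate the
technique on real tissue: the simulator has sharp-edged vessels with no
depth-dependent lateral blurring, no phantom autofluorescence or internal
reflections, idealized co-registration between wavelength channels, a
single uniform flow speed, and a depth-sensitivity model that, while
physically motivated, is not fitted to any measured depth response (none is
published). Absolute FWHM values in pixels are therefore not comparable to
experimental reports, and only their relative improvements under mixing are
meaningful.

## Numerical notes

* Zero-mean windows and pixels are masked, never divided through;
  `1/Vr^2` clamps at the configurable epsilon and flags clamped pixels.
* Isotonic (pool-adjacent-violators) regression enforces monotone
  calibration curves; inversion uses nearest-value lookup with local slopes
  estimated over +-20 px windows and floored to avoid division by zero.
* Peak ties resolve toward the smaller index; plateau peaks report their
  centroid; correlation lags require 25% overlap of the shorter profile.
* The Monte Carlo trims photon arrays in place as photons escape or lose
  the roulette; all randomness flows from one `numpy` generator per run.
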