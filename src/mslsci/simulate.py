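"""Dynamic-speckle phantom simulator.

Synthesizes 16-bit speckle stacks over parametric tissue phantoms so that
every analysis stage can be exercised without experimental data.  The model:

* Fully developed speckle.  A complex circular-Gaussian field is generated
  by low-pass filtering white complex noise to a spatial bandwidth matching
  the diffraction-limited speckle size ``dmin = 1.22 (1+M) (f/#) lambda``;
  the intensity ``|field|**2`` then has negative-exponential statistics and
  ideal contrast of 1.

* Flow.  Inside a vessel footprint the field evolves as an order-1
  autoregression with inter-step correlation ``exp(-dt/tau_c)``; the
  decorrelation time ``tau_c`` is the time a speckle grain takes to cross
  its own diameter at the sensor-plane flow speed.  Intensity is averaged
  over sub-exposure steps, reproducing the within-exposure blurring that
  lowers speckle contrast over moving scatterers.

* Depth.  Only the fraction ``S(lambda, depth)`` of detected light that has
  sampled the vessel's depth can be modulated by the flow.  ``S`` is taken
  from the photon Monte Carlo as the sampling-depth curve of diffuse
  reflectance (fraction of back-escaped weight whose path reached the given
  depth), so longer wavelengths see deeper vessels, mirroring the
  wavelength ordering of the optical-property table.  The vessel field is
  the coherent sum ``sqrt(1-S)*static + sqrt(S)*dynamic``.

Two phantom geometries are provided: a two-layer phantom with 1 mm-wide
channels at 1 mm and 2 mm depth spaced 1 cm apart, and a sloped calibration
channel spanning a continuous depth gradient.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .montecarlo import (OpticalProperties, PHANTOM_OPTICAL_PROPERTIES,
                         run_mc, sampling_depth_fraction)
from .profiles import CalibrationCurve
from .stacks import MAX_16BIT, ImageStack

__all__ = [
    "OpticsConfig",
    "Vessel",
    "PhantomSpec",
    "SpeckleModelParams",
    "speckle_size",
    "sampling_check",
    "optical_properties_for",
    "depth_sensitivity",
    "fully_developed_speckle",
    "generate_stack",
    "generate_session",
    "generate_calibration_stack",
    "generate_calibration_pair",
]


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging-path parameters that set the speckle grain on the sensor."""

    wavelength_nm: float
    magnification: float = 8.0
    f_number: float = 1.6
    camera_pixel_um: float = 3.45

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "f_number", "camera_pixel_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.magnification < 0:
            raise ValueError("magnification must be non-negative")


def speckle_size(optics: OpticsConfig) -> float:
    """Minimum resolvable speckle size 1.22 (1+M) (f/#) lambda, in microns."""
    lam_um = optics.wavelength_nm / 1000.0
    return 1.22 * (1.0 + optics.magnification) * optics.f_number * lam_um


def sampling_check(optics: OpticsConfig) -> bool:
    """True iff the speckle grain spans at least two camera pixels."""
    return speckle_size(optics) >= 2.0 * optics.camera_pixel_um


@dataclass
class Vessel:
    """A flow channel: fixed depth, or a depth range for the sloped channel."""

    lateral_position_mm: float
    width_mm: float = 1.0
    depth_mm: float | None = None
    depth_range_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.width_mm <= 0:
            raise ValueError("vessel width must be positive")
        if (self.depth_mm is None) == (self.depth_range_mm is None):
            raise ValueError("specify exactly one of depth_mm or "
                             "depth_range_mm")
        depths = ((self.depth_mm,) if self.depth_mm is not None
                  else self.depth_range_mm)
        if any(d <= 0 for d in depths):
            raise ValueError("vessel depths must be positive")


@dataclass
class PhantomSpec:
    """Parametric phantom: vessel layout, flow speed, and field of view."""

    kind: Literal["two_layer", "calibration_slope"]
    vessels: list[Vessel]
    flow_speed_mm_s: float = 23.0
    field_of_view_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.flow_speed_mm_s <= 0 or self.field_of_view_mm <= 0:
            raise ValueError("flow speed and field of view must be positive")
        for v in self.vessels:
            half = 0.5 * v.width_mm
            if (v.lateral_position_mm - half < 0
                    or v.lateral_position_mm + half > self.field_of_view_mm):
                raise ValueError(
                    f"vessel at {v.lateral_position_mm} mm extends outside "
                    f"the {self.field_of_view_mm} mm field of view")

    @classmethod
    def two_layer(cls, depth_shallow_mm: float = 1.0,
                  depth_deep_mm: float = 2.0,
                  spacing_mm: float = 10.0,
                  width_mm: float = 1.0,
                  field_of_view_mm: float = 20.0,
                  flow_speed_mm_s: float = 23.0) -> "PhantomSpec":
        """Two parallel channels (default 1 mm and 2 mm deep, 1 cm apart)."""
        center = field_of_view_mm / 2.0
        return cls(
            kind="two_layer",
            vessels=[
                Vessel(center - spacing_mm / 2.0, width_mm, depth_shallow_mm),
                Vessel(center + spacing_mm / 2.0, width_mm, depth_deep_mm),
            ],
            flow_speed_mm_s=flow_speed_mm_s,
            field_of_view_mm=field_of_view_mm,
        )

    @classmethod
    def calibration(cls, depth_start_mm: float = 0.5,
                    depth_end_mm: float = 2.5,
                    width_mm: float = 1.0,
                    field_of_view_mm: float = 20.0,
                    flow_speed_mm_s: float = 23.0) -> "PhantomSpec":
        """A single channel sloping across the full field of view."""
        return cls(
            kind="calibration_slope",
            vessels=[Vessel(field_of_view_mm / 2.0, width_mm,
                            depth_range_mm=(depth_start_mm, depth_end_mm))],
            flow_speed_mm_s=flow_speed_mm_s,
            field_of_view_mm=field_of_view_mm,
        )


@dataclass
class SpeckleModelParams:
    """Knobs of the speckle synthesis itself (camera and field model).

    ``background_level`` places the static-background mean at a fraction of
    the 16-bit full scale (default 10%, leaving headroom for the ~10x-mean
    bright grains of exponential speckle).  ``n_sub_max`` caps the number of
    sub-exposure field realizations; at the default flow speed the field
    decorrelates far faster than the exposure, so the cap sets the residual
    contrast floor of the blurred component.  ``depth_sensitivity``
    overrides the Monte Carlo-derived S(depth) when provided.
    """

    n_frames: int = 200
    frame_px: int = 256
    frame_rows: int | None = None  # defaults to frame_px (square frames)
    exposure_s: float = 0.010
    frame_period_s: float = 1.0 / 55.0
    static_background_fraction: float = 0.0
    shot_noise: bool = True
    bit_depth: int = 16
    background_level: float = 0.10
    illumination_gradient: float = 0.0
    n_sub_max: int = 12
    depth_sensitivity: Callable[[float], float] | None = None
    vessel_shadow_scale: float = 1.0  # 0 disables absorption shadows
    flow_on: bool = True  # False freezes the flow (pump-off reference)

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.frame_px < 16:
            raise ValueError("need at least 1 frame and 16 px frames")
        if not 0 < self.background_level <= 0.5:
            raise ValueError("background_level must be in (0, 0.5]")
        if not 0 <= self.static_background_fraction < 1:
            raise ValueError("static_background_fraction must be in [0, 1)")
        if self.exposure_s <= 0 or self.frame_period_s < self.exposure_s:
            raise ValueError("need 0 < exposure_s <= frame_period_s")


#: Fraction of the light that sampled a vessel absorbed by the blood analog,
#: per wavelength: hemoglobin-like, strong in the blue/green and weak in the
#: red/NIR.  This differential absorption is what wavelength differencing
#: exploits: the vessel's shadow survives the subtraction while common
#: static structure cancels.
BLOOD_ABSORPTION_CONTRAST = {450: 0.60, 515: 0.45, 658: 0.08, 850: 0.12}


def blood_absorption_contrast(wavelength_nm: float) -> float:
    wls = np.array(sorted(BLOOD_ABSORPTION_CONTRAST))
    return float(np.interp(wavelength_nm, wls,
                           [BLOOD_ABSORPTION_CONTRAST[w] for w in wls]))


def optical_properties_for(wavelength_nm: float) -> OpticalProperties:
    """Phantom optical properties, interpolated between tabulated lines."""
    table = PHANTOM_OPTICAL_PROPERTIES
    if wavelength_nm in table:
        return table[wavelength_nm]
    wls = np.array(sorted(table))
    mua = np.interp(wavelength_nm, wls, [table[w].mu_a_per_mm for w in wls])
    musp = np.interp(wavelength_nm, wls,
                     [table[w].mu_s_prime_per_mm for w in wls])
    return OpticalProperties(wavelength_nm, float(mua), float(musp))


@functools.lru_cache(maxsize=16)
def _sensitivity_curve(wavelength_nm: float) -> tuple[np.ndarray, np.ndarray]:
    """Cached Monte Carlo sampling-depth curve for one wavelength.

    Runs the photon walk once per wavelength with a fixed internal seed so
    the simulator stays deterministic regardless of the caller's seed.
    """
    props = optical_properties_for(wavelength_nm)
    fmap = run_mc(props, n_photons=60_000, seed=773)
    depths = np.arange(0.0, 6.0 + 1e-9, 0.05)
    return depths, sampling_depth_fraction(fmap, depths)


def depth_sensitivity(wavelength_nm: float) -> Callable[[float], float]:
    """S(depth): fraction of detected light a flow at that depth modulates."""
    depths, frac = _sensitivity_curve(float(wavelength_nm))

    def s_of_depth(depth_mm: float) -> float:
        return float(np.interp(depth_mm, depths, frac))

    return s_of_depth


# --- speckle field synthesis -------------------------------------------------

def _field_filter(shape: tuple[int, int], grain_px: float
                  ) -> tuple[np.ndarray, float]:
    """Fourier-domain Gaussian filter tuned so the intensity autocorrelation
    FWHM of the filtered field equals ``grain_px``; returns (filter, norm)."""
    sigma = grain_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    ky = np.fft.fftfreq(shape[0])[:, None]
    kx = np.fft.fftfreq(shape[1])[None, :]
    h = np.exp(-2.0 * (np.pi * sigma) ** 2 * (ky * ky + kx * kx))
    norm = math.sqrt(2.0 * float((h * h).sum())) / (shape[0] * shape[1])
    return h.astype(np.float32), norm


def _speckle_field(rng: np.random.Generator, h: np.ndarray,
                   norm: float, batch: int | None = None) -> np.ndarray:
    """Unit-mean-intensity circular-Gaussian speckle field(s).

    With ``batch`` set, returns ``batch`` independent fields stacked along
    the first axis (one vectorized FFT pass).  The white noise is drawn
    directly in the Fourier domain (where complex white Gaussian noise is
    statistically identical to its transform), so a single inverse FFT
    suffices.
    """
    shape = h.shape if batch is None else (batch, *h.shape)
    spec = (rng.standard_normal(shape, dtype=np.float32)
            + 1j * rng.standard_normal(shape, dtype=np.float32))
    spec *= h
    return np.fft.ifft2(spec, axes=(-2, -1)) / norm


def fully_developed_speckle(shape: tuple[int, int], seed: int = 0,
                            grain_px: float = 0.0) -> np.ndarray:
    """Unit-mean intensity of a static, fully developed speckle pattern.

    With ``grain_px = 0`` every pixel is an independent draw, so the
    intensities are i.i.d. negative-exponential with contrast exactly 1 --
    the statistics oracle against which the contrast engines are checked.
    A positive ``grain_px`` band-limits the field to that intensity
    autocorrelation FWHM instead.
    """
    rng = np.random.default_rng(seed)
    if grain_px <= 0:
        field = (rng.standard_normal(shape)
                 + 1j * rng.standard_normal(shape)) / math.sqrt(2.0)
        return np.abs(field) ** 2
    h, norm = _field_filter(shape, grain_px)
    return np.abs(_speckle_field(rng, h, norm)) ** 2


def _soft_rect(coords: np.ndarray, center: float, half_width: float,
               edge: float = 1.0) -> np.ndarray:
    """Unit top-hat with a linear rolloff of ``edge`` px on both flanks."""
    return np.clip((half_width - np.abs(coords - center)) / edge + 0.5,
                   0.0, 1.0)


def _tau_c(optics: OpticsConfig, flow_speed_mm_s: float) -> float:
    """Grain-transit decorrelation time at the sensor plane, in seconds."""
    v_sensor_um_s = optics.magnification * flow_speed_mm_s * 1000.0
    return speckle_size(optics) / v_sensor_um_s


def _randn_complex(rng: np.random.Generator, shape) -> np.ndarray:
    return (rng.standard_normal(shape, dtype=np.float32)
            + 1j * rng.standard_normal(shape, dtype=np.float32))


def _chained_whites(rng: np.random.Generator, shape,
                    rhos: list[float]) -> list[np.ndarray]:
    """Unit-variance complex white arrays correlated along a chain.

    Channel ``i`` correlates with channel ``i-1`` by ``rhos[i]``; with the
    chain ordered by wavenumber this realizes an Ornstein-Uhlenbeck process
    across the spectrum, so any two channels correlate by the product of the
    link correlations between them.
    """
    out = [_randn_complex(rng, shape)]
    for r in rhos[1:]:
        out.append(r * out[-1]
                   + math.sqrt(1.0 - r * r) * _randn_complex(rng, shape))
    return out


def generate_session(
    phantom: PhantomSpec,
    wavelengths_nm,
    params: SpeckleModelParams | None = None,
    seed: int = 0,
    spectral_corr_scale_um: float = 0.05,
    optics_by_wavelength: dict[float, OpticsConfig] | None = None,
) -> dict[float, ImageStack]:
    """Render one acquisition session: co-registered stacks at several lines.

    The static speckle of the different wavelength channels originates from
    the same rigid scatterer microstructure, so their fields are strongly
    correlated: static fields follow an exponential correlation
    ``exp(-scale * |1/lambda_a - 1/lambda_b|)`` in wavenumber (scale in
    microns).  The dynamic (flow-modulated) fields, by contrast, are drawn
    independently per channel: multiply scattered light from moving
    scatterers decorrelates across wavelengths far faster than the static
    surface speckle.  This common-mode static structure is what wavelength
    differencing cancels while the flow signal of both channels survives;
    without it, mixing could not isolate depth-differential flow.
    Deterministic per seed; single-wavelength statistics are unchanged.
    """
    params = params or SpeckleModelParams()
    optics_by_wavelength = optics_by_wavelength or {}
    optics_list = [optics_by_wavelength.get(w, OpticsConfig(wavelength_nm=w))
                   for w in wavelengths_nm]
    # chain ordered by wavenumber so pairwise correlations are exponential
    sigma = np.array([1000.0 / o.wavelength_nm for o in optics_list])
    order = np.argsort(sigma)
    rhos = [0.0]
    for j in range(1, len(order)):
        dsig = abs(sigma[order[j]] - sigma[order[j - 1]])
        rhos.append(math.exp(-spectral_corr_scale_um * dsig))
    stacks = _generate_channels(phantom, [optics_list[j] for j in order],
                                params, seed, rhos)
    out: dict[float, ImageStack] = {}
    for pos, j in enumerate(order):
        out[optics_list[j].wavelength_nm] = stacks[pos]
    return out


def generate_stack(phantom: PhantomSpec, optics: OpticsConfig,
                   params: SpeckleModelParams | None = None,
                   seed: int = 0) -> ImageStack:
    """Render a dynamic-speckle stack of the phantom at one wavelength.

    Deterministic per seed.  Vessels of a ``two_layer`` phantom run
    vertically (fixed column footprint); the sloped channel of a
    ``calibration_slope`` phantom runs horizontally with depth increasing
    along the columns.
    """
    return _generate_channels(phantom, [optics],
                              params or SpeckleModelParams(), seed, [0.0])[0]


def _generate_channels(phantom: PhantomSpec, optics_list, params,
                       seed: int, rhos: list[float]) -> list[ImageStack]:
    n_wl = len(optics_list)
    n_px = params.frame_px
    n_rows = params.frame_rows or n_px
    px_per_mm = n_px / phantom.field_of_view_mm
    pixel_pitch_um = 1000.0 / px_per_mm

    senses = [params.depth_sensitivity or depth_sensitivity(o.wavelength_nm)
              for o in optics_list]
    grains = [speckle_size(o) / o.camera_pixel_um for o in optics_list]
    taus = [_tau_c(o, phantom.flow_speed_mm_s) for o in optics_list]
    n_sub = min(params.n_sub_max,
                max(1, math.ceil(params.exposure_s / min(taus))))
    dt_sub = params.exposure_s / n_sub
    rho_sub = [math.exp(-dt_sub / tau) for tau in taus]
    rho_gap = [math.exp(-(params.frame_period_s - params.exposure_s) / tau)
               for tau in taus]

    rng = np.random.default_rng(seed)
    full_filters = [_field_filter((n_rows, n_px), g) for g in grains]
    whites = _chained_whites(rng, (n_rows, n_px), rhos)
    statics = [np.fft.ifft2(w * h) / nrm
               for w, (h, nrm) in zip(whites, full_filters)]
    int_statics = [np.abs(s) ** 2 for s in statics]

    coords = np.arange(n_px, dtype=float)
    row_coords = np.arange(n_rows, dtype=float)
    pad = max(8, int(math.ceil(4 * max(grains))))
    shadows = [np.ones((n_rows, n_px), dtype=np.float32)
               for _ in range(n_wl)]

    # Per-vessel dynamic machinery: depth-sensitivity weight map restricted
    # to a bounding slab, plus one evolving AR-1 field state per channel.
    vessels = []
    for v in phantom.vessels:
        half_px = 0.5 * v.width_mm * px_per_mm
        if v.depth_mm is not None:  # vertical channel, fixed depth
            center_px = v.lateral_position_mm * px_per_mm
            prof = _soft_rect(coords, center_px, half_px)
            cols = np.flatnonzero(prof > 0)
            lo = max(0, cols[0] - pad)
            hi = min(n_px, cols[-1] + 1 + pad)
            sl = (slice(None), slice(lo, hi))
            sub_shape = (n_rows, hi - lo)
            s_maps = [(sense(v.depth_mm) * prof[lo:hi])[None, :]
                      * np.ones(sub_shape) for sense in senses]
        else:  # sloped channel: horizontal band, depth varies along columns
            center_px = v.lateral_position_mm * px_per_mm
            prof = _soft_rect(row_coords, center_px, half_px)
            rows = np.flatnonzero(prof > 0)
            lo = max(0, rows[0] - pad)
            hi = min(n_rows, rows[-1] + 1 + pad)
            d0, d1 = v.depth_range_mm
            depth_of_col = d0 + (d1 - d0) * coords / (n_px - 1)
            sl = (slice(lo, hi), slice(None))
            s_maps = [prof[lo:hi, None]
                      * np.array([sense(d) for d in depth_of_col])[None, :]
                      for sense in senses]
            sub_shape = (hi - lo, n_px)
        s_maps = [(m * (1.0 - params.static_background_fraction)
                   ).astype(np.float32) for m in s_maps]
        if params.vessel_shadow_scale:
            # wavelength-dependent absorption shadow of the blood analog
            for i, o in enumerate(optics_list):
                kappa = (params.vessel_shadow_scale
                         * blood_absorption_contrast(o.wavelength_nm))
                shadows[i][sl] *= 1.0 - kappa * s_maps[i]
        if not params.flow_on or all(float(m.max()) == 0.0 for m in s_maps):
            continue  # static channel: shadow applies, no dynamics
        filters = [_field_filter(sub_shape, g) for g in grains]
        # dynamic states are channel-independent (see generate_session)
        states = [np.fft.ifft2(_randn_complex(rng, sub_shape) * h) / nrm
                  for (h, nrm) in filters]
        vessels.append({
            "slice": sl,
            "sqrt_s": [np.sqrt(m) for m in s_maps],
            "sqrt_1ms": [np.sqrt(1.0 - m) for m in s_maps],
            "filters": filters,
            "states": states,
            "shape": sub_shape,
        })

    gain = params.background_level * (2 ** params.bit_depth - 1)
    envelope = np.full((n_rows, n_px), gain, dtype=np.float32)
    if params.illumination_gradient:
        ramp = (coords / (n_px - 1) - 0.5) * params.illumination_gradient
        envelope *= (1.0 + ramp[None, :]).astype(np.float32)

    innov_sub = [math.sqrt(1.0 - r * r) for r in rho_sub]
    innov_gap = [math.sqrt(1.0 - r * r) for r in rho_gap]
    all_frames = [np.empty((params.n_frames, n_rows, n_px), dtype=np.uint16)
                  for _ in range(n_wl)]
    for t in range(params.n_frames):
        imgs = [s.copy() for s in int_statics]
        for ves in vessels:
            for i in range(n_wl):
                h, nrm = ves["filters"][i]
                # dynamic innovations are independent across channels
                fresh = np.fft.ifft2(
                    _randn_complex(rng, (n_sub + 1, *ves["shape"])) * h,
                    axes=(-2, -1)) / nrm
                st_part = ves["sqrt_1ms"][i] * statics[i][ves["slice"]]
                acc = np.zeros(ves["shape"], dtype=np.float32)
                state = ves["states"][i]
                for k in range(n_sub):
                    state = rho_sub[i] * state + innov_sub[i] * fresh[k]
                    acc += np.abs(st_part + ves["sqrt_s"][i] * state) ** 2
                imgs[i][ves["slice"]] = acc / n_sub
                # keep decorrelating between exposures
                ves["states"][i] = (rho_gap[i] * state
                                    + innov_gap[i] * fresh[n_sub])
        for i in range(n_wl):
            counts = imgs[i] * envelope * shadows[i]
            if params.shot_noise:
                # Gaussian approximation to shot noise; background means are
                # thousands of counts, indistinguishable from Poisson there
                counts = counts + np.sqrt(counts) * rng.standard_normal(
                    counts.shape, dtype=np.float32)
            all_frames[i][t] = np.clip(np.round(counts), 0,
                                       MAX_16BIT).astype(np.uint16)

    return [
        ImageStack(
            frames=all_frames[i],
            wavelength_nm=optics_list[i].wavelength_nm,
            exposure_s=params.exposure_s,
            frame_period_s=params.frame_period_s,
            pixel_pitch_um=pixel_pitch_um,
            metadata={
                "phantom_kind": phantom.kind,
                "seed": seed,
                "grain_px": grains[i],
                "tau_c_s": taus[i],
                "n_sub": n_sub,
                "flow_speed_mm_s": phantom.flow_speed_mm_s,
            },
        )
        for i in range(n_wl)
    ]


def generate_calibration_stack(
    depth_start_mm: float = 0.5,
    depth_end_mm: float = 2.5,
    optics: OpticsConfig | None = None,
    params: SpeckleModelParams | None = None,
    seed: int = 0,
    width_mm: float = 1.0,
    field_of_view_mm: float = 20.0,
    flow_speed_mm_s: float = 23.0,
) -> tuple[ImageStack, CalibrationCurve]:
    """Sloped-channel calibration stack plus its position-to-depth map.

    The returned affine curve maps column index to channel depth and hits
    the configured end depths exactly at the first and last column.
    """
    optics = optics or OpticsConfig(wavelength_nm=850)
    params = params or SpeckleModelParams()
    n_rows = params.frame_rows or params.frame_px
    # center the channel in the (possibly shorter) row extent
    center_mm = (field_of_view_mm * n_rows) / (2.0 * params.frame_px)
    phantom = PhantomSpec(
        kind="calibration_slope",
        vessels=[Vessel(center_mm, width_mm,
                        depth_range_mm=(depth_start_mm, depth_end_mm))],
        flow_speed_mm_s=flow_speed_mm_s,
        field_of_view_mm=field_of_view_mm)
    stack = generate_stack(phantom, optics, params, seed=seed)
    n_px = params.frame_px
    slope = (depth_end_mm - depth_start_mm) / (n_px - 1)
    curve = CalibrationCurve(d0=depth_start_mm, slope=slope,
                             valid_range=(0.0, float(n_px - 1)))
    stack.metadata["calibration_curve"] = {
        "d0": depth_start_mm, "slope": slope,
        "valid_range": (0.0, float(n_px - 1))}
    return stack, curve


def generate_calibration_pair(
    depth_start_mm: float = 0.5,
    depth_end_mm: float = 2.5,
    optics: OpticsConfig | None = None,
    params: SpeckleModelParams | None = None,
    seed: int = 0,
    **kwargs,
) -> tuple[ImageStack, ImageStack, CalibrationCurve]:
    """Calibration stack plus a pump-off reference of the same phantom.

    The reference acquisition has the flow stopped but an otherwise
    identical scene (same seed, hence the same static speckle realization).
    Ratioing the flow-on against the flow-off visibility map cancels the
    frozen static-speckle structure inside the sloped channel, which is the
    dominant uncertainty of the along-channel calibration curve; a no-flow
    reference run is standard practice when calibrating perfusion imagers.
    """
    import dataclasses

    params = params or SpeckleModelParams()
    stack, curve = generate_calibration_stack(
        depth_start_mm, depth_end_mm, optics=optics, params=params,
        seed=seed, **kwargs)
    reference, _ = generate_calibration_stack(
        depth_start_mm, depth_end_mm, optics=optics,
        params=dataclasses.replace(params, flow_on=False),
        seed=seed, **kwargs)
    reference.metadata["flow"] = "off"
    return stack, reference, curve
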