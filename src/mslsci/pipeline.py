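"""End-to-end workflow: stacks -> maps -> profiles -> depths.

The measurement chain for one acquisition session is:

1. per wavelength: temporal contrast map, visibility-ratio map, and the
   ``1/Vr**2`` line profile across the vessels;
2. per configured wavelength pair: the mixed-stack (difference) versions of
   the same outputs;
3. against a sloped-channel calibration stack: absolute depth estimates for
   every detected vessel peak.

Vessel peaks are reported when their elevation above the background exceeds
``PEAK_ELEVATION_FLOOR`` times the baseline.  The floor is calibrated on the
synthetic phantom study so that it separates the deep-vessel response of the
red/NIR lines from that of the blue/green lines, mirroring which
wavelength/depth combinations resolve flow in practice; see the methods
note.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field as dc_field

import numpy as np

from .contrast import VisibilityMap, temporal_contrast, visibility_ratio
from .profiles import (CalibrationCurve, DepthEstimate, LineProfile,
                       detect_peaks, extract_profile, fwhm)
from .stacks import ImageStack

__all__ = [
    "PEAK_ELEVATION_FLOOR",
    "PROFILE_SMOOTH_PX",
    "VesselAnalysis",
    "CalibrationTable",
    "analyze_stack",
    "flow_index",
    "intensity_scale",
    "calibration_flow_curve",
    "calibration_elevation_curve",
    "pool_flow_curves",
    "build_calibration",
    "depths_from_calibration",
]

#: Vessel detection floor: a peak counts as detected when its prominence
#: exceeds this fraction of the profile baseline.
PEAK_ELEVATION_FLOOR = 0.6

#: Moving-average width (px) applied along extracted profiles; roughly the
#: speckle grain so sub-vessel noise is suppressed without eroding peaks.
PROFILE_SMOOTH_PX = 5


@dataclass
class VesselAnalysis:
    """Single-stack analysis bundle: maps, profiles, and detected peaks.

    ``profile`` is smoothed for robust peak detection; ``profile_raw`` keeps
    the unsmoothed values so peak amplitudes can be measured without the
    smoothing dilution (the vessel center is wider than the analysis window,
    so the raw center value carries the full depth-dependent elevation).
    """

    vmap: VisibilityMap
    profile: LineProfile
    profile_raw: LineProfile
    baseline: float
    peak_positions: np.ndarray
    peak_elevations: np.ndarray
    temporal_k: np.ndarray | None = None
    depths: list[DepthEstimate] = dc_field(default_factory=list)

    def peak_fwhm(self, position: float) -> float:
        return fwhm(self.profile, position)


def analyze_stack(stack: ImageStack, window_px: int = 7,
                  epsilon: float = 1e-6, axis: str = "col",
                  with_temporal: bool = False,
                  smooth_px: int = PROFILE_SMOOTH_PX,
                  elevation_floor: float = PEAK_ELEVATION_FLOOR,
                  extremes: str = "mean_of_extremes") -> VesselAnalysis:
    """Visibility-ratio map, ``1/Vr**2`` profile, and vessel peaks."""
    vmap = visibility_ratio(stack, window_px=window_px, epsilon=epsilon,
                            extremes=extremes)
    profile = extract_profile(vmap.inv_vr2, axis=axis, mask=vmap.mask,
                              smooth_px=smooth_px)
    raw = extract_profile(vmap.inv_vr2, axis=axis, mask=vmap.mask)
    baseline = float(np.median(raw.values))
    # two-stage detection: loose prominence proposes candidates on the
    # smoothed profile, the precise raw center elevation classifies them
    cand = detect_peaks(profile, min_prominence=0.5 * elevation_floor
                        * baseline)
    cand_elev = np.array([
        float(raw.values[np.abs(raw.positions - p) <= 2.0].mean())
        / baseline - 1.0 for p in cand])
    keep = cand_elev >= elevation_floor
    peaks, elev = cand[keep], cand_elev[keep]
    kmap = temporal_contrast(stack).values if with_temporal else None
    return VesselAnalysis(vmap=vmap, profile=profile, profile_raw=raw,
                          baseline=baseline, peak_positions=peaks,
                          peak_elevations=elev, temporal_k=kmap)


def _isotonic_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit of a non-increasing sequence."""
    y = np.asarray(y, dtype=float)
    vals = list(y)
    wts = [1.0] * len(vals)
    i = 0
    while i < len(vals) - 1:
        if vals[i] < vals[i + 1]:  # violates non-increasing order
            pooled = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) \
                / (wts[i] + wts[i + 1])
            vals[i] = pooled
            wts[i] += wts[i + 1]
            del vals[i + 1], wts[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    return np.repeat(vals, np.asarray(wts, dtype=int))


def intensity_scale(stack: ImageStack) -> float:
    """Robust global intensity scale: median of the temporal-mean map.

    The median ignores the minority of pixels darkened by vessel absorption
    shadows, so the same scale is recovered from frames with very different
    vessel coverage.
    """
    return float(np.median(stack.astype_float().mean(axis=0)))


def flow_index(on: ImageStack, off: ImageStack | None,
               rows: np.ndarray | slice, cols: np.ndarray | slice,
               scale: float | None = None) -> float:
    """Shot-corrected temporal flow variance over a patch.

    The statistic is ``mean(Var_t[I] - shot floor) / (mean(<I_ref>_t) *
    scale)``.  With a pump-off reference acquisition (``off``), the
    reference variance supplies the shot-noise floor and the reference
    intensity cancels the frozen static-speckle envelope, which enters the
    flow variance linearly -- essential when the patch holds only a few
    speckle grains.  Without a reference, the Poisson floor (variance equal
    to the mean count) is subtracted analytically and the patch's own mean
    serves as the envelope estimate, adequate for patches long enough to
    average many grains.  The result grows monotonically with the fraction
    of detected light modulated by the flow, making it the quantity of
    choice for absolute depth calibration (the visibility ratio, a ratio of
    window extremes, cannot be averaged free of the frozen speckle).
    """
    fon = on.astype_float()[:, rows, cols]
    var_on = fon.var(axis=0).mean()
    if off is None:
        ref_mean = fon.mean(axis=0)
        dvar = var_on - ref_mean.mean()  # analytic Poisson shot floor
        scale = intensity_scale(on) if scale is None else scale
    else:
        foff = off.astype_float()[:, rows, cols]
        dvar = var_on - foff.var(axis=0).mean()
        ref_mean = foff.mean(axis=0)
        scale = intensity_scale(off) if scale is None else scale
    denom = float(ref_mean.mean()) * scale
    if denom <= 0:
        raise ValueError("reference intensity is zero over the patch")
    return float(dvar / denom)


def calibration_flow_curve(
    on: ImageStack,
    off: ImageStack,
    channel_band: tuple[int, int],
    col_halfwidth: int = 12,
    col_step: int = 2,
    row_halfwidth: int = 4,
    isotonic: bool = True,
) -> LineProfile:
    """Flow index along the sloped calibration channel, isotonically fitted.

    Samples the flow index in overlapping column windows along the channel
    (rows restricted to the channel core, where the flow fraction is full),
    then enforces the physical monotonicity -- a deeper channel modulates
    less light -- by a non-increasing isotonic regression.  The result is a
    position-indexed lookup curve for absolute depth assignment.
    """
    b0, b1 = channel_band
    center = (b0 + b1) // 2
    rows = slice(center - row_halfwidth, center + row_halfwidth + 1)
    n_cols = on.shape[1]
    scale = intensity_scale(off)
    positions, values = [], []
    for x in range(col_halfwidth, n_cols - col_halfwidth, col_step):
        cols = slice(x - col_halfwidth, x + col_halfwidth + 1)
        positions.append(float(x))
        values.append(flow_index(on, off, rows, cols, scale=scale))
    values = np.asarray(values)
    if isotonic:
        values = _isotonic_decreasing(values)
    return LineProfile(positions=np.asarray(positions), values=values,
                       axis="col", band_px=2 * row_halfwidth + 1, units="px")


def pool_flow_curves(curves: Sequence[LineProfile]) -> LineProfile:
    """Average repeated calibration acquisitions into one monotone curve.

    Each acquisition of the calibration phantom freezes a different static
    speckle realization; pooling several (e.g. after laterally translating
    the phantom, the usual way to refresh the pattern) beats down the
    frozen-pattern noise before the monotone fit.
    """
    if not curves:
        raise ValueError("no curves to pool")
    pos = curves[0].positions
    for c in curves[1:]:
        if not np.array_equal(c.positions, pos):
            raise ValueError("curves must share sampling positions")
    mean_vals = np.mean([c.values for c in curves], axis=0)
    return LineProfile(positions=pos,
                       values=_isotonic_decreasing(mean_vals),
                       axis=curves[0].axis, band_px=curves[0].band_px,
                       units=curves[0].units)


def calibration_elevation_curve(
    vmap_on: VisibilityMap,
    vmap_off: VisibilityMap,
    channel_band: tuple[int, int],
    col_halfwidth: int = 12,
    col_step: int = 2,
    row_halfwidth: int = 2,
) -> LineProfile:
    """``1/Vr**2`` elevation along the sloped channel, against the pump-off
    reference of the same scene.

    The pixelwise ratio of flow-on to flow-off ``1/Vr**2`` suppresses the
    frozen static-speckle pattern; averaging over the channel core (where
    the analysis window sits fully inside the channel, as at a vessel-peak
    center) and normalizing to the off-channel ratio gives the relative
    elevation a vessel of that depth would show.
    """
    b0, b1 = channel_band
    center = (b0 + b1) // 2
    good = vmap_on.mask & vmap_off.mask & (vmap_off.inv_vr2 > 0)
    ratio = np.where(good,
                     vmap_on.inv_vr2 / np.maximum(vmap_off.inv_vr2, 1e-30),
                     np.nan)
    rows = np.arange(ratio.shape[0])
    in_rows = np.abs(rows - center) <= row_halfwidth
    out_rows = np.abs(rows - center) > (b1 - b0) * 0.75 + row_halfwidth
    if not out_rows.any():
        raise ValueError("no off-channel rows to normalize against")
    bg = float(np.nanmean(ratio[out_rows, :]))
    positions, values = [], []
    for x in range(col_halfwidth, ratio.shape[1] - col_halfwidth, col_step):
        v = np.nanmean(ratio[in_rows, x - col_halfwidth:x + col_halfwidth
                             + 1])
        positions.append(float(x))
        values.append(float(v) / bg - 1.0)
    return LineProfile(positions=np.asarray(positions),
                       values=np.asarray(values), axis="col",
                       band_px=2 * row_halfwidth + 1, units="px")


@dataclass
class CalibrationTable:
    """Pooled calibration of two depth-sensitive statistics.

    For each position along the sloped channel the table holds the flow
    index and the ``1/Vr**2`` elevation (both isotonically decreasing in
    depth) together with their pooled standard errors, plus the affine
    position-to-depth curve.  Two statistics are kept because their
    sensitivities complement each other: the flow index is the more precise
    shallow metric at moderate modulation but saturates where the modulated
    fraction is high, exactly where the visibility elevation is steepest.
    """

    positions: np.ndarray
    flow: np.ndarray
    flow_sigma: np.ndarray
    elev: np.ndarray
    elev_sigma: np.ndarray
    curve: CalibrationCurve

    def _invert(self, values: np.ndarray, sigma: np.ndarray,
                measured: float, slope_halfwin_px: float = 20.0
                ) -> tuple[float, float]:
        """Invert one monotone statistic; returns (depth, depth sigma)."""
        j = int(np.argmin(np.abs(values - measured)))
        x = self.positions[j]
        lo = float(np.interp(x - slope_halfwin_px, self.positions, values))
        hi = float(np.interp(x + slope_halfwin_px, self.positions, values))
        dstat_dmm = abs(hi - lo) / (2 * slope_halfwin_px
                                    * abs(self.curve.slope))
        stat_sigma = max(float(sigma[j]), 1e-12)
        if dstat_dmm <= 0:
            return float(self.curve(x)), float("inf")
        return float(self.curve(x)), stat_sigma / dstat_dmm


def build_calibration(
    acquisitions: Sequence[tuple[ImageStack, ImageStack]],
    channel_band: tuple[int, int],
    curve: CalibrationCurve,
    window_px: int = 7,
) -> CalibrationTable:
    """Pool repeated calibration acquisitions into a lookup table.

    Each acquisition is a (flow-on, pump-off) pair of the sloped-channel
    phantom; repeated acquisitions (e.g. after laterally translating the
    phantom) freeze different static speckle realizations, so pooling beats
    down the frozen-pattern noise.  Standard errors are taken from the
    between-acquisition scatter.
    """
    if not acquisitions:
        raise ValueError("no calibration acquisitions")
    flows, elevs = [], []
    positions = None
    for on, off in acquisitions:
        fc = calibration_flow_curve(on, off, channel_band, isotonic=False)
        vm_on = visibility_ratio(on, window_px=window_px)
        vm_off = visibility_ratio(off, window_px=window_px)
        ec = calibration_elevation_curve(vm_on, vm_off, channel_band)
        if positions is None:
            positions = fc.positions
        flows.append(np.interp(positions, fc.positions, fc.values))
        elevs.append(np.interp(positions, ec.positions, ec.values))
    flows = np.asarray(flows)
    elevs = np.asarray(elevs)
    k = flows.shape[0]
    sem = 1.0 / math.sqrt(k) if k > 1 else 1.0
    flow_sigma = (flows.std(axis=0, ddof=1) * sem if k > 1
                  else 0.05 * np.abs(flows[0]) + 1e-12)
    elev_sigma = (elevs.std(axis=0, ddof=1) * sem if k > 1
                  else 0.1 * np.abs(elevs[0]) + 1e-12)
    return CalibrationTable(
        positions=positions,
        flow=_isotonic_decreasing(flows.mean(axis=0)),
        flow_sigma=flow_sigma,
        elev=_isotonic_decreasing(elevs.mean(axis=0)),
        elev_sigma=elev_sigma,
        curve=curve)


def depths_from_calibration(
    target_on: ImageStack,
    analysis: VesselAnalysis,
    table: CalibrationTable,
    target_off: ImageStack | None = None,
    max_residual: float = 0.25,
    col_halfwidth: int = 4,
    target_flow_relerr: float = 0.05,
    target_elev_err: float = 0.08,
) -> list[DepthEstimate]:
    """Assign an absolute depth to each detected vessel peak.

    For every peak of the ``1/Vr**2`` profile, two depth-sensitive
    measurements of the vessel -- its flow index over the full vessel length
    and its profile elevation -- are inverted on the pooled calibration
    table, and the two depths are fused by inverse-variance weighting.  The
    per-statistic variances combine the calibration table's standard error
    with the stated target measurement errors, each divided by the local
    slope of the statistic; where one statistic saturates (slope near zero)
    its weight vanishes and the other takes over.
    """
    out: list[DepthEstimate] = []
    n_cols = target_on.shape[1]
    for pk, elev in zip(analysis.peak_positions, analysis.peak_elevations):
        c = int(round(pk))
        cols = slice(max(0, c - col_halfwidth),
                     min(n_cols, c + col_halfwidth + 1))
        f_t = flow_index(target_on, target_off, slice(None), cols)

        d_f, s_f = table._invert(
            table.flow,
            np.hypot(table.flow_sigma, target_flow_relerr * abs(f_t)), f_t)
        d_e, s_e = table._invert(
            table.elev, np.hypot(table.elev_sigma, target_elev_err), elev)
        w_f = 1.0 / s_f ** 2 if np.isfinite(s_f) else 0.0
        w_e = 1.0 / s_e ** 2 if np.isfinite(s_e) else 0.0
        if w_f + w_e == 0:
            depth, sigma = d_f, float("inf")
        else:
            depth = (w_f * d_f + w_e * d_e) / (w_f + w_e)
            sigma = math.sqrt(1.0 / (w_f + w_e))
        in_range = (table.flow.min() <= f_t <= table.flow.max()
                    or table.elev.min() <= elev <= table.elev.max())
        residual = abs(d_f - d_e) / max(depth, 1e-9)
        out.append(DepthEstimate(
            peak_position=float(pk),
            depth_mm=float(depth),
            elevation=float(elev),
            residual=float(residual),
            low_confidence=bool(not in_range or sigma > max_residual)))
    analysis.depths = out
    return out
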