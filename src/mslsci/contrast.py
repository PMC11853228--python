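"""Speckle contrast and visibility-ratio engines.

Two statistics are computed from raw speckle stacks:

* the speckle contrast ``K = sigma / <I>`` (population standard deviation
  over the mean), either per pixel over time (temporal contrast) or over a
  centered spatial window (spatial contrast); and

* the visibility ratio ``Vr = (<Imax> - <Imin>) / <I>_st`` over a sliding
  spatial window (default 7x7): per frame the window maximum and minimum are
  extracted, ``<Imax>`` and ``<Imin>`` are their temporal means, and
  ``<I>_st`` is the mean over the whole space-time block.  ``1/Vr**2`` is the
  depth metric: subsurface flow lowers the local visibility, so its inverse
  square peaks over vessels.

Sliding windows use stride 1, the result is assigned to the window center,
and border pixels where the full window does not fit are masked invalid
rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .stacks import ImageStack

__all__ = [
    "ContrastMap",
    "VisibilityMap",
    "temporal_contrast",
    "spatial_contrast",
    "visibility_ratio",
    "inverse_vr2",
]


@dataclass
class ContrastMap:
    """Per-pixel speckle contrast K with its provenance."""

    values: np.ndarray
    mask: np.ndarray  # True where K is defined
    method: Literal["temporal", "spatial"]
    window_px: int | None = None
    source_wavelength_nm: float | None = None

    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out


@dataclass
class VisibilityMap:
    """Visibility ratio Vr and its inverse-square depth metric."""

    vr: np.ndarray
    inv_vr2: np.ndarray
    mask: np.ndarray           # True where the full window fit and mean > 0
    clamped: np.ndarray        # True where Vr < epsilon was regularized
    window_px: int = 7
    epsilon: float = 1e-6
    source_wavelength_nm: float | None = None
    metadata: dict = field(default_factory=dict)


def _check_window(window_px: int, shape: tuple[int, int]) -> None:
    if window_px % 2 == 0 or window_px < 3:
        raise ValueError("window_px must be odd and >= 3")
    if window_px > min(shape):
        raise ValueError(
            f"window {window_px} does not fit inside frame {shape}")


def _border_mask(shape: tuple[int, int], window_px: int) -> np.ndarray:
    half = window_px // 2
    mask = np.zeros(shape, dtype=bool)
    mask[half:shape[0] - half, half:shape[1] - half] = True
    return mask


def temporal_contrast(stack: ImageStack) -> ContrastMap:
    """Per-pixel K over frames: population sigma over temporal mean.

    Pixels whose temporal mean is zero are masked.  Invariant under uniform
    intensity scaling and under frame reordering.
    """
    if stack.n_frames < 2:
        raise ValueError("temporal contrast needs at least 2 frames")
    frames = stack.astype_float()
    mean = frames.mean(axis=0)
    sigma = frames.std(axis=0)  # population (divide-by-N) convention
    valid = mean > 0
    k = np.zeros_like(mean)
    np.divide(sigma, mean, out=k, where=valid)
    return ContrastMap(values=k, mask=valid, method="temporal",
                       source_wavelength_nm=stack.wavelength_nm)


def spatial_contrast(frame: np.ndarray, window_px: int = 7) -> ContrastMap:
    """K over a centered window_px x window_px neighborhood of one frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    _check_window(window_px, frame.shape)
    mean = ndimage.uniform_filter(frame, size=window_px)
    mean_sq = ndimage.uniform_filter(frame * frame, size=window_px)
    var = np.maximum(mean_sq - mean * mean, 0.0)
    valid = _border_mask(frame.shape, window_px) & (mean > 0)
    k = np.zeros_like(mean)
    np.divide(np.sqrt(var), mean, out=k, where=valid)
    return ContrastMap(values=k, mask=valid, method="spatial",
                       window_px=window_px)


def visibility_ratio(
    stack: ImageStack,
    window_px: int = 7,
    epsilon: float = 1e-6,
    extremes: Literal["mean_of_extremes", "extremes_of_mean"]
        = "mean_of_extremes",
) -> VisibilityMap:
    """Sliding-window visibility ratio of a speckle stack.

    ``extremes`` selects how the angle brackets on Imax/Imin are read:
    ``mean_of_extremes`` (default) extracts the window extremes in every
    frame and averages them over time, preserving the temporal speckle
    information; ``extremes_of_mean`` takes the extremes of the temporally
    averaged frame.
    """
    if stack.n_frames < 2:
        raise ValueError("visibility ratio needs at least 2 frames")
    frames = stack.astype_float()
    _check_window(window_px, stack.shape)

    if extremes == "mean_of_extremes":
        mx = np.zeros(stack.shape)
        mn = np.zeros(stack.shape)
        for f in frames:  # per-frame window extremes, then temporal mean
            mx += ndimage.maximum_filter(f, size=window_px)
            mn += ndimage.minimum_filter(f, size=window_px)
        mx /= stack.n_frames
        mn /= stack.n_frames
    elif extremes == "extremes_of_mean":
        tmean = frames.mean(axis=0)
        mx = ndimage.maximum_filter(tmean, size=window_px)
        mn = ndimage.minimum_filter(tmean, size=window_px)
    else:
        raise ValueError(f"unknown extremes mode {extremes!r}")

    # space-time block mean: spatial window mean of the temporal mean frame
    block_mean = ndimage.uniform_filter(frames.mean(axis=0), size=window_px)
    valid = _border_mask(stack.shape, window_px) & (block_mean > 0)
    vr = np.zeros_like(block_mean)
    np.divide(mx - mn, block_mean, out=vr, where=valid)

    vmap = VisibilityMap(
        vr=vr, inv_vr2=np.empty(0), mask=valid,
        clamped=np.zeros_like(valid), window_px=window_px, epsilon=epsilon,
        source_wavelength_nm=stack.wavelength_nm,
        metadata={"extremes": extremes},
    )
    vmap.inv_vr2, vmap.clamped = _inv_vr2_arrays(vr, valid, epsilon)
    return vmap


def _inv_vr2_arrays(vr: np.ndarray, mask: np.ndarray,
                    epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    clamped = mask & (vr < epsilon)
    out = np.zeros_like(vr)
    safe = np.maximum(vr, epsilon)
    np.divide(1.0, safe * safe, out=out, where=mask)
    return out, clamped


def inverse_vr2(vmap: VisibilityMap, epsilon: float | None = None
                ) -> np.ndarray:
    """Elementwise 1/max(Vr, epsilon)^2; updates the map's clamp flags."""
    eps = vmap.epsilon if epsilon is None else epsilon
    inv, clamped = _inv_vr2_arrays(vmap.vr, vmap.mask, eps)
    vmap.inv_vr2 = inv
    vmap.clamped = clamped
    vmap.epsilon = eps
    return inv
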