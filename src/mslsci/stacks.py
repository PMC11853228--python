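"""The raw speckle movie: a wavelength-tagged time series of intensity frames."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]

MAX_16BIT = 65535


@dataclass
class ImageStack:
    """A stack of co-registered 2-D intensity frames from one laser line.

    ``frames`` has shape (n_frames, rows, cols) with non-negative intensities
    in 16-bit camera range.  ``pixel_pitch_um`` is the object-plane pixel
    pitch (field of view / frame width), used to convert lateral positions to
    millimetres.  All grids in the package are indexed row-major, 0-based,
    as (row, col).
    """

    frames: np.ndarray
    wavelength_nm: float
    exposure_s: float = 0.010
    frame_period_s: float = 1.0 / 55.0
    pixel_pitch_um: float = 78.125  # 20 mm field of view over 256 px
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.frames.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if np.issubdtype(self.frames.dtype, np.floating):
            if not np.isfinite(self.frames).all():
                raise ValueError("frame intensities must be finite")
        if self.frames.min() < 0 or self.frames.max() > MAX_16BIT:
            raise ValueError("intensities must lie in [0, 65535]")
        for name in ("wavelength_nm", "exposure_s", "frame_period_s",
                     "pixel_pitch_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def px_per_mm(self) -> float:
        return 1000.0 / self.pixel_pitch_um

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.frames, dtype=np.float64)
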