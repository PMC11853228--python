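"""Readers and writers: TIFF stacks, float maps, CSV profiles, JSON sidecars.

Every artefact is written as the image payload plus a ``<name>.meta.json``
sidecar carrying acquisition metadata (wavelength, exposure, window,
epsilon, mask convention, configuration hash) so that results remain
self-describing and reproducible.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile

from .contrast import ContrastMap, VisibilityMap
from .profiles import CorrelationResult, LineProfile
from .stacks import ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "write_map",
    "read_map",
    "write_profile_csv",
    "read_profile_csv",
    "write_correlation_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_sidecar(path: Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    _sidecar(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=default))


def read_stack(path, wavelength_nm: float | None = None,
               **overrides) -> ImageStack:
    """Read a multi-page grayscale TIFF stack (16-bit) into an ImageStack.

    Metadata comes from the ``.meta.json`` sidecar when present; keyword
    overrides win.  Mixed bit depths or color pages raise with the page
    index named.
    """
    path = Path(path)
    try:
        tif = tifffile.TiffFile(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: not a readable TIFF ({exc})") from exc
    with tif:
        if not tif.pages:
            raise ValueError(f"{path}: empty TIFF, no pages")
        pages = []
        first = None
        for i, page in enumerate(tif.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(
                    f"{path}: page {i} is not grayscale "
                    f"(shape {arr.shape})")
            if first is None:
                first = (arr.shape, arr.dtype)
            elif arr.shape != first[0]:
                raise ValueError(
                    f"{path}: page {i} dimensions {arr.shape} differ from "
                    f"page 0 {first[0]}")
            elif arr.dtype != first[1]:
                raise ValueError(
                    f"{path}: page {i} dtype {arr.dtype} differs from "
                    f"page 0 {first[1]}")
            pages.append(arr)
    frames = np.stack(pages)

    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    kwargs = {
        "wavelength_nm": wavelength_nm or meta.get("wavelength_nm"),
        "exposure_s": meta.get("exposure_s", 0.010),
        "frame_period_s": meta.get("frame_period_s", 1.0 / 55.0),
        "pixel_pitch_um": meta.get("pixel_pitch_um", 78.125),
    }
    kwargs.update(overrides)
    if kwargs["wavelength_nm"] is None:
        raise ValueError(
            f"{path}: wavelength not in sidecar; pass wavelength_nm")
    return ImageStack(frames=frames, metadata=meta.get("metadata", {}),
                      **kwargs)


def write_stack(stack: ImageStack, path) -> Path:
    """Write the stack as multi-page TIFF plus metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = stack.frames
    if not np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames)
    _write_sidecar(path, {
        "wavelength_nm": stack.wavelength_nm,
        "exposure_s": stack.exposure_s,
        "frame_period_s": stack.frame_period_s,
        "pixel_pitch_um": stack.pixel_pitch_um,
        "n_frames": stack.n_frames,
        "shape": list(stack.shape),
        "metadata": stack.metadata,
    })
    return path


def write_map(obj: ContrastMap | VisibilityMap | np.ndarray, path,
              **extra_meta) -> Path:
    """Write a 2-D result map as 32-bit float TIFF plus sidecar.

    Invalid (masked) pixels are stored as NaN.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(extra_meta)
    if isinstance(obj, ContrastMap):
        arr = obj.masked()
        meta.update(method=obj.method, window_px=obj.window_px,
                    wavelength_nm=obj.source_wavelength_nm,
                    mask_convention="NaN marks invalid pixels")
    elif isinstance(obj, VisibilityMap):
        arr = np.where(obj.mask, obj.inv_vr2, np.nan)
        meta.update(quantity="inv_vr2", window_px=obj.window_px,
                    epsilon=obj.epsilon,
                    wavelength_nm=obj.source_wavelength_nm,
                    n_clamped=int(obj.clamped.sum()),
                    mask_convention="NaN marks invalid pixels",
                    **obj.metadata)
    else:
        arr = np.asarray(obj, dtype=np.float32)
    tifffile.imwrite(path, arr.astype(np.float32))
    _write_sidecar(path, meta)
    return path


def read_map(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arr, meta


def write_profile_csv(profile: LineProfile, path, source: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"# axis={profile.axis} band_px={profile.band_px} "
                         f"units={profile.units} source={source}"])
        writer.writerow([f"position_{profile.units}", "value"])
        for p, v in zip(profile.positions, profile.values):
            writer.writerow([f"{p:.6g}", f"{v:.8g}"])
    return path


def read_profile_csv(path) -> LineProfile:
    path = Path(path)
    positions, values = [], []
    axis, band = "col", 1
    with path.open() as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0].startswith(
                    "position"):
                if row and row[0].startswith("#"):
                    for token in row[0][1:].split():
                        if token.startswith("axis="):
                            axis = token[5:]
                        elif token.startswith("band_px="):
                            band = int(token[8:])
                continue
            positions.append(float(row[0]))
            values.append(float(row[1]))
    return LineProfile(positions=np.array(positions),
                       values=np.array(values), axis=axis, band_px=band)


def write_correlation_csv(result: CorrelationResult, path,
                          source: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"# peak_lag={result.peak_lag} "
                         f"peak_value={result.peak_value:.6g} "
                         f"fwhm_px={result.fwhm_px:.6g} source={source}"])
        writer.writerow(["lag", "coefficient"])
        for lag, c in zip(result.lags, result.coefficients):
            writer.writerow([int(lag), f"{c:.8g}"])
    return path
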