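"""Core image container and file I/O.

Every stage of the pipeline exchanges :class:`SEMImage` objects: a 2-D
intensity grid plus the physical pixel pitch in nanometres and a free-form
provenance record.  Images are written as single-channel TIFF with the pixel
size recorded in the resolution tags and a JSON sidecar of parameters.

Coordinate convention (used everywhere in this package): row-major, 0-based
indices, origin at the top-left corner, pixel centres at integer coordinates;
physical position = index * pixel_size_nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but carries no usable signal
    (e.g. a constant image where contrast is required)."""


@dataclass
class SEMImage:
    """A single-channel micrograph with physical calibration.

    Parameters
    ----------
    pixels
        2-D array of finite intensities, ``M`` rows by ``N`` columns.
    pixel_size_nm
        Physical pitch of one pixel, in nanometres.  Must be positive.
    meta
        Free-form provenance record (generation parameters, processing
        history).  Serialised to the JSON sidecar on save.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if not (self.pixel_size_nm > 0):
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def fov_nm(self) -> tuple[float, float]:
        """Physical extent (height_nm, width_nm) of the pixel grid."""
        m, n = self.pixels.shape
        return (m * self.pixel_size_nm, n * self.pixel_size_nm)

    def copy(self, **meta_updates: Any) -> "SEMImage":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return SEMImage(self.pixels.copy(), self.pixel_size_nm, meta)


def dose_ratio(fine_pixel_nm: float, coarse_pixel_nm: float) -> float:
    """Electron-exposure ratio for imaging one fixed field of view at two
    pixel pitches with equal dwell time per pixel.

    Total dose scales with the number of scanned pixels, i.e. with the inverse
    square of the pitch: halving the pixel size quadruples the exposure.
    """
    if fine_pixel_nm <= 0 or coarse_pixel_nm <= 0:
        raise ValueError("pixel sizes must be positive")
    return (coarse_pixel_nm / fine_pixel_nm) ** 2


def save_tiff(image: SEMImage, path: str | Path, *, bitdepth: int = 16) -> Path:
    """Write a 16-bit (or float32) single-channel TIFF plus a JSON sidecar.

    Pixel size is recorded in the TIFF X/Y resolution tags in pixels per
    centimetre, and verbatim (in nm) in both the ImageDescription and the
    sidecar, so a round-trip restores it exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px = image.pixels
    if bitdepth == 16:
        lo, hi = float(px.min()), float(px.max())
        scale = (hi - lo) or 1.0
        data = np.round((px - lo) / scale * 65535).astype(np.uint16)
        quant = {"offset": lo, "scale": scale / 65535.0}
    elif bitdepth == 32:
        data = px.astype(np.float32)
        quant = {"offset": 0.0, "scale": 1.0}
    else:
        raise ValueError("bitdepth must be 16 or 32")
    px_per_cm = 1e7 / image.pixel_size_nm
    desc = json.dumps({"pixel_size_nm": image.pixel_size_nm, "quant": quant})
    tifffile.imwrite(
        path,
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        description=desc,
        photometric="minisblack",
    )
    sidecar = {"pixel_size_nm": image.pixel_size_nm, "quant": quant, "meta": _jsonable(image.meta)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_tiff(path: str | Path) -> SEMImage:
    """Read an image written by :func:`save_tiff`, restoring pixel size and meta."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(np.float64)
        desc = page.tags.get("ImageDescription")
        info: dict[str, Any] = {}
        if desc is not None:
            try:
                info = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                info = {}
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta: dict[str, Any] = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        info.setdefault("pixel_size_nm", sidecar.get("pixel_size_nm"))
        info.setdefault("quant", sidecar.get("quant"))
        meta = sidecar.get("meta", {})
    quant = info.get("quant", {"offset": 0.0, "scale": 1.0})
    pixels = data * quant["scale"] + quant["offset"]
    pixel_size = info.get("pixel_size_nm")
    if pixel_size is None:
        raise ValueError(f"no pixel size recorded for {path}")
    return SEMImage(pixels, float(pixel_size), meta)


def save_png_preview(image: SEMImage, path: str | Path) -> Path:
    """8-bit contrast-stretched PNG for quick visual inspection."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px = image.pixels
    lo, hi = np.percentile(px, [0.5, 99.5])
    if hi <= lo:
        lo, hi = float(px.min()), float(px.max()) or 1.0
    data = np.clip((px - lo) / (hi - lo or 1.0), 0, 1)
    iio.imwrite(path, (data * 255).astype(np.uint8))
    return path


def zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalised cross-correlation of two equal-shape arrays.

    Defined as 0 when either array has zero variance (a flat patch carries no
    alignment information).
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("arrays must have the same shape")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
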