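"""Co-registration of low/high-resolution image pairs.

Pipeline: Lanczos upsampling of the low-resolution image onto the target
pixel grid, correlation-driven affine alignment (translation + rotation +
isotropic scale), then coarse-to-fine block-matching elastic refinement that
produces a dense sub-pixel displacement field.

Displacement convention: fields map fixed-image coordinates to sampling
positions in the moving image (pull/backward warping), stored as an
``(H, W, 2)`` array of ``(dy, dx)`` in pixels of the fixed image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .images import DegenerateInputError, SEMImage, zncc


# ---------------------------------------------------------------------------
# Lanczos resampling


def _lanczos_weights(n_out: int, n_in: int, factor: int, a: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) interpolation matrix for one axis.

    Output pixel i samples the input at x = (i + 0.5)/factor - 0.5 (centre
    aligned), with windowed-sinc taps of order ``a``; taps falling outside the
    grid are clamped to the edge sample.
    """
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        x = (i + 0.5) / factor - 0.5
        j0 = int(np.floor(x)) - a + 1
        for j in range(j0, j0 + 2 * a):
            t = x - j
            if abs(t) >= a:
                continue
            val = np.sinc(t) * np.sinc(t / a)
            w[i, min(max(j, 0), n_in - 1)] += val
    w /= w.sum(axis=1, keepdims=True)
    return w


def lanczos_upsample(image: SEMImage, factor: int, a: int = 3) -> SEMImage:
    """Up-sample by an integer factor with a Lanczos (windowed-sinc) kernel.

    Output dimensions are ``factor`` times the input dimensions and the pixel
    size is divided by ``factor``.  ``factor=1`` is an exact identity; the
    normalised kernel preserves constants exactly.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return image.copy()
    m, n = image.shape
    wr = _lanczos_weights(m * factor, m, factor, a)
    wc = _lanczos_weights(n * factor, n, factor, a)
    out = wr @ image.pixels @ wc.T
    meta = dict(image.meta)
    meta.setdefault("resampling", []).append({"op": "lanczos_upsample", "factor": factor, "a": a})
    return SEMImage(out, image.pixel_size_nm / factor, meta)


# ---------------------------------------------------------------------------
# Affine alignment


@dataclass
class AffineTransform:
    """Similarity transform (rotation + isotropic scale + translation).

    ``apply`` resamples a moving image so that it aligns with the fixed image:
    the output at pixel p takes the moving image's value at
    ``R(-rot)/scale @ (p - c) + c - shift`` where c is the image centre —
    i.e. the transform *moves* the image by ``shift_yx`` pixels and rotates it
    by ``rotation_deg`` about its centre.
    """

    rotation_deg: float = 0.0
    scale: float = 1.0
    shift_yx: tuple[float, float] = (0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        """2x3 matrix [A | t] of the forward map p -> A (p - c) + c + t (pixels)."""
        th = np.deg2rad(self.rotation_deg)
        lin = self.scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        if abs(np.linalg.det(lin)) <= 1e-6:
            raise ValueError("affine linear part is singular")
        return np.hstack([lin, np.asarray(self.shift_yx, dtype=float)[:, None]])

    def apply(self, image: SEMImage, order: int = 1) -> SEMImage:
        mat = self.matrix
        lin, t = mat[:, :2], mat[:, 2]
        inv = np.linalg.inv(lin)
        c = (np.array(image.shape, dtype=float) - 1) / 2
        offset = c - inv @ (c + t)
        out = ndimage.affine_transform(image.pixels, inv, offset=offset, order=order, mode="nearest")
        meta = dict(image.meta)
        meta["affine"] = {"rotation_deg": self.rotation_deg, "scale": self.scale, "shift_yx": list(self.shift_yx)}
        return SEMImage(out, image.pixel_size_nm, meta)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "matrix": self.matrix.tolist(),
            "rotation_deg": self.rotation_deg,
            "scale": self.scale,
            "shift_yx": list(self.shift_yx),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        d = json.loads(Path(path).read_text())
        return cls(d["rotation_deg"], d["scale"], tuple(d["shift_yx"]))


def _centre_crop(a: np.ndarray, margin: int) -> np.ndarray:
    m = min(margin, (min(a.shape) - 2) // 2)
    return a[m: a.shape[0] - m, m: a.shape[1] - m] if m > 0 else a


def _windowed_shift(fixed: np.ndarray, moving: np.ndarray, upsample: int = 50) -> np.ndarray:
    """Sub-pixel translation of moving relative to fixed by Fourier cross-
    correlation.  Mean subtraction plus a Hann window suppress the circular
    wrap-around bias that otherwise drags estimates toward zero on smooth
    non-periodic images."""
    win = np.outer(np.hanning(fixed.shape[0]), np.hanning(fixed.shape[1]))
    a = (fixed - fixed.mean()) * win
    b = (moving - moving.mean()) * win
    shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample, normalization=None)
    return shift


def _score_rot_scale(moving: np.ndarray, fixed: np.ndarray, rot: float, scale: float) -> tuple[float, tuple[float, float]]:
    cand = AffineTransform(rot, scale, (0.0, 0.0))
    m2 = cand.apply(SEMImage(moving, 1.0), order=1).pixels
    shift = _windowed_shift(fixed, m2)
    m3 = ndimage.shift(m2, shift, order=1, mode="nearest")
    margin = max(8, int(np.ceil(np.abs(shift).max())) + 4)
    score = zncc(_centre_crop(m3, margin), _centre_crop(fixed, margin))
    return score, (float(shift[0]), float(shift[1]))


def estimate_affine(
    moving: SEMImage,
    fixed: SEMImage,
    rotation_range_deg: float = 4.0,
    scale_range: float = 0.04,
) -> AffineTransform:
    """Estimate the similarity transform aligning ``moving`` onto ``fixed``.

    Coarse grid search over rotation and isotropic scale — each candidate's
    translation resolved by sub-pixel phase correlation and scored by
    zero-normalised cross-correlation — followed by a local grid refinement.
    The identity is always a candidate, so the correlation after alignment is
    never below the unaligned correlation.
    """
    if moving.shape != fixed.shape:
        raise ValueError("images must share a pixel grid (upsample first)")
    if not np.isclose(moving.pixel_size_nm, fixed.pixel_size_nm, rtol=1e-6):
        raise ValueError("images must have the same pixel size (upsample first)")
    mv, fx = moving.pixels, fixed.pixels
    if mv.std() == 0 or fx.std() == 0:
        raise DegenerateInputError("cannot register a flat (zero-variance) image")

    best: tuple[float, float, float, tuple[float, float]] | None = None
    rots = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9, 1.0)
    scales = np.arange(1 - scale_range, 1 + scale_range + 1e-9, 0.02)
    for rot in rots:
        for sc in scales:
            score, shift = _score_rot_scale(mv, fx, rot, sc)
            if best is None or score > best[0]:
                best = (score, rot, sc, shift)
    assert best is not None
    _, rot0, sc0, _ = best
    for rot in np.arange(rot0 - 1.0, rot0 + 1.0 + 1e-9, 0.1):
        for sc in np.arange(sc0 - 0.02, sc0 + 0.02 + 1e-9, 0.005):
            score, shift = _score_rot_scale(mv, fx, rot, sc)
            if score > best[0]:
                best = (score, rot, sc, shift)
    score_id = zncc(_centre_crop(mv, 8), _centre_crop(fx, 8))
    if score_id >= best[0]:
        return AffineTransform(0.0, 1.0, (0.0, 0.0))
    _, rot, sc, shift = best
    return AffineTransform(float(rot), float(sc), shift)


# ---------------------------------------------------------------------------
# Pyramid elastic registration


@dataclass
class DisplacementField:
    """Dense pull-back displacement field (H, W, 2) in fixed-image pixels."""

    dydx: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dydx = np.asarray(self.dydx, dtype=np.float64)
        if self.dydx.ndim != 3 or self.dydx.shape[2] != 2:
            raise ValueError("displacement field must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.dydx)):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dydx.shape[:2]  # type: ignore[return-value]

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.sum(self.dydx**2, axis=2))))

    def save_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(Path(path), self.dydx.astype(np.float32).transpose(2, 0, 1))

    @classmethod
    def load_tiff(cls, path: str | Path) -> "DisplacementField":
        data = tifffile.imread(Path(path)).astype(np.float64)
        return cls(data.transpose(1, 2, 0))


def warp_apply(image: SEMImage, field: DisplacementField, order: int = 1) -> SEMImage:
    """Pull-warp: sample ``image`` at position + displacement (bilinear,
    nearest-edge extension)."""
    if image.shape != field.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs field {field.shape}")
    m, n = image.shape
    yy, xx = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    out = ndimage.map_coordinates(
        image.pixels, [yy + field.dydx[..., 0], xx + field.dydx[..., 1]], order=order, mode="nearest"
    )
    return SEMImage(out, image.pixel_size_nm, dict(image.meta))


def _block_shift(fixed_blk: np.ndarray, moving_blk: np.ndarray, max_shift: float) -> tuple[float, float] | None:
    """Sub-pixel translation of one block via phase correlation; None if the
    block is flat or the estimate implausibly large."""
    if fixed_blk.std() < 1e-12 or moving_blk.std() < 1e-12:
        return None
    shift = _windowed_shift(moving_blk, fixed_blk, upsample=20)
    if np.abs(shift).max() > max_shift:
        return None
    return float(shift[0]), float(shift[1])


def _fill_invalid(grid: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid block shifts by the mean of valid neighbours
    (iteratively; falls back to 0 when nothing is valid)."""
    if valid.all():
        return grid
    if not valid.any():
        return np.zeros_like(grid)
    g = grid.copy()
    v = valid.copy()
    while not v.all():
        newly = np.zeros_like(v)
        for (i, j) in zip(*np.nonzero(~v)):
            neigh = []
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < v.shape[0] and 0 <= jj < v.shape[1] and v[ii, jj]:
                    neigh.append(g[ii, jj])
            if neigh:
                g[i, j] = np.mean(neigh, axis=0)
                newly[i, j] = True
        v |= newly
    return g


def _upsample_grid(coarse: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bicubic interpolation of block-centre shifts to a dense per-pixel field."""
    gb = coarse.shape[0]
    m, n = shape
    out = np.empty((m, n, 2))
    # block centres sit at ((i + 0.5) * block - 0.5) in pixel coordinates
    src_y = (np.arange(m) + 0.5) / (m / gb) - 0.5
    src_x = (np.arange(n) + 0.5) / (n / coarse.shape[1]) - 0.5
    yy, xx = np.meshgrid(src_y, src_x, indexing="ij")
    for c in range(2):
        out[..., c] = ndimage.map_coordinates(coarse[..., c], [yy, xx], order=3, mode="nearest")
    return out


def pyramid_elastic_register(
    moving: SEMImage,
    fixed: SEMImage,
    levels: int = 3,
    min_block_px: int = 24,
) -> DisplacementField:
    """Coarse-to-fine block-matching elastic registration.

    At level k the fixed image is split into 2^k x 2^k blocks; each block's
    translation relative to the (current-field-warped) moving image is found
    by phase correlation with sub-pixel refinement, interpolated bicubically
    to a dense smooth increment and composed additively with the running
    field.  A level whose update would lower the global zero-normalised
    correlation is discarded, so the final correlation never falls below the
    starting (affine-only) correlation.
    """
    if moving.shape != fixed.shape:
        raise ValueError("images must have the same shape")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    m, n = fixed.shape
    field = np.zeros((m, n, 2))
    best_corr = zncc(moving.pixels, fixed.pixels)
    accepted_levels = []

    for k in range(1, levels + 1):
        g = 2**k
        bm, bn = m // g, n // g
        if bm < min_block_px or bn < min_block_px:
            break
        warped = warp_apply(moving, DisplacementField(field)).pixels
        shifts = np.zeros((g, g, 2))
        valid = np.zeros((g, g), dtype=bool)
        max_shift = max(bm, bn) / 3
        for i in range(g):
            for j in range(g):
                fb = fixed.pixels[i * bm:(i + 1) * bm, j * bn:(j + 1) * bn]
                wb = warped[i * bm:(i + 1) * bm, j * bn:(j + 1) * bn]
                s = _block_shift(fb, wb, max_shift)
                if s is not None:
                    shifts[i, j] = s
                    valid[i, j] = True
        shifts = _fill_invalid(shifts, valid)
        incr = _upsample_grid(shifts, (m, n))
        cand = field + incr
        cand_corr = zncc(warp_apply(moving, DisplacementField(cand)).pixels, fixed.pixels)
        if cand_corr >= best_corr:
            field = cand
            best_corr = cand_corr
            accepted_levels.append(k)

    return DisplacementField(field, meta={"levels_accepted": accepted_levels, "final_zncc": best_corr})
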