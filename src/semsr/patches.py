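"""Normalisation, tiling, correlation filtering and dihedral augmentation of
registered low/high-resolution image pairs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Any, Iterable

import numpy as np

from .images import DegenerateInputError, SEMImage, zncc

NEAR_FLAT_STD = 1e-3


@dataclass
class NormStats:
    mean: float
    std: float

    def __post_init__(self) -> None:
        if not (self.std > 0):
            raise ValueError("std must be > 0")


def normalize(image: SEMImage) -> tuple[SEMImage, NormStats]:
    """Zero-mean unit-variance normalisation with invertible stats.

    The microscope's automatic brightness/contrast makes absolute intensities
    incomparable between acquisitions; normalising each source image by its
    own mean and standard deviation removes that nuisance before training.
    """
    px = image.pixels
    mu = float(px.mean())
    sd = float(px.std())
    if sd == 0 or np.unique(px).size < 2:
        raise DegenerateInputError("cannot normalize a constant image")
    out = (px - mu) / sd
    meta = dict(image.meta)
    meta["normalized"] = {"mean": mu, "std": sd}
    return SEMImage(out, image.pixel_size_nm, meta), NormStats(mu, sd)


def denormalize(image: SEMImage, stats: NormStats) -> SEMImage:
    out = image.pixels * stats.std + stats.mean
    meta = dict(image.meta)
    meta.pop("normalized", None)
    return SEMImage(out, image.pixel_size_nm, meta)


@dataclass
class PatchPair:
    """One co-registered, normalised training example.

    ``x`` is cut from the Lanczos-upsampled low-resolution image and ``z``
    from the high-resolution image at the same pixel offsets, so the pair
    shares a pixel grid.  ``row0``/``col0`` map the patch back to its source
    block exactly.
    """

    x: np.ndarray
    z: np.ndarray
    row0: int = 0
    col0: int = 0
    source_id: str = ""
    near_flat: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.x.shape != self.z.shape:
            raise ValueError("x and z patches must have the same shape")
        if min(self.x.std(), self.z.std()) < NEAR_FLAT_STD:
            self.near_flat = True

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape  # type: ignore[return-value]

    def correlation(self) -> float:
        return zncc(self.x, self.z)


@dataclass
class PatchDataset:
    pairs: list[PatchPair]
    provenance: dict[str, Any] = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i: int) -> PatchPair:
        return self.pairs[i]


def tile_patches(
    x_image: SEMImage | np.ndarray,
    z_image: SEMImage | np.ndarray,
    size: int,
    stride: int | None = None,
    source_id: str = "",
) -> list[PatchPair]:
    """Cut aligned patches at offsets 0, stride, 2*stride, ... wholly inside
    the image; ``stride=size`` gives non-overlapping tiling.

    Patch count is (floor((M-size)/stride)+1) * (floor((N-size)/stride)+1).
    """
    x = x_image.pixels if isinstance(x_image, SEMImage) else np.asarray(x_image)
    z = z_image.pixels if isinstance(z_image, SEMImage) else np.asarray(z_image)
    if x.shape != z.shape:
        raise ValueError("pair images must have the same shape")
    if stride is None:
        stride = size
    if stride < 1:
        raise ValueError("stride must be >= 1")
    m, n = x.shape
    if size > m or size > n:
        warnings.warn(f"patch size {size} exceeds image shape {x.shape}; no patches produced")
        return []
    out = []
    for r0 in range(0, m - size + 1, stride):
        for c0 in range(0, n - size + 1, stride):
            out.append(PatchPair(x[r0:r0 + size, c0:c0 + size].copy(),
                                 z[r0:r0 + size, c0:c0 + size].copy(),
                                 r0, c0, source_id))
    return out


def filter_by_correlation(
    dataset: PatchDataset | Iterable[PatchPair],
    threshold: float = 0.5,
) -> tuple[PatchDataset, PatchDataset]:
    """Partition pairs into (kept, removed) by zero-normalised correlation.

    Beam damage between the two acquisitions produces locally dissimilar
    patches; a pair is kept iff corr(x, z) >= threshold.  A flat patch has
    correlation 0 by definition and is removed at any positive threshold.
    """
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [-1, 1]")
    pairs = list(dataset.pairs if isinstance(dataset, PatchDataset) else dataset)
    prov = dict(dataset.provenance) if isinstance(dataset, PatchDataset) else {}
    kept, removed = [], []
    for p in pairs:
        (kept if p.correlation() >= threshold else removed).append(p)
    prov_k = dict(prov, filter_threshold=threshold, n_kept=len(kept), n_removed=len(removed))
    prov_r = dict(prov, filter_threshold=threshold, partition="removed")
    return PatchDataset(kept, prov_k), PatchDataset(removed, prov_r)


def dihedral(arr: np.ndarray, index: int) -> np.ndarray:
    """Apply one of the 8 square symmetries: index = k + 4*flip applies k
    quarter-turns (counter-clockwise) then an optional left-right flip.
    Index 0 is the identity."""
    if not (0 <= index < 8):
        raise ValueError("dihedral index must be in [0, 8)")
    if arr.shape[-2] != arr.shape[-1] and index % 4 in (1, 3):
        raise ValueError("quarter-turn rotation requires a square patch")
    out = np.rot90(arr, k=index % 4, axes=(-2, -1))
    if index >= 4:
        out = out[..., ::-1]
    return np.ascontiguousarray(out)


def augment(pair: PatchPair, seed: int) -> PatchPair:
    """Apply a seed-chosen dihedral transform identically to x and z."""
    if pair.x.shape[0] != pair.x.shape[1]:
        raise ValueError("augmentation requires square patches")
    idx = int(np.random.default_rng(seed).integers(8))
    return augment_indexed(pair, idx)


def augment_indexed(pair: PatchPair, index: int) -> PatchPair:
    if pair.x.shape[0] != pair.x.shape[1] and index % 4 in (1, 3):
        raise ValueError("quarter-turn rotation requires a square patch")
    return PatchPair(dihedral(pair.x, index), dihedral(pair.z, index),
                     pair.row0, pair.col0, pair.source_id)
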