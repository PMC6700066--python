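"""Synthetic gold-on-carbon-like specimens and paired acquisition simulation.

The simulator produces the two halves of a training pair from one ground
truth: a high-resolution rendering of bright metal particles on a darker
textured background, and a degraded low-resolution acquisition of the same
field obtained by beam-blur, plain (aliasing) decimation, per-pixel noise and
an optional automatic brightness/contrast stretch.  A smooth random warp
emulates beam-damage deformation between the two acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .images import SEMImage

DEFAULT_RADIUS_RANGE_NM = (2.5, 75.0)
DEFAULT_GAP_RANGE_NM = (5.0, 40.0)


@dataclass
class ParticleField:
    """Ground-truth particle geometry for one field of view.

    ``particles`` holds ``(x_nm, y_nm, radius_nm)`` triples; ``pairs`` records
    indices of particles that were deliberately planted as near pairs together
    with the planted edge-to-edge gap, which seeds the gap-resolvability
    studies downstream.
    """

    particles: list[tuple[float, float, float]]
    fov_nm: tuple[float, float]
    seed: int
    pairs: list[tuple[int, int, float]] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        w, h = self.fov_nm
        if w <= 0 or h <= 0:
            raise ValueError("field of view must be positive")
        for x, y, r in self.particles:
            if not (0 <= x <= w and 0 <= y <= h):
                raise ValueError(f"particle centre ({x}, {y}) outside field of view")
            if r <= 0:
                raise ValueError("particle radius must be positive")

    def __len__(self) -> int:
        return len(self.particles)


@dataclass
class DegradationConfig:
    """Forward model of the low-magnification acquisition."""

    psf_sigma_nm: float = 0.0
    downsample_factor: int = 1
    noise_poisson_scale: float = 0.0
    noise_gaussian_sigma: float = 0.0
    autocontrast: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be >= 0")
        if int(self.downsample_factor) != self.downsample_factor or self.downsample_factor < 1:
            raise ValueError("downsample_factor must be an integer >= 1")
        if self.noise_poisson_scale < 0 or self.noise_gaussian_sigma < 0:
            raise ValueError("noise amplitudes must be >= 0")


def generate_particle_field(
    n_particles: int,
    radius_range_nm: tuple[float, float] = DEFAULT_RADIUS_RANGE_NM,
    fov_nm: tuple[float, float] = (1820.0, 1820.0),
    near_pair_fraction: float = 0.0,
    seed: int = 0,
    gap_range_nm: tuple[float, float] = DEFAULT_GAP_RANGE_NM,
) -> ParticleField:
    """Scatter particles over a field of view, planting measurable near pairs.

    A ``near_pair_fraction`` of the particles is placed as pairs whose
    edge-to-edge gap is drawn uniformly from ``gap_range_nm``; the rest are
    placed independently.  Particles are kept wholly inside the field.
    Deterministic under ``seed``.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    w, h = float(fov_nm[0]), float(fov_nm[1])
    if w <= 0 or h <= 0:
        raise ValueError("field of view must be positive")
    r_lo, r_hi = radius_range_nm
    if not (0 < r_lo <= r_hi) or r_hi >= min(w, h) / 2:
        raise ValueError(f"radius range {radius_range_nm} must lie inside (0, fov/2)")
    if not (0.0 <= near_pair_fraction <= 1.0):
        raise ValueError("near_pair_fraction must lie in [0, 1]")
    g_lo, g_hi = gap_range_nm
    if not (0 < g_lo <= g_hi):
        raise ValueError("gap range must be positive")

    rng = np.random.default_rng(seed)
    n_paired = int(round(n_particles * near_pair_fraction))
    n_pairs = n_paired // 2
    n_singles = n_particles - 2 * n_pairs

    particles: list[tuple[float, float, float]] = []
    pairs: list[tuple[int, int, float]] = []

    def _place(r: float) -> tuple[float, float]:
        x = rng.uniform(r, w - r)
        y = rng.uniform(r, h - r)
        return x, y

    for _ in range(n_pairs):
        placed = False
        for _attempt in range(200):
            r1 = rng.uniform(r_lo, r_hi)
            r2 = rng.uniform(r_lo, r_hi)
            gap = rng.uniform(g_lo, g_hi)
            x1, y1 = _place(r1)
            theta = rng.uniform(0, 2 * np.pi)
            d = r1 + r2 + gap
            x2 = x1 + d * np.cos(theta)
            y2 = y1 + d * np.sin(theta)
            if r2 <= x2 <= w - r2 and r2 <= y2 <= h - r2:
                i = len(particles)
                particles.append((x1, y1, r1))
                particles.append((x2, y2, r2))
                pairs.append((i, i + 1, gap))
                placed = True
                break
        if not placed:  # pathologically tight geometry; fall back to singles
            r1 = rng.uniform(r_lo, r_hi)
            x1, y1 = _place(r1)
            particles.append((x1, y1, r1))
            r2 = rng.uniform(r_lo, r_hi)
            x2, y2 = _place(r2)
            particles.append((x2, y2, r2))

    for _ in range(n_singles):
        r = rng.uniform(r_lo, r_hi)
        x, y = _place(r)
        particles.append((x, y, r))

    return ParticleField(particles=particles, fov_nm=(w, h), seed=seed, pairs=pairs)


def render_highres(
    field: ParticleField,
    pixel_size_nm: float,
    *,
    background_level: float = 0.2,
    particle_level: float = 1.0,
    texture_amplitude: float = 0.03,
    texture_scale_px: float = 8.0,
    edge_softness_px: float = 1.0,
    rim_gain: float = 0.0,
    rim_width_nm: float = 5.0,
) -> SEMImage:
    """Anti-aliased rendering of bright disks on a darker textured background.

    Disk coverage falls off linearly over ``edge_softness_px`` pixels around
    the geometric edge; an optional bright rim (secondary-electron edge
    effect) can be added with ``rim_gain``.  The field extent is rounded down
    to a whole number of pixels and the crop recorded in ``meta``.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    w_nm, h_nm = field.fov_nm
    n_cols = int(np.floor(w_nm / pixel_size_nm + 1e-9))
    n_rows = int(np.floor(h_nm / pixel_size_nm + 1e-9))
    if n_cols < 1 or n_rows < 1:
        raise ValueError("pixel size larger than the field of view")
    crop = (h_nm - n_rows * pixel_size_nm, w_nm - n_cols * pixel_size_nm)

    rng = np.random.default_rng(field.seed + 0x5EED)
    img = np.full((n_rows, n_cols), background_level, dtype=np.float64)
    if texture_amplitude > 0:
        noise = rng.standard_normal((n_rows, n_cols))
        smooth = ndimage.gaussian_filter(noise, sigma=texture_scale_px, mode="reflect")
        s = smooth.std()
        if s > 0:
            img += texture_amplitude * smooth / s

    coverage = np.zeros_like(img)
    rim = np.zeros_like(img)
    soft_nm = max(edge_softness_px * pixel_size_nm, 1e-9)
    for x_nm, y_nm, r_nm in field.particles:
        # rasterise only a bounding box around each particle
        pad = r_nm + soft_nm + rim_width_nm
        c0 = max(int((x_nm - pad) / pixel_size_nm) - 1, 0)
        c1 = min(int((x_nm + pad) / pixel_size_nm) + 2, n_cols)
        r0 = max(int((y_nm - pad) / pixel_size_nm) - 1, 0)
        r1 = min(int((y_nm + pad) / pixel_size_nm) + 2, n_rows)
        if c0 >= c1 or r0 >= r1:
            continue
        yy = np.arange(r0, r1)[:, None] * pixel_size_nm
        xx = np.arange(c0, c1)[None, :] * pixel_size_nm
        dist = np.hypot(yy - y_nm, xx - x_nm)
        cov = np.clip(0.5 + (r_nm - dist) / soft_nm, 0.0, 1.0)
        np.maximum(coverage[r0:r1, c0:c1], cov, out=coverage[r0:r1, c0:c1])
        if rim_gain > 0:
            ring = np.exp(-0.5 * ((dist - r_nm) / rim_width_nm) ** 2)
            np.maximum(rim[r0:r1, c0:c1], ring, out=rim[r0:r1, c0:c1])

    img = img * (1.0 - coverage) + particle_level * coverage
    if rim_gain > 0:
        img += rim_gain * rim
    img = np.clip(img, 0.0, None)

    meta = {
        "source": "synth.render_highres",
        "n_particles": len(field),
        "seed": field.seed,
        "crop_nm": crop,
        "background_level": background_level,
        "particle_level": particle_level,
    }
    return SEMImage(img, pixel_size_nm, meta)


def degrade(high: SEMImage, config: DegradationConfig) -> SEMImage:
    """Simulate the low-magnification acquisition from a high-resolution image.

    Order of operations: Gaussian beam-PSF blur, plain decimation keeping the
    (0, 0) phase (deliberately aliasing — no anti-alias pre-filter beyond the
    PSF), signal-dependent Poisson-like noise, additive Gaussian read noise,
    then an optional min/max percentile contrast stretch emulating the
    microscope's automatic brightness/contrast.  Noise is applied after
    decimation because detector noise accrues per acquired pixel.
    """
    k = int(config.downsample_factor)
    px = high.pixels
    meta = dict(high.meta)
    meta["degradation"] = {
        "psf_sigma_nm": config.psf_sigma_nm,
        "downsample_factor": k,
        "noise_poisson_scale": config.noise_poisson_scale,
        "noise_gaussian_sigma": config.noise_gaussian_sigma,
        "autocontrast": config.autocontrast,
        "seed": config.seed,
    }

    if config.psf_sigma_nm > 0:
        sigma_px = config.psf_sigma_nm / high.pixel_size_nm
        px = ndimage.gaussian_filter(px, sigma=sigma_px, mode="nearest")

    m, n = px.shape
    m_crop, n_crop = m - m % k, n - n % k
    if (m_crop, n_crop) != (m, n):
        px = px[:m_crop, :n_crop]
        meta["degradation"]["cropped_to"] = [m_crop, n_crop]
    px = px[::k, ::k].copy()

    rng = np.random.default_rng(config.seed)
    if config.noise_poisson_scale > 0:
        px = px + np.sqrt(np.clip(px, 0, None) * config.noise_poisson_scale) * rng.standard_normal(px.shape)
    if config.noise_gaussian_sigma > 0:
        px = px + config.noise_gaussian_sigma * rng.standard_normal(px.shape)
    px = np.clip(px, 0.0, None)

    if config.autocontrast:
        lo, hi = np.percentile(px, [0.5, 99.5])
        if hi > lo:
            px = np.clip((px - lo) / (hi - lo), 0.0, 1.0)

    return SEMImage(px, high.pixel_size_nm * k, meta)


def apply_damage_warp(
    image: SEMImage,
    magnitude_px: float,
    smoothness_px: float,
    seed: int = 0,
    n_components: int = 4,
) -> SEMImage:
    """Warp by a smooth random displacement field, emulating beam damage.

    The field is a sum of low-frequency sinusoidal components (wavelengths of
    one to three times ``smoothness_px``) with random directions and phases,
    normalised so the maximum per-pixel displacement equals ``magnitude_px``.
    """
    if magnitude_px < 0:
        raise ValueError("magnitude_px must be >= 0")
    if smoothness_px <= 0:
        raise ValueError("smoothness_px must be > 0")
    if magnitude_px == 0:
        return image.copy(damage_warp={"magnitude_px": 0.0})

    field = damage_displacement_field(image.shape, magnitude_px, smoothness_px, seed, n_components)
    m, n = image.shape
    yy, xx = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    warped = ndimage.map_coordinates(
        image.pixels, [yy + field[..., 0], xx + field[..., 1]], order=1, mode="nearest"
    )
    meta = dict(image.meta)
    meta["damage_warp"] = {"magnitude_px": magnitude_px, "smoothness_px": smoothness_px, "seed": seed}
    return SEMImage(warped, image.pixel_size_nm, meta)


def damage_displacement_field(
    shape: Sequence[int],
    magnitude_px: float,
    smoothness_px: float,
    seed: int = 0,
    n_components: int = 4,
) -> np.ndarray:
    """The raw (H, W, 2) displacement field used by :func:`apply_damage_warp`."""
    m, n = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(m, dtype=np.float64), np.arange(n, dtype=np.float64), indexing="ij")
    field = np.zeros((m, n, 2))
    for axis in range(2):
        comp = np.zeros((m, n))
        for _ in range(n_components):
            wavelength = smoothness_px * rng.uniform(1.0, 3.0)
            theta = rng.uniform(0, 2 * np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.3, 1.0)
            karg = 2 * np.pi / wavelength * (np.cos(theta) * xx + np.sin(theta) * yy)
            comp += amp * np.sin(karg + phase)
        field[..., axis] = comp
    norm = np.hypot(field[..., 0], field[..., 1]).max()
    if norm > 0:
        field *= magnitude_px / norm
    return field
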