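"""Adversarial super-resolution: architectures, composite loss, training
schedule, and tiled full-image inference.

The generator is an image-to-image U-Net that consumes the Lanczos-upsampled
low-resolution image (so input and target share a pixel grid) and predicts a
residual correction.  Its loss combines mean absolute error, anisotropic
total variation and a least-squares adversarial term::

    l_G = L1{G(x), z} + alpha * TV{G(x)} + beta * (1 - D(G(x)))^2

while the discriminator minimises ``D(G(x))^2 + (1 - D(z))^2``.  The
discriminator output is squashed through a sigmoid so both scores live in
[0, 1].  The generator updates every iteration; the discriminator only every
``d_update_period``-th iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import nn
from .images import SEMImage
from .patches import NormStats, PatchDataset, augment_indexed, normalize
from .registration import lanczos_upsample


class TrainingDivergedError(RuntimeError):
    def __init__(self, iteration: int, record: dict[str, float]):
        super().__init__(f"non-finite loss at iteration {iteration}: {record}")
        self.iteration = iteration
        self.record = record


class CalibrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Loss terms (scalar contracts; gradients live next to the training loop)


def l1_loss(output: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute pixel difference over an M x N patch (or batch)."""
    output = np.asarray(output, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch: {output.shape} vs {target.shape}")
    return float(np.mean(np.abs(target - output)))


def tv_loss(image: np.ndarray) -> float:
    """Anisotropic total variation: sum of absolute vertical and horizontal
    neighbour differences, boundary terms omitted."""
    v = np.asarray(image, dtype=np.float64)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("tv_loss requires a single patch of at least 2x2")
    return float(np.abs(np.diff(v, axis=0)).sum() + np.abs(np.diff(v, axis=1)).sum())


@dataclass
class LossWeights:
    """alpha scales the TV term, beta the adversarial term."""

    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")


def generator_loss(g_out: np.ndarray, target: np.ndarray, d_score_on_fake: float,
                   weights: LossWeights) -> float:
    """L1 + alpha*TV + beta*(1 - D(G(x)))^2 for a single patch."""
    if not (0.0 <= d_score_on_fake <= 1.0):
        raise ValueError("discriminator score must lie in [0, 1]")
    return (l1_loss(g_out, target)
            + weights.alpha * tv_loss(g_out)
            + weights.beta * (1.0 - d_score_on_fake) ** 2)


def discriminator_loss(d_score_on_fake: float, d_score_on_real: float) -> float:
    """D(G(x))^2 + (1 - D(z))^2."""
    if not (0.0 <= d_score_on_fake <= 1.0 and 0.0 <= d_score_on_real <= 1.0):
        raise ValueError("discriminator scores must lie in [0, 1]")
    return d_score_on_fake**2 + (1.0 - d_score_on_real) ** 2


def calibrate_loss_weights(raw_l1: float, raw_tv: float, raw_adv: float) -> LossWeights:
    """Choose (alpha, beta) so the adversarial, L1 and TV terms contribute
    84%, 14% and 2% of the generator total with the L1 weight fixed at 1.

    total = raw_l1 / 0.14; alpha = 0.02*total/raw_tv; beta = 0.84*total/raw_adv.
    """
    if raw_l1 <= 0 or raw_tv <= 0 or raw_adv <= 0:
        raise CalibrationError("all raw loss terms must be positive to calibrate")
    total = raw_l1 / 0.14
    return LossWeights(alpha=0.02 * total / raw_tv, beta=0.84 * total / raw_adv)


def _l1_grad(g_out: np.ndarray, target: np.ndarray) -> np.ndarray:
    # d/dG mean|z - G| ; averaged over every element including batch
    return np.sign(g_out - target) / g_out.size


def _tv_batch(g: np.ndarray) -> float:
    """Mean per-sample anisotropic TV of a (B, 1, H, W) batch."""
    dy = np.abs(np.diff(g, axis=2)).sum()
    dx = np.abs(np.diff(g, axis=3)).sum()
    return float((dy + dx) / g.shape[0])


def _tv_batch_grad(g: np.ndarray) -> np.ndarray:
    grad = np.zeros_like(g)
    sy = np.sign(np.diff(g, axis=2))
    grad[:, :, 1:, :] += sy
    grad[:, :, :-1, :] -= sy
    sx = np.sign(np.diff(g, axis=3))
    grad[:, :, :, 1:] += sx
    grad[:, :, :, :-1] -= sx
    return grad / g.shape[0]


# ---------------------------------------------------------------------------
# Architectures


@dataclass
class GeneratorSpec:
    depth: int = 2
    base_channels: int = 8
    leaky_slope: float = 0.2
    upsampling: str = "resize-conv"  # or "transposed-conv"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must lie in (0, 1)")
        if self.upsampling not in ("resize-conv", "transposed-conv"):
            raise ValueError("upsampling must be 'resize-conv' or 'transposed-conv'")


@dataclass
class DiscriminatorSpec:
    n_blocks: int = 3
    base_channels: int = 8
    leaky_slope: float = 0.2
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.base_channels < 1:
            raise ValueError("n_blocks and base_channels must be >= 1")


class Generator:
    """U-Net with skip connections and a global residual path.

    Each block is two 3x3 convolutions, each followed by a leaky ReLU; the
    second convolution changes the channel count (doubling on the way down,
    halving on the way up).  The final 3x3 projection is initialised near
    zero so an untrained generator approximates the identity.  Training-time
    inputs must have sides divisible by 2**depth; inference pads internally.
    """

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        b, d, s = spec.base_channels, spec.depth, spec.leaky_slope
        self.stem = nn.Sequential(nn.Conv2d(1, b, rng=rng), nn.LeakyReLU(s),
                                  nn.Conv2d(b, b, rng=rng), nn.LeakyReLU(s))
        self.pools = [nn.AvgPool2() for _ in range(d)]
        self.enc = []
        for level in range(d):
            c = b * 2**level
            self.enc.append(nn.Sequential(nn.Conv2d(c, c, rng=rng), nn.LeakyReLU(s),
                                          nn.Conv2d(c, 2 * c, rng=rng), nn.LeakyReLU(s)))
        up_cls = nn.UpNearest2 if spec.upsampling == "resize-conv" else nn.UpZeroStuff2
        self.ups = [up_cls() for _ in range(d)]
        self.upconvs = []
        self.dec = []
        for level in reversed(range(d)):
            c = b * 2 ** (level + 1)
            self.upconvs.append(nn.Sequential(nn.Conv2d(c, c // 2, rng=rng), nn.LeakyReLU(s)))
            self.dec.append(nn.Sequential(nn.Conv2d(c, c // 2, rng=rng), nn.LeakyReLU(s),
                                          nn.Conv2d(c // 2, c // 2, rng=rng), nn.LeakyReLU(s)))
        self.final = nn.Conv2d(b, 1, rng=rng, weight_scale=1e-3)
        self._pad: tuple[int, int] | None = None

    @property
    def params(self) -> list[nn.Param]:
        modules = [self.stem, *self.enc, *self.upconvs, *self.dec, self.final]
        return [p for m in modules for p in m.params]

    def parameter_count(self) -> int:
        return nn.parameter_count(self.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, H, W) -> (B, 1, H, W); reflect-pads non-multiple sides
        (inference only — backward requires unpadded inputs)."""
        mult = 2**self.spec.depth
        b, _, h, w = x.shape
        ph, pw = (-h) % mult, (-w) % mult
        self._pad = (ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        self._x_in = x
        h_cur = self.stem.forward(x)
        skips = []
        for level in range(self.spec.depth):
            skips.append(h_cur)
            h_cur = self.enc[level].forward(self.pools[level].forward(h_cur))
        self._skip_channels = [sk.shape[1] for sk in skips]
        for i, level in enumerate(reversed(range(self.spec.depth))):
            h_cur = self.upconvs[i].forward(self.ups[i].forward(h_cur))
            h_cur = np.concatenate([h_cur, skips[level]], axis=1)
            h_cur = self.dec[i].forward(h_cur)
        out = x + self.final.forward(h_cur)
        if ph or pw:
            out = out[:, :, :h, :w]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._pad != (0, 0):
            raise RuntimeError("backward through reflect padding is unsupported; "
                               "train on patches with sides divisible by 2**depth")
        dx_res = dout.copy()  # global residual path
        d = self.final.backward(dout)
        skip_grads: list[np.ndarray | None] = [None] * self.spec.depth
        # decoder stage i (executed in order 0..depth-1) consumed skip level depth-1-i
        for i in reversed(range(self.spec.depth)):
            level = self.spec.depth - 1 - i
            d = self.dec[i].backward(d)
            c_up = d.shape[1] - self._skip_channels[level]
            d_up, d_skip = d[:, :c_up], d[:, c_up:]
            skip_grads[level] = d_skip
            d = self.ups[i].backward(self.upconvs[i].backward(d_up))
        for level in reversed(range(self.spec.depth)):
            d = self.pools[level].backward(self.enc[level].backward(d))
            d = d + skip_grads[level]
        d = self.stem.backward(d)
        return d + dx_res

    def predict(self, patch: np.ndarray) -> np.ndarray:
        """Single 2-D patch in, 2-D patch out (evaluation mode)."""
        return self.forward(np.asarray(patch, dtype=np.float64)[None, None])[0, 0]

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **{f"p{i}": p.value for i, p in enumerate(self.params)})
        manifest = {"kind": "generator", "spec": self.spec.__dict__,
                    "n_params": self.parameter_count()}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Generator":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        gen = cls(GeneratorSpec(**manifest["spec"]))
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            for i, p in enumerate(gen.params):
                p.value[...] = data[f"p{i}"]
        return gen


def build_generator(spec: GeneratorSpec) -> Generator:
    return Generator(spec)


class Discriminator:
    """VGG-style convolutional stack: per block two 3x3 convolutions (the
    second doubling channels) with leaky ReLUs and 2x down-sampling, then
    global average pooling and a dense sigmoid head scoring realism in [0, 1].
    """

    def __init__(self, spec: DiscriminatorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        b, s = spec.base_channels, spec.leaky_slope
        layers: list[Any] = [nn.Conv2d(1, b, rng=rng), nn.LeakyReLU(s),
                             nn.Conv2d(b, b, rng=rng), nn.LeakyReLU(s), nn.AvgPool2()]
        c = b
        for _ in range(1, spec.n_blocks):
            layers += [nn.Conv2d(c, c, rng=rng), nn.LeakyReLU(s),
                       nn.Conv2d(c, 2 * c, rng=rng), nn.LeakyReLU(s), nn.AvgPool2()]
            c *= 2
        self.body = nn.Sequential(*layers)
        self.head = nn.Sequential(nn.GlobalAvgPool(), nn.Dense(c, 1, rng=rng), nn.Sigmoid())

    @property
    def params(self) -> list[nn.Param]:
        return self.body.params + self.head.params

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, H, W) -> (B, 1) scores in [0, 1]."""
        return self.head.forward(self.body.forward(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.body.backward(self.head.backward(dout))

    def score(self, patch: np.ndarray) -> float:
        return float(self.forward(np.asarray(patch, dtype=np.float64)[None, None])[0, 0])


def build_discriminator(spec: DiscriminatorSpec) -> Discriminator:
    return Discriminator(spec)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    iterations: int = 2000
    d_update_period: int = 4
    batch_size: int = 8
    learning_rate: float = 1e-4
    seed: int = 0
    weights: LossWeights | None = None  # None -> calibrate on a warm-up batch
    augment: bool = True
    d_learning_rate: float | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.d_update_period < 1 or self.batch_size < 1:
            raise ValueError("iterations, d_update_period and batch_size must be >= 1")


@dataclass
class TrainHistory:
    records: list[dict[str, float]] = dc_field(default_factory=list)
    weights: LossWeights | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def d_update_count(self) -> int:
        return sum(1 for r in self.records if r["d_updated"])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.records).to_csv(path, index=False)


def _make_batch(dataset: PatchDataset, idx: np.ndarray, rng: np.random.Generator,
                augment_flag: bool) -> tuple[np.ndarray, np.ndarray]:
    xs, zs = [], []
    for i in idx:
        pair = dataset[int(i)]
        if augment_flag:
            pair = augment_indexed(pair, int(rng.integers(8)))
        xs.append(pair.x)
        zs.append(pair.z)
    return np.stack(xs)[:, None], np.stack(zs)[:, None]


def train(
    dataset: PatchDataset,
    g_spec: GeneratorSpec | None = None,
    d_spec: DiscriminatorSpec | None = None,
    config: TrainConfig | None = None,
) -> tuple[Generator, TrainHistory]:
    """Adversarial training on normalised patch pairs.

    The generator takes a gradient step on the composite loss at every
    iteration; the discriminator steps on its least-squares loss only when
    ``iteration % d_update_period == 0`` (1-based), giving exactly
    ``floor(iterations / period)`` discriminator updates.  All randomness
    (init, sampling order, augmentation) derives from ``config.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty (did the correlation filter remove everything?)")
    config = config or TrainConfig()
    g_spec = g_spec or GeneratorSpec(seed=config.seed)
    d_spec = d_spec or DiscriminatorSpec(seed=config.seed + 1)
    rng = np.random.default_rng(config.seed)
    gen = Generator(g_spec)
    disc = Discriminator(d_spec)
    g_opt = nn.Adam(gen.params, lr=config.learning_rate)
    d_opt = nn.Adam(disc.params, lr=config.d_learning_rate or config.learning_rate)

    weights = config.weights
    if weights is None:
        idx = rng.integers(len(dataset), size=min(config.batch_size, len(dataset)))
        xb, zb = _make_batch(dataset, idx, rng, False)
        g_out = gen.forward(xb)
        raw_l1 = l1_loss(g_out, zb)
        raw_tv = _tv_batch(g_out)
        d_fake = disc.forward(g_out)
        raw_adv = float(np.mean((1.0 - d_fake) ** 2))
        weights = calibrate_loss_weights(raw_l1, raw_tv, max(raw_adv, 1e-12))

    history = TrainHistory(weights=weights)
    b_eff = config.batch_size

    for it in range(1, config.iterations + 1):
        idx = rng.integers(len(dataset), size=b_eff)
        xb, zb = _make_batch(dataset, idx, rng, config.augment)
        g_out = gen.forward(xb)

        raw_l1 = l1_loss(g_out, zb)
        raw_tv = _tv_batch(g_out)
        grad = _l1_grad(g_out, zb) + weights.alpha * _tv_batch_grad(g_out)

        d_fake = disc.forward(g_out)
        raw_adv = float(np.mean((1.0 - d_fake) ** 2))
        if weights.beta > 0:
            # beta * mean (1 - D(G))^2 -> chain through the discriminator
            d_opt.zero_grad()  # discard adversarial pollution of D's grads
            d_head = -2.0 * weights.beta * (1.0 - d_fake) / d_fake.shape[0]
            grad = grad + disc.backward(d_head)
            d_opt.zero_grad()

        g_opt.zero_grad()
        gen.backward(grad)
        g_opt.step()

        d_updated = it % config.d_update_period == 0
        d_loss_val = float("nan")
        if d_updated:
            d_opt.zero_grad()
            s_fake = disc.forward(g_out)  # g_out is detached by construction
            disc.backward(2.0 * s_fake / s_fake.shape[0])
            s_real = disc.forward(zb)
            disc.backward(-2.0 * (1.0 - s_real) / s_real.shape[0])
            d_opt.step()
            d_loss_val = float(np.mean(s_fake**2) + np.mean((1.0 - s_real) ** 2))

        w_l1 = raw_l1
        w_tv = weights.alpha * raw_tv
        w_adv = weights.beta * raw_adv
        total = w_l1 + w_tv + w_adv
        if total > 0:
            shares = (w_l1 / total, w_tv / total, w_adv / total)
        else:
            shares = (1.0, 0.0, 0.0)
        record = {
            "iteration": it, "l1": raw_l1, "tv": raw_tv, "adv": raw_adv,
            "g_total": total, "share_l1": shares[0], "share_tv": shares[1],
            "share_adv": shares[2], "d_loss": d_loss_val, "d_updated": d_updated,
        }
        if not np.isfinite(total) or (d_updated and not np.isfinite(d_loss_val)):
            raise TrainingDivergedError(it, record)
        history.records.append(record)

    return gen, history


# ---------------------------------------------------------------------------
# Inference


def infer(
    generator: Generator,
    image: SEMImage,
    tile: int = 128,
    overlap: int = 16,
    upsample_factor: int = 2,
    stats: NormStats | None = None,
) -> SEMImage:
    """Full-image enhancement: normalise with the image's own statistics,
    Lanczos-upsample by the training magnification ratio, run tiled inference
    with feathered overlap blending, and denormalise.  Deterministic."""
    mult = 2**generator.spec.depth
    if tile < mult:
        raise ValueError(f"tile must be >= 2**depth = {mult}")
    normed, auto_stats = normalize(image)
    stats = stats or auto_stats
    up = lanczos_upsample(normed, upsample_factor)
    arr = up.pixels
    m, n = arr.shape

    if m <= tile and n <= tile:
        out = generator.predict(arr)
    else:
        out = np.zeros_like(arr)
        weight = np.zeros_like(arr)
        win = _feather(tile, overlap)
        step = max(tile - overlap, 1)
        rows = sorted({min(r, m - tile) for r in range(0, m, step) if r < m} | {max(m - tile, 0)})
        cols = sorted({min(c, n - tile) for c in range(0, n, step) if c < n} | {max(n - tile, 0)})
        for r0 in rows:
            for c0 in cols:
                t = generator.predict(arr[r0:r0 + tile, c0:c0 + tile])
                out[r0:r0 + tile, c0:c0 + tile] += t * win
                weight[r0:r0 + tile, c0:c0 + tile] += win
        out /= np.maximum(weight, 1e-12)

    result = out * stats.std + stats.mean
    meta = dict(image.meta)
    meta["enhanced"] = {"tile": tile, "overlap": overlap, "upsample_factor": upsample_factor}
    return SEMImage(result, image.pixel_size_nm / upsample_factor, meta)


def _feather(tile: int, overlap: int) -> np.ndarray:
    ramp = np.ones(tile)
    k = max(overlap, 1)
    edge = (np.arange(1, k + 1)) / (k + 1)
    ramp[:k] = edge
    ramp[-k:] = edge[::-1]
    return np.outer(ramp, ramp)


def identity_baseline_l1(pairs: Sequence, ) -> float:
    """Validation L1 of the do-nothing mapping (output = input), the natural
    floor any trained generator must beat."""
    return float(np.mean([l1_loss(p.x, p.z) for p in pairs]))
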