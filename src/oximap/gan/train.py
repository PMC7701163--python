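"""Adversarial training loop, inference, and checkpoint serialization.

One epoch runs one discriminator update and one generator update per
sample (batch size 1).  Real discriminator targets are smoothed to 0.9;
fake pairs are drawn through the image pool.  The learning rate is
constant for the first half of training and decays linearly to zero over
the second half.  Horizontal and vertical flips are applied
independently with probability 0.5 each, re-drawn every epoch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..sfdi import StO2Map
from . import autograd as ag
from .autograd import Tensor, no_grad
from .layers import Adam
from .losses import REAL_LABEL_SMOOTHING, adversarial_objective, l1_objective, total_objective
from .models import Discriminator, DiscriminatorConfig, Generator, GeneratorConfig
from .pool import ImagePool

__all__ = [
    "TrainConfig",
    "learning_rate",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    lr: float = 2e-4
    decay_start: int = 100  # epochs at constant lr before linear decay
    batch_size: int = 1
    l1_weight: float = 60.0
    betas: tuple = (0.5, 0.999)
    pool_size: int = 64
    label_smoothing: float = REAL_LABEL_SMOOTHING
    flip_probability: float = 0.5
    patch_size: int = 256
    seed: int = 0
    augment: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)

    def __post_init__(self):
        if min(self.epochs, self.lr, self.batch_size, self.patch_size) <= 0:
            raise ValueError("hyperparameters must be positive")

    @classmethod
    def toy(cls, epochs: int = 20, seed: int = 0, **overrides) -> "TrainConfig":
        """CPU-scale settings: small networks, 64-pixel patches."""
        kwargs = dict(
            epochs=epochs,
            decay_start=epochs // 2,
            patch_size=64,
            seed=seed,
            generator=GeneratorConfig.toy(),
            discriminator=DiscriminatorConfig.toy(),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """1-based epoch; constant through ``decay_start`` then linear to 0."""
    if epoch <= cfg.decay_start:
        return cfg.lr
    span = cfg.epochs - cfg.decay_start
    return cfg.lr * max(0.0, 1.0 - (epoch - cfg.decay_start) / span)


def _maybe_flip(x, y, rng, cfg):
    if not cfg.augment:
        return x, y
    if rng.random() < cfg.flip_probability:
        x, y = x[..., ::-1].copy(), y[..., ::-1].copy()
    if rng.random() < cfg.flip_probability:
        x, y = x[..., ::-1, :].copy(), y[..., ::-1, :].copy()
    return x, y


def train(dataset, cfg: TrainConfig = TrainConfig(), callback=None):
    """Train on (input, target) pairs of shapes (3, H, W) / (1, H, W),
    both in [-1, 1].

    Returns ``(generator, discriminator, history)`` where history holds
    per-epoch means of the discriminator loss, the generator adversarial
    term, and the generator L1 term.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg.generator, rng=rng)
    disc = Discriminator(cfg.discriminator, rng=rng)
    opt_g = Adam(gen.parameters(), lr=cfg.lr, betas=cfg.betas)
    opt_d = Adam(disc.parameters(), lr=cfg.lr, betas=cfg.betas)
    pool = ImagePool(cfg.pool_size, seed=int(rng.integers(2**31)))
    history = []

    for epoch in range(1, cfg.epochs + 1):
        lr = learning_rate(epoch, cfg)
        opt_g.lr = lr
        opt_d.lr = lr
        order = rng.permutation(len(dataset))
        d_losses, g_adv_losses, g_l1_losses = [], [], []
        for i in order:
            x_np, y_np = dataset[i]
            x_np, y_np = _maybe_flip(np.asarray(x_np), np.asarray(y_np), rng, cfg)
            x = Tensor(x_np[None])  # batch of one
            y = Tensor(y_np[None])

            fake = gen(x)

            # discriminator update
            gen.zero_grad()
            disc.zero_grad()
            pooled_x, pooled_fake = pool.query((x_np.copy(), fake.data[0].copy()))
            scores_real = disc(x, y)
            scores_fake = disc(Tensor(pooled_x[None]), Tensor(pooled_fake[None]))
            loss_d = adversarial_objective(
                scores_real, scores_fake, "discriminator", cfg.label_smoothing
            )
            loss_d.backward()
            opt_d.step()

            # generator update
            gen.zero_grad()
            disc.zero_grad()
            scores_gen = disc(x, fake)
            adv = adversarial_objective(None, scores_gen, "generator")
            l1 = l1_objective(fake, y)
            loss_g = total_objective(adv, l1, cfg.l1_weight)
            loss_g.backward()
            opt_g.step()

            d_losses.append(float(loss_d.data))
            g_adv_losses.append(float(adv.data))
            g_l1_losses.append(float(l1.data))
        record = {
            "epoch": epoch,
            "lr": lr,
            "d_loss": float(np.mean(d_losses)),
            "g_adv": float(np.mean(g_adv_losses)),
            "g_l1": float(np.mean(g_l1_losses)),
        }
        history.append(record)
        if callback is not None:
            callback(record, gen, disc)
    return gen, disc, history


def predict(gen: Generator, net_input, valid: np.ndarray | None = None) -> StO2Map:
    """Run the generator and map its (-1, 1) output linearly to [0, 1].

    Inputs whose spatial size is not divisible by the generator's
    downsampling factor are edge-padded, processed in one pass, and
    cropped back.
    """
    channels = net_input.channels if hasattr(net_input, "channels") else np.asarray(net_input)
    h, w = channels.shape[-2:]
    d = gen.cfg.divisor
    pad_h = (-h) % d
    pad_w = (-w) % d
    if pad_h or pad_w:
        channels = np.pad(channels, ((0, 0), (0, pad_h), (0, pad_w)), mode="edge")
    with no_grad():
        out = gen(Tensor(channels[None])).data[0, 0]
    out = out[:h, :w]
    sto2 = np.clip((out + 1.0) / 2.0, 0.0, 1.0)
    if valid is None:
        valid = np.ones_like(sto2, dtype=bool)
    return StO2Map(sto2=sto2, valid=valid)


def save_checkpoint(path, gen, disc, cfg: TrainConfig, norm_scale: float = 1.0, extra=None):
    """Native .npz weights plus a JSON sidecar describing configuration."""
    path = Path(path)
    arrays = {f"gen.{k}": v for k, v in gen.state_dict().items()}
    arrays.update({f"disc.{k}": v for k, v in disc.state_dict().items()})
    np.savez(path.with_suffix(".npz"), **arrays)
    descriptor = {
        "train_config": _jsonable(asdict(cfg)),
        "normalization_scale": norm_scale,
        "seed": cfg.seed,
    }
    if extra:
        descriptor.update(extra)
    path.with_suffix(".json").write_text(json.dumps(descriptor, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_checkpoint(path):
    """Rebuild (generator, discriminator, descriptor) from disk."""
    path = Path(path)
    descriptor = json.loads(path.with_suffix(".json").read_text())
    tc = descriptor["train_config"]
    gen_cfg = GeneratorConfig(
        levels=tc["generator"]["levels"],
        widths=tuple(tc["generator"]["widths"]),
        in_channels=tc["generator"]["in_channels"],
        out_channels=tc["generator"]["out_channels"],
        decoder_slope=tc["generator"]["decoder_slope"],
        spectral_norm=tc["generator"]["spectral_norm"],
    )
    disc_cfg = DiscriminatorConfig(
        widths=tuple(tc["discriminator"]["widths"]),
        kernel=tc["discriminator"]["kernel"],
        strides=tuple(tc["discriminator"]["strides"]),
        in_channels=tc["discriminator"]["in_channels"],
        slope=tc["discriminator"]["slope"],
        spectral_norm=tc["discriminator"]["spectral_norm"],
    )
    gen = Generator(gen_cfg, rng=np.random.default_rng(0))
    disc = Discriminator(disc_cfg, rng=np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as data:
        gen.load_state_dict(
            {k[len("gen."):]: data[k] for k in data.files if k.startswith("gen.")}
        )
        disc.load_state_dict(
            {k[len("disc."):]: data[k] for k in data.files if k.startswith("disc.")}
        )
    return gen, disc, descriptor
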