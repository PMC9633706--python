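"""Wasserstein GAN with gradient penalty for 210×210 grayscale radiographs.

The generator maps a 50-dimensional standard-normal latent vector through a
bias-free dense layer, batch normalization and ELU to a 14×14×512 tensor, then
four nearest-neighbour upsampling + 3×3 convolution stages to 224×224, a final
per-channel batch normalization and tanh, and a 7-pixel crop to 210×210×1.
The critic is five strided 5×5 convolutions (64/128/256/312/422 filters) with
ELU activations and dropout, flattened to a single unbounded score.

Training minimizes the critic loss  E[D(fake)] − E[D(real)] + λ·GP  and the
generator loss −E[D(fake)], with λ·E[(‖∇ₓD(x̃)‖₂ − 1)²] evaluated at uniform
per-sample interpolates x̃ between real and fake batches. A scaled 64×64 spec
with the same topology is provided for desk-scale runs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Adam, BatchNorm, Conv2D, Cropping2D, Dense, Dropout, ELU, Flatten,
    Reshape, Sequential, Tanh, UpSampling2D, ZeroPad2D,
)

__all__ = [
    "GeneratorSpec", "CriticSpec", "TrainConfig", "Checkpoint", "TrainResult",
    "build_generator", "build_critic", "scaled_generator_spec", "scaled_critic_spec",
    "wgan_loss", "original_gan_loss", "gradient_penalty",
    "train", "sample", "sample_latents", "to_uint8", "images_to_tensor",
    "save_checkpoint", "load_checkpoint",
]


# --------------------------------------------------------------------------
# Architecture specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    latent_dim: int = 50
    base_size: int = 14            # spatial size after the reshape
    base_channels: int = 512
    conv_filters: tuple[int, ...] = (128, 128, 128)   # intermediate up+conv stages
    kernel: int = 3
    crop: int = 7                  # pixels removed per side after the last conv
    elu_alpha: float = 0.2

    @property
    def output_size(self) -> int:
        ups = len(self.conv_filters) + 1   # one upsample before the output conv too
        return self.base_size * 2 ** ups - 2 * self.crop


@dataclass(frozen=True)
class CriticSpec:
    image_size: int = 210
    pad: int = 2
    conv_filters: tuple[int, ...] = (64, 128, 256, 312, 422)
    dropout_after: tuple[int, ...] = (1, 2)   # conv indices followed by dropout
    conv_dropout: float = 0.3
    dense_dropout: float = 0.2
    kernel: int = 5
    stride: int = 2
    elu_alpha: float = 0.2

    def feature_shape(self) -> tuple[int, int, int]:
        size = self.image_size + 2 * self.pad
        for _ in self.conv_filters:
            size = -(-size // self.stride)   # 'same' padding, ceil division
        return size, size, self.conv_filters[-1]

    @property
    def flat_features(self) -> int:
        h, w, c = self.feature_shape()
        return h * w * c


def scaled_generator_spec(latent_dim: int = 16) -> GeneratorSpec:
    """Same topology at 64×64 with reduced widths, for desk-scale training."""
    return GeneratorSpec(latent_dim=latent_dim, base_size=4, base_channels=64,
                         conv_filters=(32, 32, 32), crop=0)


def scaled_critic_spec() -> CriticSpec:
    return CriticSpec(image_size=64, conv_filters=(16, 32, 32, 32, 48))


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0) -> Sequential:
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(seed)
    dense_out = spec.base_size ** 2 * spec.base_channels
    layers = [
        Dense(spec.latent_dim, dense_out, use_bias=False, rng=rng, name="g_dense"),
        BatchNorm(dense_out, name="g_bn_in"),
        ELU(spec.elu_alpha, name="g_elu_in"),
        Reshape((spec.base_size, spec.base_size, spec.base_channels), name="g_reshape"),
    ]
    in_ch = spec.base_channels
    for i, f in enumerate(spec.conv_filters):
        layers += [
            UpSampling2D(2, name=f"g_up{i}"),
            Conv2D(in_ch, f, spec.kernel, stride=1, padding="same",
                   use_bias=False, rng=rng, name=f"g_conv{i}"),
            ELU(spec.elu_alpha, name=f"g_elu{i}"),
        ]
        in_ch = f
    layers += [
        UpSampling2D(2, name="g_up_out"),
        Conv2D(in_ch, 1, spec.kernel, stride=1, padding="same",
               use_bias=False, rng=rng, name="g_conv_out"),
        BatchNorm(1, name="g_bn_out"),
        Tanh(),
        Cropping2D(spec.crop, name="g_crop"),
    ]
    return Sequential(layers, name="generator")


def build_critic(spec: CriticSpec | None = None, seed: int = 1) -> Sequential:
    spec = spec or CriticSpec()
    rng = np.random.default_rng(seed)
    layers: list = [ZeroPad2D(spec.pad, name="d_pad")]
    in_ch = 1
    for i, f in enumerate(spec.conv_filters):
        layers += [
            Conv2D(in_ch, f, spec.kernel, stride=spec.stride, padding="same",
                   use_bias=True, rng=rng, name=f"d_conv{i}"),
            ELU(spec.elu_alpha, name=f"d_elu{i}"),
        ]
        if i in spec.dropout_after:
            layers.append(Dropout(spec.conv_dropout, name=f"d_drop{i}"))
        in_ch = f
    layers += [
        Flatten(),
        Dropout(spec.dense_dropout, name="d_drop_flat"),
        Dense(spec.flat_features, 1, use_bias=True, rng=rng, name="d_dense"),
    ]
    return Sequential(layers, name="critic")


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------

def wgan_loss(real_scores, fake_scores) -> tuple[float, float]:
    """Wasserstein losses: critic minimizes E[D(fake)] − E[D(real)],
    the generator minimizes −E[D(fake)]."""
    real_scores = np.asarray(real_scores, dtype=float).ravel()
    fake_scores = np.asarray(fake_scores, dtype=float).ravel()
    if real_scores.size == 0 or fake_scores.size == 0:
        raise ValueError("empty score batch")
    critic_loss = float(fake_scores.mean() - real_scores.mean())
    generator_loss = float(-fake_scores.mean())
    return critic_loss, generator_loss


def original_gan_loss(real_probs, fake_probs) -> tuple[float, float]:
    """The saturating minimax GAN objective, kept as a documented variant
    only; it is never used for training here."""
    real_probs = np.asarray(real_probs, dtype=float).ravel()
    fake_probs = np.asarray(fake_probs, dtype=float).ravel()
    if real_probs.size == 0 or fake_probs.size == 0:
        raise ValueError("empty probability batch")
    objective = float(np.log(real_probs).mean() + np.log1p(-fake_probs).mean())
    return -objective, objective   # discriminator maximizes, generator minimizes


def _input_gradient(critic: Sequential, x: np.ndarray, training: bool,
                    rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample gradient of D w.r.t. its input (and the scores).

    Parameter gradients accumulated by the backward pass are snapshotted and
    restored, so this is side-effect free on the critic.
    """
    saved = [p.grad.copy() for p in critic.params()]
    scores = critic.forward(x, training=training, rng=rng)
    seed_grad = np.ones_like(scores)
    g = critic.backward(seed_grad)
    for p, s in zip(critic.params(), saved):
        p.grad[...] = s
    return g, scores


def gradient_penalty(critic: Sequential, real_batch: np.ndarray,
                     fake_batch: np.ndarray, lam: float = 10.0,
                     seed: int | None = None) -> float:
    """λ·E[(‖∇ₓD(x̃)‖₂ − 1)²] at uniform interpolates x̃ = ε·real + (1−ε)·fake.

    The input gradient is computed by exact reverse-mode differentiation
    through the critic (dropout inactive), so the returned value is exact up
    to floating point.
    """
    real_batch = np.asarray(real_batch, dtype=np.float32)
    fake_batch = np.asarray(fake_batch, dtype=np.float32)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must have the same shape")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    rng = np.random.default_rng(seed)
    n = real_batch.shape[0]
    eps = rng.random((n,) + (1,) * (real_batch.ndim - 1)).astype(np.float32)
    x_tilde = eps * real_batch + (1.0 - eps) * fake_batch
    g, _ = _input_gradient(critic, x_tilde, training=False, rng=None)
    norms = np.sqrt((g.reshape(n, -1).astype(np.float64) ** 2).sum(axis=1))
    return float(lam * ((norms - 1.0) ** 2).mean())


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    latent_dim: int = 50
    lambda_gp: float = 10.0
    critic_steps_per_gen: int = 4
    epochs: int = 1000
    batch_size: int = 32
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.9
    decay: float = 1e-4
    lr_schedule: str = "inverse_time"
    seed: int = 0
    checkpoint_every: int = 1
    critic_warmup_steps: int = 0

    def validate(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (interpolation needs pairs)")
        if min(self.lr, self.beta1, self.beta2) <= 0:
            raise ValueError("all rates must be > 0")
        if self.critic_steps_per_gen < 1:
            raise ValueError("critic_steps_per_gen must be >= 1")


@dataclass
class Checkpoint:
    epoch: int
    generator_state: dict
    critic_state: dict
    wasserstein: float
    config: TrainConfig


@dataclass
class TrainResult:
    checkpoints: list[Checkpoint]
    wasserstein_history: list[float]
    config: TrainConfig


# step size for the central-difference directional derivative used in the
# penalty's weight gradient (double backprop surrogate); data lives in [-1, 1]
_GP_FD_EPS = 1e-2


def _critic_update(generator, critic, adam_c, real_b, config, rng):
    b = real_b.shape[0]
    z = rng.standard_normal((b, config.latent_dim)).astype(np.float32)
    fake_b = generator.forward(z, training=True)

    critic.zero_grad()
    real_scores = critic.forward(real_b, training=True,
                                 rng=np.random.default_rng(rng.integers(2 ** 31)))
    critic.backward(np.full_like(real_scores, -1.0 / b))
    fake_scores = critic.forward(fake_b, training=True,
                                 rng=np.random.default_rng(rng.integers(2 ** 31)))
    critic.backward(np.full_like(fake_scores, 1.0 / b))

    # gradient penalty: exact input gradient, finite-difference weight gradient
    eps = rng.random((b,) + (1,) * (real_b.ndim - 1)).astype(np.float32)
    x_tilde = eps * real_b + (1.0 - eps) * fake_b
    gp_seed = int(rng.integers(2 ** 31))
    g, _ = _input_gradient(critic, x_tilde, training=True,
                           rng=np.random.default_rng(gp_seed))
    flat = g.reshape(b, -1).astype(np.float64)
    norms = np.sqrt((flat ** 2).sum(axis=1))
    safe = np.maximum(norms, 1e-12)
    u = (flat / safe[:, None]).reshape(x_tilde.shape).astype(np.float32)
    coef = (2.0 * config.lambda_gp * (norms - 1.0) / b).astype(np.float32)
    h = _GP_FD_EPS
    out = critic.forward(x_tilde + h * u, training=True,
                         rng=np.random.default_rng(gp_seed))
    critic.backward((coef / (2.0 * h)).reshape(out.shape))
    out = critic.forward(x_tilde - h * u, training=True,
                         rng=np.random.default_rng(gp_seed))
    critic.backward((-coef / (2.0 * h)).reshape(out.shape))

    adam_c.step()
    c_loss, _ = wgan_loss(real_scores, fake_scores)
    wasserstein = float(real_scores.mean() - fake_scores.mean())
    return c_loss, wasserstein


def _generator_update(generator, critic, adam_g, config, rng):
    b = config.batch_size
    z = rng.standard_normal((b, config.latent_dim)).astype(np.float32)
    generator.zero_grad()
    fake_b = generator.forward(z, training=True)
    scores = critic.forward(fake_b, training=True,
                            rng=np.random.default_rng(rng.integers(2 ** 31)))
    d_fake = critic.backward(np.full_like(scores, -1.0 / b))
    generator.backward(d_fake)
    adam_g.step()
    return float(-scores.mean())


def train(dataset: np.ndarray, config: TrainConfig,
          generator: Sequential | None = None, critic: Sequential | None = None,
          generator_spec: GeneratorSpec | None = None,
          critic_spec: CriticSpec | None = None,
          max_steps: int | None = None) -> TrainResult:
    """Train a WGAN-GP on a stack of images scaled to [−1, 1].

    ``dataset`` is (N, H, W, 1) float32 in [−1, 1]. Per generator update the
    critic takes ``critic_steps_per_gen`` updates on fresh random batches.
    The learning rate decays per optimizer step. Deterministic under a fixed
    ``config.seed``. ``max_steps`` caps the total number of critic updates
    (for smoke runs).
    """
    config.validate()
    dataset = np.asarray(dataset, dtype=np.float32)
    if dataset.ndim != 4 or dataset.shape[-1] != 1:
        raise ValueError("dataset must be (N, H, W, 1)")
    n = dataset.shape[0]
    if n < config.batch_size:
        raise ValueError("dataset smaller than batch_size")

    if generator is None:
        generator = build_generator(generator_spec, seed=config.seed)
    if critic is None:
        critic = build_critic(critic_spec, seed=config.seed + 1)

    rng = np.random.default_rng(config.seed)
    adam_g = Adam(generator.params(), lr=config.lr, beta1=config.beta1,
                  beta2=config.beta2, decay=config.decay, schedule=config.lr_schedule)
    adam_c = Adam(critic.params(), lr=config.lr, beta1=config.beta1,
                  beta2=config.beta2, decay=config.decay, schedule=config.lr_schedule)

    checkpoints: list[Checkpoint] = []
    history: list[float] = []

    # optional critic-only warm-up so the Wasserstein estimate starts as a
    # faithful distance before adversarial updates begin
    for _ in range(config.critic_warmup_steps):
        idx = rng.choice(n, size=config.batch_size, replace=False)
        _critic_update(generator, critic, adam_c, dataset[idx], config, rng)

    gen_updates_per_epoch = max(1, (n // config.batch_size) // config.critic_steps_per_gen)
    total_critic_steps = 0
    for epoch in range(1, config.epochs + 1):
        last_w = 0.0
        for _ in range(gen_updates_per_epoch):
            for _ in range(config.critic_steps_per_gen):
                idx = rng.choice(n, size=config.batch_size, replace=False)
                c_loss, last_w = _critic_update(generator, critic, adam_c,
                                                dataset[idx], config, rng)
                if not np.isfinite(c_loss):
                    raise FloatingPointError(
                        f"non-finite critic loss at epoch {epoch}")
                history.append(last_w)
                total_critic_steps += 1
            g_loss = _generator_update(generator, critic, adam_g, config, rng)
            if not np.isfinite(g_loss):
                raise FloatingPointError(f"non-finite generator loss at epoch {epoch}")
            if max_steps is not None and total_critic_steps >= max_steps:
                break
        if epoch % config.checkpoint_every == 0:
            checkpoints.append(Checkpoint(
                epoch=epoch,
                generator_state=generator.state_dict(),
                critic_state=critic.state_dict(),
                wasserstein=last_w,
                config=config,
            ))
        if max_steps is not None and total_critic_steps >= max_steps:
            if not checkpoints or checkpoints[-1].epoch != epoch:
                checkpoints.append(Checkpoint(
                    epoch=epoch, generator_state=generator.state_dict(),
                    critic_state=critic.state_dict(), wasserstein=last_w,
                    config=config))
            break
    return TrainResult(checkpoints=checkpoints, wasserstein_history=history,
                       config=config)


# --------------------------------------------------------------------------
# Sampling and serialization
# --------------------------------------------------------------------------

def sample_latents(n: int, latent_dim: int = 50,
                   seed: int | None = None) -> np.ndarray:
    """i.i.d. standard-normal latent vectors; no truncation is applied."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, latent_dim)).astype(np.float32)


def sample(generator: Sequential, n: int, seed: int | None = None,
           latent_dim: int | None = None) -> np.ndarray:
    """Generate n images in [−1, 1] from fresh standard-normal latents."""
    if latent_dim is None:
        latent_dim = generator.layers[0].w.value.shape[0]
    z = sample_latents(n, latent_dim, seed)
    return generator.forward(z, training=False)


def to_uint8(images: np.ndarray) -> np.ndarray:
    """Map tanh-range images [−1, 1] to 8-bit gray via (x+1)·127.5 rounding."""
    return np.clip(np.rint((np.asarray(images) + 1.0) * 127.5), 0, 255).astype(np.uint8)


def images_to_tensor(images) -> np.ndarray:
    """Stack 8-bit grayscale images into an (N, H, W, 1) tensor in [−1, 1]."""
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return (arr / 127.5 - 1.0)[..., None]


def save_checkpoint(ck: Checkpoint, path: str | os.PathLike) -> None:
    """Write weights as an .npz archive with a JSON sidecar of the config."""
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    arrays = {f"g::{k}": v for k, v in ck.generator_state.items()}
    arrays.update({f"d::{k}": v for k, v in ck.critic_state.items()})
    np.savez(path, **arrays)
    with open(path + ".json", "w") as fh:
        json.dump({"epoch": ck.epoch, "wasserstein": ck.wasserstein,
                   "config": asdict(ck.config)}, fh, indent=1)


def load_checkpoint(path: str | os.PathLike) -> Checkpoint:
    path = os.fspath(path)
    npz_path = path if path.endswith(".npz") else path + ".npz"
    if not os.path.exists(npz_path):
        npz_path = path
    data = np.load(npz_path)
    gstate = {k[3:]: data[k] for k in data.files if k.startswith("g::")}
    dstate = {k[3:]: data[k] for k in data.files if k.startswith("d::")}
    with open(npz_path + ".json") as fh:
        meta = json.load(fh)
    return Checkpoint(epoch=meta["epoch"], generator_state=gstate,
                      critic_state=dstate, wasserstein=meta["wasserstein"],
                      config=TrainConfig(**meta["config"]))
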