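"""Conditional deep-convolutional Wasserstein GAN with gradient penalty.

One conditional model serves all four classes: the class label enters the
generator as an embedding concatenated to the latent vector and the critic
as an embedded extra input channel. The critic is trained to maximize the
score gap between real and generated images subject to a gradient penalty

    L = E[D(x_fake|y)] - E[D(x_real|y)] + lambda * (||grad_xhat D(xhat|y)||_2 - 1)^2,

with xhat = eps*x_real + (1-eps)*x_fake, eps ~ U(0,1) per sample. The
generator is updated once per ``n_critic`` critic updates. No normalization
layers are used in the critic (incompatible with a per-sample gradient
penalty). The generator mixes interpolation-upsample+convolution with a
transposed convolution, which avoids checkerboard artifacts at this
resolution.

Internally images are standardized by the training set's statistics so that
real structure fills the bounded (tanh) output range; samples are mapped
back to [0, 1]. The affine map is stored on the model.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distmap import DistanceMap
from .headgen import CLASSES
from .nn.layers import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    Dense,
    Embedding,
    Flatten,
    LeakyReLU,
    Reshape,
    Sequential,
    Tanh,
    Upsample2,
)
from .nn.tensor import Tensor, concat, grad, mean_, pow_, reshape, sum_


@dataclass
class GANConfig:
    latent_dim: int = 32
    label_embed_dim: int = 16
    balanced_classes: bool = True  # draw minibatches class-balanced
    learning_rate: float = 3e-5
    lambda_gp: float = 1.0
    n_critic: int = 10
    epochs: int = 200  # reference-scale value: 1000
    batch_size: int = 32
    seed: int = 0
    base_channels: int = 8
    adam_betas: tuple[float, float] = (0.0, 0.9)
    snapshot_every: int = 0  # export a sample grid every k epochs (0 = off)

    def __post_init__(self):
        for name in ("latent_dim", "label_embed_dim", "n_critic", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.lambda_gp < 0:
            raise ValueError("invalid learning rate / lambda")


class Generator:
    """z (+ label embedding) -> 7x7 feature map -> upsample+conv ->
    transposed conv -> conv -> tanh, output 28x28 in [-1, 1]."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.embed = Embedding(len(CLASSES), cfg.label_embed_dim, rng)
        self.net = Sequential(
            Dense(cfg.latent_dim + cfg.label_embed_dim, 4 * c * 7 * 7, rng),
            LeakyReLU(0.2),
            Reshape((4 * c, 7, 7)),
            Upsample2(),  # 7 -> 14
            Conv2d(4 * c, 2 * c, 3, 1, 1, rng),
            LeakyReLU(0.2),
            ConvTranspose2d(2 * c, c, 4, 2, 1, rng),  # 14 -> 28
            LeakyReLU(0.2),
            Conv2d(c, 1, 3, 1, 1, rng),
            Tanh(),
        )

    def __call__(self, z: Tensor, labels: np.ndarray) -> Tensor:
        zy = concat([z, self.embed(labels)], axis=1)
        return self.net(zy)

    def parameters(self):
        return self.embed.parameters() + self.net.parameters()

    @property
    def upsampling_kinds(self) -> list[str]:
        """Layer-kind sequence of the image-forming path."""
        return self.net.kinds


class Critic:
    """Image + embedded-label channel -> strided convolutions -> score."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.embed = Embedding(len(CLASSES), 28 * 28, rng)
        self.net = Sequential(
            Conv2d(2, c, 4, 2, 1, rng),  # 28 -> 14
            LeakyReLU(0.2),
            Conv2d(c, 2 * c, 4, 2, 1, rng),  # 14 -> 7
            LeakyReLU(0.2),
            Conv2d(2 * c, 4 * c, 4, 2, 1, rng),  # 7 -> 3
            LeakyReLU(0.2),
            Flatten(),
            Dense(4 * c * 3 * 3, 1, rng),
        )

    def __call__(self, x: Tensor, labels: np.ndarray) -> Tensor:
        n = x.shape[0]
        label_channel = reshape(self.embed(labels), (n, 1, 28, 28))
        return self.net(concat([x, label_channel], axis=1))

    def parameters(self):
        return self.embed.parameters() + self.net.parameters()


@dataclass
class GANModel:
    generator: Generator
    critic: Critic
    config: GANConfig
    train_log: dict[str, list] = field(default_factory=dict)
    # affine map between [0,1] image space and the internal tanh range:
    # internal = (image - norm_mean) / norm_scale
    norm_mean: float = 0.5
    norm_scale: float = 0.5

    def save(self, path: str | Path) -> None:
        """Checkpoint: weights + config + train log."""
        payload = {
            "gen": [p.data for p in self.generator.parameters()],
            "crit": [p.data for p in self.critic.parameters()],
            "config": self.config.__dict__ | {"adam_betas": list(self.config.adam_betas)},
            "train_log": self.train_log,
            "norm": [self.norm_mean, self.norm_scale],
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "GANModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        cfgd = dict(payload["config"])
        cfgd["adam_betas"] = tuple(cfgd["adam_betas"])
        cfg = GANConfig(**cfgd)
        rng = np.random.default_rng(cfg.seed)
        norm = payload.get("norm", [0.5, 0.5])
        model = cls(Generator(cfg, rng), Critic(cfg, rng), cfg, payload["train_log"], norm[0], norm[1])
        for p, d in zip(model.generator.parameters(), payload["gen"]):
            p.data = d
        for p, d in zip(model.critic.parameters(), payload["crit"]):
            p.data = d
        return model


def gradient_penalty(
    critic,
    real_batch: tuple[np.ndarray, np.ndarray],
    fake_batch: tuple[np.ndarray, np.ndarray],
    seed: int | np.random.Generator = 0,
) -> Tensor:
    """Mean (||grad_xhat D(xhat|y)||_2 - 1)^2 over the batch.

    ``critic`` is any differentiable map (Tensor image batch, labels) ->
    per-sample scores. The interpolation points use per-sample eps ~ U(0,1);
    labels of real and fake must agree. The caller multiplies by lambda.
    The returned Tensor carries the double-backprop graph, so it can be part
    of a loss that is differentiated w.r.t. critic parameters.
    """
    (xr, yr), (xf, yf) = real_batch, fake_batch
    xr, xf = np.asarray(xr, float), np.asarray(xf, float)
    if xr.shape != xf.shape or not np.array_equal(yr, yf):
        raise ValueError("real and fake batches must have equal shape and aligned labels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.uniform(size=(xr.shape[0],) + (1,) * (xr.ndim - 1))
    xhat = Tensor(eps * xr + (1 - eps) * xf, requires_grad=True)
    scores = critic(xhat, yr)
    (gx,) = grad(sum_(scores), [xhat])
    axes = tuple(range(1, xr.ndim))
    gnorm = pow_(sum_(pow_(gx, 2.0), axis=axes) + Tensor(1e-12), 0.5)
    return mean_(pow_(gnorm - Tensor(np.ones(xr.shape[0])), 2.0))


def _to_internal(img01: np.ndarray, mean: float, scale: float) -> np.ndarray:
    return (img01 - mean) / scale


def _to_01(internal: np.ndarray, mean: float, scale: float) -> np.ndarray:
    return np.clip(internal * scale + mean, 0.0, 1.0)


def train_cgan(
    images: list[DistanceMap],
    config: GANConfig | None = None,
    snapshot_dir: str | Path | None = None,
) -> GANModel:
    """Train the conditional WGAN-GP on labeled distance maps.

    Alternates ``n_critic`` critic updates with one generator update, Adam
    for both networks at the configured rate. Logs per-epoch mean critic
    loss, real-fake score gap, gradient penalty and generator loss. Raises
    on non-finite losses. Deterministic under ``config.seed``.
    """
    cfg = config or GANConfig()
    labels_present = {im.label for im in images}
    missing = set(CLASSES) - labels_present
    if missing:
        raise ValueError(f"every class needs at least one image; missing {sorted(missing)}")
    label_to_idx = {c: i for i, c in enumerate(CLASSES)}
    raw = np.stack([im.pixels for im in images])
    # normalize by training statistics so real structure fills the bounded
    # output range (4 sigma maps to the tanh saturation points)
    norm_mean = float(raw.mean())
    norm_scale = float(4.0 * raw.std()) or 1.0
    X = _to_internal(raw, norm_mean, norm_scale)[:, None, :, :]
    y = np.array([label_to_idx[im.label] for im in images])

    rng = np.random.default_rng(cfg.seed)
    model = GANModel(Generator(cfg, rng), Critic(cfg, rng), cfg, norm_mean=norm_mean, norm_scale=norm_scale)
    g_params = model.generator.parameters()
    c_params = model.critic.parameters()
    g_opt = Adam(g_params, cfg.learning_rate, cfg.adam_betas)
    c_opt = Adam(c_params, cfg.learning_rate, cfg.adam_betas)

    log = {"epoch": [], "critic_loss": [], "score_gap": [], "grad_penalty": [], "gen_loss": []}
    n = len(X)
    bs = min(cfg.batch_size, n)
    by_class = [np.flatnonzero(y == k) for k in range(len(CLASSES))]
    critic_since_gen = 0
    total_critic_steps = 0
    total_gen_steps = 0
    for epoch in range(cfg.epochs):
        if cfg.balanced_classes:
            # equalize per-class gradient signal: each epoch visits every
            # class equally often regardless of cohort imbalance
            per = max(1, int(np.ceil(n / len(CLASSES))))
            order = np.concatenate([rng.choice(ids, per, replace=True) for ids in by_class])
            order = rng.permutation(order)[:n]
        else:
            order = rng.permutation(n)
        ep_closs, ep_gap, ep_gp, ep_gloss = [], [], [], []
        for start in range(0, len(order) - bs + 1, bs):
            idx = order[start : start + bs]
            xr, yr = X[idx], y[idx]
            z = Tensor(rng.standard_normal((bs, cfg.latent_dim)))
            xf = model.generator(z, yr)
            xf_const = Tensor(xf.data.copy())  # critic step: generator frozen
            d_real = model.critic(Tensor(xr), yr)
            d_fake = model.critic(xf_const, yr)
            gp = gradient_penalty(model.critic, (xr, yr), (xf_const.data, yr), rng)
            gap = mean_(d_real) - mean_(d_fake)
            c_loss = mean_(d_fake) - mean_(d_real) + Tensor(cfg.lambda_gp) * gp
            if not np.isfinite(c_loss.data):
                raise RuntimeError(f"NaN critic loss at epoch {epoch}")
            c_opt.step(grad(c_loss, c_params))
            total_critic_steps += 1
            critic_since_gen += 1
            ep_closs.append(c_loss.item())
            ep_gap.append(gap.item())
            ep_gp.append(gp.item())
            if critic_since_gen >= cfg.n_critic:
                critic_since_gen = 0
                z = Tensor(rng.standard_normal((bs, cfg.latent_dim)))
                yg = rng.integers(0, len(CLASSES), size=bs)
                g_loss = -mean_(model.critic(model.generator(z, yg), yg))
                if not np.isfinite(g_loss.data):
                    raise RuntimeError(f"NaN generator loss at epoch {epoch}")
                # update only the generator: critic parameters stay fixed
                g_opt.step(grad(g_loss, g_params))
                total_gen_steps += 1
                ep_gloss.append(g_loss.item())
        log["epoch"].append(epoch)
        log["critic_loss"].append(float(np.mean(ep_closs)) if ep_closs else np.nan)
        log["score_gap"].append(float(np.mean(ep_gap)) if ep_gap else np.nan)
        log["grad_penalty"].append(float(np.mean(ep_gp)) if ep_gp else np.nan)
        log["gen_loss"].append(float(np.mean(ep_gloss)) if ep_gloss else np.nan)
        if snapshot_dir and cfg.snapshot_every and (epoch + 1) % cfg.snapshot_every == 0:
            export_sample_grid(model, Path(snapshot_dir) / f"epoch_{epoch + 1:04d}.png", seed=epoch)
    log["total_critic_steps"] = total_critic_steps
    log["total_gen_steps"] = total_gen_steps
    model.train_log = log
    return model


def sample_cgan(model: GANModel, label: str, n: int, seed: int = 0) -> list[DistanceMap]:
    """Draw n images of one class from the trained generator."""
    if label not in CLASSES:
        raise ValueError(f"unknown class label: {label!r}")
    rng = np.random.default_rng(seed)
    idx = CLASSES.index(label)
    out = []
    bs = 128
    for start in range(0, n, bs):
        k = min(bs, n - start)
        z = Tensor(rng.standard_normal((k, model.config.latent_dim)))
        imgs = model.generator(z, np.full(k, idx)).data[:, 0]
        out.extend(
            DistanceMap(_to_01(im, model.norm_mean, model.norm_scale), label, {"source": "gan"})
            for im in imgs
        )
    return out


def export_sample_grid(model: GANModel, path: str | Path, seed: int = 0, per_class: int = 1) -> None:
    """2x2 (or k per class) PNG grid of generator samples, one row per class."""
    import imageio.v3 as iio

    rows = []
    for label in CLASSES:
        maps = sample_cgan(model, label, per_class, seed=seed)
        rows.append(np.hstack([m.pixels for m in maps]))
    grid = np.vstack(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), np.round(grid * 255).astype(np.uint8))
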