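"""Reduced style-based GAN trained on diseased-only radiographs.

The generator keeps the contract the downstream feature extraction relies
on — a mapping network Z -> W and a synthesis network W -> image that is
differentiable end-to-end — in a desk-scale architecture: a 2-layer mapping
MLP, a learned 4x4 constant, and modulated-convolution upsampling blocks
with weight demodulation. Training uses the non-saturating logistic loss
with lazy R1 regularization on the discriminator (default coefficient
6.5536), Adam at learning rate 0.002 with betas (0, 0.99), and
discriminator-input augmentation that deliberately excludes horizontal
flips (curve direction is a clinical signal) and cutout.

Checkpoints are ranked by Fréchet distance between feature embeddings of
real and generated batches; the embedding is pluggable and defaults to a
fixed, seeded random convnet, which is sufficient for *ranking* checkpoints
of one run at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import linalg

from ._autodiff import DTYPE, Tensor, grad, no_grad
from .nn import (Adam, Conv2d, Dense, ModulatedConv2d, Module, Parameter,
                 frozen, pixel_norm)
from .synthdata import DatasetManifest

# ---------------------------------------------------------------------------
# models


def _channels(resolution: int, channel_base: int, channel_max: int):
    res, out = 4, {}
    while res <= resolution:
        out[res] = int(np.clip(channel_base // res, 8, channel_max))
        res *= 2
    return out


class Generator(Module):
    """Mapping (Z -> W) plus synthesis (W -> image) networks."""

    def __init__(self, resolution: int = 32, dim_z: int = 64, dim_w: int = 64,
                 channel_base: int = 256, channel_max: int = 48,
                 out_channels: int = 3, seed: int = 0):
        if resolution < 8 or resolution & (resolution - 1):
            raise ValueError("resolution must be a power of two >= 8")
        rng = np.random.default_rng(seed)
        ch = _channels(resolution, channel_base, channel_max)
        self.resolution = resolution
        self.dim_z = dim_z
        self.dim_w = dim_w
        self.out_channels = out_channels

        self.map1 = Dense(dim_z, dim_w, rng)
        self.map2 = Dense(dim_w, dim_w, rng)

        self.const = Parameter(rng.standard_normal((1, ch[4], 4, 4)))
        self.conv0 = ModulatedConv2d(ch[4], ch[4], 3, dim_w, rng)
        self.ups = []
        res, cin = 8, ch[4]
        while res <= resolution:
            self.ups.append(ModulatedConv2d(cin, ch[res], 3, dim_w, rng))
            cin = ch[res]
            res *= 2
        self.to_rgb = ModulatedConv2d(cin, out_channels, 1, dim_w, rng,
                                      demodulate=False)

    # -- graph-level API ----------------------------------------------------
    def mapping(self, z: Tensor) -> Tensor:
        h = pixel_norm(z)
        h = self.map1(h).leaky_relu(0.2)
        return self.map2(h).leaky_relu(0.2)

    def synthesis(self, w: Tensor) -> Tensor:
        """Raw image tensor, roughly in [-1, 1]."""
        B = w.shape[0]
        x = self.const.expand((B,) + self.const.shape[1:])
        x = self.conv0(x, w).leaky_relu(0.2)
        for conv in self.ups:
            x = conv(x.upsample2x(), w).leaky_relu(0.2)
        return self.to_rgb(x, w)

    # -- convenience numpy API ----------------------------------------------
    def map_latents(self, z: np.ndarray) -> np.ndarray:
        with no_grad():
            return self.mapping(Tensor(z)).data.copy()

    def synthesize01(self, w: np.ndarray) -> np.ndarray:
        """Images in [0, 1] from W codes (no gradient)."""
        with no_grad():
            raw = self.synthesis(Tensor(np.asarray(w, dtype=DTYPE))).data
        return np.clip((raw + 1.0) / 2.0, 0.0, 1.0)

    def sample01(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, self.dim_z)).astype(DTYPE)
        return self.synthesize01(self.map_latents(z))

    def style_matrix(self) -> np.ndarray:
        """First style-affine weight, (dim_w, channels): the A of w -> style."""
        return self.conv0.affine.W.data.copy()

    def arch_config(self) -> dict:
        return dict(resolution=self.resolution, dim_z=self.dim_z,
                    dim_w=self.dim_w, out_channels=self.out_channels)


class Discriminator(Module):
    """Conv stack with 2x average-pool downsampling to a single logit."""

    def __init__(self, resolution: int = 32, channel_base: int = 256,
                 channel_max: int = 48, in_channels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        ch = _channels(resolution, channel_base, channel_max)
        self.resolution = resolution
        self.from_rgb = Conv2d(in_channels, ch[resolution], 1, rng)
        self.blocks = []
        res = resolution
        while res > 4:
            cin = ch[res]
            cout = ch[res // 2]
            self.blocks.append(Conv2d(cin, cout, 3, rng))
            res //= 2
        self.final_conv = Conv2d(ch[4], ch[4], 3, rng)
        self.fc = Dense(ch[4] * 16, 64, rng)
        self.out = Dense(64, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.from_rgb(x).leaky_relu(0.2)
        for conv in self.blocks:
            h = conv(h).leaky_relu(0.2).avgpool2x()
        h = self.final_conv(h).leaky_relu(0.2)
        B = h.shape[0]
        h = h.reshape(B, -1)
        return self.out(self.fc(h).leaky_relu(0.2))


# ---------------------------------------------------------------------------
# losses and metrics


def nonsaturating_losses(real_logits, fake_logits):
    """(generator_loss, discriminator_loss) for logistic GAN training.

    d_loss = E[softplus(-real)] + E[softplus(fake)];
    g_loss = E[softplus(-fake)] (the non-saturating generator objective).
    """
    r = real_logits if isinstance(real_logits, Tensor) else Tensor(real_logits)
    f = fake_logits if isinstance(fake_logits, Tensor) else Tensor(fake_logits)
    d_loss = (-r).softplus().mean() + f.softplus().mean()
    g_loss = (-f).softplus().mean()
    return g_loss, d_loss


def r1_penalty(discriminator: Callable[[Tensor], Tensor], real_batch,
               gamma: float):
    """(gamma/2) * E[ ||d logit / d x||^2 ] at real samples.

    Returns a graph-attached scalar Tensor so the penalty can be
    backpropagated into the discriminator weights (double backward).
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    x = Tensor(np.asarray(real_batch, dtype=DTYPE), requires_grad=True)
    logits = discriminator(x)
    if not isinstance(logits, Tensor):
        raise TypeError("discriminator must return a graph Tensor "
                        "(differentiable w.r.t. its input)")
    g, = grad(logits.sum(), [x], create_graph=True)
    axes = tuple(range(1, len(x.shape)))
    per_sample = (g ** 2.0).sum(axis=axes)
    return (gamma / 2.0) * per_sample.mean()


def fid(features_real: np.ndarray, features_fake: np.ndarray) -> float:
    """Fréchet distance between Gaussian fits of two feature sets.

    ||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2}); small negative
    eigen-noise is clamped to zero, so the value is always >= 0 and exactly
    0 for identical moments.
    """
    a = np.atleast_2d(np.asarray(features_real, dtype=np.float64))
    b = np.atleast_2d(np.asarray(features_fake, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions must match")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors per set")
    mu1, mu2 = a.mean(axis=0), b.mean(axis=0)
    s1 = np.atleast_2d(np.cov(a, rowvar=False))
    s2 = np.atleast_2d(np.cov(b, rowvar=False))
    covmean = np.real(np.asarray(linalg.sqrtm(s1 @ s2)))
    value = float(
        np.sum((mu1 - mu2) ** 2) + np.trace(s1 + s2 - 2.0 * covmean)
    )
    return max(value, 0.0)


class RandomConvFeatures:
    """Fixed seeded random-convnet embedding for desk-scale FID ranking.

    Three conv/pool stages followed by global mean and standard-deviation
    pooling. Weights never train, so the embedding is a stable measurement
    instrument within and across runs of the same profile.
    """

    def __init__(self, in_channels: int = 3, seed: int = 20260928):
        rng = np.random.default_rng(seed)
        self.convs = [
            Conv2d(in_channels, 8, 3, rng),
            Conv2d(8, 16, 3, rng),
            Conv2d(16, 32, 3, rng),
        ]

    def __call__(self, images01: np.ndarray) -> np.ndarray:
        h = Tensor(np.asarray(images01, dtype=DTYPE) * 2.0 - 1.0)
        feats = []
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2).avgpool2x()
        data = h.data
        mean = data.mean(axis=(2, 3))
        std = data.std(axis=(2, 3))
        feats = np.concatenate([mean, std], axis=1)
        return feats.astype(np.float64)


# ---------------------------------------------------------------------------
# training


@dataclass
class GanTrainConfig:
    resolution: int = 32
    dim_z: int = 64
    dim_w: int = 64
    channel_base: int = 256
    channel_max: int = 48
    out_channels: int = 3
    r1_gamma: float = 6.5536
    lr: float = 0.002
    betas: tuple = (0.0, 0.99)
    batch_size: int = 16
    total_steps: int = 1200
    r1_interval: int = 16
    aug_prob: float = 0.2
    fid_interval: int = 200
    fid_n: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.r1_gamma < 0:
            raise ValueError("r1_gamma must be non-negative")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


def _augment(x: Tensor, rng: np.random.Generator, p: float) -> Tensor:
    """Differentiable discriminator-input augmentation.

    Brightness/contrast jitter and small integer translations; never a
    horizontal flip (would erase dextro/levo information) and no cutout.
    """
    if rng.random() < p:
        x = x * float(rng.uniform(0.75, 1.33))
    if rng.random() < p:
        x = x + float(rng.uniform(-0.2, 0.2))
    if rng.random() < p:
        dy, dx = int(rng.integers(-2, 3)), int(rng.integers(-2, 3))
        if dy or dx:
            x = x.shift2d(dy, dx)
    return x


@dataclass
class Checkpoint:
    step: int
    fid: float
    state: dict
    arch: dict


@dataclass
class GanTrainResult:
    generator: Generator
    discriminator: Discriminator
    checkpoints: list
    fid_trace: list                      # (step, fid) pairs
    loss_trace: list                     # (step, d_loss, g_loss)
    config: GanTrainConfig

    def fid_trace_frame(self):
        import pandas as pd

        return pd.DataFrame(self.fid_trace, columns=["iteration", "fid"])


def select_checkpoint(checkpoints: Sequence[Checkpoint]) -> Checkpoint:
    """Checkpoint with the lowest FID; ties broken by earliest iteration."""
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    return min(checkpoints, key=lambda c: (c.fid, c.step))


def build_generator(checkpoint: Checkpoint, channel_base: int = 256,
                    channel_max: int = 48) -> Generator:
    gen = Generator(channel_base=channel_base, channel_max=channel_max,
                    **checkpoint.arch)
    gen.load_state_dict(checkpoint.state)
    return gen


class StyleGan:
    """Estimator-style trainer: ``fit(X)`` on images, fitted ``generator_``.

    ``X`` is an (N, C, R, R) array in [0, 1]. After ``fit``, ``generator_``
    is the FID-selected generator, ``checkpoints_`` the recorded series and
    ``fid_trace_`` the (step, fid) log.
    """

    def __init__(self, **config):
        self.config = GanTrainConfig(**config)
        self.feature_extractor: Optional[Callable] = None

    def get_params(self, deep: bool = True):
        return asdict(self.config)

    def set_params(self, **params):
        self.config = GanTrainConfig(**{**asdict(self.config), **params})
        return self

    def fit(self, X, y=None):
        cfg = self.config
        X = np.asarray(X, dtype=DTYPE)
        if X.ndim != 4 or X.shape[2] != cfg.resolution or X.shape[3] != cfg.resolution:
            raise ValueError(
                f"expected (N, C, {cfg.resolution}, {cfg.resolution}) images"
            )
        if X.min() < 0 or X.max() > 1:
            raise ValueError("images must lie in [0, 1]")
        n = X.shape[0]
        rng = np.random.default_rng(cfg.seed)

        gen = Generator(cfg.resolution, cfg.dim_z, cfg.dim_w, cfg.channel_base,
                        cfg.channel_max, cfg.out_channels,
                        seed=int(rng.integers(2**31 - 1)))
        disc = Discriminator(cfg.resolution, cfg.channel_base, cfg.channel_max,
                             cfg.out_channels, seed=int(rng.integers(2**31 - 1)))
        opt_g = Adam(gen.parameters(), cfg.lr, cfg.betas)
        opt_d = Adam(disc.parameters(), cfg.lr, cfg.betas)

        feats = self.feature_extractor or RandomConvFeatures(cfg.out_channels)
        fid_real_idx = rng.choice(n, size=min(n, cfg.fid_n), replace=False)
        feats_real = feats(X[fid_real_idx])
        z_eval = rng.standard_normal((min(n, cfg.fid_n), cfg.dim_z)).astype(DTYPE)

        X2 = X * 2.0 - 1.0
        checkpoints, fid_trace, loss_trace = [], [], []

        def record(step):
            w = gen.map_latents(z_eval)
            fakes01 = gen.synthesize01(w)
            value = fid(feats_real, feats(fakes01))
            fid_trace.append((step, value))
            checkpoints.append(Checkpoint(step=step, fid=value,
                                          state=gen.state_dict(),
                                          arch=gen.arch_config()))

        for step in range(cfg.total_steps):
            # discriminator update (generator frozen via detached fakes)
            idx = rng.integers(0, n, size=cfg.batch_size)
            real = X2[idx]
            z = rng.standard_normal((cfg.batch_size, cfg.dim_z)).astype(DTYPE)
            with no_grad():
                fake = gen.synthesis(gen.mapping(Tensor(z))).data
            r_log = disc(_augment(Tensor(real), rng, cfg.aug_prob))
            f_log = disc(_augment(Tensor(fake), rng, cfg.aug_prob))
            _, d_loss = nonsaturating_losses(r_log, f_log)
            d_total = d_loss
            if step % cfg.r1_interval == 0:
                penalty = r1_penalty(disc, real, cfg.r1_gamma)
                d_total = d_total + penalty * float(cfg.r1_interval)
            opt_d.step(grad(d_total, disc.parameters()))

            # generator update (discriminator weights frozen: only its
            # activations carry gradient back to the generator)
            z = rng.standard_normal((cfg.batch_size, cfg.dim_z)).astype(DTYPE)
            fake = gen.synthesis(gen.mapping(Tensor(z)))
            with frozen(disc):
                g_loss, _ = nonsaturating_losses(
                    Tensor(np.zeros((1, 1), dtype=DTYPE)),
                    disc(_augment(fake, rng, cfg.aug_prob)),
                )
            opt_g.step(grad(g_loss, gen.parameters()))

            loss_trace.append((step, float(d_loss.data), float(g_loss.data)))
            if (step + 1) % cfg.fid_interval == 0 or step + 1 == cfg.total_steps:
                record(step + 1)

        self.checkpoints_ = checkpoints
        self.fid_trace_ = fid_trace
        self.loss_trace_ = loss_trace
        self.discriminator_ = disc
        best = select_checkpoint(checkpoints)
        self.generator_ = build_generator(best, cfg.channel_base, cfg.channel_max)
        self.selected_checkpoint_ = best
        return self

    def result(self) -> GanTrainResult:
        return GanTrainResult(
            generator=self.generator_, discriminator=self.discriminator_,
            checkpoints=self.checkpoints_, fid_trace=self.fid_trace_,
            loss_trace=self.loss_trace_, config=self.config,
        )


def train_gan(manifest: DatasetManifest, config: GanTrainConfig,
              images: Optional[np.ndarray] = None,
              feature_extractor: Optional[Callable] = None) -> GanTrainResult:
    """Train on a manifest's upstream split; refuses non-diseased images.

    ``images`` may carry the preprocessed (N, C, R, R) array aligned with
    the manifest rows; otherwise images are taken from the manifest and
    channel-stacked at the configured resolution.
    """
    frame = manifest.frame
    if not (frame.label == 1).all():
        raise ValueError(
            "upstream GAN training requires a diseased-only split; "
            "found normal-labelled images"
        )
    if images is None:
        from .preprocess import RadiographPreprocessor

        prep = RadiographPreprocessor(target_resolution=config.resolution)
        images = prep.transform([manifest.images[i] for i in frame.image_id])
    est = StyleGan(**asdict(config))
    if feature_extractor is not None:
        est.feature_extractor = feature_extractor
    est.fit(images)
    return est.result()


CHECKPOINT_FORMAT_VERSION = 1


def save_checkpoint(path: str, checkpoint: Checkpoint):
    np.savez(path, __version=CHECKPOINT_FORMAT_VERSION,
             __step=checkpoint.step, __fid=checkpoint.fid,
             __arch=np.array(list(checkpoint.arch.items()), dtype=object),
             **checkpoint.state)


def load_checkpoint(path: str) -> Checkpoint:
    data = np.load(path, allow_pickle=True)
    arch = {k: int(v) for k, v in data["__arch"]}
    state = {k: data[k] for k in data.files if not k.startswith("__")}
    return Checkpoint(step=int(data["__step"]), fid=float(data["__fid"]),
                      state=state, arch=arch)
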