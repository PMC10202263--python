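"""Optimization-based GAN inversion: latent features from a frozen generator.

A query image is embedded by minimizing the L2 distance between the
generator's output and the query over a *W-space* vector (the shared
intermediate latent, not the per-layer W+ extension), for a fixed number of
gradient steps with the generator weights frozen. The optimized W vector is
the classification feature handed to the projection head; the reconstructed
image supports quality analysis (PSNR/SSIM/RMSE).

Defaults follow the standard projector recipe: initialize at the mean W of
many mapped z draws, Adam on the latent with a warm-up/cosine-ramp-down
learning rate, 1000 iterations, and a noise-map regularization term whose
weight is zero here because the reduced generator carries no per-layer
noise inputs (the hook stays in the config for generators that do).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._autodiff import DTYPE, Tensor, grad, no_grad
from .nn import Adam, Module, frozen
from contextlib import nullcontext
from .synthdata import DatasetManifest, Radiograph


@dataclass
class InversionConfig:
    iterations: int = 1000
    lr: float = 0.1
    lr_warmup_frac: float = 0.05
    lr_rampdown_frac: float = 0.25
    noise_weight: float = 0.0       # no noise maps in the reduced generator
    init: str = "w_mean"            # or "zeros"
    n_mean_samples: int = 1000
    seed: int = 0
    batch_size: int = 64

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.noise_weight < 0:
            raise ValueError("noise regularization weight must be >= 0")
        if self.init not in ("w_mean", "zeros"):
            raise ValueError("init must be 'w_mean' or 'zeros'")


@dataclass
class LatentCode:
    vector: np.ndarray
    space: str                      # "Z" or "W"
    source_image_id: Optional[str] = None

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.isfinite(self.vector).all():
            raise ValueError("latent entries must be finite")
        if self.space not in ("Z", "W"):
            raise ValueError("space must be 'Z' or 'W'")


@dataclass
class InversionResult:
    latent: LatentCode
    reconstruction: np.ndarray      # [0,1], same shape as the query
    loss_trace: np.ndarray          # per-iteration total loss
    final_l2: float                 # recomputed L2(G(latent), query), [0,1] scale
    config: dict = field(default_factory=dict)
    converged: bool = True


def _lr_schedule(cfg: InversionConfig, t: int) -> float:
    T = cfg.iterations
    frac = t / max(T - 1, 1)
    warm = min(1.0, (t + 1) / max(1, int(cfg.lr_warmup_frac * T)))
    ramp = 1.0
    if frac > 1.0 - cfg.lr_rampdown_frac:
        x = (frac - (1.0 - cfg.lr_rampdown_frac)) / cfg.lr_rampdown_frac
        ramp = 0.5 * (1.0 + np.cos(np.pi * x))
    return cfg.lr * warm * ramp


def _initial_w(generator, cfg: InversionConfig, n: int) -> np.ndarray:
    if cfg.init == "zeros" or not hasattr(generator, "map_latents"):
        return np.zeros((n, generator.dim_w), dtype=DTYPE)
    rng = np.random.default_rng(cfg.seed)
    z = rng.standard_normal((cfg.n_mean_samples, generator.dim_z)).astype(DTYPE)
    w_mean = generator.map_latents(z).mean(axis=0)
    return np.tile(w_mean, (n, 1)).astype(DTYPE)


def _to01(raw: np.ndarray) -> np.ndarray:
    return np.clip((raw + 1.0) / 2.0, 0.0, 1.0)


def invert_batch(
    queries: np.ndarray, generator, config: Optional[InversionConfig] = None,
    image_ids: Optional[Sequence[str]] = None,
) -> list:
    """Invert a batch of [0,1] images jointly (per-image trajectories are
    independent: the loss decouples across the batch and Adam is diagonal).

    Returns one :class:`InversionResult` per image, tracking each image's
    best-so-far latent by total loss. The generator is asserted frozen by a
    weight hash before/after when it exposes one.
    """
    cfg = config or InversionConfig()
    queries = np.asarray(queries, dtype=DTYPE)
    n = queries.shape[0]
    res = getattr(generator, "resolution", None)
    if res is not None and queries.shape[-2:] != (res, res):
        raise ValueError(
            f"queries must be preprocessed to generator resolution {res}"
        )

    hash_before = generator.weight_hash() if hasattr(generator, "weight_hash") else None
    target = queries * 2.0 - 1.0    # optimize on the generator's raw scale

    w = Tensor(_initial_w(generator, cfg, n), requires_grad=True)
    opt = Adam([w], cfg.lr)
    sum_axes = tuple(range(1, queries.ndim))

    best_loss = np.full(n, np.inf)
    best_w = w.data.copy()
    trace = np.empty((cfg.iterations, n), dtype=np.float64)

    guard = frozen(generator) if isinstance(generator, Module) else nullcontext()
    with guard:
        for t in range(cfg.iterations):
            opt.lr = _lr_schedule(cfg, t)
            raw = generator.synthesis(w)
            diff = raw - Tensor(target)
            per_image = (diff ** 2.0).sum(axis=sum_axes)   # (n,)
            total = per_image.sum()
            g, = grad(total, [w])
            losses = per_image.data.astype(np.float64)
            trace[t] = losses
            improved = losses < best_loss
            if improved.any():
                best_loss[improved] = losses[improved]
                best_w[improved] = w.data[improved]
            opt.step([g])

    if hash_before is not None and generator.weight_hash() != hash_before:
        raise RuntimeError("generator weights changed during inversion")

    with no_grad():
        recon_raw = generator.synthesis(Tensor(best_w)).data
    recon01 = _to01(recon_raw)

    results = []
    for i in range(n):
        final_l2 = float(np.sum((recon01[i] - queries[i]) ** 2))
        converged = bool(np.isfinite(trace[:, i]).all())
        results.append(
            InversionResult(
                latent=LatentCode(
                    vector=best_w[i],
                    space="W",
                    source_image_id=None if image_ids is None else image_ids[i],
                ),
                reconstruction=recon01[i],
                loss_trace=trace[:, i].copy(),
                final_l2=final_l2,
                config=asdict(cfg),
                converged=converged,
            )
        )
    return results


def invert(query, generator, config: Optional[InversionConfig] = None) -> InversionResult:
    """Invert a single [0,1] image; see :func:`invert_batch`."""
    queries = np.asarray(query, dtype=DTYPE)[None]
    result = invert_batch(queries, generator, config)[0]
    if not result.converged:
        raise FloatingPointError(
            "inversion diverged (non-finite loss); trace attached on the result"
        )
    return result


def invert_dataset(
    manifest: DatasetManifest, generator, config: Optional[InversionConfig] = None,
    images: Optional[np.ndarray] = None, preprocessor=None,
) -> pd.DataFrame:
    """Latent table for every image of a manifest split.

    Rows are ordered by image_id (stable under manifest shuffling); columns
    are image_id, label, w1..w_dim, final_l2, converged. Divergent images
    are recorded, not fatal.
    """
    cfg = config or InversionConfig()
    frame = manifest.frame.sort_values("image_id").reset_index(drop=True)
    if images is None:
        if preprocessor is None:
            from .preprocess import RadiographPreprocessor

            preprocessor = RadiographPreprocessor(
                target_resolution=generator.resolution
            )
        images = preprocessor.transform(
            [manifest.images[i] for i in frame.image_id]
        )
    else:
        order = np.argsort(manifest.frame.image_id.to_numpy())
        images = np.asarray(images)[order]

    rows = []
    for start in range(0, len(frame), cfg.batch_size):
        chunk = frame.iloc[start : start + cfg.batch_size]
        results = invert_batch(
            images[start : start + len(chunk)], generator, cfg,
            image_ids=list(chunk.image_id),
        )
        for (_, meta), res in zip(chunk.iterrows(), results):
            row = {"image_id": meta.image_id, "label": int(meta.label)}
            row.update(
                {f"w{j + 1}": v for j, v in enumerate(res.latent.vector)}
            )
            row["final_l2"] = res.final_l2
            row["converged"] = res.converged
            rows.append(row)
    table = pd.DataFrame(rows)
    n_failed = int((~table.converged).sum())
    if n_failed:
        import logging

        logging.getLogger(__name__).warning(
            "%d of %d inversions diverged", n_failed, len(table)
        )
    return table


def latent_matrix(table: pd.DataFrame):
    """(X, y) arrays from an inversion latent table."""
    cols = [c for c in table.columns if c.startswith("w") and c[1:].isdigit()]
    return table[cols].to_numpy(dtype=np.float64), table["label"].to_numpy(dtype=int)
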