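"""Closed-form latent direction discovery and traversal rendering.

The dominant directions of variation a style-based generator has learned
can be read directly off its weights: the right singular vectors of the
first style-affine matrix (the map from W to the first layer's channel
styles) order the W-space axes by how strongly they steer synthesis. On a
generator trained on scoliotic spines one of the leading directions
empirically acts as a "scoliosis axis" — walking a latent along it sweeps
the rendered curve between left- and right-convex shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DirectionSet:
    vectors: np.ndarray          # (k, dim_w), unit rows, orthogonal
    singular_values: np.ndarray  # (k,), non-increasing

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.singular_values = np.asarray(self.singular_values, dtype=np.float64)
        gram = self.vectors @ self.vectors.T
        if not np.allclose(gram, np.eye(len(self.vectors)), atol=1e-6):
            raise ValueError("direction vectors must be orthonormal")
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise ValueError("singular values must be non-increasing")


def sefa_directions(generator, k: int) -> DirectionSet:
    """Top-k dominant W-space directions from the first style-affine weight.

    Computed as the leading eigenvectors of A A^T where A (dim_w x c) is
    the transposed weight of the first modulated layer's affine map —
    equivalently the top right singular vectors of the style projection.
    """
    A = np.asarray(generator.style_matrix(), dtype=np.float64)  # (dim_w, c)
    dim_w = A.shape[0]
    if not (1 <= k <= dim_w):
        raise ValueError(f"k must lie in [1, {dim_w}]")
    evals, evecs = np.linalg.eigh(A @ A.T)
    order = np.argsort(evals)[::-1][:k]
    sigma = np.sqrt(np.clip(evals[order], 0.0, None))
    return DirectionSet(vectors=evecs[:, order].T, singular_values=sigma)


def traverse(generator, w: np.ndarray, direction: np.ndarray, alphas) -> np.ndarray:
    """Render G(w + alpha * d) for each alpha; returns (len(alphas), C, R, R).

    ``alpha = 0`` reproduces the base reconstruction bit-exactly (same code
    path, zero offset).
    """
    alphas = np.asarray(alphas, dtype=np.float64)
    if not np.isfinite(alphas).all():
        raise ValueError("alphas must be finite")
    d = np.asarray(direction, dtype=np.float64)
    if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-5):
        raise ValueError("direction must be unit-norm")
    w = np.asarray(w, dtype=np.float64).ravel()
    ws = (w[None, :] + alphas[:, None] * d[None, :]).astype(np.float32)
    return generator.synthesize01(ws)


def spine_curvature_score(image01: np.ndarray) -> float:
    """Signed lateral-deviation score of the bright spine band.

    For each row of the (grayscale) image, the intensity-weighted centroid
    of the brightest central band is computed; the score is the half-height
    weighted mean of the centroid's signed deviation from the vertical
    midline (positive: bulge to the right in image coordinates — the
    dextro direction). Monotone in the rendered curve amplitude for
    C-shaped spines.
    """
    img = np.asarray(image01, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=0)
    H, W = img.shape
    cx = (W - 1) / 2.0
    b0 = int(0.25 * W)
    band = slice(b0, W - b0)        # mirror-symmetric about the midline
    xs = np.arange(W, dtype=np.float64)[band]
    sub = img[:, band]
    # emphasize bright structures (vertebrae) over the soft background
    wgt = np.clip(sub - np.percentile(sub, 60, axis=1, keepdims=True), 0, None)
    mass = wgt.sum(axis=1)
    safe = mass > 1e-9
    centroid = np.full(H, cx)
    centroid[safe] = (wgt[safe] * xs[None, :]).sum(axis=1) / mass[safe]
    rows = np.arange(H, dtype=np.float64) / max(H - 1, 1)
    weight = np.sin(np.pi * rows)        # apex-sensitive half-sine weighting
    return float(np.sum(weight * (centroid - cx)) / np.sum(weight))


def tile_strip(images01: np.ndarray) -> np.ndarray:
    """Horizontally tile a traversal (N, C, R, R) into one (R, N*R) image."""
    imgs = np.asarray(images01)
    if imgs.ndim == 4:
        imgs = imgs.mean(axis=1)
    return np.concatenate(list(imgs), axis=1)
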