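"""Radiograph preprocessing: spacing correction, CLAHE, pad-to-square, resize.

The chain enhances bone/soft-tissue contrast while strictly preserving the
physical aspect ratio of the film — naive resizing would change apparent
spinal curvature, which is exactly the signal being screened for. Order:

    spacing correction -> CLAHE -> aspect-preserving pad + resize -> stack

CLAHE runs before padding so the zero pad border cannot distort tile
histograms. The clip limit follows the common 8-bit convention (multiples
of the uniform histogram level per bin, default 2.0 with an (8,8) tile
grid); images are quantized to 8 bits for the histogram operation and
rescaled to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

from .synthdata import Radiograph

logger = logging.getLogger(__name__)

_warned_no_spacing = False


@dataclass
class PreprocessConfig:
    clahe_clip_limit: float = 2.0        # per-bin multiple of the uniform level
    clahe_tile_grid: tuple = (8, 8)
    clahe_nbins: int = 256
    target_resolution: int = 512         # micro profile: 64 (or 32)
    pad_value: float = 0.0

    def __post_init__(self):
        if self.clahe_clip_limit <= 0:
            raise ValueError("clip limit must be positive")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("tile grid must be at least (1, 1)")
        if self.target_resolution < 32:
            raise ValueError("target resolution must be at least 32")


def correct_spacing(image: Radiograph) -> Radiograph:
    """Resample to mm-isotropic pixels when row/column spacing differ.

    The denser axis is resampled down to the coarser spacing so the output's
    physical extent ratio matches the original film. Images without spacing
    metadata pass through unchanged (with a warning).
    """
    if image.spacing is None:
        global _warned_no_spacing
        if not _warned_no_spacing:
            logger.warning(
                "no pixel-spacing metadata; assuming isotropic pixels "
                "(warning shown once)"
            )
            _warned_no_spacing = True
        return image
    row_mm, col_mm = image.spacing
    if row_mm <= 0 or col_mm <= 0:
        raise ValueError("pixel spacing must be positive")
    if np.isclose(row_mm, col_mm):
        return image
    H, W = image.pixels.shape
    target = max(row_mm, col_mm)
    new_h = max(1, round(H * row_mm / target))
    new_w = max(1, round(W * col_mm / target))
    resampled = transform.resize(
        image.pixels, (new_h, new_w), order=1, anti_aliasing=False,
        preserve_range=True,
    )
    return Radiograph(
        pixels=np.clip(resampled, 0.0, 1.0),
        spacing=(target, target),
        label=image.label,
        cobb_angle_deg=image.cobb_angle_deg,
        has_device_artifact=image.has_device_artifact,
    )


def clahe_equalize(pixels: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] grid."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.min() < 0 or pixels.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")
    quantized = np.round(pixels * 255).astype(np.uint8)
    H, W = quantized.shape
    gy, gx = config.clahe_tile_grid
    kernel = (max(1, H // gy), max(1, W // gx))
    out = exposure.equalize_adapthist(
        quantized,
        kernel_size=kernel,
        clip_limit=config.clahe_clip_limit / config.clahe_nbins,
        nbins=config.clahe_nbins,
    )
    return np.clip(out, 0.0, 1.0)


def pad_and_resize(pixels: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Scale the long side to the target and pad the short side, centered."""
    pixels = np.asarray(pixels, dtype=np.float64)
    H, W = pixels.shape
    if H == 0 or W == 0:
        raise ValueError("image must be non-empty")
    R = config.target_resolution
    scale = R / max(H, W)
    new_h = max(1, round(H * scale))
    new_w = max(1, round(W * scale))
    if (new_h, new_w) == (H, W):
        content = pixels
    else:
        content = transform.resize(
            pixels, (new_h, new_w), order=1, anti_aliasing=(scale < 1.0),
            preserve_range=True,
        )
    out = np.full((R, R), config.pad_value, dtype=np.float64)
    top = (R - new_h) // 2
    left = (R - new_w) // 2
    out[top : top + new_h, left : left + new_w] = content
    return np.clip(out, 0.0, 1.0)


def stack_channels(pixels: np.ndarray) -> np.ndarray:
    """Replicate a single-channel image into (3, H, W)."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError("expected a single-channel (2-D) image")
    return np.stack([pixels, pixels, pixels], axis=0)


def preprocess_pipeline(image: Radiograph, config: PreprocessConfig) -> np.ndarray:
    """Full chain; returns a (3, R, R) float array in [0, 1]."""
    corrected = correct_spacing(image)
    equalized = clahe_equalize(corrected.pixels, config)
    squared = pad_and_resize(equalized, config)
    return stack_channels(squared)


class RadiographPreprocessor:
    """sklearn-style transformer wrapping the preprocessing chain.

    Stateless (``fit`` is a no-op); ``transform`` maps a list of
    :class:`Radiograph` to an (N, 3, R, R) array.
    """

    def __init__(self, clahe_clip_limit: float = 2.0, clahe_tile_grid=(8, 8),
                 target_resolution: int = 512, pad_value: float = 0.0):
        self.clahe_clip_limit = clahe_clip_limit
        self.clahe_tile_grid = clahe_tile_grid
        self.target_resolution = target_resolution
        self.pad_value = pad_value

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            clahe_clip_limit=self.clahe_clip_limit,
            clahe_tile_grid=tuple(self.clahe_tile_grid),
            target_resolution=self.target_resolution,
            pad_value=self.pad_value,
        )

    def get_params(self, deep: bool = True):
        return dict(
            clahe_clip_limit=self.clahe_clip_limit,
            clahe_tile_grid=self.clahe_tile_grid,
            target_resolution=self.target_resolution,
            pad_value=self.pad_value,
        )

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        self._config()  # validates
        return self

    def transform(self, X):
        cfg = self._config()
        return np.stack([preprocess_pipeline(rad, cfg) for rad in X])

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
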