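"""Synthetic frontal-radiograph phantoms with known spinal curvature.

The generator emulates the structure that matters for curvature screening
on a chest film: a low-contrast torso, symmetric rib arcs, and a column of
vertebral bodies laid along a parametric centerline whose ground-truth Cobb
angle is known analytically. Severity is controlled in degrees, curve
direction follows the clinical dextro/levo convention (left-convex curves
are the minority), and optional bright curved "external device" lines model
the catheter/tube confounders that inflate false positives in screening.

Dataset recipes mirror a two-stage screening study design: a diseased-only
upstream split for generative training, a 1:1 balanced downstream split for
probing, and an imbalanced held-out test split.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

DIAGNOSTIC_THRESHOLD_DEG = 20.0

# offset of the artifact stream from the spec seed, so spine geometry and
# device-line placement are independent draws
_ARTIFACT_SEED_OFFSET = 77003


@dataclass(frozen=True)
class SpineSpec:
    """Parametric spine: lateral offset x(t) = dir * sum_i a_i sin(2π f_i t + φ_i).

    ``t`` runs 0..1 from the top to the bottom of the spine; offsets and
    vertebra sizes are in units of spine length, so the derived Cobb angle
    is independent of the rendered resolution. Phases are chosen so term
    ``i`` peaks at apex position ``apexes[i]``.
    """

    n_vertebrae: int = 16
    amplitudes: tuple = ()            # unit: fraction of spine length, >= 0
    frequencies: tuple = ()           # cycles over the spine length
    apexes: tuple = ()                # normalized height of each term's apex
    direction: int = 1                # +1 dextro, -1 levo
    vertebra_width: float = 0.055
    vertebra_height: float = 0.034
    rng_seed: int = 0

    def __post_init__(self):
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 (dextro) or -1 (levo)")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if any(not (0.0 < c < 1.0) for c in self.apexes):
            raise ValueError("apex positions must lie in (0, 1)")
        if not (len(self.amplitudes) == len(self.frequencies) == len(self.apexes)):
            raise ValueError("amplitudes/frequencies/apexes must align")

    def centerline(self, t: np.ndarray) -> np.ndarray:
        """Signed lateral offset (spine-length units) at normalized height t."""
        t = np.asarray(t, dtype=np.float64)
        x = np.zeros_like(t)
        for a, f, c in zip(self.amplitudes, self.frequencies, self.apexes):
            phase = np.pi / 2.0 - 2.0 * np.pi * f * c
            x = x + a * np.sin(2.0 * np.pi * f * t + phase)
        return self.direction * x

    def tangent_angles(self, t: np.ndarray) -> np.ndarray:
        """Tangent angle (deg, from vertical) of the centerline at t."""
        t = np.asarray(t, dtype=np.float64)
        dx = np.zeros_like(t)
        for a, f, c in zip(self.amplitudes, self.frequencies, self.apexes):
            phase = np.pi / 2.0 - 2.0 * np.pi * f * c
            dx = dx + a * 2.0 * np.pi * f * np.cos(2.0 * np.pi * f * t + phase)
        return np.degrees(np.arctan(self.direction * dx))


@dataclass
class Radiograph:
    """A 2-D intensity grid with optional physical spacing and labels."""

    pixels: np.ndarray                       # (H, W), float in [0, 1]
    spacing: Optional[tuple] = None          # (row_mm, col_mm)
    label: Optional[int] = None              # 1 scoliosis, 0 normal
    cobb_angle_deg: Optional[float] = None
    has_device_artifact: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("intensities must lie in [0, 1]")
        if self.spacing is not None and any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    def validate_label(self, threshold: float = DIAGNOSTIC_THRESHOLD_DEG):
        if self.label is not None and self.cobb_angle_deg is not None:
            expected = int(self.cobb_angle_deg >= threshold)
            if self.label != expected:
                raise ValueError("label inconsistent with Cobb angle and threshold")


def cobb_angle(spec: SpineSpec, n_samples: int = 4001) -> float:
    """Ground-truth Cobb angle (degrees) of a spec's centerline.

    The maximum angle between centerline tangents over the spine — the
    continuous analogue of picking the two most-tilted endplates — computed
    on a dense grid. Direction-invariant and 0 for a straight spine.
    """
    if spec.n_vertebrae < 3:
        raise ValueError("need at least 3 vertebrae to define a Cobb angle")
    if not spec.amplitudes or all(a == 0 for a in spec.amplitudes):
        return 0.0
    theta = spec.tangent_angles(np.linspace(0.0, 1.0, n_samples))
    return float(theta.max() - theta.min())


def _scaled(spec: SpineSpec, s: float) -> SpineSpec:
    return dataclasses.replace(
        spec, amplitudes=tuple(a * s for a in spec.amplitudes)
    )


def make_spine_spec(
    rng: np.random.Generator,
    severity_range=(20.0, 45.0),
    levo_fraction: float = 0.125,
    n_vertebrae: int = 16,
) -> SpineSpec:
    """Draw a random spine whose Cobb angle falls in ``severity_range``.

    The curve shape (one or two sinusoidal terms, apex positions, relative
    amplitudes) is sampled first; the overall amplitude scale is then solved
    by bisection so the derived Cobb angle matches a target drawn uniformly
    from the range. ``levo_fraction`` is the probability of a left-convex
    curve (clinically ~10-15%).
    """
    lo, hi = float(severity_range[0]), float(severity_range[1])
    if not (0.0 <= lo <= hi <= 60.0):
        raise ValueError("severity_range must satisfy 0 <= lo <= hi <= 60 degrees")
    if not (0.0 <= levo_fraction <= 1.0):
        raise ValueError("levo_fraction must be a probability")

    target = float(rng.uniform(lo, hi))
    direction = -1 if rng.random() < levo_fraction else +1
    seed = int(rng.integers(0, 2**31 - 1))

    two_terms = rng.random() < 0.4
    freqs = [float(rng.uniform(0.5, 0.9))]
    apexes = [float(rng.uniform(0.3, 0.7))]
    amps = [1.0]
    if two_terms:
        freqs.append(float(rng.uniform(0.9, 1.4)))
        apexes.append(float(rng.uniform(0.2, 0.8)))
        amps.append(float(rng.uniform(0.2, 0.6)))

    base = SpineSpec(
        n_vertebrae=n_vertebrae,
        amplitudes=tuple(amps),
        frequencies=tuple(freqs),
        apexes=tuple(apexes),
        direction=direction,
        rng_seed=seed,
    )
    if target == 0.0:
        return _scaled(base, 0.0)

    # Cobb angle is monotone in the joint amplitude scale: bisection.
    s_lo, s_hi = 0.0, 0.02
    while cobb_angle(_scaled(base, s_hi)) < target:
        s_hi *= 2.0
        if s_hi > 10.0:
            raise RuntimeError("amplitude solve failed to bracket target angle")
    for _ in range(60):
        mid = 0.5 * (s_lo + s_hi)
        if cobb_angle(_scaled(base, mid)) < target:
            s_lo = mid
        else:
            s_hi = mid
    return _scaled(base, 0.5 * (s_lo + s_hi))


def render_radiograph(
    spec: SpineSpec,
    height: int = 64,
    width: int = 64,
    artifact_prob: float = 0.0,
    spacing: Optional[tuple] = None,
) -> Radiograph:
    """Render a spec into a torso phantom; deterministic given inputs.

    Background (torso ellipse, rib arcs) is left-right symmetric about the
    image center, so negating the spec's direction mirrors the spine
    exactly. Device-line artifacts are drawn from a stream seeded by the
    spec, independent of the spine geometry.
    """
    if height < 32 or width < 32:
        raise ValueError("height and width must be at least 32 pixels")

    H, W = int(height), int(width)
    img = np.zeros((H, W), dtype=np.float64)
    yy = np.arange(H, dtype=np.float64)[:, None]
    xx = np.arange(W, dtype=np.float64)[None, :]
    cx = (W - 1) / 2.0
    cy = (H - 1) / 2.0

    # torso: soft-edged ellipse
    ell = ((xx - cx) / (0.34 * W)) ** 2 + ((yy - cy) / (0.44 * H)) ** 2
    img += 0.22 / (1.0 + np.exp((ell - 1.0) * 12.0))

    # rib arcs: symmetric parabolic ridges
    drop = 0.035 * H * (((xx - cx) / (0.30 * W)) ** 2)
    sigma_r = max(0.35, 0.008 * H)
    for k in range(1, 7):
        y_k = 0.14 * H + 0.075 * H * k
        img += 0.085 * np.exp(-((yy - (y_k + drop)) ** 2) / (2.0 * sigma_r**2)) * (
            np.abs(xx - cx) < 0.33 * W
        )

    # vertebral bodies along the centerline
    y0, y1 = 0.08 * H, 0.92 * H
    span = y1 - y0
    t_centers = (np.arange(spec.n_vertebrae) + 0.5) / spec.n_vertebrae
    offs = spec.centerline(t_centers) * span
    wx = max(1.0, spec.vertebra_width * span / 2.0)
    wy = max(0.8, spec.vertebra_height * span / 2.0)
    dxc = xx - cx          # exact: pixel offsets from the midline
    for t_c, off in zip(t_centers, offs):
        vy = y0 + t_c * span
        # (x - cx) - off negates exactly under direction flip, and the
        # quartic via repeated squaring is sign-exact, so mirroring the
        # spec mirrors the rendered spine bit-for-bit
        ux = ((dxc - off) / wx) ** 2
        uy = ((yy - vy) / wy) ** 2
        img += 0.55 * np.exp(-(ux * ux + uy * uy))

    has_artifact = False
    art_rng = np.random.default_rng(spec.rng_seed + _ARTIFACT_SEED_OFFSET)
    if art_rng.random() < artifact_prob:
        has_artifact = True
        p0 = np.array([art_rng.uniform(0.0, 0.35) * W, art_rng.uniform(0.0, 0.15) * H])
        p2 = np.array([art_rng.uniform(0.4, 1.0) * W, art_rng.uniform(0.55, 1.0) * H])
        p1 = np.array([art_rng.uniform(0.1, 0.9) * W, art_rng.uniform(0.2, 0.8) * H])
        ts = np.linspace(0.0, 1.0, 4 * max(H, W))[:, None]
        pts = ((1 - ts) ** 2) * p0 + 2 * ts * (1 - ts) * p1 + ts**2 * p2
        sigma_a = max(0.45, 0.006 * H)
        line = np.zeros_like(img)
        for px, py in pts:
            line = np.maximum(
                line,
                np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * sigma_a**2)),
            )
        img += 0.35 * line

    return Radiograph(
        pixels=np.clip(img, 0.0, 1.0),
        spacing=spacing,
        cobb_angle_deg=cobb_angle(spec),
        has_device_artifact=has_artifact,
    )


@dataclass
class DatasetConfig:
    """Recipe for the three screening splits, at configurable scale.

    Defaults are the desk-scale ("micro") profile of the study design:
    diseased-only upstream, balanced downstream, imbalanced test. Severity
    is uniform 20-45 degrees for scoliosis and 0-9 degrees for normals,
    leaving the 10-19 degree borderline band out by default.
    """

    upstream_n: int = 256
    downstream_per_class: int = 128
    test_pos: int = 50
    test_neg: int = 150
    scoliosis_range: tuple = (20.0, 45.0)
    normal_range: tuple = (0.0, 9.0)
    threshold: float = DIAGNOSTIC_THRESHOLD_DEG
    levo_fraction: float = 0.125
    artifact_prob: float = 0.0
    image_size: int = 64
    n_vertebrae: int = 16

    def __post_init__(self):
        for n in (self.upstream_n, self.downstream_per_class, self.test_pos,
                  self.test_neg):
            if n <= 0:
                raise ValueError("all split sizes must be positive")


@dataclass
class DatasetManifest:
    """Tabular manifest plus (optionally) in-memory images keyed by image_id."""

    frame: pd.DataFrame
    images: Optional[dict] = field(default=None, repr=False)

    def validate(self, threshold: float = DIAGNOSTIC_THRESHOLD_DEG):
        f = self.frame
        up = f[f.split == "upstream"]
        if len(up) and not (up.label == 1).all():
            raise ValueError("upstream split must contain only scoliosis images")
        down = f[f.split == "downstream"]
        if len(down) and abs(down.label.mean() - 0.5) > 1e-12:
            raise ValueError("downstream split must be 1:1 balanced")
        if not ((f.label == 1) == (f.cobb_angle_deg >= threshold)).all():
            raise ValueError("labels inconsistent with Cobb angles")

    def split(self, name: str) -> "DatasetManifest":
        sub = self.frame[self.frame.split == name].reset_index(drop=True)
        imgs = None
        if self.images is not None:
            imgs = {i: self.images[i] for i in sub.image_id}
        return DatasetManifest(frame=sub, images=imgs)

    def to_csv(self, path: str):
        self.frame.to_csv(path, index=False)

    def save_images(self, out_dir: str):
        os.makedirs(out_dir, exist_ok=True)
        for _, row in self.frame.iterrows():
            rg = self.images[row.image_id]
            arr = np.round(rg.pixels * 65535).astype(np.uint16)
            Image.fromarray(arr).save(
                os.path.join(out_dir, f"{row.image_id}.png")
            )


def generate_dataset(
    config: DatasetConfig, seed: int, out_dir: Optional[str] = None
) -> DatasetManifest:
    """Generate the three splits; fully reproducible from (config, seed)."""
    rng = np.random.default_rng(seed)
    rows = []
    images = {}

    def add(split, idx, positive):
        rg_range = config.scoliosis_range if positive else config.normal_range
        spec = make_spine_spec(
            rng, severity_range=rg_range, levo_fraction=config.levo_fraction,
            n_vertebrae=config.n_vertebrae,
        )
        rad = render_radiograph(
            spec, config.image_size, config.image_size,
            artifact_prob=config.artifact_prob,
        )
        angle = rad.cobb_angle_deg
        label = int(angle >= config.threshold)
        rad.label = label
        image_id = f"{split}_{'pos' if positive else 'neg'}_{idx:05d}"
        rows.append(
            dict(
                image_id=image_id,
                path=f"{image_id}.png",
                label=label,
                cobb_angle_deg=angle,
                direction=spec.direction,
                split=split,
                seed=spec.rng_seed,
            )
        )
        images[image_id] = rad

    for i in range(config.upstream_n):
        add("upstream", i, True)
    for i in range(config.downstream_per_class):
        add("downstream", i, True)
    for i in range(config.downstream_per_class):
        add("downstream", i, False)
    for i in range(config.test_pos):
        add("test", i, True)
    for i in range(config.test_neg):
        add("test", i, False)

    manifest = DatasetManifest(frame=pd.DataFrame(rows), images=images)
    manifest.validate(config.threshold)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"))
        manifest.save_images(os.path.join(out_dir, "images"))
    return manifest


def load_manifest(csv_path: str, images_dir: Optional[str] = None) -> DatasetManifest:
    frame = pd.read_csv(csv_path)
    images = None
    if images_dir is not None:
        images = {}
        for _, row in frame.iterrows():
            arr = np.asarray(Image.open(os.path.join(images_dir, row.path)))
            scale = 65535.0 if arr.dtype == np.uint16 or arr.dtype == np.int32 else 255.0
            images[row.image_id] = Radiograph(
                pixels=arr.astype(np.float64) / scale,
                label=int(row.label),
                cobb_angle_deg=float(row.cobb_angle_deg),
            )
    return DatasetManifest(frame=frame, images=images)
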