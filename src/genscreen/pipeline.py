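"""End-to-end experiment orchestration from a single YAML config.

Stages run in the two-step screening order — synthesize data, preprocess,
train the upstream GAN on the diseased-only split, invert the downstream
and test splits, train the projection head, evaluate at the fixed
sensitivity, render a latent traversal — with per-stage artifact
persistence, config-hash bookkeeping and resume-by-artifact-presence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import gan, latent_analysis
from .evaluate import compare_groups, recon_quality, screening_report
from .inversion import InversionConfig, invert_dataset, latent_matrix
from .preprocess import RadiographPreprocessor
from .probe import LatentProbe, stress_test
from .synthdata import DatasetConfig, DatasetManifest, generate_dataset

logger = logging.getLogger(__name__)

STAGES = ("synth", "prep", "gan", "invert", "probe", "eval", "traverse")


@dataclass
class RunConfig:
    """Full-experiment configuration; ``micro`` profile fits one CPU."""

    profile: str = "micro"
    seed: int = 0
    out_dir: str = "runs"
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    preprocess: dict = field(default_factory=dict)
    gan: gan.GanTrainConfig = field(default_factory=gan.GanTrainConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    probe: dict = field(default_factory=dict)
    target_sensitivity: float = 0.9
    stress_grid: bool = False
    traverse_alphas: tuple = (-3.0, -1.5, 0.0, 1.5, 3.0)

    @staticmethod
    def micro(seed: int = 0, out_dir: str = "runs") -> "RunConfig":
        return RunConfig(
            profile="micro", seed=seed, out_dir=out_dir,
            dataset=DatasetConfig(
                upstream_n=192, downstream_per_class=128,
                test_pos=40, test_neg=80, image_size=32,
            ),
            gan=gan.GanTrainConfig(total_steps=1000, fid_interval=200),
            inversion=InversionConfig(iterations=150, batch_size=64),
        )

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        cfg = RunConfig.micro() if raw.get("profile", "micro") == "micro" \
            else RunConfig()
        for key in ("profile", "seed", "out_dir", "target_sensitivity",
                    "stress_grid"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "traverse_alphas" in raw:
            cfg.traverse_alphas = tuple(raw["traverse_alphas"])
        if "dataset" in raw:
            cfg.dataset = dataclasses.replace(cfg.dataset, **raw["dataset"])
        if "gan" in raw:
            cfg.gan = dataclasses.replace(cfg.gan, **raw["gan"])
        if "inversion" in raw:
            cfg.inversion = dataclasses.replace(cfg.inversion, **raw["inversion"])
        for key in ("preprocess", "probe"):
            if key in raw:
                setattr(cfg, key, dict(raw[key]))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["traverse_alphas"] = list(self.traverse_alphas)
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list:
    """Cross-field checks; returns a list of human-readable violations."""
    problems = []
    try:
        dataclasses.replace(config.dataset)
    except ValueError as exc:
        problems.append(f"dataset: {exc}")
    if config.profile not in ("micro", "full"):
        problems.append(f"profile must be 'micro' or 'full', got {config.profile!r}")
    if config.dataset.normal_range[1] >= config.dataset.threshold:
        problems.append(
            "dataset: normal severity range crosses the diagnostic threshold, "
            "upstream labels would be inconsistent"
        )
    n_layers = config.probe.get("n_layers", 2)
    if n_layers not in (1, 2, 3):
        problems.append(f"probe: n_layers must be one of {{1, 2, 3}}, got {n_layers}")
    if not (0.0 < config.target_sensitivity <= 1.0):
        problems.append("target_sensitivity must lie in (0, 1]")
    if config.gan.resolution != config.dataset.image_size:
        # allowed (preprocessing resizes) but worth flagging at validation
        pass
    return problems


def _stage_done(run_dir: str, stage: str, chash: str) -> bool:
    marker = os.path.join(run_dir, f".{stage}.done")
    if not os.path.exists(marker):
        return False
    with open(marker) as fh:
        return fh.read().strip() == chash


def _mark_done(run_dir: str, stage: str, chash: str):
    with open(os.path.join(run_dir, f".{stage}.done"), "w") as fh:
        fh.write(chash)


def run_pipeline(config: RunConfig, resume: bool = True) -> str:
    """Execute all stages; returns the run directory path.

    The run directory is content-addressed by the config hash. Stages with
    a matching completion marker are skipped when ``resume`` is set; any
    stage error propagates after partial state is persisted.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))

    chash = config.config_hash()
    run_dir = os.path.join(config.out_dir, f"run_{chash}")
    os.makedirs(run_dir, exist_ok=True)
    with open(os.path.join(run_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    timings = {}

    def stage(name):
        def deco(fn):
            if resume and _stage_done(run_dir, name, chash):
                logger.info("stage %s: cached, skipping", name)
                return
            t0 = time.time()
            fn()
            timings[name] = time.time() - t0
            _mark_done(run_dir, name, chash)
            logger.info("stage %s: %.1fs", name, timings[name])
        return deco

    state = {}

    @stage("synth")
    def _synth():
        man = generate_dataset(config.dataset, config.seed)
        man.to_csv(os.path.join(run_dir, "manifest.csv"))
        state["manifest"] = man

    if "manifest" not in state:  # resumed: regenerate deterministically
        state["manifest"] = generate_dataset(config.dataset, config.seed)

    prep = RadiographPreprocessor(
        target_resolution=config.gan.resolution, **config.preprocess
    )

    @stage("prep")
    def _prep():
        man = state["manifest"]
        arrays = {}
        for split in ("upstream", "downstream", "test"):
            sub = man.split(split)
            arrays[split] = prep.transform(
                [sub.images[i] for i in sub.frame.image_id]
            )
        np.savez_compressed(
            os.path.join(run_dir, "preprocessed.npz"), **arrays
        )

    data = np.load(os.path.join(run_dir, "preprocessed.npz"))

    @stage("gan")
    def _gan():
        man = state["manifest"].split("upstream")
        result = gan.train_gan(man, config.gan, images=data["upstream"])
        best = gan.select_checkpoint(result.checkpoints)
        gan.save_checkpoint(os.path.join(run_dir, "generator.npz"), best)
        result.fid_trace_frame().to_csv(
            os.path.join(run_dir, "fid_trace.csv"), index=False
        )

    checkpoint = gan.load_checkpoint(os.path.join(run_dir, "generator.npz"))
    generator = gan.build_generator(
        checkpoint, config.gan.channel_base, config.gan.channel_max
    )

    @stage("invert")
    def _invert():
        man = state["manifest"]
        for split in ("downstream", "test"):
            table = invert_dataset(
                man.split(split), generator, config.inversion,
                images=data[split],
            )
            table.to_csv(
                os.path.join(run_dir, f"latents_{split}.csv"), index=False
            )

    latents_down = pd.read_csv(os.path.join(run_dir, "latents_downstream.csv"))
    latents_test = pd.read_csv(os.path.join(run_dir, "latents_test.csv"))

    @stage("probe")
    def _probe():
        X, y = latent_matrix(latents_down)
        probe = LatentProbe(seed=config.seed, **config.probe).fit(X, y)
        np.savez(
            os.path.join(run_dir, "probe.npz"),
            mean=probe.mean_, scale=probe.scale_,
            **{f"W{i}": l.W.data for i, l in enumerate(probe.layers_)},
            **{f"b{i}": l.b.data for i, l in enumerate(probe.layers_)},
        )
        Xt, yt = latent_matrix(latents_test)
        scores = probe.score_samples(Xt)
        pd.DataFrame(
            dict(image_id=latents_test.image_id, label=yt, score=scores)
        ).to_csv(os.path.join(run_dir, "scores_test.csv"), index=False)
        if config.stress_grid:
            grid = stress_test(X, y, Xt, yt, seeds=(config.seed,),
                               probe_params=config.probe)
            grid.to_csv(os.path.join(run_dir, "stress_grid.csv"), index=False)

    scores = pd.read_csv(os.path.join(run_dir, "scores_test.csv"))

    @stage("eval")
    def _eval():
        report = screening_report(
            scores.score, scores.label,
            target_sensitivity=config.target_sensitivity,
            seed=config.seed,
        )
        report.to_json(os.path.join(run_dir, "screening_report.json"))
        with open(os.path.join(run_dir, "screening_report.txt"), "w") as fh:
            fh.write(report.summary() + "\n")
        # reconstruction-quality group comparison on the downstream split
        qual = []
        for _, row in latents_down.iterrows():
            rmse255 = float(
                np.sqrt(row.final_l2 / (3 * config.gan.resolution**2)) * 255.0
            )
            qual.append(dict(label=int(row.label), rmse=rmse255))
        qf = pd.DataFrame(qual)
        cmp_res = compare_groups(
            qf[qf.label == 1].rmse, qf[qf.label == 0].rmse, "independent"
        )
        with open(os.path.join(run_dir, "recon_quality.json"), "w") as fh:
            json.dump(
                dict(
                    rmse_scoliosis=float(qf[qf.label == 1].rmse.mean()),
                    rmse_normal=float(qf[qf.label == 0].rmse.mean()),
                    t=cmp_res.t, p=cmp_res.p,
                ),
                fh, indent=2,
            )

    @stage("traverse")
    def _traverse():
        directions = latent_analysis.sefa_directions(generator, k=3)
        cols = [c for c in latents_down.columns
                if c.startswith("w") and c[1:].isdigit()]
        base = latents_down[cols].to_numpy()[0]
        strip = latent_analysis.traverse(
            generator, base, directions.vectors[0],
            list(config.traverse_alphas),
        )
        tiled = latent_analysis.tile_strip(strip)
        from PIL import Image

        Image.fromarray(
            np.round(tiled * 255).astype(np.uint8)
        ).save(os.path.join(run_dir, "traversal.png"))

    with open(os.path.join(run_dir, "timings.json"), "w") as fh:
        json.dump(timings, fh, indent=2)
    return run_dir
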