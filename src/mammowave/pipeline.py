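"""End-to-end orchestration of the classification pipeline.

Stage order is fixed: synthesize (or ingest) -> GAN augmentation ->
CLAHE -> seam carving -> wavelet decomposition (deepest LL) -> train
(CNN or wCNN) -> evaluate. Any stage can be toggled off. A single global
seed fans out to per-stage sub-seeds by stable hashing, so a run is a pure
function of its configuration; every run writes a JSON manifest capturing
the resolved configuration, the per-stage seeds, and the artifact paths.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .eval_metrics import REPORT_KEYS, metrics_report
from .gan_synth import GanSpec, GanTrainConfig, synthesize, train_gan
from .image_core import GrayImage
from .networks import (
    NetworkSpec, TrainConfig, build_cnn, build_wcnn, predict, train_model,
)
from .preprocess import ClaheParams, apply_clahe, carve
from .synthetic_mammo import (
    CLASSES_FIVE, LabeledDataset, Split, SyntheticSpec, generate_dataset,
    split_dataset,
)
from .synthetic_mammo import _derive_seed as derive_seed
from .wavelet_activation import ActivationParams
from .wavelet_decomp import extract_ll, max_level, wavedec2

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "compare_runs"]

STAGES = ("synth", "gan_augment", "clahe", "carve", "decompose", "train", "evaluate")


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "runs/run0"
    seed: int = 0
    class_set: tuple[str, ...] = CLASSES_FIVE
    image_size: int = 64
    samples_per_class: int = 20
    noise_sd: float = 0.02
    lesion_intensity: float = 0.45
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    # stage toggles
    enable_gan_augment: bool = False
    enable_clahe: bool = True
    enable_carve: bool = True
    enable_decompose: bool = True
    enable_train: bool = True
    # stage parameters
    gan_classes: tuple[str, ...] = ()
    gan_steps: int = 30
    gan_samples_per_class: int = 8
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (4, 4)
    carve_frac: float = 0.05  # fraction of each dimension removed as seams
    decomp_depth: int = 2
    arch: str = "wcnn"  # "cnn" | "wcnn"
    beta: float = 0.5
    n_blocks: int = 2
    convs_per_block: int = 2
    filters_per_block: tuple[int, ...] = (8, 16)
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("class_set", "split_fractions", "clahe_tiles", "filters_per_block",
                    "gan_classes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    return derive_seed("pipeline", cfg.seed, stage)


def _preprocess_image(img: GrayImage, cfg: PipelineConfig) -> GrayImage:
    if cfg.enable_clahe:
        img = apply_clahe(img, ClaheParams(cfg.clahe_clip, cfg.clahe_tiles))
    if cfg.enable_carve:
        nv = int(round(cfg.carve_frac * img.width))
        nh = int(round(cfg.carve_frac * img.height))
        img = carve(img, n_vertical=nv, n_horizontal=nh)
    if cfg.enable_decompose:
        depth = min(cfg.decomp_depth, max_level(img.shape))
        img = extract_ll(wavedec2(img, depth))
    return img


def _preprocess_dataset(ds: LabeledDataset, cfg: PipelineConfig) -> LabeledDataset:
    new = tuple(
        replace(s, image=_preprocess_image(s.image, cfg)) for s in ds.samples
    )
    return LabeledDataset(new, class_set=ds.class_set, split=ds.split)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "artifacts": {}}

    # --- synth
    seed = _stage_seed(cfg, "synth")
    spec = SyntheticSpec(
        image_size=cfg.image_size,
        class_counts={c: cfg.samples_per_class for c in cfg.class_set},
        seed=seed,
        noise_sd=cfg.noise_sd,
        lesion_intensity=cfg.lesion_intensity,
    )
    ds = generate_dataset(spec, class_set=cfg.class_set)
    manifest["stages"]["synth"] = {"seed": seed, "n_samples": len(ds)}
    logger.info("synth: %d samples of %s at %dpx", len(ds), cfg.class_set, cfg.image_size)

    train_ds, val_ds, test_ds = split_dataset(ds, cfg.split_fractions,
                                              seed=_stage_seed(cfg, "split"))

    # --- gan augmentation (training split only)
    if cfg.enable_gan_augment and cfg.gan_classes:
        seed = _stage_seed(cfg, "gan")
        gan_spec = GanSpec(output_size=32, gen_filters=(64, 32, 16),
                           disc_filters=(16, 32, 64))
        extra = []
        for label in cfg.gan_classes:
            members = tuple(s for s in train_ds.samples if s.label == label)
            sub = LabeledDataset(members, class_set=cfg.class_set, split=Split.TRAIN)
            gen, _, traces = train_gan(
                sub,
                GanTrainConfig(batch_size=min(8, len(sub)), steps=cfg.gan_steps,
                               seed=derive_seed(seed, label)),
                gan_spec,
            )
            extra += synthesize(gen, cfg.gan_samples_per_class, label,
                                seed=derive_seed(seed, label, "sample"),
                                working_size=cfg.image_size)
        train_ds = LabeledDataset(train_ds.samples + tuple(extra),
                                  class_set=cfg.class_set, split=Split.TRAIN)
        manifest["stages"]["gan_augment"] = {
            "seed": seed, "classes": list(cfg.gan_classes), "added": len(extra),
        }

    # --- preprocessing chain
    train_ds = _preprocess_dataset(train_ds, cfg)
    val_ds = _preprocess_dataset(val_ds, cfg)
    test_ds = _preprocess_dataset(test_ds, cfg)
    working = train_ds.samples[0].image.shape
    for name, flag in (("clahe", cfg.enable_clahe), ("carve", cfg.enable_carve),
                       ("decompose", cfg.enable_decompose)):
        manifest["stages"][name] = {"enabled": flag}
    manifest["stages"]["decompose"]["working_shape"] = list(working)
    logger.info("preprocess: working shape %s", working)

    # --- train
    if cfg.enable_train:
        seed = _stage_seed(cfg, "train")
        net_spec = NetworkSpec(
            input_size=working[0],
            n_blocks=cfg.n_blocks,
            convs_per_block=cfg.convs_per_block,
            filters_per_block=cfg.filters_per_block,
            activation="wavelet" if cfg.arch == "wcnn" else "relu",
            activation_params=ActivationParams(cfg.beta),
            n_classes=len(cfg.class_set),
        )
        builder = build_wcnn if cfg.arch == "wcnn" else build_cnn
        model = builder(net_spec, seed=seed, class_set=cfg.class_set)
        hist = train_model(
            model, train_ds, val_ds,
            TrainConfig(learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                        epochs=cfg.epochs, seed=derive_seed(seed, "loop")),
        )
        curves = out / "training_curves.csv"
        with open(curves, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["epoch", "loss", "accuracy",
                                               "val_loss", "val_accuracy"])
            w.writeheader()
            w.writerows(hist.to_rows())
        manifest["stages"]["train"] = {
            "seed": seed, "arch": cfg.arch, "epochs": cfg.epochs,
            "final_loss": hist.loss[-1], "final_accuracy": hist.accuracy[-1],
            "final_val_accuracy": hist.val_accuracy[-1] if hist.val_accuracy else None,
        }
        manifest["artifacts"]["training_curves"] = str(curves)

        # --- evaluate
        y_true = [s.label for s in test_ds.samples]
        _, y_pred = predict(model, test_ds)
        report = metrics_report(y_true, y_pred, cfg.class_set)
        metrics_csv = out / "metrics.csv"
        report.to_csv(metrics_csv)
        report.to_json(out / "metrics.json")
        manifest["stages"]["evaluate"] = {"n_test": len(y_true), **report.as_dict()}
        manifest["artifacts"]["metrics_csv"] = str(metrics_csv)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest


def compare_runs(run_a: str | Path, run_b: str | Path) -> list[dict]:
    """Side-by-side metric table for two completed runs."""
    rows = []
    for name, path in (("A", run_a), ("B", run_b)):
        mpath = Path(path) / "manifest.json"
        if not mpath.exists():
            raise FileNotFoundError(f"run {name} has no manifest at {mpath}")
        with open(mpath) as fh:
            manifest = json.load(fh)
        ev = manifest.get("stages", {}).get("evaluate")
        if ev is None:
            raise ValueError(f"run {name} ({path}) has no metrics report")
        rows.append({"run": str(path), "arch": manifest["config"].get("arch"),
                     **{k: ev[k] for k in REPORT_KEYS}})
    if _classes(run_a) != _classes(run_b):
        raise ValueError("runs use incompatible class sets")
    return rows


def _classes(run: str | Path) -> list:
    with open(Path(run) / "manifest.json") as fh:
        return json.load(fh)["config"]["class_set"]
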