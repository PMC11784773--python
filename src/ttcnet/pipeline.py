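"""End-to-end pipeline: generate -> preprocess -> train -> evaluate.

Every artifact lands under one run directory:

``data/``        phantom PNGs + ``manifest.csv``
``patches/``     patch PNGs + ``patch_manifest.csv``
``checkpoint/``  model checkpoint
``history.csv``  per-epoch costs and gate trajectory
``alpha_trajectory.csv``  gate matrix per epoch
``report.json``  test-split metrics
``summary.json`` machine-readable run summary (byte-reproducible per seed)
``log.txt``      stage log with seed and config hash

Patches from one source image always share a split (no leakage); splits
are stratified 70/15/15 by class at the source-image level.  The area
regression target is standardized by train-split statistics, which are
stored in the summary for inversion.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .canny import canny as run_canny
from .canny import load_gray_image
from .config import RunConfig
from .model import ArchitectureSpec, TaskSpec, build_model
from .patches import detect_landmarks, edge_density, extract_patches, write_patches
from .phantoms import PhantomSpec, generate_dataset
from .training import TaskData, TrainConfig, fit, save_checkpoint, split_dataset

__all__ = ["run_pipeline", "preprocess_manifest", "train_from_arrays", "evaluate_arrays"]


class StageError(RuntimeError):
    """Pipeline failure with the responsible stage attached."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _log(run_dir: Path, stage: str, seed: int, cfg_hash: str, message: str) -> None:
    with open(run_dir / "log.txt", "a") as fh:
        fh.write(f"stage={stage} seed={seed} config={cfg_hash} {message}\n")


def preprocess_manifest(
    manifest: pd.DataFrame, data_dir: Path, config: RunConfig, out_dir: Path
) -> pd.DataFrame:
    """Edge-detect every image, find landmarks, crop and store patches."""
    size = config.train.patch_size
    all_patches = []
    for row in manifest.itertuples(index=False):
        img = load_gray_image(data_dir / row.image_path)
        edges = run_canny(
            img, config.canny.sigma, config.canny.low, config.canny.high
        )
        density = edge_density(edges, config.landmarks.density_radius)
        landmarks = detect_landmarks(
            density,
            k=config.landmarks.landmarks_per_image,
            min_dist=size / 2,
            min_score=config.landmarks.min_score,
        )
        source_id = Path(str(row.image_path)).stem
        all_patches.extend(
            extract_patches(
                img,
                landmarks,
                size,
                source_id=source_id,
                class_label=int(row.class_label),
                regression_target=float(row.regression_target),
            )
        )
    return write_patches(all_patches, out_dir)


def train_from_arrays(
    x: np.ndarray,
    y_class: np.ndarray,
    y_area: np.ndarray,
    config: RunConfig,
    n_classes: int,
    val: tuple | None = None,
):
    """Build and fit the joint classification + regression model.

    Returns ``(model, history, area_mean, area_sd)``; regression targets
    are standardized by the training statistics returned.
    """
    input_hw = x.shape[1:3]
    arch = ArchitectureSpec(
        input_hw=input_hw,
        conv_channels=config.ttc.conv_channels,
        batchnorm=config.ttc.batchnorm,
        activation=config.train.activation,
        hidden_dim=config.ttc.hidden_dim,
    )
    if n_classes == 2:
        cls_task = TaskSpec("diagnosis", "classification", 1)
        y_cls_enc = y_class.astype(float)[:, None]
    else:
        cls_task = TaskSpec("diagnosis", "classification", n_classes)
        y_cls_enc = np.eye(n_classes)[y_class]
    reg_task = TaskSpec("lesion_area", "regression", 1)

    area_mean = float(y_area.mean())
    area_sd = float(y_area.std())
    if area_sd == 0:
        area_sd = 1.0
    y_area_n = (y_area - area_mean) / area_sd

    val_cls = val_reg = (None, None)
    if val is not None:
        xv, yv_class, yv_area = val
        yv_enc = (
            yv_class.astype(float)[:, None] if n_classes == 2 else np.eye(n_classes)[yv_class]
        )
        val_cls = (xv, yv_enc)
        val_reg = (xv, (yv_area - area_mean) / area_sd)

    datasets = [
        TaskData(x, y_cls_enc, *val_cls),
        TaskData(x, y_area_n[:, None], *val_reg),
    ]
    model = build_model(
        arch,
        [cls_task, reg_task],
        seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(11,)),
        lr=config.train.learning_rate,
        momentum=config.ttc.momentum,
        lr_beta=config.ttc.lr_beta,
        clip_norm=config.ttc.clip_norm,
    )
    tc = TrainConfig(
        epochs=config.train.epochs,
        batch_size=config.train.batch_size,
        learning_rate=config.train.learning_rate,
        lr_beta=config.ttc.lr_beta,
        momentum=config.ttc.momentum,
        activation=config.train.activation,
        patch_size=config.train.patch_size,
        seed=config.seed,
        early_stopping=config.train.early_stopping,
        patience=config.train.patience,
        augment_dihedral=config.train.augment,
        allow_nonstandard=config.train.allow_nonstandard,
    )
    model, history = fit(model, datasets, tc)
    return model, history, area_mean, area_sd


def evaluate_arrays(
    model,
    x: np.ndarray,
    y_class: np.ndarray,
    y_area: np.ndarray,
    area_mean: float,
    area_sd: float,
    n_classes: int,
) -> dict:
    """Test-split metrics: macro classification metrics plus RMSE and R^2."""
    probs = model.subnets[0].forward(x, train=False)
    if n_classes == 2:
        preds = (probs[:, 0] >= 0.5).astype(int)
    else:
        preds = probs.argmax(axis=1)
    reg_out = model.subnets[1].forward(x, train=False)[:, 0]
    area_pred = reg_out * area_sd + area_mean

    cls = metrics_mod.macro_metrics(preds, y_class)
    cls.pop("per_class")
    rmse = metrics_mod.rmse(area_pred, y_area)
    rng_span = float(y_area.max() - y_area.min())
    out = dict(cls)
    out["rmse"] = rmse
    out["rmse_pct_of_range"] = 100.0 * rmse / rng_span if rng_span > 0 else None
    try:
        out["r_squared"] = metrics_mod.r_squared(area_pred, y_area)
    except ValueError:
        out["r_squared"] = None
    return out


def run_pipeline(
    config: RunConfig,
    out_dir,
    skip_generate: bool = False,
    skip_preprocess: bool = False,
) -> dict:
    """Execute the full pipeline; returns the summary written to disk."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    data_dir = run_dir / "data"
    patch_dir = run_dir / "patches"

    # -- generate ----------------------------------------------------------
    if skip_generate:
        if not (data_dir / "manifest.csv").exists():
            raise StageError("generate", "skipped but data/manifest.csv is missing")
        manifest = pd.read_csv(data_dir / "manifest.csv")
    else:
        spec = PhantomSpec(
            image_size=config.phantom.image_size, noise_sd=config.phantom.noise_sd
        )
        manifest = generate_dataset(
            config.phantom.n_total, spec, data_dir, seed=config.seed
        )
        _log(run_dir, "generate", config.seed, cfg_hash, f"n={len(manifest)}")

    n_classes = int(manifest["class_label"].nunique())

    # -- split at source-image level --------------------------------------
    fractions = (
        1.0 - config.train.validation_split - config.train.test_split,
        config.train.validation_split,
        config.train.test_split,
    )
    train_m, val_m, test_m = split_dataset(manifest, fractions, seed=config.seed)
    _log(
        run_dir,
        "split",
        config.seed,
        cfg_hash,
        f"train={len(train_m)} val={len(val_m)} test={len(test_m)}",
    )

    # -- preprocess (patch route) or direct image route --------------------
    if config.train.train_on == "patches":
        if skip_preprocess:
            if not (patch_dir / "patch_manifest.csv").exists():
                raise StageError(
                    "preprocess", "skipped but patches/patch_manifest.csv is missing"
                )
            patch_manifest = pd.read_csv(patch_dir / "patch_manifest.csv")
        else:
            patch_manifest = preprocess_manifest(manifest, data_dir, config, patch_dir)
            _log(
                run_dir, "preprocess", config.seed, cfg_hash, f"patches={len(patch_manifest)}"
            )
        if patch_manifest.empty:
            raise StageError("preprocess", "no patches were extracted")

        from .patches import read_patches

        patches = read_patches(patch_dir)
        by_source = {Path(str(p)).stem for p in train_m["image_path"]}
        val_sources = {Path(str(p)).stem for p in val_m["image_path"]}
        test_sources = {Path(str(p)).stem for p in test_m["image_path"]}

        def _collect(sources):
            sel = [p for p in patches if p.source_id in sources]
            if not sel:
                return None
            x = np.stack([p.pixels for p in sel])
            yc = np.array([p.class_label for p in sel])
            ya = np.array([p.regression_target for p in sel])
            return x, yc, ya

        train_arrays = _collect(by_source)
        val_arrays = _collect(val_sources)
        test_arrays = _collect(test_sources)
    else:

        def _load(split_m):
            if split_m.empty:
                return None
            x = np.stack(
                [
                    load_gray_image(data_dir / p).pixels
                    for p in split_m["image_path"]
                ]
            )
            return (
                x,
                split_m["class_label"].to_numpy(),
                split_m["regression_target"].to_numpy(float),
            )

        train_arrays = _load(train_m)
        val_arrays = _load(val_m)
        test_arrays = _load(test_m)

    if train_arrays is None:
        raise StageError("train", "empty training split")

    # -- train --------------------------------------------------------------
    model, history, area_mean, area_sd = train_from_arrays(
        *train_arrays, config, n_classes, val=val_arrays
    )
    save_checkpoint(model, run_dir / "checkpoint")
    history.to_csv(run_dir / "history.csv", index=False)
    alpha_cols = ["epoch"] + [c for c in history.columns if c.startswith("alpha_")]
    if not history.empty:
        history[alpha_cols].to_csv(run_dir / "alpha_trajectory.csv", index=False)
    _log(run_dir, "train", config.seed, cfg_hash, f"iterations={model.iteration}")

    # -- evaluate ------------------------------------------------------------
    if test_arrays is not None:
        report = evaluate_arrays(
            model, *test_arrays, area_mean, area_sd, n_classes
        )
    else:
        report = {}
    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _log(run_dir, "evaluate", config.seed, cfg_hash, "report written")

    summary = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_images": int(len(manifest)),
        "n_classes": n_classes,
        "split_sizes": {
            "train": int(len(train_m)),
            "validation": int(len(val_m)),
            "test": int(len(test_m)),
        },
        "train_on": config.train.train_on,
        "iterations": int(model.iteration),
        "area_standardization": {"mean": area_mean, "sd": area_sd},
        "final_alpha": model.ttc.alpha.tolist(),
        "metrics": report,
    }
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
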