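"""Training orchestration: splits, multi-epoch fitting, checkpoints,
and incremental task addition with frozen subnets.

An *epoch* is one full pass over the largest task's training set; smaller
tasks cycle through their own (reshuffled) data.  One training step
consumes one batch per task and applies the gate-weighted multi-task
update.  "Converged" is realized as a fixed epoch budget with optional
early stopping on mean validation cost.

Incremental learning (``add_task``) grows a trained model by one task:
every pre-existing subnet and every pre-existing gate is frozen, gates
from the new task into the old ones (``beta[old, new]``) are pinned fully
closed so old-task behaviour is provably unchanged, and only the new
subnet plus its incoming gates ``beta[new, old]`` learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    ArchitectureSpec,
    ModelState,
    Optimizer,
    Subnet,
    TaskSpec,
    TTCState,
    task_cost,
    train_step,
)

__all__ = [
    "TrainConfig",
    "TaskData",
    "split_dataset",
    "fit",
    "add_task",
    "save_checkpoint",
    "load_checkpoint",
    "evaluate_cost",
]

BATCH_SIZES = (16, 32, 64)
LR_RANGE = (1e-4, 1e-3)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for one training run.

    Defaults follow the typical ranges for this model family: batch sizes
    from {16, 32, 64}, learning rate in [1e-4, 1e-3], ReLU or LeakyReLU
    activations, and a 70/15/15 train/validation/test split.  Out-of-range
    values raise unless ``allow_nonstandard`` is set.
    """

    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_beta: float = 0.01
    momentum: float = 0.0
    activation: str = "relu"
    patch_size: int = 64
    seed: int = 0
    validation_fraction: float = 0.15
    test_fraction: float = 0.15
    early_stopping: bool = False
    patience: int = 10
    augment_dihedral: bool = False
    allow_nonstandard: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if not self.allow_nonstandard:
            if self.batch_size not in BATCH_SIZES:
                raise ValueError(
                    f"batch_size {self.batch_size} not in {BATCH_SIZES} "
                    "(set allow_nonstandard=True to override)"
                )
            if not (LR_RANGE[0] <= self.learning_rate <= LR_RANGE[1]):
                raise ValueError(
                    f"learning_rate {self.learning_rate} outside {LR_RANGE} "
                    "(set allow_nonstandard=True to override)"
                )
            if self.activation not in ("relu", "leaky_relu"):
                raise ValueError("activation must be 'relu' or 'leaky_relu'")
            if self.patch_size not in (32, 64):
                raise ValueError("patch_size must be 32 or 64")
        tf = self.validation_fraction + self.test_fraction
        if not (0 <= tf < 1):
            raise ValueError("validation + test fractions must lie in [0, 1)")


@dataclass
class TaskData:
    """Train/validation arrays for one task."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray | None = None
    y_val: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.x_train) != len(self.y_train):
            raise ValueError("x_train and y_train lengths differ")
        if len(self.x_train) == 0:
            raise ValueError("task has no training samples")


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    remainders = np.array([r - c for r, c in zip(raw, counts)])
    for i in np.argsort(-remainders)[:short]:
        counts[int(i)] += 1
    return counts


def _stratified_counts(
    group_sizes: Sequence[int], fractions: Sequence[float]
) -> list[list[int]]:
    """Per-group split counts whose column sums hit the global targets.

    Controlled rounding: floor each group quota, then hand out the
    remaining units by largest fractional remainder, never exceeding the
    global largest-remainder target of any split.
    """
    n = int(sum(group_sizes))
    targets = _largest_remainder(n, fractions)
    counts = [[int(np.floor(g * f)) for f in fractions] for g in group_sizes]
    need = [g - sum(row) for g, row in zip(group_sizes, counts)]
    cap = [t - sum(row[s] for row in counts) for s, t in enumerate(targets)]
    rem = sorted(
        (
            (-(g * f - np.floor(g * f)), c, s)
            for c, g in enumerate(group_sizes)
            for s, f in enumerate(fractions)
        )
    )
    for _, c, s in rem:
        if need[c] > 0 and cap[s] > 0:
            counts[c][s] += 1
            need[c] -= 1
            cap[s] -= 1
    for c in range(len(group_sizes)):  # leftovers: any split with capacity
        while need[c] > 0:
            s = int(np.argmax(cap))
            counts[c][s] += 1
            need[c] -= 1
            cap[s] -= 1
    return counts


def split_dataset(
    manifest: pd.DataFrame,
    fractions: Sequence[float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    label_column: str = "class_label",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified train/validation/test partition.

    Each class is shuffled and allotted to the three splits by largest-
    remainder rounding of the requested fractions.  A class with fewer
    samples than splits triggers a warning and an unstratified fallback.
    """
    fractions = list(fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)

    groups: list[pd.DataFrame]
    if label_column in manifest.columns:
        class_sizes = manifest[label_column].value_counts()
        if (class_sizes < len(fractions)).any():
            warnings.warn(
                "a class has fewer samples than splits; falling back to "
                "unstratified partition",
                stacklevel=2,
            )
            groups = [manifest]
        else:
            groups = [g for _, g in manifest.groupby(label_column, sort=True)]
    else:
        groups = [manifest]

    parts: list[list[pd.DataFrame]] = [[], [], []]
    all_counts = _stratified_counts([len(g) for g in groups], fractions)
    for g, counts in zip(groups, all_counts):
        idx = rng.permutation(len(g))
        start = 0
        for s, c in enumerate(counts):
            parts[s].append(g.iloc[idx[start : start + c]])
            start += c
    out = tuple(
        pd.concat(p).sort_index() if p else manifest.iloc[:0] for p in parts
    )
    return out  # type: ignore[return-value]


def _dihedral(x: np.ndarray, ops: np.ndarray) -> np.ndarray:
    """Apply one of the 8 square symmetries per sample (ops in [0, 8))."""
    out = x.copy()
    for op in range(1, 8):
        sel = ops == op
        if not sel.any():
            continue
        sub = x[sel]
        if op >= 4:
            sub = sub[:, :, ::-1]
        sub = np.rot90(sub, k=op % 4, axes=(1, 2))
        out[sel] = sub
    return out


class _Cycler:
    """Cycles through one task's samples in seeded shuffled order."""

    def __init__(self, n: int, rng: np.random.Generator) -> None:
        self.n = n
        self.rng = rng
        self.order = rng.permutation(n)
        self.pos = 0

    def take(self, count: int) -> np.ndarray:
        out = []
        while count > 0:
            avail = self.n - self.pos
            if avail == 0:
                self.order = self.rng.permutation(self.n)
                self.pos = 0
                avail = self.n
            grab = min(count, avail)
            out.append(self.order[self.pos : self.pos + grab])
            self.pos += grab
            count -= grab
        return np.concatenate(out)


def evaluate_cost(model: ModelState, datasets: Sequence[TaskData]) -> list[float]:
    """Validation cost per task (inference mode); NaN when no val data."""
    costs = []
    for q, data in enumerate(datasets):
        if data.x_val is None or len(data.x_val) == 0:
            costs.append(float("nan"))
            continue
        outputs = model.subnets[q].forward(data.x_val, train=False)
        costs.append(task_cost(outputs, data.y_val, model.tasks[q]))
    return costs


def fit(
    model: ModelState,
    datasets: Sequence[TaskData],
    config: TrainConfig,
) -> tuple[ModelState, pd.DataFrame]:
    """Train for ``config.epochs`` epochs; returns the model and history.

    History has one row per epoch with per-task mean train cost, per-task
    validation cost and the flattened alpha matrix.  A non-finite cost
    aborts the run and restores the last end-of-epoch state.
    """
    n = model.n_tasks
    if len(datasets) != n:
        raise ValueError(f"expected {n} datasets, got {len(datasets)}")
    model.optimizer.lr = config.learning_rate
    model.optimizer.lr_beta = config.lr_beta
    model.optimizer.momentum = config.momentum

    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(101,))
    streams = [np.random.default_rng(c) for c in ss.spawn(n)]
    cyclers = [_Cycler(len(d.x_train), s) for d, s in zip(datasets, streams)]
    steps_per_epoch = max(
        1, int(np.ceil(max(len(d.x_train) for d in datasets) / config.batch_size))
    )

    rows = []
    best_val = np.inf
    stale = 0
    snapshot = _snapshot(model)
    for epoch in range(config.epochs):
        epoch_costs = np.zeros(n)
        diverged = False
        for _ in range(steps_per_epoch):
            batches = []
            for q, data in enumerate(datasets):
                take = min(config.batch_size, len(data.x_train))
                idx = cyclers[q].take(take)
                xb, yb = data.x_train[idx], data.y_train[idx]
                if config.augment_dihedral:
                    # label-preserving square symmetries (targets invariant)
                    xb = _dihedral(xb, streams[q].integers(0, 8, len(xb)))
                batches.append((xb, yb))
            result = train_step(model, batches)
            if not np.all(np.isfinite(result["costs"])):
                diverged = True
                break
            epoch_costs += np.asarray(result["costs"])
        if diverged:
            _restore(model, snapshot)
            warnings.warn(
                f"non-finite cost at epoch {epoch}; restored last checkpoint",
                stacklevel=2,
            )
            break
        epoch_costs /= steps_per_epoch
        val_costs = evaluate_cost(model, datasets)
        row = {"epoch": epoch, "iteration": model.iteration}
        for q in range(n):
            row[f"train_cost_{model.tasks[q].task_id}"] = epoch_costs[q]
            row[f"val_cost_{model.tasks[q].task_id}"] = val_costs[q]
        alpha = model.ttc.alpha
        for p in range(n):
            for q in range(n):
                row[f"alpha_{p}{q}"] = alpha[p, q]
        rows.append(row)
        snapshot = _snapshot(model)

        mean_val = np.nanmean(val_costs) if not np.all(np.isnan(val_costs)) else np.nan
        if config.early_stopping and np.isfinite(mean_val):
            if mean_val < best_val - 1e-12:
                best_val = mean_val
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    history = pd.DataFrame(rows)
    return model, history


def _snapshot(model: ModelState) -> dict:
    return {
        "weights": [s.get_weights() for s in model.subnets],
        "buffers": [s.get_buffers() for s in model.subnets],
        "beta": model.ttc.beta.copy(),
        "iteration": model.iteration,
    }


def _restore(model: ModelState, snap: dict) -> None:
    for s, w, b in zip(model.subnets, snap["weights"], snap["buffers"]):
        s.set_weights(w)
        s.set_buffers(b)
    model.ttc.beta[...] = snap["beta"]
    model.iteration = snap["iteration"]


# --------------------------------------------------------------------------
# incremental task addition
# --------------------------------------------------------------------------


def add_task(
    model: ModelState,
    new_spec: TaskSpec,
    datasets: Sequence[TaskData],
    config: TrainConfig,
    warm_start_from: int | None = None,
) -> tuple[ModelState, pd.DataFrame]:
    """Grow a trained model by one task, freezing everything pre-existing.

    ``datasets`` must cover all ``n + 1`` tasks (new task last): old tasks
    still supply supervisory gradients that the new subnet's incoming
    gates weigh, but their weights, batch-norm statistics and gates never
    change.  Gates from the new task into old tasks are pinned fully
    closed.  An ``unfreeze_old_gates`` experiment is possible by editing
    ``model.ttc.frozen`` afterwards; the default is fully frozen.

    ``warm_start_from`` copies an existing subnet's congruent tensors
    (and batch-norm statistics) into the new branch before training.
    Cross-subnet gradient alignment is only informative when subnets
    share a parameter frame — independently initialized networks differ
    by hidden-unit permutations that decorrelate their gradients — so
    warm-starting is recommended when the incoming gates should reflect
    task relatedness rather than drift randomly.
    """
    n_old = model.n_tasks
    if len(datasets) != n_old + 1:
        raise ValueError(f"need datasets for all {n_old + 1} tasks (new task last)")

    ttc = model.ttc.grown()
    for q in range(n_old):
        for p in range(n_old):
            if p != q:
                ttc.frozen[p, q] = True
        ttc.freeze_gate(q, n_old, alpha_value=0.0)  # new task never drives old

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(202, n_old))
    )
    new_subnet = Subnet(model.arch, new_spec, rng)
    if warm_start_from is not None:
        source = model.subnets[warm_start_from]
        for dst, src in zip(new_subnet.params, source.params):
            if dst.shape == src.shape:
                dst[...] = src
        src_buffers = source.get_buffers()
        if set(src_buffers) == set(new_subnet.get_buffers()):
            new_subnet.set_buffers(src_buffers)

    grown = ModelState(
        model.arch,
        list(model.tasks) + [new_spec],
        list(model.subnets) + [new_subnet],
        ttc,
        Optimizer(
            lr=config.learning_rate,
            momentum=config.momentum,
            lr_beta=config.lr_beta,
        ),
        clip_norm=model.clip_norm,
    )
    grown.frozen_subnets = [True] * n_old + [False]
    grown.iteration = model.iteration

    return fit(grown, datasets, config)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_checkpoint(model: ModelState, out_dir) -> None:
    """Write the full model state; the round trip is bit-exact."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    descriptor = {
        "format_version": _FORMAT_VERSION,
        "iteration": int(model.iteration),
        "clip_norm": float(model.clip_norm),
        "frozen_subnets": [bool(f) for f in model.frozen_subnets],
        "optimizer": {
            "lr": model.optimizer.lr,
            "momentum": model.optimizer.momentum,
            "lr_beta": model.optimizer.lr_beta,
        },
        "architecture": {
            "input_hw": list(model.arch.input_hw),
            "in_channels": model.arch.in_channels,
            "conv_channels": list(model.arch.conv_channels),
            "batchnorm": model.arch.batchnorm,
            "activation": model.arch.activation,
            "hidden_dim": model.arch.hidden_dim,
        },
        "tasks": [
            {
                "task_id": t.task_id,
                "kind": t.kind,
                "output_dim": t.output_dim,
                "loss_id": t.loss_id,
            }
            for t in model.tasks
        ],
    }
    (out_dir / "descriptor.yaml").write_text(yaml.safe_dump(descriptor, sort_keys=True))
    for i, subnet in enumerate(model.subnets):
        arrays = {f"param_{j}": p for j, p in enumerate(subnet.params)}
        arrays.update({f"buffer::{k}": v for k, v in subnet.get_buffers().items()})
        np.savez(out_dir / f"subnet_{i}.npz", **arrays)
    np.savez(out_dir / "ttc.npz", beta=model.ttc.beta, frozen=model.ttc.frozen)
    opt_arrays = {}
    for key, vel in model.optimizer.state.items():
        tag = "_".join(str(k) for k in key)
        for j, v in enumerate(vel):
            opt_arrays[f"{tag}__{j}"] = v
    np.savez(out_dir / "optimizer.npz", **opt_arrays)


def load_checkpoint(ckpt_dir) -> ModelState:
    """Rebuild a :class:`ModelState` saved by :func:`save_checkpoint`."""
    ckpt_dir = Path(ckpt_dir)
    descriptor = yaml.safe_load((ckpt_dir / "descriptor.yaml").read_text())
    if descriptor.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint format {descriptor.get('format_version')}")
    arch = ArchitectureSpec(
        input_hw=tuple(descriptor["architecture"]["input_hw"]),
        in_channels=descriptor["architecture"]["in_channels"],
        conv_channels=tuple(descriptor["architecture"]["conv_channels"]),
        batchnorm=descriptor["architecture"]["batchnorm"],
        activation=descriptor["architecture"]["activation"],
        hidden_dim=descriptor["architecture"]["hidden_dim"],
    )
    tasks = [TaskSpec(**t) for t in descriptor["tasks"]]
    rng = np.random.default_rng(0)  # weights overwritten below
    subnets = [Subnet(arch, t, rng) for t in tasks]
    for i, subnet in enumerate(subnets):
        with np.load(ckpt_dir / f"subnet_{i}.npz") as data:
            n_params = len(subnet.params)
            subnet.set_weights([data[f"param_{j}"] for j in range(n_params)])
            buffers = {
                k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("buffer::")
            }
            if buffers:
                subnet.set_buffers(buffers)
    with np.load(ckpt_dir / "ttc.npz") as data:
        ttc = TTCState(len(tasks))
        ttc.beta = data["beta"]
        ttc.frozen = data["frozen"]
    opt = Optimizer(**descriptor["optimizer"])
    opt_path = ckpt_dir / "optimizer.npz"
    if opt_path.exists():
        with np.load(opt_path) as data:
            grouped: dict[tuple, dict[int, np.ndarray]] = {}
            for name in data.files:
                tag, j = name.rsplit("__", 1)
                parts = tag.split("_")
                key = (parts[0], int(parts[1]), int(parts[2]))
                grouped.setdefault(key, {})[int(j)] = data[name]
            for key, arrays in grouped.items():
                opt.state[key] = [arrays[j] for j in sorted(arrays)]
    state = ModelState(arch, tasks, subnets, ttc, opt, clip_norm=descriptor["clip_norm"])
    state.iteration = descriptor["iteration"]
    state.frozen_subnets = list(descriptor["frozen_subnets"])
    return state
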