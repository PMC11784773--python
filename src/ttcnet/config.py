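"""Run configuration: YAML-backed, validated, round-trippable.

The configuration mirrors the model family's typical hyperparameter
ranges (patch size 32 or 64, learning rate 1e-4..1e-3, batch size
16/32/64, 100-500 epochs at full scale, ReLU/LeakyReLU, 15% validation
and 15% test splits) plus sections for the edge detector, landmark
extraction, phantom generation and the task-transfer gates.  Unknown keys
are rejected at load; an empty file yields the defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


def _from_mapping(cls, data: dict, context: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if f.name in _NESTED:
                value = _from_mapping(_NESTED[f.name], value, f"{context}.{f.name}")
            kwargs[f.name] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class CannyConfig:
    sigma: float = 1.4
    low: float = 0.1
    high: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("canny.sigma must be positive")
        if not (0 <= self.low < self.high):
            raise ValueError("canny thresholds must satisfy 0 <= low < high")


@dataclass(frozen=True)
class LandmarkConfig:
    landmarks_per_image: int = 8
    density_radius: float = 3.0
    min_score: float = 0.0

    def __post_init__(self) -> None:
        if self.landmarks_per_image < 0:
            raise ValueError("landmarks_per_image must be non-negative")
        if self.density_radius <= 0:
            raise ValueError("density_radius must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    n_total: int = 300
    image_size: int = 64
    noise_sd: float = 0.05
    binary: bool = False

    def __post_init__(self) -> None:
        if self.n_total < 3:
            raise ValueError("phantom.n_total must be at least 3")
        if self.image_size < 16:
            raise ValueError("phantom.image_size must be at least 16")
        if self.noise_sd < 0:
            raise ValueError("phantom.noise_sd must be non-negative")


@dataclass(frozen=True)
class TrainSection:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    activation: str = "relu"
    patch_size: int = 32
    train_on: str = "patches"  # or "images"
    validation_split: float = 0.15
    test_split: float = 0.15
    early_stopping: bool = False
    patience: int = 10
    augment: bool = True  # dihedral flips/rotations; labels are invariant
    allow_nonstandard: bool = False

    def __post_init__(self) -> None:
        if self.train_on not in ("patches", "images"):
            raise ValueError("train.train_on must be 'patches' or 'images'")
        if not self.allow_nonstandard:
            if self.batch_size not in (16, 32, 64):
                raise ValueError(
                    "train.batch_size must be one of (16, 32, 64); "
                    "set train.allow_nonstandard to override"
                )
            if not (1e-4 <= self.learning_rate <= 1e-3):
                raise ValueError(
                    "train.learning_rate must lie in [1e-4, 1e-3]; "
                    "set train.allow_nonstandard to override"
                )
            if self.activation not in ("relu", "leaky_relu"):
                raise ValueError("train.activation must be relu or leaky_relu")
            if self.patch_size not in (32, 64):
                raise ValueError("train.patch_size must be 32 or 64")
        if not (0 < self.validation_split < 1 and 0 < self.test_split < 1):
            raise ValueError("splits must lie in (0, 1)")
        if self.validation_split + self.test_split >= 1:
            raise ValueError("validation + test splits must leave room for training")


@dataclass(frozen=True)
class TTCConfig:
    lr_beta: float = 0.01
    momentum: float = 0.0
    clip_norm: float = 5.0
    conv_channels: tuple[int, ...] = (8, 16, 32)
    hidden_dim: int = 64
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.lr_beta < 0 or self.clip_norm <= 0:
            raise ValueError("ttc.lr_beta must be >= 0 and ttc.clip_norm > 0")
        object.__setattr__(self, "conv_channels", tuple(self.conv_channels))


_NESTED = {
    "canny": CannyConfig,
    "landmarks": LandmarkConfig,
    "phantom": PhantomConfig,
    "train": TrainSection,
    "ttc": TTCConfig,
}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    canny: CannyConfig = field(default_factory=CannyConfig)
    landmarks: LandmarkConfig = field(default_factory=LandmarkConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    train: TrainSection = field(default_factory=TrainSection)
    ttc: TTCConfig = field(default_factory=TTCConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        text = yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; empty file = defaults."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    return _from_mapping(RunConfig, data, "config")


def save_config(config: RunConfig, path) -> None:
    """Serialize so that load_config(save_config(c)) == c."""
    Path(path).write_text(yaml.safe_dump(_listify(config.to_dict()), sort_keys=True))
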