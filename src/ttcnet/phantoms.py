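"""Deterministic brain-like phantom generator with joint labels.

Each phantom is a smooth low-frequency background (a sum of seeded
Gaussian blobs) plus one lesion, with additive Gaussian pixel noise,
clipped to [0, 1].  Three lesion families mimic the structure (not the
radiology) of the common three-class brain-tumor benchmark:

* class 0, "meningioma-like": smooth high-contrast ellipse near the
  periphery;
* class 1, "glioma-like": larger irregular region (radial perturbation of
  an ellipse) with mid contrast;
* class 2, "pituitary-like": small central round lesion.

The default class proportions follow the 708 : 1426 : 930 split of that
benchmark (3,064 images in total at full scale), and the binary mode
follows the 155-of-253 tumor prevalence of the smaller two-class set.
Images default to 64 x 64 for desk-scale runs; 512 x 512 is supported.

The regression target is the lesion area in px^2 (the 2-D stand-in for
tumor volume), defined as the pixel count of the emitted lesion mask; the
analytic boundary area ``0.5 * integral R(theta)^2 dtheta`` (which reduces
to ``pi*a*b`` for an unperturbed ellipse) agrees with it to within
discretization error.  A severity score (area x contrast) is emitted as an
optional second regression target for three-task experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .canny import GrayImage

__all__ = [
    "PhantomSpec",
    "LabeledSample",
    "generate_phantom",
    "generate_samples",
    "generate_dataset",
    "binary_mode",
    "samples_to_arrays",
]

DEFAULT_CLASS_WEIGHTS = (708, 1426, 930)
DEFAULT_TUMOR_FRACTION = 155 / 253


@dataclass(frozen=True)
class PhantomSpec:
    """Generator conditions; lesion ranges scale with image size.

    Ranges are in pixels at 64 x 64 and scale linearly with
    ``image_size / 64``.  ``contrast`` is the lesion's additive intensity
    offset against the background.
    """

    image_size: int = 64
    class_weights: tuple[float, ...] = DEFAULT_CLASS_WEIGHTS
    noise_sd: float = 0.05
    n_background_blobs: int = 6
    # per-class (semi_axis_range, center_radius_range, roughness_range,
    # contrast_range); center radius is the offset of the lesion centre
    # from the image centre, as a fraction of image size
    lesion_params: dict = field(
        default_factory=lambda: {
            0: {
                "semi_axis": (7.0, 11.0),
                "center_radius": (0.24, 0.34),
                "roughness": (0.0, 0.05),
                "contrast": (0.35, 0.50),
            },
            1: {
                "semi_axis": (9.0, 14.0),
                "center_radius": (0.05, 0.22),
                "roughness": (0.15, 0.30),
                "contrast": (0.20, 0.30),
            },
            2: {
                "semi_axis": (5.0, 7.0),
                "center_radius": (0.0, 0.05),
                "roughness": (0.0, 0.05),
                "contrast": (0.25, 0.40),
            },
        }
    )

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)


@dataclass(frozen=True)
class LabeledSample:
    image: GrayImage
    class_label: int
    regression_target: float  # lesion area, px^2
    severity: float  # area x contrast
    lesion_mask: np.ndarray  # diagnostics only; not a model input


def _background(size: int, n_blobs: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    bg = np.zeros((size, size))
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, size, 2)
        sd = rng.uniform(0.15, 0.45) * size
        amp = rng.uniform(0.3, 1.0)
        bg += amp * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sd**2)))
    lo, hi = bg.min(), bg.max()
    if hi > lo:
        bg = (bg - lo) / (hi - lo)
    return 0.15 + 0.30 * bg  # background intensities in [0.15, 0.45]


def _boundary_radius(
    theta: np.ndarray,
    a: float,
    b: float,
    tilt: float,
    roughness: float,
    harmonics: np.ndarray,
    phases: np.ndarray,
) -> np.ndarray:
    """Polar boundary: tilted ellipse radius times a rough modulation."""
    t = theta - tilt
    r_e = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    mod = np.ones_like(theta)
    for h, (amp, ph) in enumerate(zip(harmonics, phases), start=2):
        mod += roughness * amp * np.cos(h * theta + ph)
    return r_e * np.clip(mod, 0.2, None)


def generate_phantom(
    class_id: int, spec: PhantomSpec, rng: np.random.Generator
) -> LabeledSample:
    """One phantom of the given class, fully determined by ``rng``."""
    if class_id not in spec.lesion_params:
        raise ValueError(f"unknown class id {class_id}")
    size = spec.image_size
    scale = size / 64.0
    params = spec.lesion_params[class_id]
    bg = _background(size, spec.n_background_blobs, rng)

    for _attempt in range(100):
        a = rng.uniform(*params["semi_axis"]) * scale
        b = rng.uniform(*params["semi_axis"]) * scale
        if class_id == 2:  # pituitary-like lesions are round
            b = a * rng.uniform(0.9, 1.1)
        tilt = rng.uniform(0, np.pi)
        roughness = rng.uniform(*params["roughness"])
        contrast = rng.uniform(*params["contrast"])
        cr = rng.uniform(*params["center_radius"]) * size
        ang = rng.uniform(0, 2 * np.pi)
        cx = size / 2 + cr * np.cos(ang)
        cy = size / 2 + cr * np.sin(ang)
        harmonics = rng.uniform(0.3, 1.0, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        r_max = max(a, b) * (1 + roughness * harmonics.sum())
        if 1 + r_max < cx < size - 2 - r_max and 1 + r_max < cy < size - 2 - r_max:
            break
    else:
        raise RuntimeError("could not place lesion inside image bounds")

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - cx, yy - cy
    theta = np.arctan2(dy, dx)
    rr = np.hypot(dx, dy)
    boundary = _boundary_radius(theta, a, b, tilt, roughness, harmonics, phases)
    mask = rr <= boundary

    image = np.clip(bg + contrast * mask, 0.0, 1.0)
    if spec.noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, spec.noise_sd, image.shape), 0.0, 1.0)

    area = float(mask.sum())
    return LabeledSample(
        image=GrayImage(image),
        class_label=int(class_id),
        regression_target=area,
        severity=area * contrast,
        lesion_mask=mask,
    )


def analytic_lesion_area(
    a: float,
    b: float,
    roughness: float = 0.0,
    harmonics: np.ndarray | None = None,
    phases: np.ndarray | None = None,
    n_theta: int = 4096,
) -> float:
    """Closed-boundary area ``0.5 * integral R^2 dtheta`` by quadrature.

    Reduces to ``pi * a * b`` for an unperturbed ellipse.
    """
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    if harmonics is None:
        harmonics = np.zeros(3)
        phases = np.zeros(3)
    r = _boundary_radius(theta, a, b, 0.0, roughness, harmonics, phases)
    return float(0.5 * np.mean(r**2) * 2 * np.pi)


def _class_counts(n_total: int, weights: tuple[float, ...]) -> list[int]:
    total_w = sum(weights)
    raw = [n_total * w / total_w for w in weights]
    counts = [int(np.floor(r)) for r in raw]
    short = n_total - sum(counts)
    rem = np.array([r - c for r, c in zip(raw, counts)])
    for i in np.argsort(-rem)[:short]:
        counts[int(i)] += 1
    return counts


def generate_samples(
    n_total: int, spec: PhantomSpec, seed: int = 0
) -> list[LabeledSample]:
    """Shuffled list of phantoms with class counts proportional to weights."""
    if n_total < spec.n_classes:
        raise ValueError("n_total must cover at least one sample per class")
    counts = _class_counts(n_total, spec.class_weights)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(7,))
    rng = np.random.default_rng(ss)
    class_ids = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(class_ids)
    return [generate_phantom(int(c), spec, rng) for c in class_ids]


def generate_dataset(
    n_total: int, spec: PhantomSpec, out_dir, seed: int = 0
) -> pd.DataFrame:
    """Write phantoms as 16-bit PNGs plus a manifest CSV."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n_total, spec, seed=seed)
    rows = []
    for i, s in enumerate(samples):
        name = f"phantom_{i:05d}.png"
        arr16 = np.round(s.image.pixels * 65535).astype(np.uint16)
        Image.fromarray(arr16).save(out_dir / name)
        rows.append(
            {
                "image_path": name,
                "class_label": s.class_label,
                "regression_target": s.regression_target,
                "severity": s.severity,
                "seed": seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def binary_mode(
    n_total: int,
    spec: PhantomSpec,
    tumor_fraction: float = DEFAULT_TUMOR_FRACTION,
    seed: int = 0,
) -> list[LabeledSample]:
    """Two-class phantoms: tumor present (any lesion family) vs absent.

    Tumor-absent images are background plus noise only, with zero lesion
    area; labels are 1 = tumor, 0 = no tumor.
    """
    if not (0 < tumor_fraction < 1):
        raise ValueError("tumor_fraction must lie in (0, 1)")
    n_tumor = int(round(n_total * tumor_fraction))
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(8,))
    rng = np.random.default_rng(ss)
    flags = np.array([1] * n_tumor + [0] * (n_total - n_tumor))
    rng.shuffle(flags)
    out = []
    for flag in flags:
        if flag:
            family = int(rng.integers(0, spec.n_classes))
            s = generate_phantom(family, spec, rng)
            out.append(
                LabeledSample(
                    image=s.image,
                    class_label=1,
                    regression_target=s.regression_target,
                    severity=s.severity,
                    lesion_mask=s.lesion_mask,
                )
            )
        else:
            bg = _background(spec.image_size, spec.n_background_blobs, rng)
            if spec.noise_sd > 0:
                bg = bg + rng.normal(0.0, spec.noise_sd, bg.shape)
            img = GrayImage(np.clip(bg, 0.0, 1.0))
            out.append(
                LabeledSample(
                    image=img,
                    class_label=0,
                    regression_target=0.0,
                    severity=0.0,
                    lesion_mask=np.zeros((spec.image_size,) * 2, dtype=bool),
                )
            )
    return out


def samples_to_arrays(
    samples: list[LabeledSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack samples into (images, class_labels, areas, severities)."""
    x = np.stack([s.image.pixels for s in samples])
    y_cls = np.array([s.class_label for s in samples])
    y_area = np.array([s.regression_target for s in samples])
    y_sev = np.array([s.severity for s in samples])
    return x, y_cls, y_area, y_sev
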