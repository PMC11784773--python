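"""Landmark detection on edge evidence and fixed-size patch extraction.

Landmarks are local maxima of a Gaussian-smoothed edge-density surface,
selected greedily with a minimum-separation constraint.  Patches are square
crops centred on landmarks; crops that overhang the image border are
reflect-padded so every landmark yields a patch.  Coordinates are 0-based
``(x, y) = (column, row)`` and patch windows are half-open:
``[cx - size//2, cx - size//2 + size)`` in each axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .canny import EdgeMap, GrayImage

__all__ = [
    "Landmark",
    "Patch",
    "edge_density",
    "detect_landmarks",
    "extract_patch",
    "extract_patches",
    "write_patches",
    "read_patches",
]


@dataclass(frozen=True)
class Landmark:
    x: int
    y: int
    score: float


@dataclass(frozen=True)
class Patch:
    pixels: np.ndarray
    source_id: str
    center: tuple[int, int]
    size: int
    padded: bool
    class_label: int | None = None
    regression_target: float | None = None

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.size, self.size):
            raise ValueError(
                f"patch pixels {self.pixels.shape} do not match size {self.size}"
            )


def edge_density(edge_map: EdgeMap, radius: float) -> np.ndarray:
    """Gaussian-smoothed final binary edge map; values stay in [0, 1]."""
    if not (radius > 0):
        raise ValueError(f"radius must be positive, got {radius}")
    density = ndimage.gaussian_filter(
        edge_map.final.astype(float), sigma=radius, mode="constant"
    )
    return np.clip(density, 0.0, 1.0)


def detect_landmarks(
    density: np.ndarray,
    k: int,
    min_dist: float,
    min_score: float = 0.0,
) -> list[Landmark]:
    """Greedy top-k selection of strict local density maxima.

    A candidate pixel must exceed all in-bounds 8-neighbours and score at
    least ``min_score``.  Candidates are taken in order of decreasing score
    (ties broken by row, then column) and accepted when at least
    ``min_dist`` away from every previously accepted landmark.
    """
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    if not (min_dist > 0):
        raise ValueError(f"min_dist must be positive, got {min_dist}")
    if k == 0:
        return []
    density = np.asarray(density, dtype=float)
    h, w = density.shape

    padded = np.full((h + 2, w + 2), -np.inf)
    padded[1:-1, 1:-1] = density
    center = padded[1:-1, 1:-1]
    is_max = np.ones((h, w), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            neigh = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
            is_max &= center > neigh
    is_max &= density >= min_score

    rows, cols = np.nonzero(is_max)
    scores = density[rows, cols]
    order = np.lexsort((cols, rows, -scores))

    chosen: list[Landmark] = []
    for idx in order:
        x, y, s = int(cols[idx]), int(rows[idx]), float(scores[idx])
        if all((x - lm.x) ** 2 + (y - lm.y) ** 2 >= min_dist**2 for lm in chosen):
            chosen.append(Landmark(x=x, y=y, score=s))
            if len(chosen) == k:
                break
    return chosen


def extract_patch(
    img: GrayImage, center: tuple[int, int], size: int, source_id: str = ""
) -> Patch:
    """Crop a ``size`` x ``size`` window centred at ``center`` (x, y).

    Pixels outside the image are filled by reflection and the ``padded``
    flag records that the window overhung the border.
    """
    cx, cy = center
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    if not (0 <= cx < img.width and 0 <= cy < img.height):
        raise ValueError(f"center {center} outside image {img.width}x{img.height}")
    half = size // 2
    x0, y0 = cx - half, cy - half
    x1, y1 = x0 + size, y0 + size
    needs_pad = x0 < 0 or y0 < 0 or x1 > img.width or y1 > img.height
    if needs_pad:
        pad = size  # ample: window can overhang by at most size-1
        big = np.pad(img.pixels, pad, mode="reflect")
        window = big[y0 + pad : y1 + pad, x0 + pad : x1 + pad]
    else:
        window = img.pixels[y0:y1, x0:x1]
    return Patch(
        pixels=window.copy(),
        source_id=source_id,
        center=(int(cx), int(cy)),
        size=int(size),
        padded=bool(needs_pad),
    )


def extract_patches(
    img: GrayImage,
    landmarks: Sequence[Landmark],
    size: int,
    source_id: str = "",
    class_label: int | None = None,
    regression_target: float | None = None,
) -> list[Patch]:
    """One labeled patch per landmark, inheriting the source image's labels."""
    out = []
    for lm in landmarks:
        p = extract_patch(img, (lm.x, lm.y), size, source_id=source_id)
        out.append(
            Patch(
                pixels=p.pixels,
                source_id=source_id,
                center=p.center,
                size=p.size,
                padded=p.padded,
                class_label=class_label,
                regression_target=regression_target,
            )
        )
    return out


def write_patches(patches: Sequence[Patch], out_dir) -> pd.DataFrame:
    """Write patches as 16-bit PNGs plus a manifest CSV; returns the manifest."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        patch_id = f"{p.source_id}_p{i:04d}" if p.source_id else f"p{i:04d}"
        path = out_dir / f"{patch_id}.png"
        arr16 = np.round(np.clip(p.pixels, 0.0, 1.0) * 65535).astype(np.uint16)
        Image.fromarray(arr16).save(path)
        rows.append(
            {
                "patch_id": patch_id,
                "source_id": p.source_id,
                "center_x": p.center[0],
                "center_y": p.center[1],
                "size": p.size,
                "padded": p.padded,
                "class_label": p.class_label,
                "regression_target": p.regression_target,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "patch_manifest.csv", index=False)
    return manifest


def read_patches(patch_dir) -> list[Patch]:
    """Re-load patches written by :func:`write_patches`."""
    from PIL import Image

    patch_dir = Path(patch_dir)
    manifest = pd.read_csv(patch_dir / "patch_manifest.csv")
    patches = []
    for row in manifest.itertuples(index=False):
        with Image.open(patch_dir / f"{row.patch_id}.png") as im:
            arr = np.asarray(im, dtype=np.uint16).astype(float) / 65535.0
        label = None if pd.isna(row.class_label) else int(row.class_label)
        target = None if pd.isna(row.regression_target) else float(row.regression_target)
        patches.append(
            Patch(
                pixels=arr,
                source_id="" if pd.isna(row.source_id) else str(row.source_id),
                center=(int(row.center_x), int(row.center_y)),
                size=int(row.size),
                padded=bool(row.padded),
                class_label=label,
                regression_target=target,
            )
        )
    return patches
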