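"""Naive per-pixel reference implementations used as independent oracles.

Everything here is written with explicit Python loops and breadth-first
search, sharing only the documented pixel-level conventions (reflect
borders, 4-bin orientation quantization with ties to the lower bin,
plateau-preserving suppression, 8-connected hysteresis) with the
vectorized implementations under test — never their code.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def _reflect(i: int, n: int) -> int:
    # scipy.ndimage 'reflect' mode: (d c b a | a b c d)
    while i < 0 or i >= n:
        if i < 0:
            i = -1 - i
        else:
            i = 2 * n - 1 - i
    return i


def ref_gaussian_smooth(pixels: np.ndarray, sigma: float) -> np.ndarray:
    radius = int(math.ceil(3.0 * sigma))
    ax = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    kernel = np.outer(g1, g1)
    kernel /= kernel.sum()
    h, w = pixels.shape
    out = np.zeros_like(pixels, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    acc += (
                        kernel[dr + radius, dc + radius]
                        * pixels[_reflect(r + dr, h), _reflect(c + dc, w)]
                    )
            out[r, c] = acc
    return np.clip(out, 0.0, 1.0)


_SX = [[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]
_SY = [[-1.0, -2.0, -1.0], [0.0, 0.0, 0.0], [1.0, 2.0, 1.0]]


def ref_sobel(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h, w = pixels.shape
    gx = np.zeros_like(pixels, dtype=float)
    gy = np.zeros_like(pixels, dtype=float)
    for r in range(h):
        for c in range(w):
            ax = ay = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    v = pixels[_reflect(r + dr, h), _reflect(c + dc, w)]
                    ax += _SX[dr + 1][dc + 1] * v
                    ay += _SY[dr + 1][dc + 1] * v
            gx[r, c] = ax
            gy[r, c] = ay
    return gx, gy


def _bin_angle(deg: float) -> int:
    folded = deg % 180.0
    if folded <= 22.5 or folded > 157.5:
        return 0
    if folded <= 67.5:
        return 45
    if folded <= 112.5:
        return 90
    return 135


_OFFSETS = {
    0: ((0, 1), (0, -1)),
    45: ((1, 1), (-1, -1)),
    90: ((1, 0), (-1, 0)),
    135: ((1, -1), (-1, 1)),
}


def ref_nms(magnitude: np.ndarray, orientation_deg: np.ndarray) -> np.ndarray:
    h, w = magnitude.shape
    out = np.zeros_like(magnitude)
    for r in range(h):
        for c in range(w):
            b = _bin_angle(float(orientation_deg[r, c]))
            keep = True
            for dr, dc in _OFFSETS[b]:
                rr, cc = r + dr, c + dc
                neigh = magnitude[rr, cc] if 0 <= rr < h and 0 <= cc < w else 0.0
                if magnitude[r, c] < neigh:
                    keep = False
                    break
            if keep:
                out[r, c] = magnitude[r, c]
    return out


def ref_hysteresis(strength: np.ndarray, low: float, high: float):
    """Returns (labels, final) with labels in {0 none, 1 weak, 2 strong}."""
    h, w = strength.shape
    labels = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            if strength[r, c] >= high:
                labels[r, c] = 2
            elif strength[r, c] >= low:
                labels[r, c] = 1
    final = np.zeros((h, w), dtype=np.uint8)
    queue = deque(
        (r, c) for r in range(h) for c in range(w) if labels[r, c] == 2
    )
    for r, c in queue:
        final[r, c] = 1
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] >= 1 and not final[rr, cc]:
                    final[rr, cc] = 1
                    queue.append((rr, cc))
    return labels, final


def ref_canny(pixels: np.ndarray, sigma: float, low: float, high: float):
    smoothed = ref_gaussian_smooth(pixels, sigma)
    gx, gy = ref_sobel(smoothed)
    magnitude = np.sqrt(gx**2 + gy**2)
    orientation = np.degrees(np.arctan2(gy, gx))
    strength = ref_nms(magnitude, orientation)
    return ref_hysteresis(strength, low, high)
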