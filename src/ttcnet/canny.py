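"""Four-stage Canny edge detection used as the preprocessing front end.

The detector runs Gaussian smoothing, Sobel gradients, non-maximum
suppression along the quantized gradient direction, and two-threshold
hysteresis tracking.  Conventions are fixed explicitly because downstream
stages (landmark scoring, patch extraction) depend on exact pixel-level
behaviour:

* images are 2-D float arrays with intensities in [0, 1];
* the Gaussian kernel has radius ``ceil(3 * sigma)`` and unit mass;
* convolutions use reflect padding;
* gradient orientation uses the full-quadrant arctangent, in degrees;
* orientation is quantized to {0, 45, 90, 135} degrees with ties at the
  22.5-degree bin boundaries assigned to the lower bin;
* a pixel survives suppression when its magnitude is >= both neighbours
  along the quantized direction (plateaus survive; outside pixels count 0);
* hysteresis keeps STRONG pixels and WEAK pixels 8-connected to a STRONG
  pixel, transitively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "NONE",
    "WEAK",
    "STRONG",
    "GrayImage",
    "GaussianKernel",
    "GradientField",
    "EdgeMap",
    "gaussian_kernel",
    "gaussian_smooth",
    "compute_gradient",
    "quantize_orientation",
    "non_maximum_suppression",
    "hysteresis_threshold",
    "canny",
    "load_gray_image",
    "save_edge_map",
]

# tri-state edge labels
NONE = 0
WEAK = 1
STRONG = 2

SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T

# neighbour offsets (drow, dcol) for each quantized orientation bin; the
# gradient points across the edge, so the comparison is along the gradient
_BIN_OFFSETS = {
    0: ((0, 1), (0, -1)),
    45: ((1, 1), (-1, -1)),
    90: ((1, 0), (-1, 0)),
    135: ((1, -1), (-1, 1)),
}


@dataclass(frozen=True)
class GrayImage:
    """2-D intensity raster normalized to [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={px.ndim}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(f"image must be at least 3x3, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GaussianKernel:
    """Normalized isotropic Gaussian kernel with radius ceil(3*sigma)."""

    sigma: float
    radius: int
    weights: np.ndarray


@dataclass(frozen=True)
class GradientField:
    """Sobel responses plus derived magnitude/orientation (degrees)."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray


@dataclass(frozen=True)
class EdgeMap:
    """Tri-state labels plus the final binary map after hysteresis."""

    labels: np.ndarray
    final: np.ndarray
    low_threshold: float
    high_threshold: float


def gaussian_kernel(sigma: float) -> GaussianKernel:
    """Build the unit-mass Gaussian kernel used for smoothing."""
    if not (sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = int(math.ceil(3.0 * sigma))
    ax = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    weights = np.outer(g1, g1)
    weights /= weights.sum()
    return GaussianKernel(sigma=float(sigma), radius=radius, weights=weights)


def gaussian_smooth(img: GrayImage, sigma: float) -> GrayImage:
    """Convolve the image with a normalized Gaussian (reflect borders)."""
    kernel = gaussian_kernel(sigma)
    out = ndimage.convolve(img.pixels, kernel.weights, mode="reflect")
    # unit-mass kernel keeps values in [0,1] up to float round-off
    return GrayImage(np.clip(out, 0.0, 1.0))


def compute_gradient(img: GrayImage) -> GradientField:
    """Sobel gradients, magnitude and full-quadrant orientation.

    ``gx`` responds to intensity change along columns (x), ``gy`` along
    rows (y).  Orientation is ``atan2(gy, gx)`` in degrees, in
    (-180, 180].
    """
    px = img.pixels
    gx = ndimage.correlate(px, SOBEL_X, mode="reflect")
    gy = ndimage.correlate(px, SOBEL_Y, mode="reflect")
    magnitude = np.hypot(gx, gy)
    orientation = np.degrees(np.arctan2(gy, gx))
    # atan2 returns [-180, 180]; map -180 to +180 for the documented range
    orientation = np.where(orientation == -180.0, 180.0, orientation)
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, orientation=orientation)


def quantize_orientation(orientation_deg: np.ndarray) -> np.ndarray:
    """Quantize orientations to {0, 45, 90, 135} degrees.

    The orientation is folded to [0, 180); an angle exactly on a 22.5-degree
    bin boundary is assigned to the lower bin.
    """
    folded = np.mod(np.asarray(orientation_deg, dtype=float), 180.0)
    bins = np.zeros(folded.shape, dtype=int)
    bins[(folded > 22.5) & (folded <= 67.5)] = 45
    bins[(folded > 67.5) & (folded <= 112.5)] = 90
    bins[(folded > 112.5) & (folded <= 157.5)] = 135
    # (157.5, 180) folds back to the 0-degree bin
    return bins


def non_maximum_suppression(grad: GradientField) -> np.ndarray:
    """Keep magnitudes that are local maxima along the gradient direction.

    A pixel survives when its magnitude is >= both neighbours along its
    quantized gradient direction; neighbours outside the image count as 0.
    """
    mag = grad.magnitude
    bins = quantize_orientation(grad.orientation)
    out = np.zeros_like(mag)
    h, w = mag.shape
    for angle, ((dr1, dc1), (dr2, dc2)) in _BIN_OFFSETS.items():
        sel = bins == angle
        n1 = _shifted(mag, dr1, dc1)
        n2 = _shifted(mag, dr2, dc2)
        keep = sel & (mag >= n1) & (mag >= n2)
        out[keep] = mag[keep]
    assert out.shape == (h, w)
    return out


def _shifted(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Array of neighbour values at offset (dr, dc); outside pixels are 0."""
    h, w = arr.shape
    out = np.zeros_like(arr)
    rs_src = slice(max(dr, 0), h + min(dr, 0))
    cs_src = slice(max(dc, 0), w + min(dc, 0))
    rs_dst = slice(max(-dr, 0), h + min(-dr, 0))
    cs_dst = slice(max(-dc, 0), w + min(-dc, 0))
    out[rs_dst, cs_dst] = arr[rs_src, cs_src]
    return out


def hysteresis_threshold(strength: np.ndarray, low: float, high: float) -> EdgeMap:
    """Two-threshold labeling plus 8-connected edge tracking.

    STRONG where strength >= high, WEAK where low <= strength < high,
    NONE otherwise.  The final binary map keeps STRONG pixels and every
    WEAK pixel transitively 8-connected to a STRONG pixel.
    """
    if not (0 <= low < high):
        raise ValueError(f"thresholds must satisfy 0 <= low < high, got {low}, {high}")
    strength = np.asarray(strength, dtype=float)
    labels = np.full(strength.shape, NONE, dtype=np.uint8)
    labels[strength >= high] = STRONG
    labels[(strength >= low) & (strength < high)] = WEAK

    candidate = labels > NONE
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    comp, n_comp = ndimage.label(candidate, structure=structure)
    final = np.zeros(strength.shape, dtype=np.uint8)
    if n_comp:
        has_strong = ndimage.labeled_comprehension(
            labels == STRONG, comp, np.arange(1, n_comp + 1), np.any, bool, False
        )
        keep_ids = np.flatnonzero(has_strong) + 1
        final[np.isin(comp, keep_ids)] = 1
    return EdgeMap(labels=labels, final=final, low_threshold=float(low), high_threshold=float(high))


def canny(img: GrayImage, sigma: float = 1.4, low: float = 0.1, high: float = 0.2) -> EdgeMap:
    """Full detector: smooth, gradient, suppression, hysteresis."""
    smoothed = gaussian_smooth(img, sigma)
    grad = compute_gradient(smoothed)
    strength = non_maximum_suppression(grad)
    return hysteresis_threshold(strength, low, high)


def canny_quantile(
    img: GrayImage, sigma: float = 1.4, low_q: float = 0.90, high_q: float = 0.98
) -> EdgeMap:
    """Variant with thresholds given as quantiles of the suppressed magnitude.

    Useful when absolute thresholds are brittle across contrast levels;
    off by default in the pipeline.
    """
    if not (0 <= low_q < high_q <= 1):
        raise ValueError("quantiles must satisfy 0 <= low_q < high_q <= 1")
    smoothed = gaussian_smooth(img, sigma)
    grad = compute_gradient(smoothed)
    strength = non_maximum_suppression(grad)
    positive = strength[strength > 0]
    if positive.size == 0:
        return hysteresis_threshold(strength, 0.0, np.finfo(float).tiny)
    low = float(np.quantile(positive, low_q))
    high = float(np.quantile(positive, high_q))
    if not low < high:
        high = np.nextafter(low, np.inf)
    return hysteresis_threshold(strength, low, high)


def load_gray_image(path) -> GrayImage:
    """Read a PNG/TIFF file as a normalized grayscale image.

    8-bit sources are scaled by 255, 16-bit by 65535; float sources are
    assumed already normalized.
    """
    from PIL import Image

    with Image.open(path) as im:
        if im.mode in ("I;16", "I;16B", "I;16L", "I"):
            arr = np.asarray(im, dtype=float) / 65535.0
        elif im.mode == "F":
            arr = np.asarray(im, dtype=float)
        else:
            arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return GrayImage(np.clip(arr, 0.0, 1.0))


def save_edge_map(edge_map: EdgeMap, path) -> None:
    """Write the final binary edge map as an 8-bit PNG (0/255)."""
    from PIL import Image

    Image.fromarray((edge_map.final * 255).astype(np.uint8)).save(path)
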