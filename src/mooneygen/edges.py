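"""Canny edge maps and the directed Hausdorff distance between them.

Both spatial threshold selectors reduce a candidate two-tone image to a
binary edge map and score it: the max-edge selector by the number of edge
pixels, the edge-similarity selector by the directed Hausdorff distance
from the template's edge map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny as _skimage_canny


@dataclass(frozen=True)
class EdgeConfig:
    """Canny detector parameters.

    ``sigma`` is the Gaussian scale of the gradient estimate (the
    stimulus pipeline uses 1). ``low_fraction`` and ``high_fraction``
    are the hysteresis thresholds expressed as fractions of the image's
    own gradient-magnitude maximum, so the detector adapts to the
    contrast of each candidate image.
    """

    sigma: float = 1.0
    low_fraction: float = 0.1
    high_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (0 <= self.low_fraction <= self.high_fraction <= 1):
            raise ValueError(
                "need 0 <= low_fraction <= high_fraction <= 1, got "
                f"({self.low_fraction}, {self.high_fraction})"
            )


def _as_float01(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.dtype == bool:
        return arr.astype(np.float64)
    return arr.astype(np.float64) / 255.0


def canny_edges(img: np.ndarray, cfg: EdgeConfig | None = None) -> np.ndarray:
    """Binary edge map of a grayscale or two-tone image.

    Standard Canny pipeline: Gaussian-derivative gradient at
    ``cfg.sigma``, non-maximum suppression, double-threshold hysteresis.
    The hysteresis thresholds are ``cfg.low_fraction`` and
    ``cfg.high_fraction`` of the image's gradient-magnitude maximum;
    a constant image (zero gradient everywhere) yields an empty map.

    Returns a boolean array of the input's shape. The gradient magnitude
    is polarity-invariant, so an inverted image produces the same map.
    """
    if cfg is None:
        cfg = EdgeConfig()
    arr = _as_float01(img)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {arr.shape}")
    if min(arr.shape) < 3:
        raise ValueError(
            f"image of shape {arr.shape} is too thin for edge detection "
            "(need at least 3 pixels per axis)"
        )
    # Same gradient estimate skimage uses internally, to turn the
    # fraction-of-maximum thresholds into the absolute values it expects.
    smoothed = ndi.gaussian_filter(arr, sigma=cfg.sigma, mode="constant", cval=0.0)
    magnitude = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    mag_max = float(magnitude.max())
    if mag_max == 0.0:
        return np.zeros(arr.shape, dtype=bool)
    return _skimage_canny(
        arr,
        sigma=cfg.sigma,
        low_threshold=cfg.low_fraction * mag_max,
        high_threshold=cfg.high_fraction * mag_max,
        mode="constant",
        cval=0.0,
    )


def edge_pixel_count(edge_map: np.ndarray) -> int:
    """Number of edge (True) pixels in a binary edge map."""
    return int(np.count_nonzero(np.asarray(edge_map, dtype=bool)))


def directed_hausdorff(
    template_edges: np.ndarray,
    mooney_edges: np.ndarray,
    *,
    symmetric: bool = False,
) -> float:
    """Directed Hausdorff distance between two binary edge maps, in pixels.

    The maximum over template edge pixels of the Euclidean distance to
    the nearest edge pixel of the candidate (Mooney) map; 0 whenever the
    template's edge set is contained in the candidate's. Tolerant of
    small positional shifts, which is why it suits edge-map comparison.

    Degenerate sets: an empty template gives 0; a non-empty template
    against an empty candidate map returns the image diagonal
    ``sqrt(H^2 + W^2)`` so that all-black / all-white candidate
    thresholds are maximally penalized in the argmin search instead of
    being undefined.

    With ``symmetric=True``, returns the max of the two directed
    distances (the classical Hausdorff distance).
    """
    a = np.asarray(template_edges, dtype=bool)
    b = np.asarray(mooney_edges, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if symmetric:
        return max(directed_hausdorff(a, b), directed_hausdorff(b, a))
    if not a.any():
        return 0.0
    if not b.any():
        h, w = a.shape
        return math.hypot(h, w)
    # exact Euclidean distance from every pixel to the nearest b-pixel
    dist_to_b = ndi.distance_transform_edt(~b)
    return float(dist_to_b[a].max())
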