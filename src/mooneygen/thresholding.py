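"""Global threshold selection and binarization.

Four selectors, spanning the main families of global thresholding:

* ``mean`` — the mean pixel intensity (simplest possible baseline);
* ``otsu`` — histogram clustering: the intensity maximizing between-class
  variance, equivalently minimizing within-class variance;
* ``max_edge`` — spatial: the threshold whose two-tone image contains the
  most Canny edge pixels;
* ``edge_similarity`` — spatial: the threshold whose two-tone edge map is
  closest (directed Hausdorff) to the template's edge map.

All selectors search the 256 candidate thresholds of an 8-bit image.
Binarization is strict: a pixel is white iff its intensity exceeds the
threshold, so for any two thresholds the white sets are nested and two
global-threshold variants of one image can never be full polarity
reversals of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_image import SmoothingConfig, CIE1931_WEIGHTS, preprocess
from .edges import EdgeConfig, canny_edges, directed_hausdorff, edge_pixel_count

TECHNIQUES = ("mean", "otsu", "max_edge", "edge_similarity")


@dataclass(frozen=True)
class ThresholdResult:
    """A selected threshold with its provenance.

    ``value`` is on the 0-255 intensity scale: real-valued for the mean
    selector, an integer for the three search-based selectors.
    ``objective_curve``, when present, holds the per-candidate objective
    for every integer threshold 0..255.
    """

    technique: str
    value: float
    objective_curve: np.ndarray | None = field(default=None, repr=False)
    source_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.value <= 255):
            raise ValueError(f"threshold {self.value} outside [0, 255]")
        if self.objective_curve is not None and len(self.objective_curve) != 256:
            raise ValueError("objective_curve must have exactly 256 entries")


@dataclass(frozen=True)
class MooneyImage:
    """A two-tone image: boolean pixels (True = white) plus provenance."""

    pixels: np.ndarray = field(repr=False)
    threshold_used: float = math.nan
    technique: str | None = None
    source_id: str | None = None

    def to_uint8(self) -> np.ndarray:
        """0/255 uint8 encoding used for serialization."""
        return np.where(self.pixels, 255, 0).astype(np.uint8)


def _check_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected non-empty 2-D grayscale image, got shape {arr.shape}")
    return arr


def apply_threshold(
    img: np.ndarray,
    t: float,
    *,
    technique: str | None = None,
    source_id: str | None = None,
) -> MooneyImage:
    """Binarize: white iff intensity strictly greater than ``t``."""
    arr = _check_gray(img)
    if not math.isfinite(t):
        raise ValueError(f"threshold must be finite, got {t}")
    return MooneyImage(
        pixels=arr > t, threshold_used=float(t), technique=technique, source_id=source_id
    )


def mean_threshold(img: np.ndarray, *, source_id: str | None = None) -> ThresholdResult:
    """Mean pixel intensity as threshold (kept real-valued, not rounded)."""
    arr = _check_gray(img)
    return ThresholdResult("mean", float(arr.mean()), source_id=source_id)


def otsu_threshold(img: np.ndarray, *, source_id: str | None = None) -> ThresholdResult:
    """Threshold maximizing between-class variance of black vs white.

    For each candidate t the pixels split into a black class (<= t) and
    a white class (> t); the objective is
    ``w0(t) * w1(t) * (mu0(t) - mu1(t))**2`` from the 256-bin histogram.
    Minimizing within-class variance is equivalent. Ties break toward
    the smallest t; a constant image has no two classes to separate and
    raises.
    """
    arr = _check_gray(img)
    hist = np.bincount(arr.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined: image has a single intensity")
    omega0 = np.cumsum(hist) / n                    # weight of class <= t
    cum_mean = np.cumsum(hist * np.arange(256)) / n
    total_mean = cum_mean[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / omega0
        mu1 = (total_mean - cum_mean) / omega1
    between = omega0 * omega1 * (mu0 - mu1) ** 2
    between = np.where(np.isfinite(between), between, 0.0)
    t = int(np.argmax(between))  # argmax takes the first (smallest) maximizer
    return ThresholdResult("otsu", float(t), objective_curve=between, source_id=source_id)


def max_edge_threshold(
    img: np.ndarray,
    cfg: EdgeConfig | None = None,
    *,
    source_id: str | None = None,
) -> ThresholdResult:
    """Threshold whose two-tone image yields the most Canny edge pixels.

    Exhaustive search: every integer threshold 0..255 is applied, the
    resulting two-tone image is run through the Canny detector, and the
    edge pixels are counted. Ties break toward the smallest threshold,
    so a degenerate image whose candidates all score zero returns 0.
    """
    arr = _check_gray(img)
    if cfg is None:
        cfg = EdgeConfig()
    counts = np.empty(256, dtype=np.int64)
    for t in range(256):
        counts[t] = edge_pixel_count(canny_edges(arr > t, cfg))
    t_best = int(np.argmax(counts))
    return ThresholdResult(
        "max_edge", float(t_best), objective_curve=counts, source_id=source_id
    )


def edge_similarity_threshold(
    img: np.ndarray,
    cfg: EdgeConfig | None = None,
    *,
    source_id: str | None = None,
) -> ThresholdResult:
    """Threshold whose two-tone edge map best matches the template's.

    The template edge map is computed once from the (smoothed, 8-bit)
    grayscale image; each candidate threshold's two-tone edge map is
    scored by the directed Hausdorff distance from the template map, and
    the argmin is returned (smallest threshold on ties). A template with
    no detectable edges makes every distance identically zero, which
    would select arbitrarily, so that case raises.
    """
    arr = _check_gray(img)
    if cfg is None:
        cfg = EdgeConfig()
    template = canny_edges(arr, cfg)
    if not template.any():
        raise ValueError(
            "edge-similarity threshold undefined: template image has no Canny edges"
        )
    distances = np.empty(256, dtype=np.float64)
    for t in range(256):
        distances[t] = directed_hausdorff(template, canny_edges(arr > t, cfg))
    t_best = int(np.argmin(distances))
    return ThresholdResult(
        "edge_similarity", float(t_best), objective_curve=distances, source_id=source_id
    )


_SELECTORS = {
    "mean": lambda img, cfg, sid: mean_threshold(img, source_id=sid),
    "otsu": lambda img, cfg, sid: otsu_threshold(img, source_id=sid),
    "max_edge": lambda img, cfg, sid: max_edge_threshold(img, cfg, source_id=sid),
    "edge_similarity": lambda img, cfg, sid: edge_similarity_threshold(
        img, cfg, source_id=sid
    ),
}


def select_threshold(
    img: np.ndarray,
    technique: str,
    edge_cfg: EdgeConfig | None = None,
    *,
    source_id: str | None = None,
) -> ThresholdResult:
    """Dispatch to one of the four selectors by name."""
    if technique not in _SELECTORS:
        raise ValueError(
            f"unknown technique {technique!r}; expected one of {TECHNIQUES}"
        )
    return _SELECTORS[technique](img, edge_cfg, source_id)


def generate_mooney(
    img: np.ndarray,
    sigma: float,
    technique: str,
    *,
    edge_cfg: EdgeConfig | None = None,
    smoothing: SmoothingConfig | None = None,
    weights: tuple[float, float, float] = CIE1931_WEIGHTS,
    gamma_decode: bool = False,
    source_id: str | None = None,
) -> tuple[MooneyImage, ThresholdResult]:
    """Full pipeline: RGB/gray template -> two-tone Mooney image.

    Composition of grayscale conversion, Gaussian smoothing at ``sigma``
    (in float), 8-bit quantization, threshold selection with the named
    technique, and strict binarization. Deterministic given inputs and
    configuration.
    """
    if technique not in TECHNIQUES:
        raise ValueError(
            f"unknown technique {technique!r}; expected one of {TECHNIQUES}"
        )
    if smoothing is None:
        smoothing = SmoothingConfig(sigma=sigma)
    elif smoothing.sigma != sigma:
        raise ValueError("sigma argument disagrees with smoothing.sigma")
    try:
        gray8 = preprocess(img, smoothing, weights, gamma_decode=gamma_decode)
    except ValueError as err:
        raise ValueError(f"preprocessing failed for {source_id!r}: {err}") from err
    result = select_threshold(gray8, technique, edge_cfg, source_id=source_id)
    mooney = apply_threshold(
        gray8, result.value, technique=technique, source_id=source_id
    )
    return mooney, result
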