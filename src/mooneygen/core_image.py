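"""Grayscale conversion, Gaussian smoothing and 8-bit quantization.

These are the preprocessing stages of the two-tone (Mooney) pipeline:
an RGB photograph is reduced to a single luminance channel, blurred with
a truncated Gaussian kernel, and mapped to 8-bit integers so that a
global threshold search has exactly 256 candidate values.

All images are plain numpy arrays: RGB inputs are ``(H, W, 3)`` uint8 (or
integer-valued) arrays, the working luminance representation is a float64
``(H, W)`` array on the 0-255 scale, and quantized images are uint8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

#: CIE 1931 Y coefficients for sRGB primaries (Rec. 709 luma weights),
#: applied directly to the stored 8-bit channel values by default.
CIE1931_WEIGHTS: tuple[float, float, float] = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class SmoothingConfig:
    """Parameters of the Gaussian blur applied before thresholding.

    Parameters
    ----------
    sigma : float
        Standard deviation of the Gaussian kernel in pixels. ``0`` means
        no smoothing. Typical stimulus-generation values are 2 (light
        blur) up to 6 (strong blur that merges fine texture).
    truncate_factor : float
        Kernel cutoff in units of sigma; the kernel extends
        ``ceil(truncate_factor * sigma)`` pixels from its centre.
    boundary_mode : str
        Edge-extension rule passed to the convolution
        (scipy ``mode``: 'mirror', 'reflect', 'nearest', 'constant', 'wrap').
        Mirror-reflection avoids darkening at the borders, which would
        bias mean-based threshold selection.
    """

    sigma: float = 2.0
    truncate_factor: float = 4.0
    boundary_mode: str = "mirror"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.truncate_factor <= 0:
            raise ValueError(
                f"truncate_factor must be > 0, got {self.truncate_factor}"
            )


def _srgb_decode(c: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer: encoded [0,1] -> linear [0,1]."""
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_encode(y: np.ndarray) -> np.ndarray:
    return np.where(y <= 0.0031308, 12.92 * y, 1.055 * y ** (1 / 2.4) - 0.055)


def to_grayscale(
    img: np.ndarray,
    weights: tuple[float, float, float] = CIE1931_WEIGHTS,
    *,
    gamma_decode: bool = False,
) -> np.ndarray:
    """Convert an RGB image to a single luminance channel.

    Computes the per-pixel weighted sum of the three channels with the
    CIE 1931 Y coefficients by default. An already-2-D (grayscale) array
    is passed through as float unchanged, so achromatic inputs map to
    themselves.

    Parameters
    ----------
    img : ndarray
        ``(H, W, 3)`` RGB array with channel values in [0, 255], or an
        ``(H, W)`` grayscale array.
    weights : tuple of 3 floats
        Non-negative channel weights; normalized to sum to 1.
    gamma_decode : bool
        If True, decode sRGB gamma before the weighted sum and re-encode
        afterwards, i.e. compute relative luminance in linear-light and
        return it on the perceptual 0-255 scale. Default applies the
        weights directly to the stored channel values.

    Returns
    -------
    ndarray
        ``(H, W)`` float64 luminance on the 0-255 scale.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected (H, W, 3) RGB or (H, W) grayscale array, got shape {arr.shape}"
        )
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,) or np.any(w < 0):
        raise ValueError("weights must be 3 non-negative coefficients")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    w = w / w.sum()
    if gamma_decode:
        linear = _srgb_decode(arr / 255.0)
        y = linear @ w
        return 255.0 * _srgb_encode(y)
    return arr @ w


def smooth(img: np.ndarray, cfg: SmoothingConfig | None = None) -> np.ndarray:
    """Blur a luminance image with a normalized truncated Gaussian kernel.

    Separable convolution; the kernel is cut off at
    ``truncate_factor * sigma`` and renormalized, so constant images are
    preserved exactly and output values stay inside the input's range.
    ``sigma = 0`` returns the input unchanged.
    """
    if cfg is None:
        cfg = SmoothingConfig()
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D grayscale array, got shape {arr.shape}")
    if cfg.sigma == 0:
        return arr.copy()
    return ndi.gaussian_filter(
        arr, sigma=cfg.sigma, truncate=cfg.truncate_factor, mode=cfg.boundary_mode
    )


def quantize8(img: np.ndarray) -> np.ndarray:
    """Map a float luminance image to 8-bit integers.

    Round-half-away-from-zero, then clip to [0, 255]. Idempotent on
    integer-valued input. Raises on NaN or infinite pixels.
    """
    arr = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains NaN or infinite values")
    # round half away from zero: platform-independent, unlike banker's rounding
    rounded = np.trunc(arr + np.copysign(0.5, arr))
    return np.clip(rounded, 0, 255).astype(np.uint8)


def preprocess(
    img: np.ndarray,
    cfg: SmoothingConfig | None = None,
    weights: tuple[float, float, float] = CIE1931_WEIGHTS,
    *,
    gamma_decode: bool = False,
) -> np.ndarray:
    """Full preprocessing: grayscale -> smooth (in float) -> quantize to uint8."""
    return quantize8(smooth(to_grayscale(img, weights, gamma_decode=gamma_decode), cfg))
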