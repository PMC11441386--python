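"""Reading templates and writing two-tone images and edge maps as PNG."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .thresholding import MooneyImage


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG raster as uint8; RGBA is reduced to RGB."""
    try:
        arr = iio.imread(path, plugin="pillow")
    except Exception as err:
        raise ValueError(f"cannot decode image {path}: {err}") from err
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        scale = 255.0 / info.max if info else 255.0
        arr = np.clip(np.round(arr.astype(np.float64) * scale), 0, 255).astype(np.uint8)
    return arr


def write_png(path, img) -> None:
    """Write a single-channel 8-bit PNG.

    Accepts a uint8 array, a boolean array or edge map (encoded 0/255),
    or a MooneyImage.
    """
    if isinstance(img, MooneyImage):
        arr = img.to_uint8()
    else:
        arr = np.asarray(img)
        if arr.dtype == bool:
            arr = np.where(arr, 255, 0).astype(np.uint8)
        arr = arr.astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), arr, extension=".png")
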