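"""Deterministic synthetic test images for the two-tone pipeline.

Small grayscale scenes with the statistical structure the pipeline
assumes in real photographs: smooth bimodal-intensity scenes (an object
blob on a background, so mean and Otsu thresholds are well defined and
distinct), intensity ramps, images with known edge geometry for the two
spatial selectors, pure noise, and polarity-reversed binary pairs for
dissimilarity tests.

All randomness comes from numpy's PCG64 generator seeded explicitly, so
a given spec reproduces byte-identical uint8 images on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_image import quantize8

KINDS = ("ramp", "bimodal", "nested_rects", "disk", "noise", "polarity_pair")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic image.

    ``params`` depend on ``kind``:

    * ``bimodal``: ``mu0``/``mu1`` (background/object mean luminance,
      defaults 40/200), ``sd`` (pixel noise SD, default 10),
      ``radius_frac`` (object radius as fraction of the smaller image
      side, default 0.3);
    * ``disk``: ``bg``/``fg`` (default 40/200), ``radius_frac``;
    * ``nested_rects``: ``values`` (outer-to-inner luminances,
      default (60, 120, 180));
    * ``noise``: uniform 8-bit noise, no parameters;
    * ``ramp``: left-to-right linear ramp 0..255, no parameters;
    * ``polarity_pair``: binary blob and its complement, ``radius_frac``.
    """

    kind: str
    shape: tuple[int, int] = (64, 64)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; expected one of {KINDS}")
        h, w = self.shape
        if h < 8 or w < 8:
            raise ValueError(f"fixture shape must be at least 8x8, got {self.shape}")


def _disk_mask(shape: tuple[int, int], radius_frac: float) -> np.ndarray:
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    r = radius_frac * min(h, w)
    return (rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2 <= r**2


def make_fixture(spec: FixtureSpec):
    """Build the image (uint8 array) described by ``spec``.

    ``polarity_pair`` returns a tuple ``(B, complement_of_B)`` of two
    uint8 0/255 images; every other kind returns one uint8 image.
    """
    h, w = spec.shape
    p = spec.params
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "ramp":
        return quantize8(np.linspace(0.0, 255.0, h * w).reshape(h, w))

    if spec.kind == "noise":
        return rng.integers(0, 256, size=(h, w), dtype=np.int64).astype(np.uint8)

    if spec.kind == "bimodal":
        mu0, mu1 = p.get("mu0", 40.0), p.get("mu1", 200.0)
        sd = p.get("sd", 10.0)
        mask = _disk_mask(spec.shape, p.get("radius_frac", 0.3))
        img = rng.normal(mu0, sd, size=(h, w))
        img[mask] = rng.normal(mu1, sd, size=int(mask.sum()))
        return quantize8(img)

    if spec.kind == "disk":
        bg, fg = p.get("bg", 40), p.get("fg", 200)
        mask = _disk_mask(spec.shape, p.get("radius_frac", 0.3))
        img = np.full((h, w), float(bg))
        img[mask] = float(fg)
        return quantize8(img)

    if spec.kind == "nested_rects":
        values = p.get("values", (60, 120, 180))
        img = np.full((h, w), float(values[0]))
        for level, v in enumerate(values[1:], start=1):
            mh, mw = level * h // (2 * len(values)), level * w // (2 * len(values))
            img[mh : h - mh, mw : w - mw] = float(v)
        return quantize8(img)

    if spec.kind == "polarity_pair":
        mask = _disk_mask(spec.shape, p.get("radius_frac", 0.3))
        b = np.where(mask, 255, 0).astype(np.uint8)
        return b, (255 - b).astype(np.uint8)

    raise ValueError(f"unknown fixture kind {spec.kind!r}")  # pragma: no cover


def fixture_suite(
    n: int, shape: tuple[int, int] = (64, 64), seed: int = 0
) -> dict[str, np.ndarray]:
    """A deterministic batch of n varied scenes keyed by fixture id.

    Cycles through bimodal, disk and nested-rectangle scenes with
    spread-out luminance parameters; used as the stand-in template set
    for batch runs and evaluation statistics.
    """
    rng = np.random.default_rng(seed)
    images: dict[str, np.ndarray] = {}
    for i in range(n):
        sub = int(rng.integers(0, 2**31 - 1))
        kind = ("bimodal", "disk", "nested_rects")[i % 3]
        if kind == "bimodal":
            params = {
                "mu0": 30.0 + 40.0 * rng.random(),
                "mu1": 150.0 + 70.0 * rng.random(),
                "sd": 5.0 + 10.0 * rng.random(),
                "radius_frac": 0.2 + 0.15 * rng.random(),
            }
        elif kind == "disk":
            params = {
                "bg": int(rng.integers(20, 90)),
                "fg": int(rng.integers(150, 230)),
                "radius_frac": 0.2 + 0.15 * rng.random(),
            }
        else:
            lo = int(rng.integers(30, 80))
            params = {"values": (lo, lo + 60, lo + 120)}
        images[f"fix{i:03d}_{kind}"] = make_fixture(
            FixtureSpec(kind, shape=shape, seed=sub, params=params)
        )
    return images
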