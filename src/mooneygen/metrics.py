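"""Image-side evaluation statistics for sets of Mooney images.

How different are the two-tone images produced by different threshold
selectors from the same template? The dissimilarity ratio (normalized
Hamming distance between binary images), the spread of the four selected
thresholds per image, per-technique threshold distributions, and the
difficulty stratification rule used to sample templates by identification
performance.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .thresholding import TECHNIQUES, MooneyImage


def _binary_pixels(img) -> np.ndarray:
    if isinstance(img, MooneyImage):
        return img.pixels
    arr = np.asarray(img)
    if arr.dtype != bool:
        arr = arr > 0
    return arr


def dissimilarity_ratio(a, b) -> float:
    """Fraction of pixel positions at which two binary images disagree.

    0 means identical images; 1 means exact polarity reversal (every
    white pixel of one is black in the other). This is the normalized
    Hamming distance, hence a metric on binary images of a given shape.
    """
    pa, pb = _binary_pixels(a), _binary_pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    return float(np.count_nonzero(pa != pb) / pa.size)


def per_image_threshold_sd(thresholds: Sequence[float], *, ddof: int = 1) -> float:
    """Standard deviation of the thresholds selected for one image.

    Expects the four per-technique thresholds; sample SD (``ddof=1``) by
    default, population SD with ``ddof=0``.
    """
    arr = np.asarray(thresholds, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"need at least 2 threshold values, got {arr.size}")
    return float(arr.std(ddof=ddof))


def threshold_distribution_summary(
    table: pd.DataFrame, *, whisker: float = 1.5
) -> pd.DataFrame:
    """Per-technique summary of a threshold table (boxplot statistics).

    ``table`` needs columns ``technique`` and ``threshold`` (one row per
    image x technique x sigma). Quartiles use linear interpolation;
    whiskers are the most extreme data points within ``whisker`` x IQR of
    the quartiles. Empty technique groups are skipped with a warning.
    """
    if table.empty:
        raise ValueError("threshold table is empty")
    rows = []
    for technique, group in table.groupby("technique", sort=False):
        t = group["threshold"].to_numpy(dtype=np.float64)
        if t.size == 0:
            import warnings

            warnings.warn(f"no thresholds for technique {technique!r}; skipped")
            continue
        q1, med, q3 = np.percentile(t, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        in_lo = t[t >= q1 - whisker * iqr]
        in_hi = t[t <= q3 + whisker * iqr]
        rows.append(
            {
                "technique": technique,
                "n": t.size,
                "mean": t.mean(),
                "sd": t.std(ddof=1) if t.size > 1 else 0.0,
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_low": in_lo.min() if in_lo.size else q1,
                "whisker_high": in_hi.max() if in_hi.size else q3,
            }
        )
    return pd.DataFrame(rows).set_index("technique")


def pairwise_dissimilarity_matrix(
    mooneys: Mapping[str, Mapping[str, MooneyImage]],
    techniques: Sequence[str] = TECHNIQUES,
) -> pd.DataFrame:
    """Mean pairwise dissimilarity between technique variants over images.

    ``mooneys`` maps each image id to its per-technique Mooney variants;
    entry (i, j) of the result is the dissimilarity ratio between the
    technique-i and technique-j variants averaged over all images.
    Symmetric with zero diagonal.
    """
    if not mooneys:
        raise ValueError("no images given")
    for image_id, variants in mooneys.items():
        missing = [t for t in techniques if t not in variants]
        if missing:
            raise ValueError(f"image {image_id!r} is missing variants: {missing}")
    k = len(techniques)
    acc = np.zeros((k, k), dtype=np.float64)
    for variants in mooneys.values():
        for i in range(k):
            for j in range(i + 1, k):
                d = dissimilarity_ratio(variants[techniques[i]], variants[techniques[j]])
                acc[i, j] += d
                acc[j, i] += d
    acc /= len(mooneys)
    return pd.DataFrame(acc, index=list(techniques), columns=list(techniques))


def difficulty_stratify(proportion_correct: Iterable[float]) -> list[str]:
    """Label images easy / medium / difficult by identification rate.

    easy: p > 0.75; medium: 0.25 < p <= 0.75; difficult: p <= 0.25.
    The three bins partition [0, 1] exactly.
    """
    labels = []
    for p in proportion_correct:
        p = float(p)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"proportion correct {p} outside [0, 1]")
        if p > 0.75:
            labels.append("easy")
        elif p > 0.25:
            labels.append("medium")
        else:
            labels.append("difficult")
    return labels
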