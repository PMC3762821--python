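"""Restoration-quality metrics: SD, information entropy, and IQMFV.

Three no-reference indices score a grayscale frame on the 8-bit scale:

* ``std_dev`` — population standard deviation of pixel values (1/MN
  normalization).  Higher means a more dispersed gray-level distribution,
  i.e. more contrast and detail.
* ``entropy`` — Shannon entropy in bits of the 256-level gray histogram
  (values rounded to the nearest integer level before binning).
* ``iqmfv`` — the image-quality measurement function value, the squared
  population standard deviation (variance).  Reported in intensity^2
  units; higher is better.

``quality_report`` tabulates all three per frame plus aggregate means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sequence_io import ImageSequence

__all__ = ["std_dev", "entropy", "iqmfv", "quality_report"]


def std_dev(image: np.ndarray) -> float:
    """Population standard deviation of pixel values (divide by M*N)."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("image is empty")
    return float(np.std(image))


def entropy(image: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy in bits over the gray-level histogram.

    Pixel values are rounded to the nearest integer level and clipped to
    [0, bins-1]; empty histogram cells contribute 0 (0*log 0 == 0).
    Bounded by log2(bins) — 8 bits for the default 256 levels.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("image is empty")
    levels = np.clip(np.round(image), 0, bins - 1).astype(np.int64)
    counts = np.bincount(levels.reshape(-1), minlength=bins)
    p = counts[counts > 0] / image.size
    return float(-np.sum(p * np.log2(p)))


def iqmfv(image: np.ndarray) -> float:
    """Image-quality measurement function value: the population variance.

    Equals ``std_dev(image)**2``; this identity reproduces every printed
    (SD, IQMFV) pair of the reference comparisons to their last decimal.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("image is empty")
    return float(np.var(image))


def quality_report(seq: ImageSequence, bins: int = 256) -> pd.DataFrame:
    """Per-frame SD / IE / IQMFV table with an aggregate mean row.

    Columns: frame, SD, IE, IQMFV.  The final row (frame == "mean")
    averages each metric over frames; the table is CSV-serializable.
    """
    rows = [
        {
            "frame": seq.source_ids[i],
            "SD": std_dev(f),
            "IE": entropy(f, bins=bins),
            "IQMFV": iqmfv(f),
        }
        for i, f in enumerate(seq.frames)
    ]
    df = pd.DataFrame(rows)
    mean_row = {
        "frame": "mean",
        "SD": df["SD"].mean(),
        "IE": df["IE"].mean(),
        "IQMFV": df["IQMFV"].mean(),
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
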