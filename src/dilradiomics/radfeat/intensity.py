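"""Intensity-based histogram features (IBHF) on the pooled ROI voxels."""

from __future__ import annotations

import numpy as np

__all__ = ["extract_ibhf"]


def extract_ibhf(roi_values: np.ndarray) -> np.ndarray:
    """Nine first-order statistics of the in-mask intensity distribution.

    Order: mean, standard deviation, skewness, kurtosis, histogram entropy
    (256 bins, bits), and central moments of order 3, 4, 5 and 6.
    Skewness and kurtosis of zero-variance data are 0 by convention.
    """
    x = np.asarray(roi_values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("IBHF requires at least 2 voxels")
    mu = x.mean()
    d = x - mu
    m2 = np.mean(d ** 2)
    std = np.sqrt(m2)
    cm = [np.mean(d ** k) for k in (3, 4, 5, 6)]
    if std > 0:
        skew = cm[0] / std ** 3
        kurt = cm[1] / std ** 4
    else:
        skew = kurt = 0.0

    lo, hi = x.min(), x.max()
    if hi > lo:
        counts, _ = np.histogram(x, bins=256, range=(lo, hi))
        p = counts[counts > 0] / x.size
        entropy = float(-np.sum(p * np.log2(p)))
    else:
        entropy = 0.0
    return np.array([mu, std, skew, kurt, entropy, *cm], dtype=float)
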