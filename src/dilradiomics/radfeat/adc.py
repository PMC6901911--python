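"""ADC map construction from DWI and NT-mean intensity harmonization.

The apparent diffusion coefficient is obtained per voxel from the
mono-exponential decay S(b) = S0 * exp(-b * ADC) by ordinary least squares
of -ln S(b) against b. With exactly two b-values this reduces to
ADC = ln(S1/S2) / (b2 - b1).
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_adc", "harmonize"]


def fit_adc(dwi_volumes, b_values) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel log-linear least-squares ADC fit.

    Parameters
    ----------
    dwi_volumes
        Sequence of same-shape DWI arrays, one per b-value.
    b_values
        Diffusion weightings in s/mm^2, at least two distinct values.

    Returns
    -------
    adc : ndarray
        ADC in mm^2/s (the negative slope of ln S vs b).
    qc_flags : ndarray of bool
        True where any input signal was non-positive; those voxels get
        ADC 0 instead of a log of a non-positive number.
    """
    b = np.asarray(b_values, dtype=float)
    if b.size < 2 or np.unique(b).size != b.size:
        raise ValueError("need at least 2 distinct b-values")
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    vols = np.stack([np.asarray(v, dtype=float) for v in dwi_volumes])
    if vols.shape[0] != b.size:
        raise ValueError("one DWI volume per b-value required")

    bad = np.any(vols <= 0, axis=0)
    safe = np.where(vols <= 0, 1.0, vols)
    logs = np.log(safe)
    # slope of ln S vs b; ADC = -slope
    b_c = b - b.mean()
    denom = float((b_c ** 2).sum())
    slope = np.tensordot(b_c, logs - logs.mean(axis=0), axes=(0, 0)) / denom
    adc = -slope
    adc[bad] = 0.0
    return adc, bad


def harmonize(volume: np.ndarray, nt_mask: np.ndarray) -> np.ndarray:
    """Divide intensities by the mean over the normal-tissue mask.

    This cancels any global scanner gain: the same multiplicative factor
    applied to the whole volume leaves the harmonized output unchanged.
    """
    vol = np.asarray(volume, dtype=float)
    m = np.asarray(nt_mask, dtype=bool)
    if vol.shape != m.shape:
        raise ValueError("volume and NT mask shapes differ")
    if not m.any():
        raise ValueError("empty NT mask")
    ref = vol[m].mean()
    if ref == 0:
        raise ValueError("NT mean intensity is zero; cannot harmonize")
    return vol / ref
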