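"""Transform-domain texture features: Stockwell (DOST), wavelet, Gabor.

The discrete orthonormal Stockwell transform is built as an FFT-based
dyadic band partition: the unitary DFT spectrum is split into octave bands
({0}, {1}, {2,3}, {4..7}, ...) and each band is inverse-transformed with a
unitary DFT of its own length. The composition is unitary, so total
coefficient energy equals image energy (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

__all__ = ["WaveletSpec", "GaborBankSpec", "dost2", "extract_dost",
           "extract_2dwt", "extract_2dgf"]


# ---------------------------------------------------------------------------
# Discrete orthonormal Stockwell transform
# ---------------------------------------------------------------------------

def _dyadic_bands(n: int) -> list[np.ndarray]:
    """Octave partition of DFT bin indices 0..n-1 for n a power of two."""
    bands = [np.array([0])]
    start = 1
    while start < n:
        width = start
        bands.append(np.arange(start, start + width))
        start += width
    return bands


def _dost1(x: np.ndarray, axis: int) -> np.ndarray:
    n = x.shape[axis]
    X = np.fft.fft(x, axis=axis) / np.sqrt(n)          # unitary DFT
    out = np.empty_like(X)
    idx = [slice(None)] * x.ndim
    for band in _dyadic_bands(n):
        idx[axis] = band
        seg = X[tuple(idx)]
        # unitary inverse DFT of the band
        out[tuple(idx)] = np.fft.ifft(seg, axis=axis) * np.sqrt(band.size)
    return out


def _next_pow2(n: int) -> int:
    return 1 << max(2, int(np.ceil(np.log2(max(n, 1)))))


def dost2(image: np.ndarray) -> np.ndarray:
    """2-D discrete orthonormal Stockwell coefficients of a dyadic image.

    The input is edge-padded to the next power-of-two square before
    transforming.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("dost2 needs a 2-D image of at least 2x2")
    n = _next_pow2(max(img.shape))
    if img.shape != (n, n):
        img = np.pad(img, ((0, n - img.shape[0]), (0, n - img.shape[1])),
                     mode="edge")
    return _dost1(_dost1(img, axis=0), axis=1)


def extract_dost(image: np.ndarray) -> np.ndarray:
    """Energy and entropy of the 9 equal blocks of the |DOST| matrix.

    The coefficient magnitude matrix is split into a 3x3 grid; the 9 block
    energies followed by the 9 block entropies give 18 features.
    """
    from .core import map_energy, map_entropy

    mag = np.abs(dost2(image))
    energies, entropies = [], []
    for rows in np.array_split(mag, 3, axis=0):
        for block in np.array_split(rows, 3, axis=1):
            energies.append(map_energy(block))
            entropies.append(map_entropy(block))
    return np.array(energies + entropies)


# ---------------------------------------------------------------------------
# 2-D wavelet decomposition
# ---------------------------------------------------------------------------

@dataclass
class WaveletSpec:
    """Six-level 2-D wavelet decomposition settings.

    ``periodization`` mode keeps the transform orthonormal for the default
    Daubechies-4 family, so sub-band energies sum to the image energy.
    """

    wavelet: str = "db4"
    n_levels: int = 6
    mode: str = "periodization"
    min_size: int = 16


def extract_2dwt(image: np.ndarray, spec: WaveletSpec | None = None) -> np.ndarray:
    """48 features: energy and entropy of 24 maps (6 levels x A/H/V/D).

    At each level the approximation is decomposed further; the level's
    approximation, horizontal, vertical and diagonal maps all contribute.
    """
    from .core import map_energy, map_entropy

    spec = spec or WaveletSpec()
    img = np.asarray(image, dtype=float)
    pad_y = max(0, spec.min_size - img.shape[0])
    pad_x = max(0, spec.min_size - img.shape[1])
    # symmetric padding to the working size; keep dimensions even
    pad_y += (img.shape[0] + pad_y) % 2
    pad_x += (img.shape[1] + pad_x) % 2
    if pad_y or pad_x:
        img = np.pad(img, ((pad_y // 2, pad_y - pad_y // 2),
                           (pad_x // 2, pad_x - pad_x // 2)), mode="symmetric")
    feats = []
    approx = img
    for _ in range(spec.n_levels):
        approx, (ch, cv, cd) = pywt.dwt2(approx, spec.wavelet, mode=spec.mode)
        for m in (approx, ch, cv, cd):
            feats += [map_energy(m), map_entropy(m)]
    return np.array(feats)


# ---------------------------------------------------------------------------
# 2-D Gabor filter bank
# ---------------------------------------------------------------------------

@dataclass
class GaborBankSpec:
    """Five-scale, four-orientation Gabor bank (20 filters).

    Wavelengths are in voxels; orientations in radians. Kernels are
    DC-subtracted so a constant image yields (near-)zero response.
    """

    wavelengths: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0, 32.0)
    orientations: tuple[float, ...] = field(
        default=(0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4))
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if len(self.wavelengths) * len(self.orientations) != 20:
            raise ValueError("Gabor bank must have 5 scales x 4 orientations")


@lru_cache(maxsize=8)
def _gabor_bank(wavelengths: tuple, orientations: tuple,
                bandwidth: float) -> tuple[np.ndarray, ...]:
    kernels = []
    for lam in wavelengths:
        for theta in orientations:
            k = gabor_kernel(frequency=1.0 / lam, theta=theta,
                             bandwidth=bandwidth)
            k = k - k.mean()  # zero-DC
            kernels.append(np.asarray(k))
    return tuple(kernels)


def gabor_bank(spec: GaborBankSpec | None = None) -> tuple[np.ndarray, ...]:
    spec = spec or GaborBankSpec()
    return _gabor_bank(tuple(spec.wavelengths), tuple(spec.orientations),
                       float(spec.bandwidth))


def gabor_response(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Magnitude response with edge-replicated padding.

    Padding by the kernel half-width before a 'valid' convolution keeps
    the zero-DC property exact on constant images (no cropped kernels at
    the borders).
    """
    img = np.asarray(image, dtype=float)
    ky, kx = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(img, ((ky, ky), (kx, kx)), mode="edge")
    resp = fftconvolve(padded, kernel, mode="valid")
    # 'valid' output of odd kernels has the original shape; crop if even
    return np.abs(resp[:img.shape[0], :img.shape[1]])


def extract_2dgf(image: np.ndarray, mask: np.ndarray | None = None,
                 spec: GaborBankSpec | None = None) -> np.ndarray:
    """40 features: energy and entropy of the 20 magnitude response maps."""
    from .core import map_energy, map_entropy

    img = np.asarray(image, dtype=float)
    mask = np.ones(img.shape, bool) if mask is None else np.asarray(mask, bool)
    feats = []
    for k in gabor_bank(spec):
        resp = gabor_response(img, k)[mask]
        feats += [map_energy(resp), map_entropy(resp)]
    return np.array(feats)
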