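"""Core containers and the 168-feature radiomics extractor.

The descriptor is organised in eight categories computed per ROI per
modality: intensity histogram statistics (IBHF, 9), gray-level run length
(GLRL, 7), Laws texture energy (LAWS, 18), discrete orthonormal Stockwell
transform (DOST, 18), local binary patterns (LBP, 6), 2-D wavelet
decomposition (2DWT, 48), 2-D Gabor filter bank (2DGF, 40) and gray-level
co-occurrence matrices (GLCM, 22) — 168 values in a fixed canonical order.

Conventions shared by every category:

* texture categories operate per axial slice on the ROI bounding box, with
  out-of-mask voxels replaced by the slice's in-mask mean, and per-slice
  results averaged over usable slices; IBHF pools the 3-D masked voxels;
* ``energy`` of a map is the mean of its squared values;
* ``entropy`` is the Shannon entropy (log base 2) of a 256-bin normalized
  histogram of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intensity import extract_ibhf
from .texture import extract_glcm, extract_glrl, extract_laws, extract_lbp
from .transforms import (
    GaborBankSpec,
    WaveletSpec,
    extract_2dgf,
    extract_2dwt,
    extract_dost,
)

__all__ = [
    "VoxelVolume",
    "QuantizationSpec",
    "FeatureVector",
    "FEATURE_NAMES",
    "CATEGORY_SIZES",
    "quantize",
    "roi_slices",
    "extract_all",
]

#: number of features per category, in canonical order
CATEGORY_SIZES = {
    "IBHF": 9,
    "GLRL": 7,
    "LAWS": 18,
    "DOST": 18,
    "LBP": 6,
    "2DWT": 48,
    "2DGF": 40,
    "GLCM": 22,
}

#: minimum number of in-mask pixels for a slice to enter texture estimation
MIN_SLICE_PIXELS = 16


@dataclass
class VoxelVolume:
    """A 3-D scalar image with axis order (z, y, x) and mm spacing."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("VoxelVolume expects a 3-D array (z, y, x)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelVolume values must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")


@dataclass
class QuantizationSpec:
    """Linear min–max gray-level quantization onto 2**bit_depth levels."""

    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not 3 <= self.bit_depth <= 8:
            raise ValueError("bit_depth must be in 3..8")

    @property
    def n_levels(self) -> int:
        return 2 ** self.bit_depth


@dataclass
class FeatureVector:
    """Ordered 168-value radiomics descriptor for one ROI of one modality."""

    modality: str
    roi_kind: str
    subject_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (168,):
            raise ValueError("FeatureVector must hold exactly 168 values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureVector values must be finite")


def _make_feature_names() -> list[str]:
    names: list[str] = []
    names += [
        "IBHF_Mean", "IBHF_Std", "IBHF_Skewness", "IBHF_Kurtosis",
        "IBHF_Entropy", "IBHF_CentralMoment3", "IBHF_CentralMoment4",
        "IBHF_CentralMoment5", "IBHF_CentralMoment6",
    ]
    names += [f"GLRL_{n}" for n in ("SRE", "LRE", "GLN", "RP", "RLN", "LGRE", "HGRE")]
    for pair in ("L5E5", "L5R5", "E5S5", "S5S5", "R5R5", "L5S5", "E5E5", "E5R5", "S5R5"):
        names += [f"LAWS_{pair}_Energy", f"LAWS_{pair}_Entropy"]
    for stat in ("Energy", "Entropy"):
        names += [f"DOST_Block{r}{c}_{stat}" for r in range(3) for c in range(3)]
    names += [f"LBP_{n}" for n in ("Energy", "Entropy", "Mean", "Std", "Skewness", "Kurtosis")]
    for level in range(1, 7):
        for attr in ("A", "H", "V", "D"):
            names += [f"2DWT_L{level}{attr}_Energy", f"2DWT_L{level}{attr}_Entropy"]
    for s in range(5):
        for o in range(4):
            names += [f"2DGF_S{s}O{o}_Energy", f"2DGF_S{s}O{o}_Entropy"]
    names += [
        "GLCM_Autocorrelation", "GLCM_Contrast", "GLCM_Correlation2",
        "GLCM_Correlation1", "GLCM_ClusterProminence", "GLCM_ClusterShade",
        "GLCM_Dissimilarity", "GLCM_Energy", "GLCM_Entropy",
        "GLCM_Homogeneity1", "GLCM_Homogeneity2", "GLCM_MaxProbability",
        "GLCM_SumOfSquaresVariance", "GLCM_SumAverage", "GLCM_SumVariance",
        "GLCM_SumEntropy", "GLCM_DifferenceVariance", "GLCM_DifferenceEntropy",
        "GLCM_IMC1", "GLCM_IMC2", "GLCM_InverseDifferenceNormalized",
        "GLCM_InverseDifferenceMomentNormalized",
    ]
    assert len(names) == 168
    return names


#: canonical, stable ordering of the 168 feature names
FEATURE_NAMES: list[str] = _make_feature_names()


def map_energy(x: np.ndarray) -> float:
    """Energy of a response map: mean of squared values."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("energy of an empty map is undefined")
    return float(np.mean(x * x))


def map_entropy(x: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of a normalized histogram of the map."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("entropy of an empty map is undefined")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def quantize(roi_values: np.ndarray, spec: QuantizationSpec | None = None) -> np.ndarray:
    """Map values linearly onto integer levels ``0 .. n_levels-1``.

    A constant input maps to all zeros (degenerate-ROI convention).
    """
    spec = spec or QuantizationSpec()
    x = np.asarray(roi_values, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.zeros(x.shape, dtype=np.intp)
    q = np.floor((x - lo) / (hi - lo) * spec.n_levels).astype(np.intp)
    return np.minimum(q, spec.n_levels - 1)


def roi_slices(volume: np.ndarray, mask: np.ndarray,
               min_pixels: int = MIN_SLICE_PIXELS) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-slice (filled bounding box, 2-D mask) pairs for texture estimation.

    Only axial slices with at least ``min_pixels`` in-mask pixels are used;
    out-of-mask voxels inside the bounding box are replaced by the slice's
    in-mask mean so that filter responses near the mask edge are not
    dominated by background.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    out = []
    for z in range(volume.shape[0]):
        m = mask[z]
        n = int(m.sum())
        if n < min_pixels:
            continue
        ys, xs = np.nonzero(m)
        sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        patch = volume[z][sl].copy()
        m2 = m[sl]
        patch[~m2] = patch[m2].mean()
        out.append((patch, m2))
    if not out:
        raise ValueError(
            f"no usable slice: mask needs >= {min_pixels} in-plane pixels on at least one slice"
        )
    return out


def extract_all(volume, mask, modality: str = "T2W", roi_kind: str = "DIL",
                subject_id: str = "s0",
                glcm_spec: QuantizationSpec | None = None,
                glrl_spec: QuantizationSpec | None = None,
                wavelet_spec: WaveletSpec | None = None,
                gabor_spec: GaborBankSpec | None = None) -> FeatureVector:
    """Compute the full 168-feature descriptor for one ROI.

    Parameters
    ----------
    volume
        3-D scalar image (``VoxelVolume`` or array), harmonized upstream.
    mask
        Binary ROI mask of the same shape.
    """
    values = np.asarray(volume.values if isinstance(volume, VoxelVolume) else volume,
                        dtype=float)
    mask = np.asarray(mask, dtype=bool)
    glcm_spec = glcm_spec or QuantizationSpec(8)
    glrl_spec = glrl_spec or QuantizationSpec(4)   # 16 levels for run-length stats
    wavelet_spec = wavelet_spec or WaveletSpec()
    gabor_spec = gabor_spec or GaborBankSpec()

    pooled = values[mask]
    if pooled.size == 0:
        raise ValueError("empty ROI mask")
    slices = roi_slices(values, mask)

    def averaged(fn, *args, **kwargs):
        rows = [np.asarray(fn(patch, m2, *args, **kwargs), dtype=float)
                for patch, m2 in slices]
        return np.mean(rows, axis=0)

    parts = {
        "IBHF": extract_ibhf(pooled),
        "GLRL": averaged(lambda p, m: extract_glrl(quantize(p, glrl_spec), m,
                                                   n_levels=glrl_spec.n_levels)),
        "LAWS": averaged(extract_laws),
        "DOST": averaged(lambda p, m: extract_dost(p)),
        "LBP": averaged(extract_lbp),
        "2DWT": averaged(lambda p, m: extract_2dwt(p, wavelet_spec)),
        "2DGF": averaged(lambda p, m: extract_2dgf(p, m, gabor_spec)),
        "GLCM": averaged(lambda p, m: extract_glcm(quantize(p, glcm_spec),
                                                   n_levels=glcm_spec.n_levels)),
    }
    for cat, vals in parts.items():
        if len(vals) != CATEGORY_SIZES[cat]:
            raise RuntimeError(f"{cat} produced {len(vals)} features, "
                               f"expected {CATEGORY_SIZES[cat]}")
        if not np.all(np.isfinite(vals)):
            raise RuntimeError(f"{cat} produced non-finite features")
    vec = np.concatenate([parts[c] for c in CATEGORY_SIZES])
    return FeatureVector(modality=modality, roi_kind=roi_kind,
                         subject_id=subject_id, values=vec)
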