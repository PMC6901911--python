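"""Sliding-window lesion probability mapping and contour robustness.

A trained PLSC + MLP pair is applied to every 25x25 in-plane window of a
co-registered T2W/ADC pair: the window (full-square ROI) is harmonized by
the subject's NT-mask mean, the 168 features are extracted per modality,
projected onto the selected latent variables and scored by the network;
p = (score + 1)/2 maps the bipolar output to [0, 1]. Robustness to
contouring is probed by re-running the feature extraction and projection
with masks scaled 1.2x about their centroid and shifted one voxel along
every axis, comparing original and perturbed latent scores per latent
variable with one-way ANOVA against the F critical value at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from . import radfeat
from .ann import ANNModel, forward
from .plsc import LatentFeatureSet, PLSCModel, project_selected

__all__ = ["ProbabilityMap", "ContourPerturbSpec", "VariabilityTestResult",
           "probability_map", "threshold_map", "dice", "perturb_contour",
           "contour_variability_test"]


@dataclass
class ProbabilityMap:
    """Per-slice grid of DIL probabilities at window centers."""

    probabilities: np.ndarray       # (n_slices, ny_out, nx_out)
    window: int
    stride: int
    slice_indices: np.ndarray       # which z-slices were mapped
    center_offset: int              # first window center along y/x


@dataclass
class ContourPerturbSpec:
    """Isotropic scaling about the centroid followed by a voxel shift."""

    scale: float = 1.2
    shift: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class VariabilityTestResult:
    F: np.ndarray                   # per latent variable
    F_critical: float
    passed: np.ndarray              # F < Fc per latent
    alpha: float = 0.05

    @property
    def all_passed(self) -> bool:
        return bool(self.passed.all())


def _window_features(patch_t2w: np.ndarray, patch_adc: np.ndarray):
    # the whole square window is the ROI
    full = np.ones((1,) + patch_t2w.shape, dtype=bool)
    fx = radfeat.extract_all(patch_t2w[None], full, modality="T2W").values
    fy = radfeat.extract_all(patch_adc[None], full, modality="ADC").values
    return fx, fy


def probability_map(t2w: np.ndarray, adc: np.ndarray, nt_mask: np.ndarray,
                    plsc_model: PLSCModel, selection: LatentFeatureSet,
                    ann_model: ANNModel, window: int = 25, stride: int = 1,
                    slice_indices=None,
                    latent_scaler=None) -> ProbabilityMap:
    """DIL probability at each window position of each requested slice.

    Both volumes are harmonized against the subject's NT mask before
    windows are extracted; ``latent_scaler``, when given, is a callable
    applied to the 8-dim latent rows (e.g. the training z-scoring).
    """
    t2w = np.asarray(t2w, dtype=float)
    adc = np.asarray(adc, dtype=float)
    nz, ny, nx = t2w.shape
    if window > ny or window > nx:
        raise ValueError("window larger than slice")
    t2w_h = radfeat.harmonize(t2w, nt_mask)
    adc_h = radfeat.harmonize(adc, nt_mask)
    if slice_indices is None:
        slice_indices = np.arange(nz)
    slice_indices = np.asarray(slice_indices, dtype=int)

    ys = np.arange(0, ny - window + 1, stride)
    xs = np.arange(0, nx - window + 1, stride)
    prob = np.empty((slice_indices.size, ys.size, xs.size))
    for zi, z in enumerate(slice_indices):
        rows_x, rows_y = [], []
        for y0 in ys:
            for x0 in xs:
                pt = t2w_h[z, y0:y0 + window, x0:x0 + window]
                pa = adc_h[z, y0:y0 + window, x0:x0 + window]
                fx, fy = _window_features(pt, pa)
                rows_x.append(fx)
                rows_y.append(fy)
        latent = project_selected(plsc_model, selection,
                                  np.asarray(rows_x), np.asarray(rows_y))
        if latent_scaler is not None:
            latent = latent_scaler(latent)
        scores = forward(ann_model, latent)
        prob[zi] = ((scores + 1.0) / 2.0).reshape(ys.size, xs.size)
    return ProbabilityMap(probabilities=np.clip(prob, 0.0, 1.0),
                          window=window, stride=stride,
                          slice_indices=slice_indices,
                          center_offset=window // 2)


def threshold_map(pmap: ProbabilityMap, volume_shape: tuple[int, int, int],
                  p_thr: float = 0.001) -> np.ndarray:
    """Binary patch mask on the voxel grid: probability > p_thr.

    Each window probability is assigned to the stride x stride block of
    voxels nearest its center (nearest-window upsampling).
    """
    nz, ny, nx = volume_shape
    out = np.zeros(volume_shape, dtype=bool)
    w, s, off = pmap.window, pmap.stride, pmap.center_offset
    for zi, z in enumerate(pmap.slice_indices):
        hot = pmap.probabilities[zi] > p_thr
        for (iy, ix) in zip(*np.nonzero(hot)):
            cy, cx = off + iy * s, off + ix * s
            y0, y1 = max(0, cy - s // 2), min(ny, cy - s // 2 + s)
            x0, x1 = max(0, cx - s // 2), min(nx, cx - s // 2 + s)
            out[z, y0:y1, x0:x1] = True
    return out


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks give 1.0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def perturb_contour(mask: np.ndarray, spec: ContourPerturbSpec | None = None) -> np.ndarray:
    """Scale the mask about its centroid, then shift it by whole voxels.

    Scaling uses nearest-neighbor resampling of the binary mask; the
    result is clipped to the volume and must remain non-empty.
    """
    spec = spec or ContourPerturbSpec()
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    centroid = np.array(ndimage.center_of_mass(m))
    # affine_transform maps output coords through the matrix: pull-back by 1/scale
    inv = 1.0 / spec.scale
    offset = centroid * (1.0 - inv)
    scaled = ndimage.affine_transform(m.astype(float), np.diag([inv] * 3),
                                      offset=offset, order=0) > 0.5
    shifted = ndimage.shift(scaled.astype(float), spec.shift, order=0) > 0.5
    if not shifted.any():
        raise ValueError("perturbed mask is empty after clipping")
    return shifted


def contour_variability_test(subjects, plsc_model: PLSCModel,
                             selection: LatentFeatureSet,
                             spec: ContourPerturbSpec | None = None,
                             alpha: float = 0.05,
                             harmonize_adc: bool = True,
                             extract_kwargs: dict | None = None) -> VariabilityTestResult:
    """ANOVA of original vs perturbed-contour latent scores per latent.

    For each of n subjects the DIL-row latent scores are computed from the
    original and the perturbed DIL contour (NT reference unchanged);
    each latent variable is tested original-vs-perturbed with one-way
    ANOVA (two groups of n, df (1, 2n-2)). The test passes when every F
    statistic stays below the critical value at ``alpha``.
    """
    spec = spec or ContourPerturbSpec()
    subjects = list(subjects)
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    extract_kwargs = extract_kwargs or {}

    def dil_latents(use_perturbed: bool) -> np.ndarray:
        rows_x, rows_y = [], []
        for s in subjects:
            dil = perturb_contour(s.dil_mask, spec) if use_perturbed else s.dil_mask
            t2w = radfeat.harmonize(s.t2w_volume, s.nt_mask)
            adc = radfeat.harmonize(s.adc_volume, s.nt_mask) if harmonize_adc \
                else s.adc_volume
            try:
                rows_x.append(radfeat.extract_all(t2w, dil, modality="T2W",
                                                  subject_id=s.subject_id,
                                                  **extract_kwargs).values)
                rows_y.append(radfeat.extract_all(adc, dil, modality="ADC",
                                                  subject_id=s.subject_id,
                                                  **extract_kwargs).values)
            except ValueError as e:
                raise ValueError(f"extraction failed for {s.subject_id}: {e}") from e
        return project_selected(plsc_model, selection,
                                np.asarray(rows_x), np.asarray(rows_y))

    orig = dil_latents(False)
    pert = dil_latents(True)
    n_latent = orig.shape[1]
    F = np.empty(n_latent)
    for k in range(n_latent):
        f, _ = stats.f_oneway(orig[:, k], pert[:, k])
        F[k] = 0.0 if not np.isfinite(f) else f
    fc = float(stats.f.ppf(1.0 - alpha, 1, 2 * n - 2))
    return VariabilityTestResult(F=F, F_critical=fc, passed=F < fc, alpha=alpha)
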