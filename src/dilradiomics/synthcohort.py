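"""Synthetic paired-modality prostate MR cohorts.

Each subject carries two co-registered scalar volumes (a pseudo
T2-weighted image and a pseudo ADC map in mm^2/s), a lesion (DIL) mask and
its mirrored contralateral normal-tissue (NT) mask. Tissue appearance is a
Gaussian random field: white noise smoothed with a Gaussian kernel whose
width sets the texture correlation length, scaled to a marginal standard
deviation and shifted by a tissue mean. The lesion is hypo-intense in both
modalities and texturally distinct; both contrasts scale linearly with
``effect_size`` (0 = null cohort: DIL voxels come from the identical
generative process as NT). A latent field shared between the modalities
(weight ``cross_modality_coupling``) gives the two blocks common variance
for the latent-variable analysis to find.

Cohorts are sized 117 subjects by default, split into a development group
"A" (98) and a held-out group "B" (19).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["TissueTexture", "CohortConfig", "SyntheticSubject",
           "generate_subject", "generate_cohort", "simulate_dwi",
           "make_fixture_image", "write_cohort"]


@dataclass(frozen=True)
class TissueTexture:
    """Gaussian-random-field texture parameters for one tissue/modality."""

    mean: float
    std: float
    corr_length: float  # voxels, in-plane


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults emulate the cohort structure the analysis expects: 117
    subjects (98 in group A, 19 in group B), an ellipsoidal lesion of
    in-plane radius ``dil_radius`` voxels mirrored across the mid-sagittal
    plane for the NT reference, and a large lesion/normal contrast
    (``effect_size`` = 2) in both modalities.
    """

    n_subjects: int = 117
    volume_shape: tuple[int, int, int] = (12, 64, 64)   # (z, y, x) voxels
    voxel_spacing: tuple[float, float, float] = (3.0, 0.5, 0.5)  # mm
    dil_radius: int = 8
    effect_size: float = 2.0
    cross_modality_coupling: float = 0.5
    # per-modality NT texture; DIL texture is derived from these + effect_size
    t2w_texture: TissueTexture = field(
        default_factory=lambda: TissueTexture(mean=2.0, std=0.25, corr_length=1.5))
    adc_texture: TissueTexture = field(
        default_factory=lambda: TissueTexture(mean=1.4e-3, std=1.5e-4, corr_length=1.5))
    # relative contrasts per unit effect size
    mean_contrast: float = 1.0       # DIL mean deficit, in NT-std units
    corr_contrast: float = 0.35      # relative increase of DIL correlation length
    # per-subject lesion severity multiplier ~ U(1-s, 1+s): cohorts span a
    # range of tumor grades rather than replicating one lesion
    severity_spread: float = 0.4
    b_values: tuple[float, ...] = (50.0, 400.0, 800.0)  # s/mm^2
    s0_level: float = 1000.0
    dwi_noise_sigma: float = 0.0
    with_dwi: bool = False
    n_group_b: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.dil_radius < 1 or any(s < 1 for s in self.volume_shape):
            raise ValueError("radii and shapes must be positive")
        b = np.asarray(self.b_values, float)
        if np.any(b < 0) or np.unique(b).size != b.size:
            raise ValueError("b_values must be non-negative and distinct")
        nz, ny, nx = self.volume_shape
        r = self.dil_radius
        rz = max(1, r // 3)
        if 2 * r + 2 > ny or 4 * r + 4 > nx or 2 * rz + 2 > nz:
            raise ValueError("dil_radius too large for volume_shape")


@dataclass
class SyntheticSubject:
    """One simulated patient: co-registered volumes, masks and metadata."""

    subject_id: str
    t2w_volume: np.ndarray
    adc_volume: np.ndarray
    dil_mask: np.ndarray
    nt_mask: np.ndarray
    group_tag: str = "A"
    dwi_volumes: list[np.ndarray] | None = None
    b_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        shape = self.t2w_volume.shape
        for name in ("adc_volume", "dil_mask", "nt_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape differs from t2w_volume")
        if not (self.dil_mask.any() and self.nt_mask.any()):
            raise ValueError("masks must be non-empty")
        if np.any(self.dil_mask & self.nt_mask):
            raise ValueError("DIL and NT masks must be disjoint")
        for vol in (self.t2w_volume, self.adc_volume):
            if not np.all(np.isfinite(vol)):
                raise ValueError("voxel values must be finite")


@lru_cache(maxsize=32)
def _kernel_gain(sigma: tuple[float, float, float]) -> float:
    """L2 norm of the smoothing kernel (shrinkage of white-noise std)."""
    impulse = np.zeros((33, 33, 33))
    impulse[16, 16, 16] = 1.0
    return float(np.sqrt(
        (gaussian_filter(impulse, sigma=sigma, mode="constant") ** 2).sum()))


def _smooth_noise(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    """Unit-variance Gaussian random field with in-plane correlation length."""
    sigma = (max(corr_length / 2.0, 0.3), corr_length, corr_length)
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=sigma, mode="wrap")
    return smooth / _kernel_gain(sigma)


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _lesion_masks(config: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DIL mask, mirrored NT mask and the smooth lesion blend weight.

    The contoured mask is the lesion *core*; the signal abnormality itself
    extends ~30% beyond it with a blurred rim (point-spread/partial-volume
    behaviour of real lesions, whose visible margin exceeds a conservative
    contour). Returns weights in [0, 1] used to blend lesion texture into
    the background.
    """
    nz, ny, nx = config.volume_shape
    r = config.dil_radius
    rz = max(1, r // 3)   # slice thickness >> in-plane spacing
    center = (nz // 2, ny // 2, max(r + 1, nx // 4 - 2))  # off-midline in x
    dil = _ellipsoid_mask(config.volume_shape, center, (rz, r, r))
    nt = dil[:, :, ::-1]                    # mirror across the x midline
    if np.any(dil & nt):
        raise ValueError("DIL and mirrored NT masks overlap; reduce dil_radius")
    halo = _ellipsoid_mask(config.volume_shape, center,
                           (rz + 3, 1.5 * r, 1.5 * r))
    weight = gaussian_filter(halo.astype(float), sigma=(0.7, 1.5, 1.5))
    weight = np.clip(weight, 0.0, 1.0)
    if np.any((weight > 1e-3) & nt):
        raise ValueError("lesion rim reaches the NT region; reduce dil_radius")
    return dil, nt, weight


def _modality_field(rng: np.random.Generator, config: CohortConfig,
                    texture: TissueTexture, shared_nt: np.ndarray,
                    shared_dil: np.ndarray, lesion_weight: np.ndarray,
                    effect: float) -> np.ndarray:
    """One modality volume: NT field blended with lesion field by weight."""
    c = config.cross_modality_coupling
    shape = config.volume_shape
    own_nt = _smooth_noise(rng, shape, texture.corr_length)
    nt_field = np.sqrt(c) * shared_nt + np.sqrt(1.0 - c) * own_nt
    vol = texture.mean + texture.std * nt_field
    if effect > 0:
        dil_corr = texture.corr_length * (1.0 + config.corr_contrast * effect)
        own_dil = _smooth_noise(rng, shape, dil_corr)
        dil_field = np.sqrt(c) * shared_dil + np.sqrt(1.0 - c) * own_dil
        dil_mean = texture.mean - config.mean_contrast * effect * texture.std
        lesion = dil_mean + texture.std * dil_field
        vol = vol + lesion_weight * (lesion - vol)
    return vol


def generate_subject(config: CohortConfig, subject_index: int,
                     rng: np.random.Generator, group_tag: str) -> SyntheticSubject:
    dil, nt, weight = _lesion_masks(config)
    shape = config.volume_shape
    # per-subject lesion severity (tumor-grade heterogeneity)
    s = config.severity_spread
    effect = config.effect_size * rng.uniform(1.0 - s, 1.0 + s) \
        if config.effect_size > 0 else 0.0
    # shared latent fields couple the two modalities
    shared_nt = _smooth_noise(rng, shape, config.t2w_texture.corr_length)
    if effect > 0:
        dil_corr = config.t2w_texture.corr_length * (
            1.0 + config.corr_contrast * effect)
        shared_dil = _smooth_noise(rng, shape, dil_corr)
    else:
        shared_dil = shared_nt
    t2w = _modality_field(rng, config, config.t2w_texture, shared_nt,
                          shared_dil, weight, effect)
    adc = _modality_field(rng, config, config.adc_texture, shared_nt,
                          shared_dil, weight, effect)
    adc = np.maximum(adc, 1e-6)  # ADC is physically non-negative

    dwi = None
    if config.with_dwi:
        s0 = np.full(shape, config.s0_level)
        dwi = simulate_dwi(adc, s0, config.b_values,
                           noise_sigma=config.dwi_noise_sigma, rng=rng)
    return SyntheticSubject(
        subject_id=f"sub{subject_index:03d}", t2w_volume=t2w, adc_volume=adc,
        dil_mask=dil, nt_mask=nt, group_tag=group_tag, dwi_volumes=dwi,
        b_values=config.b_values if dwi is not None else None)


def generate_cohort(config: CohortConfig) -> list[SyntheticSubject]:
    """Deterministically generate the full cohort from ``config.seed``.

    The last ``n_group_b`` subjects are tagged "B" (held-out cohort); the
    rest are group "A".
    """
    rng = np.random.default_rng(config.seed)
    n_b = min(config.n_group_b, max(0, config.n_subjects - 1))
    subjects = []
    for i in range(config.n_subjects):
        tag = "B" if i >= config.n_subjects - n_b and config.n_subjects > n_b else "A"
        subjects.append(generate_subject(config, i, rng, tag))
    return subjects


def simulate_dwi(true_adc_volume: np.ndarray, s0_volume: np.ndarray,
                 b_values, noise_sigma: float = 0.0,
                 rng: np.random.Generator | None = None,
                 rician: bool = False) -> list[np.ndarray]:
    """Mono-exponential DWI signals S(b) = S0 * exp(-b * ADC).

    Optional additive Gaussian noise of standard deviation ``noise_sigma``;
    with ``rician=True`` the noisy magnitude |S + n1 + i n2| is returned.
    """
    adc = np.asarray(true_adc_volume, dtype=float)
    s0 = np.asarray(s0_volume, dtype=float)
    if adc.shape != s0.shape:
        raise ValueError("ADC and S0 shapes differ")
    if np.any(adc < 0):
        raise ValueError("negative ADC voxels are unphysical")
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0) or np.unique(b).size != b.size:
        raise ValueError("b_values must be non-negative and distinct")
    out = []
    for bv in b:
        s = s0 * np.exp(-bv * adc)
        if noise_sigma > 0:
            if rng is None:
                rng = np.random.default_rng()
            if rician:
                s = np.abs(s + noise_sigma * rng.standard_normal(s.shape)
                           + 1j * noise_sigma * rng.standard_normal(s.shape))
            else:
                s = s + noise_sigma * rng.standard_normal(s.shape)
        out.append(s)
    return out


def make_fixture_image(kind: str, size: int) -> np.ndarray:
    """Analytically tractable 2-D images for feature-extractor unit tests."""
    if size < 1:
        raise ValueError("size must be positive")
    if kind == "constant":
        return np.ones((size, size))
    if kind == "checkerboard":
        yy, xx = np.indices((size, size))
        return ((yy + xx) % 2).astype(float)
    if kind == "ramp":
        return np.tile(np.arange(size, dtype=float), (size, 1))
    if kind == "single_run_rows":
        img = np.zeros((size, size))
        img[::2] = 1.0
        return img
    if kind == "impulse":
        img = np.zeros((size, size))
        img[size // 2, size // 2] = 1.0
        return img
    if kind == "two_level":
        img = np.zeros((size, size))
        img[:, size // 2:] = 1.0
        return img
    raise ValueError(f"unknown fixture kind: {kind!r}")


def null_config(config: CohortConfig | None = None, **overrides) -> CohortConfig:
    """A copy of ``config`` with effect_size 0 (exchangeable DIL/NT)."""
    base = config or CohortConfig()
    return replace(base, effect_size=0.0, **overrides)


def write_cohort(subjects: list[SyntheticSubject], out_dir: str | Path,
                 spacing: tuple[float, float, float] = (3.0, 0.5, 0.5)) -> Path:
    """Write per-subject NIfTI volumes/masks and a subjects.csv manifest."""
    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    rows = []
    for s in subjects:
        paths = {}
        for key, arr in (("t2w", s.t2w_volume), ("adc", s.adc_volume),
                         ("dil_mask", s.dil_mask.astype(np.uint8)),
                         ("nt_mask", s.nt_mask.astype(np.uint8))):
            p = out / f"{s.subject_id}_{key}.nii.gz"
            # NIfTI stores x,y,z fastest-first; transpose from (z,y,x)
            nib.save(nib.Nifti1Image(np.ascontiguousarray(arr.T), affine), p)
            paths[key] = p.name
        rows.append({"subject_id": s.subject_id, "group_tag": s.group_tag, **paths})
    manifest = out / "subjects.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | Path) -> list[SyntheticSubject]:
    """Load a cohort written by :func:`write_cohort`."""
    import nibabel as nib
    import pandas as pd

    manifest = Path(manifest)
    base = manifest.parent
    subjects = []
    for _, row in pd.read_csv(manifest).iterrows():
        def load(key):
            return np.asarray(nib.load(base / row[key]).dataobj).T.astype(float)

        subjects.append(SyntheticSubject(
            subject_id=row["subject_id"], t2w_volume=load("t2w"),
            adc_volume=load("adc"), dil_mask=load("dil_mask") > 0,
            nt_mask=load("nt_mask") > 0, group_tag=row["group_tag"]))
    return subjects
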