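"""Two-block partial least squares correlation (PLSC) with inference.

Given aligned observation blocks X (one modality) and Y (the other), both
column-standardized, the method decomposes the cross-block covariance
R = X'Y/(n-1) by SVD: R = U diag(delta) V'. The columns of U and V
(saliences) define paired latent variables Lx = X U, Ly = Y V with maximal
covariance; the inertia sum(delta^2) = ||R||_F^2 measures the total
common variance. Inference is non-parametric:

* a permutation test on the inertia (rows of one block permuted) for the
  overall association;
* bootstrap ratios (mean/std of a salience element over resamples, with
  sign alignment to the original axes) for ranking original features,
  significant when |ratio| > 2;
* per-latent one-way ANOVA of DIL vs NT scores with Holm step-down
  correction, plus a mean-silhouette filter, for selecting discriminant
  latent variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

__all__ = ["ObservationBlock", "PLSCModel", "AnovaResult", "BootstrapRanking",
           "PermutationResult", "LatentFeatureSet", "build_blocks", "fit_plsc",
           "permutation_test_inertia", "bootstrap_ratios", "anova_latent",
           "silhouette_filter", "select_discriminant", "project"]


@dataclass
class ObservationBlock:
    """A standardized ROI-by-feature matrix for one modality."""

    data: np.ndarray                 # standardized, rows = ROIs
    modality: str
    subject_ids: np.ndarray          # per row
    roi_kinds: np.ndarray            # per row, "DIL" or "NT"
    col_means: np.ndarray
    col_scales: np.ndarray           # zero-variance columns keep scale 1, data 0
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def standardize_new(self, raw: np.ndarray) -> np.ndarray:
        """Apply the stored column means/scales to new raw feature rows."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if raw.shape[1] != self.data.shape[1]:
            raise ValueError("feature dimensionality mismatch")
        return (raw - self.col_means) / self.col_scales


@dataclass
class PLSCModel:
    """Saliences, singular values and latent scores of a fitted PLSC."""

    U: np.ndarray                    # saliences of block X, columns orthonormal
    V: np.ndarray                    # saliences of block Y
    singular_values: np.ndarray      # non-increasing
    Lx: np.ndarray                   # X @ U
    Ly: np.ndarray                   # Y @ V
    block_x: ObservationBlock
    block_y: ObservationBlock

    @property
    def inertia(self) -> float:
        return float((self.singular_values ** 2).sum())


@dataclass
class AnovaResult:
    F: np.ndarray
    p: np.ndarray
    reject: np.ndarray               # Holm-adjusted decisions at alpha
    alpha: float = 0.05


@dataclass
class BootstrapRanking:
    """Per-feature bootstrap ratios of one latent dimension's saliences."""

    ratios: np.ndarray
    ranks: np.ndarray                # permutation of feature indices, by |ratio| desc
    significant: np.ndarray          # |ratio| > threshold
    threshold: float = 2.0
    feature_names: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{i}" for i in range(len(self.ratios))]
        order = self.ranks
        return pd.DataFrame({
            "rank": np.arange(1, len(order) + 1),
            "feature": [names[i] for i in order],
            "bootstrap_ratio": self.ratios[order],
            "significant": self.significant[order],
        })


@dataclass
class PermutationResult:
    observed_inertia: float
    null_inertia: np.ndarray
    p_value: float


@dataclass
class LatentFeatureSet:
    """Selected latent scores per ROI (default 4 per modality = 8 values)."""

    features: np.ndarray             # rows aligned with the blocks
    labels: np.ndarray               # "DIL"/"NT" per row
    subject_ids: np.ndarray
    selected_x: np.ndarray           # latent indices kept per block
    selected_y: np.ndarray

    @property
    def is_empty(self) -> bool:
        return self.features.shape[1] == 0


def _standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = mat.mean(axis=0)
    scales = mat.std(axis=0, ddof=1)
    zero = scales == 0
    scales = np.where(zero, 1.0, scales)
    data = (mat - means) / scales
    data[:, zero] = 0.0
    return data, means, scales


def build_blocks(feature_table: pd.DataFrame,
                 feature_names: list[str] | None = None,
                 modalities: tuple[str, str] = ("T2W", "ADC"),
                 ) -> tuple[ObservationBlock, ObservationBlock]:
    """Aligned, column-standardized observation blocks from a feature table.

    ``feature_table`` must have columns ``subject_id``, ``roi_kind``,
    ``modality`` and one column per feature. Rows of the two blocks are
    aligned on (subject_id, roi_kind).
    """
    meta = {"subject_id", "roi_kind", "modality", "group_tag"}
    if feature_names is None:
        feature_names = [c for c in feature_table.columns if c not in meta]
    key = ["subject_id", "roi_kind"]
    pivots = {}
    for mod in modalities:
        sub = feature_table[feature_table["modality"] == mod]
        pivots[mod] = sub.set_index(key)[feature_names]
    idx = pivots[modalities[0]].index
    other = pivots[modalities[1]].index
    if len(other) != len(idx) or len(idx.difference(other)) or len(other.difference(idx)):
        missing = idx.symmetric_difference(other)
        raise ValueError(f"ROIs missing one modality: {list(missing)[:5]}")
    blocks = []
    for mod in modalities:
        mat = pivots[mod].loc[idx].to_numpy(dtype=float)
        if np.isnan(mat).any():
            raise ValueError(f"missing values in block {mod}")
        data, means, scales = _standardize(mat)
        blocks.append(ObservationBlock(
            data=data, modality=mod,
            subject_ids=np.asarray([i[0] for i in idx]),
            roi_kinds=np.asarray([i[1] for i in idx]),
            col_means=means, col_scales=scales,
            feature_names=list(feature_names)))
    return blocks[0], blocks[1]


def _cross_product(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    return X.T @ Y / (n - 1)


def _signed_svd(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD with a deterministic sign convention.

    Each left singular vector's largest-magnitude element is made
    positive; the matching right vector is flipped with it.
    """
    U, d, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for k in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
    return U, d, V


def fit_plsc(block_x: ObservationBlock, block_y: ObservationBlock) -> PLSCModel:
    """SVD of the cross-block covariance; saliences, scores, inertia."""
    X, Y = block_x.data, block_y.data
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks have different numbers of rows")
    if X.shape[0] < 3:
        raise ValueError("PLSC needs at least 3 rows")
    R = _cross_product(X, Y)
    if not np.any(R):
        raise ValueError("rank-0 cross-product; blocks are uncorrelated constants")
    U, d, V = _signed_svd(R)
    return PLSCModel(U=U, V=V, singular_values=d, Lx=X @ U, Ly=Y @ V,
                     block_x=block_x, block_y=block_y)


def inertia_of(X: np.ndarray, Y: np.ndarray) -> float:
    """||X'Y/(n-1)||_F^2 without an explicit SVD."""
    R = _cross_product(X, Y)
    return float((R * R).sum())


def permutation_test_inertia(block_x: ObservationBlock, block_y: ObservationBlock,
                             n_permutations: int = 10_000,
                             seed: int | None = None) -> PermutationResult:
    """Row-permutation null for the total cross-block inertia.

    Rows of Y are permuted as wholes (within-block feature correlation is
    preserved); p = (#{null >= observed} + 1) / (B + 1).
    """
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    X, Y = block_x.data, block_y.data
    rng = np.random.default_rng(seed)
    observed = inertia_of(X, Y)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = inertia_of(X, Y[rng.permutation(Y.shape[0])])
    p = (np.count_nonzero(null >= observed) + 1) / (n_permutations + 1)
    return PermutationResult(observed_inertia=observed, null_inertia=null,
                             p_value=p)


def bootstrap_ratios(block_x: ObservationBlock, block_y: ObservationBlock,
                     n_boot: int = 500, seed: int | None = None,
                     latent: int = 0, threshold: float = 2.0,
                     ) -> tuple[BootstrapRanking, BootstrapRanking]:
    """Bootstrap ratios of the saliences of one latent dimension.

    Rows are resampled with replacement; the PLSC is refitted per
    resample and each resampled salience column is sign-aligned to the
    original axes before accumulation. Features with zero bootstrap
    variance get an infinite ratio (ranked first). Returns one ranking
    per block.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    model = fit_plsc(block_x, block_y)
    X, Y = block_x.data, block_y.data
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    sal_x = np.empty((n_boot, X.shape[1]))
    sal_y = np.empty((n_boot, Y.shape[1]))
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(idx).size >= 3:
                break
        Ub, db, Vb = _signed_svd(_cross_product(X[idx], Y[idx]))
        k = min(latent, Ub.shape[1] - 1)
        u, v = Ub[:, k], Vb[:, k]
        if u @ model.U[:, latent] + v @ model.V[:, latent] < 0:
            u, v = -u, -v
        sal_x[b], sal_y[b] = u, v

    def ranking(samples: np.ndarray, names: list[str]) -> BootstrapRanking:
        mean = samples.mean(axis=0)
        std = samples.std(axis=0, ddof=1)
        # a salience reproduced identically in every resample (up to float
        # noise) gets the infinite-ratio sentinel and ranks first
        degenerate = std <= 1e-9 * np.abs(mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(~degenerate, mean / np.where(std > 0, std, 1.0),
                              np.where(mean == 0, 0.0, np.inf * np.sign(mean)))
        order = np.argsort(-np.abs(ratios), kind="stable")
        return BootstrapRanking(ratios=ratios, ranks=order,
                                significant=np.abs(ratios) > threshold,
                                threshold=threshold, feature_names=names)

    return (ranking(sal_x, block_x.feature_names),
            ranking(sal_y, block_y.feature_names))


def anova_latent(scores: np.ndarray, labels: np.ndarray,
                 alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA per latent variable, Holm-corrected.

    ``scores`` is (n_rows, n_latent); ``labels`` gives the two groups
    (DIL/NT). The Holm step-down family is the set of tested latent
    variables.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("ANOVA needs two groups")
    g0, g1 = scores[labels == groups[0]], scores[labels == groups[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs >= 2 observations")
    F = np.empty(scores.shape[1])
    p = np.empty(scores.shape[1])
    for k in range(scores.shape[1]):
        F[k], p[k] = stats.f_oneway(g0[:, k], g1[:, k])
    F = np.nan_to_num(F, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")[:4]
    return AnovaResult(F=F, p=p, reject=reject, alpha=alpha)


def silhouette_filter(scores: np.ndarray, labels: np.ndarray,
                      threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Mean silhouette coefficient of the DIL/NT clustering per latent.

    Returns (mean silhouette per latent, pass flags at ``threshold``).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    sil = np.empty(scores.shape[1])
    for k in range(scores.shape[1]):
        col = scores[:, k:k + 1]
        if np.allclose(col, col[0]):
            sil[k] = 0.0
        else:
            sil[k] = float(silhouette_samples(col, labels).mean())
    return sil, sil >= threshold


def select_discriminant(model: PLSCModel, k_per_modality: int = 4,
                        alpha: float = 0.05, silhouette_threshold: float = 0.5,
                        n_test: int | None = None) -> LatentFeatureSet:
    """Assemble the discriminant latent feature set (default 8 values/ROI).

    For each block, the first ``n_test`` latent variables are tested with
    Holm-corrected ANOVA and the silhouette filter; the first
    ``k_per_modality`` that pass both are retained. The result is empty
    when nothing passes.
    """
    labels = model.block_x.roi_kinds
    n_test = n_test or max(k_per_modality * 2, 8)
    selected = []
    for scores in (model.Lx, model.Ly):
        s = scores[:, :min(n_test, scores.shape[1])]
        anova = anova_latent(s, labels, alpha=alpha)
        _, sil_pass = silhouette_filter(s, labels, threshold=silhouette_threshold)
        passing = np.nonzero(anova.reject & sil_pass)[0][:k_per_modality]
        selected.append(passing)
    feats = np.hstack([model.Lx[:, selected[0]], model.Ly[:, selected[1]]]) \
        if (len(selected[0]) or len(selected[1])) else np.empty((model.Lx.shape[0], 0))
    return LatentFeatureSet(features=feats, labels=labels,
                            subject_ids=model.block_x.subject_ids,
                            selected_x=selected[0], selected_y=selected[1])


def project(model: PLSCModel, raw_x: np.ndarray | None = None,
            raw_y: np.ndarray | None = None) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Latent scores of new raw feature rows under the fitted model.

    Rows are standardized with the stored column means/scales of each
    block, then multiplied by the saliences.
    """
    lx = model.block_x.standardize_new(raw_x) @ model.U if raw_x is not None else None
    ly = model.block_y.standardize_new(raw_y) @ model.V if raw_y is not None else None
    return lx, ly


def project_selected(model: PLSCModel, selection: LatentFeatureSet,
                     raw_x: np.ndarray, raw_y: np.ndarray) -> np.ndarray:
    """New rows projected onto the selected latent variables (8-dim rows)."""
    lx, ly = project(model, raw_x, raw_y)
    return np.hstack([lx[:, selection.selected_x], ly[:, selection.selected_y]])
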