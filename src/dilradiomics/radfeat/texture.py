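"""Second-order and filter-bank texture features on 2-D ROI slices.

GLRL and Laws are implemented directly (run enumeration, separable 5-tap
kernels); the GLCM matrix itself comes from ``skimage.feature.graycomatrix``
with the Haralick-family statistics computed here; LBP uses the plain square
eight-neighborhood (no sub-pixel interpolation) with threshold
``neighbor >= center``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

from .intensity import extract_ibhf

__all__ = ["extract_glrl", "extract_glcm", "extract_laws", "extract_lbp",
           "run_length_encode", "glcm_features_from_matrix", "LAWS_KERNELS_1D"]


# ---------------------------------------------------------------------------
# Gray-level run length
# ---------------------------------------------------------------------------

#: the four in-plane directions as (dy, dx) unit offsets
_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _lines(shape: tuple[int, int], direction: tuple[int, int]):
    """Index arrays of every maximal lattice line along ``direction``."""
    h, w = shape
    dy, dx = direction
    if (dy, dx) == (0, 1):
        for y in range(h):
            yield np.full(w, y), np.arange(w)
    elif (dy, dx) == (1, 0):
        for x in range(w):
            yield np.arange(h), np.full(h, x)
    elif (dy, dx) == (1, 1):
        for off in range(-(h - 1), w):
            ys = np.arange(max(0, -off), min(h, w - off))
            yield ys, ys + off
    elif (dy, dx) == (1, -1):
        for s in range(h + w - 1):
            ys = np.arange(max(0, s - w + 1), min(h, s + 1))
            yield ys, s - ys
    else:  # pragma: no cover
        raise ValueError(f"unsupported direction {direction}")


def run_length_encode(seq: np.ndarray) -> list[tuple[int, int]]:
    """(value, run length) pairs of a 1-D integer sequence."""
    seq = np.asarray(seq)
    if seq.size == 0:
        return []
    breaks = np.nonzero(np.diff(seq) != 0)[0] + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [seq.size]])
    return [(int(seq[s]), int(e - s)) for s, e in zip(starts, ends)]


def run_length_matrix(quantized: np.ndarray, mask: np.ndarray,
                      direction: tuple[int, int], n_levels: int) -> np.ndarray:
    """Run-length matrix R[g, l-1] over in-mask runs along one direction.

    Runs are counted within maximal in-mask segments of each lattice line,
    so that sum_g sum_l R[g, l] * l equals the in-mask pixel count.
    """
    q = np.asarray(quantized)
    m = np.asarray(mask, dtype=bool)
    max_len = max(q.shape)
    R = np.zeros((n_levels, max_len), dtype=float)
    for ys, xs in _lines(q.shape, direction):
        inside = m[ys, xs]
        vals = q[ys, xs]
        # split the line into maximal in-mask segments
        idx = 0
        for seg_in, seg_len in run_length_encode(inside.astype(int)):
            if seg_in:
                for g, length in run_length_encode(vals[idx:idx + seg_len]):
                    R[g, length - 1] += 1
            idx += seg_len
    return R


def _glrl_from_matrix(R: np.ndarray, n_pixels: int) -> np.ndarray:
    n_runs = R.sum()
    if n_runs == 0:
        raise ValueError("empty ROI for GLRL")
    lengths = np.arange(1, R.shape[1] + 1, dtype=float)
    levels = np.arange(1, R.shape[0] + 1, dtype=float)  # 1-based gray levels
    per_len = R.sum(axis=0)
    per_lvl = R.sum(axis=1)
    sre = float((per_len / lengths ** 2).sum() / n_runs)
    lre = float((per_len * lengths ** 2).sum() / n_runs)
    gln = float((per_lvl ** 2).sum() / n_runs)
    rp = float(n_runs / n_pixels)
    rln = float((per_len ** 2).sum() / n_runs)
    lgre = float((per_lvl / levels ** 2).sum() / n_runs)
    hgre = float((per_lvl * levels ** 2).sum() / n_runs)
    return np.array([sre, lre, gln, rp, rln, lgre, hgre])


def extract_glrl(quantized: np.ndarray, mask: np.ndarray | None = None,
                 n_levels: int = 16) -> np.ndarray:
    """Seven Galloway run-length descriptors averaged over the 4 directions.

    Order: SRE, LRE, GLN, RP, RLN, LGRE, HGRE.
    """
    q = np.asarray(quantized)
    mask = np.ones(q.shape, bool) if mask is None else np.asarray(mask, bool)
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise ValueError("empty ROI for GLRL")
    feats = [_glrl_from_matrix(run_length_matrix(q, mask, d, n_levels), n_pixels)
             for d in _DIRECTIONS]
    return np.mean(feats, axis=0)


# ---------------------------------------------------------------------------
# Gray-level co-occurrence
# ---------------------------------------------------------------------------

def glcm_features_from_matrix(P: np.ndarray) -> np.ndarray:
    """The 22 Haralick/Soh/Clausi statistics of a normalized symmetric GLCM.

    Order: autocorrelation, contrast, correlation (product form),
    correlation (deviation form), cluster prominence, cluster shade,
    dissimilarity, energy, entropy, homogeneity |i-j|, homogeneity (i-j)^2,
    maximum probability, sum-of-squares variance, sum average, sum variance,
    sum entropy, difference variance, difference entropy, information
    measures of correlation 1 and 2, inverse difference normalized and
    inverse difference moment normalized.

    Correlation-type statistics of a degenerate (zero marginal variance)
    matrix are 0 by convention. Entropies are in bits.
    """
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    i = np.arange(L, dtype=float)[:, None]
    j = np.arange(L, dtype=float)[None, :]
    pi = P.sum(axis=1)      # marginal of i (== marginal of j: P symmetric)
    mu_x = float((i * P).sum())
    mu_y = float((j * P).sum())
    var_x = float(((i - mu_x) ** 2 * P).sum())
    var_y = float(((j - mu_y) ** 2 * P).sum())
    sx, sy = np.sqrt(var_x), np.sqrt(var_y)

    absdiff = np.abs(i - j)
    sqdiff = (i - j) ** 2

    autoc = float((i * j * P).sum())
    contrast = float((sqdiff * P).sum())
    if sx > 0 and sy > 0:
        corr1 = float((((i - mu_x) * (j - mu_y) * P).sum()) / (sx * sy))
        corr2 = (autoc - mu_x * mu_y) / (sx * sy)
    else:
        corr1 = corr2 = 0.0
    cprom = float(((i + j - mu_x - mu_y) ** 4 * P).sum())
    cshade = float(((i + j - mu_x - mu_y) ** 3 * P).sum())
    dissim = float((absdiff * P).sum())
    energy = float((P ** 2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    homom = float((P / (1.0 + absdiff)).sum())
    homop = float((P / (1.0 + sqdiff)).sum())
    maxp = float(P.max())
    sosvar = float(((i - mu_x) ** 2 * P).sum())

    k_sum = (np.arange(L)[:, None] + np.arange(L)[None, :]).ravel()
    p_sum = np.bincount(k_sum, weights=P.ravel(), minlength=2 * L - 1)
    ks = np.arange(2 * L - 1, dtype=float)
    sum_avg = float((ks * p_sum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    nzs = p_sum[p_sum > 0]
    sum_ent = float(-(nzs * np.log2(nzs)).sum())

    k_diff = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]).ravel()
    p_diff = np.bincount(k_diff, weights=P.ravel(), minlength=L)
    kd = np.arange(L, dtype=float)
    diff_avg = float((kd * p_diff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * p_diff).sum())
    nzd = p_diff[p_diff > 0]
    diff_ent = float(-(nzd * np.log2(nzd)).sum())

    # information measures of correlation (marginals equal for symmetric P)
    nzp = pi[pi > 0]
    hx = float(-(nzp * np.log2(nzp)).sum())
    pij_prod = pi[:, None] * pi[None, :]
    valid = (P > 0)
    hxy1 = float(-(P[valid] * np.log2(np.maximum(pij_prod[valid], 1e-300))).sum())
    vp = pij_prod > 0
    hxy2 = float(-(pij_prod[vp] * np.log2(pij_prod[vp])).sum())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    inn = float((P / (1.0 + absdiff / L)).sum())
    idn = float((P / (1.0 + sqdiff / L ** 2)).sum())

    return np.array([autoc, contrast, corr2, corr1, cprom, cshade, dissim,
                     energy, entropy, homom, homop, maxp, sosvar, sum_avg,
                     sum_var, sum_ent, diff_var, diff_ent, imc1, imc2,
                     inn, idn])


def glcm_matrix(quantized: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """Symmetric normalized GLCM averaged over the 4 in-plane unit offsets."""
    q = np.ascontiguousarray(quantized, dtype=np.uint16)
    angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    M = graycomatrix(q, distances=[1], angles=angles, levels=n_levels,
                     symmetric=True, normed=False).astype(float)
    mats = M[:, :, 0, :]  # (L, L, n_angles)
    totals = mats.sum(axis=(0, 1))
    if np.all(totals == 0):
        raise ValueError("ROI too small for co-occurrence estimation")
    keep = totals > 0
    return (mats[:, :, keep] / totals[keep]).mean(axis=2)


def extract_glcm(quantized: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """22 co-occurrence features from the direction-averaged symmetric GLCM."""
    return glcm_features_from_matrix(glcm_matrix(quantized, n_levels))


# ---------------------------------------------------------------------------
# Laws texture energy
# ---------------------------------------------------------------------------

LAWS_KERNELS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

#: the nine map groups; asymmetric pairs are averaged into one map
LAWS_PAIRS = [("L5", "E5"), ("L5", "R5"), ("E5", "S5"), ("S5", "S5"),
              ("R5", "R5"), ("L5", "S5"), ("E5", "E5"), ("E5", "R5"),
              ("S5", "R5")]


def laws_map(image: np.ndarray, a: str, b: str) -> np.ndarray:
    """Response to the 2-D kernel outer(a, b); pairs averaged before stats."""
    k = np.outer(LAWS_KERNELS_1D[a], LAWS_KERNELS_1D[b])
    out = ndimage.convolve(np.asarray(image, float), k, mode="reflect")
    if a != b:
        k2 = np.outer(LAWS_KERNELS_1D[b], LAWS_KERNELS_1D[a])
        out = 0.5 * (out + ndimage.convolve(np.asarray(image, float), k2,
                                            mode="reflect"))
    return out


def extract_laws(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Energy and entropy of the 9 Laws map groups (18 features)."""
    from .core import map_energy, map_entropy

    img = np.asarray(image, dtype=float)
    if min(img.shape) < 5:
        raise ValueError("Laws features need a bounding box of at least 5x5")
    mask = np.ones(img.shape, bool) if mask is None else np.asarray(mask, bool)
    feats = []
    for a, b in LAWS_PAIRS:
        m = laws_map(img, a, b)[mask]
        feats += [map_energy(m), map_entropy(m)]
    return np.array(feats)


# ---------------------------------------------------------------------------
# Local binary patterns
# ---------------------------------------------------------------------------

#: eight-neighborhood offsets (dy, dx), bit order LSB->MSB
_LBP_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1),
                (0, -1), (1, -1), (1, 0), (1, 1)]


def lbp_codes(image: np.ndarray) -> np.ndarray:
    """Square eight-neighborhood LBP code map of the interior pixels.

    Bit k is set when the k-th neighbor (counter-clockwise from east) is
    greater than or equal to the center.
    """
    img = np.asarray(image, dtype=float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("LBP needs a bounding box of at least 3x3")
    center = img[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.intp)
    for bit, (dy, dx) in enumerate(_LBP_OFFSETS):
        nb = img[1 + dy: img.shape[0] - 1 + dy, 1 + dx: img.shape[1] - 1 + dx]
        codes |= (nb >= center).astype(np.intp) << bit
    return codes


def extract_lbp(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Energy, entropy, mean, std, skewness and kurtosis of the LBP code map."""
    from .core import map_energy

    codes = lbp_codes(image)
    if mask is not None:
        inner = np.asarray(mask, bool)[1:-1, 1:-1]
        vals = codes[inner] if inner.any() else codes.ravel()
    else:
        vals = codes.ravel()
    if vals.size < 2:
        vals = codes.ravel()
    counts = np.bincount(vals, minlength=256)
    p = counts[counts > 0] / vals.size
    entropy = float(-(p * np.log2(p)).sum())
    mean, std, skew, kurt = extract_ibhf(vals.astype(float))[:4]
    return np.array([map_energy(vals), entropy, mean, std, skew, kurt])
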