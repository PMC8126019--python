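"""Gray-level co-occurrence and run-length texture features.

Texture is computed on the axial slice decomposition of an ROI (clinical MR
volumes are anisotropic through-plane, so in-plane offsets are the
meaningful ones).  For each of the four distance-1 in-plane directions
(0°, 45°, 90° and 135°) a single co-occurrence matrix and a single
run-length matrix are accumulated over all slices; only pixel pairs / runs
fully inside the region mask contribute.  Co-occurrence counts are
symmetric (each pair counted in both orders) and normalized per direction;
features are averaged over the direction set, which is closed under 90°
rotation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: (drow, dcol) offsets for 0°, 45°, 90°, 135°
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

GLCM_NAMES: tuple[str, ...] = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Dissimilarity", "Energy",
    "Entropy", "Homogeneity1", "Homogeneity2", "Imc1", "Imc2", "Idmn",
    "Idn", "InverseVariance", "MaximumProbability", "SumEntropy",
)

GLRLM_NAMES: tuple[str, ...] = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "RunLengthNonUniformity", "RunPercentage", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


@dataclass
class TextureMatrices:
    """Slice-pooled GLCM and GLRLM, one matrix per in-plane direction.

    ``glcm_by_direction`` holds normalized symmetric co-occurrence matrices
    (entries sum to 1); ``glrlm_by_direction`` holds raw run counts.  The
    ``glcm`` property is the direction-averaged matrix.  ``n_pixels`` is the
    number of masked pixels over all pooled slices, which every direction's
    run-length matrix conserves: sum over (count x run length) == n_pixels.
    """

    n_levels: int
    directions: tuple[tuple[int, int], ...]
    glcm_by_direction: list[np.ndarray]
    glrlm_by_direction: list[np.ndarray]
    n_pixels: int

    @property
    def glcm(self) -> np.ndarray:
        return np.mean([g for g in self.glcm_by_direction], axis=0)

    def validate(self) -> None:
        for g in self.glcm_by_direction:
            if g.sum() > 0 and not np.isclose(g.sum(), 1.0, atol=1e-12):
                raise AssertionError("GLCM is not normalized")
            if not np.allclose(g, g.T):
                raise AssertionError("GLCM is not symmetric")
        for r in self.glrlm_by_direction:
            lengths = np.arange(1, r.shape[1] + 1)
            if int((r * lengths).sum()) != self.n_pixels:
                raise AssertionError("GLRLM does not conserve the pixel count")


def _glcm_one_direction(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int], n_levels: int
) -> np.ndarray:
    """Raw symmetric co-occurrence counts for one slice and one offset."""
    dr, dc = offset
    rows, cols = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    r0s, r0e = max(0, -dr), min(rows, rows - dr)
    c0s, c0e = max(0, -dc), min(cols, cols - dc)
    if r0s >= r0e or c0s >= c0e:
        return counts
    a = levels[r0s:r0e, c0s:c0e]
    b = levels[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    ok = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    if not ok.any():
        return counts
    np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1.0)
    return counts + counts.T


def _lines_for_direction(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int]
):
    """Yield (level_line, mask_line) 1D arrays along the offset direction."""
    dr, dc = offset
    if (dr, dc) in ((0, 1), (0, -1)):
        for r in range(levels.shape[0]):
            yield levels[r, :], mask[r, :]
    elif (dr, dc) in ((1, 0), (-1, 0)):
        for c in range(levels.shape[1]):
            yield levels[:, c], mask[:, c]
    elif (dr, dc) in ((-1, 1), (1, -1)):  # 45°: anti-diagonals
        flipped_l, flipped_m = levels[::-1, :], mask[::-1, :]
        for d in range(-levels.shape[0] + 1, levels.shape[1]):
            yield np.diagonal(flipped_l, d), np.diagonal(flipped_m, d)
    else:  # 135°: main diagonals
        for d in range(-levels.shape[0] + 1, levels.shape[1]):
            yield np.diagonal(levels, d), np.diagonal(mask, d)


def _glrlm_one_direction(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int],
    n_levels: int, max_run: int,
) -> np.ndarray:
    """Run counts for one slice and one direction (runs break at mask gaps)."""
    counts = np.zeros((n_levels, max_run), dtype=np.float64)
    for line, mline in _lines_for_direction(levels, mask, offset):
        run_level, run_len = 0, 0
        for lev, inside in zip(line.tolist(), mline.tolist()):
            if inside and lev == run_level:
                run_len += 1
            else:
                if run_len:
                    counts[run_level - 1, run_len - 1] += 1
                run_level, run_len = (lev, 1) if inside else (0, 0)
        if run_len:
            counts[run_level - 1, run_len - 1] += 1
    return counts


def compute_texture_matrices(
    slice_levels: list[np.ndarray], slice_masks: list[np.ndarray], n_levels: int
) -> TextureMatrices:
    """Accumulate slice-pooled GLCM/GLRLM over the 4-direction set.

    ``slice_levels`` are discretized patches (integer levels 1..n_levels);
    pixels outside the matching mask are ignored entirely.
    """
    if not slice_levels:
        raise ValueError("texture matrices need at least one slice")
    max_run = max(max(l.shape) for l in slice_levels)
    glcms, glrlms = [], []
    for offset in DIRECTIONS:
        glcm = np.zeros((n_levels, n_levels), dtype=np.float64)
        glrlm = np.zeros((n_levels, max_run), dtype=np.float64)
        for levels, mask in zip(slice_levels, slice_masks):
            glcm += _glcm_one_direction(levels, mask, offset, n_levels)
            glrlm += _glrlm_one_direction(levels, mask, offset, n_levels, max_run)
        total = glcm.sum()
        if total > 0:
            glcm /= total
        glcms.append(glcm)
        glrlms.append(glrlm)
    n_pixels = int(sum(m.sum() for m in slice_masks))
    return TextureMatrices(
        n_levels=n_levels,
        directions=DIRECTIONS,
        glcm_by_direction=glcms,
        glrlm_by_direction=glrlms,
        n_pixels=n_pixels,
    )


# ---------------------------------------------------------------------------
# GLCM features
# ---------------------------------------------------------------------------

def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features_single(p: np.ndarray) -> dict[str, float]:
    """The 22 co-occurrence statistics of one normalized symmetric GLCM."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    # difference |i-j| and sum i+j marginals
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, p)

    contrast = float((((ii - jj) ** 2) * p).sum())
    autocorr = float((ii * jj * p).sum())
    correlation = (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 0.0
    diff_avg = float((k_diff * p_diff).sum())
    entropy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(px).sum())
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-(pxpy * log_pxpy).sum())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    off = ii != jj
    inv_var = float((p[off] / (ii - jj)[off] ** 2).sum())

    cs = ii + jj - 2 * mu
    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": float((cs ** 4 * p).sum()),
        "ClusterShade": float((cs ** 3 * p).sum()),
        "ClusterTendency": float((cs ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-_xlog2(p_diff).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "Energy": float((p ** 2).sum()),
        "Entropy": entropy,
        "Homogeneity1": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Homogeneity2": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-_xlog2(p_sum).sum()),
    }


def glcm_features(matrices: TextureMatrices) -> dict[str, float]:
    """Direction-averaged co-occurrence features."""
    per_dir = [glcm_features_single(g) for g in matrices.glcm_by_direction]
    return {n: float(np.mean([d[n] for d in per_dir])) for n in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM features
# ---------------------------------------------------------------------------

def glrlm_features_single(r: np.ndarray, n_pixels: int) -> dict[str, float]:
    """The 11 classic run-length statistics of one run-count matrix."""
    nr = r.sum()
    if nr == 0:
        return {n: 0.0 for n in GLRLM_NAMES}
    i = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    return {
        "ShortRunEmphasis": float((r / l ** 2).sum() / nr),
        "LongRunEmphasis": float((r * l ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((r.sum(axis=1) ** 2).sum() / nr),
        "RunLengthNonUniformity": float((r.sum(axis=0) ** 2).sum() / nr),
        "RunPercentage": float(nr / n_pixels),
        "LowGrayLevelRunEmphasis": float((r / i ** 2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((r * i ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((r / (i ** 2 * l ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((r * i ** 2 / l ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((r * l ** 2 / i ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((r * i ** 2 * l ** 2).sum() / nr),
    }


def glrlm_features(matrices: TextureMatrices) -> dict[str, float]:
    """Direction-averaged run-length features."""
    per_dir = [
        glrlm_features_single(r, matrices.n_pixels)
        for r in matrices.glrlm_by_direction
    ]
    return {n: float(np.mean([d[n] for d in per_dir])) for n in GLRLM_NAMES}
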