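"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain enumeration loops, deliberately sharing
no code with the package: co-occurrence matrices by visiting every pixel
pair, run-length matrices by walking every line, texture statistics from
their textbook definitions, LBP codes by explicit circle sampling, AUC by
concordant-pair counting.
"""
from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# GLCM by pair enumeration
# ---------------------------------------------------------------------------

def naive_glcm(slices, masks, offset, n_levels):
    """Symmetric normalized co-occurrence matrix by visiting every pixel pair."""
    dr, dc = offset
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for levels, mask in zip(slices, masks):
        rows, cols = levels.shape
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                    a, b = levels[r, c] - 1, levels[r2, c2] - 1
                    counts[a, b] += 1
                    counts[b, a] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def naive_glcm_features(p):
    """The 22 co-occurrence statistics from their definitions, loop-style."""
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))

    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i][j]
            p_sum[i + j] += p[i][j]

    def h(values):  # entropy in bits of a probability list
        return -sum(v * math.log2(v) for v in values if v > 0)

    autocorr = sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    diff_avg = sum(k * p_diff[k] for k in range(ng))
    entropy = h([p[i][j] for i in range(ng) for j in range(ng)])
    hx = h(px)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if p[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if px[i] * px[j] > 0
    )
    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": sum(
            (i + j + 2 - 2 * mu) ** 4 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            (i + j + 2 - 2 * mu) ** 3 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            (i + j + 2 - 2 * mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum(
            (i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "Correlation": (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 0.0,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": h(p_diff),
        "DifferenceVariance": sum(
            (k - diff_avg) ** 2 * p_diff[k] for k in range(ng)
        ),
        "Dissimilarity": sum(
            abs(i - j) * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "Energy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "Entropy": entropy,
        "Homogeneity1": sum(
            p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        ),
        "Homogeneity2": sum(
            p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
        ),
        "Imc1": (entropy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy)))),
        "Idmn": sum(
            p[i][j] / (1 + (i - j) ** 2 / ng ** 2) for i in range(ng) for j in range(ng)
        ),
        "Idn": sum(
            p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        ),
        "InverseVariance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "MaximumProbability": max(p[i][j] for i in range(ng) for j in range(ng)),
        "SumEntropy": h(p_sum),
    }


# ---------------------------------------------------------------------------
# GLRLM by run enumeration
# ---------------------------------------------------------------------------

def _naive_lines(levels, mask, offset):
    rows, cols = levels.shape
    dr, dc = offset
    # starting points: cells with no predecessor along (dr, dc)
    starts = []
    for r in range(rows):
        for c in range(cols):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < rows and 0 <= pc < cols):
                starts.append((r, c))
    for r0, c0 in starts:
        line = []
        r, c = r0, c0
        while 0 <= r < rows and 0 <= c < cols:
            line.append((levels[r, c], bool(mask[r, c])))
            r, c = r + dr, c + dc
        yield line


def naive_glrlm(slices, masks, offset, n_levels, max_run):
    """Run-count matrix by walking every line and splitting at mask gaps."""
    counts = np.zeros((n_levels, max_run), dtype=float)
    for levels, mask in zip(slices, masks):
        for line in _naive_lines(levels, mask, offset):
            run_level, run_len = None, 0
            for lev, inside in line + [(None, False)]:
                if inside and lev == run_level:
                    run_len += 1
                else:
                    if run_len:
                        counts[run_level - 1, run_len - 1] += 1
                    run_level, run_len = (lev, 1) if inside else (None, 0)
    return counts


def naive_glrlm_features(r, n_pixels):
    """The 11 run statistics from their definitions, loop-style."""
    ng, lmax = r.shape
    nr = sum(r[i][l] for i in range(ng) for l in range(lmax))
    if nr == 0:
        return {}

    def agg(f):
        return sum(f(i + 1, l + 1) * r[i][l] for i in range(ng) for l in range(lmax)) / nr

    return {
        "ShortRunEmphasis": agg(lambda i, l: 1 / l ** 2),
        "LongRunEmphasis": agg(lambda i, l: l ** 2),
        "GrayLevelNonUniformity": sum(
            sum(r[i][l] for l in range(lmax)) ** 2 for i in range(ng)
        ) / nr,
        "RunLengthNonUniformity": sum(
            sum(r[i][l] for i in range(ng)) ** 2 for l in range(lmax)
        ) / nr,
        "RunPercentage": nr / n_pixels,
        "LowGrayLevelRunEmphasis": agg(lambda i, l: 1 / i ** 2),
        "HighGrayLevelRunEmphasis": agg(lambda i, l: i ** 2),
        "ShortRunLowGrayLevelEmphasis": agg(lambda i, l: 1 / (i ** 2 * l ** 2)),
        "ShortRunHighGrayLevelEmphasis": agg(lambda i, l: i ** 2 / l ** 2),
        "LongRunLowGrayLevelEmphasis": agg(lambda i, l: l ** 2 / i ** 2),
        "LongRunHighGrayLevelEmphasis": agg(lambda i, l: i ** 2 * l ** 2),
    }


# ---------------------------------------------------------------------------
# LBP by explicit circle sampling
# ---------------------------------------------------------------------------

def naive_lbp_code(img, r, c, P=8, R=1.0):
    """Rotation-invariant uniform LBP code of one pixel (bilinear sampling)."""
    center = img[r, c]
    bits = []
    for i in range(P):
        rr = r + round(-R * math.sin(2 * math.pi * i / P), 8)
        cc = c + round(R * math.cos(2 * math.pi * i / P), 8)
        minr, minc = int(math.floor(rr)), int(math.floor(cc))
        dr, dc = rr - minr, cc - minc

        def px(a, b):
            if 0 <= a < img.shape[0] and 0 <= b < img.shape[1]:
                return float(img[a, b])
            return 0.0

        top = (1 - dc) * px(minr, minc) + dc * px(minr, minc + 1)
        bot = (1 - dc) * px(minr + 1, minc) + dc * px(minr + 1, minc + 1)
        val = (1 - dr) * top + dr * bot
        bits.append(1 if val - center >= 0 else 0)
    transitions = sum(bits[i] != bits[(i + 1) % P] for i in range(P))
    return sum(bits) if transitions <= 2 else P + 1


def naive_lbp_codes(image, mask):
    """Pooled codes at masked pixels; neighborhood edge-replicated like the
    implementation's convention."""
    padded = np.pad(np.asarray(image, dtype=float), 1, mode="edge")
    out = []
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            if mask[r, c]:
                out.append(naive_lbp_code(padded, r + 1, c + 1))
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# AUC by concordant-pair counting
# ---------------------------------------------------------------------------

def naive_auc(scores, y):
    """Mann-Whitney AUC: concordant pairs + half ties over n_pos * n_neg."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
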