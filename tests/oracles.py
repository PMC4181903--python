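"""Independent brute-force oracles used by the tests.

Everything here is written as plain per-pixel / per-cell loops, deliberately
avoiding the vectorized code paths of the package so that agreement between
the two is meaningful.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

# ---------------------------------------------------------------------------
# first-order statistics straight from pixel values (no histogram)


def histogram_features_oracle(values: np.ndarray) -> dict[str, float]:
    vals = [float(v) for v in values.ravel()]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    std = math.sqrt(var)
    counts = Counter(vals)
    energy = sum((c / n) ** 2 for c in counts.values())
    entropy = -sum((c / n) * math.log2(c / n) for c in counts.values())
    if std > 0:
        skew = sum((v - mean) ** 3 for v in vals) / n / std**3
        kurt = sum((v - mean) ** 4 for v in vals) / n / std**4
    else:
        skew = kurt = 0.0
    return {
        "ih_mean": mean,
        "ih_standard_deviation": std,
        "ih_average_energy": energy,
        "ih_entropy": entropy,
        "ih_skewness": skew,
        "ih_kurtosis": kurt,
    }


# ---------------------------------------------------------------------------
# GLCM by exhaustive pair enumeration

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_counts_oracle(levels: np.ndarray, mask: np.ndarray, G: int, d: int,
                       theta: int, symmetric: bool) -> np.ndarray:
    h, w = levels.shape
    dr, dc = (o * d for o in OFFSETS[theta])
    P = np.zeros((G, G))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                P[levels[r, c], levels[r2, c2]] += 1
                if symmetric:
                    P[levels[r2, c2], levels[r, c]] += 1
    return P


def glcm_features_oracle(P: np.ndarray) -> dict[str, float]:
    """Literal double-loop transcription of the 22 co-occurrence features
    (1-based indices, natural log)."""
    G = P.shape[0]
    rng = range(G)
    px = [sum(P[i][j] for j in rng) for i in rng]
    py = [sum(P[i][j] for i in rng) for j in rng]
    mu_x = sum((i + 1) * px[i] for i in rng)
    mu_y = sum((j + 1) * py[j] for j in rng)
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in rng))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in rng))

    pxy = [0.0] * (2 * G - 1)   # k = 2..2G
    pxmy = [0.0] * G            # k = 0..G-1
    for i in rng:
        for j in rng:
            pxy[(i + 1) + (j + 1) - 2] += P[i][j]
            pxmy[abs(i - j)] += P[i][j]

    def ent(vals):
        return -sum(v * math.log(v) for v in vals if v > 0)

    out = {}
    out["glcm_autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i][j] for i in rng for j in rng)
    out["glcm_contrast"] = sum((i - j) ** 2 * P[i][j] for i in rng for j in rng)
    if sig_x > 0 and sig_y > 0:
        out["glcm_correlation"] = (
            out["glcm_autocorrelation"] - mu_x * mu_y) / (sig_x * sig_y)
    else:
        out["glcm_correlation"] = 0.0
    out["glcm_cluster_prominence"] = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 4 * P[i][j] for i in rng for j in rng)
    out["glcm_cluster_shade"] = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 3 * P[i][j] for i in rng for j in rng)
    out["glcm_dissimilarity"] = sum(
        abs(i - j) * P[i][j] for i in rng for j in rng)
    out["glcm_energy"] = sum(P[i][j] ** 2 for i in rng for j in rng)
    out["glcm_entropy"] = ent([P[i][j] for i in rng for j in rng])
    out["glcm_homogeneity_1"] = sum(
        P[i][j] / (1 + abs(i - j)) for i in rng for j in rng)
    out["glcm_homogeneity_2"] = sum(
        P[i][j] / (1 + (i - j) ** 2) for i in rng for j in rng)
    out["glcm_maximum_probability"] = max(P[i][j] for i in rng for j in rng)
    out["glcm_sum_of_squares"] = sum(
        (i + 1 - mu_x) ** 2 * P[i][j] for i in rng for j in rng)
    out["glcm_sum_average"] = sum((k + 2) * pxy[k] for k in range(2 * G - 1))
    se = ent(pxy)
    out["glcm_sum_entropy"] = se
    out["glcm_sum_variance"] = sum(
        (k + 2 - se) ** 2 * pxy[k] for k in range(2 * G - 1))
    mu_d = sum(k * pxmy[k] for k in range(G))
    out["glcm_difference_variance"] = sum(
        (k - mu_d) ** 2 * pxmy[k] for k in range(G))
    out["glcm_difference_entropy"] = ent(pxmy)
    hx, hy, hxy = ent(px), ent(py), out["glcm_entropy"]
    hxy1 = -sum(P[i][j] * math.log(px[i] * py[j])
                for i in rng for j in rng if px[i] * py[j] > 0 and P[i][j] > 0)
    hxy2 = ent([px[i] * py[j] for i in rng for j in rng])
    out["glcm_info_measure_corr_1"] = (
        (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0)
    out["glcm_info_measure_corr_2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["glcm_inverse_difference"] = out["glcm_homogeneity_1"]
    out["glcm_inverse_difference_normalized"] = sum(
        P[i][j] / (1 + abs(i - j) / G) for i in rng for j in rng)
    out["glcm_inverse_difference_moment_normalized"] = sum(
        P[i][j] / (1 + (i - j) ** 2 / G**2) for i in rng for j in rng)
    return out


# ---------------------------------------------------------------------------
# GLRLM by naive per-line run scanning


def glrlm_runs_oracle(levels: np.ndarray, mask: np.ndarray,
                      direction: int) -> list[tuple[int, int]]:
    h, w = levels.shape
    step = {0: (0, 1), 45: (-1, 1), 90: (1, 0), 135: (1, 1)}[direction]
    dr, dc = step
    if direction == 0:
        starts = [(r, 0) for r in range(h)]
    elif direction == 90:
        starts = [(0, c) for c in range(w)]
    elif direction == 45:
        starts = [(r, 0) for r in range(h)] + [(h - 1, c) for c in range(1, w)]
    else:  # 135
        starts = [(0, c) for c in range(w)] + [(r, 0) for r in range(1, h)]
    runs = []
    for r0, c0 in starts:
        r, c = r0, c0
        cur_level, cur_len = None, 0
        while 0 <= r < h and 0 <= c < w:
            if mask[r, c]:
                lv = int(levels[r, c])
                if lv == cur_level:
                    cur_len += 1
                else:
                    if cur_level is not None:
                        runs.append((cur_level, cur_len))
                    cur_level, cur_len = lv, 1
            else:
                if cur_level is not None:
                    runs.append((cur_level, cur_len))
                cur_level, cur_len = None, 0
            r += dr
            c += dc
        if cur_level is not None:
            runs.append((cur_level, cur_len))
    return runs


def glrlm_features_oracle(runs: list[tuple[int, int]], n_pixels: int) -> dict[str, float]:
    n_runs = len(runs)
    s = {
        "glrlm_sre": sum(1.0 / ln**2 for _, ln in runs),
        "glrlm_lre": sum(float(ln**2) for _, ln in runs),
        "glrlm_lgre": sum(1.0 / (lv + 1) ** 2 for lv, _ in runs),
        "glrlm_hgre": sum(float(lv + 1) ** 2 for lv, _ in runs),
        "glrlm_srlge": sum(1.0 / ((lv + 1) ** 2 * ln**2) for lv, ln in runs),
        "glrlm_srhge": sum((lv + 1) ** 2 / ln**2 for lv, ln in runs),
        "glrlm_lrlge": sum(ln**2 / (lv + 1) ** 2 for lv, ln in runs),
        "glrlm_lrhge": sum(float((lv + 1) ** 2 * ln**2) for lv, ln in runs),
    }
    by_level = Counter(lv for lv, _ in runs)
    by_length = Counter(ln for _, ln in runs)
    s["glrlm_gln"] = sum(c**2 for c in by_level.values())
    s["glrlm_rln"] = sum(c**2 for c in by_length.values())
    out = {k: v / n_runs for k, v in s.items()}
    out["glrlm_rp"] = n_runs / n_pixels
    return out


# ---------------------------------------------------------------------------
# intensity-weighted moments and Hu invariants, explicit loops


def hu_moments_oracle(pixels: np.ndarray, mask: np.ndarray) -> list[float]:
    h, w = pixels.shape
    def m(p, q, x0=0.0, y0=0.0):
        return sum(
            (c - x0) ** p * (r - y0) ** q * float(pixels[r, c])
            for r in range(h) for c in range(w) if mask[r, c]
        )
    m00 = m(0, 0)
    xb, yb = m(1, 0) / m00, m(0, 1) / m00
    def eta(p, q):
        return m(p, q, xb, yb) / m00 ** (1 + (p + q) / 2)
    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n03, n21, n12 = eta(3, 0), eta(0, 3), eta(2, 1), eta(1, 2)
    return [
        n20 + n02,
        (n20 - n02) ** 2 + 4 * n11**2,
        (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2,
        (n30 + n12) ** 2 + (n21 + n03) ** 2,
        (n30 - 3 * n12) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
        + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2),
        (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2)
        + 4 * n11 * (n30 + n12) * (n21 + n03),
        (3 * n21 - n03) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
        - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2),
    ]


# ---------------------------------------------------------------------------
# AUC by Mann-Whitney pair counting


def auc_pair_count_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = [s for s, l in zip(scores, labels) if l == "abnormal"]
    neg = [s for s, l in zip(scores, labels) if l == "normal"]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
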