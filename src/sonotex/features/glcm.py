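"""Gray-level co-occurrence matrix (GLCM) and Haralick-style features.

The GLCM P(i, j) is the joint probability that a pixel of quantized level i
has a neighbour of level j at displacement (d, theta).  In-mask intensities
are quantized to G equal-width bins over [0, 255]; a pair is counted only
when BOTH pixels fall inside the ROI mask, so co-occurrences never cross the
liver boundary.  With ``symmetric=True`` the transposed pair is accumulated
as well (the usual Haralick convention).

Twenty-two scalar features are emitted per matrix.  Formulas follow the
standard Haralick/Soh/Clausi definitions with 1-based gray-level indices
i, j = 1..G; entropies use the natural logarithm.  ``glcm_inverse_difference``
carries the |i-j| denominator and therefore duplicates homogeneity-1, which
keeps the classical 21-feature panel intact while the two homogeneity
variants bring the count to 22.  Degenerate conventions: correlation and the
information measures are 0 when their denominators vanish, and the IMC-2
radicand is clamped at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image import GrayImage

__all__ = [
    "GLCMatrix",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "glcm_feature_vector",
    "GLCM_FEATURE_NAMES",
    "GLCM_ANGLES",
]

GLCM_ANGLES = (0, 45, 90, 135)

#: displacement (drow, dcol) per unit distance for each angle (image
#: convention: row increases downward, so 45 deg points up-right)
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = (
    "glcm_autocorrelation",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity_1",
    "glcm_homogeneity_2",
    "glcm_maximum_probability",
    "glcm_sum_of_squares",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_info_measure_corr_1",
    "glcm_info_measure_corr_2",
    "glcm_inverse_difference",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment_normalized",
)


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Quantize 8-bit intensities to ``levels`` equal-width bins over
    [0, 255]; returns 0-based level indices."""
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    return np.minimum((pixels.astype(np.int64) * levels) // 256, levels - 1)


@dataclass
class GLCMatrix:
    """Normalized co-occurrence matrix with its derived marginals."""

    P: np.ndarray
    G: int
    d: int
    theta: int
    symmetric: bool

    @property
    def p_x(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def p_y(self) -> np.ndarray:
        return self.P.sum(axis=0)

    @property
    def p_xplusy(self) -> np.ndarray:
        """p_{x+y}(k) for k = 2..2G (index 0 of the array is k=2)."""
        G = self.G
        out = np.zeros(2 * G - 1)
        i = np.arange(1, G + 1)
        s = i[:, None] + i[None, :]  # 2..2G
        np.add.at(out, (s - 2).ravel(), self.P.ravel())
        return out

    @property
    def p_xminusy(self) -> np.ndarray:
        """p_{x-y}(k) for k = 0..G-1."""
        G = self.G
        out = np.zeros(G)
        i = np.arange(G)
        dmat = np.abs(i[:, None] - i[None, :])
        np.add.at(out, dmat.ravel(), self.P.ravel())
        return out

    @property
    def mu_x(self) -> float:
        return float(np.sum(np.arange(1, self.G + 1) * self.p_x))

    @property
    def mu_y(self) -> float:
        return float(np.sum(np.arange(1, self.G + 1) * self.p_y))

    @property
    def sigma_x(self) -> float:
        i = np.arange(1, self.G + 1)
        return float(np.sqrt(np.sum((i - self.mu_x) ** 2 * self.p_x)))

    @property
    def sigma_y(self) -> float:
        i = np.arange(1, self.G + 1)
        return float(np.sqrt(np.sum((i - self.mu_y) ** 2 * self.p_y)))

    @property
    def HX(self) -> float:
        return _entropy(self.p_x)

    @property
    def HY(self) -> float:
        return _entropy(self.p_y)

    @property
    def HXY(self) -> float:
        return _entropy(self.P)

    @property
    def HXY1(self) -> float:
        prod = np.outer(self.p_x, self.p_y)
        valid = prod > 0
        return float(-np.sum(self.P[valid] * np.log(prod[valid])))

    @property
    def HXY2(self) -> float:
        return _entropy(np.outer(self.p_x, self.p_y))


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def compute_glcm(image: GrayImage, G: int = 64, d: int = 1, theta: int = 0,
                 symmetric: bool = True) -> GLCMatrix:
    """Co-occurrence matrix of the in-mask pixels at offset (d, theta)."""
    if d < 1:
        raise ValueError("distance d must be >= 1")
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {GLCM_ANGLES}")
    levels = quantize(image.pixels, G)
    mask = image.effective_mask()
    dr, dc = (o * d for o in _OFFSETS[theta])
    h, w = levels.shape

    # align source pixel (r, c) with neighbour (r + dr, c + dc)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = levels[r0:r1, c0:c1]
    dst = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]

    counts = np.zeros((G, G))
    np.add.at(counts, (src[valid], dst[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask pixel pairs at this offset")
    return GLCMatrix(counts / total, G=G, d=d, theta=theta, symmetric=symmetric)


def glcm_features(glcm: GLCMatrix) -> dict[str, float]:
    """The 22 scalar GLCM features, 1-based gray-level indexing."""
    P = glcm.P
    G = glcm.G
    i = np.arange(1, G + 1, dtype=float)
    I = i[:, None]  # noqa: E741
    J = i[None, :]
    mu_x, mu_y = glcm.mu_x, glcm.mu_y
    sigma_x, sigma_y = glcm.sigma_x, glcm.sigma_y

    autocorr = float(np.sum(I * J * P))
    contrast = float(np.sum((I - J) ** 2 * P))
    if sigma_x > 0 and sigma_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        correlation = 0.0
    prominence = float(np.sum((I + J - mu_x - mu_y) ** 4 * P))
    shade = float(np.sum((I + J - mu_x - mu_y) ** 3 * P))
    dissim = float(np.sum(np.abs(I - J) * P))
    energy = float(np.sum(P**2))
    entropy = _entropy(P)
    homog1 = float(np.sum(P / (1.0 + np.abs(I - J))))
    homog2 = float(np.sum(P / (1.0 + (I - J) ** 2)))
    maxprob = float(P.max())
    sum_sq = float(np.sum((I - mu_x) ** 2 * P))

    pxy = glcm.p_xplusy
    k_plus = np.arange(2, 2 * G + 1, dtype=float)
    sum_avg = float(np.sum(k_plus * pxy))
    sum_ent = _entropy(pxy)
    # Haralick's original sum variance is centred on the sum entropy
    sum_var = float(np.sum((k_plus - sum_ent) ** 2 * pxy))

    pxmy = glcm.p_xminusy
    k_minus = np.arange(G, dtype=float)
    mu_d = float(np.sum(k_minus * pxmy))
    diff_var = float(np.sum((k_minus - mu_d) ** 2 * pxmy))
    diff_ent = _entropy(pxmy)

    HX, HY = glcm.HX, glcm.HY
    HXY, HXY1, HXY2 = glcm.HXY, glcm.HXY1, glcm.HXY2
    denom = max(HX, HY)
    imc1 = (HXY - HXY1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))

    inv_diff = homog1
    inn = float(np.sum(P / (1.0 + np.abs(I - J) / G)))
    idmn = float(np.sum(P / (1.0 + (I - J) ** 2 / G**2)))

    values = (
        autocorr, contrast, correlation, prominence, shade, dissim, energy,
        entropy, homog1, homog2, maxprob, sum_sq, sum_avg, sum_var, sum_ent,
        diff_var, diff_ent, imc1, imc2, inv_diff, inn, idmn,
    )
    return dict(zip(GLCM_FEATURE_NAMES, values))


def glcm_feature_vector(image: GrayImage, G: int = 64, d: int = 1,
                        angles: tuple[int, ...] = GLCM_ANGLES,
                        symmetric: bool = True) -> dict[str, float]:
    """GLCM features averaged over the four standard directions."""
    acc = {name: 0.0 for name in GLCM_FEATURE_NAMES}
    for theta in angles:
        feats = glcm_features(compute_glcm(image, G=G, d=d, theta=theta,
                                           symmetric=symmetric))
        for name in GLCM_FEATURE_NAMES:
            acc[name] += feats[name]
    return {name: acc[name] / len(angles) for name in GLCM_FEATURE_NAMES}
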