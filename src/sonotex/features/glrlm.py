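"""Gray-level run-length matrix (GLRLM) and its eleven scalar features.

p(i, j) counts the maximal runs of quantized gray level i (1-based) and
length j along one of the four standard directions.  Runs are confined to
the ROI mask: a run breaks wherever the scan line leaves the mask, so runs
never bridge the liver boundary.  The eleven emphases (SRE, LRE, GLN, RLN,
RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE) are computed per direction and
averaged over the four directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ..image import GrayImage
from .glcm import quantize

__all__ = [
    "GLRLMatrix",
    "compute_glrlm",
    "compute_glrlm_all_directions",
    "glrlm_features",
    "glrlm_feature_vector",
    "GLRLM_FEATURE_NAMES",
    "GLRLM_DIRECTIONS",
]

GLRLM_DIRECTIONS = (0, 45, 90, 135)

GLRLM_FEATURE_NAMES = (
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_rln",
    "glrlm_rp",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_srlge",
    "glrlm_srhge",
    "glrlm_lrlge",
    "glrlm_lrhge",
)


@dataclass
class GLRLMatrix:
    """Run-length count matrix: rows are gray levels 1..M, columns run
    lengths 1..N_run."""

    p: np.ndarray
    M: int
    direction: int
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.p.sum())

    @property
    def max_run_length(self) -> int:
        return self.p.shape[1]


def _scan_lines(levels: np.ndarray, mask: np.ndarray, direction: int) -> Iterable[tuple[np.ndarray, np.ndarray]]:
    """Yield (levels, validity) 1-D arrays along each scan line of a
    direction."""
    h, w = levels.shape
    if direction == 0:
        for r in range(h):
            yield levels[r], mask[r]
    elif direction == 90:
        for c in range(w):
            yield levels[:, c], mask[:, c]
    elif direction == 45:
        # up-right diagonals: flip rows then take main-style diagonals
        lv, mk = levels[::-1], mask[::-1]
        for off in range(-(h - 1), w):
            yield lv.diagonal(off), mk.diagonal(off)
    elif direction == 135:
        for off in range(-(h - 1), w):
            yield levels.diagonal(off), mask.diagonal(off)
    else:
        raise ValueError(f"direction must be one of {GLRLM_DIRECTIONS}")


def compute_glrlm(image: GrayImage, M: int = 16, direction: int = 0) -> GLRLMatrix:
    """Run-length matrix of the in-mask pixels along one direction.

    All scan lines are joined with a sentinel so one vectorized run-length
    encoding covers the whole image; runs still break at mask boundaries
    and at line ends.
    """
    levels = quantize(image.pixels, M)
    mask = image.effective_mask()
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise ValueError("empty mask: no pixels to scan")
    sentinel = np.array([-1], dtype=levels.dtype)
    parts = []
    for line, valid in _scan_lines(levels, mask, direction):
        parts.append(np.where(valid, line, -1))
        parts.append(sentinel)
    coded = np.concatenate(parts)
    change = np.flatnonzero(np.diff(coded) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [coded.size]])
    keep = coded[starts] >= 0
    run_levels = coded[starts[keep]]
    run_lengths = (ends - starts)[keep]
    max_len = int(run_lengths.max())
    p = np.zeros((M, max_len))
    np.add.at(p, (run_levels, run_lengths - 1), 1.0)
    return GLRLMatrix(p=p, M=M, direction=direction, n_pixels=n_pixels)


def compute_glrlm_all_directions(image: GrayImage, M: int = 16) -> list[GLRLMatrix]:
    return [compute_glrlm(image, M=M, direction=d) for d in GLRLM_DIRECTIONS]


def _features_single(mat: GLRLMatrix) -> dict[str, float]:
    p = mat.p
    n_runs = mat.n_runs
    if n_runs == 0:
        raise ValueError("run-length matrix contains no runs")
    i = np.arange(1, p.shape[0] + 1, dtype=float)[:, None]  # gray level >= 1
    j = np.arange(1, p.shape[1] + 1, dtype=float)[None, :]  # run length
    sre = float(np.sum(p / j**2) / n_runs)
    lre = float(np.sum(j**2 * p) / n_runs)
    gln = float(np.sum(p.sum(axis=1) ** 2) / n_runs)
    rln = float(np.sum(p.sum(axis=0) ** 2) / n_runs)
    rp = float(n_runs / mat.n_pixels)
    lgre = float(np.sum(p / i**2) / n_runs)
    hgre = float(np.sum(i**2 * p) / n_runs)
    srlge = float(np.sum(p / (i**2 * j**2)) / n_runs)
    srhge = float(np.sum(i**2 * p / j**2) / n_runs)
    lrlge = float(np.sum(j**2 * p / i**2) / n_runs)
    lrhge = float(np.sum(i**2 * j**2 * p) / n_runs)
    values = (sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge)
    return dict(zip(GLRLM_FEATURE_NAMES, values))


def glrlm_features(matrices: Sequence[GLRLMatrix]) -> dict[str, float]:
    """Eleven run-length features, averaged over the supplied directional
    matrices (normally the four standard directions of one image)."""
    if not matrices:
        raise ValueError("need at least one run-length matrix")
    acc = {name: 0.0 for name in GLRLM_FEATURE_NAMES}
    for mat in matrices:
        feats = _features_single(mat)
        for name in GLRLM_FEATURE_NAMES:
            acc[name] += feats[name]
    return {name: acc[name] / len(matrices) for name in GLRLM_FEATURE_NAMES}


def glrlm_feature_vector(image: GrayImage, M: int = 16) -> dict[str, float]:
    return glrlm_features(compute_glrlm_all_directions(image, M=M))
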