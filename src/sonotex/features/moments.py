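"""Image moments and Hu's seven invariant moments.

Moments are computed over in-mask pixels with intensity as mass:
M_pq = sum x^p y^q f(x, y) with x = column, y = row and out-of-mask pixels
contributing zero.  Central moments are taken about the intensity centroid,
normalized as eta_pq = mu_pq / mu_00^(1 + (p+q)/2), and combined into Hu's
standard seven invariants, which are invariant to translation and scale and
(up to the sign of I7 under reflection) to rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image import GrayImage

__all__ = ["MomentSet", "compute_moments", "hu_moments", "IM_FEATURE_NAMES"]

IM_FEATURE_NAMES = ("im_i1", "im_i2", "im_i3", "im_i4", "im_i5", "im_i6", "im_i7")


@dataclass
class MomentSet:
    raw: dict[tuple[int, int], float]        # M_pq, p+q <= 3
    central: dict[tuple[int, int], float]    # mu_pq
    normalized: dict[tuple[int, int], float]  # eta_pq
    centroid: tuple[float, float]            # (x_bar, y_bar)
    invariants: tuple[float, ...]            # I1..I7


def compute_moments(image: GrayImage) -> MomentSet:
    mask = image.effective_mask()
    f = np.where(mask, image.pixels.astype(float), 0.0)
    total = f.sum()
    if total <= 0:
        raise ValueError("zero total intensity mass inside the mask")
    h, w = f.shape
    y = np.arange(h, dtype=float)[:, None]
    x = np.arange(w, dtype=float)[None, :]

    raw = {
        (p, q): float(np.sum(x**p * y**q * f))
        for p in range(4)
        for q in range(4)
        if p + q <= 3
    }
    x_bar = raw[(1, 0)] / raw[(0, 0)]
    y_bar = raw[(0, 1)] / raw[(0, 0)]
    xc = x - x_bar
    yc = y - y_bar
    central = {
        (p, q): float(np.sum(xc**p * yc**q * f))
        for p in range(4)
        for q in range(4)
        if p + q <= 3
    }
    mu00 = central[(0, 0)]
    eta = {
        (p, q): central[(p, q)] / mu00 ** (1.0 + (p + q) / 2.0)
        for (p, q) in central
        if p + q >= 2
    }

    n20, n02, n11 = eta[(2, 0)], eta[(0, 2)], eta[(1, 1)]
    n30, n03 = eta[(3, 0)], eta[(0, 3)]
    n21, n12 = eta[(2, 1)], eta[(1, 2)]
    i1 = n20 + n02
    i2 = (n20 - n02) ** 2 + 4 * n11**2
    i3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    i4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    i5 = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (
        3 * (n30 + n12) ** 2 - (n21 + n03) ** 2
    )
    i6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    i7 = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (
        3 * (n30 + n12) ** 2 - (n21 + n03) ** 2
    )
    return MomentSet(
        raw=raw,
        central=central,
        normalized=eta,
        centroid=(x_bar, y_bar),
        invariants=(i1, i2, i3, i4, i5, i6, i7),
    )


def hu_moments(image: GrayImage) -> dict[str, float]:
    """The seven Hu invariants as a named feature mapping."""
    ms = compute_moments(image)
    return dict(zip(IM_FEATURE_NAMES, (float(v) for v in ms.invariants)))
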