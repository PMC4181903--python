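"""First-order (intensity histogram) texture features.

Six moments of the 256-bin in-mask intensity histogram p(i): mean, standard
deviation, average energy sum p(i)^2, Shannon entropy in bits, skewness and
(non-excess) kurtosis.  Skewness and kurtosis are defined as 0 for a
constant region (sigma = 0).
"""

from __future__ import annotations

import numpy as np

from ..image import GrayImage

__all__ = ["intensity_histogram", "intensity_histogram_features", "IH_FEATURE_NAMES"]

IH_FEATURE_NAMES = (
    "ih_mean",
    "ih_standard_deviation",
    "ih_average_energy",
    "ih_entropy",
    "ih_skewness",
    "ih_kurtosis",
)


def intensity_histogram(image: GrayImage) -> np.ndarray:
    """Normalized 256-bin histogram of in-mask intensities."""
    values = image.masked_values()
    if values.size == 0:
        raise ValueError("empty mask: no pixels to histogram")
    counts = np.bincount(values.ravel(), minlength=256).astype(float)
    return counts / counts.sum()


def intensity_histogram_features(image: GrayImage) -> dict[str, float]:
    p = intensity_histogram(image)
    i = np.arange(256, dtype=float)
    mean = float(np.sum(i * p))
    var = float(np.sum((i - mean) ** 2 * p))
    std = float(np.sqrt(var))
    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    if std > 0:
        skew = float(np.sum((i - mean) ** 3 * p) / std**3)
        kurt = float(np.sum((i - mean) ** 4 * p) / std**4)
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "ih_mean": mean,
        "ih_standard_deviation": std,
        "ih_average_energy": energy,
        "ih_entropy": entropy,
        "ih_skewness": skew,
        "ih_kurtosis": kurt,
    }
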