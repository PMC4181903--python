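"""Texture-feature extraction: five named feature sets per case.

====== ===========================================  =====
set    contents                                     count
====== ===========================================  =====
IH     intensity-histogram moments                      6
GLCM   co-occurrence (Haralick) features               22
GLRLM  run-length emphases                             11
IM     Hu invariant moments                             7
MIXED  IH + GLCM + GLRLM + IM + liver length           47
====== ===========================================  =====

All sets operate strictly on in-mask pixels.  ``extract_features`` returns a
:class:`FeatureVector`; ``build_feature_table`` assembles a pandas DataFrame
(one row per case, plus ``case_id`` and ``class`` columns) ready for ARFF or
CSV serialization and for the selection / classification stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..image import GrayImage
from .glcm import (GLCM_FEATURE_NAMES, GLCMatrix, compute_glcm, glcm_feature_vector,
                   glcm_features)
from .glrlm import (GLRLM_FEATURE_NAMES, GLRLMatrix, compute_glrlm,
                    compute_glrlm_all_directions, glrlm_feature_vector,
                    glrlm_features)
from .histogram import IH_FEATURE_NAMES, intensity_histogram, intensity_histogram_features
from .moments import IM_FEATURE_NAMES, MomentSet, compute_moments, hu_moments

__all__ = [
    "FeatureVector",
    "FEATURE_SETS",
    "feature_names",
    "extract_features",
    "extract_mixed",
    "build_feature_table",
    "intensity_histogram",
    "intensity_histogram_features",
    "compute_glcm",
    "glcm_features",
    "glcm_feature_vector",
    "compute_glrlm",
    "compute_glrlm_all_directions",
    "glrlm_features",
    "glrlm_feature_vector",
    "compute_moments",
    "hu_moments",
    "GLCMatrix",
    "GLRLMatrix",
    "MomentSet",
    "IH_FEATURE_NAMES",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "IM_FEATURE_NAMES",
]

FEATURE_SETS = ("IH", "GLCM", "GLRLM", "IM", "MIXED")

_EXPECTED_CARDINALITY = {"IH": 6, "GLCM": 22, "GLRLM": 11, "IM": 7, "MIXED": 47}


def feature_names(feature_set: str) -> tuple[str, ...]:
    """Stable feature-name order for a set."""
    fs = feature_set.upper()
    if fs == "IH":
        return IH_FEATURE_NAMES
    if fs == "GLCM":
        return GLCM_FEATURE_NAMES
    if fs == "GLRLM":
        return GLRLM_FEATURE_NAMES
    if fs == "IM":
        return IM_FEATURE_NAMES
    if fs == "MIXED":
        return (IH_FEATURE_NAMES + GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES
                + IM_FEATURE_NAMES + ("liver_length",))
    raise ValueError(f"unknown feature set {feature_set!r}")


@dataclass
class FeatureVector:
    """Named numeric features of one case."""

    values: dict[str, float]
    feature_set: str
    case_id: str = ""
    binary_label: str = ""

    def __post_init__(self) -> None:
        expected = _EXPECTED_CARDINALITY[self.feature_set]
        if len(self.values) != expected:
            raise ValueError(
                f"{self.feature_set} vector must have {expected} features, "
                f"got {len(self.values)}"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


def extract_features(image: GrayImage, feature_set: str, *,
                     liver_length: float | None = None,
                     glcm_levels: int = 64, glcm_distance: int = 1,
                     glrlm_levels: int = 16,
                     case_id: str = "", binary_label: str = "") -> FeatureVector:
    """Extract one feature set from a preprocessed (masked) image."""
    fs = feature_set.upper()
    if fs == "IH":
        values = intensity_histogram_features(image)
    elif fs == "GLCM":
        values = glcm_feature_vector(image, G=glcm_levels, d=glcm_distance)
    elif fs == "GLRLM":
        values = glrlm_feature_vector(image, M=glrlm_levels)
    elif fs == "IM":
        values = hu_moments(image)
    elif fs == "MIXED":
        if liver_length is None:
            raise ValueError("the mixed set requires the per-case liver_length")
        values = {}
        values.update(intensity_histogram_features(image))
        values.update(glcm_feature_vector(image, G=glcm_levels, d=glcm_distance))
        values.update(glrlm_feature_vector(image, M=glrlm_levels))
        values.update(hu_moments(image))
        values["liver_length"] = float(liver_length)
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")
    return FeatureVector(values=values, feature_set=fs, case_id=case_id,
                         binary_label=binary_label)


def extract_mixed(image: GrayImage, liver_length: float, **kwargs) -> FeatureVector:
    """The 47-element mixed panel: all 46 texture features plus liver
    length."""
    return extract_features(image, "MIXED", liver_length=liver_length, **kwargs)


def build_feature_table(cases, feature_set: str, **kwargs) -> pd.DataFrame:
    """Feature table over labeled cases: feature columns + case_id +
    class."""
    rows = []
    for case in cases:
        fv = extract_features(
            case.image, feature_set, liver_length=case.liver_length,
            case_id=case.case_id, binary_label=case.binary_label, **kwargs
        )
        row = dict(fv.values)
        row["case_id"] = case.case_id
        row["class"] = case.binary_label
        rows.append(row)
    cols = list(feature_names(feature_set)) + ["case_id", "class"]
    return pd.DataFrame(rows, columns=cols)
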