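"""Texture features against brute-force oracles, plus invariance and
degenerate-case conventions."""

import numpy as np
import pytest

from oracles import (auc_pair_count_oracle, glcm_counts_oracle,
                     glcm_features_oracle, glrlm_features_oracle,
                     glrlm_runs_oracle, histogram_features_oracle,
                     hu_moments_oracle)
from sonotex.features import (GLCM_FEATURE_NAMES, GLRLM_FEATURE_NAMES,
                              compute_glcm, compute_glrlm,
                              compute_glrlm_all_directions, extract_features,
                              extract_mixed, glcm_features, glrlm_features,
                              hu_moments, intensity_histogram,
                              intensity_histogram_features)
from sonotex.features.glcm import quantize
from sonotex.image import GrayImage
from conftest import seeded_images

ANGLES = (0, 45, 90, 135)


# -- intensity histogram ----------------------------------------------------

def test_histogram_constant_image_degenerate_conventions():
    img = GrayImage(np.full((16, 16), 100, np.uint8))
    f = intensity_histogram_features(img)
    assert f == {"ih_mean": 100.0, "ih_standard_deviation": 0.0,
                 "ih_average_energy": 1.0, "ih_entropy": 0.0,
                 "ih_skewness": 0.0, "ih_kurtosis": 0.0}


def test_histogram_two_point_uniform():
    px = np.zeros((16, 16), np.uint8)
    px[:8] = 255
    f = intensity_histogram_features(GrayImage(px))
    assert f["ih_entropy"] == pytest.approx(1.0)
    assert f["ih_average_energy"] == pytest.approx(0.5)
    assert f["ih_mean"] == pytest.approx(127.5)


def test_histogram_matches_per_pixel_oracle():
    for img in seeded_images(5, mask_fraction=0.7, seed=3):
        ours = intensity_histogram_features(img)
        ref = histogram_features_oracle(img.masked_values())
        for k in ours:
            assert ours[k] == pytest.approx(ref[k], abs=1e-10), k


def test_histogram_entropy_bounded_by_distinct_levels(masked_random_image):
    f = intensity_histogram_features(masked_random_image)
    distinct = len(np.unique(masked_random_image.masked_values()))
    assert f["ih_entropy"] <= np.log2(distinct) + 1e-12


def test_histogram_empty_mask_rejected():
    img = GrayImage(np.zeros((16, 16), np.uint8), np.zeros((16, 16), bool))
    with pytest.raises(ValueError):
        intensity_histogram(img)


# -- GLCM -------------------------------------------------------------------

def test_glcm_constant_image_single_cell():
    img = GrayImage(np.full((16, 16), 100, np.uint8))
    glcm = compute_glcm(img, G=8, d=1, theta=0)
    k = quantize(np.array([[100]]), 8)[0, 0]
    assert glcm.P[k, k] == pytest.approx(1.0)
    f = glcm_features(glcm)
    assert f["glcm_energy"] == pytest.approx(1.0)
    assert f["glcm_entropy"] == pytest.approx(0.0)
    assert f["glcm_contrast"] == pytest.approx(0.0)
    assert f["glcm_dissimilarity"] == pytest.approx(0.0)
    assert f["glcm_maximum_probability"] == pytest.approx(1.0)
    assert f["glcm_homogeneity_2"] == pytest.approx(1.0)
    assert f["glcm_correlation"] == 0.0  # sigma = 0 convention


def test_glcm_toy_matrix_matches_pair_enumeration():
    img = GrayImage(np.array([
        [0, 0, 64, 64],
        [0, 64, 128, 128],
        [192, 192, 128, 64],
        [0, 0, 0, 64],
    ], dtype=np.uint8))
    glcm = compute_glcm(img, G=4, d=1, theta=0, symmetric=False)
    levels = quantize(img.pixels, 4)
    ref = glcm_counts_oracle(levels, np.ones((4, 4), bool), 4, 1, 0, False)
    assert np.allclose(glcm.P, ref / ref.sum(), atol=1e-15)


@pytest.mark.parametrize("theta", ANGLES)
def test_glcm_symmetric_flag_gives_symmetric_matrix(masked_random_image, theta):
    glcm = compute_glcm(masked_random_image, G=16, d=1, theta=theta, symmetric=True)
    assert np.array_equal(glcm.P, glcm.P.T)
    assert glcm.P.sum() == pytest.approx(1.0, abs=1e-12)


def test_glcm_checkerboard_closed_form():
    px = np.indices((8, 8)).sum(axis=0) % 2
    img = GrayImage((px * 255).astype(np.uint8))
    f = glcm_features(compute_glcm(img, G=2, d=1, theta=0, symmetric=True))
    assert f["glcm_contrast"] == pytest.approx(1.0)
    assert f["glcm_correlation"] == pytest.approx(-1.0)


@pytest.mark.parametrize("theta", ANGLES)
def test_glcm_features_match_double_loop_oracle(theta):
    for img in seeded_images(5, mask_fraction=0.8, seed=11):
        glcm = compute_glcm(img, G=8, d=1, theta=theta, symmetric=True)
        ours = glcm_features(glcm)
        ref = glcm_features_oracle(glcm.P)
        for k in GLCM_FEATURE_NAMES:
            assert ours[k] == pytest.approx(ref[k], rel=1e-10, abs=1e-10), k


def test_glcm_mask_too_thin_rejected():
    mask = np.zeros((16, 16), bool)
    mask[::2, ::2] = True  # isolated pixels: no adjacent in-mask pairs
    img = GrayImage(np.zeros((16, 16), np.uint8), mask)
    with pytest.raises(ValueError):
        compute_glcm(img, G=4, d=1, theta=0)


# -- GLRLM ------------------------------------------------------------------

def test_glrlm_constant_rows():
    img = GrayImage(np.full((4, 4), 200, np.uint8))
    mat = compute_glrlm(img, M=4, direction=0)
    assert mat.n_runs == 4
    assert mat.p[quantize(np.array([[200]]), 4)[0, 0], 3] == 4
    f = glrlm_features([mat])
    assert f["glrlm_sre"] == pytest.approx(1 / 16)
    assert f["glrlm_lre"] == pytest.approx(16)
    assert f["glrlm_rp"] == pytest.approx(1 / 4)


def test_glrlm_checkerboard_all_runs_length_one():
    px = (np.indices((8, 8)).sum(axis=0) % 2 * 255).astype(np.uint8)
    img = GrayImage(px)
    mat = compute_glrlm(img, M=2, direction=0)
    assert mat.n_runs == 64
    f = glrlm_features([mat])
    assert f["glrlm_sre"] == pytest.approx(1.0)
    assert f["glrlm_lre"] == pytest.approx(1.0)
    assert f["glrlm_rp"] == pytest.approx(1.0)


@pytest.mark.parametrize("direction", ANGLES)
def test_glrlm_matches_run_scanner_oracle(direction):
    for img in seeded_images(5, mask_fraction=0.7, seed=23):
        levels = quantize(img.pixels, 8)
        mat = compute_glrlm(img, M=8, direction=direction)
        runs = glrlm_runs_oracle(levels, img.effective_mask(), direction)
        # pixel-count identity per direction
        assert sum(ln for _, ln in runs) == mat.n_pixels
        assert (np.arange(1, mat.p.shape[1] + 1) * mat.p).sum() == mat.n_pixels
        ref_p = np.zeros_like(mat.p)
        for lv, ln in runs:
            ref_p[lv, ln - 1] += 1
        assert np.array_equal(mat.p, ref_p)
        ours = glrlm_features([mat])
        ref = glrlm_features_oracle(runs, mat.n_pixels)
        for k in GLRLM_FEATURE_NAMES:
            assert ours[k] == pytest.approx(ref[k], rel=1e-10), k


# -- Hu moments -------------------------------------------------------------

def test_hu_matches_explicit_loop_oracle():
    for img in seeded_images(3, mask_fraction=0.8, seed=31):
        ours = list(hu_moments(img).values())
        ref = hu_moments_oracle(img.pixels, img.effective_mask())
        assert np.allclose(ours, ref, rtol=1e-10, atol=1e-14)


def test_hu_translation_invariance(rng):
    blob = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
    base = np.zeros((64, 64), np.uint8)
    base[5:25, 5:25] = blob
    moved = np.zeros((64, 64), np.uint8)
    moved[12:32, 12:32] = blob
    a = np.array(list(hu_moments(GrayImage(base)).values()))
    b = np.array(list(hu_moments(GrayImage(moved)).values()))
    assert np.all(np.abs(a - b) / (np.abs(a) + 1e-12) < 1e-9)


def test_hu_rotation_invariance(rng):
    px = rng.integers(0, 256, size=(33, 33), dtype=np.uint8)
    a = np.array(list(hu_moments(GrayImage(px)).values()))
    b = np.array(list(hu_moments(GrayImage(np.rot90(px).copy())).values()))
    assert np.all(np.abs(a - b) / (np.abs(a) + 1e-12) < 1e-9)


def test_hu_scale_stability_under_upsampling(rng):
    px = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
    up = np.kron(px, np.ones((2, 2), dtype=np.uint8))
    a = np.array(list(hu_moments(GrayImage(px)).values()))
    b = np.array(list(hu_moments(GrayImage(up)).values()))
    assert np.all(np.abs(a - b) / (np.abs(a) + 1e-12) < 1e-2)


def test_hu_zero_mass_rejected():
    img = GrayImage(np.zeros((16, 16), np.uint8))
    with pytest.raises(ValueError):
        hu_moments(img)


# -- assembled vectors ------------------------------------------------------

def test_feature_set_cardinalities(liver_case):
    img = liver_case.image
    sizes = {fs: len(extract_features(img, fs, liver_length=14.0).values)
             for fs in ("IH", "GLCM", "GLRLM", "IM", "MIXED")}
    assert sizes == {"IH": 6, "GLCM": 22, "GLRLM": 11, "IM": 7, "MIXED": 47}
    assert sizes["IH"] + sizes["GLCM"] + sizes["GLRLM"] + sizes["IM"] == 46


def test_mixed_differs_only_in_length(liver_case):
    a = extract_mixed(liver_case.image, 12.0).values
    b = extract_mixed(liver_case.image, 18.0).values
    diff = [k for k in a if a[k] != b[k]]
    assert diff == ["liver_length"]


def test_mixed_requires_length(liver_case):
    with pytest.raises(ValueError):
        extract_features(liver_case.image, "MIXED")


def test_features_ignore_out_of_mask_pixels(liver_case, rng):
    """Poisoning every out-of-mask pixel must not move any feature."""
    clean = liver_case.image
    poisoned_px = clean.pixels.copy()
    outside = ~liver_case.mask
    poisoned_px[outside] = rng.integers(0, 256, outside.sum())
    poisoned = GrayImage(poisoned_px, liver_case.mask)
    for fs in ("IH", "GLCM", "GLRLM", "IM"):
        a = extract_features(clean, fs).values
        b = extract_features(poisoned, fs).values
        assert a == b, fs


def test_all_features_finite_on_generated_cases():
    from sonotex.synthetic import generate_dataset

    cases = generate_dataset(50, 50, 50, 50, master_seed=9, height=96, width=96)
    for case in cases:
        fv = extract_mixed(case.image, case.liver_length)
        assert all(np.isfinite(v) for v in fv.values.values())
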