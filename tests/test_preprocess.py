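"""Cropping, polygon fill, background exclusion, and the greedy snake."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation
from skimage import measure

from sonotex.image import GrayImage
from sonotex.preprocess import (Contour, SnakeConfig, background_subtract,
                                contour_to_mask, crop_roi, snake_segment)


def _disk_image(h=256, w=256, radius=50.0, center=(128.0, 128.0)):
    rr, cc = np.mgrid[0:h, 0:w]
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return GrayImage(np.where(disk, 200, 20).astype(np.uint8))


def _circle(center, radius, n=100):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([center[0] + radius * np.sin(t),
                                    center[1] + radius * np.cos(t)]))


# -- crop_roi ---------------------------------------------------------------

def test_crop_full_image_is_identity(random_image):
    out = crop_roi(random_image, (0, 0, 32, 32))
    assert np.array_equal(out.pixels, random_image.pixels)


def test_crop_coordinate_bookkeeping(rng):
    img = GrayImage(rng.integers(0, 256, size=(100, 100), dtype=np.uint8))
    out = crop_roi(img, (10, 10, 50, 40))
    assert out.shape == (50, 40)
    assert out.pixels[0, 0] == img.pixels[10, 10]
    assert out.pixels[49, 39] == img.pixels[59, 49]


def test_crop_composition(rng):
    img = GrayImage(rng.integers(0, 256, size=(80, 80), dtype=np.uint8))
    two_step = crop_roi(crop_roi(img, (5, 10, 60, 50)), (3, 2, 30, 20))
    one_step = crop_roi(img, (8, 12, 30, 20))
    assert np.array_equal(two_step.pixels, one_step.pixels)


def test_crop_out_of_bounds_raises(random_image):
    with pytest.raises(ValueError):
        crop_roi(random_image, (20, 20, 20, 20))


def test_crop_to_mask_bbox_keeps_all_mask_pixels(liver_case):
    mask = liver_case.mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    rect = (rows[0], cols[0], rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
    out = crop_roi(liver_case.image, rect)
    assert out.mask.sum() == mask.sum()


# -- contour_to_mask --------------------------------------------------------

def test_polygon_fill_matches_point_in_polygon_oracle(rng):
    import shapely.geometry as geom

    for _ in range(5):
        n = 9
        t = np.sort(rng.uniform(0, 2 * np.pi, n))
        rad = rng.uniform(8, 14, n)
        verts = np.column_stack([16 + rad * np.sin(t), 16 + rad * np.cos(t)])
        mask = contour_to_mask(Contour(verts), 32, 32)
        poly = geom.Polygon([(c, r) for r, c in verts])
        for r in range(32):
            for c in range(32):
                assert mask[r, c] == poly.contains(geom.Point(c, r)), (r, c)


def test_polygon_fill_orientation_invariant(rng):
    t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    verts = np.column_stack([16 + 10 * np.sin(t), 16 + 10 * np.cos(t)])
    fwd = contour_to_mask(Contour(verts), 32, 32)
    rev = contour_to_mask(Contour(verts[::-1]), 32, 32)
    assert np.array_equal(fwd, rev)


def test_axis_aligned_square_area():
    verts = np.array([(10.0, 10.0), (10, 15), (10, 20), (15, 20),
                      (20, 20), (20, 15), (20, 10), (15, 10)])
    mask = contour_to_mask(Contour(verts), 32, 32)
    # half-open rule: rows/cols 10..19 inclusive, 20 excluded on both axes
    assert mask.sum() == 10 * 10
    assert mask[10, 10] and mask[19, 19] and not mask[20, 10] and not mask[10, 20]


def test_degenerate_collinear_contour_rejected():
    verts = np.column_stack([np.linspace(5, 20, 8), np.full(8, 10.0)])
    with pytest.raises(ValueError):
        contour_to_mask(Contour(verts), 32, 32)


def test_too_few_vertices_rejected():
    with pytest.raises(ValueError):
        Contour(np.array([(0.0, 0), (0, 5), (5, 5), (5, 0)]))


# -- background_subtract ----------------------------------------------------

def test_all_true_mask_keeps_image(random_image):
    out = background_subtract(random_image, np.ones((32, 32), bool))
    assert np.array_equal(out.pixels, random_image.pixels)


def test_in_mask_values_unchanged_and_idempotent(liver_case):
    img = liver_case.image
    out = background_subtract(GrayImage(img.pixels), liver_case.mask)
    assert np.array_equal(out.pixels[liver_case.mask],
                          img.pixels[liver_case.mask])
    assert np.all(out.pixels[~liver_case.mask] == 0)
    again = background_subtract(out, liver_case.mask)
    assert np.array_equal(again.pixels, out.pixels)


def test_half_mask_on_constant_image_histogram(rng):
    img = GrayImage(np.full((32, 32), 99, np.uint8))
    mask = np.zeros((32, 32), bool)
    mask[:16] = True
    out = background_subtract(img, mask)
    vals = out.masked_values()
    assert np.all(vals == 99) and vals.size == 512


def test_empty_mask_rejected(random_image):
    with pytest.raises(ValueError):
        background_subtract(random_image, np.zeros((32, 32), bool))


# -- snake ------------------------------------------------------------------

def test_snake_recovers_sharp_disk_boundary():
    img = _disk_image()
    out = snake_segment(img, _circle((128, 128), 80), SnakeConfig())
    r = np.hypot(out.vertices[:, 0] - 128, out.vertices[:, 1] - 128)
    assert np.abs(r - 50.0).mean() < 2.0


def test_snake_energy_non_increasing():
    img = _disk_image()
    out = snake_segment(img, _circle((128, 128), 80), SnakeConfig())
    trace = np.asarray(out.energy_trace)
    assert np.all(np.diff(trace) <= 1e-9)


def test_snake_shrinks_on_uniform_image():
    img = GrayImage(np.full((160, 160), 77, np.uint8))
    cfg = SnakeConfig(max_iterations=40, convergence_tol=1e-6)
    out = snake_segment(img, _circle((80, 80), 55), cfg)
    init_area = _circle((80, 80), 55, n=cfg.n_vertices).area()
    trace = np.asarray(out.energy_trace)
    assert np.all(np.diff(trace) <= 1e-9)
    assert out.area() < 0.9 * init_area


def test_snake_liver_overlap_with_dilated_truth_init():
    from sonotex.synthetic import class_preset, generate_liver_image

    for seed in (1, 2):
        case = generate_liver_image(class_preset("normal", seed=seed))
        dil = binary_dilation(case.mask, iterations=8)
        boundary = measure.find_contours(dil.astype(float), 0.5)[0]
        init = Contour(boundary[:: max(1, len(boundary) // 80)])
        out = snake_segment(case.image, init, SnakeConfig())
        m = contour_to_mask(out, *case.image.shape)
        jac = (m & case.mask).sum() / (m | case.mask).sum()
        assert jac >= 0.90


def test_snake_rejects_degenerate_initial_contour():
    img = _disk_image()
    collinear = Contour(np.column_stack([np.linspace(10, 40, 8), np.full(8, 20.0)]))
    with pytest.raises(ValueError):
        snake_segment(img, collinear, SnakeConfig())


def test_snake_reports_iterations(liver_case):
    out = snake_segment(liver_case.image, _circle((64, 64), 55),
                        SnakeConfig(max_iterations=5, convergence_tol=1e-9))
    assert out.iterations_used == 5
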