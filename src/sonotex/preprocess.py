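"""ROI preprocessing: cropping, greedy active-contour (snake) segmentation,
and background exclusion.

The snake is a greedy discrete active contour: each vertex in turn moves to
the position in a local search window that minimizes the energy terms it
participates in,

    E = sum_i  alpha * |v_i - v_{i-1}|^2            (continuity)
             + beta  * |v_{i-1} - 2 v_i + v_{i+1}|^2 (curvature)
             - gamma * edge(v_i)                     (image attraction)

where ``edge`` is the normalized gradient magnitude of a Gaussian-smoothed
copy of the image (sigma = ``smoothing_sigma``), bilinearly interpolated at
sub-pixel vertex positions.  Because a vertex move is accepted only when it
lowers the sum of all terms it appears in, the total energy is non-increasing
across greedy sweeps.  On gradient-free regions the internal terms contract
the contour, which gives the deform-to-boundary behaviour of semi-automatic
snake tools without a balloon force.

"Background subtraction" here means exclusion: pixels outside the contour
are flagged (and zeroed in exported rasters) so that no downstream feature
computation ever reads them; in-mask values are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .image import GrayImage

__all__ = [
    "Contour",
    "SnakeConfig",
    "crop_roi",
    "snake_segment",
    "snake_energy",
    "contour_to_mask",
    "background_subtract",
    "inscribed_ellipse_contour",
]


@dataclass
class Contour:
    """Closed polygonal contour: ordered (row, col) vertices, sub-pixel,
    0-based."""

    vertices: np.ndarray
    closed: bool = True
    iterations_used: int | None = field(default=None, compare=False)
    energy_trace: list[float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 8:
            raise ValueError("contour needs at least 8 vertices")

    def area(self) -> float:
        """Enclosed (shoelace) area, absolute value."""
        r = self.vertices[:, 0]
        c = self.vertices[:, 1]
        return 0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))


@dataclass
class SnakeConfig:
    alpha: float = 0.10          # continuity weight
    beta: float = 0.02           # curvature weight
    gamma: float = 1.0           # image (edge) energy weight
    max_iterations: int = 500
    convergence_tol: float = 0.05  # mean vertex displacement per sweep (px)
    n_vertices: int = 60
    smoothing_sigma: float = 2.0
    search_radius: float = 1.0   # largest candidate move per vertex (px)

    def validate(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("energy weights must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.n_vertices < 8:
            raise ValueError("n_vertices must be >= 8")


def crop_roi(image: GrayImage, rect: tuple[int, int, int, int]) -> GrayImage:
    """Rectangular crop ``(top, left, height, width)``; the mask, if present,
    is cropped identically."""
    top, left, height, width = rect
    h, w = image.shape
    if height <= 0 or width <= 0:
        raise ValueError("crop height and width must be positive")
    if top < 0 or left < 0 or top + height > h or left + width > w:
        raise ValueError(f"rect {rect} outside image bounds {h}x{w}")
    sub = image.pixels[top:top + height, left:left + width]
    mask = None
    if image.mask is not None:
        mask = image.mask[top:top + height, left:left + width]
    return GrayImage(sub.copy(), None if mask is None else mask.copy())


def _resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` equally spaced vertices."""
    pts = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate contour: zero perimeter")
    t = np.linspace(0.0, total, n, endpoint=False)
    rows = np.interp(t, s, pts[:, 0])
    cols = np.interp(t, s, pts[:, 1])
    return np.column_stack([rows, cols])


def snake_energy(vertices: np.ndarray, edge_at: np.ndarray, config: SnakeConfig) -> float:
    """Total snake energy for diagnostics and the non-increase property."""
    prev = np.roll(vertices, 1, axis=0)
    nxt = np.roll(vertices, -1, axis=0)
    cont = np.sum((vertices - prev) ** 2)
    curv = np.sum((prev - 2 * vertices + nxt) ** 2)
    return float(config.alpha * cont + config.beta * curv - config.gamma * np.sum(edge_at))


def _edge_map(image: GrayImage, sigma: float) -> np.ndarray:
    smoothed = gaussian_filter(image.pixels.astype(float), sigma)
    gy, gx = np.gradient(smoothed)
    edge = np.hypot(gy, gx)
    m = edge.max()
    if m > 0:
        edge = edge / m
    return edge


def snake_segment(image: GrayImage, initial: Contour, config: SnakeConfig | None = None) -> Contour:
    """Deform ``initial`` to the strongest nearby edge by greedy energy
    minimization; returns the converged contour with ``iterations_used`` set.
    """
    config = config or SnakeConfig()
    config.validate()
    if initial.area() <= 0:
        raise ValueError("degenerate initial contour: zero enclosed area")
    h, w = image.shape
    verts = _resample_closed(initial.vertices, config.n_vertices)
    if verts[:, 0].min() < 0 or verts[:, 0].max() > h - 1 or \
       verts[:, 1].min() < 0 or verts[:, 1].max() > w - 1:
        raise ValueError("initial contour lies outside the image")

    edge = _edge_map(image, config.smoothing_sigma)

    # candidate moves: stay (first, so exact ties keep the vertex in place)
    # plus three sub-pixel rings of eight directions.  The fine rings matter:
    # the internal-energy gain of a lone-vertex move scales with the local
    # polygon sag, which is well below one pixel, so a pixel-only search
    # window would freeze the contour on gradient-free regions.
    dirs = np.array([(np.sin(t), np.cos(t))
                     for t in np.linspace(0, 2 * np.pi, 8, endpoint=False)])
    rings = [config.search_radius * f for f in (1.0, 0.5, 0.25)]
    offs = np.vstack([np.zeros((1, 2))] + [r_ * dirs for r_ in rings])
    n = len(verts)
    a, b, g = config.alpha, config.beta, config.gamma

    def total_energy() -> float:
        edge_at = map_coordinates(edge, verts.T, order=1, mode="nearest")
        return snake_energy(verts, edge_at, config)

    energy_trace = [total_energy()]
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        total_disp = 0.0
        for i in range(n):
            vm2, vm1 = verts[(i - 2) % n], verts[(i - 1) % n]
            vp1, vp2 = verts[(i + 1) % n], verts[(i + 2) % n]
            cand = verts[i] + offs
            cand[:, 0] = np.clip(cand[:, 0], 0, h - 1)
            cand[:, 1] = np.clip(cand[:, 1], 0, w - 1)
            # all energy terms that involve v_i
            cont = np.sum((cand - vm1) ** 2, axis=1) + np.sum((vp1 - cand) ** 2, axis=1)
            curv = (
                np.sum((vm2 - 2 * vm1 + cand) ** 2, axis=1)
                + np.sum((vm1 - 2 * cand + vp1) ** 2, axis=1)
                + np.sum((cand - 2 * vp1 + vp2) ** 2, axis=1)
            )
            eimg = map_coordinates(edge, cand.T, order=1, mode="nearest")
            e = a * cont + b * curv - g * eimg
            best = int(np.argmin(e))
            total_disp += float(np.linalg.norm(cand[best] - verts[i]))
            verts[i] = cand[best]
        energy_trace.append(total_energy())
        if total_disp / n < config.convergence_tol:
            break
    return Contour(verts.copy(), closed=True, iterations_used=iterations,
                   energy_trace=energy_trace)


def contour_to_mask(contour: Contour, height: int, width: int) -> np.ndarray:
    """Even-odd polygon fill: pixel centers (integer coordinates) strictly
    inside the closed contour are ``True``.  Orientation-invariant."""
    if not contour.closed:
        raise ValueError("contour must be closed")
    if contour.area() <= 0:
        raise ValueError("degenerate contour: zero enclosed area")
    verts = contour.vertices
    rows = np.arange(height, dtype=float)
    cols = np.arange(width, dtype=float)
    cc, rr = np.meshgrid(cols, rows)
    inside = np.zeros((height, width), dtype=bool)
    n = len(verts)
    for k in range(n):
        r1, c1 = verts[k]
        r2, c2 = verts[(k + 1) % n]
        if r1 == r2:
            continue
        # half-open rule in the row coordinate avoids double-counting vertices
        crosses = (np.minimum(r1, r2) <= rr) & (rr < np.maximum(r1, r2))
        c_int = c1 + (rr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (cc < c_int)
    return inside


def inscribed_ellipse_contour(height: int, width: int, n_vertices: int = 64,
                              margin: float = 0.02) -> Contour:
    """Ellipse inscribed in an image rectangle — the default automatic snake
    initialization for a cropped ROI."""
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry = (1 - margin) * (height - 1) / 2.0
    rx = (1 - margin) * (width - 1) / 2.0
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return Contour(np.column_stack([cy + ry * np.sin(t), cx + rx * np.cos(t)]))


def background_subtract(image: GrayImage, mask: np.ndarray) -> GrayImage:
    """Exclude pixels outside ``mask``: attach the mask and zero out-of-mask
    pixels in the raster.  In-mask values are unchanged; idempotent."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape:
        raise ValueError("mask dimensions must match image dimensions")
    if not mask.any():
        raise ValueError("empty mask: nothing inside the region of interest")
    pixels = image.pixels.copy()
    pixels[~mask] = 0
    return GrayImage(pixels, mask)
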