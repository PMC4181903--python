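"""Synthetic B-mode-like liver sonogram generator.

Real B-mode liver images show class-dependent echo texture: normal parenchyma
has homogeneous medium echogenicity, fatty liver is hyperechoic with fine
texture, cirrhosis is darker with an inhomogeneous/nodular surface, and
hepatomegaly is an enlargement of the organ (captured here as a per-case
liver-length scalar rather than a pixel-level change).  The generator emulates
these contrasts with a fully-developed-speckle model: the magnitude of a
complex zero-mean Gaussian scatterer field, low-pass filtered at a class
coarseness scale, has a Rayleigh-distributed envelope; scaling it sets the
mean echogenicity, and cirrhotic inhomogeneity is a low-frequency
multiplicative nodularity field.  The liver occupies a jittered convex
polygon on a dark background.

The class presets are configuration, not physics: no public accession exists
for the hospital dataset the study design refers to, so the generator is the
package's stand-in study population (30 normal / 10 fatty / 10 cirrhosis /
10 hepatomegaly by default).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull

from .image import GrayImage, write_image, write_mask

__all__ = [
    "SyntheticSpec",
    "LabeledCase",
    "CLASS_PRESETS",
    "class_preset",
    "generate_liver_image",
    "generate_envelope",
    "generate_dataset",
    "write_dataset",
]

CLASS_LABELS = ("normal", "fatty", "cirrhosis", "hepatomegaly")
ABNORMAL_LABELS = ("fatty", "cirrhosis", "hepatomegaly")

#: Fixed out-of-liver intensity; non-zero so segmentation has a gradient.
BACKGROUND_LEVEL = 8

#: Correlation length (px) of the multiplicative nodularity field.
NODULE_SCALE = 12.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic case.

    echogenicity_scale is the mean in-liver envelope amplitude before 8-bit
    quantization (arbitrary units on the 0-255 scale); coarseness is the
    speckle correlation length in pixels; nodularity_amplitude is the
    relative amplitude of the low-frequency multiplicative field (cirrhosis
    only); liver_length is a cm-equivalent scalar used by the mixed feature
    set.
    """

    class_label: str
    image_height: int = 128
    image_width: int = 128
    echogenicity_scale: float = 105.0
    coarseness: float = 1.2
    nodularity_amplitude: float = 0.0
    liver_length: float = 13.5
    seed: int = 0

    def validate(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be >= 64")
        if self.echogenicity_scale <= 0:
            raise ValueError("echogenicity_scale must be > 0")
        if self.coarseness < 0.5:
            raise ValueError("coarseness must be >= 0.5")
        if not (0.0 <= self.nodularity_amplitude < 1.0):
            raise ValueError("nodularity_amplitude must lie in [0, 1)")
        if self.liver_length <= 0:
            raise ValueError("liver_length must be > 0")


@dataclass
class LabeledCase:
    """One synthetic sonogram with ground truth."""

    image: GrayImage
    class_label: str
    binary_label: str
    liver_length: float
    seed: int
    case_id: str = ""

    def __post_init__(self) -> None:
        expected = "abnormal" if self.class_label in ABNORMAL_LABELS else "normal"
        if self.binary_label != expected:
            raise ValueError(
                f"binary_label {self.binary_label!r} inconsistent with class "
                f"{self.class_label!r}"
            )

    @property
    def mask(self) -> np.ndarray:
        return self.image.mask


# Preset magnitudes are invented (the echo-texture contrasts are qualitative
# in the clinical literature) and documented as such in docs/methods.md.
# Ordering constraints: echogenicity fatty > normal > cirrhosis; nodularity
# only for cirrhosis; hepatomegaly length > normal length.
CLASS_PRESETS: dict[str, dict[str, float]] = {
    "normal": dict(echogenicity_scale=105.0, coarseness=1.2,
                   nodularity_amplitude=0.0, liver_length=13.5, length_sd=0.8),
    "fatty": dict(echogenicity_scale=160.0, coarseness=0.8,
                  nodularity_amplitude=0.0, liver_length=14.0, length_sd=1.0),
    "cirrhosis": dict(echogenicity_scale=70.0, coarseness=2.0,
                      nodularity_amplitude=0.35, liver_length=12.5, length_sd=1.0),
    "hepatomegaly": dict(echogenicity_scale=105.0, coarseness=1.2,
                         nodularity_amplitude=0.0, liver_length=17.5, length_sd=1.0),
}


def class_preset(class_label: str, seed: int = 0, *, height: int = 128,
                 width: int = 128) -> SyntheticSpec:
    """Build the default :class:`SyntheticSpec` for a disease class."""
    if class_label not in CLASS_PRESETS:
        raise ValueError(f"unknown class_label {class_label!r}")
    p = CLASS_PRESETS[class_label]
    return SyntheticSpec(
        class_label=class_label,
        image_height=height,
        image_width=width,
        echogenicity_scale=p["echogenicity_scale"],
        coarseness=p["coarseness"],
        nodularity_amplitude=p["nodularity_amplitude"],
        liver_length=p["liver_length"],
        seed=seed,
    )


def _liver_polygon(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """Jittered convex polygon (rows, cols) covering the central image region."""
    n = 10
    cy, cx = height / 2.0, width / 2.0
    r0 = 0.40 * min(height, width)
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ang = ang + rng.uniform(-0.12, 0.12, size=n)
    rad = r0 * (1.0 + rng.uniform(-0.12, 0.12, size=n))
    pts = np.column_stack([cy + rad * np.sin(ang), cx + rad * np.cos(ang)])
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def _polygon_mask(vertices: np.ndarray, height: int, width: int) -> np.ndarray:
    # local import: preprocess depends on image only, no cycle through here
    from .preprocess import Contour, contour_to_mask

    return contour_to_mask(Contour(vertices), height, width)


def generate_envelope(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pre-quantization envelope field and liver mask for ``spec``.

    Returns ``(envelope, mask)`` where envelope is the float amplitude image
    (Rayleigh-distributed inside the mask when nodularity is zero) scaled so
    the in-mask mean equals ``echogenicity_scale``, and mask is the boolean
    liver polygon.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    verts = _liver_polygon(rng, h, w)
    mask = _polygon_mask(verts, h, w)

    # fully developed speckle: |smoothed complex Gaussian| is Rayleigh
    re = rng.standard_normal((h, w))
    im = rng.standard_normal((h, w))
    re = gaussian_filter(re, spec.coarseness)
    im = gaussian_filter(im, spec.coarseness)
    env = np.hypot(re, im)
    env *= spec.echogenicity_scale / env[mask].mean()

    if spec.nodularity_amplitude > 0:
        g = gaussian_filter(rng.standard_normal((h, w)), NODULE_SCALE)
        g /= g.std()
        nod = 1.0 + spec.nodularity_amplitude * g
        env = env * np.clip(nod, 0.1, None)
    return env, mask


def generate_liver_image(spec: SyntheticSpec) -> LabeledCase:
    """Render one labeled synthetic case; deterministic for a fixed seed."""
    env, mask = generate_envelope(spec)
    pixels = np.clip(np.rint(env), 0, 255).astype(np.uint8)
    pixels[~mask] = BACKGROUND_LEVEL
    binary = "abnormal" if spec.class_label in ABNORMAL_LABELS else "normal"
    return LabeledCase(
        image=GrayImage(pixels, mask),
        class_label=spec.class_label,
        binary_label=binary,
        liver_length=spec.liver_length,
        seed=spec.seed,
    )


def generate_dataset(
    n_normal: int = 30,
    n_fatty: int = 10,
    n_cirrhosis: int = 10,
    n_hepatomegaly: int = 10,
    master_seed: int = 0,
    *,
    height: int = 128,
    width: int = 128,
    echogenicity_jitter: float = 0.05,
) -> list[LabeledCase]:
    """Generate a labeled dataset; the default mirrors a 30-normal /
    10-fatty / 10-cirrhosis / 10-hepatomegaly study composition.

    Per-case seeds, echogenicity jitter (lognormal-free multiplicative
    Gaussian, sd ``echogenicity_jitter``) and liver-length draws all derive
    deterministically from ``master_seed``.
    """
    counts = dict(normal=n_normal, fatty=n_fatty, cirrhosis=n_cirrhosis,
                  hepatomegaly=n_hepatomegaly)
    for k, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count for {k}")
    master = np.random.default_rng(master_seed)
    cases: list[LabeledCase] = []
    idx = 0
    for label in CLASS_LABELS:
        preset = CLASS_PRESETS[label]
        for _ in range(counts[label]):
            seed = int(master.integers(0, 2**31 - 1))
            echo = preset["echogenicity_scale"] * float(
                np.clip(1.0 + echogenicity_jitter * master.standard_normal(), 0.5, 1.5)
            )
            length = float(
                max(preset["liver_length"] + preset["length_sd"] * master.standard_normal(), 1.0)
            )
            spec = SyntheticSpec(
                class_label=label,
                image_height=height,
                image_width=width,
                echogenicity_scale=echo,
                coarseness=preset["coarseness"],
                nodularity_amplitude=preset["nodularity_amplitude"],
                liver_length=length,
                seed=seed,
            )
            case = generate_liver_image(spec)
            case.case_id = f"case_{idx:03d}_{label}"
            cases.append(case)
            idx += 1
    return cases


def write_dataset(cases: list[LabeledCase], outdir: str | Path) -> Path:
    """Write images, masks and a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "class_label", "binary_label", "liver_length", "seed"])
        for case in cases:
            write_image(case.image, outdir / "images" / f"{case.case_id}.png")
            write_mask(case.mask, outdir / "masks" / f"{case.case_id}.png")
            writer.writerow(
                [case.case_id, case.class_label, case.binary_label,
                 f"{case.liver_length:.4f}", case.seed]
            )
    return manifest
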