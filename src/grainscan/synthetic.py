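"""Synthetic scanner scenes with exact per-kernel ground truth.

Emulates a flatbed scan of rice spread in a single non-overlapping layer on
a black sheet: a dark noisy background, bright convex kernels of known mm
dimensions at a known pixels-per-mm scale, an optional bright calibration
disk near the left edge, and per-kernel paint classes (plain, yellow,
chalky patch, damaged patch, paddy hull texture). Kernels are drawn as
rotated *capsules* (a rectangle with semicircular ends) so the specified
length and width are exactly the extents of the minimum-area rotated
rectangle — unambiguous ground truth for morphometry.

True weight follows a smooth volume-like law

    weight_g = c * L * W**alpha * (1 + eps),   eps ~ N(0, sigma^2), eps > -1

with defaults c = 8e-4 g/mm^3 and alpha = 2 so a nominal 6.4 x 2.0 mm
kernel weighs about 0.02 g. Every generator is deterministic under its
seed; the rendered manifest is the oracle for end-to-end evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import shapely

from .errors import InvalidInputError, SceneTooCrowdedError
from .kernel_classifier import KernelCrop
from .weight_model import WeightSample

PAINT_CLASSES = ("plain", "yellow", "chalky_patch", "damaged_patch", "paddy_texture")

# Render palette (RGB). Plain/yellow/chalky/damaged chosen so the default
# HSV ranges in colorimetry separate the classes exactly; paddy hue sits
# below the yellow band and carries hull-stripe texture.
COLOR_PLAIN = (185, 178, 165)
COLOR_YELLOW = (210, 190, 60)
COLOR_CHALK = (246, 246, 246)
COLOR_DAMAGE = (70, 45, 25)
COLOR_PADDY = (190, 150, 95)
COLOR_DISK = (235, 235, 235)

DEFAULT_WEIGHT_C = 8e-4  # g / mm^3 at alpha = 2
DEFAULT_WEIGHT_ALPHA = 2.0

# IRRI-6-like population: nominal 6.4 mm length
IRRI6_LENGTH_MEAN = 6.4
IRRI6_LENGTH_SD = 0.5
IRRI6_LENGTH_RANGE = (3.0, 8.0)
IRRI6_WIDTH_MEAN = 2.0
IRRI6_WIDTH_SD = 0.15
IRRI6_WIDTH_RANGE = (1.5, 2.6)

DEFAULT_BACKGROUND_LEVEL = 15
DEFAULT_BACKGROUND_NOISE = 3.0
DEFAULT_PPM = 12.5
DEFAULT_SCENE_SIZE = (1200, 900)  # (width, height) px
DEFAULT_MIN_SEPARATION_PX = 8.0
PLACEMENT_RETRIES = 500


def true_weight(
    length_mm: float,
    width_mm: float,
    c: float = DEFAULT_WEIGHT_C,
    alpha: float = DEFAULT_WEIGHT_ALPHA,
    eps: float = 0.0,
) -> float:
    """Ground-truth weight law c * L * W**alpha * (1 + eps)."""
    return c * length_mm * width_mm**alpha * (1.0 + eps)


@dataclass
class KernelSpec:
    """Geometry, paint class and true weight of one kernel to render."""

    length_mm: float
    width_mm: float
    rotation_deg: float = 0.0
    centroid_px: Optional[Tuple[float, float]] = None  # (x, y)
    paint_class: str = "plain"
    patch_fraction: float = 0.4  # area fraction of chalky/damaged patches
    true_weight_g: float = 0.0

    def __post_init__(self) -> None:
        if not (self.length_mm >= self.width_mm > 0):
            raise InvalidInputError(
                f"need length >= width > 0, got ({self.length_mm}, {self.width_mm})"
            )
        if self.paint_class not in PAINT_CLASSES:
            raise InvalidInputError(f"unknown paint class {self.paint_class!r}")
        if self.paint_class in ("chalky_patch", "damaged_patch") and not (
            0.0 < self.patch_fraction < 1.0
        ):
            raise InvalidInputError(
                f"patch_fraction must be in (0, 1), got {self.patch_fraction}"
            )
        if self.true_weight_g == 0.0:
            self.true_weight_g = true_weight(self.length_mm, self.width_mm)


@dataclass
class ReferenceDiskSpec:
    diameter_mm: float = 22.5
    position_px: Optional[Tuple[float, float]] = None  # default: left margin


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; deterministic under seed."""

    ppm: float = DEFAULT_PPM
    width_px: int = DEFAULT_SCENE_SIZE[0]
    height_px: int = DEFAULT_SCENE_SIZE[1]
    background_level: int = DEFAULT_BACKGROUND_LEVEL
    background_noise_sigma: float = DEFAULT_BACKGROUND_NOISE
    kernels: List[KernelSpec] = field(default_factory=list)
    reference_disk: Optional[ReferenceDiskSpec] = None
    seed: int = 0


def _capsule_polygon(k: KernelSpec, ppm: float) -> shapely.Geometry:
    half = max((k.length_mm - k.width_mm) / 2.0 * ppm, 1e-9)
    theta = np.deg2rad(k.rotation_deg)
    ux, uy = np.cos(theta), np.sin(theta)
    cx, cy = k.centroid_px
    seg = shapely.LineString(
        [(cx - half * ux, cy - half * uy), (cx + half * ux, cy + half * uy)]
    )
    return seg.buffer(k.width_mm / 2.0 * ppm, quad_segs=32)


def place_kernels(
    spec: SceneSpec,
    rng: np.random.Generator,
    min_separation_px: float = DEFAULT_MIN_SEPARATION_PX,
    keep_clear_left: bool = False,
) -> None:
    """Assign non-overlapping centroids to kernels lacking one (in place).

    Rejection-samples positions keeping every capsule fully inside the
    bounds, at least ``min_separation_px`` from every other capsule, and
    (when a reference disk is present or requested) out of the left quarter
    reserved for calibration.
    """
    placed = [
        _capsule_polygon(k, spec.ppm) for k in spec.kernels if k.centroid_px is not None
    ]
    clear_left = keep_clear_left or spec.reference_disk is not None
    x_min_edge = spec.width_px / 4.0 if clear_left else 0.0
    for k in spec.kernels:
        if k.centroid_px is not None:
            continue
        r = k.length_mm / 2.0 * spec.ppm + min_separation_px
        lo_x, hi_x = x_min_edge + r, spec.width_px - r
        lo_y, hi_y = r, spec.height_px - r
        if lo_x >= hi_x or lo_y >= hi_y:
            raise SceneTooCrowdedError("kernel too large for the scene bounds")
        for _ in range(PLACEMENT_RETRIES):
            k.centroid_px = (rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y))
            poly = _capsule_polygon(k, spec.ppm)
            if all(poly.distance(p) >= min_separation_px for p in placed):
                placed.append(poly)
                break
        else:
            raise SceneTooCrowdedError(
                f"could not place kernel after {PLACEMENT_RETRIES} tries"
            )


def sample_irri6_kernels(
    n: int,
    rng: np.random.Generator,
    class_fractions: Optional[Dict[str, float]] = None,
    rotations: Optional[Sequence[float]] = None,
    weight_noise_sigma: float = 0.0,
    patch_fraction: float = 0.4,
) -> List[KernelSpec]:
    """Draw an IRRI-6-like kernel population (lengths ~ N(6.4, 0.5^2) mm).

    ``class_fractions`` maps paint classes to fractions (remainder plain);
    assignment is by deterministic proportional counts, shuffled. With
    ``rotations`` given, orientations cycle through that list instead of
    being uniform.
    """
    if n < 0:
        raise InvalidInputError("n must be >= 0")
    lengths = _truncated_normal(rng, IRRI6_LENGTH_MEAN, IRRI6_LENGTH_SD, IRRI6_LENGTH_RANGE, n)
    widths = _truncated_normal(rng, IRRI6_WIDTH_MEAN, IRRI6_WIDTH_SD, IRRI6_WIDTH_RANGE, n)
    widths = np.minimum(widths, lengths - 1e-6)
    classes = ["plain"] * n
    if class_fractions:
        idx = 0
        for name, frac in class_fractions.items():
            if name not in PAINT_CLASSES:
                raise InvalidInputError(f"unknown paint class {name!r}")
            count = int(round(frac * n))
            for _ in range(count):
                if idx < n:
                    classes[idx] = name
                    idx += 1
        rng.shuffle(classes)
    kernels = []
    for i in range(n):
        rot = rotations[i % len(rotations)] if rotations else rng.uniform(0.0, 180.0)
        eps = 0.0
        if weight_noise_sigma > 0:
            eps = _truncated_eps(rng, weight_noise_sigma)
        kernels.append(
            KernelSpec(
                length_mm=float(lengths[i]),
                width_mm=float(widths[i]),
                rotation_deg=float(rot),
                paint_class=classes[i],
                patch_fraction=patch_fraction,
                true_weight_g=true_weight(float(lengths[i]), float(widths[i]), eps=eps),
            )
        )
    return kernels


def _truncated_normal(rng, mean, sd, bounds, n):
    out = rng.normal(mean, sd, size=n)
    bad = (out < bounds[0]) | (out > bounds[1])
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < bounds[0]) | (out > bounds[1])
    return out


def _truncated_eps(rng, sigma):
    eps = rng.normal(0.0, sigma)
    while eps <= -1.0:
        eps = rng.normal(0.0, sigma)
    return float(eps)


def build_scene_spec(
    n_kernels: int = 64,
    seed: int = 0,
    ppm: float = DEFAULT_PPM,
    size_px: Tuple[int, int] = DEFAULT_SCENE_SIZE,
    class_fractions: Optional[Dict[str, float]] = None,
    rotations: Optional[Sequence[float]] = None,
    include_reference_disk: bool = False,
    reference_diameter_mm: float = 22.5,
    weight_noise_sigma: float = 0.0,
) -> SceneSpec:
    """Sample an IRRI-6-like scene spec with non-overlapping placement."""
    rng = np.random.default_rng(seed)
    spec = SceneSpec(
        ppm=ppm,
        width_px=size_px[0],
        height_px=size_px[1],
        seed=seed,
        reference_disk=(
            ReferenceDiskSpec(diameter_mm=reference_diameter_mm)
            if include_reference_disk
            else None
        ),
    )
    spec.kernels = sample_irri6_kernels(
        n_kernels,
        rng,
        class_fractions=class_fractions,
        rotations=rotations,
        weight_noise_sigma=weight_noise_sigma,
    )
    place_kernels(spec, rng)
    return spec


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint_kernel(canvas: np.ndarray, k: KernelSpec, ppm: float) -> None:
    h, w = canvas.shape[:2]
    cx, cy = k.centroid_px
    half_ext = k.length_mm / 2.0 * ppm + 2.0
    x0, x1 = int(max(0, np.floor(cx - half_ext))), int(min(w, np.ceil(cx + half_ext)))
    y0, y1 = int(max(0, np.floor(cy - half_ext))), int(min(h, np.ceil(cy + half_ext)))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    theta = np.deg2rad(k.rotation_deg)
    ux, uy = np.cos(theta), np.sin(theta)
    dx, dy = xs - cx, ys - cy
    t = dx * ux + dy * uy  # along-axis coordinate
    half = max((k.length_mm - k.width_mm) / 2.0 * ppm, 0.0)
    tc = np.clip(t, -half, half)
    dist = np.hypot(dx - tc * ux, dy - tc * uy)
    mask = dist <= k.width_mm / 2.0 * ppm
    if not mask.any():
        return
    base = {
        "plain": COLOR_PLAIN,
        "yellow": COLOR_YELLOW,
        "chalky_patch": COLOR_PLAIN,
        "damaged_patch": COLOR_PLAIN,
        "paddy_texture": COLOR_PADDY,
    }[k.paint_class]
    patch = np.zeros_like(mask)
    if k.paint_class in ("chalky_patch", "damaged_patch"):
        cut = np.quantile(t[mask], k.patch_fraction)
        patch = mask & (t <= cut)
    region = canvas[y0:y1, x0:x1]
    region[mask] = base
    if k.paint_class == "chalky_patch":
        region[patch] = COLOR_CHALK
    elif k.paint_class == "damaged_patch":
        region[patch] = COLOR_DAMAGE
    elif k.paint_class == "paddy_texture":
        # hull striation: brightness ripple along the grain axis (~0.8 mm)
        stripe = 0.78 + 0.22 * 0.5 * (1.0 + np.sin(2.0 * np.pi * t / (0.8 * ppm)))
        region[mask] = np.clip(
            np.asarray(base, dtype=float)[None, :] * stripe[mask, None], 0, 255
        )


def render_scene(spec: SceneSpec) -> Tuple[np.ndarray, List[Dict]]:
    """Render a scene spec to an RGB uint8 image plus its truth manifest.

    Bit-identical for identical specs (noise is drawn from ``spec.seed``).
    Kernels must already have centroids (see :func:`place_kernels` /
    :func:`build_scene_spec`).
    """
    rng = np.random.default_rng(spec.seed + 1)  # rendering noise stream
    canvas = np.full(
        (spec.height_px, spec.width_px, 3), float(spec.background_level), dtype=float
    )
    if spec.reference_disk is not None:
        d = spec.reference_disk
        r_px = d.diameter_mm / 2.0 * spec.ppm
        pos = d.position_px or (r_px + 10.0, spec.height_px / 2.0)
        ys, xs = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
        canvas[np.hypot(xs - pos[0], ys - pos[1]) <= r_px] = COLOR_DISK
    manifest: List[Dict] = []
    for i, k in enumerate(spec.kernels):
        if k.centroid_px is None:
            raise InvalidInputError("kernel has no centroid; run place_kernels first")
        _paint_kernel(canvas, k, spec.ppm)
        manifest.append(
            {
                "index": i,
                "centroid_px": [float(k.centroid_px[0]), float(k.centroid_px[1])],
                "length_mm": k.length_mm,
                "width_mm": k.width_mm,
                "rotation_deg": k.rotation_deg,
                "paint_class": k.paint_class,
                "patch_fraction": (
                    k.patch_fraction
                    if k.paint_class in ("chalky_patch", "damaged_patch")
                    else None
                ),
                "true_weight_g": k.true_weight_g,
            }
        )
    if spec.background_noise_sigma > 0:
        canvas += rng.normal(0.0, spec.background_noise_sigma, size=canvas.shape)
    return np.clip(canvas, 0, 255).astype(np.uint8), manifest


def write_manifest(manifest: List[Dict], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps({"kernels": manifest}, indent=2) + "\n")


def read_manifest(path: Union[str, Path]) -> List[Dict]:
    return json.loads(Path(path).read_text())["kernels"]


# ---------------------------------------------------------------------------
# tabular + crop dataset generators
# ---------------------------------------------------------------------------

def generate_weight_dataset(
    n: int,
    c: float = DEFAULT_WEIGHT_C,
    alpha: float = DEFAULT_WEIGHT_ALPHA,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> List[WeightSample]:
    """(L, W, weight) samples on the weight law, standing in for a manually
    weighed kernel dataset."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = _truncated_normal(rng, IRRI6_LENGTH_MEAN, IRRI6_LENGTH_SD, IRRI6_LENGTH_RANGE, n)
    W = _truncated_normal(rng, IRRI6_WIDTH_MEAN, IRRI6_WIDTH_SD, IRRI6_WIDTH_RANGE, n)
    eps = np.zeros(n)
    if noise_sigma > 0:
        eps = rng.normal(0.0, noise_sigma, size=n)
        bad = eps <= -1.0
        while bad.any():
            eps[bad] = rng.normal(0.0, noise_sigma, size=int(bad.sum()))
            bad = eps <= -1.0
    return [
        WeightSample(float(L[i]), float(W[i]), true_weight(L[i], W[i], c, alpha, eps[i]))
        for i in range(n)
    ]


def generate_crop_dataset(
    n_per_class: int,
    task: str = "damaged",
    seed: int = 0,
    size: int = 64,
    ppm: float = DEFAULT_PPM,
) -> List[KernelCrop]:
    """Labelled single-kernel crops for one classification task.

    ``task`` is ``"damaged"`` (dark-patch positives vs plain negatives) or
    ``"paddy"`` (hull-textured positives vs plain negatives). Returns
    2 * n_per_class crops, positives labelled 1.
    """
    if n_per_class < 10:
        raise InvalidInputError(f"n_per_class must be >= 10, got {n_per_class}")
    if task not in ("damaged", "paddy"):
        raise InvalidInputError(f"task must be 'damaged' or 'paddy', got {task!r}")
    positive_class = "damaged_patch" if task == "damaged" else "paddy_texture"
    rng = np.random.default_rng(seed)
    crops: List[KernelCrop] = []
    for label, paint in ((1, positive_class), (0, "plain")):
        for j in range(n_per_class):
            k = sample_irri6_kernels(1, rng)[0]
            k.paint_class = paint
            if paint == "damaged_patch":
                k.patch_fraction = float(rng.uniform(0.25, 0.6))
            side = int(np.ceil(k.length_mm * ppm * 1.3))
            k.centroid_px = (side / 2.0, side / 2.0)
            scene_spec = SceneSpec(
                ppm=ppm,
                width_px=side,
                height_px=side,
                kernels=[k],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, _ = render_scene(scene_spec)
            # crop exactly the way the analysis pipeline crops detected
            # kernels, so trained models see the deployment distribution
            from .calibration import CalibrationProfile
            from .kernel_classifier import prepare_crop
            from .segmentation import GrainScene, KernelContour

            outline = np.asarray(_capsule_polygon(k, ppm).exterior.coords)
            contour = KernelContour(
                points=outline, area_px=k.length_mm * k.width_mm * ppm**2
            )
            scene = GrainScene(
                image=img, profile=CalibrationProfile(ppm=ppm, source="manual")
            )
            crop = prepare_crop(scene, contour, size=size)
            crop.label = label
            crop.origin = f"synthetic:{task}:{paint}:{j}"
            crops.append(crop)
    return crops
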