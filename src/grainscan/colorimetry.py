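"""Per-kernel yellowness / chalkiness scoring via HSV range masks.

Each kernel's pixels are converted to HSV and the fraction falling inside a
configured [lower, upper] box on all three channels is its score for that
color class. HSV is used because it decouples chromaticity from scanner
illumination. The hue channel uses the half-degree 0-179 convention
(saturation and value 0-255), the dominant scale in imaging toolchains;
ranges written for other conventions must be rescaled. Hue wraparound
(lower > upper across red) is not supported — yellow and white targets do
not need it — and is rejected at validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage import color as skcolor

from .errors import InvalidInputError

HUE_MAX = 179
SV_MAX = 255

# Calibration starting points; per-rice-type configs override these.
DEFAULT_YELLOW_RANGE = ((20, 80, 80), (35, 255, 255))
DEFAULT_CHALKY_RANGE = ((0, 0, 200), (179, 40, 255))
DEFAULT_FLAG_THRESHOLD = 0.30


@dataclass(frozen=True)
class HSVRange:
    """Inclusive HSV box: hue 0-179, saturation/value 0-255."""

    lower: Tuple[float, float, float]
    upper: Tuple[float, float, float]

    def __post_init__(self) -> None:
        lo, hi = self.lower, self.upper
        if len(lo) != 3 or len(hi) != 3:
            raise InvalidInputError("HSV bounds must have 3 components")
        bounds = (HUE_MAX, SV_MAX, SV_MAX)
        for i, (a, b, m) in enumerate(zip(lo, hi, bounds)):
            name = "HSV"[i]
            if not (0 <= a <= m and 0 <= b <= m):
                raise InvalidInputError(
                    f"{name} bounds must lie in [0, {m}], got ({a}, {b})"
                )
            if a > b:
                raise InvalidInputError(
                    f"{name} lower bound {a} exceeds upper bound {b}; hue "
                    "wraparound ranges are not supported"
                )


def rgb_to_hsv179(image: np.ndarray) -> np.ndarray:
    """RGB (uint8 or float) -> HSV on the H 0-179 / S,V 0-255 scale."""
    img = np.asarray(image)[..., :3]
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    hsv = skcolor.rgb2hsv(img)
    hsv[..., 0] *= HUE_MAX
    hsv[..., 1] *= SV_MAX
    hsv[..., 2] *= SV_MAX
    return hsv


def mask_fraction(image: np.ndarray, kernel_mask: np.ndarray, rng: HSVRange) -> float:
    """Fraction of the masked pixels whose HSV lies inside ``rng``.

    ``kernel_mask`` is a boolean raster of the same height/width as the
    image with at least one True pixel.
    """
    mask = np.asarray(kernel_mask).astype(bool)
    img = np.asarray(image)
    if mask.shape != img.shape[:2]:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match image {img.shape[:2]}"
        )
    n = int(mask.sum())
    if n == 0:
        raise InvalidInputError("kernel mask is empty")
    hsv = rgb_to_hsv179(img)[mask]
    lo = np.asarray(rng.lower, dtype=float)
    hi = np.asarray(rng.upper, dtype=float)
    inside = np.all((hsv >= lo) & (hsv <= hi), axis=1)
    return float(inside.sum()) / n


@dataclass(frozen=True)
class ColorScore:
    yellow_fraction: float
    chalky_fraction: float
    is_yellow: bool
    is_chalky: bool

    def __post_init__(self) -> None:
        for name in ("yellow_fraction", "chalky_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")


def score_kernel_color(
    image: np.ndarray,
    kernel_mask: np.ndarray,
    yellow_range: HSVRange = HSVRange(*DEFAULT_YELLOW_RANGE),
    chalky_range: HSVRange = HSVRange(*DEFAULT_CHALKY_RANGE),
    yellow_flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
    chalky_flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
) -> ColorScore:
    """Yellow/chalky fractions for one kernel, flagged against thresholds."""
    for name, t in (
        ("yellow_flag_threshold", yellow_flag_threshold),
        ("chalky_flag_threshold", chalky_flag_threshold),
    ):
        if not (0.0 < t <= 1.0):
            raise InvalidInputError(f"{name} must lie in (0, 1], got {t}")
    yf = mask_fraction(image, kernel_mask, yellow_range)
    cf = mask_fraction(image, kernel_mask, chalky_range)
    return ColorScore(
        yellow_fraction=yf,
        chalky_fraction=cf,
        is_yellow=yf >= yellow_flag_threshold,
        is_chalky=cf >= chalky_flag_threshold,
    )


def contour_mask(shape: Tuple[int, int], contour_points: np.ndarray) -> np.ndarray:
    """Filled boolean mask of a closed (x, y) contour on an image grid."""
    from skimage.draw import polygon

    pts = np.asarray(contour_points, dtype=float)
    rr, cc = polygon(pts[:, 1], pts[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask
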