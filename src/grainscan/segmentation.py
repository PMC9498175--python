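"""Kernel localisation and length/width measurement.

The pipeline mirrors classical bright-object-on-dark-sheet scanner imaging:
grayscale conversion, Gaussian smoothing, binary thresholding (Otsu by
default) and contour tracing; a Canny edge map is computed alongside for
diagnostics. Each kernel contour is enclosed in its minimum-area rotated
rectangle, the midpoints of the four box edges are joined, and the two
midpoint-to-midpoint Euclidean distances divided by the pixels-per-mm scale
give the kernel's length (larger) and width (smaller) in millimetres.

Contours are traced at sub-pixel precision (iso-level 0.5 on the binary
mask), so box extents track the true object boundary rather than the pixel
grid. Touching kernels are not split; they produce one oversized contour
which downstream sanity bounds flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
import shapely
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import feature, filters, measure

from .calibration import CalibrationProfile
from .errors import DegenerateKernelError, InvalidInputError, InvalidParameterError

DEFAULT_SMOOTHING_KERNEL = 7
DEFAULT_CANNY_THRESHOLDS = (50.0, 150.0)


@dataclass(frozen=True)
class GrainScene:
    """An RGB scanner image plus the calibration that applies to it."""

    image: np.ndarray  # uint8 HxWx3, origin top-left
    profile: CalibrationProfile
    source_path: str = ""

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] < 3 or img.shape[0] < 2 or img.shape[1] < 2:
            raise InvalidInputError(
                f"scene image must be HxWx3 with H,W >= 2, got shape {img.shape}"
            )


@dataclass
class KernelContour:
    """One segmented kernel: boundary, rotated box and its edge midpoints.

    ``points`` are (x, y) sub-pixel boundary coordinates (0-based, origin
    top-left, x rightward, y downward). ``box_corners`` holds the four
    corners of the minimum-area rotated rectangle in cyclic order starting
    from the top-left; ``edge_midpoints`` are the means of adjacent corner
    pairs in the same cyclic order.
    """

    points: np.ndarray  # (N, 2) float, (x, y)
    area_px: float
    box_corners: np.ndarray = field(default=None)  # (4, 2)
    edge_midpoints: np.ndarray = field(default=None)  # (4, 2)
    centroid: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise InvalidInputError("contour needs >= 3 (x, y) points")
        if not self.area_px > 0:
            raise InvalidInputError(f"contour area must be > 0, got {self.area_px}")
        self.points = pts
        if self.box_corners is None:
            corners = _min_area_rect(pts)
            self.box_corners = corners
        if self.edge_midpoints is None:
            self.edge_midpoints = _edge_midpoints(self.box_corners)


def _min_area_rect(points: np.ndarray) -> np.ndarray:
    """Minimum-area rotated rectangle corners, cyclic from top-left.

    The cyclic start corner is the one minimising x + y (top-left in image
    coordinates); orientation is made consistent (clockwise on screen) so
    that midpoint pairing is stable.
    """
    geom = shapely.MultiPoint(points).minimum_rotated_rectangle
    if geom.geom_type != "Polygon":  # degenerate: collinear points
        raise DegenerateKernelError("contour collapses to a line or point")
    corners = np.asarray(geom.exterior.coords)[:4]
    # shapely returns CCW in mathematical axes = CW in image axes; normalise
    e1, e2 = corners[1] - corners[0], corners[2] - corners[0]
    area2 = e1[0] * e2[1] - e1[1] * e2[0]
    if area2 < 0:
        corners = corners[::-1]
    start = int(np.argmin(corners.sum(axis=1)))
    return np.roll(corners, -start, axis=0)


def _edge_midpoints(corners: np.ndarray) -> np.ndarray:
    return 0.5 * (corners + np.roll(corners, -1, axis=0))


def _as_gray_u8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        gray = skcolor.rgb2gray(img[..., :3]) * 255.0
    elif img.dtype == np.uint8:
        gray = img.astype(float)
    else:
        gray = img.astype(float)
    return gray


def preprocess(
    image: np.ndarray,
    smoothing_kernel: int = DEFAULT_SMOOTHING_KERNEL,
    threshold: Union[str, float] = "otsu",
    canny_thresholds: Tuple[float, float] = DEFAULT_CANNY_THRESHOLDS,
    invert: bool = False,
) -> np.ndarray:
    """Grayscale -> Gaussian smoothing -> binary threshold.

    Returns a boolean raster with kernel pixels True. ``threshold`` is
    ``"otsu"`` or a fixed gray level in [0, 255]. ``invert=True`` handles
    dark objects on a bright background.
    """
    result = preprocess_debug(
        image,
        smoothing_kernel=smoothing_kernel,
        threshold=threshold,
        canny_thresholds=canny_thresholds,
        invert=invert,
    )
    return result.binary


@dataclass(frozen=True)
class PreprocessResult:
    gray: np.ndarray
    smoothed: np.ndarray
    binary: np.ndarray
    edges: np.ndarray  # Canny edge map, kept for diagnostics


def preprocess_debug(
    image: np.ndarray,
    smoothing_kernel: int = DEFAULT_SMOOTHING_KERNEL,
    threshold: Union[str, float] = "otsu",
    canny_thresholds: Tuple[float, float] = DEFAULT_CANNY_THRESHOLDS,
    invert: bool = False,
) -> PreprocessResult:
    if smoothing_kernel < 3 or smoothing_kernel % 2 == 0:
        raise InvalidParameterError(
            f"smoothing kernel size must be odd and >= 3, got {smoothing_kernel}"
        )
    gray = _as_gray_u8(image)
    # sigma chosen from the kernel size with the usual auto rule
    sigma = 0.3 * ((smoothing_kernel - 1) * 0.5 - 1) + 0.8
    smoothed = ndi.gaussian_filter(gray, sigma=sigma, truncate=(smoothing_kernel // 2) / sigma)
    if invert:
        smoothed_fg = 255.0 - smoothed
    else:
        smoothed_fg = smoothed
    if threshold == "otsu":
        if smoothed_fg.max() > smoothed_fg.min():
            level = filters.threshold_otsu(smoothed_fg)
        else:
            level = smoothed_fg.max()  # flat image: nothing above threshold
    else:
        level = float(threshold)
    binary = smoothed_fg > level
    lo, hi = canny_thresholds
    edges = feature.canny(smoothed, sigma=0.0, low_threshold=lo, high_threshold=hi)
    return PreprocessResult(gray=gray, smoothed=smoothed, binary=binary, edges=edges)


def default_min_area_px(ppm: float) -> float:
    """Dust filter: no real kernel is under 1 mm, so (1 mm * ppm)^2 pixels."""
    return float(ppm) ** 2


def find_kernels(
    binary: np.ndarray,
    min_area_px: float = 0.0,
    intensity: Optional[np.ndarray] = None,
    level: Optional[float] = None,
) -> List[KernelContour]:
    """Trace external contours of connected components above an area floor.

    Each surviving component gets a sub-pixel boundary, its minimum-area
    rotated box and edge midpoints. Components are ordered top-to-bottom
    then left-to-right by centroid.

    When the smoothed grayscale ``intensity`` is supplied, boundaries are
    traced on it at ``level`` (default: midway between the foreground and
    background median levels). A blurred step edge crosses its
    half-amplitude at the true object boundary, so this localises edges to
    sub-pixel accuracy; without it, boundaries come from the binary mask at
    half-pixel resolution.
    """
    binary = np.asarray(binary).astype(bool)
    labels, n = ndi.label(binary)
    if intensity is not None and level is None and binary.any() and not binary.all():
        level = 0.5 * (
            float(np.median(intensity[binary])) + float(np.median(intensity[~binary]))
        )
    kernels: List[KernelContour] = []
    for prop in measure.regionprops(labels):
        if prop.area < min_area_px:
            continue
        r0, c0, r1, c1 = prop.bbox
        if intensity is not None:
            pad = 3
            r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
            sub = np.array(intensity[r0p : r1 + pad, c0p : c1 + pad], dtype=float)
            # suppress neighbouring components inside the window
            other = (labels[r0p : r1 + pad, c0p : c1 + pad] != prop.label) & (
                labels[r0p : r1 + pad, c0p : c1 + pad] > 0
            )
            sub[other] = sub.min()
            contours = measure.find_contours(sub, level)
            off_r, off_c = r0p, c0p
        else:
            # pad so border-touching components still yield closed contours
            mask = np.pad(prop.image.astype(float), 1)
            contours = measure.find_contours(mask, 0.5)
            off_r, off_c = r0 - 1, c0 - 1
        if not contours:
            continue
        boundary = max(contours, key=len)
        # find_contours yields (row, col) in the local frame -> global (x, y)
        xy = np.empty_like(boundary)
        xy[:, 0] = boundary[:, 1] + off_c
        xy[:, 1] = boundary[:, 0] + off_r
        cy, cx = prop.centroid
        kernels.append(
            KernelContour(
                points=xy,
                area_px=float(prop.area),
                centroid=(float(cx), float(cy)),
            )
        )
    kernels.sort(key=lambda k: (k.centroid[1], k.centroid[0]))
    return kernels


@dataclass(frozen=True)
class KernelGeometry:
    """Physical size of one kernel: length >= width, both in mm."""

    length_mm: float
    width_mm: float
    centroid: Tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.length_mm >= self.width_mm > 0):
            raise InvalidInputError(
                f"need length >= width > 0, got ({self.length_mm}, {self.width_mm})"
            )


def measure_kernel(contour: KernelContour, profile: CalibrationProfile) -> KernelGeometry:
    """Length and width from opposite box-edge midpoint distances / ppm."""
    m = np.asarray(contour.edge_midpoints, dtype=float)
    d1 = float(np.hypot(*(m[0] - m[2])))
    d2 = float(np.hypot(*(m[1] - m[3])))
    if min(d1, d2) <= 0:
        raise DegenerateKernelError("rotated box has zero extent on one axis")
    length_mm = max(d1, d2) / profile.ppm
    width_mm = min(d1, d2) / profile.ppm
    return KernelGeometry(length_mm=length_mm, width_mm=width_mm, centroid=contour.centroid)


def draw_overlay(
    image: np.ndarray,
    kernels: List[KernelContour],
    contour_color: Tuple[int, int, int] = (255, 140, 0),
    box_color: Tuple[int, int, int] = (0, 120, 255),
    midpoint_color: Tuple[int, int, int] = (255, 0, 0),
) -> np.ndarray:
    """Annotated copy of the scene: contours, rotated boxes and midpoints."""
    from skimage.draw import disk as draw_disk
    from skimage.draw import line as draw_line

    out = np.ascontiguousarray(np.asarray(image)[..., :3].copy())
    h, w = out.shape[:2]

    def _put(rr, cc, color):
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        out[rr[ok], cc[ok]] = color

    for k in kernels:
        pts = np.round(k.points).astype(int)
        _put(pts[:, 1], pts[:, 0], contour_color)
        corners = np.round(k.box_corners).astype(int)
        for i in range(4):
            x0, y0 = corners[i]
            x1, y1 = corners[(i + 1) % 4]
            rr, cc = draw_line(y0, x0, y1, x1)
            _put(rr, cc, box_color)
        for mx, my in k.edge_midpoints:
            rr, cc = draw_disk((my, mx), 2.5, shape=(h, w))
            _put(rr, cc, midpoint_color)
    return out
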