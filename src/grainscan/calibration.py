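"""Pixel <-> millimetre calibration from a reference disk of known diameter.

A flatbed-scanner setup is calibrated with the *pixels-per-metric* (ppm)
method: an object of known physical width (by default a 22.5 mm disk placed
near the left edge of the scanner bed) is located in the image and

    ppm = reference object width in pixels / known width in mm.

All downstream millimetre measurements divide pixel distances by this scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import filters, measure

from .errors import CalibrationError, InvalidInputError

DEFAULT_REFERENCE_DIAMETER_MM = 22.5
DEFAULT_MIN_CIRCULARITY = 0.8


@dataclass(frozen=True)
class CalibrationProfile:
    """Pixel-per-millimetre scale of one scanner setup.

    Attributes
    ----------
    ppm:
        Pixels per millimetre; strictly positive.
    reference_width_mm, reference_width_px:
        The known physical width and the measured pixel width of the
        reference object, when the profile came from an image.
    source:
        ``"reference_image"`` or ``"manual"``.
    """

    ppm: float
    reference_width_mm: Optional[float] = None
    reference_width_px: Optional[float] = None
    source: str = "manual"

    def __post_init__(self) -> None:
        if not self.ppm > 0:
            raise InvalidInputError(f"ppm must be > 0, got {self.ppm}")
        if self.source not in ("reference_image", "manual"):
            raise InvalidInputError(f"unknown profile source {self.source!r}")
        if self.source == "reference_image":
            if self.reference_width_mm is None or self.reference_width_px is None:
                raise InvalidInputError(
                    "reference_image profiles require reference_width_mm and "
                    "reference_width_px"
                )
            expected = self.ppm * self.reference_width_mm
            if abs(expected - self.reference_width_px) > 1e-9 * max(
                1.0, abs(self.reference_width_px)
            ):
                raise InvalidInputError(
                    "inconsistent profile: ppm * reference_width_mm != "
                    "reference_width_px"
                )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ppm": self.ppm,
                    "reference_width_mm": self.reference_width_mm,
                    "reference_width_px": self.reference_width_px,
                    "source": self.source,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CalibrationProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            ppm=d["ppm"],
            reference_width_mm=d.get("reference_width_mm"),
            reference_width_px=d.get("reference_width_px"),
            source=d.get("source", "manual"),
        )


def compute_ppm(reference_width_px: float, known_width_mm: float) -> float:
    """Pixels-per-millimetre scale from a reference object.

    Parameters
    ----------
    reference_width_px:
        Measured pixel width of the reference object; > 0.
    known_width_mm:
        Its known physical width in millimetres; > 0.
    """
    if not reference_width_px > 0:
        raise InvalidInputError(
            f"reference_width_px must be > 0, got {reference_width_px}"
        )
    if not known_width_mm > 0:
        raise InvalidInputError(f"known_width_mm must be > 0, got {known_width_mm}")
    return reference_width_px / known_width_mm


def px_to_mm(distance_px: float, profile: CalibrationProfile) -> float:
    """Convert a pixel distance to millimetres using a calibration profile."""
    if distance_px < 0:
        raise InvalidInputError(f"distance_px must be >= 0, got {distance_px}")
    return distance_px / profile.ppm


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 0.0
    return 4.0 * np.pi * area / perimeter**2


def detect_reference_disk(
    image: np.ndarray,
    expected_diameter_mm: float = DEFAULT_REFERENCE_DIAMETER_MM,
    search_region: str = "left",
    min_circularity: float = DEFAULT_MIN_CIRCULARITY,
) -> float:
    """Locate the circular reference object and return its pixel diameter.

    The disk is assumed bright on a dark background. ``search_region`` is
    ``"left"`` (the left quarter of the image, where the reference is
    conventionally placed) or ``"full"``. Among sufficiently circular
    connected components the most circular one wins; its major-axis pixel
    extent is returned.
    """
    if expected_diameter_mm <= 0:
        raise InvalidInputError(
            f"expected_diameter_mm must be > 0, got {expected_diameter_mm}"
        )
    img = np.asarray(image)
    if img.ndim == 3:
        gray = skcolor.rgb2gray(img[..., :3])
    else:
        gray = img.astype(float) / (255.0 if img.dtype == np.uint8 else 1.0)

    if search_region == "left":
        x_limit = max(2, gray.shape[1] // 4)
    elif search_region == "full":
        x_limit = gray.shape[1]
    else:
        raise InvalidInputError(f"search_region must be 'left' or 'full', got {search_region!r}")

    if gray.max() <= gray.min():
        raise CalibrationError("no contrast in calibration image")
    thresh = filters.threshold_otsu(gray)
    binary = gray > thresh
    labels, n = ndi.label(binary)
    if n == 0:
        raise CalibrationError("no bright object found in calibration image")

    # select by centroid so a disk straddling the region edge is not clipped
    best = None
    for prop in measure.regionprops(labels):
        if prop.centroid[1] >= x_limit:
            continue
        circ = _circularity(prop.area, prop.perimeter)
        if circ >= min_circularity and (best is None or circ > best[0]):
            best = (circ, prop)
    if best is None:
        raise CalibrationError(
            f"no contour with circularity >= {min_circularity} in search region"
        )
    return float(best[1].axis_major_length)


def calibrate_from_image(
    image: np.ndarray,
    known_diameter_mm: float = DEFAULT_REFERENCE_DIAMETER_MM,
    search_region: str = "left",
    min_circularity: float = DEFAULT_MIN_CIRCULARITY,
) -> CalibrationProfile:
    """Detect the reference disk and build a ``CalibrationProfile`` from it."""
    width_px = detect_reference_disk(
        image,
        expected_diameter_mm=known_diameter_mm,
        search_region=search_region,
        min_circularity=min_circularity,
    )
    ppm = compute_ppm(width_px, known_diameter_mm)
    return CalibrationProfile(
        ppm=ppm,
        reference_width_mm=known_diameter_mm,
        reference_width_px=width_px,
        source="reference_image",
    )
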