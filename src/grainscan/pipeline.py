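"""End-to-end analysis of one scanner image, and evaluation against truth.

``analyze`` chains the whole method: preprocess -> find kernels -> measure
-> color-score -> classify (broken by threshold; damaged/paddy by trained
models when configured) -> predict weight -> summarize into a
``QualityReport``. ``evaluate_run`` scores such a run against a synthetic
ground-truth manifest by nearest-centroid matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .calibration import CalibrationProfile
from .colorimetry import contour_mask, score_kernel_color
from .config import RiceTypeConfig
from .errors import InvalidInputError
from .grading import KernelAssessment, QualityReport, assess_kernel, summarize
from .kernel_classifier import KernelClassifier, prepare_crop
from .segmentation import (
    GrainScene,
    KernelContour,
    default_min_area_px,
    draw_overlay,
    find_kernels,
    measure_kernel,
    preprocess_debug,
)
from .weight_model import WeightModel, predict_weight

logger = logging.getLogger("grainscan")


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an HxWx3 uint8 array."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.ascontiguousarray(img[..., :3])


def write_image(path: Union[str, Path], image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image))


@dataclass
class AnalysisRun:
    """One analyzed scene: inputs, per-kernel assessments and the report."""

    scene_path: str
    config: RiceTypeConfig
    profile: CalibrationProfile
    contours: List[KernelContour] = field(default_factory=list)
    assessments: List[KernelAssessment] = field(default_factory=list)
    report: Optional[QualityReport] = None
    overlay_path: Optional[str] = None
    warnings: List[str] = field(default_factory=list)


def analyze(
    image: Union[str, Path, np.ndarray],
    config: RiceTypeConfig,
    profile: CalibrationProfile,
    weight_model: Optional[WeightModel] = None,
    damaged_classifier: Optional[KernelClassifier] = None,
    paddy_classifier: Optional[KernelClassifier] = None,
    out_dir: Optional[Union[str, Path]] = None,
    count_basis: bool = False,
    sample_grams: Optional[float] = None,
    exclude_reference_region: bool = False,
    min_area_px: Optional[float] = None,
) -> AnalysisRun:
    """Run the full quality-analysis pipeline on one scene.

    Models not supplied as arguments are loaded from the paths in
    ``config`` when present; with no weight model at all, a weight
    proportional to L*W^2 is used so that percent-by-weight figures remain
    defined (flagged in the run warnings). With
    ``exclude_reference_region`` the left quarter (the calibration-disk
    area) is masked out before kernel detection. Writes ``report.json``,
    ``report.csv`` and ``overlay.png`` into ``out_dir`` when given.
    """
    if isinstance(image, (str, Path)):
        scene_path = str(image)
        img = read_image(image)
    else:
        scene_path = "<array>"
        img = np.asarray(image)
    scene = GrainScene(image=img, profile=profile, source_path=scene_path)
    run = AnalysisRun(scene_path=scene_path, config=config, profile=profile)

    if weight_model is None and config.weight_model_path:
        weight_model = WeightModel.load(config.weight_model_path)
    if damaged_classifier is None and config.damaged_model_path:
        damaged_classifier = KernelClassifier.load(config.damaged_model_path)
    if paddy_classifier is None and config.paddy_model_path:
        paddy_classifier = KernelClassifier.load(config.paddy_model_path)
    if weight_model is None:
        run.warnings.append(
            "no weight model configured; using the L*W^2 volume proxy for weights"
        )

    pre = preprocess_debug(img)
    binary = pre.binary
    if exclude_reference_region:
        binary = binary.copy()
        binary[:, : img.shape[1] // 4] = False
    if min_area_px is None:
        min_area_px = default_min_area_px(profile.ppm)
    contours = find_kernels(binary, min_area_px=min_area_px, intensity=pre.smoothed)
    run.contours = contours
    logger.info("%s: %d kernel contours", scene_path, len(contours))
    if not contours:
        run.warnings.append("empty sample: no kernels found")
        run.report = None
        return run

    for contour in contours:
        geom = measure_kernel(contour, profile)
        if geom.length_mm > config.sanity_length_mm:
            run.warnings.append(
                f"kernel at {contour.centroid} measures {geom.length_mm:.1f} mm "
                f"(> {config.sanity_length_mm} mm sanity bound); possibly touching kernels"
            )
        # score color on the contour's bounding box, not the whole scene
        pts = np.asarray(contour.points)
        x0 = max(int(np.floor(pts[:, 0].min())) - 1, 0)
        y0 = max(int(np.floor(pts[:, 1].min())) - 1, 0)
        x1 = min(int(np.ceil(pts[:, 0].max())) + 2, img.shape[1])
        y1 = min(int(np.ceil(pts[:, 1].max())) + 2, img.shape[0])
        local = pts - np.array([x0, y0])
        mask = contour_mask((y1 - y0, x1 - x0), local)
        color = score_kernel_color(
            img[y0:y1, x0:x1],
            mask,
            yellow_range=config.yellow_range,
            chalky_range=config.chalky_range,
            yellow_flag_threshold=config.yellow_flag_threshold,
            chalky_flag_threshold=config.chalky_flag_threshold,
        )
        if weight_model is not None:
            w = predict_weight(weight_model, geom.length_mm, geom.width_mm)
        else:
            w = 8e-4 * geom.length_mm * geom.width_mm**2
        is_damaged = is_paddy = False
        if damaged_classifier is not None or paddy_classifier is not None:
            crop = prepare_crop(scene, contour, size=_crop_size(damaged_classifier, paddy_classifier))
            if damaged_classifier is not None:
                is_damaged = bool(damaged_classifier.predict([crop])[0])
            if paddy_classifier is not None:
                is_paddy = bool(paddy_classifier.predict([crop])[0])
        run.assessments.append(
            assess_kernel(
                geometry=geom,
                color=color,
                predicted_weight_g=max(w, 1e-12),
                broken_threshold_mm=config.broken_threshold_mm,
                is_paddy=is_paddy,
                is_damaged=is_damaged,
            )
        )

    run.report = summarize(run.assessments, count_basis=count_basis, sample_grams=sample_grams)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        run.report.to_json(out / "report.json")
        run.report.to_csv(out / "report.csv")
        overlay = draw_overlay(img, contours)
        write_image(out / "overlay.png", overlay)
        run.overlay_path = str(out / "overlay.png")
    return run


def _crop_size(*classifiers: Optional[KernelClassifier]) -> int:
    for clf in classifiers:
        if clf is not None:
            return clf.spec.input_size
    return 224


def evaluate_run(run: AnalysisRun, manifest: Sequence[Dict]) -> Dict:
    """Score an analysis run against a ground-truth manifest.

    Manifest kernels are matched to assessments by nearest centroid (one
    to one, greedy by distance); unmatched kernels on either side count as
    detection errors. Returns count error, per-dimension MAE in mm,
    per-flag confusion counts, and the broken-percent-by-weight error in
    percentage points (truth computed from manifest weights and lengths).
    """
    if not manifest:
        raise InvalidInputError("manifest is empty")
    detected = run.assessments
    n_true, n_det = len(manifest), len(detected)
    pairs = []
    for i, m in enumerate(manifest):
        mx, my = m["centroid_px"]
        for j, a in enumerate(detected):
            ax, ay = a.geometry.centroid
            pairs.append((float(np.hypot(mx - ax, my - ay)), i, j))
    pairs.sort()
    used_m, used_d, matches = set(), set(), []
    for dist, i, j in pairs:
        if i in used_m or j in used_d:
            continue
        # a match farther than half a typical kernel length is spurious
        if dist > 0.75 * manifest[i]["length_mm"] * run.profile.ppm:
            continue
        used_m.add(i)
        used_d.add(j)
        matches.append((i, j))

    length_err, width_err = [], []
    flags = {"yellow": [0, 0, 0, 0], "chalky": [0, 0, 0, 0],
             "damaged": [0, 0, 0, 0], "paddy": [0, 0, 0, 0]}  # tp, fp, fn, tn
    for i, j in matches:
        m, a = manifest[i], detected[j]
        length_err.append(abs(a.geometry.length_mm - m["length_mm"]))
        width_err.append(abs(a.geometry.width_mm - m["width_mm"]))
        true_flags = {
            "yellow": m["paint_class"] == "yellow",
            "chalky": m["paint_class"] == "chalky_patch",
            "damaged": m["paint_class"] == "damaged_patch",
            "paddy": m["paint_class"] == "paddy_texture",
        }
        pred_flags = {
            "yellow": a.is_yellow,
            "chalky": a.is_chalky,
            "damaged": a.is_damaged,
            "paddy": a.is_paddy,
        }
        for name in flags:
            t, p = true_flags[name], pred_flags[name]
            flags[name][0 if (t and p) else 1 if (not t and p) else 2 if t else 3] += 1

    threshold = run.config.broken_threshold_mm
    true_w = np.array([m["true_weight_g"] for m in manifest])
    true_broken = np.array([m["length_mm"] < threshold for m in manifest])
    true_broken_pct = 100.0 * true_w[true_broken].sum() / true_w.sum()
    pred_broken_pct = run.report.broken_percent_by_weight if run.report else 0.0

    return {
        "n_true": n_true,
        "n_detected": n_det,
        "count_error": n_det - n_true,
        "n_matched": len(matches),
        "length_mae_mm": float(np.mean(length_err)) if length_err else float("nan"),
        "width_mae_mm": float(np.mean(width_err)) if width_err else float("nan"),
        "flag_confusions": {
            name: {"tp": v[0], "fp": v[1], "fn": v[2], "tn": v[3]}
            for name, v in flags.items()
        },
        "broken_percent_by_weight_true": float(true_broken_pct),
        "broken_percent_by_weight_pred": float(pred_broken_pct),
        "broken_percent_by_weight_error": float(pred_broken_pct - true_broken_pct),
    }
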