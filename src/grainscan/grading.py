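"""Broken/head-rice grading and the sample-level quality report.

A kernel is *broken* when its length is strictly below the rice-type's
broken-length threshold; a kernel strictly above the threshold is *head
rice* (the premium fraction). The threshold is a per-rice-type commercial
parameter, not a universal constant. The report aggregates the sample:
totals, average grain length/width (AGL/AGW), head-rice AGL, per-feature
counts and weights (yellow, chalky, damaged, paddy), and a 1-10 mm unit-bin
length histogram whose per-bin percent is expressed by *weight* (summed
predicted kernel weights over total weight), the basis the rice trade uses
for broken-grain limits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .colorimetry import ColorScore
from .errors import ConfigError, InvalidInputError
from .segmentation import KernelGeometry

HISTOGRAM_EDGES = list(range(1, 11))  # unit bins [1,2) ... [9,10)


def classify_broken(length_mm: float, broken_threshold_mm: float) -> bool:
    """True iff the kernel is broken (length strictly below the threshold).

    A length exactly equal to the threshold counts as unbroken.
    """
    if not broken_threshold_mm > 0:
        raise ConfigError(f"broken threshold must be > 0, got {broken_threshold_mm}")
    if not length_mm > 0:
        raise InvalidInputError(f"length must be > 0, got {length_mm}")
    return length_mm < broken_threshold_mm


@dataclass
class KernelAssessment:
    """Everything measured about one kernel, plus its grading flags."""

    geometry: KernelGeometry
    color: Optional[ColorScore] = None
    predicted_weight_g: float = 0.0
    is_broken: bool = False
    is_paddy: bool = False
    is_damaged: bool = False
    broken_threshold_mm: Optional[float] = None

    @property
    def is_head_rice(self) -> bool:
        """Head rice: length strictly above the broken threshold."""
        if self.broken_threshold_mm is None:
            return not self.is_broken
        return self.geometry.length_mm > self.broken_threshold_mm

    @property
    def is_yellow(self) -> bool:
        return bool(self.color and self.color.is_yellow)

    @property
    def is_chalky(self) -> bool:
        return bool(self.color and self.color.is_chalky)


def assess_kernel(
    geometry: KernelGeometry,
    color: Optional[ColorScore],
    predicted_weight_g: float,
    broken_threshold_mm: float,
    is_paddy: bool = False,
    is_damaged: bool = False,
) -> KernelAssessment:
    if not predicted_weight_g > 0:
        raise InvalidInputError(
            f"predicted weight must be > 0, got {predicted_weight_g}"
        )
    return KernelAssessment(
        geometry=geometry,
        color=color,
        predicted_weight_g=predicted_weight_g,
        is_broken=classify_broken(geometry.length_mm, broken_threshold_mm),
        is_paddy=is_paddy,
        is_damaged=is_damaged,
        broken_threshold_mm=broken_threshold_mm,
    )


@dataclass
class LengthBinRow:
    """One histogram row: [lo, hi) mm, count, mean length, percent by weight."""

    lo_mm: Optional[float]  # None for the overflow row
    hi_mm: Optional[float]
    count: int = 0
    agl_mm: float = 0.0
    percent_by_weight: float = 0.0
    percent_by_weight_unrounded: float = 0.0
    weight_g: float = 0.0

    @property
    def is_overflow(self) -> bool:
        return self.lo_mm is None

    @property
    def range_label(self) -> str:
        if self.is_overflow:
            return "outside 1-10"
        return f"({self.lo_mm:g}-{self.hi_mm:g})"


def build_histogram(
    assessments: Sequence[KernelAssessment],
    count_basis: bool = False,
) -> List[LengthBinRow]:
    """Unit-mm length histogram with per-bin AGL and percent by weight.

    Bins are [lo, lo+1) for lo = 1..9; kernels outside [1, 10) mm land in a
    trailing overflow row. Percents are rounded to 1 decimal for display
    (the unrounded column, which sums to 100, is kept alongside).
    With ``count_basis`` percents use kernel counts instead of weights.
    """
    if not assessments:
        raise InvalidInputError("cannot histogram an empty sample")
    rows = [LengthBinRow(lo_mm=float(lo), hi_mm=float(lo + 1)) for lo in HISTOGRAM_EDGES[:-1]]
    overflow = LengthBinRow(lo_mm=None, hi_mm=None)
    lengths_by_row: Dict[int, List[float]] = {i: [] for i in range(len(rows))}
    overflow_lengths: List[float] = []
    for a in assessments:
        L = a.geometry.length_mm
        w = 1.0 if count_basis else a.predicted_weight_g
        idx = int(np.floor(L)) - 1
        if 0 <= idx < len(rows) and 1.0 <= L < 10.0:
            rows[idx].count += 1
            rows[idx].weight_g += w
            lengths_by_row[idx].append(L)
        else:
            overflow.count += 1
            overflow.weight_g += w
            overflow_lengths.append(L)
    total_w = sum(r.weight_g for r in rows) + overflow.weight_g
    for i, r in enumerate(rows):
        r.agl_mm = float(np.mean(lengths_by_row[i])) if r.count else 0.0
        r.percent_by_weight_unrounded = 100.0 * r.weight_g / total_w if total_w > 0 else 0.0
        r.percent_by_weight = round(r.percent_by_weight_unrounded, 1)
    overflow.agl_mm = float(np.mean(overflow_lengths)) if overflow.count else 0.0
    overflow.percent_by_weight_unrounded = (
        100.0 * overflow.weight_g / total_w if total_w > 0 else 0.0
    )
    overflow.percent_by_weight = round(overflow.percent_by_weight_unrounded, 1)
    out = rows
    if overflow.count:
        out = rows + [overflow]
    return out


def percent_deviation(manual_agl: float, software_agl: float) -> float:
    """Percent deviation of a manual AGL from the software AGL.

    Computed as 100 * (manual - software) / software, rounded to 2
    decimals; negative when the software over-measures relative to manual.
    """
    if software_agl == 0:
        raise InvalidInputError("software AGL must be nonzero")
    return round(100.0 * (manual_agl - software_agl) / software_agl, 2)


@dataclass
class FeatureTally:
    count: int = 0
    weight_g: float = 0.0


@dataclass
class QualityReport:
    """Sample-level quality summary."""

    total_grains: int
    total_weight_g: float
    agl_mm: float
    agw_mm: float
    head_rice_agl_mm: float
    whole_count: int
    broken_count: int
    head_rice_count: int
    features: Dict[str, FeatureTally]
    histogram: List[LengthBinRow]
    broken_percent_by_weight: float = 0.0
    has_overflow_lengths: bool = False
    sample_grams: Optional[float] = None  # weighed sample mass, if recorded

    def to_dict(self) -> Dict:
        return {
            "total_grains": self.total_grains,
            "total_weight_g": round(self.total_weight_g, 6),
            "agl_mm": round(self.agl_mm, 3),
            "agw_mm": round(self.agw_mm, 3),
            "head_rice_agl_mm": round(self.head_rice_agl_mm, 3),
            "whole_count": self.whole_count,
            "broken_count": self.broken_count,
            "head_rice_count": self.head_rice_count,
            "broken_percent_by_weight": round(self.broken_percent_by_weight, 1),
            "has_overflow_lengths": self.has_overflow_lengths,
            "sample_grams": self.sample_grams,
            "features": {
                name: {"count": t.count, "weight_g": round(t.weight_g, 6)}
                for name, t in self.features.items()
            },
            "histogram": [
                {
                    "range": r.range_label,
                    "count": r.count,
                    "agl_mm": round(r.agl_mm, 3),
                    "percent_by_weight": r.percent_by_weight,
                }
                for r in self.histogram
            ],
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def to_csv(self, path: Union[str, Path]) -> None:
        """Two-section CSV: the length histogram, then the summary rows."""
        import pandas as pd

        hist = pd.DataFrame(
            [
                {
                    "Range (mm)": r.range_label,
                    "Count": r.count,
                    "Average Length (AGL)": round(r.agl_mm, 3),
                    "Percent by Weight": r.percent_by_weight,
                }
                for r in self.histogram
            ]
        )
        summary_rows = [
            ("total_grains", self.total_grains),
            ("total_weight_g", round(self.total_weight_g, 6)),
            ("agl_mm", round(self.agl_mm, 3)),
            ("agw_mm", round(self.agw_mm, 3)),
            ("head_rice_agl_mm", round(self.head_rice_agl_mm, 3)),
            ("whole_count", self.whole_count),
            ("broken_count", self.broken_count),
            ("head_rice_count", self.head_rice_count),
            ("broken_percent_by_weight", round(self.broken_percent_by_weight, 1)),
        ]
        for name, t in self.features.items():
            summary_rows.append((f"{name}_count", t.count))
            summary_rows.append((f"{name}_weight_g", round(t.weight_g, 6)))
        summary = pd.DataFrame(summary_rows, columns=["Field", "Value"])
        with open(path, "w") as fh:
            hist.to_csv(fh, index=False)
            fh.write("\n")
            summary.to_csv(fh, index=False)


def summarize(
    assessments: Sequence[KernelAssessment],
    count_basis: bool = False,
    sample_grams: Optional[float] = None,
) -> QualityReport:
    """Aggregate per-kernel assessments into a ``QualityReport``.

    AGL/AGW are unweighted means; feature counts are non-exclusive (a
    kernel can be both yellow and broken); feature weights sum predicted
    weights over flagged kernels.
    """
    if not assessments:
        raise InvalidInputError("cannot summarize an empty sample")
    lengths = np.array([a.geometry.length_mm for a in assessments])
    widths = np.array([a.geometry.width_mm for a in assessments])
    weights = np.array([a.predicted_weight_g for a in assessments])
    broken = np.array([a.is_broken for a in assessments])
    head = np.array([a.is_head_rice for a in assessments])
    total_w = float(weights.sum())

    features: Dict[str, FeatureTally] = {}
    for name, flag in (
        ("yellow", [a.is_yellow for a in assessments]),
        ("chalky", [a.is_chalky for a in assessments]),
        ("damaged", [a.is_damaged for a in assessments]),
        ("paddy", [a.is_paddy for a in assessments]),
    ):
        flag = np.array(flag)
        features[name] = FeatureTally(
            count=int(flag.sum()), weight_g=float(weights[flag].sum())
        )

    hist = build_histogram(assessments, count_basis=count_basis)
    if count_basis:
        broken_pct = 100.0 * broken.sum() / len(assessments)
    else:
        broken_pct = 100.0 * float(weights[broken].sum()) / total_w if total_w > 0 else 0.0
    return QualityReport(
        total_grains=len(assessments),
        total_weight_g=total_w,
        agl_mm=float(lengths.mean()),
        agw_mm=float(widths.mean()),
        head_rice_agl_mm=float(lengths[head].mean()) if head.any() else 0.0,
        whole_count=int((~broken).sum()),
        broken_count=int(broken.sum()),
        head_rice_count=int(head.sum()),
        features=features,
        histogram=hist,
        broken_percent_by_weight=broken_pct,
        has_overflow_lengths=any(r.is_overflow for r in hist),
        sample_grams=sample_grams,
    )
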