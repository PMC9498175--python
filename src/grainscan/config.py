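"""Per-rice-type configuration.

Every trader grades against its own standards (broken-length threshold,
color bands, flag fractions), so all grading parameters live in one YAML
document per rice type. Shipped presets cover six common Pakistani
commercial varieties with illustrative, NON-normative thresholds; real
deployments tune them per contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import List, Optional, Union

import yaml

from .colorimetry import (
    DEFAULT_CHALKY_RANGE,
    DEFAULT_FLAG_THRESHOLD,
    DEFAULT_YELLOW_RANGE,
    HSVRange,
)
from .errors import ConfigError

DEFAULT_SANITY_LENGTH_MM = 15.0


@dataclass
class RiceTypeConfig:
    """All tunable grading parameters for one rice type."""

    name: str
    broken_threshold_mm: float
    yellow_range: HSVRange = field(default_factory=lambda: HSVRange(*DEFAULT_YELLOW_RANGE))
    chalky_range: HSVRange = field(default_factory=lambda: HSVRange(*DEFAULT_CHALKY_RANGE))
    yellow_flag_threshold: float = DEFAULT_FLAG_THRESHOLD
    chalky_flag_threshold: float = DEFAULT_FLAG_THRESHOLD
    sanity_length_mm: float = DEFAULT_SANITY_LENGTH_MM
    reference_diameter_mm: float = 22.5
    weight_model_path: Optional[str] = None
    damaged_model_path: Optional[str] = None
    paddy_model_path: Optional[str] = None

    def __post_init__(self) -> None:
        for nm in (
            "broken_threshold_mm",
            "yellow_flag_threshold",
            "chalky_flag_threshold",
            "sanity_length_mm",
            "reference_diameter_mm",
        ):
            if not getattr(self, nm) > 0:
                raise ConfigError(f"{nm} must be > 0, got {getattr(self, nm)}")
        for nm in ("weight_model_path", "damaged_model_path", "paddy_model_path"):
            p = getattr(self, nm)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{nm} references missing file {p!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RiceTypeConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RiceTypeConfig":
        try:
            yr = d.get("yellow_range")
            cr = d.get("chalky_range")
            return cls(
                name=d["name"],
                broken_threshold_mm=float(d["broken_threshold_mm"]),
                yellow_range=(
                    HSVRange(tuple(yr["lower"]), tuple(yr["upper"]))
                    if yr
                    else HSVRange(*DEFAULT_YELLOW_RANGE)
                ),
                chalky_range=(
                    HSVRange(tuple(cr["lower"]), tuple(cr["upper"]))
                    if cr
                    else HSVRange(*DEFAULT_CHALKY_RANGE)
                ),
                yellow_flag_threshold=float(
                    d.get("yellow_flag_threshold", DEFAULT_FLAG_THRESHOLD)
                ),
                chalky_flag_threshold=float(
                    d.get("chalky_flag_threshold", DEFAULT_FLAG_THRESHOLD)
                ),
                sanity_length_mm=float(d.get("sanity_length_mm", DEFAULT_SANITY_LENGTH_MM)),
                reference_diameter_mm=float(d.get("reference_diameter_mm", 22.5)),
                weight_model_path=d.get("weight_model_path"),
                damaged_model_path=d.get("damaged_model_path"),
                paddy_model_path=d.get("paddy_model_path"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid rice-type config: {exc}") from exc

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = {
            "name": self.name,
            "broken_threshold_mm": self.broken_threshold_mm,
            "yellow_range": {
                "lower": list(self.yellow_range.lower),
                "upper": list(self.yellow_range.upper),
            },
            "chalky_range": {
                "lower": list(self.chalky_range.lower),
                "upper": list(self.chalky_range.upper),
            },
            "yellow_flag_threshold": self.yellow_flag_threshold,
            "chalky_flag_threshold": self.chalky_flag_threshold,
            "sanity_length_mm": self.sanity_length_mm,
            "reference_diameter_mm": self.reference_diameter_mm,
            "weight_model_path": self.weight_model_path,
            "damaged_model_path": self.damaged_model_path,
            "paddy_model_path": self.paddy_model_path,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def list_presets() -> List[str]:
    pkg = resources.files("grainscan") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> RiceTypeConfig:
    """Load a shipped per-variety preset (see :func:`list_presets`)."""
    pkg = resources.files("grainscan") / "presets" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise ConfigError(f"no preset named {name!r}; available: {list_presets()}")
    return RiceTypeConfig.from_dict(yaml.safe_load(text))
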