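"""Per-kernel weight prediction from length and width.

The rice trade expresses broken-grain limits as a percent *by weight*, so
each segmented kernel needs a weight estimate. A random-forest regressor is
fit on manually weighed kernels with (length_mm, width_mm) as the feature
matrix, using a shuffled 80/20 holdout; fit quality is reported as RMSE
(grams) and MAPE (percent) on the held-out split:

    RMSE = sqrt( (1/n) * sum_i (A_i - B_i)^2 )
    MAPE = (100/n) * sum_i |A_i - B_i| / A_i

with A the actual and B the predicted weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .errors import InvalidInputError, NotFittedError

MODEL_FORMAT_VERSION = 1


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error between actual and predicted values."""
    a = np.asarray(actual, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError(
            f"actual and predicted must be equal-length vectors, got {a.shape} vs {b.shape}"
        )
    if a.size == 0:
        raise InvalidInputError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mape(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent of the actual values."""
    a = np.asarray(actual, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError(
            f"actual and predicted must be equal-length vectors, got {a.shape} vs {b.shape}"
        )
    if a.size == 0:
        raise InvalidInputError("mape of empty vectors is undefined")
    if np.any(a == 0):
        raise InvalidInputError("mape undefined when an actual value is 0")
    return float(100.0 * np.mean(np.abs(a - b) / np.abs(a)))


@dataclass(frozen=True)
class WeightSample:
    """One manually weighed kernel."""

    length_mm: float
    width_mm: float
    weight_g: float

    def __post_init__(self) -> None:
        for name in ("length_mm", "width_mm", "weight_g"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class WeightModel:
    """A fitted (length, width) -> grams forest plus its holdout metrics."""

    n_estimators: int = 100
    seed: int = 0
    metrics: Dict[str, float] = field(default_factory=dict)
    estimator: Optional[RandomForestRegressor] = None

    @property
    def fitted(self) -> bool:
        return self.estimator is not None and hasattr(self.estimator, "estimators_")

    def save(self, path: Union[str, Path]) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "n_estimators": self.n_estimators,
                "seed": self.seed,
                "metrics": self.metrics,
                "estimator_params": self.estimator.get_params() if self.estimator else None,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "WeightModel":
        d = joblib.load(path)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise InvalidInputError(
                f"unsupported weight model format {d.get('format_version')}"
            )
        return cls(
            n_estimators=d["n_estimators"],
            seed=d["seed"],
            metrics=d["metrics"],
            estimator=d["estimator"],
        )


def train_weight_model(
    samples: Sequence[WeightSample],
    n_estimators: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> WeightModel:
    """Shuffle, split, fit the forest, and record holdout RMSE/MAPE.

    Requires at least 10 samples and 0 < train_fraction < 1; identical
    samples and seed reproduce identical metrics.
    """
    if len(samples) < 10:
        raise InvalidInputError(f"need >= 10 weight samples, got {len(samples)}")
    if not (0.0 < train_fraction < 1.0):
        raise InvalidInputError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if n_estimators < 1:
        raise InvalidInputError(f"n_estimators must be >= 1, got {n_estimators}")
    X = np.array([[s.length_mm, s.width_mm] for s in samples])
    y = np.array([s.weight_g for s in samples])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed, shuffle=True
    )
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    forest.fit(X_tr, y_tr)
    pred = forest.predict(X_te)
    model = WeightModel(
        n_estimators=n_estimators,
        seed=seed,
        metrics={"rmse": rmse(y_te, pred), "mape": mape(y_te, pred)},
        estimator=forest,
    )
    return model


def predict_weight(model: WeightModel, length_mm: float, width_mm: float) -> float:
    """Predicted kernel weight in grams."""
    if not model.fitted:
        raise NotFittedError("weight model is not fitted")
    if not (length_mm > 0 and width_mm > 0):
        raise InvalidInputError(
            f"length and width must be > 0, got ({length_mm}, {width_mm})"
        )
    return float(model.estimator.predict([[length_mm, width_mm]])[0])


def load_samples_csv(path: Union[str, Path]) -> List[WeightSample]:
    """Read a samples CSV with columns length_mm, width_mm, weight_g."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"length_mm", "width_mm", "weight_g"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"samples CSV missing columns {sorted(missing)}")
    return [
        WeightSample(r.length_mm, r.width_mm, r.weight_g)
        for r in df.itertuples(index=False)
    ]
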