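"""Error and agreement statistics for pKa prediction tables.

Conventions: signed error = predicted - observed; s.d. is the sample
(n-1) standard deviation of the *absolute* errors; two squared-correlation
flavours are exposed because they answer different questions —
``r2_pearson_sq`` (squared Pearson r of observed vs predicted, the
external-validation statistic) and ``r2_train`` (coefficient of
determination 1 - SS_res/SS_tot, the training-fit statistic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "mae", "rmse", "sd_abs", "r2_pearson_sq", "r2_train",
    "count_exceeding", "ModelReport",
]


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size:
        raise ValueError(f"length mismatch: {o.size} observed vs {p.size} predicted")
    if o.size == 0:
        raise ValueError("empty input")
    return o, p


def mae(observed, predicted) -> float:
    """Mean absolute error in pKa units."""
    o, p = _paired(observed, predicted)
    return float(np.mean(np.abs(p - o)))


def rmse(observed, predicted) -> float:
    """Root-mean-squared error in pKa units."""
    o, p = _paired(observed, predicted)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def sd_abs(observed, predicted) -> float:
    """Sample standard deviation (n-1) of the absolute errors."""
    o, p = _paired(observed, predicted)
    if o.size < 2:
        raise ValueError("need at least 2 pairs")
    return float(np.std(np.abs(p - o), ddof=1))


def r2_pearson_sq(observed, predicted) -> float:
    """Squared Pearson correlation of observed vs predicted."""
    o, p = _paired(observed, predicted)
    if o.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(o) == 0.0 or np.ptp(p) == 0.0:
        raise ValueError("zero variance")
    return float(np.corrcoef(o, p)[0, 1] ** 2)


def r2_train(observed, fitted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative)."""
    o, f = _paired(observed, fitted)
    if o.size < 3:
        raise ValueError("need at least 3 pairs")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero variance in observed values")
    return 1.0 - float(np.sum((o - f) ** 2)) / ss_tot


def count_exceeding(observed, predicted, threshold: float) -> int:
    """Number of absolute errors strictly greater than ``threshold``."""
    o, p = _paired(observed, predicted)
    return int(np.sum(np.abs(p - o) > threshold))


@dataclass
class ModelReport:
    """Per-compound predictions with summary statistics for one method."""

    method: str
    ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if not (len(self.ids) == self.observed.size == self.predicted.size):
            raise ValueError("ids, observed and predicted must align")

    @property
    def n(self) -> int:
        return self.observed.size

    @property
    def signed_errors(self) -> np.ndarray:
        return self.predicted - self.observed

    def summary(self) -> dict[str, float]:
        out = {"mae": mae(self.observed, self.predicted),
               "rmse": rmse(self.observed, self.predicted),
               "sd_abs": sd_abs(self.observed, self.predicted),
               "n": self.n}
        try:
            out["r2_pearson_sq"] = r2_pearson_sq(self.observed, self.predicted)
        except ValueError:
            out["r2_pearson_sq"] = float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "observed": self.observed,
            "predicted": self.predicted, "signed_error": self.signed_errors,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path) -> None:
        payload = {"method": self.method, "summary": self.summary(),
                   "rows": self.to_frame().to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
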