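"""Fit statistics between predicted and observed peak bloom dates.

Errors are ``e = predicted − observed`` in days (day-of-year scale), so a
positive bias means the model predicts later bloom than observed.  ``r²``
is the squared Pearson correlation of predictions and observations, the
convention common in phenology-model evaluation; it is undefined (NaN) when
either series is constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["FitStatistics", "evaluate"]


@dataclass(frozen=True)
class FitStatistics:
    rmse: float
    mae: float
    bias: float
    r2: float  # NaN when undefined (constant series)
    n: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "bias": self.bias,
            "r2": None if np.isnan(self.r2) else self.r2,
            "n": self.n,
        }


def evaluate(pred: Sequence[float], obs: Sequence[float]) -> FitStatistics:
    """RMSE, MAE, bias and r² between aligned predicted and observed DOY.

    Raises on empty input or length mismatch; pairs must be aligned by
    season.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError(f"pred and obs must be equal-length 1-D, got {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    e = p - o
    rmse = float(np.sqrt(np.mean(e**2)))
    mae = float(np.mean(np.abs(e)))
    bias = float(np.mean(e))
    if p.size < 2 or np.all(p == p[0]) or np.all(o == o[0]):
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    return FitStatistics(rmse=rmse, mae=mae, bias=bias, r2=r2, n=int(p.size))
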