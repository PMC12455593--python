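"""Fit metrics: RMSE, its systematic/unsystematic decomposition, and
Willmott's index of agreement.

With predictions P and observations O, the least-squares line of P on O,
P_hat = a + b*O, splits the error into a systematic part
RMSEs = sqrt(mean (P_hat - O)^2) and an unsystematic part
RMSEu = sqrt(mean (P - P_hat)^2); OLS orthogonality makes
RMSEs^2 + RMSEu^2 = RMSE^2 an exact identity. The index of agreement
d = 1 - sum (P-O)^2 / sum (|P - Obar| + |O - Obar|)^2 lies in [0, 1]
(triangle inequality), with d := 1 when the denominator vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["FitReport", "rmse", "willmott_decomposition", "index_of_agreement", "evaluate"]


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty data")
    return arr


def rmse(predictions, observations) -> float:
    p, o = _as_1d(predictions), _as_1d(observations)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def willmott_decomposition(predictions, observations) -> tuple[float, float, float]:
    """Return (rmse, rmse_s, rmse_u) from the OLS line of P on O."""
    p, o = _as_1d(predictions), _as_1d(observations)
    var_o = np.var(o)
    if var_o == 0.0:
        b = 0.0
        a = float(np.mean(p))
    else:
        b = float(np.cov(p, o, bias=True)[0, 1] / var_o)
        a = float(np.mean(p) - b * np.mean(o))
    p_hat = a + b * o
    rmse_s = float(np.sqrt(np.mean((p_hat - o) ** 2)))
    rmse_u = float(np.sqrt(np.mean((p - p_hat) ** 2)))
    return rmse(p, o), rmse_s, rmse_u


def index_of_agreement(predictions, observations) -> float:
    p, o = _as_1d(predictions), _as_1d(observations)
    o_bar = np.mean(o)
    denom = np.sum((np.abs(p - o_bar) + np.abs(o - o_bar)) ** 2)
    if denom == 0.0:
        return 1.0
    return float(1.0 - np.sum((p - o) ** 2) / denom)


@dataclass
class FitReport:
    """Evaluation of one model on one split."""

    model: str
    split: str
    rmse: float
    rmse_s: float
    rmse_u: float
    d: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(model, X, y, split: str = "test", name: str | None = None) -> FitReport:
    """Score a fitted model on (X, y) with the full metric set."""
    y_arr = _as_1d(y)
    if len(X) != y_arr.size:
        raise ValueError("X and y length mismatch")
    p = np.asarray(model.predict(X), dtype=float).ravel()
    r, r_s, r_u = willmott_decomposition(p, y_arr)
    return FitReport(
        model=name or getattr(model, "name", type(model).__name__),
        split=split,
        rmse=r,
        rmse_s=r_s,
        rmse_u=r_u,
        d=index_of_agreement(p, y_arr),
        n=int(y_arr.size),
    )


def reports_to_frame(reports: list[FitReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])
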