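"""Regression evaluation: r, RMSEP, RPD and relative improvements.

RPD is the ratio of the standard deviation of the evaluation set's
measured reference values (n-1 denominator) to the RMSEP; values above ~3
are conventionally read as good quantitative prediction.  The same RMSE
implementation backs both the cross-validated calibration error used for
model selection and the held-out prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvaluationReport", "rmse", "evaluate", "improvement_pct"]


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error — single source of truth for RMSECV/RMSEP."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between measured and predicted values")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


@dataclass
class EvaluationReport:
    r: float
    rmsep: float
    rpd: float
    n: int
    split: str = "prediction"
    scale: str = "transformed"

    def as_dict(self) -> dict:
        return {"r": self.r, "rmsep": self.rmsep, "rpd": self.rpd,
                "n": self.n, "split": self.split, "scale": self.scale}


def evaluate(y_measured: np.ndarray, y_predicted: np.ndarray,
             split: str = "prediction", scale: str = "transformed") -> EvaluationReport:
    """Pearson r, RMSEP and RPD of predictions against measured values."""
    y_measured = np.asarray(y_measured, dtype=float)
    y_predicted = np.asarray(y_predicted, dtype=float)
    if y_measured.shape != y_predicted.shape:
        raise ValueError("length mismatch between measured and predicted values")
    n = y_measured.size
    if n < 3:
        raise ValueError("need at least 3 samples to evaluate")
    sd = float(np.std(y_measured, ddof=1))
    if sd == 0.0:
        raise ValueError("constant measured values: r and RPD are undefined")
    err = rmse(y_measured, y_predicted)
    if np.std(y_predicted) == 0.0:
        r = 0.0  # constant predictions carry no correlation
    else:
        r = float(np.corrcoef(y_measured, y_predicted)[0, 1])
    rpd = float(sd / err) if err > 0 else float("inf")
    return EvaluationReport(r=r, rmsep=err, rpd=rpd, n=n, split=split, scale=scale)


def improvement_pct(metric_single: float, metric_fused: float) -> float:
    """Relative change in percent, rounded to one decimal for reporting."""
    if metric_single == 0:
        raise ValueError("zero baseline metric")
    return round(100.0 * (metric_fused - metric_single) / metric_single, 1)
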