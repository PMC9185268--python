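"""Model evaluation statistics and quality classification bands.

Statistic conventions:

* ``SD`` — reference-value standard deviation, n-1 denominator.
* ``SEC`` — standard error of calibration, ``sqrt(SSE / (n - p - 1))``
  with p the number of regression factors.
* ``SECV``/``SEP`` — standard errors of cross-validation and of
  prediction, both corrected for bias:
  ``sqrt(sum((e - bias)^2) / (n - 1))``.
* ``RPD = SD / SE`` and ``RER = range / SE`` — the dimensionless ratios
  used to judge calibration quality. RPD > 3 marks an excellent
  equation and RPD < 1.5 an unsuitable one; RER between 4 and 8 lets a
  model discriminate high from low samples and 8-12 supports
  quantitative prediction.
* ``R^2`` — ratio of the sum of squares of the predictions about the
  reference mean to the total sum of squares of the reference values;
  for an ordinary least-squares fit this equals the squared Pearson
  correlation.

Reported values are rounded to two decimals (round-half-even); raw
values are kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd

__all__ = [
    "summary_stats",
    "r_squared",
    "prediction_error",
    "sec",
    "rpd",
    "rer",
    "round2",
    "classify_model",
    "QualityBand",
    "EvaluationReport",
]


def round2(x: float) -> float:
    """Two-decimal reporting rounding, round-half-even."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_EVEN))


def summary_stats(y: np.ndarray) -> dict:
    """Mean, (min, max) range, SD (n-1) and CV = SD/mean of a trait vector."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(y.std(ddof=1))
    mean = float(y.mean())
    return {
        "mean": mean,
        "range": (float(y.min()), float(y.max())),
        "sd": sd,
        "cv": sd / mean if mean != 0 else float("nan"),
    }


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Explained-to-total sum-of-squares ratio about the reference mean."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero-variance y: R^2 undefined")
    return float(np.sum((yhat - y.mean()) ** 2)) / tss


def prediction_error(y: np.ndarray, yhat: np.ndarray) -> dict:
    """Bias and bias-corrected standard error of prediction (SEP)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 values")
    e = yhat - y
    bias = float(e.mean())
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (e.size - 1)))
    return {"sep": sep, "bias": bias}


def sec(y: np.ndarray, yhat: np.ndarray, n_factors: int) -> float:
    """Standard error of calibration with n - p - 1 degrees of freedom."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    dof = y.size - n_factors - 1
    if dof < 1:
        raise ValueError("not enough samples for SEC degrees of freedom")
    return float(np.sqrt(np.sum((y - yhat) ** 2) / dof))


def rpd(sd: float, se: float) -> float:
    """Ratio of reference SD to a standard error (SECV or SEP)."""
    if not (se > 0):
        raise ValueError("standard error must be > 0")
    return float(sd) / float(se)


def rer(value_range: float, se: float) -> float:
    """Ratio of the reference range to a standard error."""
    if not (se > 0):
        raise ValueError("standard error must be > 0")
    if value_range < 0:
        raise ValueError("range must be >= 0")
    return float(value_range) / float(se)


# ---------------------------------------------------------------------------
# Quality classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityBand:
    r2_band: str
    rpd_band: str
    rer_band: str
    combined: str


# ordinal scale shared by the three statistics, for the conservative merge
_RANKS = {
    "very low correlation": 0, "unsuitable": 0,
    "low correlation": 1,
    "discriminate high/low": 2, "screening": 2,
    "rough prediction": 3,
    "good correlation": 4, "very good": 4, "quantitative": 4,
    "excellent": 5,
}


def _r2_band(r2: float) -> str:
    if r2 > 0.90:
        return "excellent"
    if r2 >= 0.82:
        return "good correlation"
    if r2 >= 0.65:
        return "rough prediction"
    if r2 >= 0.50:
        return "discriminate high/low"
    if r2 >= 0.26:
        return "low correlation"
    return "very low correlation"


def _rpd_band(v: float) -> str:
    if v > 3.0:
        return "excellent"
    if v >= 2.5:
        return "very good"
    if v >= 1.5:
        return "screening"
    return "unsuitable"


def _rer_band(v: float) -> str:
    if v >= 8.0:
        return "quantitative"
    if v >= 4.0:
        return "discriminate high/low"
    return "unsuitable"


def classify_model(r2_val: float, rpd_value: float, rer_value: float) -> QualityBand:
    """Classify a model against the R^2 / RPD / RER interpretation bands.

    The combined label is the most conservative of the three individual
    labels on a shared ordinal scale.
    """
    bands = (_r2_band(r2_val), _rpd_band(rpd_value), _rer_band(rer_value))
    combined = min(bands, key=lambda b: _RANKS[b])
    return QualityBand(*bands, combined=combined)


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "trait", "treatment", "n_factors", "n_cal", "n_val",
    "range_cal_low", "range_cal_high", "range_val_low", "range_val_high",
    "mean", "sd", "cv",
    "sec", "r2_cal", "r2_cv", "secv", "rpd_cv",
    "sep", "bias", "r2_val", "rpd_p", "rer",
    "r2_band", "rpd_band", "rer_band", "quality_band",
]


@dataclass
class EvaluationReport:
    """Calibration / cross-validation / external-validation statistics,
    one row per trait (the shape of a NIRS calibration summary table)."""

    rows: pd.DataFrame

    @classmethod
    def from_records(cls, records: list[dict]) -> "EvaluationReport":
        df = pd.DataFrame.from_records(records)
        return cls(df.reindex(columns=_REPORT_COLUMNS))

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6g")

    def rounded(self) -> pd.DataFrame:
        df = self.rows.copy()
        for c in df.columns:
            if df[c].dtype.kind == "f":
                df[c] = df[c].map(round2)
        return df

    def to_text(self) -> str:
        df = self.rounded()
        cols = ["trait", "treatment", "n_factors", "sd", "sec", "r2_cal",
                "r2_cv", "secv", "rpd_cv", "sep", "r2_val", "rpd_p", "rer",
                "quality_band"]
        cols = [c for c in cols if c in df.columns]
        return df[cols].to_string(index=False)
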