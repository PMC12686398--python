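"""Age-estimation metrics and linear bias correction of the age gap.

Metrics: mean absolute error (MAE, years), cumulative score
CS(alpha) = 100 * #{|error| <= alpha} / n (percent; threshold comparison is
inclusive), and the Pearson / Spearman correlations between predicted and
chronological age.

Bias correction: age-prediction models systematically overestimate young
subjects and underestimate old ones (regression dilution), inducing a
negative correlation between the raw gap (prediction - age) and age.  The
standard linear fix regresses the gap on chronological age in a designated
healthy reference population, gap_hat = a*x + b, and subtracts the fitted
bias from every prediction:

    y_corrected = y_hat - (a*x + b),   gap_corrected = y_corrected - x.

By OLS orthogonality the corrected gap is uncorrelated with age on the
fitting population; the same (a, b) are applied unchanged to any other
group, so disease-related gap differences are preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = ["MetricsReport", "BiasModel", "compute_metrics", "cs_curve",
           "fit_bias_model", "correct_ages"]


@dataclass
class MetricsReport:
    mae: float
    cs: float                 # percent at threshold cs_alpha
    cs_alpha: float
    pearson_r: float
    spearman_rs: float
    n: int

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class BiasModel:
    """Slope/intercept of the gap-vs-age regression on a healthy reference."""

    slope: float              # years of bias per year of age
    intercept: float          # years
    fit_n: int
    fit_population_tag: str

    def __post_init__(self):
        if self.fit_n < 2:
            raise ValueError("bias model requires at least two fitting points")

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path: str) -> "BiasModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def compute_metrics(predicted: np.ndarray, chronological: np.ndarray,
                    alpha: float = 5.0) -> MetricsReport:
    """MAE, CS(alpha), Pearson r and Spearman r_s (average-rank ties).

    With n < 2 the correlations are reported as NaN (undefined).
    """
    yhat = np.asarray(predicted, dtype=np.float64)
    x = np.asarray(chronological, dtype=np.float64)
    if yhat.shape != x.shape:
        raise ValueError("predicted and chronological vectors differ in length")
    if yhat.size == 0:
        raise ValueError("empty input")
    err = np.abs(yhat - x)
    mae = float(err.mean())
    cs = float(100.0 * int((err <= alpha).sum()) / err.size)
    if yhat.size < 2 or np.ptp(x) == 0 or np.ptp(yhat) == 0:
        r = rs = float("nan")
    else:
        r = float(stats.pearsonr(yhat, x).statistic)
        rs = float(stats.spearmanr(yhat, x).statistic)
    return MetricsReport(mae=mae, cs=cs, cs_alpha=float(alpha),
                         pearson_r=r, spearman_rs=rs, n=int(yhat.size))


def cs_curve(errors: np.ndarray, alpha_grid: np.ndarray) -> np.ndarray:
    """CS evaluated on a grid of thresholds; non-decreasing in alpha."""
    err = np.abs(np.asarray(errors, dtype=np.float64))
    if err.size == 0:
        raise ValueError("empty error vector")
    grid = np.asarray(alpha_grid, dtype=np.float64)
    return 100.0 * (err[None, :] <= grid[:, None]).sum(axis=1) / err.size


def fit_bias_model(predicted: np.ndarray, chronological: np.ndarray,
                   fit_population_tag: str) -> BiasModel:
    """OLS of the raw gap (predicted - chronological) on chronological age.

    ``fit_population_tag`` names the reference population the coefficients
    come from (e.g. "validation-healthy"); requiring it makes silent
    refitting on case groups impossible.
    """
    yhat = np.asarray(predicted, dtype=np.float64)
    x = np.asarray(chronological, dtype=np.float64)
    if yhat.shape != x.shape or yhat.size < 2:
        raise ValueError("need at least two (predicted, chronological) pairs")
    if np.ptp(x) == 0:
        raise ValueError("chronological age is constant; slope unidentifiable")
    gap = yhat - x
    slope, intercept = np.polyfit(x, gap, 1)
    return BiasModel(slope=float(slope), intercept=float(intercept),
                     fit_n=int(x.size), fit_population_tag=fit_population_tag)


def correct_ages(predicted: np.ndarray, chronological: np.ndarray,
                 bias: BiasModel) -> tuple[np.ndarray, np.ndarray]:
    """Apply the healthy-reference bias model elementwise.

    Returns (corrected predicted ages, corrected gaps); the coefficients
    are used unchanged whatever group the inputs come from.
    """
    yhat = np.asarray(predicted, dtype=np.float64)
    x = np.asarray(chronological, dtype=np.float64)
    if yhat.shape != x.shape:
        raise ValueError("length mismatch")
    corrected = yhat - (bias.slope * x + bias.intercept)
    return corrected, corrected - x
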