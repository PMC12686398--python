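"""Breast-age-gap association and risk analysis.

Given per-exam bias-corrected age gaps, this module answers the three
questions the gap is a biomarker for:

* Do cancer-diagnosed exams show larger gaps than healthy exams after
  adjusting for chronological age and density?  (ANCOVA: a linear model
  ``gap ~ group + age + density``; the group coefficient is the adjusted
  mean difference.)
* Does a gap above the cohort median stratify survival?  (Kaplan-Meier
  curves for high/low groups and a two-sided log-rank test.)
* What is the hazard ratio per year of gap?  (Cox proportional-hazards
  models: model 1 unadjusted; model 2 adjusted for age and density;
  model 3 adjusted for a configurable risk-factor set.  The proportional-
  hazards assumption is checked per covariate with scaled Schoenfeld
  residuals against identity-transformed time; violating covariates are
  handled by stratification, quartile-binned first if continuous.)

All tests are two-sided.  Density 'unknown' is kept as its own level,
never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test

__all__ = ["GapTable", "HazardReport", "KMResult", "build_gap_table",
           "adjusted_group_difference", "median_risk_groups", "km_logrank",
           "cox_models", "schoenfeld_check"]

logger = logging.getLogger(__name__)

DENSITY_LEVELS = ("A", "B", "C", "D", "unknown")

#: required columns of a gap table (one row per exam)
GAP_TABLE_COLUMNS = ("gap", "age", "density", "group", "followup_time", "event")


@dataclass
class GapTable:
    """Per-exam gap table; ``extra`` names additional covariate columns."""

    data: pd.DataFrame
    extra_covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in GAP_TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"gap table missing columns {missing}")
        if self.data[["gap", "age"]].isna().any().any():
            raise ValueError("gap and age must have no missing values")
        bad = set(self.data["density"]) - set(DENSITY_LEVELS)
        if bad:
            raise ValueError(f"unknown density levels {sorted(bad)}")


def build_gap_table(predictions: pd.DataFrame, manifest: pd.DataFrame,
                    corrected_gaps: np.ndarray,
                    extra_covariates: list[str] | None = None) -> GapTable:
    """Join corrected gaps onto the manifest labels (exam_id keyed)."""
    df = predictions[["exam_id"]].copy()
    df["gap"] = np.asarray(corrected_gaps, dtype=np.float64)
    man = manifest.set_index("exam_id")
    df = df.set_index("exam_id")
    df["age"] = man["age"]
    df["density"] = man["density"].astype(str)
    df["group"] = man["cancer"].astype(bool).map({True: "cancer", False: "healthy"})
    df["followup_time"] = man["followup_time"]
    df["event"] = man["event"].astype(int)
    extra = extra_covariates or []
    for c in extra:
        df[c] = man[c]
    return GapTable(df.reset_index(), extra_covariates=list(extra))


def adjusted_group_difference(table: GapTable) -> tuple[float, float]:
    """Age- and density-adjusted mean gap difference, cancer vs healthy.

    Fits ``gap ~ group + age + density`` by OLS and returns the cancer
    group coefficient (years) with its two-sided p-value.
    """
    df = table.data
    groups = set(df["group"])
    if groups != {"healthy", "cancer"}:
        raise ValueError("need both a healthy and a cancer group")
    model = smf.ols(
        "gap ~ C(group, Treatment('healthy')) + age + C(density)", data=df).fit()
    name = "C(group, Treatment('healthy'))[T.cancer]"
    return float(model.params[name]), float(model.pvalues[name])


def median_risk_groups(gaps: np.ndarray) -> np.ndarray:
    """Median split: gap > median -> 'high'; gap <= median -> 'low'.

    Ties at the median go to the low-risk group (the threshold is strict).
    """
    gaps = np.asarray(gaps, dtype=np.float64)
    if gaps.size < 2:
        raise ValueError("need at least two gaps to split")
    med = np.median(gaps)
    return np.where(gaps > med, "high", "low")


@dataclass
class KMResult:
    curves: pd.DataFrame          # columns: group, time, survival, ci_low, ci_high
    logrank_p: float
    statistic: float
    flagged: bool                 # True when a group has no events


def km_logrank(labels: np.ndarray, followup_time: np.ndarray,
               event: np.ndarray) -> KMResult:
    """Product-limit curves with 95% CIs per group plus a log-rank test."""
    labels = np.asarray(labels)
    t = np.asarray(followup_time, dtype=np.float64)
    e = np.asarray(event).astype(bool)
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise ValueError("expected exactly two risk groups")
    flagged = any(e[labels == g].sum() == 0 for g in names)
    if flagged:
        logger.warning("a risk group has no events; log-rank test is degenerate")
    frames = []
    for g in names:
        kmf = KaplanMeierFitter()
        kmf.fit(t[labels == g], e[labels == g], label=str(g))
        ci = kmf.confidence_interval_survival_function_
        frames.append(pd.DataFrame({
            "group": str(g),
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        }))
    res = logrank_test(t[labels == names[0]], t[labels == names[1]],
                       e[labels == names[0]], e[labels == names[1]])
    return KMResult(curves=pd.concat(frames, ignore_index=True),
                    logrank_p=float(res.p_value),
                    statistic=float(res.test_statistic), flagged=flagged)


@dataclass
class HazardReport:
    """Continuous-gap and high/low-group hazard ratios for models 1-3."""

    models: dict[str, dict]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.models.items():
            rows.append({"model": name, "term": "gap (per year)",
                         "hr": m["hr"], "ci_low": m["ci_low"],
                         "ci_high": m["ci_high"], "p": m["p"]})
            rows.append({"model": name, "term": "high vs low gap",
                         "hr": m["group_hr"], "ci_low": m["group_ci_low"],
                         "ci_high": m["group_ci_high"], "p": m["group_p"]})
        return pd.DataFrame(rows)


def _prepare_cox_frame(df: pd.DataFrame, main: str, covariates: list[str]
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Numeric design frame: categorical covariates dummy-coded."""
    out = df[["followup_time", "event", main]].copy()
    cov_cols: list[str] = []
    for c in covariates:
        if df[c].dtype == object or str(df[c].dtype) == "category":
            dummies = pd.get_dummies(df[c].astype(str), prefix=c, drop_first=True)
            for col in dummies.columns:
                out[col] = dummies[col].astype(float)
                cov_cols.append(col)
        else:
            out[c] = df[c].astype(float)
            cov_cols.append(c)
    return out, cov_cols


def _fit_cox(frame: pd.DataFrame, main: str, cov_cols: list[str],
             alpha_violation: float = 0.05) -> dict:
    """Fit, Schoenfeld-check, and refit with stratification if needed."""
    n_events = int(frame["event"].sum())
    n_params = 1 + len(cov_cols)
    if n_events < 10 * n_params:
        logger.warning("only %d events for %d parameters; estimates may be unstable",
                       n_events, n_params)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="followup_time", event_col="event")
    sch = schoenfeld_check(cph, frame)
    strata: list[str] = []
    violators = [c for c, p in sch.items() if c != main and p < alpha_violation]
    if violators:
        strat_frame = frame.copy()
        for c in violators:
            if strat_frame[c].nunique() > 5:
                strat_frame[c] = pd.qcut(strat_frame[c], 4, labels=False,
                                         duplicates="drop")
            strata.append(c)
        cph = CoxPHFitter()
        cph.fit(strat_frame, duration_col="followup_time", event_col="event",
                strata=strata)
        sch = {c: p for c, p in sch.items() if c not in strata}
    s = cph.summary.loc[main]
    return {
        "hr": float(s["exp(coef)"]),
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "p": float(s["p"]),
        "coef": float(s["coef"]),
        "schoenfeld": sch,
        "stratified": strata,
        "n_events": n_events,
    }


def cox_models(table: GapTable,
               model3_covariates: list[str] | None = None) -> HazardReport:
    """The three Cox models on the continuous gap and the median split.

    Model 1: gap only.  Model 2: gap + chronological age + density.
    Model 3: gap + the configured risk-factor covariate set (defaults to
    the model 2 set when none is given).
    """
    df = table.data.copy()
    df["high_gap"] = (median_risk_groups(df["gap"].to_numpy()) == "high").astype(float)
    covariate_sets = {
        "model1_unadjusted": [],
        "model2_age_density_adjusted": ["age", "density"],
        "model3_risk_factor_adjusted": model3_covariates
        if model3_covariates is not None else ["age", "density"] + table.extra_covariates,
    }
    models: dict[str, dict] = {}
    for name, covs in covariate_sets.items():
        for c in covs:
            if df[c].isna().any():
                raise ValueError(f"missing values in covariate {c!r}")
        frame, cov_cols = _prepare_cox_frame(df, "gap", covs)
        res = _fit_cox(frame, "gap", cov_cols)
        gframe, gcov = _prepare_cox_frame(df, "high_gap", covs)
        gres = _fit_cox(gframe, "high_gap", gcov)
        res.update({"group_hr": gres["hr"], "group_ci_low": gres["ci_low"],
                    "group_ci_high": gres["ci_high"], "group_p": gres["p"]})
        models[name] = res
    return HazardReport(models=models)


def schoenfeld_check(fitted: CoxPHFitter, frame: pd.DataFrame) -> dict[str, float]:
    """Per-covariate proportional-hazards p-values from scaled Schoenfeld
    residuals against identity-transformed time."""
    if int(frame["event"].sum()) < 2:
        raise ValueError("need at least two events for the Schoenfeld check")
    res = proportional_hazard_test(fitted, frame, time_transform="identity")
    out = {}
    for cov in res.summary.index:
        name = cov[0] if isinstance(cov, tuple) else cov
        out[str(name)] = float(res.summary.loc[cov, "p"])
    return out
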