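"""Statistical layer: ANCOVA recovery/confounding control, median split,
KM/log-rank behavior and Cox parameter recovery on simulated gap tables."""

import numpy as np
import pandas as pd
import pytest

from mammoage.gap_risk import (GapTable, adjusted_group_difference, cox_models,
                               km_logrank, median_risk_groups, schoenfeld_check)
from mammoage.synthetic import simulate_followup


def _table(gap, age, density, group, t, e):
    return GapTable(pd.DataFrame({
        "gap": gap, "age": age, "density": density, "group": group,
        "followup_time": t, "event": np.asarray(e).astype(int)}))


def _sim_table(rng, n_healthy=500, n_cancer=500, effect=0.0, age_effect=0.0,
               confounded=False):
    n = n_healthy + n_cancer
    group = np.array(["healthy"] * n_healthy + ["cancer"] * n_cancer)
    if confounded:
        age = np.where(group == "cancer", rng.uniform(50, 90, n),
                       rng.uniform(20, 60, n))
    else:
        age = rng.uniform(20, 90, n)
    density = rng.choice(list("ABCD"), n)
    gap = rng.normal(0, 3, n) + age_effect * age + effect * (group == "cancer")
    t = rng.uniform(0.1, 10, n)
    e = rng.random(n) < 0.3
    return _table(gap, age, density, group, t, e)


class TestAdjustedGroupDifference:
    def test_known_effect_recovered(self, rng):
        table = _sim_table(rng, effect=2.0)
        diff, p = adjusted_group_difference(table)
        assert diff == pytest.approx(2.0, abs=0.2)
        assert p < 1e-6

    def test_confounded_design_adjusted_away(self, rng):
        # crude difference is driven by the age effect; adjusted is ~0
        table = _sim_table(rng, effect=0.0, age_effect=0.05, confounded=True)
        crude = (table.data.loc[table.data.group == "cancer", "gap"].mean()
                 - table.data.loc[table.data.group == "healthy", "gap"].mean())
        assert crude > 0.5
        diff, _ = adjusted_group_difference(table)
        assert abs(diff) < 0.5

    def test_null_rejection_rate_calibrated(self):
        rejections = 0
        runs = 1000
        for s in range(runs):
            rng = np.random.default_rng(s)
            table = _sim_table(rng, n_healthy=100, n_cancer=100)
            _, p = adjusted_group_difference(table)
            rejections += p < 0.05
        assert 0.03 <= rejections / runs <= 0.07

    def test_matches_normal_equations_on_small_instance(self, rng):
        table = _sim_table(rng, n_healthy=60, n_cancer=60, effect=1.5)
        diff, _ = adjusted_group_difference(table)
        df = table.data
        X = np.column_stack([
            np.ones(len(df)),
            (df["group"] == "cancer").astype(float),
            df["age"].to_numpy(),
            pd.get_dummies(df["density"], drop_first=True).to_numpy(float),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ df["gap"].to_numpy())
        assert diff == pytest.approx(beta[1], abs=1e-8)

    def test_single_group_rejected(self, rng):
        table = _sim_table(rng, n_cancer=0)
        table.data["group"] = "healthy"
        with pytest.raises(ValueError):
            adjusted_group_difference(table)


class TestMedianRiskGroups:
    def test_even_split(self):
        labels = median_risk_groups(np.array([1.0, 2, 3, 4]))
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_all_equal_gaps_all_low(self):
        assert (median_risk_groups(np.full(5, 2.0)) == "low").all()

    def test_hand_median(self):
        labels = median_risk_groups(np.array([-1.0, 0.0, 5.0]))
        assert labels.tolist() == ["low", "low", "high"]

    def test_split_sizes_differ_only_by_ties(self, rng):
        for _ in range(20):
            gaps = rng.normal(size=int(rng.integers(2, 50)))
            labels = median_risk_groups(gaps)
            ties = (gaps == np.median(gaps)).sum()
            assert abs((labels == "high").sum() - (labels == "low").sum()) <= ties


class TestKmLogrank:
    def test_identical_groups_give_p_one(self):
        t = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        e = np.array([1, 0, 1, 1, 0] * 2)
        labels = np.array(["high"] * 5 + ["low"] * 5)
        res = km_logrank(labels, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_survival_starts_at_one(self, rng):
        t = rng.exponential(5, 40).clip(0.01, 10)
        e = rng.random(40) < 0.5
        labels = np.where(rng.random(40) < 0.5, "high", "low")
        res = km_logrank(labels, t, e)
        for g in ("high", "low"):
            curve = res.curves[res.curves.group == g]
            assert curve.loc[curve.time == curve.time.min(), "survival"].iloc[0] == 1.0

    def test_power_against_twofold_hazard(self):
        detections = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            n = 1000
            hi = rng.random(2 * n) < 0.5
            rate = np.where(hi, 0.2, 0.1)
            t = rng.exponential(1 / rate)
            e = t < 10
            t = np.minimum(t, 10)
            res = km_logrank(np.where(hi, "high", "low"), t, e)
            detections += res.logrank_p < 0.01
        assert detections >= 19

    def test_no_event_group_flagged(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 1, 0, 0])
        labels = np.array(["high", "high", "low", "low"])
        assert km_logrank(labels, t, e).flagged


def _cox_sim(rng, n, beta, horizon=10.0, baseline=0.02):
    gap = rng.normal(0, 3, n)
    out = [simulate_followup(g, horizon, baseline, beta, rng) for g in gap]
    t = np.array([o[0] for o in out])
    e = np.array([o[1] for o in out])
    return _table(gap, rng.uniform(30, 80, n), rng.choice(list("ABCD"), n),
                  rng.choice(["healthy", "cancer"], n), t, e)


class TestCoxModels:
    def test_effect_recovered_and_robust_to_noise_covariate(self, rng):
        beta = np.log(1.05)
        table = _cox_sim(rng, 8000, beta)
        report = cox_models(table)
        m1 = report.models["model1_unadjusted"]
        assert m1["ci_low"] < np.exp(beta) < m1["ci_high"]
        # an independent noise covariate barely moves the gap HR
        table.data["noise"] = rng.normal(size=len(table.data))
        table2 = GapTable(table.data, extra_covariates=["noise"])
        report2 = cox_models(table2, model3_covariates=["age", "density", "noise"])
        m3 = report2.models["model3_risk_factor_adjusted"]
        assert m3["hr"] == pytest.approx(m1["hr"], abs=0.01)

    def test_report_structure(self, rng):
        report = cox_models(_cox_sim(rng, 1500, np.log(1.05)))
        assert set(report.models) == {"model1_unadjusted",
                                      "model2_age_density_adjusted",
                                      "model3_risk_factor_adjusted"}
        for m in report.models.values():
            assert m["ci_low"] <= m["hr"] <= m["ci_high"]
            assert m["hr"] > 0 and 0 <= m["p"] <= 1
        frame = report.to_frame()
        assert len(frame) == 6

    def test_missing_covariate_rejected(self, rng):
        table = _cox_sim(rng, 200, 0.0)
        table.data.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cox_models(table)


class TestSchoenfeld:
    def test_proportional_simulation_mostly_passes(self):
        passes = 0
        for s in range(20):
            rng = np.random.default_rng(2000 + s)
            table = _cox_sim(rng, 1200, np.log(1.1))
            report = cox_models(table)
            passes += report.models["model1_unadjusted"]["schoenfeld"]["gap"] > 0.05
        assert passes >= 16  # ~95% expected; allow binomial slack

    def test_time_varying_effect_detected(self):
        detections = 0
        for s in range(10):
            rng = np.random.default_rng(3000 + s)
            n = 3000
            gap = rng.normal(0, 3, n)
            beta = np.log(1.4)
            # effect reverses at t = 5: piecewise-exponential via inversion
            h1 = 0.05 * np.exp(beta * gap)
            h2 = 0.05 * np.exp(-beta * gap)
            u = rng.exponential(1.0, n)
            t = np.where(u < h1 * 5, u / h1, 5 + (u - h1 * 5) / h2)
            e = t < 10
            t = np.minimum(t, 10)
            table = _table(gap, rng.uniform(30, 80, n),
                           rng.choice(list("ABCD"), n),
                           rng.choice(["healthy", "cancer"], n), t, e)
            from lifelines import CoxPHFitter
            cph = CoxPHFitter()
            frame = table.data[["followup_time", "event", "gap"]]
            cph.fit(frame, duration_col="followup_time", event_col="event")
            p = schoenfeld_check(cph, frame)["gap"]
            detections += p < 0.05
        assert detections >= 8

    def test_one_p_per_covariate(self, rng):
        from lifelines import CoxPHFitter
        table = _cox_sim(rng, 800, np.log(1.1))
        frame = table.data[["followup_time", "event", "gap", "age"]]
        cph = CoxPHFitter()
        cph.fit(frame, duration_col="followup_time", event_col="event")
        p = schoenfeld_check(cph, frame)
        assert set(p) == {"gap", "age"}

    def test_too_few_events_rejected(self):
        from lifelines import CoxPHFitter
        df = pd.DataFrame({"followup_time": [1.0, 2, 3, 4],
                           "event": [1, 0, 0, 0],
                           "gap": [0.1, 0.2, -0.1, 0.3]})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="followup_time", event_col="event")
        with pytest.raises(ValueError):
            schoenfeld_check(cph, df.assign(event=[1, 0, 0, 0]))
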