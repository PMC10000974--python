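"""Survival machinery: KM/MCF hand oracles, Cox engine vs independent
references, LVCF counting-process construction, PWP and person-year rates."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctctrack.survival import (
    ConvergenceError,
    CoxPH,
    apply_death_imputation,
    build_counting_process,
    cox_fit,
    incidence_rate,
    irr,
    km_fit,
    nelson_mcf,
    pwp_fit,
)


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_hand_product_limit_no_censoring(self):
        res = km_fit([1, 2, 3], [1, 1, 1])
        assert res.survival_at(1) == pytest.approx(2 / 3)
        assert res.survival_at(2) == pytest.approx(1 / 3)
        assert res.survival_at(3) == pytest.approx(0.0)
        assert res.median == pytest.approx(2.0)

    def test_single_censored_subject(self):
        res = km_fit([5], [0])
        assert res.survival_at(5) == 1.0
        assert res.median is None

    def test_hand_product_limit_with_censoring(self):
        # times {1, 2+, 3}: risk set of 1 at t=3
        res = km_fit([1, 2, 3], [1, 0, 1])
        assert res.survival_at(1) == pytest.approx(2 / 3)
        assert res.survival_at(2.5) == pytest.approx(2 / 3)
        assert res.survival_at(3) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 40).round(3)
        res = km_fit(times, np.ones(40))
        for t in [1, 5, 12]:
            assert res.survival_at(t) == pytest.approx((times > t).mean())

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_fit([0.0, 1.0], [1, 1])


# ---------------------------------------------------------------------------
# Cox engine


def breslow_logpl(beta, times, events, x):
    """Hand-written Breslow log partial likelihood (independent oracle)."""
    ll = 0.0
    for t, d, xi in zip(times, events, x):
        if not d:
            continue
        risk = [math.exp(beta * xj) for tj, xj in zip(times, x) if tj >= t]
        ll += beta * xi - math.log(sum(risk))
    return ll


class TestCoxOracle:
    def test_coefficient_matches_grid_search(self):
        """Newton-Raphson agrees with brute-force maximization to 1e-4."""
        times = [1.0, 2.5, 3.0, 4.2, 5.1, 6.7]
        events = [1, 0, 1, 1, 0, 1]
        x = [1, 1, 0, 1, 0, 0]
        df = pd.DataFrame({"time": times, "event": events, "x": x})
        res = cox_fit(df, duration_col="time", event_col="event", covariates=["x"])
        grid = np.arange(-5, 5, 0.01)
        best = grid[np.argmax([breslow_logpl(b, times, events, x) for b in grid])]
        fine = np.arange(best - 0.02, best + 0.02, 1e-5)
        best = fine[np.argmax([breslow_logpl(b, times, events, x) for b in fine])]
        assert res.params["x"] == pytest.approx(best, abs=1e-4)
        assert res.loglik == pytest.approx(
            breslow_logpl(res.params["x"], times, events, x), abs=1e-8
        )

    def test_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(12)
        n = 200
        x1 = rng.binomial(1, 0.5, n)
        x2 = rng.normal(size=n)
        t = rng.exponential(1 / (0.08 * np.exp(0.6 * x1 - 0.4 * x2)))
        c = rng.exponential(15, n)
        df = pd.DataFrame(
            {
                "time": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "x1": x1,
                "x2": x2,
            }
        )
        from lifelines import CoxPHFitter

        mine = cox_fit(df, duration_col="time", event_col="event",
                       covariates=["x1", "x2"])
        ref = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        np.testing.assert_allclose(mine.params.values, ref.params_.values, atol=1e-6)
        np.testing.assert_allclose(mine.bse.values,
                                   ref.standard_errors_.values, atol=1e-6)

    def test_robust_clustered_matches_lifelines(self):
        rng = np.random.default_rng(13)
        n = 150
        df = pd.DataFrame(
            {
                "time": rng.exponential(8, n),
                "event": rng.binomial(1, 0.7, n),
                "x": rng.normal(size=n),
                "cl": np.arange(n) % 40,
            }
        )
        from lifelines import CoxPHFitter

        mine = cox_fit(df, duration_col="time", event_col="event",
                       covariates=["x"], cluster_col="cl", robust=True)
        ref = CoxPHFitter().fit(df, duration_col="time", event_col="event",
                                cluster_col="cl", formula="x")
        assert mine.variance_type == "robust_sandwich"
        np.testing.assert_allclose(mine.bse.values,
                                   ref.standard_errors_.values, atol=1e-6)

    def test_simulation_recovery_two_groups(self):
        """Exponential two-group data with true HR 2 at large n."""
        rng = np.random.default_rng(99)
        n = 2000
        x = rng.binomial(1, 0.5, n)
        t = rng.exponential(1 / (0.05 * np.exp(math.log(2) * x)))
        df = pd.DataFrame({"time": t, "event": np.ones(n, int), "x": x})
        res = cox_fit(df, duration_col="time", event_col="event", covariates=["x"])
        assert 1.7 <= res.hazard_ratio("x") <= 2.35

    def test_perfect_separation_raises(self):
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 4, 5, 6],
                "event": [1, 1, 1, 0, 0, 0],
                "x": [1, 1, 1, 0, 0, 0],
            }
        )
        with pytest.raises(ConvergenceError, match="x"):
            cox_fit(df, duration_col="time", event_col="event", covariates=["x"])

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1, 2], "event": [1, 1], "x": [1, 1]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, duration_col="time", event_col="event", covariates=["x"])

    def test_start_stop_equals_simple_when_no_change(self):
        """Splitting rows without covariate change leaves the fit unchanged."""
        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.1 * np.exp(0.5 * x)))
        ev = rng.binomial(1, 0.8, n)
        simple = pd.DataFrame({"time": t, "event": ev, "x": x})
        rows = []
        for i in range(n):
            mid = t[i] / 2
            rows.append({"start": 0.0, "stop": mid, "event": 0, "x": x[i]})
            rows.append({"start": mid, "stop": t[i], "event": ev[i], "x": x[i]})
        split = pd.DataFrame(rows)
        r1 = cox_fit(simple, duration_col="time", event_col="event", covariates=["x"])
        r2 = cox_fit(split, start_col="start", stop_col="stop", event_col="event",
                     covariates=["x"])
        assert r1.params["x"] == pytest.approx(r2.params["x"], abs=1e-10)
        assert r1.bse["x"] == pytest.approx(r2.bse["x"], abs=1e-10)

    def test_efron_option_handles_ties(self):
        df = pd.DataFrame(
            {
                "time": [1, 1, 2, 2, 3, 4, 5, 6],
                "event": [1, 1, 1, 1, 1, 0, 1, 0],
                "x": [1.0, 0.5, 0.0, 1.0, -0.5, 0.0, 1.5, -1.0],
            }
        )
        from lifelines import CoxPHFitter

        mine = CoxPH(df, duration_col="time", event_col="event",
                     covariates=["x"], ties="efron").fit()
        ref = CoxPHFitter().fit(
            df.assign(time=df.time.astype(float)), "time", "event"
        )
        # lifelines uses Efron for tied event times
        assert mine.params["x"] == pytest.approx(float(ref.params_.iloc[0]), abs=1e-6)


# ---------------------------------------------------------------------------
# Counting-process construction


class TestBuildCountingProcess:
    def test_lvcf_single_event(self):
        ep = pd.DataFrame(
            [{"patient_id": "A", "time_to_progression": 5.0,
              "progression_observed": True}]
        )
        meas = pd.DataFrame(
            [
                {"patient_id": "A", "time": 0.0, "count": 2},
                {"patient_id": "A", "time": 3.0, "count": 7},
            ]
        )
        tab = build_counting_process(ep, meas, endpoint="pfs")
        assert len(tab) == 2
        r0, r1 = tab.iloc[0], tab.iloc[1]
        assert (r0["start"], r0["stop"], r0["event"], r0["count"]) == (0.0, 3.0, 0, 2)
        assert (r1["start"], r1["stop"], r1["event"], r1["count"]) == (3.0, 5.0, 1, 7)

    def test_recurrent_pwp_layout(self):
        ep = pd.DataFrame([{"patient_id": "A", "follow_up_time": 12.0}])
        meas = pd.DataFrame([{"patient_id": "A", "time": 0.0, "x": 1}])
        events = pd.DataFrame(
            [{"patient_id": "A", "time": 4.0}, {"patient_id": "A", "time": 9.0}]
        )
        tab = build_counting_process(
            ep, meas, mode="recurrent_pwp", recurrent_events=events
        )
        assert [tuple(r) for r in tab[["start", "stop", "event", "stratum"]].values] == [
            (0.0, 4.0, 1, 1),
            (4.0, 9.0, 1, 2),
            (9.0, 12.0, 0, 3),
        ]

    def test_time_conservation(self, small_cohort, small_thresholds):
        from ctctrack.pipeline import build_measurements

        meas = build_measurements(small_cohort, small_thresholds)
        ep = small_cohort.endpoints
        tab = build_counting_process(
            ep,
            meas[["patient_id", "time", "ctc_high"]],
            mode="recurrent_pwp",
            recurrent_events=small_cohort.recurrent_events,
        )
        spans = tab.groupby("patient_id").apply(
            lambda g: (g["stop"] - g["start"]).sum(), include_groups=False
        )
        fu = ep.set_index("patient_id")["follow_up_time"]
        for pid, span in spans.items():
            assert span == pytest.approx(fu[pid])
        assert (tab["start"] < tab["stop"]).all()

    def test_event_at_measurement_time_uses_prior_value(self):
        ep = pd.DataFrame(
            [{"patient_id": "A", "time_to_progression": 6.0,
              "progression_observed": True}]
        )
        meas = pd.DataFrame(
            [
                {"patient_id": "A", "time": 0.0, "count": 1},
                {"patient_id": "A", "time": 6.0, "count": 9},  # at the event
            ]
        )
        tab = build_counting_process(ep, meas, endpoint="pfs")
        assert len(tab) == 1
        assert tab.iloc[0]["count"] == 1  # change takes effect just after

    def test_truncation_applied_to_count_covariate(self):
        ep = pd.DataFrame(
            [{"patient_id": "A", "time_to_progression": 4.0,
              "progression_observed": True}]
        )
        meas = pd.DataFrame([{"patient_id": "A", "time": 0.0, "count": 5000}])
        tab = build_counting_process(ep, meas, endpoint="pfs",
                                     truncate_cols=["count"])
        assert tab.iloc[0]["count"] == 40.0

    def test_patient_without_measurements_excluded(self, caplog):
        ep = pd.DataFrame(
            [
                {"patient_id": "A", "time_to_progression": 4.0,
                 "progression_observed": True},
                {"patient_id": "B", "time_to_progression": 5.0,
                 "progression_observed": True},
            ]
        )
        meas = pd.DataFrame([{"patient_id": "A", "time": 0.0, "count": 1}])
        with caplog.at_level("WARNING"):
            tab = build_counting_process(ep, meas, endpoint="pfs")
        assert set(tab["patient_id"]) == {"A"}
        assert any("B" in rec.message for rec in caplog.records)


class TestDeathImputation:
    def test_death_without_progression_becomes_progression(self):
        ep = pd.DataFrame(
            [
                {"patient_id": "A", "time_to_progression": 10.0,
                 "progression_observed": False, "time_to_death": 10.0,
                 "death_observed": True},
                {"patient_id": "B", "time_to_progression": 4.0,
                 "progression_observed": True, "time_to_death": 8.0,
                 "death_observed": True},
            ]
        )
        out = apply_death_imputation(ep)
        a = out[out["patient_id"] == "A"].iloc[0]
        assert a["progression_observed"] and a["progression_imputed"]
        assert a["time_to_progression"] == 10.0
        b = out[out["patient_id"] == "B"].iloc[0]
        assert not b["progression_imputed"]


# ---------------------------------------------------------------------------
# PWP


class TestPWP:
    def test_single_event_per_patient_degenerates_to_cox(self):
        rng = np.random.default_rng(21)
        n = 120
        x = rng.binomial(1, 0.5, n)
        t = rng.exponential(1 / (0.1 * np.exp(0.6 * x)))
        ev = rng.binomial(1, 0.8, n)
        table = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "start": 0.0,
                "stop": t,
                "event": ev,
                "stratum": 1,
                "x": x,
            }
        )
        pwp = pwp_fit(table, covariates=["x"])
        simple = cox_fit(
            pd.DataFrame({"time": t, "event": ev, "x": x,
                          "pid": [f"P{i}" for i in range(n)]}),
            duration_col="time", event_col="event", covariates=["x"],
            cluster_col="pid", robust=True,
        )
        assert pwp.params["x"] == pytest.approx(simple.params["x"], abs=1e-10)
        assert pwp.bse["x"] == pytest.approx(simple.bse["x"], abs=1e-10)

    def test_recovers_doubled_per_event_hazard(self):
        """Recurrent events with hazard doubled for x=1: HR recovered."""
        rng = np.random.default_rng(22)
        rows = []
        n = 1000
        for i in range(n):
            x = i % 2
            rate = 0.08 * (2.0 if x else 1.0)
            t, stratum = 0.0, 1
            cens = 24.0
            while True:
                gap = rng.exponential(1 / rate)
                if t + gap >= cens or stratum > 6:
                    rows.append({"patient_id": i, "start": t, "stop": cens,
                                 "event": 0, "stratum": stratum, "x": x})
                    break
                t += gap
                rows.append({"patient_id": i, "start": t - gap, "stop": t,
                             "event": 1, "stratum": stratum, "x": x})
                stratum += 1
        res = pwp_fit(pd.DataFrame(rows), covariates=["x"])
        assert 1.6 <= res.hazard_ratio("x") <= 2.5

    def test_eventless_stratum_dropped_with_warning(self, caplog):
        table = pd.DataFrame(
            [
                {"patient_id": "A", "start": 0, "stop": 2, "event": 1,
                 "stratum": 1, "x": 1},
                {"patient_id": "B", "start": 0, "stop": 3, "event": 1,
                 "stratum": 1, "x": 0},
                {"patient_id": "C", "start": 0, "stop": 4, "event": 1,
                 "stratum": 1, "x": 0},
                {"patient_id": "D", "start": 0, "stop": 5, "event": 0,
                 "stratum": 1, "x": 1},
                {"patient_id": "A", "start": 2, "stop": 6, "event": 0,
                 "stratum": 2, "x": 1},
            ]
        )
        with caplog.at_level("WARNING"):
            res = pwp_fit(table, covariates=["x"])
        assert any("no events" in rec.message for rec in caplog.records)
        assert res.n_events == 3  # only the eventful stratum contributes


# ---------------------------------------------------------------------------
# Nelson MCF


class TestNelsonMCF:
    def test_hand_risk_set_computation(self):
        mcf = nelson_mcf({"A": [1, 3], "B": [2]}, {"A": 5, "B": 4})
        expect = {1.0: 0.5, 2.0: 1.0, 3.0: 1.5}
        for t, v in expect.items():
            assert mcf.loc[mcf["time"] == t, "mcf"].iloc[0] == pytest.approx(v)

    def test_no_events_identically_zero(self):
        mcf = nelson_mcf({"A": [], "B": []}, {"A": 5, "B": 4})
        assert mcf.empty

    def test_single_subject_counts_events(self):
        mcf = nelson_mcf({"A": [1, 2, 3]}, {"A": 4})
        assert mcf["mcf"].iloc[-1] == pytest.approx(3.0)

    def test_pooled_single_events_equal_ecdf_counts(self):
        rng = np.random.default_rng(31)
        times = rng.uniform(1, 10, 25)
        ev = {f"S{i}": [t] for i, t in enumerate(times)}
        cens = {f"S{i}": 12.0 for i in range(25)}
        mcf = nelson_mcf(ev, cens)
        for _, row in mcf.iterrows():
            assert row["mcf"] == pytest.approx((times <= row["time"]).mean())

    def test_event_after_censor_rejected(self):
        with pytest.raises(ValueError):
            nelson_mcf({"A": [6]}, {"A": 5})


# ---------------------------------------------------------------------------
# Incidence rates


class TestIncidenceRates:
    def test_rate_per_100_person_years(self):
        r = incidence_rate(10, 50)
        assert r["rate"] == pytest.approx(20.0)
        # exact Poisson bounds on the count, scaled
        assert r["ci_low"] == pytest.approx(100 * stats.chi2.ppf(0.025, 20) / 2 / 50)
        assert r["ci_high"] == pytest.approx(100 * stats.chi2.ppf(0.975, 22) / 2 / 50)

    def test_zero_events_one_sided(self):
        r = incidence_rate(0, 10)
        assert r["rate"] == 0.0 and r["ci_low"] == 0.0
        # exact Poisson 97.5% bound for a count of zero is ~3.689 events
        assert r["ci_high"] == pytest.approx(100 * 3.68888 / 10, rel=1e-4)

    def test_irr_ratio_and_ci(self):
        out = irr(10, 50, 5, 50)
        assert out["irr"] == pytest.approx(2.0)
        se = math.sqrt(1 / 10 + 1 / 5)
        assert out["ci_low"] == pytest.approx(2.0 * math.exp(-1.959964 * se), rel=1e-4)

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValueError):
            incidence_rate(3, 0)
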