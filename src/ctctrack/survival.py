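"""Survival machinery for longitudinal CTC analyses.

The centerpiece is a Cox proportional-hazards model on counting-process
(start, stop] data, fitted by Newton-Raphson on the partial likelihood
(Breslow ties by default, Efron optional) with an optional robust sandwich
variance clustered on patient. On top of it sit:

* :func:`build_counting_process` — last-value-carried-forward (LVCF)
  construction of time-dependent covariate tables, in single-event and
  recurrent (PWP total-time) layouts;
* :func:`pwp_fit` — the Prentice-Williams-Peterson recurrent-event model
  (Cox stratified on event number, sandwich variance clustered on patient);
* :func:`km_fit` — Kaplan-Meier product-limit curves with Greenwood/log-log
  confidence intervals (via lifelines);
* :func:`nelson_mcf` — the Nelson estimator of the mean cumulative number
  of recurrent events;
* :func:`incidence_rate` / :func:`irr` — events per 100 person-years with
  exact-Poisson confidence intervals and their ratio.

Time is measured in months from the consent date throughout; a death
without documented progression is treated as a progression at the death
date (see :func:`apply_death_imputation`).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxPH",
    "CoxPHResults",
    "ConvergenceError",
    "cox_fit",
    "pwp_fit",
    "km_fit",
    "KaplanMeierResult",
    "build_counting_process",
    "apply_death_imputation",
    "nelson_mcf",
    "incidence_rate",
    "irr",
    "DAYS_PER_MONTH",
]

logger = logging.getLogger(__name__)

#: Months are days/30.4375 when converting from calendar dates.
DAYS_PER_MONTH = 30.4375


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (non-convergence or separation)."""


# ---------------------------------------------------------------------------
# Cox proportional hazards on counting-process data


class CoxPH:
    """Cox proportional-hazards model on simple or (start, stop] data.

    Parameters
    ----------
    data
        One row per subject (simple mode) or per at-risk interval
        (counting-process mode).
    duration_col, event_col
        Simple mode: time-to-event and event indicator columns.
    start_col, stop_col, event_col
        Counting-process mode: left-open interval (start, stop] and event
        indicator at ``stop``. Left truncation is expressed by ``start > 0``.
    covariates
        Covariate columns (numeric). Defaults to every column not otherwise
        claimed.
    strata_col
        Optional stratification column; each stratum keeps its own baseline
        hazard (used by the PWP model with the event-number stratum).
    cluster_col
        Grouping for the robust sandwich variance (typically patient id).
        Requesting a cluster implies ``robust=True`` at fit time.
    ties
        ``"breslow"`` (default, matching SAS PHREG's default) or ``"efron"``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        duration_col: str | None = None,
        event_col: str = "event",
        start_col: str | None = None,
        stop_col: str | None = None,
        covariates: Sequence[str] | None = None,
        strata_col: str | None = None,
        cluster_col: str | None = None,
        ties: str = "breslow",
    ) -> None:
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie method {ties!r}")
        if duration_col is None and (start_col is None or stop_col is None):
            raise ValueError("give either duration_col or start_col/stop_col")
        self.ties = ties
        df = data.reset_index(drop=True)
        if duration_col is not None:
            start = np.zeros(len(df))
            stop = df[duration_col].to_numpy(float)
        else:
            start = df[start_col].to_numpy(float)
            stop = df[stop_col].to_numpy(float)
        if np.any(stop <= start):
            raise ValueError("every row needs start < stop")
        event = df[event_col].to_numpy()
        if set(np.unique(event)) - {0, 1, True, False}:
            raise ValueError("event column must be 0/1")
        event = event.astype(float)
        if event.sum() < 1:
            raise ValueError("at least one event is required")

        claimed = {duration_col, event_col, start_col, stop_col, strata_col, cluster_col}
        if covariates is None:
            covariates = [c for c in df.columns if c not in claimed]
        self.covariate_names = list(covariates)
        X = df[self.covariate_names].to_numpy(float)
        for j, name in enumerate(self.covariate_names):
            if np.ptp(X[:, j]) == 0:
                raise ValueError(f"covariate {name!r} is constant")

        if strata_col is not None:
            strata = pd.factorize(df[strata_col])[0]
        else:
            strata = np.zeros(len(df), dtype=int)
        if cluster_col is not None:
            clusters = pd.factorize(df[cluster_col])[0]
        else:
            clusters = np.arange(len(df))

        self.start, self.stop, self.event = start, stop, event
        self.X, self.strata, self.clusters = X, strata, clusters
        self._x_ptp = np.ptp(X, axis=0)
        self.n_subjects = len(np.unique(clusters)) if cluster_col else len(df)
        self.cluster_col = cluster_col

    # -- partial likelihood pieces ------------------------------------------------

    def _stratum_terms(self, beta: np.ndarray):
        """Yield (loglik, gradient, information) contributions per stratum."""
        p = self.X.shape[1]
        eta = self.X @ beta
        # guard against overflow during aggressive NR steps
        w = np.exp(np.clip(eta, -500, 500))
        for s in np.unique(self.strata):
            idx = np.flatnonzero(self.strata == s)
            Xs, ws = self.X[idx], w[idx]
            start_s, stop_s, ev_s = self.start[idx], self.stop[idx], self.event[idx]
            event_times = np.unique(stop_s[ev_s == 1])
            ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
            for t in event_times:
                at_risk = (start_s < t) & (t <= stop_s)
                tied = (stop_s == t) & (ev_s == 1)
                d = int(tied.sum())
                Xr, wr = Xs[at_risk], ws[at_risk]
                S0 = wr.sum()
                S1 = wr @ Xr
                S2 = (wr[:, None] * Xr).T @ Xr
                x_ev = Xs[tied]
                eta_ev = eta[idx][tied]
                if self.ties == "breslow" or d == 1:
                    ll += eta_ev.sum() - d * math.log(S0)
                    grad += x_ev.sum(axis=0) - d * S1 / S0
                    xbar = S1 / S0
                    info += d * (S2 / S0 - np.outer(xbar, xbar))
                else:  # Efron
                    w_ev = ws[tied]
                    S0e = w_ev.sum()
                    S1e = w_ev @ x_ev
                    S2e = (w_ev[:, None] * x_ev).T @ x_ev
                    ll += eta_ev.sum()
                    for k in range(d):
                        f = k / d
                        S0k = S0 - f * S0e
                        S1k = S1 - f * S1e
                        S2k = S2 - f * S2e
                        ll -= math.log(S0k)
                        grad -= S1k / S0k
                        xbar = S1k / S0k
                        info += S2k / S0k - np.outer(xbar, xbar)
                    grad += x_ev.sum(axis=0)
            yield ll, grad, info

    def _loglik_grad_info(self, beta: np.ndarray):
        p = self.X.shape[1]
        ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
        for l, g, i in self._stratum_terms(beta):
            ll += l
            grad += g
            info += i
        return ll, grad, info

    def loglik(self, beta: Sequence[float]) -> float:
        """Log partial likelihood at ``beta`` (Breslow or Efron per ``ties``)."""
        return self._loglik_grad_info(np.asarray(beta, float))[0]

    def _score_residuals(self, beta: np.ndarray) -> np.ndarray:
        """Per-row score residuals (Breslow form) for the sandwich variance."""
        n, p = self.X.shape
        eta = self.X @ beta
        w = np.exp(np.clip(eta, -500, 500))
        U = np.zeros((n, p))
        for s in np.unique(self.strata):
            idx = np.flatnonzero(self.strata == s)
            Xs, ws = self.X[idx], w[idx]
            start_s, stop_s, ev_s = self.start[idx], self.stop[idx], self.event[idx]
            event_times = np.unique(stop_s[ev_s == 1])
            for t in event_times:
                at_risk = (start_s < t) & (t <= stop_s)
                tied = (stop_s == t) & (ev_s == 1)
                d = int(tied.sum())
                wr = ws[at_risk]
                S0 = wr.sum()
                xbar = (wr @ Xs[at_risk]) / S0
                dev = Xs - xbar  # only at-risk rows are used below
                U[idx[tied]] += dev[tied]
                U[idx[at_risk]] -= (d * wr / S0)[:, None] * dev[at_risk]
        return U

    def fit(
        self,
        robust: bool | None = None,
        tol: float = 1e-8,
        max_iter: int = 100,
        alpha: float = 0.05,
    ) -> "CoxPHResults":
        """Maximize the partial likelihood by Newton-Raphson.

        Converges when the gradient's max-norm falls below ``tol``. Raises
        :class:`ConvergenceError` on non-convergence or monotone likelihood
        (perfect separation), naming the runaway covariate.
        """
        if robust is None:
            robust = self.cluster_col is not None
        if robust and self.ties != "breslow":
            raise ValueError("robust sandwich variance implemented for Breslow ties")
        p = self.X.shape[1]
        beta = np.zeros(p)
        ll, grad, info = self._loglik_grad_info(beta)
        for _ in range(max_iter):
            if np.max(np.abs(grad)) <= tol:
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            new_beta = beta + step
            new_ll, new_grad, new_info = self._loglik_grad_info(new_beta)
            halvings = 0
            while new_ll < ll - 1e-12 and halvings < 30:
                step /= 2.0
                new_beta = beta + step
                new_ll, new_grad, new_info = self._loglik_grad_info(new_beta)
                halvings += 1
            beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
            if np.max(np.abs(beta) * self._x_ptp) > 200:
                j = int(np.argmax(np.abs(beta) * self._x_ptp))
                raise ConvergenceError(
                    f"monotone likelihood (possible perfect separation) in "
                    f"covariate {self.covariate_names[j]!r}"
                )
        else:
            if np.max(np.abs(grad)) > tol:
                raise ConvergenceError(
                    f"Newton-Raphson did not reach gradient norm {tol} "
                    f"in {max_iter} iterations"
                )
        if np.max(np.abs(grad)) > tol:
            raise ConvergenceError("gradient norm above tolerance at termination")
        # a coefficient this extreme on the covariate's own scale signals a
        # monotone partial likelihood (the gradient only vanishes numerically)
        scaled = np.abs(beta) * self._x_ptp
        if np.max(scaled) > 15:
            j = int(np.argmax(scaled))
            raise ConvergenceError(
                f"monotone likelihood (possible perfect separation) in "
                f"covariate {self.covariate_names[j]!r}"
            )

        cov_model = np.linalg.inv(info)
        if robust:
            U = self._score_residuals(beta)
            G = np.zeros((p, p))
            for g in np.unique(self.clusters):
                u = U[self.clusters == g].sum(axis=0)
                G += np.outer(u, u)
            cov = cov_model @ G @ cov_model
            variance_type = "robust_sandwich"
        else:
            cov = cov_model
            variance_type = "model"
        return CoxPHResults(
            model=self,
            params=pd.Series(beta, index=self.covariate_names),
            cov=pd.DataFrame(cov, index=self.covariate_names,
                             columns=self.covariate_names),
            cov_model=pd.DataFrame(cov_model, index=self.covariate_names,
                                   columns=self.covariate_names),
            loglik=ll,
            variance_type=variance_type,
            alpha=alpha,
        )


@dataclass
class CoxPHResults:
    """Estimates, uncertainties and Wald inference from a :class:`CoxPH` fit."""

    model: CoxPH
    params: pd.Series
    cov: pd.DataFrame
    cov_model: pd.DataFrame
    loglik: float
    variance_type: str
    alpha: float = 0.05

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def hazard_ratio(self, name: str) -> float:
        return float(np.exp(self.params[name]))

    def conf_int(self, name: str | None = None) -> tuple[float, float] | pd.DataFrame:
        """Wald confidence bounds on the log-hazard scale."""
        z = stats.norm.ppf(1 - self.alpha / 2)
        lo, hi = self.params - z * self.bse, self.params + z * self.bse
        if name is not None:
            return float(lo[name]), float(hi[name])
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[name])

    @property
    def n(self) -> int:
        return self.model.n_subjects

    @property
    def n_events(self) -> int:
        return int(self.model.event.sum())

    def summary(self) -> pd.DataFrame:
        """Per-covariate table: coef, HR, SE, 95% CI (HR scale), p-value."""
        z = stats.norm.ppf(1 - self.alpha / 2)
        return pd.DataFrame(
            {
                "coef": self.params,
                "hr": self.hazard_ratios,
                "se": self.bse,
                "hr_ci_low": np.exp(self.params - z * self.bse),
                "hr_ci_high": np.exp(self.params + z * self.bse),
                "p": self.pvalues,
            }
        )

    def to_dict(self) -> dict:
        z = stats.norm.ppf(1 - self.alpha / 2)
        return {
            "covariates": {
                name: {
                    "coef": float(self.params[name]),
                    "hr": float(np.exp(self.params[name])),
                    "se": float(self.bse[name]),
                    "hr_ci": [
                        float(np.exp(self.params[name] - z * self.bse[name])),
                        float(np.exp(self.params[name] + z * self.bse[name])),
                    ],
                    "p": float(self.pvalues[name]),
                }
                for name in self.params.index
            },
            "n": self.n,
            "n_events": self.n_events,
            "log_partial_likelihood": float(self.loglik),
            "variance_type": self.variance_type,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = (
            f"CoxPH fit: n={self.n}, events={self.n_events}, "
            f"variance={self.variance_type}, logPL={self.loglik:.4f}\n"
        )
        return head + self.summary().to_string(float_format=lambda v: f"{v:.4g}")


def cox_fit(
    data: pd.DataFrame,
    duration_col: str | None = None,
    event_col: str = "event",
    start_col: str | None = None,
    stop_col: str | None = None,
    covariates: Sequence[str] | None = None,
    strata_col: str | None = None,
    cluster_col: str | None = None,
    ties: str = "breslow",
    robust: bool | None = None,
) -> CoxPHResults:
    """Fit a Cox model; thin functional wrapper over :class:`CoxPH`."""
    model = CoxPH(
        data,
        duration_col=duration_col,
        event_col=event_col,
        start_col=start_col,
        stop_col=stop_col,
        covariates=covariates,
        strata_col=strata_col,
        cluster_col=cluster_col,
        ties=ties,
    )
    return model.fit(robust=robust)


def pwp_fit(
    table: pd.DataFrame,
    covariates: Sequence[str],
    cluster_col: str = "patient_id",
    strata_col: str = "stratum",
) -> CoxPHResults:
    """Fit the PWP recurrent-event model on a counting-process table.

    A Cox fit stratified on the event-number stratum (each k-th event has
    its own baseline hazard; a subject is at risk for event k only after
    event k-1) with a robust sandwich variance clustered on patient. Strata
    without events are dropped with a warning.
    """
    keep = []
    for s, grp in table.groupby(strata_col):
        if grp["event"].sum() == 0:
            logger.warning("PWP: stratum %s has no events and is dropped", s)
        else:
            keep.append(grp)
    if not keep:
        raise ValueError("no stratum with events")
    data = pd.concat(keep, ignore_index=True)
    return cox_fit(
        data,
        start_col="start",
        stop_col="stop",
        event_col="event",
        covariates=list(covariates),
        strata_col=strata_col,
        cluster_col=cluster_col,
        robust=True,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KaplanMeierResult:
    """Product-limit estimate, Greenwood/log-log CIs and median survival."""

    survival_function: pd.DataFrame  # columns: time, estimate, ci_low, ci_high
    median: float | None
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        sf = self.survival_function
        prior = sf[sf["time"] <= t]
        return 1.0 if prior.empty else float(prior["estimate"].iloc[-1])


def km_fit(times, event_flags, alpha: float = 0.05) -> KaplanMeierResult:
    """Kaplan-Meier fit of right-censored times.

    Median survival is the first time the curve reaches 0.5 or below;
    reported as None (with a None CI) when the curve never does, e.g. under
    heavy censoring. Confidence bands are lifelines' exponential Greenwood
    (log-log) intervals.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    times = np.asarray(times, float)
    events = np.asarray(event_flags).astype(bool)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    ci = kmf.confidence_interval_
    sf = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(float),
            "estimate": kmf.survival_function_.iloc[:, 0].to_numpy(float),
            "ci_low": ci.iloc[:, 0].to_numpy(float),
            "ci_high": ci.iloc[:, 1].to_numpy(float),
        }
    )
    sf = sf[sf["time"] > 0].reset_index(drop=True)
    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
    to_none = lambda v: None if math.isinf(v) else v
    return KaplanMeierResult(
        survival_function=sf,
        median=to_none(median),
        median_ci=(to_none(lo), to_none(hi)),
        n=len(times),
        n_events=int(events.sum()),
    )


# ---------------------------------------------------------------------------
# Endpoint preparation and LVCF counting-process construction


def apply_death_imputation(endpoints: pd.DataFrame) -> pd.DataFrame:
    """Treat death without documented progression as progression at death.

    Expects columns time_to_progression, progression_observed, time_to_death
    and death_observed; returns a copy with the progression endpoint updated.
    """
    out = endpoints.copy()
    dead = out["death_observed"].astype(bool)
    no_prog = ~out["progression_observed"].astype(bool)
    imputed = dead & no_prog
    out.loc[imputed, "time_to_progression"] = out.loc[imputed, "time_to_death"]
    out.loc[imputed, "progression_observed"] = True
    if "progression_imputed" in out.columns:  # idempotent on pre-imputed tables
        imputed = imputed | out["progression_imputed"].astype(bool)
    out["progression_imputed"] = imputed
    return out


def build_counting_process(
    endpoints: pd.DataFrame,
    measurements: pd.DataFrame,
    mode: str = "single_event",
    endpoint: str = "pfs",
    covariate_cols: Sequence[str] | None = None,
    truncate_cols: Sequence[str] = (),
    recurrent_events: pd.DataFrame | None = None,
    time_col: str = "time",
) -> pd.DataFrame:
    """Build an LVCF counting-process table for time-dependent Cox fits.

    Each patient's follow-up is split at covariate measurement times; a
    covariate holds its most recent measured value until the next
    measurement (LVCF), with the first measurement carried back to the
    consent date (visit 1 is effectively at consent). An event coinciding
    with a measurement time keeps the preceding interval's covariate value.
    Columns named in ``truncate_cols`` are capped at 40 before entering the
    table (the continuous CTC-count convention).

    Parameters
    ----------
    endpoints
        Per-patient frame with patient_id and, for single-event mode,
        time_to_progression/progression_observed (``endpoint="pfs"``) or
        time_to_death/death_observed (``endpoint="os"``); for recurrent
        mode, a follow_up_time column (end of observation: death or censor)
        and death-imputed progression times in ``recurrent_events``.
    measurements
        Long frame: patient_id, ``time_col`` (months from consent) and the
        covariate columns.
    mode
        ``"single_event"`` or ``"recurrent_pwp"`` (total-time PWP layout:
        rows additionally split at each progression event, with
        ``stratum`` = 1 + number of prior events).
    recurrent_events
        Long frame patient_id / time of each progression event (recurrent
        mode only).

    Returns
    -------
    DataFrame with patient_id, start, stop, event, stratum and covariates.
    Patients without any usable measurement are excluded and logged.
    """
    if mode not in ("single_event", "recurrent_pwp"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "recurrent_pwp" and recurrent_events is None:
        raise ValueError("recurrent mode needs recurrent_events")
    if covariate_cols is None:
        covariate_cols = [
            c for c in measurements.columns if c not in ("patient_id", time_col)
        ]

    rows = []
    meas_by_pid = dict(tuple(measurements.groupby("patient_id")))
    for _, pat in endpoints.iterrows():
        pid = pat["patient_id"]
        if mode == "single_event":
            if endpoint == "pfs":
                T = float(pat["time_to_progression"])
                terminal_event = bool(pat["progression_observed"])
            elif endpoint == "os":
                T = float(pat["time_to_death"])
                terminal_event = bool(pat["death_observed"])
            else:
                raise ValueError(f"unknown endpoint {endpoint!r}")
            event_times: list[float] = []
        else:
            T = float(pat["follow_up_time"])
            sub = recurrent_events[recurrent_events["patient_id"] == pid]
            event_times = sorted(float(t) for t in sub["time"])
            if any(t <= 0 for t in event_times):
                raise ValueError(f"patient {pid}: non-positive event time")
            if event_times and event_times[-1] > T:
                raise ValueError(f"patient {pid}: event after follow-up end")
            terminal_event = bool(event_times) and event_times[-1] == T

        if T <= 0:
            raise ValueError(f"patient {pid}: non-positive follow-up time")
        meas = meas_by_pid.get(pid)
        if meas is None or meas.empty:
            logger.warning("patient %s: no measurements, excluded", pid)
            continue
        meas = meas.sort_values(time_col)
        late = meas[meas[time_col] >= T]
        if len(late):
            logger.info(
                "patient %s: %d measurement(s) at/after follow-up end ignored",
                pid, len(late),
            )
        meas = meas[meas[time_col] < T]
        if meas.empty:
            # keep the earliest measurement as the baseline value
            meas = meas_by_pid[pid].sort_values(time_col).iloc[:1]
        meas_times = meas[time_col].to_numpy(float)
        values = meas[list(covariate_cols)].reset_index(drop=True)

        cuts = sorted(
            {float(t) for t in meas_times if 0.0 < t < T}
            | {float(t) for t in event_times if t < T}
            | {T}
        )
        start_t = 0.0
        n_prior = 0
        ev_set = set(event_times)
        for stop_t in cuts:
            # LVCF: latest measurement at or before the interval start;
            # first measurement carried back to consent when needed
            k = int(np.searchsorted(meas_times, start_t, side="right")) - 1
            k = max(k, 0)
            row = {
                "patient_id": pid,
                "start": start_t,
                "stop": stop_t,
                "stratum": n_prior + 1,
            }
            if mode == "single_event":
                row["event"] = int(stop_t == T and terminal_event)
            else:
                row["event"] = int(stop_t in ev_set)
            for c in covariate_cols:
                v = values.loc[k, c]
                if c in truncate_cols:
                    v = min(float(v), 40.0)
                row[c] = v
            rows.append(row)
            if row["event"] and mode == "recurrent_pwp":
                n_prior += 1
            start_t = stop_t
    out = pd.DataFrame(rows)
    if not out.empty and (out["stop"] <= out["start"]).any():
        raise AssertionError("zero-length interval produced")
    return out


# ---------------------------------------------------------------------------
# Nelson estimator of the mean cumulative function


def nelson_mcf(
    event_times: Mapping[str, Sequence[float]],
    censor_times: Mapping[str, float],
) -> pd.DataFrame:
    """Nelson estimator of the mean cumulative number of recurrent events.

    ``MCF(t)`` sums, over event times ``s <= t``, the number of events at
    ``s`` divided by the number of subjects still under observation at
    ``s`` (not yet censored or dead; experiencing an event does not remove
    a subject from the risk set).

    Parameters
    ----------
    event_times
        Per-subject sequences of event times (months).
    censor_times
        Per-subject end of observation (censoring or death), months.

    Returns
    -------
    Tidy step function: time, n_events, n_at_risk, mcf.
    """
    missing = set(event_times) - set(censor_times)
    if missing:
        raise ValueError(f"subjects without censor time: {sorted(missing)}")
    for pid, evs in event_times.items():
        if any(t > censor_times[pid] for t in evs):
            raise ValueError(f"subject {pid}: event after end of observation")
    all_events = sorted(t for evs in event_times.values() for t in evs)
    censor = np.array([censor_times[p] for p in censor_times])
    rows, mcf = [], 0.0
    for t in sorted(set(all_events)):
        d = all_events.count(t)
        n_risk = int((censor >= t).sum())
        mcf += d / n_risk
        rows.append({"time": t, "n_events": d, "n_at_risk": n_risk, "mcf": mcf})
    return pd.DataFrame(rows, columns=["time", "n_events", "n_at_risk", "mcf"])


def mcf_by_group(
    event_times: Mapping[str, Sequence[float]],
    censor_times: Mapping[str, float],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Nelson MCF per group (e.g. baseline CTC >=5 vs <5), tidy long format."""
    frames = []
    for g in sorted(set(groups.values())):
        pids = [p for p, lab in groups.items() if lab == g]
        sub_ev = {p: event_times.get(p, []) for p in pids}
        sub_cens = {p: censor_times[p] for p in pids}
        df = nelson_mcf(sub_ev, sub_cens)
        df.insert(0, "group", g)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Incidence rates per 100 person-years


def incidence_rate(events: int, person_years: float, alpha: float = 0.05) -> dict:
    """Events per 100 person-years with an exact Poisson confidence interval.

    With zero events the interval is one-sided (lower bound 0).
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("negative event count")
    rate = 100.0 * events / person_years
    if events == 0:
        lo = 0.0
    else:
        lo = stats.chi2.ppf(alpha / 2, 2 * events) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    return {
        "events": int(events),
        "person_years": float(person_years),
        "rate": rate,
        "ci_low": 100.0 * lo / person_years,
        "ci_high": 100.0 * hi / person_years,
    }


def irr(
    events_a: int,
    person_years_a: float,
    events_b: int,
    person_years_b: float,
    alpha: float = 0.05,
) -> dict:
    """Incidence rate ratio a/b with a log-normal confidence interval.

    The standard error of the log ratio is sqrt(1/events_a + 1/events_b);
    both groups need at least one event.
    """
    ra = incidence_rate(events_a, person_years_a, alpha)
    rb = incidence_rate(events_b, person_years_b, alpha)
    if events_a == 0 or events_b == 0:
        raise ValueError("IRR needs at least one event in each group")
    ratio = ra["rate"] / rb["rate"]
    se = math.sqrt(1 / events_a + 1 / events_b)
    z = stats.norm.ppf(1 - alpha / 2)
    return {
        "irr": ratio,
        "ci_low": ratio * math.exp(-z * se),
        "ci_high": ratio * math.exp(z * se),
        "rate_a": ra,
        "rate_b": rb,
    }
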