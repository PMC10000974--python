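"""Synthetic metastatic-breast-cancer cohorts for end-to-end validation.

No patient-level data accompany the study design this package implements,
so every analysis stage is exercised against generated cohorts that emulate
its statistical structure:

* baseline CTC counts from a zero-inflated negative binomial calibrated to
  observed marginals (39% zeros, 84% below 5 per ~9.5 mL draw), declining
  over up to 9 visits at 3-month intervals through a shared latent burden;
* gene-level Ct values built from healthy-donor background minus a tumor
  signal proportional to log1p(count), with an epithelial-mesenchymal
  polarity state that drifts mesenchymal in patients who progress;
* progression (recurrent) and death times from piecewise-constant hazards
  multiplied by the current CTC >= 5 state, TNBC subtype and FGFR1-high
  status — the same covariate structure the time-dependent Cox fits assume;
* healthy-donor calibration sets for both processing arms.

Events are generated conditional on the count trajectories (trajectory ->
hazard -> event); the EM polarity drift is then assigned from the realized
progressor status, so no circularity arises. Same config and seed give
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .expression import ExpressionSample
from .panel import CT_MAX, GenePanel, default_panel

__all__ = [
    "CohortConfig",
    "CohortTables",
    "calibrate_count_model",
    "generate_cohort",
    "generate_hd_set",
]

SUBTYPES = ("HR+/HER2-", "HR-/HER2+", "HR+/HER2+", "TNBC", "NA")


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    Hazard-ratio defaults are the time-dependent multivariate estimates the
    pipeline is expected to recover (progression/death multipliers for
    CTC >= 5, TNBC and FGFR1-high). Count-model defaults are calibrated at
    construction so that P(count = 0) and P(count < 5) at baseline hit the
    configured targets; an unreachable target raises with a hint.
    """

    n_patients: int = 184
    n_hd_lysis: int = 54
    n_hd_nolysis: int = 55
    n_visits: int = 9
    visit_spacing_months: float = 3.0
    max_follow_up_months: float = 24.0

    # metastatic-site subtype mix (HR = hormone receptor)
    subtype_probs: dict = field(
        default_factory=lambda: {
            "HR+/HER2-": 0.576,
            "HR-/HER2+": 0.054,
            "HR+/HER2+": 0.076,
            "TNBC": 0.201,
            "NA": 0.092,
        }
    )

    # baseline CTC count model: zero-inflated negative binomial
    p_zero_target: float = 0.39
    p_lt5_target: float = 0.84
    nb_dispersion: float = 0.7  # NB size parameter; smaller = heavier tail
    count_decay: float = 0.75  # per-visit multiplicative decline of burden

    # CTC clusters: Poisson(cluster_rate * max(0, count - cluster_threshold));
    # rate calibrated so ~4% of samples are cluster-positive at default
    cluster_rate: float = 0.15
    cluster_threshold: int = 2

    # hazards per month and multiplicative effects (hazard-ratio scale)
    base_progression_hazard: float = 0.045
    base_death_hazard: float = 0.010
    hr_ctc_progression: float = 2.251
    hr_ctc_death: float = 4.894
    hr_tnbc_progression: float = 1.725
    hr_tnbc_death: float = 3.389
    hr_fgfr1_progression: float = 1.470
    ctc_cutoff: int = 5
    dropout_hazard: float = 0.010

    # expression model
    hd_ct_mean_ctc: float = 36.5  # HD background Ct for CTC-related genes
    hd_ct_sd: float = 1.0
    arm_offset_ct: float = 0.5  # no-lysis arm shifted this many cycles up
    signal_slope: float = 2.5  # Ct decrease per unit log1p(count), weight 1
    ct_noise_sd: float = 1.0
    hk_ct_mean: float = 24.0  # housekeeping background
    wbc_ct_mean_hd: float = 21.0
    wbc_ct_mean_patient: float = 26.0  # leukocyte-depleted patient samples
    rbc_ct_mean: float = 27.0

    # EM polarity latent state and its drift (per visit)
    em_baseline_mean: float = -0.4
    em_baseline_sd: float = 0.25
    em_drift_progressor: float = 0.05
    em_drift_nonprogressor: float = -0.03

    # baseline tumor phenotypes
    fgfr1_high_prob: float = 0.30
    fgfr1_high_shift_ct: float = 4.0  # cycles below HD background when high
    fgfr1_low_shift_ct: float = 1.0  # cycles above HD background when low
    her2_ctc_prob_tissue_pos: float = 0.60
    her2_ctc_prob_tissue_neg: float = 0.10
    erbb2_weight_her2_ctc: float = 1.0
    erbb2_weight_other: float = 0.15
    signaling_weight: float = 0.6

    seed: int | None = None

    # derived at construction
    zi_pi0: float = field(init=False)
    nb_mean: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.subtype_probs.values())
        if not math.isclose(total, 1.0, abs_tol=0.02):
            raise ValueError(f"subtype probabilities sum to {total}, expected ~1")
        self.subtype_probs = {k: v / total for k, v in self.subtype_probs.items()}
        if any(v < 0 for v in self.subtype_probs.values()):
            raise ValueError("negative subtype probability")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        self.zi_pi0, self.nb_mean = calibrate_count_model(
            self.p_zero_target, self.p_lt5_target, self.nb_dispersion
        )

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("zi_pi0")
        d.pop("nb_mean")
        return d


def calibrate_count_model(
    p_zero: float, p_lt5: float, dispersion: float
) -> tuple[float, float]:
    """Solve the zero-inflated NB for the baseline count marginals.

    Finds (pi0, mu) such that P(count = 0) = ``p_zero`` and
    P(count < 5) = ``p_lt5`` with NB size ``dispersion``. Raises when the
    targets are unreachable at this dispersion (with a hint to change it).
    """
    if not (0 < p_zero < p_lt5 < 1):
        raise ValueError("need 0 < P(0) < P(<5) < 1")
    r = dispersion

    def nb_p0(mu: float) -> float:
        return (r / (r + mu)) ** r

    def nb_cdf4(mu: float) -> float:
        return float(stats.nbinom.cdf(4, r, r / (r + mu)))

    def gap(mu: float) -> float:
        # P(<5) - P(0) contributed by the NB component, scaled to hit p_zero
        p0 = nb_p0(mu)
        if p0 >= p_zero:
            return math.inf
        pi0 = (p_zero - p0) / (1 - p0)
        return (1 - pi0) * (nb_cdf4(mu) - p0) - (p_lt5 - p_zero)

    lo, hi = 1e-6, 1e6
    # smallest mu with NB-alone P(0) below the zero target
    try:
        mu_min = optimize.brentq(lambda m: nb_p0(m) - p_zero, lo, hi)
    except ValueError as exc:
        raise ValueError(
            "zero-inflation target unreachable; increase nb_dispersion"
        ) from exc
    f_lo, f_hi = gap(mu_min * 1.0001), gap(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"count targets P(0)={p_zero}, P(<5)={p_lt5} unreachable at "
            f"dispersion {dispersion}; try a different nb_dispersion"
        )
    mu = optimize.brentq(gap, mu_min * 1.0001, hi, xtol=1e-10)
    pi0 = (p_zero - nb_p0(mu)) / (1 - nb_p0(mu))
    return float(pi0), float(mu)


@dataclass
class CohortTables:
    """Generated cohort: clinical, visit, endpoint and expression tables."""

    config: CohortConfig
    seed: int
    patients: pd.DataFrame
    visits: pd.DataFrame
    endpoints: pd.DataFrame
    recurrent_events: pd.DataFrame
    samples: list[ExpressionSample]
    hd_samples: list[ExpressionSample]

    @property
    def ct_long(self) -> pd.DataFrame:
        """Long-format Ct table for all patient samples."""
        rows = []
        for s in self.samples:
            for gene, ct in s.ct.items():
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "patient_id": s.patient_id,
                        "visit": s.visit,
                        "rbc_lysis": s.rbc_lysis,
                        "gene": gene,
                        "ct": ct,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def hd_ct_long(self) -> pd.DataFrame:
        rows = []
        for s in self.hd_samples:
            for gene, ct in s.ct.items():
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "patient_id": s.patient_id,
                        "visit": s.visit,
                        "rbc_lysis": s.rbc_lysis,
                        "gene": gene,
                        "ct": ct,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, outdir) -> dict:
        """Write the cohort as the CSV dialects the analysis modules read."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("patients", self.patients),
            ("visits", self.visits),
            ("endpoints", self.endpoints),
            ("recurrent_events", self.recurrent_events),
            ("ct_long", self.ct_long),
            ("hd_ct_long", self.hd_ct_long),
        ]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.6g")
            paths[name] = p
        return paths


def _piecewise_exponential_time(
    rng: np.random.Generator, hazards: Sequence[float], breakpoints: Sequence[float]
) -> float:
    """Draw one event time from a piecewise-constant hazard.

    ``hazards[i]`` applies on [breakpoints[i], breakpoints[i+1]); the last
    hazard extends to infinity.
    """
    u = rng.exponential(1.0)  # cumulative hazard at the event
    acc = 0.0
    for i, h in enumerate(hazards):
        t0 = breakpoints[i]
        t1 = breakpoints[i + 1] if i + 1 < len(breakpoints) else math.inf
        width = t1 - t0
        seg = h * width
        if acc + seg >= u:
            if h == 0:
                return math.inf
            return t0 + (u - acc) / h
        acc += seg
    return math.inf


def _recurrent_event_times(
    rng: np.random.Generator,
    hazards: Sequence[float],
    breakpoints: Sequence[float],
    t_end: float,
) -> list[float]:
    """Poisson-process event times on (0, t_end] under a piecewise hazard."""
    times = []
    for i, h in enumerate(hazards):
        t0 = breakpoints[i]
        t1 = breakpoints[i + 1] if i + 1 < len(breakpoints) else math.inf
        t1 = min(t1, t_end)
        if t1 <= t0 or h <= 0:
            if t1 >= t_end:
                break
            continue
        n = rng.poisson(h * (t1 - t0))
        times.extend(np.sort(rng.uniform(t0, t1, n)))
        if t1 >= t_end:
            break
    return [float(t) for t in times]


def _gene_ct(
    rng: np.random.Generator,
    cfg: CohortConfig,
    panel: GenePanel,
    count: int,
    theta: float,
    fgfr1_high: bool,
    her2_ctc: bool,
    no_lysis: bool,
) -> dict[str, float]:
    """Draw one patient sample's Ct vector given burden and polarity."""
    offset = cfg.arm_offset_ct if no_lysis else 0.0
    signal = cfg.signal_slope * math.log1p(count)
    w_epi = (1 - theta) / 2
    w_mes = (1 + theta) / 2
    ct = {}
    for g in panel:
        if g.gene_class == "housekeeping":
            base = cfg.hk_ct_mean + offset
            shift = 0.0
        elif g.gene_class == "wbc_control":
            base = cfg.wbc_ct_mean_patient + offset
            shift = 0.0
        elif g.gene_class == "rbc_control":
            base = cfg.rbc_ct_mean + offset
            shift = 0.0
        elif g.symbol == "FGFR1":
            base = cfg.hd_ct_mean_ctc + offset
            shift = cfg.fgfr1_high_shift_ct if fgfr1_high else -cfg.fgfr1_low_shift_ct
        elif g.symbol == "ERBB2":
            base = cfg.hd_ct_mean_ctc + offset
            w = cfg.erbb2_weight_her2_ctc if her2_ctc else cfg.erbb2_weight_other
            shift = w * signal
        elif g.gene_class in ("epithelial",):
            base = cfg.hd_ct_mean_ctc + offset
            shift = w_epi * signal
        elif g.gene_class in ("emt", "csc"):
            base = cfg.hd_ct_mean_ctc + offset
            shift = w_mes * signal
        else:  # remaining signaling genes
            base = cfg.hd_ct_mean_ctc + offset
            shift = cfg.signaling_weight * signal
        value = base - shift + rng.normal(0.0, cfg.ct_noise_sd)
        ct[g.symbol] = float(min(max(value, 0.0), CT_MAX))
    return ct


def generate_hd_set(
    config: CohortConfig, seed: int | None = None, n_per_arm: tuple[int, int] | None = None
) -> list[ExpressionSample]:
    """Generate healthy-donor calibration samples for both processing arms.

    HD Ct values are normal around the configured per-class background
    means (CTC-related genes share one background), clipped to [0, 40];
    the no-lysis arm is shifted by the configured offset.
    """
    seed = config.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    rng = np.random.default_rng(seed)
    panel = default_panel()
    n_lysis, n_nolysis = n_per_arm or (config.n_hd_lysis, config.n_hd_nolysis)
    samples = []
    for arm_lysis, n_arm in ((True, n_lysis), (False, n_nolysis)):
        offset = 0.0 if arm_lysis else config.arm_offset_ct
        for i in range(n_arm):
            ct = {}
            for g in panel:
                if g.gene_class == "housekeeping":
                    base = config.hk_ct_mean
                elif g.gene_class == "wbc_control":
                    base = config.wbc_ct_mean_hd
                elif g.gene_class == "rbc_control":
                    base = config.rbc_ct_mean
                else:
                    base = config.hd_ct_mean_ctc
                v = base + offset + rng.normal(0.0, config.hd_ct_sd)
                ct[g.symbol] = float(min(max(v, 0.0), CT_MAX))
            arm_tag = "L" if arm_lysis else "N"
            samples.append(
                ExpressionSample(
                    sample_id=f"HD{arm_tag}{i + 1:03d}",
                    patient_id=f"HD{arm_tag}{i + 1:03d}",
                    visit=None,
                    rbc_lysis=arm_lysis,
                    ct=ct,
                    panel=panel,
                )
            )
    return samples


def generate_cohort(config: CohortConfig, seed: int | None = None) -> CohortTables:
    """Generate a full synthetic cohort under ``config``.

    Per patient: baseline burden -> count trajectory -> piecewise hazards
    (current CTC state, subtype, FGFR1) -> recurrent progression and death
    times -> EM polarity drift by realized progressor status -> per-visit
    Ct matrices. Administrative censoring at the configured maximum
    follow-up, with independent exponential dropout.
    """
    seed = config.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    rng = np.random.default_rng(seed)
    panel = default_panel()
    cfg = config

    subtype_names = list(cfg.subtype_probs)
    subtype_p = np.array([cfg.subtype_probs[s] for s in subtype_names])
    spacing = cfg.visit_spacing_months
    visit_times = [spacing * k for k in range(cfg.n_visits)]

    patients_rows, visit_rows, endpoint_rows, recur_rows = [], [], [], []
    samples: list[ExpressionSample] = []

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:04d}"
        subtype = subtype_names[rng.choice(len(subtype_names), p=subtype_p)]
        is_tnbc = subtype == "TNBC"
        tissue_her2 = "positive" if "HER2+" in subtype else "negative"
        her2_ctc = rng.random() < (
            cfg.her2_ctc_prob_tissue_pos
            if tissue_her2 == "positive"
            else cfg.her2_ctc_prob_tissue_neg
        )
        fgfr1_high = rng.random() < cfg.fgfr1_high_prob
        rbc_lysis = bool(rng.random() < 0.5)
        ibc = bool(rng.random() < 0.125)
        lines = 1 if rng.random() < 0.761 else 2

        # latent burden and count trajectory (zero-inflated gamma-Poisson)
        if rng.random() < cfg.zi_pi0:
            lam = 0.0
        else:
            lam = rng.gamma(cfg.nb_dispersion, cfg.nb_mean / cfg.nb_dispersion)
        counts = [
            int(rng.poisson(lam * cfg.count_decay**k)) if lam > 0 else 0
            for k in range(cfg.n_visits)
        ]

        # observation window
        dropout = rng.exponential(1.0 / cfg.dropout_hazard) if cfg.dropout_hazard > 0 else math.inf
        censor = min(cfg.max_follow_up_months, dropout)

        # piecewise hazards driven by the current (LVCF) CTC state
        high = [c >= cfg.ctc_cutoff for c in counts]
        prog_hazards = [
            cfg.base_progression_hazard
            * (cfg.hr_ctc_progression if h else 1.0)
            * (cfg.hr_tnbc_progression if is_tnbc else 1.0)
            * (cfg.hr_fgfr1_progression if fgfr1_high else 1.0)
            for h in high
        ]
        death_hazards = [
            cfg.base_death_hazard
            * (cfg.hr_ctc_death if h else 1.0)
            * (cfg.hr_tnbc_death if is_tnbc else 1.0)
            for h in high
        ]
        death_time = _piecewise_exponential_time(rng, death_hazards, visit_times)
        follow_up = min(censor, death_time)
        death_observed = death_time <= censor
        prog_times = _recurrent_event_times(rng, prog_hazards, visit_times, follow_up)
        # death without prior progression counts as progression at death
        progression_imputed = death_observed and not prog_times
        if progression_imputed:
            prog_times = [death_time]

        progression_observed = len(prog_times) > 0
        time_to_prog = prog_times[0] if progression_observed else follow_up
        time_to_death = death_time if death_observed else censor

        patients_rows.append(
            {
                "patient_id": pid,
                "subtype": subtype,
                "is_tnbc": is_tnbc,
                "tissue_her2": tissue_her2,
                "fgfr1_high": fgfr1_high,
                "ibc": ibc,
                "lines_of_therapy": lines,
                "rbc_lysis": rbc_lysis,
            }
        )
        endpoint_rows.append(
            {
                "patient_id": pid,
                "time_to_progression": time_to_prog,
                "progression_observed": progression_observed,
                "progression_imputed": progression_imputed,
                "time_to_death": time_to_death,
                "death_observed": death_observed,
                "censor_time": censor,
                "follow_up_time": follow_up,
            }
        )
        for t in prog_times:
            recur_rows.append({"patient_id": pid, "time": t})

        # EM polarity drift by realized progressor status
        theta0 = float(
            np.clip(rng.normal(cfg.em_baseline_mean, cfg.em_baseline_sd), -1, 1)
        )
        drift = (
            cfg.em_drift_progressor
            if progression_observed
            else cfg.em_drift_nonprogressor
        )

        for k, t_k in enumerate(visit_times):
            attended = k == 0 or (t_k <= censor and t_k < death_time)
            if not attended:
                continue
            count = counts[k]
            excess = max(0, count - cfg.cluster_threshold)
            n_clusters = int(rng.poisson(cfg.cluster_rate * excess)) if excess else 0
            cells = (
                int(n_clusters * 2 + rng.poisson(0.7 * n_clusters))
                if n_clusters
                else 0
            )
            visit_rows.append(
                {
                    "patient_id": pid,
                    "visit": k + 1,
                    "months_from_baseline": t_k,
                    "ctc_count": count,
                    "cluster_count": n_clusters,
                    "cells_in_clusters": cells,
                }
            )
            theta_k = float(np.clip(theta0 + drift * k, -1, 1))
            ct = _gene_ct(
                rng, cfg, panel, count, theta_k, fgfr1_high, her2_ctc,
                no_lysis=not rbc_lysis,
            )
            samples.append(
                ExpressionSample(
                    sample_id=f"{pid}V{k + 1}",
                    patient_id=pid,
                    visit=k + 1,
                    rbc_lysis=rbc_lysis,
                    ct=ct,
                    panel=panel,
                )
            )

    hd_samples = generate_hd_set(cfg, seed=int(rng.integers(0, 2**31 - 1)))
    return CohortTables(
        config=cfg,
        seed=seed,
        patients=pd.DataFrame(patients_rows),
        visits=pd.DataFrame(visit_rows),
        endpoints=pd.DataFrame(endpoint_rows),
        recurrent_events=pd.DataFrame(recur_rows, columns=["patient_id", "time"]),
        samples=samples,
        hd_samples=hd_samples,
    )
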