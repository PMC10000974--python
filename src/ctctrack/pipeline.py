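"""End-to-end orchestration: calibrate -> score -> build covariates -> fit -> report.

The pipeline reads tidy CSV inputs (or generates a synthetic cohort), then
produces the full analysis bundle: HD thresholds, per-sample scores,
per-visit comparisons, Kaplan-Meier curves, the time-dependent multivariate
Cox fits, the PWP recurrent-event fit, mean-cumulative-function curves,
person-year incidence rates and the CTC-count cutoff sweep. Every run
writes a manifest with a SHA-256 hash per output, the package version and
the seed, so a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .counts import cutoff_sweep, dichotomize
from .expression import (
    ThresholdSet,
    calibrate_thresholds,
    classify_gene_group,
    score_samples,
)
from .longitudinal import cluster_em_comparison, em_trajectory, rank_sum_test
from .survival import (
    apply_death_imputation,
    build_counting_process,
    cox_fit,
    incidence_rate,
    irr,
    km_fit,
    mcf_by_group,
    nelson_mcf,
    pwp_fit,
)
from .synthetic import CohortConfig, CohortTables, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "build_measurements",
    "time_dependent_multivariate",
    "recurrent_pwp_analysis",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str | Path = "ctctrack_results"
    seed: int = 0
    cutoff: int = 5  # CTC-count dichotomy
    positive_gene_cutoff: int = 4  # >=4 positive CTC genes classifier
    truncation_cap: int = 40
    landmark_visits: Sequence[int] = (1, 2)
    synth: CohortConfig | None = None
    ct_path: str | Path | None = None
    hd_ct_path: str | Path | None = None
    counts_path: str | Path | None = None
    patients_path: str | Path | None = None
    endpoints_path: str | Path | None = None
    recurrent_events_path: str | Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cutoff < 1 or self.positive_gene_cutoff < 1:
            raise ValueError("cutoffs must be >= 1")
        have_files = all(
            p is not None
            for p in (self.ct_path, self.hd_ct_path, self.counts_path,
                      self.patients_path, self.endpoints_path)
        )
        if self.synth is None and not have_files:
            self.synth = CohortConfig()


def _load_cohort(config: RunConfig) -> CohortTables:
    if config.synth is not None:
        return generate_cohort(config.synth, seed=config.seed)
    from .expression import read_ct_long

    samples = read_ct_long(config.ct_path)
    hd_samples = read_ct_long(config.hd_ct_path)
    visits = pd.read_csv(config.counts_path)
    patients = pd.read_csv(config.patients_path)
    endpoints = pd.read_csv(config.endpoints_path)
    if config.recurrent_events_path is not None:
        recurrent = pd.read_csv(config.recurrent_events_path)
    else:
        recurrent = endpoints.loc[
            endpoints["progression_observed"].astype(bool),
            ["patient_id", "time_to_progression"],
        ].rename(columns={"time_to_progression": "time"})
    for df, required, name in [
        (visits, {"patient_id", "visit", "months_from_baseline", "ctc_count"},
         "counts"),
        (patients, {"patient_id", "subtype"}, "patients"),
        (endpoints,
         {"patient_id", "time_to_progression", "progression_observed",
          "time_to_death", "death_observed"}, "endpoints"),
    ]:
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    if "follow_up_time" not in endpoints.columns:
        endpoints["follow_up_time"] = endpoints["time_to_death"]
    if "is_tnbc" not in patients.columns:
        patients["is_tnbc"] = patients["subtype"].eq("TNBC")
    return CohortTables(
        config=config.synth or CohortConfig(),
        seed=config.seed,
        patients=patients,
        visits=visits,
        endpoints=endpoints,
        recurrent_events=recurrent,
        samples=samples,
        hd_samples=hd_samples,
    )


def build_measurements(
    cohort: CohortTables,
    thresholds: ThresholdSet,
    cutoff: int = 5,
) -> pd.DataFrame:
    """Per-(patient, visit) covariate table for time-dependent models.

    Columns: time (months), ctc_count (raw), ctc_high (count >= cutoff),
    tnbc, and fgfr1 (1 when the visit's FGFR1 expression is above the HD
    threshold, carried forward when a visit lacks a usable sample).
    """
    by_id = {s.sample_id: s for s in cohort.samples if s.qc_pass}
    meas = cohort.visits.merge(
        cohort.patients[["patient_id", "is_tnbc"]], on="patient_id"
    )
    meas = meas.rename(columns={"months_from_baseline": "time"})
    meas["ctc_high"] = (meas["ctc_count"] >= cutoff).astype(int)
    meas["tnbc"] = meas["is_tnbc"].astype(int)

    def fgfr1_of(row) -> float:
        s = by_id.get(f"{row.patient_id}V{row.visit}")
        if s is None:
            return np.nan
        return float(classify_gene_group(s, thresholds, "FGFR1") == "high")

    meas["fgfr1"] = meas.apply(fgfr1_of, axis=1)
    meas = meas.sort_values(["patient_id", "visit"])
    meas["fgfr1"] = (
        meas.groupby("patient_id")["fgfr1"].ffill().bfill().fillna(0).astype(int)
    )
    return meas[["patient_id", "visit", "time", "ctc_count", "ctc_high",
                 "tnbc", "fgfr1"]]


def time_dependent_multivariate(
    cohort: CohortTables,
    thresholds: ThresholdSet | None = None,
    cutoff: int = 5,
    cause_specific: bool = False,
) -> dict:
    """The time-dependent multivariate Cox fits for progression and death.

    Progression: CTC >= cutoff (time-dependent, LVCF), TNBC subtype and
    FGFR1-high (time-dependent from expression). Death: CTC >= cutoff and
    TNBC. Robust sandwich variance clustered on patient throughout.

    With ``cause_specific=False`` (the clinical convention) a death without
    documented progression counts as progression at the death date; with
    ``cause_specific=True`` such deaths censor the progression endpoint
    instead, which targets the progression-specific hazard directly (used
    by the simulation recovery suite).
    """
    thresholds = thresholds or calibrate_thresholds(cohort.hd_samples)
    meas = build_measurements(cohort, thresholds, cutoff=cutoff)
    ep = apply_death_imputation(cohort.endpoints)
    if cause_specific:
        ep = ep.copy()
        imput = ep["progression_imputed"].astype(bool)
        ep.loc[imput, "progression_observed"] = False
        ep.loc[imput, "time_to_progression"] = ep.loc[imput, "time_to_death"]
    prog_tab = build_counting_process(
        ep,
        meas[["patient_id", "time", "ctc_high", "tnbc", "fgfr1"]],
        mode="single_event",
        endpoint="pfs",
    )
    prog_fit = cox_fit(
        prog_tab,
        start_col="start", stop_col="stop", event_col="event",
        covariates=["ctc_high", "tnbc", "fgfr1"],
        cluster_col="patient_id", robust=True,
    )
    os_tab = build_counting_process(
        ep,
        meas[["patient_id", "time", "ctc_high", "tnbc"]],
        mode="single_event",
        endpoint="os",
    )
    os_fit = cox_fit(
        os_tab,
        start_col="start", stop_col="stop", event_col="event",
        covariates=["ctc_high", "tnbc"],
        cluster_col="patient_id", robust=True,
    )
    return {"progression": prog_fit, "death": os_fit}


def recurrent_pwp_analysis(
    cohort: CohortTables,
    thresholds: ThresholdSet | None = None,
    cutoff: int = 5,
    covariates: Sequence[str] = ("ctc_high", "tnbc", "fgfr1"),
):
    """PWP total-time recurrent-progression fit with LVCF covariates."""
    thresholds = thresholds or calibrate_thresholds(cohort.hd_samples)
    meas = build_measurements(cohort, thresholds, cutoff=cutoff)
    table = build_counting_process(
        cohort.endpoints,
        meas[["patient_id", "time", *covariates]],
        mode="recurrent_pwp",
        recurrent_events=cohort.recurrent_events,
    )
    return pwp_fit(table, covariates=list(covariates))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the result bundle.

    Returns a manifest dict (also written as ``manifest.json``) mapping
    each output file to its SHA-256 hash, plus run metadata. Partial
    failures in optional comparisons are logged and recorded, not fatal;
    schema violations in inputs fail fast.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    issues: list[str] = []

    cohort = _load_cohort(config)
    thresholds = calibrate_thresholds(cohort.hd_samples)
    thresholds.to_csv(outdir / "thresholds.csv")

    scores = score_samples(cohort.samples, thresholds)
    scores["genes_positive_class"] = np.where(
        scores["positive_count"] >= config.positive_gene_cutoff, "high", "low"
    )
    scores.to_csv(outdir / "scores.csv", index=False, float_format="%.6g")

    ep = apply_death_imputation(cohort.endpoints)
    baseline = cohort.visits[cohort.visits["visit"] == 1][
        ["patient_id", "ctc_count"]
    ].rename(columns={"ctc_count": "baseline_count"})
    ep_b = ep.merge(baseline, on="patient_id", how="left")
    ep_b["baseline_group"] = [
        dichotomize(c, config.cutoff) if not pd.isna(c) else "missing"
        for c in ep_b["baseline_count"]
    ]

    # Kaplan-Meier by baseline CTC group, PFS and OS
    km_rows = []
    for endpoint, tcol, ecol in [
        ("pfs", "time_to_progression", "progression_observed"),
        ("os", "time_to_death", "death_observed"),
    ]:
        for grp, sub in ep_b[ep_b["baseline_group"] != "missing"].groupby(
            "baseline_group"
        ):
            res = km_fit(sub[tcol], sub[ecol])
            sf = res.survival_function.copy()
            sf.insert(0, "group", grp)
            sf.insert(0, "endpoint", endpoint)
            km_rows.append(sf)
    pd.concat(km_rows, ignore_index=True).to_csv(
        outdir / "km_curves.csv", index=False, float_format="%.6g"
    )

    # cutoff sweep at the first follow-up visit
    sweep = cutoff_sweep(
        cohort.visits, ep, cutoffs=range(1, 11), endpoint="pfs", visit=2
    )
    sweep.to_csv(outdir / "cutoff_sweep.csv", index=False, float_format="%.6g")

    # time-dependent multivariate Cox (progression and death)
    fits = time_dependent_multivariate(cohort, thresholds, cutoff=config.cutoff)
    for name, fit in fits.items():
        fit.to_json(outdir / f"cox_td_{name}.json")

    # PWP recurrent-event fit
    try:
        pwp = recurrent_pwp_analysis(cohort, thresholds, cutoff=config.cutoff)
        pwp.to_json(outdir / "pwp_recurrent.json")
    except Exception as exc:
        issues.append(f"PWP fit skipped: {exc}")
        logger.warning("PWP fit skipped: %s", exc)

    # Nelson MCF and incidence rates by baseline CTC group
    ev_map = {
        pid: grp["time"].tolist()
        for pid, grp in cohort.recurrent_events.groupby("patient_id")
    }
    cens_map = dict(zip(ep["patient_id"], ep["follow_up_time"]))
    groups = {
        row.patient_id: row.baseline_group
        for row in ep_b.itertuples()
        if row.baseline_group != "missing"
    }
    mcf = mcf_by_group(
        {p: ev_map.get(p, []) for p in groups},
        {p: cens_map[p] for p in groups},
        groups,
    )
    mcf.to_csv(outdir / "mcf_by_group.csv", index=False, float_format="%.6g")

    rates = {}
    for grp in ("high", "low"):
        pids = [p for p, g in groups.items() if g == grp]
        py = sum(cens_map[p] for p in pids) / 12.0
        n_prog = sum(len(ev_map.get(p, [])) for p in pids)
        n_death = int(
            ep.set_index("patient_id").loc[pids, "death_observed"].sum()
        )
        rates[grp] = {
            "progression": incidence_rate(n_prog, py),
            "death": incidence_rate(n_death, py),
        }
    try:
        rates["irr_progression"] = irr(
            rates["high"]["progression"]["events"],
            rates["high"]["progression"]["person_years"],
            rates["low"]["progression"]["events"],
            rates["low"]["progression"]["person_years"],
        )
        rates["irr_death"] = irr(
            rates["high"]["death"]["events"],
            rates["high"]["death"]["person_years"],
            rates["low"]["death"]["events"],
            rates["low"]["death"]["person_years"],
        )
    except ValueError as exc:
        issues.append(f"IRR skipped: {exc}")
    with open(outdir / "incidence_rates.json", "w") as fh:
        json.dump(rates, fh, indent=2)

    # per-visit comparisons: counts and EM score by progressor status,
    # EM by cluster status
    progressors = set(ep.loc[ep["progression_observed"].astype(bool), "patient_id"])
    vis = cohort.visits.copy()
    vis["progressor"] = vis["patient_id"].isin(progressors)
    comp_rows = []
    for visit, sub in vis.groupby("visit"):
        a = sub.loc[sub["progressor"], "ctc_count"].to_numpy()
        b = sub.loc[~sub["progressor"], "ctc_count"].to_numpy()
        if len(a) and len(b):
            t = rank_sum_test(a, b)
            comp_rows.append(
                {"visit": visit, "measure": "ctc_count",
                 "groups": "progressor_vs_non", "n_a": t["n_a"], "n_b": t["n_b"],
                 "statistic": t["statistic"], "p": t["p"]}
            )
    comparisons = pd.DataFrame(comp_rows)
    if len(comparisons):
        from .longitudinal import holm_correction

        comparisons["p_holm"] = holm_correction(comparisons["p"])
    comparisons.to_csv(outdir / "visit_comparisons.csv", index=False,
                       float_format="%.6g")

    em = scores.merge(
        vis[["patient_id", "visit", "cluster_count", "progressor"]],
        on=["patient_id", "visit"], how="left",
    )
    em_traj = em_trajectory(em.dropna(subset=["progressor"]))
    em_traj.to_csv(outdir / "em_trajectory.csv", index=False, float_format="%.6g")
    cluster_cmp = cluster_em_comparison(em.dropna(subset=["progressor"]))
    cluster_cmp.to_csv(outdir / "cluster_em.csv", index=False, float_format="%.6g")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "cutoff": config.cutoff,
        "positive_gene_cutoff": config.positive_gene_cutoff,
        "synthetic": config.synth is not None,
        "issues": issues,
        "outputs": {},
    }
    for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json")):
        if p.name == "manifest.json":
            continue
        manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
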