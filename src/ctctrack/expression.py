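"""Ct-to-expression transforms, healthy-donor calibration and sample scores.

Expression is measured on the ``40 - Ct`` scale: an undetected gene (Ct at
the 40-cycle assay limit) has expression 0, and lower Ct means higher
expression. Positivity of a gene in a patient sample is judged against
healthy-donor (HD) blood processed the same way: a gene is positive when its
expression exceeds the HD mean by more than one HD standard deviation, with
thresholds calibrated separately for the two processing arms (with and
without red-blood-cell lysis).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import CT_MAX, GenePanel, default_panel

__all__ = [
    "ExpressionSample",
    "ThresholdSet",
    "EMScoreResult",
    "CalibrationError",
    "expression_from_ct",
    "calibrate_thresholds",
    "call_positive_genes",
    "classify_gene_group",
    "total_expression",
    "em_score",
    "hd_zscore",
    "her2_concordance",
    "read_ct_long",
    "read_ct_wide",
    "score_samples",
]

logger = logging.getLogger(__name__)

#: Fraction of panel wells that may be missing before a sample is excluded
#: from score computations.
MAX_MISSING_FRACTION = 0.25

# Expression subsets used for per-sample totals. The epithelial total keeps
# MUC1 (an epithelial marker outside the 4-gene EM subset); the
# mesenchymal/CSC total matches the EM mesenchymal subset.
TOTAL_SUBSETS = {
    "epithelial": ("CDH1", "EPCAM", "KRT18", "KRT7", "MUC1"),
    "mesenchymal": ("ALDH1A1", "CDH2", "FN1", "ZEB2"),
}


class CalibrationError(ValueError):
    """Raised when HD threshold calibration is impossible for an arm."""


def expression_from_ct(ct: float, ct_max: float = CT_MAX) -> float:
    """Convert a cycle-threshold value to an expression level (``ct_max - ct``).

    Parameters
    ----------
    ct
        Cycle threshold in ``[0, ct_max]``; ``ct == ct_max`` encodes an
        undetected gene and maps to expression 0.
    ct_max
        Assay limit in cycles (default 40).
    """
    if not (0.0 <= ct <= ct_max):
        raise ValueError(f"Ct value {ct} outside [0, {ct_max}]")
    return ct_max - ct


@dataclass
class ExpressionSample:
    """One qRT-PCR sample: Ct values plus processing arm and identity.

    Missing panel wells are recorded as undetected (Ct = ``ct_max``) and
    logged; a sample missing more than :data:`MAX_MISSING_FRACTION` of panel
    wells is flagged (``qc_pass = False``) and excluded from score
    computations.
    """

    sample_id: str
    patient_id: str
    visit: int | None
    rbc_lysis: bool
    ct: dict[str, float]
    panel: GenePanel = field(default_factory=default_panel)
    ct_max: float = CT_MAX
    qc_notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ct = {g.upper(): float(v) for g, v in self.ct.items()}
        for g, v in self.ct.items():
            if not (0.0 <= v <= self.ct_max):
                raise ValueError(
                    f"sample {self.sample_id}: Ct {v} for {g} outside [0, {self.ct_max}]"
                )
        missing = [g for g in self.panel.symbols if g not in self.ct]
        for g in missing:
            self.ct[g] = self.ct_max
            self.qc_notes.append(f"missing well {g}: recorded as undetected")
        self.n_missing = len(missing)
        if missing:
            logger.warning(
                "sample %s: %d missing wells recorded as undetected (%s)",
                self.sample_id, len(missing), ",".join(missing),
            )

    @property
    def qc_pass(self) -> bool:
        return self.n_missing <= MAX_MISSING_FRACTION * len(self.panel)

    @property
    def expression(self) -> dict[str, float]:
        """Per-gene expression level on the ``ct_max - Ct`` scale."""
        return {g: self.ct_max - v for g, v in self.ct.items()}

    def expression_of(self, gene: str) -> float:
        return self.ct_max - self.ct[gene.upper()]

    @property
    def arm(self) -> str:
        return "lysis" if self.rbc_lysis else "no_lysis"


@dataclass
class ThresholdSet:
    """Per-(gene, arm) HD summary statistics and positivity thresholds.

    ``table`` is indexed by (gene, arm) with columns ``hd_mean``, ``hd_sd``,
    ``threshold`` (= mean + 1 SD) and ``n_hd``. Arms are named ``lysis`` and
    ``no_lysis``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"hd_mean", "hd_sd", "threshold", "n_hd"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"threshold table needs columns {sorted(required)}")
        if (self.table["hd_sd"] < 0).any():
            raise ValueError("negative hd_sd in threshold table")

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(self.table.index.get_level_values("arm").unique())

    def threshold(self, gene: str, arm: str) -> float:
        return float(self.table.loc[(gene.upper(), arm), "threshold"])

    def stats(self, gene: str, arm: str) -> tuple[float, float]:
        row = self.table.loc[(gene.upper(), arm)]
        return float(row["hd_mean"]), float(row["hd_sd"])

    def to_csv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ThresholdSet":
        df = pd.read_csv(path).set_index(["gene", "arm"])
        return cls(df)


def calibrate_thresholds(hd_samples: Iterable[ExpressionSample]) -> ThresholdSet:
    """Calibrate per-(gene, arm) positivity thresholds from HD samples.

    For each gene and processing arm the threshold is the HD mean expression
    plus one sample standard deviation (n-1 divisor). Both arms must supply
    at least two HD samples so the SD is defined.
    """
    samples = list(hd_samples)
    if not samples:
        raise CalibrationError("no HD samples supplied")
    panel = samples[0].panel
    rows = []
    by_arm: dict[str, list[ExpressionSample]] = {"lysis": [], "no_lysis": []}
    for s in samples:
        by_arm[s.arm].append(s)
    for arm, arm_samples in by_arm.items():
        if len(arm_samples) < 2:
            raise CalibrationError(
                f"arm {arm!r}: {len(arm_samples)} HD sample(s); need at least 2"
            )
        for gene in panel.symbols:
            levels = np.array([s.expression_of(gene) for s in arm_samples])
            mean = float(levels.mean())
            sd = float(levels.std(ddof=1))
            rows.append(
                {
                    "gene": gene,
                    "arm": arm,
                    "hd_mean": mean,
                    "hd_sd": sd,
                    "threshold": mean + sd,
                    "n_hd": len(arm_samples),
                }
            )
    table = pd.DataFrame(rows).set_index(["gene", "arm"])
    return ThresholdSet(table)


def call_positive_genes(
    sample: ExpressionSample, thresholds: ThresholdSet
) -> tuple[set[str], int]:
    """Call positive genes in a sample against its arm's thresholds.

    A gene is positive when expression is *strictly* greater than the HD
    mean + 1 SD threshold; equality is negative. Returns the set of positive
    gene symbols (all panel genes considered) and ``positive_count``, which
    counts CTC-related genes only.
    """
    arm = sample.arm
    if arm not in thresholds.arms:
        raise KeyError(f"processing arm {arm!r} absent from threshold set")
    positives: set[str] = set()
    for gene, level in sample.expression.items():
        try:
            thr = thresholds.threshold(gene, arm)
        except KeyError:
            raise KeyError(f"gene {gene!r} has no calibrated threshold") from None
        if level > thr:
            positives.add(gene)
    ctc = set(sample.panel.ctc_genes)
    return positives, len(positives & ctc)


def classify_gene_group(
    sample: ExpressionSample, thresholds: ThresholdSet, gene: str
) -> str:
    """Classify one gene as ``"high"`` (> HD mean + 1 SD) or ``"low"``.

    This is the covariate-building rule for expression groups (e.g. FGFR1
    high/low) and the HER2+ CTC call on ERBB2.
    """
    gene = gene.upper()
    thr = thresholds.threshold(gene, sample.arm)
    return "high" if sample.expression_of(gene) > thr else "low"


def total_expression(sample: ExpressionSample, gene_subset: str = "all_ctc") -> float:
    """Sum expression over a gene subset.

    ``gene_subset`` is ``"all_ctc"`` (the 17 CTC-related genes),
    ``"epithelial"`` or ``"mesenchymal"``.
    """
    if gene_subset == "all_ctc":
        genes = sample.panel.ctc_genes
    elif gene_subset in TOTAL_SUBSETS:
        genes = TOTAL_SUBSETS[gene_subset]
    else:
        raise ValueError(f"unknown gene subset {gene_subset!r}")
    return float(sum(sample.expression_of(g) for g in genes))


@dataclass(frozen=True)
class EMScoreResult:
    """EM score with its component sums (all on the ``40 - Ct`` scale).

    ``value`` is in [-1, +1] when defined: +1 when only mesenchymal/stem EM
    genes are detected, -1 when only epithelial EM genes are detected. The
    score is undefined (``value is None``) when none of the 8 EM genes is
    detected; such samples are excluded from downstream EM analyses.
    """

    epi_sum: float
    mes_sum: float

    @property
    def all_sum(self) -> float:
        return self.epi_sum + self.mes_sum

    @property
    def defined(self) -> bool:
        return self.all_sum > 0

    @property
    def value(self) -> float | None:
        if not self.defined:
            return None
        return (self.mes_sum - self.epi_sum) / self.all_sum


def em_score(sample: ExpressionSample) -> EMScoreResult:
    """Compute the epithelial-mesenchymal score of a sample.

    EM = (sum over 4 mes genes of (40-Ct) - sum over 4 epi genes of (40-Ct))
    divided by the sum over all 8 EM genes of (40-Ct).
    """
    panel = sample.panel
    missing = [g for g in panel.em_genes if g not in sample.ct]
    if missing:
        raise ValueError(f"sample {sample.sample_id}: missing EM genes {missing}")
    epi = sum(sample.expression_of(g) for g in panel.em_epi_genes)
    mes = sum(sample.expression_of(g) for g in panel.em_mes_genes)
    return EMScoreResult(epi_sum=epi, mes_sum=mes)


def hd_zscore(
    sample: ExpressionSample, thresholds: ThresholdSet
) -> dict[str, float]:
    """Per-gene Z-scores relative to HD statistics of the matching arm.

    Z = (expression - hd_mean) / hd_sd; NaN (with a QC note) where hd_sd is
    zero. Expression exactly at the positivity threshold maps to Z = 1.
    """
    arm = sample.arm
    out: dict[str, float] = {}
    for gene, level in sample.expression.items():
        mean, sd = thresholds.stats(gene, arm)
        if sd == 0:
            out[gene] = math.nan
            sample.qc_notes.append(f"hd_sd=0 for {gene} ({arm}): Z undefined")
        else:
            out[gene] = (level - mean) / sd
    return out


def her2_concordance(
    ctc_calls: Mapping[str, str], tissue_status: Mapping[str, str]
) -> pd.DataFrame:
    """Cross-tabulate per-patient HER2 status on CTCs vs metastatic tissue.

    Both mappings use values ``"positive"`` / ``"negative"``. Patients
    missing either status are excluded and logged. Returns a tidy frame with
    one row per evaluable patient and a ``concordance`` label
    (``concordant_positive`` / ``concordant_negative`` / ``discordant``).
    """
    rows = []
    for pid in sorted(set(ctc_calls) | set(tissue_status)):
        ctc = ctc_calls.get(pid)
        tissue = tissue_status.get(pid)
        if ctc is None or tissue is None:
            logger.info("HER2 concordance: patient %s missing a status, excluded", pid)
            continue
        if ctc == tissue:
            label = f"concordant_{ctc}"
        else:
            label = "discordant"
        rows.append({"patient_id": pid, "ctc": ctc, "tissue": tissue,
                     "concordance": label})
    return pd.DataFrame(rows, columns=["patient_id", "ctc", "tissue", "concordance"])


def normalize_delta_ct(
    sample: ExpressionSample, reference_ct: float = 25.0
) -> ExpressionSample:
    """Optional housekeeping (ΔCt) normalization; off by default in scoring.

    Shifts every gene's Ct by the difference between the sample's mean
    housekeeping Ct and ``reference_ct``, so samples with more input RNA are
    brought to a common scale. The result is clipped to [0, ct_max] and the
    default raw ``40 - Ct`` scale is retained downstream; calibration and
    scoring work unchanged on the normalized sample.
    """
    hk = [sample.ct[g] for g in sample.panel.housekeeping_genes]
    detected = [v for v in hk if v < sample.ct_max]
    if not detected:
        sample.qc_notes.append("no housekeeping gene detected; dCt skipped")
        return sample
    shift = float(np.mean(detected)) - reference_ct
    ct = {
        g: (v if v >= sample.ct_max else min(max(v - shift, 0.0), sample.ct_max))
        for g, v in sample.ct.items()
    }
    return ExpressionSample(
        sample_id=sample.sample_id,
        patient_id=sample.patient_id,
        visit=sample.visit,
        rbc_lysis=sample.rbc_lysis,
        ct=ct,
        panel=sample.panel,
        ct_max=sample.ct_max,
    )


# ---------------------------------------------------------------------------
# CSV input / scoring output


def read_ct_long(path: str | Path, panel: GenePanel | None = None) -> list[ExpressionSample]:
    """Read a long-format Ct CSV: sample_id, patient_id, visit, rbc_lysis, gene, ct."""
    df = pd.read_csv(path)
    required = {"sample_id", "patient_id", "visit", "rbc_lysis", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct CSV missing columns {sorted(missing)}")
    panel = panel or default_panel()
    samples = []
    for (sid, pid, visit, lysis), grp in df.groupby(
        ["sample_id", "patient_id", "visit", "rbc_lysis"], sort=False, dropna=False
    ):
        ct = dict(zip(grp["gene"].str.upper(), grp["ct"].astype(float)))
        samples.append(
            ExpressionSample(
                sample_id=str(sid),
                patient_id=str(pid),
                visit=None if pd.isna(visit) else int(visit),
                rbc_lysis=bool(lysis),
                ct=ct,
                panel=panel,
            )
        )
    return samples


def read_ct_wide(path: str | Path, panel: GenePanel | None = None) -> list[ExpressionSample]:
    """Read a wide-format Ct CSV: one row per sample, one column per gene."""
    df = pd.read_csv(path)
    panel = panel or default_panel()
    meta = {"sample_id", "patient_id", "visit", "rbc_lysis"}
    missing = meta - set(df.columns)
    if missing:
        raise ValueError(f"Ct CSV missing columns {sorted(missing)}")
    gene_cols = [c for c in df.columns if c not in meta]
    samples = []
    for _, row in df.iterrows():
        ct = {g: float(row[g]) for g in gene_cols if not pd.isna(row[g])}
        samples.append(
            ExpressionSample(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                visit=None if pd.isna(row["visit"]) else int(row["visit"]),
                rbc_lysis=bool(row["rbc_lysis"]),
                ct=ct,
                panel=panel,
            )
        )
    return samples


def score_samples(
    samples: Iterable[ExpressionSample], thresholds: ThresholdSet
) -> pd.DataFrame:
    """Score samples against a threshold set into a tidy per-sample table.

    Columns: identity, QC flag, positive_count, expression totals, EM score
    (NaN when undefined), FGFR1/ERBB2 groups, and per-gene HD Z-scores
    (``z_<GENE>``). Samples failing QC are kept in the table with scores NaN.
    """
    rows = []
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "visit": s.visit,
            "rbc_lysis": s.rbc_lysis,
            "qc_pass": s.qc_pass,
        }
        if s.qc_pass:
            _, pos = call_positive_genes(s, thresholds)
            em = em_score(s)
            row.update(
                positive_count=pos,
                total_all_ctc=total_expression(s, "all_ctc"),
                total_epithelial=total_expression(s, "epithelial"),
                total_mesenchymal=total_expression(s, "mesenchymal"),
                em_score=em.value if em.defined else math.nan,
                fgfr1_group=classify_gene_group(s, thresholds, "FGFR1"),
                erbb2_group=classify_gene_group(s, thresholds, "ERBB2"),
            )
            for g, z in hd_zscore(s, thresholds).items():
                row[f"z_{g}"] = z
        else:
            logger.warning("sample %s failed QC; scores omitted", s.sample_id)
        rows.append(row)
    return pd.DataFrame(rows)
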