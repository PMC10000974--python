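"""Per-visit group comparisons and trajectory summaries.

Rank-based two-sample and paired tests (Wilcoxon), Bonferroni-Holm
multiplicity correction, EM-score trajectories by progression status, and
cluster-vs-no-cluster EM comparisons. All tests are two-sided.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test",
    "signed_rank_change",
    "holm_correction",
    "em_trajectory",
    "cluster_em_comparison",
]

logger = logging.getLogger(__name__)


def rank_sum_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_below_n: int = 25,
) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have at most ``exact_below_n``
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = len(a) <= exact_below_n and len(b) <= exact_below_n and not ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n_a": len(a),
        "n_b": len(b),
        "method": "exact" if exact else "normal_approx",
    }


def signed_rank_change(
    baseline_values: Sequence[float],
    followup_values: Sequence[float],
    exact_below_n: int = 20,
) -> dict:
    """Wilcoxon signed-rank test of paired within-patient change.

    Pairs with zero difference are dropped (Wilcoxon convention); with no
    nonzero pairs the p-value is reported missing. Exact when at most
    ``exact_below_n`` nonzero pairs, normal approximation otherwise.
    """
    base = np.asarray(baseline_values, float)
    fol = np.asarray(followup_values, float)
    if base.shape != fol.shape:
        raise ValueError("baseline and follow-up must pair one-to-one")
    diffs = fol - base
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        logger.info("signed-rank: all differences zero, p undefined")
        return {"statistic": math.nan, "p": math.nan, "n_nonzero": 0,
                "method": "undefined"}
    exact = len(nonzero) <= exact_below_n
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=not exact,
        mode="exact" if exact else "approx",
    )
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n_nonzero": int(len(nonzero)),
        "method": "exact" if exact else "normal_approx",
    }


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Bonferroni-Holm adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


def em_trajectory(
    scores: pd.DataFrame,
    group_col: str = "progressor",
    visit_col: str = "visit",
    score_col: str = "em_score",
) -> pd.DataFrame:
    """Per-visit EM-score medians by progression status with Welch t-tests.

    Samples with an undefined EM score (NaN) are excluded. A visit with
    fewer than two defined scores in either group gets its test skipped
    (p reported NaN, with a log entry). Also reports per-visit median
    change from baseline per group, pairing each patient's visit score with
    their own baseline.
    """
    df = scores.dropna(subset=[score_col]).copy()
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    g0, g1 = groups
    baseline = (
        df[df[visit_col] == 1]
        .set_index("patient_id")[score_col]
        .to_dict()
    )
    rows = []
    for visit, at_visit in df.groupby(visit_col):
        a = at_visit.loc[at_visit[group_col] == g0, score_col].to_numpy()
        b = at_visit.loc[at_visit[group_col] == g1, score_col].to_numpy()
        delta = at_visit[score_col] - at_visit["patient_id"].map(baseline)
        rec = {
            "visit": visit,
            "group_a": g0,
            "group_b": g1,
            "n_a": len(a),
            "n_b": len(b),
            "median_a": float(np.median(a)) if len(a) else math.nan,
            "median_b": float(np.median(b)) if len(b) else math.nan,
            "median_change_a": float(
                delta[at_visit[group_col] == g0].median()
            ) if len(a) else math.nan,
            "median_change_b": float(
                delta[at_visit[group_col] == g1].median()
            ) if len(b) else math.nan,
            "p": math.nan,
        }
        if len(a) >= 2 and len(b) >= 2:
            rec["p"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            logger.info("em_trajectory: visit %s skipped (<2 scores in a group)", visit)
        rows.append(rec)
    return pd.DataFrame(rows).sort_values("visit").reset_index(drop=True)


def cluster_em_comparison(
    scores: pd.DataFrame,
    cluster_col: str = "cluster_count",
    group_col: str = "progressor",
    score_col: str = "em_score",
) -> pd.DataFrame:
    """Rank-sum EM-score comparison of cluster-positive vs -negative samples.

    Run separately within each progression stratum; strata with an empty
    side are skipped with a log entry.
    """
    df = scores.dropna(subset=[score_col])
    rows = []
    for stratum, sub in df.groupby(group_col):
        with_cl = sub.loc[sub[cluster_col] > 0, score_col].to_numpy()
        without = sub.loc[sub[cluster_col] == 0, score_col].to_numpy()
        if len(with_cl) == 0 or len(without) == 0:
            logger.info("cluster EM comparison: stratum %s skipped (empty side)",
                        stratum)
            continue
        test = rank_sum_test(with_cl, without)
        rows.append(
            {
                "stratum": stratum,
                "n_clusters": len(with_cl),
                "n_no_clusters": len(without),
                "median_clusters": float(np.median(with_cl)),
                "median_no_clusters": float(np.median(without)),
                "statistic": test["statistic"],
                "p": test["p"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["stratum", "n_clusters", "n_no_clusters", "median_clusters",
                 "median_no_clusters", "statistic", "p"],
    )
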