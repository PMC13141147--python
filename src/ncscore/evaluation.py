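"""The four evaluation procedures and their metrics.

* Region-stratified AUROC/AUPR report (global + six region rows, canonical
  order), per score column.
* Per-gene region-bias analysis: medians of common-variant scores per
  (gene, region), compared against pathogenic scores region by region.
* Simulated disease-genome spike-in: within-individual rank percentile of
  inserted pathogenic variants vs their matched common variants.
* Splice added-value: per-gene top splice position score vs the model's score
  at that position, compared across disease and non-disease genes on the gene
  rank percentile scale.

AUROC uses the rank-statistic formulation (probability a random positive
outranks a random negative, ties half-credited); AUPR is the average
precision step-sum with tied scores grouped into one step.  Percentiles use
the midrank (k + t/2)/(n+1) convention, avoiding 0/100 saturation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .regions import REGION_NAMES
from .stats import ranksum_test, signed_rank_test


# ---------------------------------------------------------------------------
# metrics


def auroc(labels, scores) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2).

    Equals the trapezoidal area under the ROC curve.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - npos * (npos + 1) / 2) / (npos * nneg))


def aupr(labels, scores) -> float:
    """Average precision: step-sum over recalled positives, ties grouped."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    npos = int((y == 1).sum())
    if npos == 0 or (y == 0).sum() == 0:
        raise ValueError("aupr requires both classes present")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    # group equal scores into single thresholds
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    ends = np.append(boundaries, len(s_sorted))
    tp = np.cumsum(y_sorted)[ends - 1]
    n_seen = ends
    precision = tp / n_seen
    recall = tp / npos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev_recall) * precision).sum())


def rank_percentiles(values) -> np.ndarray:
    """Midrank percentiles on the (rank)/(n+1) scale, in [0, 100]."""
    v = np.asarray(values, dtype=float)
    return 100.0 * rankdata(v) / (len(v) + 1)


# ---------------------------------------------------------------------------
# region-stratified report


def region_stratified_report(
    scored: pd.DataFrame,
    score_columns: Sequence[str] = ("score",),
    setting: str = "cross-validation",
) -> pd.DataFrame:
    """Global + per-region AUROC/AUPR rows for each score column.

    ``scored`` needs ``label``, ``region`` and the score columns.  Regions
    with a single class present get NA metrics and a warning, never silent
    dropping.  Region counts sum to the global counts.
    """
    rows = []
    subsets = [("global", scored)] + [
        (r, scored[scored["region"] == r]) for r in REGION_NAMES
    ]
    for region, sub in subsets:
        row: dict = {
            "setting": setting,
            "region": region,
            "n_pathogenic": int((sub["label"] == 1).sum()),
            "n_benign": int((sub["label"] == 0).sum()),
        }
        for col in score_columns:
            ok = sub[col].notna()
            try:
                row[f"auroc_{col}"] = auroc(sub.loc[ok, "label"], sub.loc[ok, col])
                row[f"aupr_{col}"] = aupr(sub.loc[ok, "label"], sub.loc[ok, col])
            except ValueError:
                if len(sub):
                    warnings.warn(
                        f"region {region!r}: single class present, metrics set to NA")
                row[f"auroc_{col}"] = np.nan
                row[f"aupr_{col}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-gene region-bias analysis


def gene_region_bias(
    common_scored: pd.DataFrame,
    pathogenic_scored: pd.DataFrame,
    score_column: str = "score",
) -> pd.DataFrame:
    """Compare per-gene 5'UTR medians of common scores against pathogenic scores.

    ``common_scored`` (unlabeled common variants) needs gene_id, region and
    the score column; ``pathogenic_scored`` needs region and the score column.
    For each region r, a one-sided rank-sum test asks whether pathogenic
    scores in r exceed the per-gene 5'UTR common medians.  Gene-region medians
    from a single variant are kept but flagged in ``n_singleton_genes``.
    """
    med = (common_scored.groupby(["gene_id", "region"])[score_column]
           .agg(["median", "size"]).reset_index())
    utr5 = med[med["region"] == "UTR5"]
    utr5_medians = utr5["median"].to_numpy()
    rows = []
    for r in REGION_NAMES:
        sub = med[med["region"] == r]
        patho = pathogenic_scored.loc[
            pathogenic_scored["region"] == r, score_column].dropna().to_numpy()
        row = {
            "region": r,
            "n_genes": int(len(sub)),
            "n_singleton_genes": int((sub["size"] == 1).sum()),
            "common_median_of_gene_medians": float(sub["median"].median()) if len(sub) else np.nan,
            "n_pathogenic": int(len(patho)),
        }
        if len(patho) and len(utr5_medians):
            stat, p = ranksum_test(patho, utr5_medians, alternative="greater")
            row["p_pathogenic_gt_utr5_common"] = p
            row["direction"] = float(np.median(patho) - np.median(utr5_medians))
        else:
            row["p_pathogenic_gt_utr5_common"] = np.nan
            row["direction"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulated disease-genome spike-in


@dataclass
class SpikeInResult:
    """Within-individual rank percentiles of inserted variants."""

    table: pd.DataFrame  # individual, insertion, pathogenic_pct, common_pct
    median_pathogenic_pct: float
    median_common_pct: float
    p_pathogenic_gt_common: float
    statistic: float

    def to_dict(self) -> dict:
        return {
            "median_pathogenic_pct": self.median_pathogenic_pct,
            "median_common_pct": self.median_common_pct,
            "p_pathogenic_gt_common": self.p_pathogenic_gt_common,
            "statistic": self.statistic,
        }


def _percentile_in_background(background_sorted: np.ndarray, value: float) -> float:
    n = len(background_sorted)
    lo = np.searchsorted(background_sorted, value, side="left")
    hi = np.searchsorted(background_sorted, value, side="right")
    return 100.0 * (lo + 0.5 * (hi - lo)) / (n + 1)


def spike_in_ranking(
    backgrounds: Sequence[np.ndarray],
    insertions: Sequence[tuple[float, float]],
) -> SpikeInResult:
    """Rank each inserted (pathogenic, matched common) score pair within each
    individual's background score distribution.

    Percentile = 100 * (#background strictly below + ties/2) / (n + 1); the
    inserted variant itself is not part of the background.  The paired
    one-sided Wilcoxon signed-rank test asks whether pathogenic percentiles
    exceed the matched-common percentiles.
    """
    if len(backgrounds) == 0 or len(insertions) == 0:
        raise ValueError("backgrounds and insertions must be non-empty")
    rows = []
    for i, bg in enumerate(backgrounds):
        bg = np.sort(np.asarray(bg, dtype=float))
        if len(bg) == 0:
            raise ValueError(f"individual {i}: empty background")
        for j, (p_score, c_score) in enumerate(insertions):
            rows.append((i, j,
                         _percentile_in_background(bg, p_score),
                         _percentile_in_background(bg, c_score)))
    table = pd.DataFrame(rows, columns=["individual", "insertion",
                                        "pathogenic_pct", "common_pct"])
    diffs = table["pathogenic_pct"].to_numpy() - table["common_pct"].to_numpy()
    stat, p = signed_rank_test(diffs, alternative="greater")
    return SpikeInResult(
        table=table,
        median_pathogenic_pct=float(table["pathogenic_pct"].median()),
        median_common_pct=float(table["common_pct"].median()),
        p_pathogenic_gt_common=p,
        statistic=stat,
    )


def compare_spike_in_methods(a: SpikeInResult, b: SpikeInResult) -> tuple[float, float]:
    """One-sided paired signed-rank: method a's pathogenic percentiles > b's."""
    if len(a.table) != len(b.table):
        raise ValueError("methods must rank the same (individual, insertion) pairs")
    diffs = a.table["pathogenic_pct"].to_numpy() - b.table["pathogenic_pct"].to_numpy()
    return signed_rank_test(diffs, alternative="greater")


# ---------------------------------------------------------------------------
# splice added-value


def splice_added_value(
    per_gene: pd.DataFrame,
    splice_column: str = "splice_score",
    model_column: str = "model_score",
    disease_column: str = "is_disease_gene",
) -> dict:
    """Compare gene-rank percentiles of the top splice position's raw splice
    score vs the model's score at that position, across disease and
    non-disease genes.

    One row per gene.  Both columns are converted to midrank percentiles over
    all genes; each column gets a two-sided rank-sum test of disease vs
    non-disease percentiles, and the two columns are compared with a paired
    two-sided signed-rank test restricted to disease genes.
    """
    disease = per_gene[disease_column].astype(bool).to_numpy()
    if disease.sum() < 2 or (~disease).sum() < 2:
        raise ValueError("need at least 2 genes in each of disease/non-disease")
    out: dict = {"n_disease": int(disease.sum()), "n_non_disease": int((~disease).sum())}
    pcts = {}
    for col in (splice_column, model_column):
        pct = rank_percentiles(per_gene[col].to_numpy())
        pcts[col] = pct
        stat, p = ranksum_test(pct[disease], pct[~disease], alternative="two-sided")
        out[f"p_disease_vs_nondisease_{col}"] = p
        out[f"median_disease_pct_{col}"] = float(np.median(pct[disease]))
        out[f"median_nondisease_pct_{col}"] = float(np.median(pct[~disease]))
    diffs = pcts[model_column][disease] - pcts[splice_column][disease]
    stat, p = signed_rank_test(diffs, alternative="two-sided")
    out["p_model_vs_splice_disease_genes"] = p
    out["statistic_model_vs_splice"] = stat
    out["direction_model_minus_splice"] = float(np.median(diffs))
    return out
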