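"""High-confidence curation of clinical assertion records and negative pools.

The positive set is built from ClinVar/HGMD-style assertion tables by a fixed
filter cascade: SNVs only, scorable non-coding region assigned, internally
consistent pathogenic assertions, monogenic Mendelian inheritance, no evidence
of homozygosity in population references, rare in the population, and finally
de-duplication by variant key.  The filters are pure predicates, so the final
set is order-insensitive; the telescoping per-filter report is order-defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .regions import REGION_NAMES, variant_key

logger = logging.getLogger(__name__)

PATHOGENIC_SIDE = {"pathogenic", "likely_pathogenic"}
BENIGN_SIDE = {"benign", "likely_benign"}
UNCERTAIN = {"uncertain"}

DEFAULT_MAX_HOMOZYGOTES = 0
DEFAULT_MAX_AF = 0.001
DEFAULT_COMMON_AF_MIN = 0.01
DEFAULT_RARE_AF_MAX = 0.001


@dataclass
class CurationReport:
    """Telescoping per-filter record counts: out of filter i feeds filter i+1."""

    steps: list[dict] = field(default_factory=list)
    final_size: int = 0
    n_genes: int = 0

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.steps.append({"filter": name, "n_in": n_in,
                           "n_removed": n_in - n_out, "n_out": n_out})

    def to_dict(self) -> dict:
        return {"steps": self.steps, "final_size": self.final_size,
                "n_genes": self.n_genes}


def _assertion_set(value) -> set[str]:
    if isinstance(value, (list, tuple, set)):
        return {str(v).strip() for v in value}
    return {s.strip() for s in str(value).split(",") if s.strip()}


def _consistent_pathogenic(assertions: set[str]) -> bool:
    """High-confidence pathogenic: at least one pathogenic-side assertion and
    no benign-side or uncertain assertion alongside it."""
    return bool(assertions & PATHOGENIC_SIDE) and not (assertions & (BENIGN_SIDE | UNCERTAIN))


def curate_positive_set(
    records: pd.DataFrame,
    max_homozygotes: int = DEFAULT_MAX_HOMOZYGOTES,
    max_af: float = DEFAULT_MAX_AF,
) -> tuple[pd.DataFrame, CurationReport]:
    """Apply the high-confidence filter cascade to clinical assertion records.

    ``records`` must already carry region assignments (columns ``region`` and
    ``gene_id``) plus ``assertions`` (comma-separated labels), ``inheritance``,
    ``n_homozygotes`` and ``pop_af``.  Returns the surviving variants labelled
    positive and the telescoping :class:`CurationReport`.  Empty output is
    legal and logged, not an error.
    """
    report = CurationReport()
    df = records.copy()

    n = len(df)
    df = df[(df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)]
    report.add("snv_only", n, len(df))

    n = len(df)
    df = df[df["region"].isin(REGION_NAMES)]
    report.add("scorable_noncoding_region", n, len(df))

    n = len(df)
    # assertion-conflict filter applies across all sources for a variant key
    df = df.assign(_key=variant_key(df))
    merged = df.groupby("_key")["assertions"].apply(
        lambda col: set().union(*(_assertion_set(v) for v in col)))
    ok_keys = set(merged[merged.map(_consistent_pathogenic)].index)
    df = df[df["_key"].isin(ok_keys)]
    report.add("consistent_pathogenic_assertions", n, len(df))

    n = len(df)
    df = df[df["inheritance"] == "monogenic_mendelian"]
    report.add("monogenic_mendelian", n, len(df))

    n = len(df)
    df = df[(df["n_homozygotes"] <= max_homozygotes) & (df["pop_af"] <= max_af)]
    report.add("no_homozygotes_and_rare", n, len(df))

    n = len(df)
    df = df.drop_duplicates(subset="_key", keep="first").drop(columns="_key")
    report.add("dedup_variant_key", n, len(df))

    report.final_size = len(df)
    report.n_genes = df["gene_id"].nunique()
    if report.final_size == 0:
        logger.warning("curate_positive_set: no records survived the filters")
    out = df.copy()
    out["label"] = 1
    return out.reset_index(drop=True), report


def build_negative_pool(
    variants: pd.DataFrame,
    mode: str = "common",
    common_af_min: float = DEFAULT_COMMON_AF_MIN,
    rare_af_max: float = DEFAULT_RARE_AF_MAX,
    positives: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the common or rare candidate negative pool.

    ``variants`` must be region-assigned and carry ``pop_af``; variants that
    also appear in the positive set are removed with a logged count.  The
    returned frame keeps region and gene columns so the matched sampler can
    index it by (partition, region, gene).
    """
    if mode not in ("common", "rare"):
        raise ValueError(f"mode must be 'common' or 'rare', got {mode!r}")
    df = variants[variants["region"].isin(REGION_NAMES)].copy()
    if mode == "common":
        df = df[df["pop_af"] >= common_af_min]
    else:
        df = df[(df["pop_af"] > 0) & (df["pop_af"] <= rare_af_max)]
    if positives is not None and len(positives):
        pos_keys = set(variant_key(positives))
        before = len(df)
        df = df[~variant_key(df).isin(pos_keys)]
        removed = before - len(df)
        if removed:
            logger.info("build_negative_pool: removed %d variants overlapping the positive set", removed)
    out = df.copy()
    out["label"] = 0
    return out.reset_index(drop=True)
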