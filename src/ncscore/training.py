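"""Training-table construction: per-gene positive capping and region- and
partition-matched negative sampling at a fixed positive:negative ratio.

Each curated positive is paired with ``ratio`` negatives drawn without
replacement from the candidate pool, restricted to the positive's genomic
partition and region type.  At most one positive per gene enters the table,
and by default at most one negative per gene across the whole table; when the
distinct-gene constraint cannot be met for some positive it is relaxed for
that positive only (repeat genes allowed across pairing groups, still at most
one per gene within a group) and the relaxation is recorded in the sampling
metadata.  The global ratio is exact whenever the call succeeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partitioning import PartitionMap
from .regions import variant_key

logger = logging.getLogger(__name__)

DEFAULT_RATIO = 10


@dataclass
class TrainingTable:
    """Label-1/label-0 rows plus pairing ids and sampling metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_positives(self) -> int:
        return int((self.table["label"] == 1).sum())

    @property
    def n_negatives(self) -> int:
        return int((self.table["label"] == 0).sum())


def cap_positives_per_gene(positives: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Retain at most one positive per gene, chosen uniformly with the seed."""
    rng = np.random.default_rng(seed)
    df = positives.sort_values(["gene_id", "chrom", "pos", "ref", "alt"]).reset_index(drop=True)
    keep = []
    for _, idx in df.groupby("gene_id", sort=True).groups.items():
        idx = list(idx)
        keep.append(idx[int(rng.integers(len(idx)))])
    return df.loc[sorted(keep)].reset_index(drop=True)


def sample_matched_negatives(
    positives: pd.DataFrame,
    pool: pd.DataFrame,
    partition_map: PartitionMap,
    ratio: int = DEFAULT_RATIO,
    seed: int = 0,
    exclude_positive_gene: bool = False,
) -> TrainingTable:
    """Pair every positive with ``ratio`` matched negatives.

    ``positives`` and ``pool`` must carry gene_id and region; partitions are
    looked up through ``partition_map``.  Candidates must match the positive's
    (partition, region) cell.  Raises ``ValueError`` naming the exhausted cell
    when even the relaxed draw cannot supply ``ratio`` negatives.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)

    pos = positives.copy().reset_index(drop=True)
    pos["partition"] = partition_map.partitions_of(pos["gene_id"])
    pl = pool.copy().reset_index(drop=True)
    pl["partition"] = partition_map.partitions_of(pl["gene_id"])
    pl["_key"] = variant_key(pl)

    # deterministic positive processing order
    pos = pos.sort_values(["chrom", "pos", "ref", "alt"]).reset_index(drop=True)

    cells: dict[tuple[int, str], list[int]] = {
        (int(part), str(region)): list(idx)
        for (part, region), idx in pl.groupby(["partition", "region"], sort=True).groups.items()
    }
    pool_gene = pl["gene_id"].to_numpy()
    used_rows: set[int] = set()
    used_genes: set[str] = set()
    relaxations: list[str] = []

    neg_rows: list[int] = []
    neg_pairing: list[int] = []
    for pid, p in enumerate(pos.itertuples(index=False)):
        cell_key = (int(p.partition), str(p.region))
        cell = cells.get(cell_key, [])
        avail = [i for i in cell if i not in used_rows]
        if exclude_positive_gene:
            avail = [i for i in avail if pool_gene[i] != p.gene_id]
        order = rng.permutation(len(avail))
        chosen: list[int] = []
        group_genes: set[str] = set()
        # strict pass: genes unused globally
        for j in order:
            i = avail[j]
            g = pool_gene[i]
            if g in used_genes or g in group_genes:
                continue
            chosen.append(i)
            group_genes.add(g)
            if len(chosen) == ratio:
                break
        if len(chosen) < ratio:
            # relaxed pass: allow genes already used in other pairing groups,
            # still at most one per gene within this group
            for j in order:
                i = avail[j]
                g = pool_gene[i]
                if i in chosen or g in group_genes:
                    continue
                chosen.append(i)
                group_genes.add(g)
                if len(chosen) == ratio:
                    break
            if len(chosen) < ratio:
                raise ValueError(
                    f"negative pool exhausted for partition={cell_key[0]} "
                    f"region={cell_key[1]!r}: needed {ratio}, found {len(chosen)} "
                    "eligible candidates — enlarge the pool or lower the ratio"
                )
            relaxations.append(
                f"positive {p.chrom}:{p.pos}:{p.ref}:{p.alt} "
                f"(partition={cell_key[0]}, region={cell_key[1]}): "
                "distinct-gene constraint relaxed"
            )
        used_rows.update(chosen)
        used_genes.update(pool_gene[i] for i in chosen)
        neg_rows.extend(chosen)
        neg_pairing.extend([pid] * ratio)

    pos_out = pos.copy()
    pos_out["label"] = 1
    pos_out["pairing_id"] = np.arange(len(pos_out))
    neg_out = pl.loc[neg_rows].drop(columns="_key").copy()
    neg_out["label"] = 0
    neg_out["pairing_id"] = neg_pairing

    cols = ["chrom", "pos", "ref", "alt", "gene_id", "region", "partition",
            "label", "pairing_id"]
    extra = [c for c in pos_out.columns if c not in cols]
    table = pd.concat(
        [pos_out[cols], neg_out[cols]], ignore_index=True
    )
    if relaxations:
        logger.info("sample_matched_negatives: %d relaxations applied", len(relaxations))
    meta = {
        "seed": seed,
        "ratio": ratio,
        "n_positives": len(pos_out),
        "n_negatives": len(neg_out),
        "relaxations": relaxations,
        "exclude_positive_gene": exclude_positive_gene,
    }
    return TrainingTable(table, meta)


def build_training_table(
    positives: pd.DataFrame,
    pool: pd.DataFrame,
    partition_map: PartitionMap,
    ratio: int = DEFAULT_RATIO,
    seed: int = 0,
    **kwargs,
) -> TrainingTable:
    """Cap positives per gene then sample matched negatives (one-call helper)."""
    capped = cap_positives_per_gene(positives, seed=seed)
    return sample_matched_negatives(capped, pool, partition_map,
                                    ratio=ratio, seed=seed, **kwargs)
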