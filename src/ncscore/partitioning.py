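"""Gene-level genomic partitions — the anti-leakage backbone.

Protein-coding genes are split into k partitions, stratified by chromosome
and by whether the gene carries a high-quality non-coding pathogenic variant.
Within every (chromosome, has_pathogenic) stratum the partition counts differ
by at most one: genes are shuffled with a seeded generator and dealt
round-robin starting at a per-stratum random offset.

Model j of the scoring bundle is trained with partition j excluded, so any
variant in a mapped gene can be scored by a model that never saw that gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import GeneModel


@dataclass
class PartitionMap:
    """gene_id -> partition index in 0..k-1, plus the stratum tallies."""

    assignments: dict[str, int]
    k: int
    seed: int
    tallies: pd.DataFrame  # columns: chrom, has_pathogenic, partition, n_genes

    def __getitem__(self, gene_id: str) -> int:
        return self.assignments[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)

    def partitions_of(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Vectorised lookup; raises KeyError naming the first unmapped gene."""
        out = []
        for g in gene_ids:
            if g not in self.assignments:
                raise KeyError(f"gene {g!r} absent from PartitionMap")
            out.append(self.assignments[g])
        return np.asarray(out, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignments.items()), columns=["gene_id", "partition"]
        )

    def save(self, tsv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if meta_path is not None:
            meta = {
                "k": self.k,
                "seed": self.seed,
                "tallies": self.tallies.to_dict(orient="records"),
            }
            Path(meta_path).write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def load(cls, tsv_path: str | Path, meta_path: str | Path | None = None) -> "PartitionMap":
        df = pd.read_csv(tsv_path, sep="\t", dtype={"gene_id": str})
        if meta_path is not None:
            meta = json.loads(Path(meta_path).read_text())
            k, seed = meta["k"], meta["seed"]
            tallies = pd.DataFrame(meta["tallies"])
        else:
            k, seed = int(df["partition"].max()) + 1, -1
            tallies = pd.DataFrame()
        return cls(dict(zip(df["gene_id"], df["partition"].astype(int))), k, seed, tallies)


def make_partitions(
    genes: Sequence[GeneModel] | pd.DataFrame,
    pathogenic_gene_ids: Iterable[str],
    k: int = 10,
    seed: int = 0,
) -> PartitionMap:
    """Stratified round-robin split of genes into k partitions.

    Strata are (chromosome, has_pathogenic) cells; each is shuffled with the
    seeded generator and dealt round-robin from a random per-stratum offset,
    so within every cell the partition counts spread by at most 1.
    Deterministic given (genes, pathogenic ids, k, seed).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(genes, pd.DataFrame):
        gene_df = genes[["gene_id", "chrom"]].astype(str)
    else:
        if not genes:
            raise ValueError("genes must be non-empty")
        gene_df = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes], "chrom": [g.chrom for g in genes]}
        )
    if len(gene_df) == 0:
        raise ValueError("genes must be non-empty")
    if gene_df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids")
    pathogenic = set(pathogenic_gene_ids)
    gene_df = gene_df.assign(has_pathogenic=gene_df["gene_id"].isin(pathogenic))

    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    tally_rows = []
    # fixed stratum iteration order for determinism
    strata = gene_df.sort_values(["chrom", "has_pathogenic", "gene_id"]).groupby(
        ["chrom", "has_pathogenic"], sort=True
    )
    for (chrom, has_path), sub in strata:
        ids = sub["gene_id"].tolist()
        rng.shuffle(ids)
        offset = int(rng.integers(k))
        counts = np.zeros(k, dtype=int)
        for i, gid in enumerate(ids):
            p = (offset + i) % k
            assignments[gid] = p
            counts[p] += 1
        for p in range(k):
            tally_rows.append(
                {"chrom": chrom, "has_pathogenic": bool(has_path),
                 "partition": p, "n_genes": int(counts[p])}
            )
    tallies = pd.DataFrame(tally_rows)
    return PartitionMap(assignments, k, seed, tallies)


def assert_no_leakage(
    partition_map: PartitionMap,
    training: pd.DataFrame,
    held_out_partition: int,
) -> bool:
    """True iff no training variant's gene maps to the held-out partition.

    Every training row must carry a mapped ``gene_id``; an unmapped gene is a
    hard error — silent pass-through would defeat the leakage gate.
    """
    parts = partition_map.partitions_of(training["gene_id"])
    return not bool((parts == held_out_partition).any())
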