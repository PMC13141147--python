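"""Gene models and non-coding region assignment.

Every scorable SNV is typed into exactly one of six non-coding region
classes relative to its assigned protein-coding gene: ``upstream``, ``UTR5``,
``intronic``, ``UTR3``, ``downstream`` or ``intergenic``.  Positions falling
inside coding exons are marked ``coding`` and excluded from scoring; positions
further than ``intergenic_cap`` from any transcript span are unscorable.

All coordinates are 1-based inclusive (VCF convention).  Gene models carry a
single canonical transcript; collapsing isoforms is the data producer's job.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_WINDOW = 1000
DEFAULT_DOWNSTREAM_WINDOW = 1000
DEFAULT_INTERGENIC_CAP = 10_000


class RegionType(str, Enum):
    """The six scorable non-coding region classes, plus the coding sentinel."""

    UPSTREAM = "upstream"
    UTR5 = "UTR5"
    INTRONIC = "intronic"
    UTR3 = "UTR3"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"
    CODING = "coding"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical report order for the six scorable classes
SCORABLE_REGIONS: tuple[RegionType, ...] = (
    RegionType.UPSTREAM,
    RegionType.UTR5,
    RegionType.INTRONIC,
    RegionType.UTR3,
    RegionType.DOWNSTREAM,
    RegionType.INTERGENIC,
)

REGION_NAMES: tuple[str, ...] = tuple(r.value for r in SCORABLE_REGIONS)

# precedence when several genes claim a position (lower wins); coding exons
# exclude the position outright, genic non-coding beats flanking classes.
_PRECEDENCE = {
    RegionType.CODING: 0,
    RegionType.UTR5: 1,
    RegionType.UTR3: 2,
    RegionType.INTRONIC: 3,
    RegionType.UPSTREAM: 4,
    RegionType.DOWNSTREAM: 5,
    RegionType.INTERGENIC: 6,
}


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene's canonical transcript geometry.

    Parameters
    ----------
    gene_id : str
        Unique gene identifier.
    chrom : str
        Chromosome name.
    strand : str
        ``"+"`` or ``"-"``.
    tx_start, tx_end : int
        Transcript span, 1-based inclusive.
    cds_start, cds_end : int
        Coding span, 1-based inclusive; must lie within the transcript span
        and be covered by exons.
    exons : tuple of (int, int)
        Sorted, non-overlapping exon blocks, 1-based inclusive.
    is_disease_gene : bool
        Monogenic-Mendelian-disease gene flag (used only by evaluation).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]
    is_disease_gene: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(
                f"{self.gene_id}: require tx_start <= cds_start <= cds_end <= tx_end, "
                f"got {self.tx_start}, {self.cds_start}, {self.cds_end}, {self.tx_end}"
            )
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.gene_id}: exon start {start} > end {end}")
            if start < self.tx_start or end > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon ({start},{end}) outside transcript span")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = end
        if not (self._in_exon(self.cds_start) and self._in_exon(self.cds_end)):
            raise ValueError(f"{self.gene_id}: CDS boundaries not covered by exons")

    def _in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def distance_to_span(self, pos: int) -> int:
        if pos < self.tx_start:
            return self.tx_start - pos
        if pos > self.tx_end:
            return pos - self.tx_end
        return 0


@dataclass(frozen=True)
class RegionAssignment:
    """A single (gene, region) assignment for one SNV."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    region: RegionType
    distance_to_gene: int


def _type_within_gene(
    gene: GeneModel,
    pos: int,
    upstream_window: int,
    downstream_window: int,
    intergenic_cap: int,
) -> RegionType | None:
    """Strand-aware region type of `pos` relative to one gene, or None if out of reach."""
    fwd = gene.strand == "+"
    if gene.tx_start <= pos <= gene.tx_end:
        if gene._in_exon(pos):
            if gene.cds_start <= pos <= gene.cds_end:
                return RegionType.CODING
            if pos < gene.cds_start:
                return RegionType.UTR5 if fwd else RegionType.UTR3
            return RegionType.UTR3 if fwd else RegionType.UTR5
        return RegionType.INTRONIC
    dist = gene.distance_to_span(pos)
    before = pos < gene.tx_start  # lower genomic coordinate side
    five_prime = before if fwd else not before
    if five_prime and dist <= upstream_window:
        return RegionType.UPSTREAM
    if not five_prime and dist <= downstream_window:
        return RegionType.DOWNSTREAM
    if dist <= intergenic_cap:
        return RegionType.INTERGENIC
    return None


class GeneIndex:
    """Per-chromosome interval index over gene models for fast neighbourhood queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._cummax_end: dict[str, list[int]] = {}
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.tx_start, g.gene_id))
            self._starts[chrom] = [g.tx_start for g in gs]
            cm, m = [], -1
            for g in gs:
                m = max(m, g.tx_end)
                cm.append(m)
            self._cummax_end[chrom] = cm

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def near(self, chrom: str, pos: int, reach: int) -> list[GeneModel]:
        """Genes whose transcript span is within `reach` bp of `pos`."""
        if chrom not in self._by_chrom:
            return []
        gs = self._by_chrom[chrom]
        hi = bisect.bisect_right(self._starts[chrom], pos + reach)
        lo = bisect.bisect_left(self._cummax_end[chrom], pos - reach)
        return [g for g in gs[lo:hi] if g.distance_to_span(pos) <= reach]


def classify_region(
    variant: tuple[str, int, str, str],
    gene_models: GeneIndex | Sequence[GeneModel],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    downstream_window: int = DEFAULT_DOWNSTREAM_WINDOW,
    intergenic_cap: int = DEFAULT_INTERGENIC_CAP,
) -> RegionAssignment | None:
    """Assign one SNV a gene and region type.

    Returns a :class:`RegionAssignment` (region may be ``coding``, meaning the
    position is excluded from scoring) or ``None`` for unscorable positions
    (unknown chromosome, or further than ``intergenic_cap`` from any gene).

    Precedence when several genes are candidates: any coding-exon overlap
    excludes the position; otherwise genic non-coding (UTR5 > UTR3 > intronic)
    beats upstream, which beats downstream, which beats intergenic; remaining
    ties go to the smaller distance to the transcript span, then to the
    lexicographically smaller gene id.
    """
    chrom, pos, ref, alt = variant
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not an SNV: {chrom}:{pos} {ref}>{alt}")
    if upstream_window <= 0 or downstream_window <= 0 or intergenic_cap <= 0:
        raise ValueError("windows and cap must be positive")
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    if chrom not in index.chroms:
        logger.debug("unscorable %s:%d — chromosome absent from gene models", chrom, pos)
        return None
    reach = max(upstream_window, downstream_window, intergenic_cap)
    best: tuple[int, int, str, RegionType] | None = None
    for g in index.near(chrom, pos, reach):
        rt = _type_within_gene(g, pos, upstream_window, downstream_window, intergenic_cap)
        if rt is None:
            continue
        key = (_PRECEDENCE[rt], g.distance_to_span(pos), g.gene_id, rt)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is None:
        logger.debug("unscorable %s:%d — beyond intergenic cap", chrom, pos)
        return None
    _, dist, gene_id, region = best
    return RegionAssignment(chrom, pos, ref, alt, gene_id, region, dist)


def assign_regions(
    variants: pd.DataFrame,
    gene_models: GeneIndex | Sequence[GeneModel],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    downstream_window: int = DEFAULT_DOWNSTREAM_WINDOW,
    intergenic_cap: int = DEFAULT_INTERGENIC_CAP,
) -> pd.DataFrame:
    """Vectorised wrapper: add ``gene_id``, ``region``, ``distance_to_gene``.

    Input needs columns chrom/pos/ref/alt.  Unscorable variants get
    gene_id=NA, region=NA; coding positions get region="coding".
    """
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    genes, regions, dists = [], [], []
    n_unscorable = 0
    for chrom, pos, ref, alt in variants[["chrom", "pos", "ref", "alt"]].itertuples(index=False):
        a = classify_region((chrom, int(pos), ref, alt), index,
                            upstream_window, downstream_window, intergenic_cap)
        if a is None:
            genes.append(pd.NA)
            regions.append(pd.NA)
            dists.append(pd.NA)
            n_unscorable += 1
        else:
            genes.append(a.gene_id)
            regions.append(a.region.value)
            dists.append(a.distance_to_gene)
    if n_unscorable:
        logger.info("assign_regions: %d unscorable variants", n_unscorable)
    out = variants.copy()
    out["gene_id"] = genes
    out["region"] = regions
    out["distance_to_gene"] = dists
    return out


# ---------------------------------------------------------------------------
# readers


def _parse_exon_blocks(text: str) -> tuple[tuple[int, int], ...]:
    blocks = []
    for part in str(text).split(","):
        part = part.strip()
        if not part:
            continue
        s, e = part.split("-")
        blocks.append((int(s), int(e)))
    return tuple(blocks)


def _load_gene_model_tsv(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "strand", "tx_start", "tx_end",
                "cds_start", "cds_end", "exons"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    models, n_skipped = [], 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.cds_start) or pd.isna(row.cds_end):
            n_skipped += 1
            continue
        try:
            models.append(GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                exons=_parse_exon_blocks(row.exons),
                is_disease_gene=bool(getattr(row, "is_disease_gene", False)),
            ))
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    if n_skipped:
        logger.info("load_gene_models: skipped %d records without CDS", n_skipped)
    return models


def _load_gene_model_gff(path: Path, fmt: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    models, n_skipped = [], 0
    for gene in db.features_of_type("gene"):
        txs = list(db.children(gene, featuretype=("transcript", "mRNA"), level=1))
        best = None
        for tx in txs:
            cds = sorted(db.children(tx, featuretype="CDS", level=1),
                         key=lambda f: f.start)
            if not cds:
                continue
            span = cds[-1].end - cds[0].start
            if best is None or span > best[1]:
                best = (tx, span, cds)
        if best is None:
            n_skipped += 1
            continue
        tx, _, cds = best
        exons = sorted(
            ((f.start, f.end) for f in db.children(tx, featuretype="exon", level=1)),
            key=lambda b: b[0],
        )
        if not exons:
            exons = [(f.start, f.end) for f in cds]
        if gene.start > gene.end:
            raise ValueError(f"{path}: gene {gene.id} start > end")
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        models.append(GeneModel(
            gene_id=gene_id,
            chrom=gene.seqid,
            strand=gene.strand,
            tx_start=tx.start,
            tx_end=tx.end,
            cds_start=cds[0].start,
            cds_end=cds[-1].end,
            exons=tuple(exons),
        ))
    if n_skipped:
        logger.info("load_gene_models: skipped %d non-coding transcripts/genes", n_skipped)
    return models


def load_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Load gene models from GTF, GFF3 or the simplified 8-column TSV.

    Records without a CDS (non-coding transcripts) are skipped with a logged
    count; malformed coordinates raise ``ValueError`` naming the offending
    record.  Output is sorted by (chrom, tx_start).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".gtf": "gtf", ".gff": "gff3", ".gff3": "gff3"}.get(suffix, "tsv")
    if format == "tsv":
        models = _load_gene_model_tsv(path)
    elif format in ("gtf", "gff3"):
        models = _load_gene_model_gff(path, format)
    else:
        raise ValueError(f"unknown gene-model format: {format}")
    models.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return models


def read_variants(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read variants from VCF or 4-column TSV into a chrom/pos/ref/alt frame.

    Only CHROM/POS/REF/ALT are consumed from VCF; multi-allelic records are
    split into one row per ALT.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".bcf") or str(path).endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        import pysam

        rows = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    rows.append((rec.chrom, rec.pos, rec.ref, alt))
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
                     comment="#")
    if not {"chrom", "pos", "ref", "alt"}.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "pos", "ref", "alt"],
                         dtype={0: str, 2: str, 3: str})
    df["pos"] = df["pos"].astype(int)
    return df[["chrom", "pos", "ref", "alt"] + [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]]


def variant_key(df: pd.DataFrame) -> pd.Series:
    """Canonical string key chrom:pos:ref:alt for joining variant tables."""
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"].astype(str) + ":" + df["alt"].astype(str))
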