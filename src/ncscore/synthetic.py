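"""Synthetic gene models, variant pools, clinical records and feature matrices.

The generator emulates the statistical structure the scoring framework is
built to exploit, without any external data: protein-coding genes laid out
along chromosomes with fixed two-exon geometry; a curated-style positive set
(one pathogenic SNV per disease gene, region mix matching the reported
cross-validation composition); a large region-assigned common-variant pool;
and a 58-column feature matrix in which pathogenic and benign variants are
separably shifted.

Signal structure
----------------
* Position-level continuous features are unit-variance Gaussians with mean 0
  for benign variants and ``d`` (the per-category effect size, in SD units)
  for pathogenic ones; bounded features pass through a logistic squash, which
  preserves separability for tree learners (monotone transform).
* A per-region baseline shift (``region_bias``, default +0.5 SD for 5'UTR)
  is added to the features of *all* variants in that region, emulating the
  observed regional score bias; the bias is applied to features, not labels,
  so the per-gene bias analysis has a true positive control.
* Gene-level features are constant per gene, shifted for genes hosting a
  pathogenic variant.
* A configurable fraction of positives is "splice-driven": their separation
  is carried mainly by the two splice-delta slots (their other shifts are
  scaled down), and the splice slots' separation itself scales with ``d`` so
  a ``d=0`` configuration carries no signal at all.
* Missingness is applied uniformly at a per-category rate.

The same seed reproduces the dataset exactly, including written files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import CATEGORIES, FeatureSchema, default_schema
from .regions import REGION_NAMES, GeneModel

logger = logging.getLogger(__name__)

# positive region mix: cross-validation composition of the curated positive set
DEFAULT_REGION_WEIGHTS: dict[str, float] = {
    "upstream": 61, "UTR5": 133, "intronic": 475,
    "UTR3": 77, "downstream": 9, "intergenic": 10,
}

# fixed two-exon gene geometry (offsets from tx_start)
_TX_LEN = 2400
_EXON_OFFSETS = ((0, 599), (1799, 2399))
_CDS_OFFSETS = (300, 2099)
_SPACING = 8000  # tx_start to tx_start within a chromosome
_FIRST_TX_START = 2001

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; defaults are the framework's reference study conditions."""

    n_genes: int = 10_000
    chromosomes: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
    fraction_disease_genes: float = 0.33
    n_positives: int = 765
    pool_per_gene_region: int = 1
    ratio: int = 10
    effect_size: float | Mapping[str, float] = 1.0  # d, SD units, per category
    region_bias: Mapping[str, float] = field(
        default_factory=lambda: {"UTR5": 0.5})
    missing_rate: Mapping[str, float] = field(default_factory=lambda: {
        "interspecies_conservation": 0.10, "human_constraint": 0.10,
        "gene_level": 0.05, "sequence_context": 0.0})
    fraction_splice_driven: float = 0.3
    splice_dampening: float = 0.25  # non-splice shift scale for splice-driven positives
    positive_region_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS))
    seed: int = 0
    # curation-test decoys (all zero under reference conditions)
    n_conflicting_records: int = 0
    n_somatic_records: int = 0
    n_homozygous_records: int = 0
    n_coding_records: int = 0
    duplicate_positive_genes: int = 0  # extra positives placed in used genes

    def effect_of(self, category: str) -> float:
        if isinstance(self.effect_size, Mapping):
            return float(self.effect_size.get(category, 0.0))
        return float(self.effect_size)

    def validate(self) -> None:
        if not (0 <= self.fraction_disease_genes <= 1):
            raise ValueError("fraction_disease_genes must be in [0,1]")
        if not (0 <= self.fraction_splice_driven <= 1):
            raise ValueError("fraction_splice_driven must be in [0,1]")
        for c in CATEGORIES:
            if self.effect_of(c) < 0:
                raise ValueError("effect sizes must be >= 0")
        n_disease = int(round(self.fraction_disease_genes * self.n_genes))
        if self.n_positives > n_disease:
            raise ValueError(
                f"n_positives={self.n_positives} exceeds the number of disease "
                f"genes ({n_disease}) — one positive per gene")
        # rough pool feasibility: every region must be able to supply the ratio
        weights = np.array([self.positive_region_weights.get(r, 0.0)
                            for r in REGION_NAMES], dtype=float)
        weights = weights / weights.sum()
        pool_per_region = self.pool_per_gene_region * self.n_genes
        demand = self.ratio * self.n_positives * weights
        if (demand > pool_per_region).any():
            r = REGION_NAMES[int(np.argmax(demand - pool_per_region))]
            raise ValueError(
                f"negative pool too small for ratio {self.ratio} in region {r!r}: "
                "increase pool_per_gene_region or n_genes")


@dataclass
class SynthDataset:
    config: SynthConfig
    genes: list[GeneModel]
    clinical_records: pd.DataFrame
    pool: pd.DataFrame        # common negative candidates, region-assigned
    variants: pd.DataFrame    # all variants (positives + pool) with labels
    features: pd.DataFrame    # 58 columns, aligned to `variants` rows
    schema: FeatureSchema


def _region_range(tx_start: int, strand: str, region: str) -> tuple[int, int]:
    """Inclusive genomic position range that classifies as `region` for this gene."""
    tx_end = tx_start + _TX_LEN - 1
    cds_start = tx_start + _CDS_OFFSETS[0]
    cds_end = tx_start + _CDS_OFFSETS[1]
    fwd = strand == "+"
    low_flank = (tx_start - 950, tx_start - 50)
    high_flank = (tx_end + 50, tx_end + 950)
    if region == "upstream":
        return low_flank if fwd else high_flank
    if region == "downstream":
        return high_flank if fwd else low_flank
    if region == "UTR5":
        return (tx_start, cds_start - 1) if fwd else (cds_end + 1, tx_end)
    if region == "UTR3":
        return (cds_end + 1, tx_end) if fwd else (tx_start, cds_start - 1)
    if region == "intronic":
        return (tx_start + _EXON_OFFSETS[0][1] + 1, tx_start + _EXON_OFFSETS[1][0] - 1)
    if region == "intergenic":
        return (tx_end + 1001, tx_end + 2400)
    if region == "coding":
        return (cds_start, cds_start + 200)
    raise ValueError(region)


def _make_genes(cfg: SynthConfig, rng: np.random.Generator) -> tuple[list[GeneModel], np.ndarray]:
    n_chrom = len(cfg.chromosomes)
    n_disease = int(round(cfg.fraction_disease_genes * cfg.n_genes))
    disease_idx = rng.choice(cfg.n_genes, size=n_disease, replace=False)
    is_disease = np.zeros(cfg.n_genes, dtype=bool)
    is_disease[disease_idx] = True
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes = []
    for i in range(cfg.n_genes):
        chrom = cfg.chromosomes[i % n_chrom]
        idx_in_chrom = i // n_chrom
        tx_start = _FIRST_TX_START + idx_in_chrom * _SPACING
        genes.append(GeneModel(
            gene_id=f"G{i:05d}",
            chrom=chrom,
            strand=str(strands[i]),
            tx_start=tx_start,
            tx_end=tx_start + _TX_LEN - 1,
            cds_start=tx_start + _CDS_OFFSETS[0],
            cds_end=tx_start + _CDS_OFFSETS[1],
            exons=tuple((tx_start + s, tx_start + e) for s, e in _EXON_OFFSETS),
            is_disease_gene=bool(is_disease[i]),
        ))
    return genes, is_disease


def generate_dataset(config: SynthConfig | None = None, **overrides) -> SynthDataset:
    """Generate the full synthetic study: genes, records, pool, features."""
    cfg = config or SynthConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    schema = default_schema()

    genes, is_disease = _make_genes(cfg, rng)
    gene_ids = np.array([g.gene_id for g in genes])

    # --- choose positive sites -------------------------------------------
    disease_gene_idx = np.flatnonzero(is_disease)
    pos_gene_idx = rng.choice(disease_gene_idx, size=cfg.n_positives, replace=False)
    weights = np.array([cfg.positive_region_weights.get(r, 0.0) for r in REGION_NAMES],
                       dtype=float)
    weights /= weights.sum()
    pos_regions = rng.choice(REGION_NAMES, size=cfg.n_positives, p=weights)
    if cfg.duplicate_positive_genes:
        extra_idx = rng.choice(pos_gene_idx, size=cfg.duplicate_positive_genes)
        pos_gene_idx = np.concatenate([pos_gene_idx, extra_idx])
        pos_regions = np.concatenate(
            [pos_regions, rng.choice(REGION_NAMES, size=cfg.duplicate_positive_genes, p=weights)])

    # --- per-(gene, region) position demand ------------------------------
    demand: dict[tuple[int, str], int] = {}
    for gi in range(cfg.n_genes):
        for r in REGION_NAMES:
            demand[(gi, r)] = cfg.pool_per_gene_region
    for gi, r in zip(pos_gene_idx, pos_regions):
        demand[(int(gi), str(r))] += 1
    n_decoys = (cfg.n_conflicting_records + cfg.n_somatic_records
                + cfg.n_homozygous_records)
    decoy_gene_idx = rng.integers(cfg.n_genes, size=n_decoys)
    decoy_regions = rng.choice(REGION_NAMES, size=n_decoys) if n_decoys else np.array([])
    for gi, r in zip(decoy_gene_idx, decoy_regions):
        demand[(int(gi), str(r))] += 1
    coding_gene_idx = rng.integers(cfg.n_genes, size=cfg.n_coding_records)
    for gi in coding_gene_idx:
        demand[(int(gi), "coding")] = demand.get((int(gi), "coding"), 0) + 1

    positions: dict[tuple[int, str], list[int]] = {}
    for (gi, r), n in demand.items():
        if n == 0:
            continue
        lo, hi = _region_range(genes[gi].tx_start, genes[gi].strand, r)
        positions[(gi, r)] = list(rng.choice(np.arange(lo, hi + 1), size=n,
                                             replace=False))

    def take(gi: int, r: str) -> int:
        return int(positions[(int(gi), str(r))].pop())

    def alleles(n: int) -> tuple[np.ndarray, np.ndarray]:
        ref = rng.integers(4, size=n)
        alt = (ref + rng.integers(1, 4, size=n)) % 4
        return _BASES[ref], _BASES[alt]

    # --- positives --------------------------------------------------------
    n_pos = len(pos_gene_idx)
    pos_ref, pos_alt = alleles(n_pos)
    splice_driven = rng.random(n_pos) < cfg.fraction_splice_driven
    positives = pd.DataFrame({
        "chrom": [genes[gi].chrom for gi in pos_gene_idx],
        "pos": [take(gi, r) for gi, r in zip(pos_gene_idx, pos_regions)],
        "ref": pos_ref, "alt": pos_alt,
        "gene_id": gene_ids[pos_gene_idx],
        "region": pos_regions,
        "label": 1,
        "is_splice_driven": splice_driven,
        "pop_af": rng.uniform(1e-5, 5e-4, size=n_pos).round(7),
    })

    # --- common negative pool --------------------------------------------
    pool_rows = []
    for gi in range(cfg.n_genes):
        for r in REGION_NAMES:
            for _ in range(cfg.pool_per_gene_region):
                pool_rows.append((genes[gi].chrom, take(gi, r), gene_ids[gi], r))
    pool = pd.DataFrame(pool_rows, columns=["chrom", "pos", "gene_id", "region"])
    ref, alt = alleles(len(pool))
    pool["ref"], pool["alt"] = ref, alt
    pool["label"] = 0
    pool["is_splice_driven"] = False
    pool["pop_af"] = rng.uniform(0.01, 0.5, size=len(pool)).round(6)
    pool = pool[["chrom", "pos", "ref", "alt", "gene_id", "region",
                 "label", "is_splice_driven", "pop_af"]]

    # --- clinical records -------------------------------------------------
    rec = positives.drop(columns=["label", "is_splice_driven"]).copy()
    rec["source"] = "clinvar-like"
    rec["assertions"] = "pathogenic"
    rec["inheritance"] = "monogenic_mendelian"
    rec["n_homozygotes"] = 0
    records = [rec]
    def _decoy(n, gidx, regs, **fields):
        if n == 0:
            return
        r_ref, r_alt = alleles(n)
        d = pd.DataFrame({
            "chrom": [genes[int(g)].chrom for g in gidx],
            "pos": [take(g, rr) for g, rr in zip(gidx, regs)],
            "ref": r_ref, "alt": r_alt,
            "gene_id": gene_ids[np.asarray(gidx, dtype=int)],
            "region": regs,
            "pop_af": rng.uniform(1e-5, 5e-4, size=n).round(7),
            "source": "hgmd-like",
            "assertions": fields.get("assertions", "pathogenic"),
            "inheritance": fields.get("inheritance", "monogenic_mendelian"),
            "n_homozygotes": fields.get("n_homozygotes", 0),
        })
        records.append(d)

    off = 0
    for n, kw in ((cfg.n_conflicting_records, {"assertions": "pathogenic,benign"}),
                  (cfg.n_somatic_records, {"inheritance": "somatic"}),
                  (cfg.n_homozygous_records, {"n_homozygotes": 2})):
        _decoy(n, decoy_gene_idx[off:off + n], decoy_regions[off:off + n], **kw)
        off += n
    if cfg.n_coding_records:
        _decoy(cfg.n_coding_records, coding_gene_idx,
               np.array(["coding"] * cfg.n_coding_records))
    clinical = pd.concat(records, ignore_index=True)
    cols = ["chrom", "pos", "ref", "alt", "source", "assertions", "inheritance",
            "n_homozygotes", "pop_af", "gene_id", "region"]
    clinical = clinical[cols]

    # --- feature matrix ---------------------------------------------------
    variants = pd.concat(
        [positives, pool], ignore_index=True
    ).sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)
    features = _generate_features(cfg, schema, variants, genes, gene_ids,
                                  set(gene_ids[pos_gene_idx]), rng)

    return SynthDataset(cfg, genes, clinical, pool, variants, features, schema)


def _generate_features(
    cfg: SynthConfig,
    schema: FeatureSchema,
    variants: pd.DataFrame,
    genes: Sequence[GeneModel],
    gene_ids: np.ndarray,
    positive_genes: set[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(variants)
    is_patho = (variants["label"] == 1).to_numpy()
    is_splice = variants["is_splice_driven"].to_numpy(dtype=bool)
    region = variants["region"].to_numpy()
    bias = np.array([cfg.region_bias.get(r, 0.0) for r in region])
    # splice-driven positives carry most of their separation in the splice slots
    patho_scale = np.where(is_patho, np.where(is_splice, cfg.splice_dampening, 1.0), 0.0)

    def sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-z))

    out = pd.DataFrame(index=variants.index)
    # position-level continuous categories
    for cat in ("interspecies_conservation", "human_constraint"):
        d = cfg.effect_of(cat)
        for f in schema.features:
            if f.category != cat:
                continue
            z = rng.normal(d * patho_scale + bias, 1.0)
            out[f.name] = sigmoid(z) if f.domain == (0.0, 1.0) else z

    # gene-level: constant per gene, shifted for genes hosting a positive
    d_gene = cfg.effect_of("gene_level")
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    vidx = variants["gene_id"].map(gene_index).to_numpy()
    hosts_positive = np.array([g in positive_genes for g in gene_ids], dtype=float)
    for f in schema.features:
        if f.category != "gene_level":
            continue
        base = rng.normal(d_gene * hosts_positive, 1.0)
        vals = base[vidx]
        out[f.name] = sigmoid(vals) if f.domain == (0.0, 1.0) else vals

    # sequence context: gc/cpg (continuous), one-hot region, splice maxima
    d_ctx = cfg.effect_of("sequence_context")
    for name in ("gc_content", "cpg_content"):
        out[name] = sigmoid(rng.normal(d_ctx * patho_scale + bias, 1.0))
    for r in REGION_NAMES:
        out[f"region_is_{r}"] = (region == r).astype(float)
    # splice slots: no signal at d=0; splice-driven positives separate strongly
    splice_gain = 2.0
    zs = rng.normal(-3.0 + splice_gain * d_ctx * is_splice, 1.0)
    out["spliceai_max_variant"] = sigmoid(zs)
    out["spliceai_max_position"] = sigmoid(zs + np.abs(rng.normal(0.0, 0.2, size=n)))

    # missingness per category (region one-hot exempt unless rate explicitly set)
    for cat in CATEGORIES:
        rate = float(cfg.missing_rate.get(cat, 0.0)) if isinstance(cfg.missing_rate, Mapping) else float(cfg.missing_rate)
        if rate <= 0:
            continue
        for fname in schema.names_in_category(cat):
            mask = rng.random(n) < rate
            col = out[fname].to_numpy(dtype=float)
            col[mask] = np.nan
            out[fname] = col

    return out[schema.names]


# ---------------------------------------------------------------------------
# standard-format output (path-identical with real runs)


def write_dataset(ds: SynthDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the formats the real pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    gm = pd.DataFrame({
        "gene_id": [g.gene_id for g in ds.genes],
        "chrom": [g.chrom for g in ds.genes],
        "strand": [g.strand for g in ds.genes],
        "tx_start": [g.tx_start for g in ds.genes],
        "tx_end": [g.tx_end for g in ds.genes],
        "cds_start": [g.cds_start for g in ds.genes],
        "cds_end": [g.cds_end for g in ds.genes],
        "exons": [",".join(f"{s}-{e}" for s, e in g.exons) for g in ds.genes],
        "is_disease_gene": [g.is_disease_gene for g in ds.genes],
    })
    paths["gene_models"] = outdir / "gene_models.tsv"
    gm.to_csv(paths["gene_models"], sep="\t", index=False)

    paths["clinical_records"] = outdir / "clinical_records.tsv"
    ds.clinical_records.to_csv(paths["clinical_records"], sep="\t", index=False)

    paths["negative_pool"] = outdir / "negative_pool.tsv"
    ds.pool.to_csv(paths["negative_pool"], sep="\t", index=False)

    ann = pd.concat(
        [ds.variants[["chrom", "pos", "ref", "alt"]].reset_index(drop=True),
         ds.features.reset_index(drop=True)], axis=1)
    paths["annotations"] = outdir / "annotations.tsv"
    ann.to_csv(paths["annotations"], sep="\t", index=False, float_format="%.6g")

    paths["schema"] = outdir / "feature_schema.yaml"
    ds.schema.to_yaml(paths["schema"])
    return paths
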