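"""The 58-feature annotation schema and pluggable lookup sources.

Features fall into four categories:

* ``interspecies_conservation`` — long-term conservation of the position
  across vertebrate/mammal/primate alignments (phyloP/phastCons-style,
  GERP-style), including large-alignment slots new in this version.
* ``human_constraint`` — recent and ongoing purifying selection in humans:
  context-adjusted depletion scores and per-subpopulation constraint slots
  for nine major subpopulations.
* ``gene_level`` — conservation/intolerance of the associated protein-coding
  gene (e.g. the loeuf loss-of-function depletion score).
* ``sequence_context`` — local GC and CpG content, the one-hot encoded
  non-coding region type, and the maximum splice-delta score at the variant
  and position levels.

The default schema has exactly 58 features, 26 of them new relative to the
first release.  Individual feature *names* outside the structurally fixed
slots (subpopulations, loeuf, the four context features) are provisional
placeholders that preserve the category structure and counts; swap in a
custom schema to rename them.

Missing values are passed to the tree learner as native missing (NaN), never
imputed.
"""

from __future__ import annotations

import logging
import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .regions import REGION_NAMES

logger = logging.getLogger(__name__)

CATEGORIES = (
    "interspecies_conservation",
    "human_constraint",
    "gene_level",
    "sequence_context",
)

SUBPOPULATIONS = ("afr", "amr", "asj", "eas", "fin", "mid", "nfe", "sas", "oth")

DEFAULT_CONTEXT_WINDOW = 101

SCHEMA_VERSION = "2.0"


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str
    new_in_v2: bool = False
    domain: tuple[float, float] | None = None  # closed interval, None = unbounded

    def in_domain(self, value: float) -> bool:
        if self.domain is None or np.isnan(value):
            return True
        lo, hi = self.domain
        return lo <= value <= hi


class FeatureSchema:
    """Ordered, named feature definitions; fixes the feature-vector columns."""

    def __init__(self, features: Sequence[FeatureDef], version: str = SCHEMA_VERSION):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        for f in features:
            if f.category not in CATEGORIES:
                raise ValueError(f"unknown category {f.category!r} for {f.name}")
        self.features: tuple[FeatureDef, ...] = tuple(features)
        self.version = version

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, name: str) -> FeatureDef:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def names_in_category(self, category: str) -> list[str]:
        return [f.name for f in self.features if f.category == category]

    @property
    def n_new(self) -> int:
        return sum(f.new_in_v2 for f in self.features)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "features": [
                {"name": f.name, "category": f.category, "new_in_v2": f.new_in_v2,
                 "domain": list(f.domain) if f.domain else None}
                for f in self.features
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSchema":
        feats = [
            FeatureDef(f["name"], f["category"], bool(f.get("new_in_v2", False)),
                       tuple(f["domain"]) if f.get("domain") else None)
            for f in d["features"]
        ]
        return cls(feats, version=d.get("version", SCHEMA_VERSION))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureSchema) and self.to_dict() == other.to_dict()


def default_schema() -> FeatureSchema:
    """The default 58-feature schema (26 new-in-v2 slots)."""
    F = FeatureDef
    unit = (0.0, 1.0)
    feats: list[FeatureDef] = []

    # (i) interspecies conservation: 10 legacy + 4 large-alignment slots
    for name in ("phylop_7way", "phylop_20way", "phylop_100way",
                 "phastcons_7way", "phastcons_20way", "phastcons_100way"):
        feats.append(F(name, "interspecies_conservation",
                       domain=unit if name.startswith("phastcons") else None))
    feats += [
        F("gerp_n", "interspecies_conservation"),
        F("gerp_rs", "interspecies_conservation"),
        F("siphy_logodds", "interspecies_conservation"),
        F("fitcons", "interspecies_conservation", domain=unit),
        F("phylop_mammals_241way", "interspecies_conservation", new_in_v2=True),
        F("phastcons_mammals_241way", "interspecies_conservation", new_in_v2=True, domain=unit),
        F("phylop_primates_43way", "interspecies_conservation", new_in_v2=True),
        F("phastcons_primates_43way", "interspecies_conservation", new_in_v2=True, domain=unit),
    ]

    # (ii) human constraint: 4 legacy + global & nine-subpopulation slots
    feats += [
        F("cdts_score", "human_constraint"),
        F("mean_daf", "human_constraint", domain=unit),
        F("mean_het", "human_constraint", domain=unit),
        F("tajimas_d", "human_constraint"),
        F("constraint_z_global", "human_constraint", new_in_v2=True),
    ]
    feats += [F(f"constraint_z_{p}", "human_constraint", new_in_v2=True)
              for p in SUBPOPULATIONS]

    # (iii) gene level: 10 legacy + 10 population-scale gene scores
    feats += [
        F("rvis", "gene_level"),
        F("ncrvis", "gene_level"),
        F("gdi", "gene_level"),
        F("gene_age", "gene_level"),
        F("pli", "gene_level", domain=unit),
        F("ncgerp", "gene_level"),
        F("pcgerp", "gene_level"),
        F("dnds_macaque", "gene_level"),
        F("dnds_mouse", "gene_level"),
        F("family_member_count", "gene_level"),
        F("loeuf", "gene_level", new_in_v2=True),
        F("lof_oe", "gene_level", new_in_v2=True),
        F("mis_oe", "gene_level", new_in_v2=True),
        F("syn_oe", "gene_level", new_in_v2=True),
        F("mis_z", "gene_level", new_in_v2=True),
        F("syn_z", "gene_level", new_in_v2=True),
        F("p_null", "gene_level", new_in_v2=True, domain=unit),
        F("p_recessive", "gene_level", new_in_v2=True, domain=unit),
        F("gene_mean_phylop", "gene_level", new_in_v2=True),
        F("gene_mean_cdts", "gene_level", new_in_v2=True),
    ]

    # (iv) sequence context: GC/CpG, region one-hot, splice-delta maxima
    feats += [
        F("gc_content", "sequence_context", domain=unit),
        F("cpg_content", "sequence_context", domain=unit),
    ]
    feats += [F(f"region_is_{r}", "sequence_context", domain=unit)
              for r in REGION_NAMES]
    feats += [
        F("spliceai_max_variant", "sequence_context", new_in_v2=True, domain=unit),
        F("spliceai_max_position", "sequence_context", new_in_v2=True, domain=unit),
    ]

    schema = FeatureSchema(feats)
    assert len(schema) == 58 and schema.n_new == 26
    return schema


# ---------------------------------------------------------------------------
# variant-level context features


def spliceai_max_features(
    delta_scores_by_alt: Mapping[str, Sequence[float]], alt: str
) -> tuple[float, float]:
    """Variant- and position-level maxima of the four splice delta scores.

    ``delta_scores_by_alt`` maps each alt allele at the position to its four
    deltas (acceptor gain/loss, donor gain/loss), each in [0, 1].  The
    variant-level max is over the queried alt's four deltas; the position-level
    max is over the variant-level maxima of every alt at the position.
    A missing alt yields (nan, nan).
    """
    if alt not in delta_scores_by_alt:
        return (float("nan"), float("nan"))
    per_alt = {a: float(max(d)) for a, d in delta_scores_by_alt.items()}
    return (per_alt[alt], max(per_alt.values()))


def gc_cpg_content(sequence: str) -> tuple[float, float]:
    """GC fraction and CpG dinucleotide fraction of a context window.

    GC fraction is (#G + #C) / #non-N bases; CpG fraction counts "CG"
    dinucleotides over the window's length-1 dinucleotide positions, with
    N-containing dinucleotides excluded from the numerator.  Truncated
    windows (chromosome ends) simply shorten the denominators.
    """
    seq = sequence.upper()
    non_n = sum(1 for b in seq if b != "N")
    gc = float("nan") if non_n == 0 else sum(1 for b in seq if b in "GC") / non_n
    if len(seq) < 2:
        return gc, 0.0
    n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
    return gc, n_cpg / (len(seq) - 1)


# ---------------------------------------------------------------------------
# annotation sources


class AnnotationSource(ABC):
    """Contract: a source declares a feature subset and fills it per variant.

    ``lookup`` returns a partial mapping feature -> value; keys must be within
    the declared subset.  Position-keyed sources ignore ref/alt.
    """

    @property
    @abstractmethod
    def declared_features(self) -> tuple[str, ...]:
        ...

    @abstractmethod
    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> dict[str, float]:
        ...


class TableAnnotationSource(AnnotationSource):
    """In-memory table keyed by (chrom, pos, ref, alt) or (chrom, pos)."""

    def __init__(self, table: pd.DataFrame, features: Sequence[str] | None = None,
                 position_keyed: bool = False):
        self._position_keyed = position_keyed
        key_cols = ["chrom", "pos"] if position_keyed else ["chrom", "pos", "ref", "alt"]
        feats = list(features) if features is not None else [
            c for c in table.columns if c not in ("chrom", "pos", "ref", "alt")
        ]
        self._features = tuple(feats)
        self._map: dict[tuple, dict[str, float]] = {}
        for row in table.itertuples(index=False):
            d = row._asdict()
            key = tuple(d[c] if c != "pos" else int(d[c]) for c in key_cols)
            self._map[key] = {f: float(d[f]) for f in feats if f in d and pd.notna(d[f])}

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "TableAnnotationSource":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}), **kwargs)

    @property
    def declared_features(self) -> tuple[str, ...]:
        return self._features

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> dict[str, float]:
        key = (chrom, int(pos)) if self._position_keyed else (chrom, int(pos), ref, alt)
        return self._map.get(key, {})


class TabixAnnotationSource(AnnotationSource):
    """bgzipped, tabix-indexed TSV with a header row naming the features.

    The first columns must be chrom/pos (position-keyed) or
    chrom/pos/ref/alt (variant-keyed); remaining header names are the
    declared features.
    """

    def __init__(self, path: str | Path, position_keyed: bool = True):
        import pysam

        self._tbx = pysam.TabixFile(str(path))
        header = self._tbx.header[-1].lstrip("#").split("\t")
        n_key = 2 if position_keyed else 4
        self._position_keyed = position_keyed
        self._columns = header
        self._features = tuple(header[n_key:])

    @property
    def declared_features(self) -> tuple[str, ...]:
        return self._features

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> dict[str, float]:
        n_key = 2 if self._position_keyed else 4
        try:
            rows = list(self._tbx.fetch(chrom, pos - 1, pos))
        except ValueError:
            return {}
        for line in rows:
            parts = line.split("\t")
            if int(parts[1]) != pos:
                continue
            if not self._position_keyed and (parts[2] != ref or parts[3] != alt):
                continue
            out = {}
            for name, value in zip(self._columns[n_key:], parts[n_key:]):
                if value not in (".", "", "NA"):
                    out[name] = float(value)
            return out
        return {}


class FastaContextSource(AnnotationSource):
    """GC/CpG content from a reference FASTA, window centred on the position."""

    def __init__(self, fasta_path: str | Path, window: int = DEFAULT_CONTEXT_WINDOW):
        import pyfaidx

        if window % 2 == 0:
            raise ValueError("context window must be odd")
        self._fa = pyfaidx.Fasta(str(fasta_path))
        self.window = window

    @property
    def declared_features(self) -> tuple[str, ...]:
        return ("gc_content", "cpg_content")

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> dict[str, float]:
        half = self.window // 2
        start = max(0, pos - 1 - half)  # 0-based slice, truncated at ends
        end = pos + half
        seq = str(self._fa[chrom][start:end])
        gc, cpg = gc_cpg_content(seq)
        return {"gc_content": gc, "cpg_content": cpg}


class RegionOneHotSource(AnnotationSource):
    """One-hot region-type slots, filled from a region-assignment table."""

    def __init__(self, assignments: pd.DataFrame):
        self._regions = {
            (r.chrom, int(r.pos), r.ref, r.alt): r.region
            for r in assignments.itertuples(index=False)
        }

    @property
    def declared_features(self) -> tuple[str, ...]:
        return tuple(f"region_is_{r}" for r in REGION_NAMES)

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> dict[str, float]:
        region = self._regions.get((chrom, int(pos), ref, alt))
        if region is None:
            return {}
        return {f"region_is_{r}": float(r == region) for r in REGION_NAMES}


class SpliceDeltaSource(AnnotationSource):
    """Variant/position splice-delta maxima from a per-alt delta table.

    ``deltas`` maps (chrom, pos) -> {alt: (4 delta scores)}.
    """

    def __init__(self, deltas: Mapping[tuple[str, int], Mapping[str, Sequence[float]]]):
        self._deltas = dict(deltas)

    @property
    def declared_features(self) -> tuple[str, ...]:
        return ("spliceai_max_variant", "spliceai_max_position")

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> dict[str, float]:
        by_alt = self._deltas.get((chrom, int(pos)))
        if not by_alt:
            return {}
        v, p = spliceai_max_features(by_alt, alt)
        if np.isnan(v):
            return {}
        return {"spliceai_max_variant": v, "spliceai_max_position": p}


def annotate(
    variants: pd.DataFrame,
    sources: Sequence[AnnotationSource],
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Fill one feature vector per variant from the given sources.

    Two sources declaring the same feature is a configuration error raised at
    setup.  A source whose lookup raises leaves its features missing for that
    variant (warning counted).  Features no source declares stay missing.
    Returns a frame with the schema's 58 columns, NaN for missing, indexed
    like ``variants``.
    """
    schema = schema or default_schema()
    seen: dict[str, int] = {}
    for i, src in enumerate(sources):
        for f in src.declared_features:
            if f not in schema.names:
                raise ValueError(f"source {i} declares unknown feature {f!r}")
            if f in seen:
                raise ValueError(
                    f"feature {f!r} declared by sources {seen[f]} and {i}")
            seen[f] = i

    out = np.full((len(variants), len(schema)), np.nan)
    col_idx = {name: j for j, name in enumerate(schema.names)}
    n_failures = 0
    rows = list(variants[["chrom", "pos", "ref", "alt"]].itertuples(index=False))
    for src in sources:
        for i, (chrom, pos, ref, alt) in enumerate(rows):
            try:
                values = src.lookup(str(chrom), int(pos), str(ref), str(alt))
            except Exception:  # noqa: BLE001 - source failure -> missing
                n_failures += 1
                continue
            for name, value in values.items():
                if not schema[name].in_domain(float(value)):
                    raise ValueError(
                        f"{name}={value} out of domain {schema[name].domain} "
                        f"at {chrom}:{pos}")
                out[i, col_idx[name]] = value
    if n_failures:
        warnings.warn(f"annotate: {n_failures} source lookups failed; features left missing")
    return pd.DataFrame(out, columns=schema.names, index=variants.index)
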