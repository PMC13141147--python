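"""Stage orchestration: file-level wrappers the CLI exposes one-to-one.

Every stage writes its outputs plus a ``resolved_config.yaml`` capturing the
parameters and derived seed it ran with, so any output directory can be
reproduced exactly.  Per-stage seeds derive from the global seed through
``numpy.random.SeedSequence([seed, stage_index])``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import curation, evaluation, model, partitioning, regions, synthetic, training
from .features import default_schema
from .regions import variant_key

logger = logging.getLogger(__name__)

STAGES = ("synth", "curate", "partition", "build_train", "annotate",
          "train", "score", "evaluate", "spike_in", "splice_value")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {},  # SynthConfig field overrides
    "regions": {"upstream_window": 1000, "downstream_window": 1000,
                "intergenic_cap": 10000},
    "curation": {"max_homozygotes": 0, "max_af": 0.001},
    "partition": {"k": 10},
    "training": {"ratio": 10},
    "model": {},  # PartitionedBoostingScorer kwargs
    "evaluation": {"n_individuals": 20, "background_size": 10000,
                   "n_background_pool": 5000},
}


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed; stable across runs."""
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _write_resolved(outdir: Path, stage: str, resolved: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump({"stage": stage, **resolved}, sort_keys=True))


# ---------------------------------------------------------------------------
# stages


def run_synth(outdir: str | Path, config: dict) -> dict[str, Path]:
    outdir = Path(outdir)
    seed = stage_seed(config["seed"], "synth")
    scfg = synthetic.SynthConfig(**{**config.get("synth", {}), "seed": seed})
    ds = synthetic.generate_dataset(scfg)
    paths = synthetic.write_dataset(ds, outdir)
    _write_resolved(outdir, "synth", {"seed": seed,
                                      "synth": dataclasses.asdict(scfg)})
    return paths


def run_curate(records_path: str | Path, gene_models_path: str | Path,
               outdir: str | Path, config: dict) -> Path:
    outdir = Path(outdir)
    records = pd.read_csv(records_path, sep="\t", dtype={"chrom": str, "ref": str,
                                                         "alt": str})
    if "region" not in records.columns or "gene_id" not in records.columns:
        genes = regions.load_gene_models(gene_models_path)
        records = regions.assign_regions(records, genes, **config["regions"])
    positives, report = curation.curate_positive_set(records, **config["curation"])
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "positives.tsv"
    positives.to_csv(out, sep="\t", index=False)
    (outdir / "curation_report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True))
    _write_resolved(outdir, "curate", {"curation": config["curation"]})
    return out


def run_partition(gene_models_path: str | Path, positives_path: str | Path,
                  outdir: str | Path, config: dict) -> Path:
    outdir = Path(outdir)
    genes = regions.load_gene_models(gene_models_path)
    positives = pd.read_csv(positives_path, sep="\t")
    seed = stage_seed(config["seed"], "partition")
    pmap = partitioning.make_partitions(
        genes, set(positives["gene_id"]), k=config["partition"]["k"], seed=seed)
    outdir.mkdir(parents=True, exist_ok=True)
    pmap.save(outdir / "partitions.tsv", outdir / "partitions_meta.json")
    _write_resolved(outdir, "partition", {"seed": seed, "partition": config["partition"]})
    return outdir / "partitions.tsv"


def run_build_train(positives_path: str | Path, pool_path: str | Path,
                    partitions_dir: str | Path, outdir: str | Path,
                    config: dict) -> Path:
    outdir = Path(outdir)
    positives = pd.read_csv(positives_path, sep="\t", dtype={"chrom": str})
    pool = pd.read_csv(pool_path, sep="\t", dtype={"chrom": str})
    pmap = partitioning.PartitionMap.load(
        Path(partitions_dir) / "partitions.tsv",
        Path(partitions_dir) / "partitions_meta.json")
    seed = stage_seed(config["seed"], "build_train")
    table = training.build_training_table(
        positives, pool, pmap, ratio=config["training"]["ratio"], seed=seed)
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "training_table.tsv"
    table.table.to_csv(out, sep="\t", index=False)
    (outdir / "sampling_meta.json").write_text(
        json.dumps(table.metadata, indent=1, sort_keys=True))
    _write_resolved(outdir, "build_train", {"seed": seed, "training": config["training"]})
    return out


def run_annotate(table_path: str | Path, annotations_path: str | Path,
                 outdir: str | Path, config: dict) -> Path:
    """Join the 58 feature columns onto a variant table by variant key."""
    outdir = Path(outdir)
    table = pd.read_csv(table_path, sep="\t", dtype={"chrom": str})
    ann = pd.read_csv(annotations_path, sep="\t", dtype={"chrom": str})
    schema = default_schema()
    ann = ann.assign(_key=variant_key(ann)).set_index("_key")
    keys = variant_key(table)
    missing = ~keys.isin(ann.index)
    if missing.any():
        raise ValueError(f"{int(missing.sum())} variants lack annotations")
    feats = ann.loc[keys, schema.names].reset_index(drop=True)
    merged = pd.concat([table.reset_index(drop=True), feats], axis=1)
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "annotated_table.tsv"
    merged.to_csv(out, sep="\t", index=False, float_format="%.6g")
    _write_resolved(outdir, "annotate", {"n_variants": int(len(merged))})
    return out


def run_train(annotated_table_path: str | Path, partitions_dir: str | Path,
              outdir: str | Path, config: dict) -> Path:
    outdir = Path(outdir)
    df = pd.read_csv(annotated_table_path, sep="\t", dtype={"chrom": str})
    pmap = partitioning.PartitionMap.load(
        Path(partitions_dir) / "partitions.tsv",
        Path(partitions_dir) / "partitions_meta.json")
    schema = default_schema()
    seed = stage_seed(config["seed"], "train")
    bundle = model.train_bundle(df, df[schema.names], pmap,
                                hyperparams=config.get("model", {}),
                                seed=seed, schema=schema)
    bundle.save(outdir)
    _write_resolved(outdir, "train", {"seed": seed, "model": config.get("model", {})})
    return outdir


def run_score(bundle_dir: str | Path, annotated_path: str | Path,
              outdir: str | Path, config: dict) -> Path:
    outdir = Path(outdir)
    bundle = model.ModelBundle.load(bundle_dir)
    df = pd.read_csv(annotated_path, sep="\t", dtype={"chrom": str})
    records = model.score_variants(bundle, df, df[bundle.schema.names])
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "scores.tsv"
    model.write_precomputed_scores(records, out)
    _write_resolved(outdir, "score", {"bundle": Path(bundle_dir).name})
    return out


def run_evaluate(scored_path: str | Path, outdir: str | Path, config: dict,
                 extra_score_columns: tuple[str, ...] = (),
                 setting: str = "cross-validation") -> Path:
    outdir = Path(outdir)
    df = pd.read_csv(scored_path, sep="\t", dtype={"chrom": str})
    cols = ["score", *extra_score_columns]
    report = evaluation.region_stratified_report(df, score_columns=cols,
                                                 setting=setting)
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "evaluation_report.tsv"
    report.to_csv(out, sep="\t", index=False, float_format="%.6g")
    _write_resolved(outdir, "evaluate", {"score_columns": list(cols)})
    return out


# ---------------------------------------------------------------------------
# synthetic end-to-end


def run_all_synthetic(outdir: str | Path, config: dict) -> dict:
    """Chain every stage on a fresh synthetic dataset; returns summary dict."""
    outdir = Path(outdir)
    cfg = config
    paths = run_synth(outdir / "synth", cfg)

    pos_path = run_curate(paths["clinical_records"], paths["gene_models"],
                          outdir / "curate", cfg)
    part_path = run_partition(paths["gene_models"], pos_path,
                              outdir / "partition", cfg)
    table_path = run_build_train(pos_path, paths["negative_pool"],
                                 outdir / "partition", outdir / "build_train", cfg)
    annotated = run_annotate(table_path, paths["annotations"],
                             outdir / "annotate", cfg)
    bundle_dir = run_train(annotated, outdir / "partition", outdir / "train", cfg)
    scores_path = run_score(bundle_dir, annotated, outdir / "score", cfg)

    # evaluation on the partition-held-out (cross-validation) scores
    scored = model.read_precomputed_scores(scores_path)
    table = pd.read_csv(table_path, sep="\t", dtype={"chrom": str})
    scored = scored.merge(
        table[["chrom", "pos", "ref", "alt", "label"]],
        on=["chrom", "pos", "ref", "alt"], how="left")
    eval_in = outdir / "evaluate" / "scored_labelled.tsv"
    eval_in.parent.mkdir(parents=True, exist_ok=True)
    scored.to_csv(eval_in, sep="\t", index=False)
    report_path = run_evaluate(eval_in, outdir / "evaluate", cfg)

    # spike-in: score a pool sample as per-individual backgrounds
    bundle = model.ModelBundle.load(bundle_dir)
    ann = pd.read_csv(paths["annotations"], sep="\t", dtype={"chrom": str})
    pool = pd.read_csv(paths["negative_pool"], sep="\t", dtype={"chrom": str})
    schema = bundle.schema
    ann_idx = ann.assign(_key=variant_key(ann)).set_index("_key")
    rng = np.random.default_rng(stage_seed(cfg["seed"], "spike_in"))
    ecfg = cfg["evaluation"]
    bg_pool = pool.sample(n=min(ecfg["n_background_pool"], len(pool)),
                          random_state=int(rng.integers(2**31)))
    bg_feats = ann_idx.loc[variant_key(bg_pool), schema.names].reset_index(drop=True)
    bg_scores, _ = bundle.estimator.decision_scores(
        bg_feats, gene_ids=bg_pool["gene_id"].to_numpy())
    backgrounds = [rng.choice(bg_scores, size=min(ecfg["background_size"],
                                                  len(bg_scores)), replace=True)
                   for _ in range(ecfg["n_individuals"])]
    # insertions: each positive's held-out score + matched common from same gene/region
    positives_scored = scored[scored["label"] == 1]
    pool_idx = pool.set_index(["gene_id", "region"]).sort_index()
    insertions = []
    for r in positives_scored.itertuples(index=False):
        try:
            match = pool_idx.loc[(r.gene_id, r.region)]
        except KeyError:
            continue
        m = match.iloc[0] if isinstance(match, pd.DataFrame) else match
        mkey = f"{m.chrom}:{int(m.pos)}:{m.ref}:{m.alt}"
        mfeats = ann_idx.loc[[mkey], schema.names]
        mscore, _ = bundle.estimator.decision_scores(mfeats, gene_ids=[r.gene_id])
        insertions.append((float(r.score), float(mscore[0])))
    spike = evaluation.spike_in_ranking(backgrounds, insertions)
    (outdir / "spike_in").mkdir(parents=True, exist_ok=True)
    spike.table.to_csv(outdir / "spike_in" / "spike_in.tsv", sep="\t",
                       index=False, float_format="%.6g")
    (outdir / "spike_in" / "spike_in_summary.json").write_text(
        json.dumps(spike.to_dict(), indent=1, sort_keys=True))

    # splice added-value: per-gene top splice position vs its model score
    pool_feats = ann_idx.loc[variant_key(pool), schema.names].reset_index(drop=True)
    pool_scores, _ = bundle.estimator.decision_scores(
        pool_feats, gene_ids=pool["gene_id"].to_numpy())
    sp = pd.DataFrame({
        "gene_id": pool["gene_id"],
        "splice_score": pool_feats["spliceai_max_position"].fillna(0.0).to_numpy(),
        "model_score": pool_scores,
    })
    top = sp.loc[sp.groupby("gene_id")["splice_score"].idxmax()]
    gm = pd.read_csv(paths["gene_models"], sep="\t")
    top = top.merge(gm[["gene_id", "is_disease_gene"]], on="gene_id")
    splice_report = evaluation.splice_added_value(top)
    (outdir / "splice_value").mkdir(parents=True, exist_ok=True)
    (outdir / "splice_value" / "splice_value.json").write_text(
        json.dumps(splice_report, indent=1, sort_keys=True))

    summary = {
        "n_positives": int((table["label"] == 1).sum()),
        "n_negatives": int((table["label"] == 0).sum()),
        "report": str(report_path.relative_to(outdir)),
        "spike_in": spike.to_dict(),
        "splice_value": splice_report,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
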