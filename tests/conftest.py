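import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ncscore import (GeneModel, ModelBundle, build_negative_pool,
                     cap_positives_per_gene, curate_positive_set,
                     make_partitions, sample_matched_negatives, score_variants,
                     train_bundle)
from ncscore.regions import variant_key
from ncscore.synthetic import SynthConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_gene():
    """+strand gene: tx 1000-2000, exons [1000-1200],[1800-2000], CDS 1100-1900."""
    return GeneModel("GENE1", "chr1", "+", 1000, 2000, 1100, 1900,
                     ((1000, 1200), (1800, 2000)))


@pytest.fixture(scope="session")
def toy_gene_minus():
    """Same geometry mirrored onto the minus strand."""
    return GeneModel("GENE1M", "chr1", "-", 1000, 2000, 1100, 1900,
                     ((1000, 1200), (1800, 2000)))


def _build_study(effect_size, seed):
    """Desk-scale study: generate, curate, partition, pair, train, CV-score."""
    cfg = SynthConfig(n_genes=400, n_positives=100, fraction_disease_genes=0.5,
                      pool_per_gene_region=3, effect_size=effect_size, seed=seed)
    ds = generate_dataset(cfg)
    positives, report = curate_positive_set(ds.clinical_records)
    pool = build_negative_pool(ds.pool, "common", positives=positives)
    pmap = make_partitions(ds.genes, set(positives["gene_id"]), k=10, seed=seed + 1)
    capped = cap_positives_per_gene(positives, seed=seed + 2)
    tt = sample_matched_negatives(capped, pool, pmap, ratio=10, seed=seed + 3)
    feat_index = ds.features.set_index(variant_key(ds.variants))
    feats = feat_index.loc[variant_key(tt.table)].reset_index(drop=True)
    bundle = train_bundle(tt.table, feats, pmap, seed=seed + 4)
    records = score_variants(bundle, tt.table, feats)
    scored = records.merge(
        tt.table[["chrom", "pos", "ref", "alt", "label", "pairing_id"]],
        on=["chrom", "pos", "ref", "alt"])
    return {"config": cfg, "dataset": ds, "positives": positives,
            "report": report, "pool": pool, "pmap": pmap, "table": tt,
            "features": feats, "feature_index": feat_index, "bundle": bundle,
            "scored": scored}


@pytest.fixture(scope="session")
def study_d1():
    """Reference-condition effect size (d=1): moderate, non-separable signal."""
    return _build_study(effect_size=1.0, seed=100)


@pytest.fixture(scope="session")
def study_d3():
    """Near-separable construction (d=3)."""
    return _build_study(effect_size=3.0, seed=300)
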