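import numpy as np
import pandas as pd
import pytest
import xgboost as xgb
from sklearn.base import clone
from sklearn.model_selection import GroupKFold

from ncscore import (ModelBundle, PartitionedBoostingScorer, auroc,
                     score_variants, train_bundle, write_precomputed_scores)
from ncscore.model import read_precomputed_scores


class TestEstimatorContract:
    def test_get_set_params_and_clone(self):
        est = PartitionedBoostingScorer(learning_rate=0.1, max_depth=3)
        params = est.get_params()
        assert params["learning_rate"] == 0.1
        est2 = clone(est).set_params(max_depth=4)
        assert est2.get_params()["max_depth"] == 4

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            PartitionedBoostingScorer().decision_scores(np.zeros((2, 3)))


class TestBundleTraining:
    def test_bundle_has_k_models_and_passes_leakage_gate(self, study_d1):
        bundle = study_d1["bundle"]
        assert bundle.k == 10
        assert len(bundle.estimator.boosters_) == 10
        # re-check the no-leakage invariant from bundle metadata
        from ncscore import assert_no_leakage
        table = study_d1["table"].table
        pmap = bundle.partition_map
        for j in range(bundle.k):
            training_rows = table[pmap.partitions_of(table["gene_id"]) != j]
            assert assert_no_leakage(pmap, training_rows, j)

    def test_near_separable_every_model_strong(self, study_d3):
        """d=3 construction: each member's held-out AUROC is >= 0.95."""
        scored = study_d3["scored"]
        pmap = study_d3["pmap"]
        parts = pmap.partitions_of(scored["gene_id"])
        for j in np.unique(parts):
            sub = scored[parts == j]
            if sub["label"].nunique() < 2:
                continue
            assert auroc(sub["label"], sub["score"]) >= 0.95

    def test_label_permutation_gives_chance_auroc(self, study_d1):
        rng = np.random.default_rng(0)
        table = study_d1["table"].table.copy()
        perm = rng.permutation(len(table))
        table["label"] = table["label"].to_numpy()[perm]
        bundle = train_bundle(table, study_d1["features"], study_d1["pmap"], seed=1)
        recs = score_variants(bundle, table, study_d1["features"])
        merged = recs.merge(table[["chrom", "pos", "ref", "alt", "label"]],
                            on=["chrom", "pos", "ref", "alt"])
        a = auroc(merged["label"], merged["score"])
        assert 0.4 <= a <= 0.6

    def test_scores_bounded_and_deterministic(self, study_d1):
        bundle = study_d1["bundle"]
        feats = study_d1["features"]
        genes = study_d1["table"].table["gene_id"].to_numpy()
        s1, _ = bundle.estimator.decision_scores(feats, gene_ids=genes)
        s2, _ = bundle.estimator.decision_scores(feats, gene_ids=genes)
        assert ((s1 >= 0) & (s1 <= 1)).all()
        assert np.array_equal(s1, s2)

    def test_missing_positive_partition_rejected(self, study_d1):
        table = study_d1["table"].table
        feats = study_d1["features"]
        # keep positives of a single partition only: its complement has none
        parts = study_d1["pmap"].partitions_of(table["gene_id"])
        keep = (table["label"] == 0) | (parts == 0)
        with pytest.raises(ValueError, match="no positives"):
            train_bundle(table[keep].reset_index(drop=True),
                         feats[keep].reset_index(drop=True),
                         study_d1["pmap"], seed=0,
                         hyperparams={"early_stopping_rounds": 0, "n_rounds": 10})

    def test_bundle_close_to_grouped_cv_single_model(self, study_d1):
        """The bundle is a leakage-control device, not a different learner."""
        table = study_d1["table"].table
        feats = study_d1["features"]
        bundle_auroc = auroc(study_d1["scored"]["label"], study_d1["scored"]["score"])
        X = feats.to_numpy(dtype=float)
        y = table["label"].to_numpy()
        genes = table["gene_id"].to_numpy()
        scores = np.zeros(len(y))
        for tr, te in GroupKFold(n_splits=10).split(X, y, groups=genes):
            booster = xgb.train(
                {"objective": "binary:logistic", "eta": 0.05, "max_depth": 6,
                 "subsample": 0.8, "colsample_bytree": 0.8,
                 "tree_method": "hist", "nthread": 1, "seed": 0},
                xgb.DMatrix(X[tr], label=y[tr], missing=np.nan),
                num_boost_round=150)
            scores[te] = booster.predict(xgb.DMatrix(X[te], missing=np.nan))
        cv_auroc = auroc(y, scores)
        assert abs(bundle_auroc - cv_auroc) < 0.05


class TestScoring:
    def test_mapped_variants_use_their_partition_model(self, study_d1):
        scored = study_d1["scored"]
        pmap = study_d1["pmap"]
        expected = pmap.partitions_of(scored["gene_id"])
        assert (scored["model_index"].astype(int).to_numpy() == expected).all()

    def test_novel_gene_scored_by_mean_of_members(self, study_d1):
        bundle = study_d1["bundle"]
        feats = study_d1["features"].iloc[:5]
        novel = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(5), "ref": "A", "alt": "C",
            "gene_id": "NOVEL_GENE", "region": "intronic"})
        recs = score_variants(bundle, novel, feats)
        assert (recs["model_index"] == "mean").all()
        per_model = np.stack([
            bundle.estimator._scores_from_model(j, feats.to_numpy(dtype=float))
            for j in range(bundle.k)])
        manual = per_model.mean(axis=0)
        recs_sorted = recs.sort_values("pos")
        assert np.allclose(recs_sorted["score"], np.round(manual, 6), atol=5e-7)

    def test_feature_length_mismatch_rejected(self, study_d1):
        bundle = study_d1["bundle"]
        with pytest.raises(ValueError, match="length"):
            bundle.estimator.decision_scores(np.zeros((3, 10)))

    def test_save_load_identical_scores(self, study_d1, tmp_path):
        bundle = study_d1["bundle"]
        feats = study_d1["features"]
        genes = study_d1["table"].table["gene_id"].to_numpy()
        bundle.save(tmp_path / "bundle")
        back = ModelBundle.load(tmp_path / "bundle")
        assert back.k == bundle.k
        s1, m1 = bundle.estimator.decision_scores(feats, gene_ids=genes)
        s2, m2 = back.estimator.decision_scores(feats[back.schema.names],
                                                gene_ids=genes)
        assert np.allclose(s1, s2, atol=1e-7)
        assert list(m1) == list(m2)


class TestPrecomputedScores:
    def test_roundtrip_byte_identical(self, study_d1, tmp_path):
        recs = score_variants(study_d1["bundle"], study_d1["table"].table.head(100),
                              study_d1["features"].head(100))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_precomputed_scores(recs, p1)
        back = read_precomputed_scores(p1)
        write_precomputed_scores(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.allclose(back["score"], recs["score"], atol=1e-6)

    def test_unsorted_input_rejected(self, study_d1, tmp_path):
        recs = score_variants(study_d1["bundle"], study_d1["table"].table.head(10),
                              study_d1["features"].head(10))
        shuffled = recs.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            write_precomputed_scores(shuffled, tmp_path / "x.tsv")

    def test_empty_set_writes_header_only(self, study_d1, tmp_path):
        recs = score_variants(study_d1["bundle"], study_d1["table"].table.head(0),
                              study_d1["features"].head(0))
        write_precomputed_scores(recs, tmp_path / "e.tsv")
        lines = (tmp_path / "e.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#chrom")
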