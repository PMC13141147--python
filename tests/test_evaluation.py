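import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from ncscore import (auroc, aupr, gene_region_bias, rank_percentiles,
                     region_stratified_report, spike_in_ranking,
                     splice_added_value)
from ncscore.evaluation import compare_spike_in_methods


def brute_force_auroc(labels, scores):
    """Oracle: direct count over all positive-negative pairs."""
    labels, scores = np.asarray(labels), np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_aupr(labels, scores):
    """Oracle: exhaustive step enumeration over distinct thresholds."""
    labels, scores = np.asarray(labels), np.asarray(scores)
    thresholds = sorted(set(scores), reverse=True)
    npos = (labels == 1).sum()
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        called = scores >= t
        tp = int((labels[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / npos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 0], [0.9, 0.1]) == 1.0

    def test_all_ties_half(self):
        assert auroc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_hand_example(self):
        assert auroc([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([1, 1], [0.1, 0.2])

    @given(st.integers(0, 10_000))
    def test_equals_pair_count_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 200)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        scores = rng.choice(np.linspace(0, 1, 20), size=n)  # force ties
        ours = auroc(labels, scores)
        assert ours == pytest.approx(brute_force_auroc(labels, scores))
        assert ours == pytest.approx(roc_auc_score(labels, scores))

    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([0, 1] * 10)
        scores = rng.uniform(size=20)
        assert auroc(labels, scores) == pytest.approx(
            auroc(labels, np.exp(3 * scores) + 7))
        assert aupr(labels, scores) == pytest.approx(
            aupr(labels, np.exp(3 * scores) + 7))


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_worst_ranking_single_positive(self):
        assert aupr([1, 0, 0, 0], [0.1, 0.9, 0.8, 0.7]) == 0.25

    @given(st.integers(0, 10_000))
    def test_equals_step_sum_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 200)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        scores = rng.choice(np.linspace(0, 1, 15), size=n)
        ours = aupr(labels, scores)
        assert ours == pytest.approx(brute_force_aupr(labels, scores))
        assert ours == pytest.approx(average_precision_score(labels, scores))


class TestRegionReport:
    def _frame(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "label": rng.integers(0, 2, n),
            "region": rng.choice(["upstream", "UTR5", "intronic", "UTR3",
                                  "downstream", "intergenic"], n),
            "score": rng.uniform(size=n),
        })

    def test_single_region_global_equals_region_row(self):
        df = self._frame()
        df["region"] = "intronic"
        rep = region_stratified_report(df)
        g = rep[rep["region"] == "global"].iloc[0]
        r = rep[rep["region"] == "intronic"].iloc[0]
        assert g["auroc_score"] == r["auroc_score"]
        assert g["aupr_score"] == r["aupr_score"]

    def test_counts_sum_and_canonical_order(self):
        df = self._frame(1)
        rep = region_stratified_report(df)
        assert list(rep["region"]) == ["global", "upstream", "UTR5", "intronic",
                                       "UTR3", "downstream", "intergenic"]
        assert rep.iloc[0]["n_pathogenic"] == rep.iloc[1:]["n_pathogenic"].sum()
        assert rep.iloc[0]["n_benign"] == rep.iloc[1:]["n_benign"].sum()

    def test_matches_direct_per_subset_calls(self):
        df = self._frame(2)
        rep = region_stratified_report(df).set_index("region")
        for r in ("upstream", "intronic", "UTR3"):
            sub = df[df["region"] == r]
            assert rep.loc[r, "auroc_score"] == pytest.approx(
                auroc(sub["label"], sub["score"]))
            assert rep.loc[r, "aupr_score"] == pytest.approx(
                aupr(sub["label"], sub["score"]))

    def test_single_class_region_gets_na_with_warning(self):
        df = self._frame(3)
        df.loc[df["region"] == "UTR3", "label"] = 1
        with pytest.warns(UserWarning, match="single class"):
            rep = region_stratified_report(df)
        assert np.isnan(rep.set_index("region").loc["UTR3", "auroc_score"])

    def test_extra_score_column_adds_metric_pair(self):
        df = self._frame(4)
        df["other"] = df["score"] * 0.5
        rep = region_stratified_report(df, score_columns=("score", "other"))
        assert {"auroc_other", "aupr_other"} <= set(rep.columns)


class TestSpikeIn:
    def test_percentile_example(self):
        res = spike_in_ranking([np.array([0.1, 0.2, 0.3])], [(0.9, 0.15)])
        row = res.table.iloc[0]
        assert row["pathogenic_pct"] == 75.0
        assert row["common_pct"] == pytest.approx(100 * 1 / 4)

    def test_floor_case(self):
        res = spike_in_ranking([np.array([0.5, 0.6, 0.7])], [(0.1, 0.1)])
        assert res.table.iloc[0]["pathogenic_pct"] == 0.0

    def test_tie_gets_half_credit(self):
        res = spike_in_ranking([np.array([0.5, 0.5, 0.9])], [(0.5, 0.5)])
        assert res.table.iloc[0]["pathogenic_pct"] == pytest.approx(100 * 1 / 4)

    def test_percentile_monotone_in_score(self):
        bg = np.sort(np.random.default_rng(0).uniform(size=50))
        scores = np.linspace(0, 1, 21)
        res = spike_in_ranking([bg], [(s, 0.0) for s in scores])
        pcts = res.table["pathogenic_pct"].to_numpy()
        assert (np.diff(pcts) >= 0).all()

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            spike_in_ranking([np.array([])], [(0.5, 0.5)])

    def test_identical_methods_compare_to_p_one(self):
        bg = [np.linspace(0, 1, 20)] * 3
        res = spike_in_ranking(bg, [(0.8, 0.2), (0.6, 0.1)])
        with pytest.warns(UserWarning):
            _, p = compare_spike_in_methods(res, res)
        assert p == 1.0


class TestSpliceAddedValue:
    def _frame(self, shift=2.0, n=160, seed=0):
        rng = np.random.default_rng(seed)
        disease = np.repeat([True, False], n // 2)
        splice = rng.normal(disease * 0.5, 1.0)
        model = rng.normal(disease * shift, 1.0)
        return pd.DataFrame({"gene_id": [f"G{i}" for i in range(n)],
                             "splice_score": splice, "model_score": model,
                             "is_disease_gene": disease})

    def test_model_advantage_detected(self):
        out = splice_added_value(self._frame())
        assert out["p_model_vs_splice_disease_genes"] < 0.05
        assert out["direction_model_minus_splice"] > 0
        assert out["p_disease_vs_nondisease_model_score"] < 0.01

    def test_identical_columns_give_p_one(self):
        df = self._frame()
        df["splice_score"] = df["model_score"]
        with pytest.warns(UserWarning):
            out = splice_added_value(df)
        assert out["p_model_vs_splice_disease_genes"] == 1.0
        assert out["statistic_model_vs_splice"] == 0.0

    def test_top_gene_percentile_convention(self):
        # max of G=4 distinct values -> midrank 4 of n+1=5 -> 80%
        pct = rank_percentiles([1.0, 2.0, 3.0, 4.0])
        assert pct[-1] == pytest.approx(80.0)

    def test_too_few_genes_rejected(self):
        df = self._frame(n=4).iloc[:3]
        with pytest.raises(ValueError, match="at least 2"):
            splice_added_value(df)


class TestGeneRegionBias:
    def test_gene_median_toy(self):
        common = pd.DataFrame({
            "gene_id": ["G1"] * 3, "region": ["UTR5"] * 3,
            "score": [0.2, 0.4, 0.9]})
        patho = pd.DataFrame({"region": ["UTR5"], "score": [0.95]})
        rep = gene_region_bias(common, patho).set_index("region")
        assert rep.loc["UTR5", "common_median_of_gene_medians"] == 0.4
        assert rep.loc["UTR5", "n_genes"] == 1

    def test_null_data_no_systematic_direction(self):
        """Zero-signal zero-bias: one-sided p-values not systematically small."""
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(10):
            common = pd.DataFrame({
                "gene_id": rng.choice([f"G{i}" for i in range(30)], 300),
                "region": rng.choice(["UTR5", "intronic"], 300),
                "score": rng.uniform(size=300)})
            patho = pd.DataFrame({"region": ["intronic"] * 20,
                                  "score": rng.uniform(size=20)})
            rep = gene_region_bias(common, patho).set_index("region")
            ps.append(rep.loc["intronic", "p_pathogenic_gt_utr5_common"])
        ps = np.array(ps)
        assert ps.mean() > 0.15  # uniform-ish, not piled near 0
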