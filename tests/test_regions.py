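import numpy as np
import pandas as pd
import pytest

from ncscore import GeneModel, classify_region, load_gene_models
from ncscore.regions import GeneIndex, RegionType


class TestGeneModelInvariants:
    def test_exon_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside transcript span"):
            GeneModel("G", "chr1", "+", 1000, 2000, 1100, 1900,
                      ((900, 1200), (1800, 2000)))

    def test_cds_outside_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("G", "chr1", "+", 1000, 2000, 900, 1900,
                      ((1000, 1200), (1800, 2000)))

    def test_cds_not_covered_by_exons_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            GeneModel("G", "chr1", "+", 1000, 2000, 1500, 1900,
                      ((1000, 1200), (1800, 2000)))

    def test_reversed_exon_rejected(self):
        with pytest.raises(ValueError, match="start"):
            GeneModel("G", "chr1", "+", 1000, 2000, 1100, 1900,
                      ((1200, 1000), (1800, 2000)))


class TestClassifyRegion:
    @pytest.mark.parametrize("pos,expected", [
        (950, RegionType.UPSTREAM),
        (1050, RegionType.UTR5),
        (1500, RegionType.INTRONIC),
        (1950, RegionType.UTR3),
        (2100, RegionType.DOWNSTREAM),
        (1150, RegionType.CODING),
    ])
    def test_plus_strand_examples(self, toy_gene, pos, expected):
        a = classify_region(("chr1", pos, "A", "C"), [toy_gene])
        assert a.region is expected
        assert a.gene_id == "GENE1"

    @pytest.mark.parametrize("pos,expected", [
        (2100, RegionType.UPSTREAM),
        (1950, RegionType.UTR5),
        (1500, RegionType.INTRONIC),
        (1050, RegionType.UTR3),
        (950, RegionType.DOWNSTREAM),
    ])
    def test_minus_strand_mirror(self, toy_gene_minus, pos, expected):
        a = classify_region(("chr1", pos, "A", "C"), [toy_gene_minus])
        assert a.region is expected

    def test_unknown_chromosome_unscorable(self, toy_gene):
        assert classify_region(("chrX", 1500, "A", "C"), [toy_gene]) is None

    def test_beyond_cap_unscorable(self, toy_gene):
        assert classify_region(("chr1", 50_000, "A", "C"), [toy_gene]) is None

    def test_intergenic_within_cap(self, toy_gene):
        a = classify_region(("chr1", 5000, "A", "C"), [toy_gene])
        assert a.region is RegionType.INTERGENIC
        assert a.distance_to_gene == 3000

    def test_non_snv_rejected(self, toy_gene):
        with pytest.raises(ValueError, match="SNV"):
            classify_region(("chr1", 1500, "AT", "A"), [toy_gene])

    def test_equidistant_tie_breaks_lexicographically(self):
        # two identical genes flanking pos 5000 at equal distance
        ga = GeneModel("GB", "chr1", "+", 1000, 2000, 1100, 1900,
                       ((1000, 1200), (1800, 2000)))
        gb = GeneModel("GA", "chr1", "+", 8000, 9000, 8100, 8900,
                       ((8000, 8200), (8800, 9000)))
        a = classify_region(("chr1", 5000, "A", "C"), [ga, gb])
        assert a.region is RegionType.INTERGENIC
        assert a.gene_id == "GA"  # equal distance -> lexicographic gene id

    def test_genic_precedence_over_flank(self):
        # pos intronic for g1 and upstream of g2: genic wins
        g1 = GeneModel("G1", "chr1", "+", 1000, 2000, 1100, 1900,
                       ((1000, 1200), (1800, 2000)))
        g2 = GeneModel("G2", "chr1", "+", 2100, 3000, 2200, 2900,
                       ((2100, 2400), (2800, 3000)))
        a = classify_region(("chr1", 1500, "A", "C"), [g1, g2])
        assert (a.gene_id, a.region) == ("G1", RegionType.INTRONIC)


class TestRegionPartitionOfLine:
    def test_every_position_gets_exactly_one_region(self, toy_gene):
        """Scanning the whole neighbourhood of a gene partitions the line."""
        idx = GeneIndex([toy_gene])
        seen = set()
        prev = None
        for pos in range(toy_gene.tx_start - 1100, toy_gene.tx_end + 1101):
            a = classify_region(("chr1", pos, "A", "C"), idx)
            if toy_gene.tx_start - 1000 <= pos <= toy_gene.tx_end + 1000:
                assert a is not None
            if a is not None:
                seen.add(a.region)
                prev = a.region
        assert RegionType.UPSTREAM in seen and RegionType.DOWNSTREAM in seen
        assert seen >= {RegionType.UTR5, RegionType.UTR3, RegionType.INTRONIC,
                        RegionType.CODING}

    def test_strand_symmetry(self, toy_gene, toy_gene_minus):
        """Flipping strand maps upstream<->downstream, UTR5<->UTR3."""
        swap = {RegionType.UPSTREAM: RegionType.DOWNSTREAM,
                RegionType.DOWNSTREAM: RegionType.UPSTREAM,
                RegionType.UTR5: RegionType.UTR3,
                RegionType.UTR3: RegionType.UTR5,
                RegionType.INTRONIC: RegionType.INTRONIC,
                RegionType.CODING: RegionType.CODING,
                RegionType.INTERGENIC: RegionType.INTERGENIC}
        for pos in range(800, 2201, 7):
            a = classify_region(("chr1", pos, "A", "C"), [toy_gene])
            b = classify_region(("chr1", pos, "A", "C"), [toy_gene_minus])
            assert swap[a.region] is b.region

    def test_determinism(self, toy_gene):
        runs = [classify_region(("chr1", p, "A", "C"), [toy_gene])
                for p in (950, 1500, 2100)]
        again = [classify_region(("chr1", p, "A", "C"), [toy_gene])
                 for p in (950, 1500, 2100)]
        assert runs == again


GTF_ONE_GENE = """\
chr1\ttest\tgene\t1000\t2000\t.\t+\t.\tgene_id "G1";
chr1\ttest\ttranscript\t1000\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\texon\t1000\t1200\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\texon\t1800\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\tCDS\t1100\t1200\t.\t+\t0\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\tCDS\t1800\t1900\t.\t+\t0\tgene_id "G1"; transcript_id "G1.t1";
"""

GTF_NONCODING_TX = """\
chr1\ttest\tgene\t5000\t6000\t.\t+\t.\tgene_id "G2";
chr1\ttest\ttranscript\t5000\t6000\t.\t+\t.\tgene_id "G2"; transcript_id "G2.t1";
chr1\ttest\texon\t5000\t6000\t.\t+\t.\tgene_id "G2"; transcript_id "G2.t1";
"""


class TestLoaders:
    def test_one_gene_gtf(self, tmp_path):
        p = tmp_path / "toy.gtf"
        p.write_text(GTF_ONE_GENE)
        models = load_gene_models(p)
        assert len(models) == 1
        g = models[0]
        assert (g.gene_id, g.tx_start, g.tx_end) == ("G1", 1000, 2000)
        assert (g.cds_start, g.cds_end) == (1100, 1900)
        assert g.exons == ((1000, 1200), (1800, 2000))

    def test_mixed_gtf_skips_noncoding(self, tmp_path, caplog):
        p = tmp_path / "mixed.gtf"
        p.write_text(GTF_ONE_GENE + GTF_NONCODING_TX)
        with caplog.at_level("INFO"):
            models = load_gene_models(p)
        assert [g.gene_id for g in models] == ["G1"]
        assert any("skipped 1" in r.message for r in caplog.records)

    def test_tsv_roundtrip_and_sorting(self, tmp_path):
        p = tmp_path / "genes.tsv"
        pd.DataFrame({
            "gene_id": ["B", "A"], "chrom": ["chr2", "chr1"],
            "strand": ["+", "-"], "tx_start": [1000, 1000],
            "tx_end": [2000, 2000], "cds_start": [1100, 1100],
            "cds_end": [1900, 1900],
            "exons": ["1000-1200,1800-2000"] * 2,
        }).to_csv(p, sep="\t", index=False)
        models = load_gene_models(p)
        assert [g.gene_id for g in models] == ["A", "B"]  # (chrom, tx_start) order

    def test_tsv_malformed_coordinates_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        pd.DataFrame({
            "gene_id": ["G"], "chrom": ["chr1"], "strand": ["+"],
            "tx_start": [2000], "tx_end": [1000], "cds_start": [1100],
            "cds_end": [1900], "exons": ["1000-1200"],
        }).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="line 2"):
            load_gene_models(p)
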