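import numpy as np
import pandas as pd
import pytest

from dmrscan.annotation import (
    FeatureModel,
    annotate_dmrs,
    build_feature_model,
    feature_enrichment,
    genes_with_promoter_dmrs,
    promoter_interval,
)
from oracles import all_pairs_overlaps

GFF = """\
##gff-version 3
chr1\ttest\tgene\t10000\t15000\t.\t+\t.\tID=geneA;gene_id=geneA
chr1\ttest\tmRNA\t10000\t15000\t.\t+\t.\tID=tA;Parent=geneA
chr1\ttest\texon\t10000\t10500\t.\t+\t.\tParent=tA
chr1\ttest\texon\t12000\t12500\t.\t+\t.\tParent=tA
chr1\ttest\tCDS\t10100\t10500\t.\t+\t.\tParent=tA
chr1\ttest\tfive_prime_UTR\t10000\t10099\t.\t+\t.\tParent=tA
chr2\ttest\tgene\t5000\t8000\t.\t-\t.\tID=geneB;gene_id=geneB
chr2\ttest\tmRNA\t5000\t8000\t.\t-\t.\tID=tB;Parent=geneB
chr2\ttest\texon\t5000\t8000\t.\t-\t.\tParent=tB
"""


@pytest.fixture
def gff_model(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF)
    return build_feature_model(path, chrom_sizes={"chr1": 50_000, "chr2": 50_000})


class TestPromoterRule:
    def test_plus_strand(self):
        assert promoter_interval(10_000, "+") == (8700, 10_200)

    def test_minus_strand_reflection(self):
        # gene span [5000, 8000] on '-': TSS is 8000
        assert promoter_interval(8000, "-") == (7800, 9300)

    def test_clipping_at_chromosome_bounds(self):
        assert promoter_interval(1000, "+") == (1, 1200)
        assert promoter_interval(900, "-", chrom_size=1500) == (700, 1500)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_width_is_constant(self, strand):
        rng = np.random.default_rng(0)
        for tss in rng.integers(2000, 1_000_000, 25):
            s, e = promoter_interval(int(tss), strand)
            assert e - s + 1 == 1501
            assert (tss - s == 1300) if strand == "+" else (e - tss == 1300)


class TestBuildFeatureModel:
    def test_gene_features_and_promoters(self, gff_model):
        f = gff_model.features
        prom_a = f[(f["type"] == "promoter") & (f["gene_id"] == "geneA")].iloc[0]
        assert (prom_a["start"], prom_a["end"]) == (8700, 10_200)
        prom_b = f[(f["type"] == "promoter") & (f["gene_id"] == "geneB")].iloc[0]
        assert (prom_b["start"], prom_b["end"]) == (7800, 9300)

    def test_intron_is_gene_minus_exons(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tt\tgene\t100\t500\t.\t+\t.\tID=g1;gene_id=g1\n"
            "chr1\tt\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tt\texon\t100\t200\t.\t+\t.\tParent=t1\n"
            "chr1\tt\texon\t400\t500\t.\t+\t.\tParent=t1\n"
        )
        path = tmp_path / "g.gff3"
        path.write_text(gff)
        model = build_feature_model(path)
        introns = model.features[model.features["type"] == "intron"]
        assert [(r.start, r.end) for r in introns.itertuples()] == [(201, 399)]

    def test_upstream_excludes_promoter(self, gff_model):
        f = gff_model.features
        up_a = f[(f["type"] == "upstream") & (f["gene_id"] == "geneA")].iloc[0]
        assert (up_a["start"], up_a["end"]) == (8000, 8699)  # 5' of the promoter
        down_a = f[(f["type"] == "downstream") & (f["gene_id"] == "geneA")].iloc[0]
        assert (down_a["start"], down_a["end"]) == (15_001, 17_000)

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "genes.xyz"
        path.write_text("")
        with pytest.raises(ValueError, match="format"):
            build_feature_model(path)

    def test_bed_input(self, tmp_path):
        path = tmp_path / "feat.bed"
        path.write_text("chr1\t999\t2000\tregionX\t0\t+\n")
        model = build_feature_model(path)
        region = model.features[model.features["type"] == "region"].iloc[0]
        assert (region["start"], region["end"]) == (1000, 2000)  # BED converts to 1-based


class TestAnnotateDmrs:
    def test_promoter_overlap_arithmetic(self, gff_model):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [8900], "end": [9100]})
        hits = annotate_dmrs(dmrs, gff_model)
        prom = hits[hits["feature_type"] == "promoter"]
        assert len(prom) == 1
        assert prom.iloc[0]["overlap_bp"] == 201

    def test_intergenic_dmr_has_no_rows(self, gff_model):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [40_000], "end": [40_500]})
        assert annotate_dmrs(dmrs, gff_model).empty

    def test_missing_chromosome_warns(self, gff_model):
        dmrs = pd.DataFrame({"chrom": ["chrZ"], "start": [1], "end": [100]})
        with pytest.warns(UserWarning, match="chrZ"):
            annotate_dmrs(dmrs, gff_model)

    def test_matches_all_pairs_scan(self):
        rng = np.random.default_rng(21)
        n = 300
        feats = []
        for i in range(n):
            s = int(rng.integers(1, 100_000))
            feats.append(("chr1", s, s + int(rng.integers(1, 3000)), f"f{i}"))
        model = FeatureModel(
            features=pd.DataFrame(
                [dict(chrom=c, start=s, end=e, strand="+", type="region", gene_id=g)
                 for c, s, e, g in feats]
            )
        )
        dmrs = []
        for _ in range(n):
            s = int(rng.integers(1, 100_000))
            dmrs.append(("chr1", s, s + int(rng.integers(1, 2000))))
        got = annotate_dmrs(pd.DataFrame(dmrs, columns=["chrom", "start", "end"]), model)
        got_set = {(int(r.dmr_id.split("_")[1]) - 1, r.gene_id, r.overlap_bp)
                   for r in got.itertuples()}
        assert got_set == all_pairs_overlaps(dmrs, feats)

    def test_promoter_gene_list(self, gff_model):
        dmrs = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [8900, 8000], "end": [9100, 9000]})
        genes = genes_with_promoter_dmrs(annotate_dmrs(dmrs, gff_model))
        assert set(genes["gene_id"]) == {"geneA", "geneB"}


class TestEnrichment:
    def test_whole_genome_feature_has_ratio_one(self):
        model = FeatureModel(
            features=pd.DataFrame([dict(chrom="chr1", start=1, end=10_000,
                                        strand="+", type="everything", gene_id="g")]),
            chrom_sizes={"chr1": 10_000},
        )
        dmrs = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [100, 5000, 9000],
                             "end": [200, 5400, 9100]})
        enr = feature_enrichment(dmrs, model)
        assert enr.iloc[0]["ratio"] == pytest.approx(1.0)

    def test_constructed_tenfold_enrichment(self):
        # CDS occupies 10% of the toy genome; DMRs sit entirely inside it
        model = FeatureModel(
            features=pd.DataFrame([dict(chrom="chr1", start=1, end=1000,
                                        strand="+", type="CDS", gene_id="g")]),
            chrom_sizes={"chr1": 10_000},
        )
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [101], "end": [400]})
        enr = feature_enrichment(dmrs, model)
        assert enr.iloc[0]["ratio"] == pytest.approx(10.0)
        assert enr.iloc[0]["p_value"] < 1e-6

    def test_random_placement_is_unenriched(self):
        rng = np.random.default_rng(8)
        genome = 200_000
        # one feature type covering 50% of the genome in 1 kb stripes
        feats = [dict(chrom="chr1", start=s, end=s + 999, strand="+", type="stripe", gene_id=f"s{s}")
                 for s in range(1, genome, 2000)]
        model = FeatureModel(features=pd.DataFrame(feats), chrom_sizes={"chr1": genome})
        starts = rng.integers(1, genome - 500, 1000)
        dmrs = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 499})
        enr = feature_enrichment(dmrs, model)
        assert 0.8 < enr.iloc[0]["ratio"] < 1.25

    def test_partition_fractions_sum_to_one(self):
        half = 5000
        feats = [dict(chrom="chr1", start=1, end=half, strand="+", type="left", gene_id="l"),
                 dict(chrom="chr1", start=half + 1, end=10_000, strand="+", type="right", gene_id="r")]
        model = FeatureModel(features=pd.DataFrame(feats), chrom_sizes={"chr1": 10_000})
        dmrs = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [4001, 7001], "end": [6000, 7500]})
        enr = feature_enrichment(dmrs, model)
        assert enr["observed_frac"].sum() == pytest.approx(1.0)
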