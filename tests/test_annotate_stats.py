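import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_genome
from ssrmine.annotate_stats import (
    DensityConfig,
    RegionConfig,
    assign_regions,
    build_region_model,
    density_track,
    funnel_report,
    gc_content,
    interval_stats,
    motif_class_shares,
    overlap_marker_sets,
    percent,
    pic,
    pic_from_alleles,
)
from ssrmine.io_formats import GFFFeature
from ssrmine.ssr_finder import SSRTract, find_ssrs


def feat(type_, start, end, strand="+", fid=None, parent=None, seq_id="c1"):
    return GFFFeature(seq_id=seq_id, type=type_, start=start, end=end, strand=strand,
                      feature_id=fid, parent=parent)


@pytest.fixture()
def two_gene_model():
    """Plus-strand gene at [2001,5000] 1-based; minus-strand gene at [8001,11000].

    The plus gene's promoter [1,2000] deliberately overlaps nothing; the CDS of
    the minus gene lies inside the plus gene's downstream region.
    """
    feats = [
        feat("gene", 2001, 5000, "+", fid="g1"),
        feat("mRNA", 2001, 5000, "+", fid="m1", parent="g1"),
        feat("exon", 2001, 3000, "+", parent="m1"),
        feat("exon", 4001, 5000, "+", parent="m1"),
        feat("five_prime_UTR", 2001, 2200, "+", parent="m1"),
        feat("CDS", 2201, 3000, "+", parent="m1"),
        feat("CDS", 4001, 4800, "+", parent="m1"),
        feat("three_prime_UTR", 4801, 5000, "+", parent="m1"),
        feat("gene", 8001, 11000, "-", fid="g2"),
        feat("mRNA", 8001, 11000, "-", fid="m2", parent="g2"),
        feat("exon", 8001, 11000, "-", parent="m2"),
        feat("CDS", 8001, 11000, "-", parent="m2"),
    ]
    return feats, {"c1": 20_000}


class TestRegionModel:
    def test_partition_is_exact(self, two_gene_model):
        feats, lengths = two_gene_model
        model = build_region_model(feats, lengths)
        assert sum(model.region_lengths().values()) == 20_000

    def test_known_labels(self, two_gene_model):
        feats, lengths = two_gene_model
        model = build_region_model(feats, lengths)
        assert model.label_at("c1", 2100) == "five_prime_UTR"
        assert model.label_at("c1", 2500) == "CDS"
        assert model.label_at("c1", 3500) == "intron"
        assert model.label_at("c1", 4900) == "three_prime_UTR"
        assert model.label_at("c1", 15_000) == "intergenic"

    def test_promoter_upstream_of_plus_tss(self, two_gene_model):
        feats, lengths = two_gene_model
        model = build_region_model(feats, lengths)
        # 1500 bp upstream of the plus-strand TSS (base 2000 0-based)
        assert model.label_at("c1", 2000 - 1500) == "promoter"
        assert model.label_at("c1", 0) == "promoter"  # 2000 bp window edge

    def test_promoter_mirrored_on_minus_strand(self, two_gene_model):
        feats, lengths = two_gene_model
        model = build_region_model(feats, lengths)
        # minus-strand TSS is the gene end (base 10999); promoter extends right
        assert model.label_at("c1", 11_000 + 1500) == "promoter"
        assert model.label_at("c1", 11_000 + 2500) == "intergenic"

    def test_cds_wins_over_other_genes_promoter(self):
        # promoter of gene B covers gene A's CDS -> CDS by precedence
        feats = [
            feat("gene", 1001, 2000, "+", fid="gA"),
            feat("mRNA", 1001, 2000, "+", fid="mA", parent="gA"),
            feat("exon", 1001, 2000, "+", parent="mA"),
            feat("CDS", 1001, 2000, "+", parent="mA"),
            feat("gene", 2501, 4000, "+", fid="gB"),
            feat("mRNA", 2501, 4000, "+", fid="mB", parent="gB"),
            feat("exon", 2501, 4000, "+", parent="mB"),
            feat("CDS", 2501, 4000, "+", parent="mB"),
        ]
        model = build_region_model(feats, {"c1": 6000})
        assert model.label_at("c1", 1500) == "CDS"
        assert model.label_at("c1", 2200) == "promoter"

    def test_feature_beyond_contig_rejected(self):
        feats = [feat("gene", 1, 5000, "+", fid="g1")]
        with pytest.raises(ValueError, match="beyond"):
            build_region_model(feats, {"c1": 4000})

    def test_assignment_by_start_base(self, two_gene_model):
        feats, lengths = two_gene_model
        model = build_region_model(feats, lengths)
        # tract straddles the CDS/intron boundary at base 3000; starts in CDS
        straddler = SSRTract("g", "c1", 2990, 3010, "AG", 10)
        intronic = SSRTract("g", "c1", 3500, 3520, "AG", 10)
        labels = assign_regions([straddler, intronic], model)
        assert labels[straddler] == "CDS"
        assert labels[intronic] == "intron"

    def test_synthetic_panel_partition_conservation(self, small_panel):
        cfg, res = small_panel
        g1 = res.genomes[0]
        model = build_region_model(res.gff, g1.lengths())
        assert sum(model.region_lengths().values()) == g1.total_length()
        tracts = find_ssrs(g1)
        labels = assign_regions(tracts, model)
        assert len(labels) == len(tracts)  # every tract got exactly one label


class TestIntervalStats:
    @pytest.mark.parametrize(
        "count,expected",
        [(135_693, 15.48), (264_658, 7.93), (77_974, 26.93)],
    )
    def test_published_genome_scale_intervals(self, count, expected):
        assert interval_stats(count, DensityConfig(genome_size=2.1e9)) == expected

    def test_small_case(self):
        assert interval_stats(1000, DensityConfig(genome_size=1e6)) == 1.00

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            interval_stats(0)

    def test_strictly_decreasing_in_count(self):
        vals = [interval_stats(n) for n in (10_000, 50_000, 200_000, 500_000)]
        assert vals == sorted(vals, reverse=True)


class TestGcAndPic:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 100.0), ("ATAT", 0.0), ("ACGT", 50.0)])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == expected

    @pytest.mark.parametrize(
        "freqs,expected",
        [([1.0], 0.0), ([0.5, 0.5], 0.5), ([0.25] * 4, 0.75)],
    )
    def test_pic_closed_forms(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected)

    def test_pic_rejects_bad_frequencies(self):
        with pytest.raises(ValueError):
            pic([0.5, 0.4])
        with pytest.raises(ValueError):
            pic([1.2, -0.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 50), min_size=1, max_size=8))
    def test_pic_bounds(self, counts):
        n = sum(counts)
        freqs = [c / n for c in counts]
        v = pic(freqs)
        k = len(counts)
        assert 0 <= v < 1
        assert v <= 1 - 1 / k + 1e-12

    def test_pic_from_alleles_skips_missing(self):
        assert pic_from_alleles([200, 200, 202, None]) == pytest.approx(1 - (2 / 3) ** 2 - (1 / 3) ** 2)


class TestFunnel:
    def test_published_ratio_arithmetic(self):
        assert percent(9240, 25_437) == 36.33

    def test_funnel_counts_and_shares(self, small_panel):
        cfg, res = small_panel
        g1 = res.genomes[0]
        tracts = find_ssrs(g1)
        # synthetic funnel: thin the stages deterministically
        unique = tracts[::2]
        designed = unique[: len(unique) // 2]
        epcr_u = designed[:10]
        poly = designed[:4]
        df = funnel_report(tracts, unique, designed, epcr_u, poly)
        total = df.loc["total"]
        assert total["all_ssrs"] == len(tracts)
        assert total["unique_flanks"] == len(unique)
        assert total["polymorphic"] == 4
        assert total["unique_flanks_pct"] == percent(len(unique), len(tracts))
        # per-class counts add up to the totals
        classes = df.drop(index="total")
        for stage in ("all_ssrs", "unique_flanks", "primers_designed", "epcr_unique", "polymorphic"):
            assert classes[stage].sum() == total[stage]

    def test_motif_shares_sum_to_100(self, small_panel):
        cfg, res = small_panel
        tracts = find_ssrs(res.genomes[0])
        shares = motif_class_shares(tracts)
        assert shares["share_pct"].sum() == pytest.approx(100.0, abs=0.05)


def test_density_track_counts_sum_to_total(small_panel):
    cfg, res = small_panel
    g1 = res.genomes[0]
    tracts = find_ssrs(g1)
    track = density_track(tracts, g1.lengths(), window=5000)
    assert track["count"].sum() == len(tracts)
    assert (track["end"] - track["start"] <= 5000).all()


def test_overlap_marker_sets_with_slop():
    a = [("c1", 100, 120), ("c1", 5000, 5040)]
    b = [("c1", 115, 130), ("c2", 100, 120), ("c1", 5050, 5060)]
    assert overlap_marker_sets(a, b) == [(0, 0)]
    assert (1, 2) in overlap_marker_sets(a, b, slop=20)
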