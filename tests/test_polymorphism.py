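"""Alignment column-walk calling, region stratification, rate contrasts."""

import numpy as np
import pytest
from scipy import stats as sps

from cregulon import polymorphism as poly
from cregulon import synthetic_data as synth
from cregulon.io_formats import GeneModel, VariantRecord


class TestCallVariants:
    def test_single_mismatch(self):
        (v,) = poly.call_variants_from_alignment("ACGT", "ACCT", "c1")
        assert (v.vtype, v.position, v.ref_allele, v.alt_allele) == \
            ("SNP", 3, "G", "C")

    def test_insertion_gap_run(self):
        (v,) = poly.call_variants_from_alignment("AC-GT", "ACTGT", "c1")
        assert (v.vtype, v.position, v.alt_allele, v.indel_length) == \
            ("INS", 3, "T", 1)

    def test_deletion_gap_run(self):
        (v,) = poly.call_variants_from_alignment("ACGGT", "AC--T", "c1")
        assert (v.vtype, v.position, v.ref_allele, v.indel_length) == \
            ("DEL", 3, "GG", 2)

    def test_n_columns_emit_nothing(self):
        assert poly.call_variants_from_alignment("ANGT", "ATGT", "c1") == []
        # a gap run containing N is dropped whole
        assert poly.call_variants_from_alignment("A--T", "ANCT", "c1") == []

    def test_length_mismatch_and_double_gap(self):
        with pytest.raises(poly.AlignmentError, match="length"):
            poly.call_variants_from_alignment("ACG", "AC", "c1")
        with pytest.raises(poly.AlignmentError, match="gap in both"):
            poly.call_variants_from_alignment("A-G", "A-G", "c1")

    def test_ref_offset_shifts_coordinates(self):
        (v,) = poly.call_variants_from_alignment("ACGT", "ACCT", "c1",
                                                 ref_offset=100)
        assert v.position == 103

    def test_simulator_round_trip_small(self):
        config = synth.SimulationConfig(seed=21, n_genes=6)
        genome, genes, _ = synth.simulate_genome(config)
        mutated, aligned, truth = synth.simulate_variant_pair(
            config, genome, genes)
        called = []
        for cid, (ref_aln, qry_aln) in aligned.items():
            called.extend(poly.call_variants_from_alignment(
                ref_aln, qry_aln, contig_id=cid))
        assert called == truth.edit_script
        # applying the script to the reference reconstructs the query
        for cid in genome.records:
            contig_script = [v for v in truth.edit_script
                             if v.contig_id == cid]
            assert poly.apply_variants(genome[cid], contig_script) == \
                mutated[cid]


class TestAnnotateRegions:
    def test_single_gene_arithmetic(self):
        gene = GeneModel("g", "c1", "+", 1101, [(1101, 1200), (1301, 1400)])
        regions = poly.annotate_regions([gene], {"c1": 2000})
        totals = regions.bp_totals()
        assert totals["exon"] == 200
        assert totals["intron"] == 100
        assert totals["promoter"] == 1000  # 101..1100
        assert totals["intergenic"] == 700
        assert totals["gene"] == 300
        assert regions.label_of("c1", 101) == "promoter"
        assert regions.label_of("c1", 1250) == "intron"

    def test_promoter_overlapping_exon_precedence(self):
        up = GeneModel("up", "c1", "+", 100, [(100, 400)])
        down = GeneModel("down", "c1", "+", 600, [(600, 700)])
        regions = poly.annotate_regions([up, down], {"c1": 1000},
                                        promoter_length=500)
        # down's promoter window 100..599 overlaps up's exon 100..400
        assert regions.label_of("c1", 300) == "exon"
        assert regions.label_of("c1", 500) == "promoter"

    def test_tiling_property(self, small_simulation):
        config, genome, genes, _ = small_simulation
        regions = poly.annotate_regions(
            genes, genome.lengths, config.promoter_length)
        totals = regions.bp_totals()
        assert totals["genome"] == sum(genome.lengths.values())
        assert totals["promoter"] + totals["exon"] + totals["intron"] + \
            totals["intergenic"] == totals["genome"]


class TestFrequencies:
    def test_rate_arithmetic(self):
        gene = GeneModel("g", "c1", "+", 1, [(1, 1000)])
        regions = poly.annotate_regions([gene], {"c1": 1000})
        variants = [VariantRecord("c1", 10, "SNP", "A", "T", 0),
                    VariantRecord("c1", 20, "SNP", "C", "G", 0)]
        report = poly.polymorphism_frequencies(variants, regions)
        assert report.rate("exon", "SNP") == pytest.approx(2.0)
        row = report.frame[(report.frame.region == "exon") &
                           (report.frame.vclass == "SNP")]
        assert float(row["one_per_n_bp"].iloc[0]) == pytest.approx(500.0)

    def test_zero_variants_inf_sentinel(self):
        gene = GeneModel("g", "c1", "+", 1, [(1, 100)])
        regions = poly.annotate_regions([gene], {"c1": 100})
        report = poly.polymorphism_frequencies([], regions)
        assert (report.frame["count"] == 0).all()
        assert np.isinf(report.frame["one_per_n_bp"]).all()

    def test_off_contig_variant_skipped(self, caplog):
        gene = GeneModel("g", "c1", "+", 1, [(1, 100)])
        regions = poly.annotate_regions([gene], {"c1": 100})
        with caplog.at_level("WARNING"):
            report = poly.polymorphism_frequencies(
                [VariantRecord("c1", 500, "SNP", "A", "T", 0)], regions)
        assert report.count("genome", "SNP") == 0


class TestIndelClasses:
    @pytest.mark.parametrize("length,expected", [
        (1, "ultra"), (2, "ultra"), (3, "micro"), (10, "micro"),
        (11, "mini"), (50, "mini"), (51, "midi"), (100, "midi"),
    ])
    def test_bin_boundaries(self, length, expected):
        allele = "A" * length
        v = VariantRecord("c", 1, "DEL", allele, "", length)
        frame = poly.indel_length_classes([v])
        row = frame[(frame.polarity == "DEL") & (frame["count"] == 1)]
        assert list(row["length_class"]) == [expected]

    def test_over_100_excluded_from_shares(self):
        vs = [VariantRecord("c", 1, "INS", "", "A" * 2, 2),
              VariantRecord("c", 5, "INS", "", "A" * 150, 150)]
        frame = poly.indel_length_classes(vs)
        ins = frame[frame.polarity == "INS"]
        assert float(ins[ins.length_class == "ultra"]["share_pct"].iloc[0]) == 100.0
        assert int(ins[ins.length_class == "over_100"]["count"].iloc[0]) == 1

    def test_random_vector_matches_hand_histogram(self):
        rng = np.random.default_rng(13)
        lengths = rng.integers(1, 101, size=500)
        vs = [VariantRecord("c", i + 1, "DEL", "A" * int(x), "", int(x))
              for i, x in enumerate(lengths)]
        frame = poly.indel_length_classes(vs)
        dele = frame[(frame.polarity == "DEL") &
                     (frame.length_class != "over_100")]
        bins = {"ultra": (1, 2), "micro": (3, 10),
                "mini": (11, 50), "midi": (51, 100)}
        for _, row in dele.iterrows():
            lo, hi = bins[row["length_class"]]
            want = int(((lengths >= lo) & (lengths <= hi)).sum())
            assert row["count"] == want
        assert dele["share_pct"].sum() == pytest.approx(100.0, abs=0.2)

    def test_non_indel_rejected(self):
        with pytest.raises(ValueError, match="non-INDEL"):
            poly.indel_length_classes(
                [VariantRecord("c", 1, "SNP", "A", "T", 0)])


class TestCompareRates:
    def test_identical_arms(self):
        t, p = poly.compare_region_rates([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_equal_arms(self):
        assert poly.compare_region_rates([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_welch_closed_form_toy_table(self):
        """Matches the textbook Welch formula on a fixed 5+5 table."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_expected = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p_expected = 2 * sps.t.sf(abs(t_expected), df)
        t, p = poly.compare_region_rates(a, b)
        assert t == pytest.approx(t_expected)
        assert p == pytest.approx(p_expected)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            poly.compare_region_rates([1.0], [1.0, 2.0])
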