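"""Occurrence statistics: shares, means, null probabilities, density."""

import numpy as np
import pytest

from cregulon import cre_stats as cs
from cregulon.motif_scan import BUILTIN_MOTIFS, scan_all
from cregulon.promoters import Promoter

from conftest import enumerate_hits, random_promoter


def prom(seq, gene_id="g1", complete=True):
    return Promoter(gene_id=gene_id, sequence=seq, length=len(seq),
                    complete=complete)


class TestRelativeContent:
    def test_reference_occurrence_counts(self):
        got = cs.relative_content({"ABRE": 1294, "DRE": 4118, "ERE": 449})
        assert got == {"ABRE": 22.1, "DRE": 70.3, "ERE": 7.7}

    def test_single_element_degeneracy(self):
        got = cs.relative_content({"ABRE": 5, "DRE": 0, "ERE": 0})
        assert got == {"ABRE": 100.0, "DRE": 0.0, "ERE": 0.0}

    def test_random_counts_sum_to_100(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = {f"m{i}": int(rng.integers(0, 1000)) for i in range(4)}
            if sum(counts.values()) == 0:
                continue
            got = cs.relative_content(counts)
            # each value is rounded to 1 decimal: worst-case drift 0.05/motif
            assert abs(sum(got.values()) - 100.0) <= 0.05 * len(counts)
            total = sum(counts.values())
            for m, c in counts.items():
                assert got[m] == round(100.0 * c / total, 1)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cs.relative_content({"ABRE": 0})


class TestMeanPerPositive:
    def test_reference_pairs(self):
        got = cs.mean_per_positive(
            {"ABRE": 1294, "DRE": 4118, "ERE": 449},
            {"ABRE": 1158, "DRE": 3500, "ERE": 438})
        assert got == {"ABRE": 1.1174, "DRE": 1.1766, "ERE": 1.0251}

    def test_lower_bound_attained(self):
        assert cs.mean_per_positive({"m": 7}, {"m": 7}) == {"m": 1.0}

    def test_zero_carriers_omitted(self):
        assert cs.mean_per_positive({"m": 0}, {"m": 0}) == {}


class TestElementProbability:
    UNIFORM = {b: 0.25 for b in "ACGT"}

    def test_closed_forms_at_uniform_composition(self):
        p_abre = cs.element_probability(
            [], BUILTIN_MOTIFS["ABRE"], frequencies=self.UNIFORM)
        assert p_abre == pytest.approx(0.25 ** 7)
        p_dre = cs.element_probability(
            [], BUILTIN_MOTIFS["DRE"], frequencies=self.UNIFORM)
        assert p_dre == pytest.approx(2 * 0.25 ** 6)

    def test_matches_empirical_window_rate(self):
        """p_e agrees with the observed per-window match rate at 36.6% GC."""
        rng = np.random.default_rng(6)
        promoters = [prom(random_promoter(rng, 500), f"g{i}")
                     for i in range(2000)]
        motif = BUILTIN_MOTIFS["DRE"]
        p = cs.element_probability(promoters, motif)
        windows = sum(pr.length - motif.length + 1 for pr in promoters)
        observed = sum(
            len(enumerate_hits(pr.sequence, motif.iupac_pattern))
            for pr in promoters)
        se = np.sqrt(windows * p * (1 - p))
        assert abs(observed - windows * p) <= 3 * se

    def test_n_bases_excluded(self):
        freqs = cs.nucleotide_frequencies([prom("AANN")])
        assert freqs == {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}


class TestRarity:
    def test_reference_quotient(self):
        assert cs.rarity_factor({"ABRE": 1158}, 20745) == {"ABRE": 0.0558}

    def test_bounds(self):
        assert cs.rarity_factor({"m": 10}, 10) == {"m": 1.0}
        assert cs.rarity_factor({"m": 0}, 10) == {"m": 0.0}
        with pytest.raises(ValueError):
            cs.rarity_factor({"m": 11}, 10)


class TestEnrichment:
    def test_invalid_strand_factor(self):
        with pytest.raises(ValueError):
            cs.enrichment_factor(
                scan_all([prom("ACGT")]), [prom("ACGT")],
                BUILTIN_MOTIFS["ABRE"], strand_factor=3)

    def test_gene_and_occurrence_variants_agree_when_rare(self):
        """In the rare-element limit (p*L << 1) both conventions coincide."""
        rng = np.random.default_rng(9)
        promoters = [prom(random_promoter(rng, 1000), f"g{i}")
                     for i in range(2000)]
        table = scan_all(promoters, [BUILTIN_MOTIFS["ABRE"]])
        res = cs.enrichment_factor(table, promoters, BUILTIN_MOTIFS["ABRE"])
        # expected counts under the two conventions differ only at O(pL)
        assert res.expected_occurrences == pytest.approx(
            res.expected_positive_promoters, rel=0.05)


class TestDensityProfile:
    def test_boundary_bins(self):
        # ABRE ending adjacent to the ATG -> distance 1 -> bin 1;
        # ABRE at offset 1 -> distance 994 -> bin 20
        near = prom("T" * 993 + "ACGTGTC", "near")
        far = prom("ACGTGTC" + "T" * 993, "far")
        table = scan_all([near, far], [BUILTIN_MOTIFS["ABRE"]])
        profiles = cs.density_profile(table, [BUILTIN_MOTIFS["ABRE"]])
        assert profiles["ABRE"].bins == {1: 1, 20: 1}

    def test_five_prime_anchor_mode(self):
        far = prom("ACGTGTC" + "T" * 993, "far")
        table = scan_all([far], [BUILTIN_MOTIFS["ABRE"]])
        profiles = cs.density_profile(
            table, [BUILTIN_MOTIFS["ABRE"]], anchor="5prime")
        assert profiles["ABRE"].bins == {20: 1}  # distance 1000

    def test_bins_sum_to_complete_promoter_occurrences(self):
        rng = np.random.default_rng(12)
        promoters = [prom(random_promoter(rng, 1000), f"g{i}")
                     for i in range(300)]
        promoters.append(Promoter("trunc", random_promoter(rng, 400), 400, False))
        table = scan_all(promoters)
        profiles = cs.density_profile(table)
        for name, profile in profiles.items():
            expected = sum(
                1 for h in table.hits
                if h.motif == name and table.promoters[h.gene_id].complete)
            assert profile.total() == expected


def test_stats_report_invariant_under_promoter_order():
    rng = np.random.default_rng(3)
    promoters = [prom(random_promoter(rng, 800), f"g{i}") for i in range(200)]
    a = cs.stats_report(scan_all(promoters), promoters)
    shuffled = list(promoters)
    rng.shuffle(shuffled)
    b = cs.stats_report(scan_all(shuffled), shuffled)
    a = a.sort_values("motif").reset_index(drop=True)
    b = b.sort_values("motif").reset_index(drop=True)
    assert a.equals(b)
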