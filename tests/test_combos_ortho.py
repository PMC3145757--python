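"""Combination classification and ortholog-group Venn partitions."""

from itertools import combinations

import numpy as np
import pytest

from cregulon import combos_ortho as co
from cregulon.io_formats import OrthologGroupTable

MOTIFS = ("ABRE", "DRE", "ERE")


def profile(sets, species=None):
    return co.CREPresenceProfile(
        genes={f"g{i}": frozenset(s) for i, s in enumerate(sets)},
        species=species, motif_universe=frozenset(MOTIFS))


class TestCombinationCounts:
    def test_hand_enumeration(self):
        counts = co.combination_counts(profile([
            {"ABRE"}, {"ABRE", "DRE"}, {"ABRE", "DRE", "ERE"}]))
        ad = frozenset({"ABRE", "DRE"})
        assert counts.inclusive[ad] == 2
        assert counts.exclusive[ad] == 1
        assert counts.inclusive[frozenset({"ABRE"})] == 3

    def test_all_empty(self):
        counts = co.combination_counts(profile([set(), set()]))
        assert all(v == 0 for v in counts.inclusive.values())
        assert counts.n_nonempty == 0

    def test_random_sets_against_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sets = [set(np.array(MOTIFS)[rng.random(3) < 0.5])
                    for _ in range(50)]
            counts = co.combination_counts(profile(sets))
            for k in (1, 2, 3):
                for combo in combinations(MOTIFS, k):
                    want_inc = sum(1 for s in sets if set(combo) <= s)
                    want_exc = sum(1 for s in sets if set(combo) == s)
                    assert counts.inclusive[frozenset(combo)] == want_inc
                    assert counts.exclusive[frozenset(combo)] == want_exc
            assert sum(counts.exclusive.values()) == counts.n_nonempty

    def test_unknown_motif_rejected(self):
        with pytest.raises(ValueError, match="unknown motif"):
            co.combination_counts(profile([{"ABRE"}]), motifs=("XRE",))


class TestGroupPresence:
    def _setup(self):
        groups = OrthologGroupTable({
            "og1": {"A": ["a1", "a2"], "B": ["b1"]},
        })
        profiles = {
            "A": co.CREPresenceProfile(
                genes={"a1": frozenset({"ABRE"}), "a2": frozenset()},
                species="A"),
            "B": co.CREPresenceProfile(
                genes={"b1": frozenset({"ABRE", "DRE"})}, species="B"),
        }
        return groups, profiles

    def test_any_vs_all_gene_rule(self):
        groups, profiles = self._setup()
        assert co.group_presence(profiles, groups, "ABRE")["A"] == {"og1"}
        assert co.group_presence(
            profiles, groups, "ABRE", rule="all_genes")["A"] == set()

    def test_combination_must_be_in_one_promoter(self):
        # ABRE and DRE split across paralogs does not count
        groups = OrthologGroupTable({"og1": {"A": ["a1", "a2"]},
                                     "og2": {"A": ["a3"]}})
        profiles = {"A": co.CREPresenceProfile(genes={
            "a1": frozenset({"ABRE"}), "a2": frozenset({"DRE"}),
            "a3": frozenset({"ABRE", "DRE"})}, species="A")}
        presence = co.group_presence(profiles, groups, ["ABRE", "DRE"])
        assert presence["A"] == {"og2"}

    def test_any_gene_superset_of_all_genes(self):
        rng = np.random.default_rng(5)
        groups = OrthologGroupTable({
            f"og{i}": {"A": [f"a{i}_0", f"a{i}_1"], "B": [f"b{i}"]}
            for i in range(30)})
        genes_a = {g: frozenset(np.array(MOTIFS)[rng.random(3) < 0.4])
                   for i in range(30) for g in (f"a{i}_0", f"a{i}_1")}
        genes_b = {f"b{i}": frozenset(np.array(MOTIFS)[rng.random(3) < 0.4])
                   for i in range(30)}
        profiles = {"A": co.CREPresenceProfile(genes=genes_a, species="A"),
                    "B": co.CREPresenceProfile(genes=genes_b, species="B")}
        for motif in MOTIFS:
            any_p = co.group_presence(profiles, groups, motif, rule="any_gene")
            all_p = co.group_presence(profiles, groups, motif, rule="all_genes")
            for sp in profiles:
                assert all_p[sp] <= any_p[sp]

    def test_missing_species_rejected(self):
        groups, profiles = self._setup()
        profiles["C"] = co.CREPresenceProfile(genes={}, species="C")
        with pytest.raises(ValueError, match="missing"):
            co.group_presence(profiles, groups, "ABRE")


class TestVennPartition:
    def test_identical_sets_all_common(self):
        presence = {"A": {"g1", "g2"}, "B": {"g1", "g2"}}
        part = co.venn_partition(presence, {"g1", "g2", "g3"})
        assert part.subset_counts == {frozenset({"A", "B"}): 2}
        assert part.common == 2

    def test_disjoint_sets_zero_common(self):
        part = co.venn_partition({"A": {"g1"}, "B": {"g2"}}, {"g1", "g2"})
        assert part.common == 0
        assert part.present_anywhere() == 2

    def test_five_species_random_sets_against_brute_force(self):
        rng = np.random.default_rng(8)
        species = [f"sp{i}" for i in range(5)]
        universe = {f"og{i}" for i in range(200)}
        presence = {
            sp: {g for g in universe if rng.random() < 0.4} for sp in species}
        part = co.venn_partition(presence, universe)
        # brute-force per-group classification
        want: dict[frozenset, int] = {}
        for g in universe:
            sig = frozenset(sp for sp in species if g in presence[sp])
            if sig:
                want[sig] = want.get(sig, 0) + 1
        assert part.subset_counts == want
        union = set().union(*presence.values())
        assert part.present_anywhere() == len(union)
        assert part.common == want.get(frozenset(species), 0)

    def test_presence_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            co.venn_partition({"A": {"gX"}}, {"g1"})
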