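"""CRE-combination classification and cross-species ortholog comparison.

A promoter's *presence set* is the set of elements with at least one
occurrence. Combination counts come in two flavours: *inclusive* (a
promoter carrying all three elements counts toward every pair and the
triple) and *exclusive* (the partition of promoters by exact presence
set). Ortholog groups are compared across species by whether any (or
every) member gene's promoter carries a target element or combination,
and the resulting per-species presence sets are partitioned Venn-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import OrthologGroupTable
from .motif_scan import MotifHitTable

ANY_GENE = "any_gene"
ALL_GENES = "all_genes"


@dataclass
class CREPresenceProfile:
    """gene_id -> set of motif names with >=1 occurrence in its promoter."""

    genes: dict[str, frozenset[str]]
    species: str | None = None
    motif_universe: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_hit_table(cls, table: MotifHitTable,
                       species: str | None = None) -> "CREPresenceProfile":
        return cls(
            genes=table.presence_sets(),
            species=species,
            motif_universe=frozenset(table.counts.columns),
        )

    def carriers(self, target: Iterable[str]) -> set[str]:
        """Genes whose promoter carries every element of the target combo."""
        t = frozenset(target)
        return {g for g, present in self.genes.items() if t <= present}


def combo_label(combo: Iterable[str],
                order: Sequence[str] = ("ABRE", "DRE", "ERE")) -> str:
    c = set(combo)
    ordered = [m for m in order if m in c] + sorted(c - set(order))
    return "+".join(ordered)


def all_combos(motifs: Sequence[str]) -> list[frozenset[str]]:
    """Every non-empty subset, singletons first, then by size."""
    out = []
    for k in range(1, len(motifs) + 1):
        out.extend(frozenset(c) for c in combinations(motifs, k))
    return out


@dataclass
class CombinationCounts:
    inclusive: dict[frozenset[str], int]
    exclusive: dict[frozenset[str], int]
    n_genes: int
    n_nonempty: int


def combination_counts(
    profile: CREPresenceProfile,
    motifs: Sequence[str] = ("ABRE", "DRE", "ERE"),
) -> CombinationCounts:
    """Inclusive and exclusive counts over every non-empty combination."""
    unknown = set(motifs) - set(profile.motif_universe or motifs)
    if profile.motif_universe and unknown:
        raise ValueError(f"unknown motif names: {sorted(unknown)}")
    combos = all_combos(list(motifs))
    inclusive = {c: 0 for c in combos}
    exclusive = {c: 0 for c in combos}
    n_nonempty = 0
    for present in profile.genes.values():
        present = present & set(motifs)
        if present:
            n_nonempty += 1
        for c in combos:
            if c <= present:
                inclusive[c] += 1
            if c == present:
                exclusive[c] += 1
    return CombinationCounts(
        inclusive=inclusive, exclusive=exclusive,
        n_genes=len(profile.genes), n_nonempty=n_nonempty)


def combination_frame(counts: CombinationCounts) -> pd.DataFrame:
    rows = []
    for combo in sorted(counts.inclusive, key=lambda c: (len(c), combo_label(c))):
        rows.append({
            "combination": combo_label(combo),
            "inclusive_count": counts.inclusive[combo],
            "exclusive_count": counts.exclusive[combo],
        })
    return pd.DataFrame(rows, columns=["combination", "inclusive_count",
                                       "exclusive_count"])


# ---------------------------------------------------------------------------
# Ortholog-group presence and Venn partition
# ---------------------------------------------------------------------------

def group_presence(
    profiles: Mapping[str, CREPresenceProfile],
    groups: OrthologGroupTable,
    target: str | Iterable[str],
    rule: str = ANY_GENE,
) -> dict[str, set[str]]:
    """Per-species sets of ortholog groups carrying the target.

    Only groups complete for the profiled species set are considered,
    and member genes are restricted to those present in the species
    profile (i.e. genes with analyzed, complete promoters). Under
    ``any_gene`` a group is present in a species if at least one of its
    genes there carries every element of the target in one promoter;
    under ``all_genes`` every (profiled) member gene must.
    """
    if rule not in (ANY_GENE, ALL_GENES):
        raise ValueError(f"rule must be any_gene or all_genes, got {rule!r}")
    t = frozenset([target]) if isinstance(target, str) else frozenset(target)
    species_set = set(profiles)
    missing = species_set - groups.species()
    if missing:
        raise ValueError(f"species missing from group table: {sorted(missing)}")
    universe = groups.complete_groups(species_set)
    presence: dict[str, set[str]] = {sp: set() for sp in profiles}
    for gid in universe:
        members = groups.groups[gid]
        for sp, profile in profiles.items():
            genes = [g for g in members.get(sp, []) if g in profile.genes]
            if not genes:
                continue
            carries = [t <= profile.genes[g] for g in genes]
            if (rule == ANY_GENE and any(carries)) or \
                    (rule == ALL_GENES and all(carries)):
                presence[sp].add(gid)
    return presence


@dataclass
class VennPartition:
    """Counts of groups by the exact subset of species where they are present."""

    universe: set[str]
    subset_counts: dict[frozenset[str], int]
    common: int
    species: frozenset[str]

    def present_anywhere(self) -> int:
        return sum(self.subset_counts.values())


def venn_partition(
    presence: Mapping[str, set[str]],
    universe: Iterable[str],
) -> VennPartition:
    """Partition the universe of groups by their exact species presence set."""
    uni = set(universe)
    species = frozenset(presence)
    for sp, ids in presence.items():
        extra = ids - uni
        if extra:
            raise ValueError(
                f"species {sp}: presence ids outside universe: {sorted(extra)[:5]}")
    counts: dict[frozenset[str], int] = {}
    common = 0
    for gid in uni:
        signature = frozenset(sp for sp, ids in presence.items() if gid in ids)
        if not signature:
            continue
        counts[signature] = counts.get(signature, 0) + 1
        if signature == species:
            common += 1
    return VennPartition(
        universe=uni, subset_counts=counts, common=common, species=species)


def venn_frame(partition: VennPartition) -> pd.DataFrame:
    rows = []
    for sig in sorted(partition.subset_counts,
                      key=lambda s: (len(s), ",".join(sorted(s)))):
        rows.append({
            "subset": ",".join(sorted(sig)),
            "n_species": len(sig),
            "count": partition.subset_counts[sig],
        })
    return pd.DataFrame(rows, columns=["subset", "n_species", "count"])
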