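"""Occurrence statistics over a motif-hit table.

For each element e with O_e total occurrences in G_e distinct promoters
out of T analyzed genes:

* relative content  = 100 * O_e / sum_f O_f      (percent of all CRE hits)
* mean per positive = O_e / G_e                  (mean copies per carrier)
* rarity factor     = G_e / T                    (carrier fraction of genes)
* element probability p_e: per-position, per-strand chance of the motif
  under an i.i.d. nucleotide-frequency null estimated from the promoter
  set itself (N bases excluded from the frequency estimate)
* enrichment factor = O_e / E_e with E_e = sum over promoters of
  (len - N + 1) * p_e * strand_factor; a gene-level variant divides G_e
  by the expected number of promoters with >=1 hit under a binomial
  approximation
* positional density: hits binned by distance to the ATG in 50-bp bins,
  over complete promoters only.

Percentages are reported to 1 decimal and per-carrier means to 4
decimals, matching the conventional display of such tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .motif_scan import MotifDefinition, MotifHitTable, builtin_motifs
from .promoters import Promoter


def relative_content(occurrences: Mapping[str, int]) -> dict[str, float]:
    """Percent share of each element among all counted occurrences.

    Input may be a MotifHitTable's occurrence totals or any mapping
    motif -> count. Values are rounded to 1 decimal.
    """
    total = sum(occurrences.values())
    if total <= 0:
        raise ValueError("relative content undefined: no occurrences at all")
    return {m: round(100.0 * o / total, 1) for m, o in occurrences.items()}


def mean_per_positive(
    occurrences: Mapping[str, int], carriers: Mapping[str, int]
) -> dict[str, float]:
    """Mean occurrences per promoter that has at least one (O_e/G_e).

    Motifs with zero carrier promoters are omitted.
    """
    out: dict[str, float] = {}
    for m, o in occurrences.items():
        g = carriers.get(m, 0)
        if g == 0:
            continue
        out[m] = round(o / g, 4)
    return out


def nucleotide_frequencies(promoters: Sequence[Promoter]) -> dict[str, float]:
    """Base composition over all promoter bases; N excluded entirely."""
    if not promoters:
        raise ValueError("empty promoter set")
    counts: Counter[str] = Counter()
    for p in promoters:
        counts.update(p.sequence)
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("promoter set contains no unambiguous bases")
    return {b: counts[b] / total for b in "ACGT"}


def element_probability(
    promoters: Sequence[Promoter], motif: MotifDefinition,
    frequencies: Mapping[str, float] | None = None,
) -> float:
    """Per-position, per-strand match probability under the i.i.d. null.

    Equals the sum over the expansion words of the product of base
    frequencies, computed position-wise via the IUPAC degeneracy.
    """
    from .motif_scan import _IUPAC

    f = dict(frequencies) if frequencies is not None \
        else nucleotide_frequencies(promoters)
    p = 1.0
    for c in motif.iupac_pattern:
        p *= sum(f[b] for b in _IUPAC[c])
    return p


def scannable_positions(promoters: Sequence[Promoter], motif_length: int) -> int:
    """Total number of window start positions per strand."""
    return sum(max(p.length - motif_length + 1, 0) for p in promoters)


@dataclass
class EnrichmentResult:
    motif: str
    probability: float
    expected_occurrences: float
    observed_occurrences: int
    occurrence_enrichment: float
    expected_positive_promoters: float
    observed_positive_promoters: int
    gene_enrichment: float
    strand_factor: int


def enrichment_factor(
    table: MotifHitTable,
    promoters: Sequence[Promoter],
    motif: MotifDefinition,
    probability: float | None = None,
    strand_factor: int = 1,
) -> EnrichmentResult:
    """Observed-over-expected occurrence ratio under the nucleotide null.

    The occurrence-level ratio O_e/E_e is the primary figure; the
    gene-level variant (carriers over binomially-expected carriers) is
    also reported. ``strand_factor=2`` doubles the scanned positions for
    a double-strand null.
    """
    if strand_factor not in (1, 2):
        raise ValueError("strand_factor must be 1 or 2")
    p = probability if probability is not None \
        else element_probability(promoters, motif)
    expected = 0.0
    expected_pos = 0.0
    for prom in promoters:
        n_win = max(prom.length - motif.length + 1, 0) * strand_factor
        expected += n_win * p
        expected_pos += 1.0 - (1.0 - p) ** n_win
    if expected == 0.0:
        raise ValueError(f"motif {motif.name}: zero expected occurrences")
    observed = table.total_occurrences(motif.name)
    carriers = table.promoters_with(motif.name)
    return EnrichmentResult(
        motif=motif.name,
        probability=p,
        expected_occurrences=expected,
        observed_occurrences=observed,
        occurrence_enrichment=observed / expected,
        expected_positive_promoters=expected_pos,
        observed_positive_promoters=carriers,
        gene_enrichment=carriers / expected_pos if expected_pos > 0 else float("nan"),
        strand_factor=strand_factor,
    )


def rarity_factor(carriers: Mapping[str, int], total_genes: int) -> dict[str, float]:
    """Carrier promoters as a fraction of all analyzed genes."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    out = {}
    for m, g in carriers.items():
        if g > total_genes:
            raise ValueError(f"motif {m}: carriers {g} exceed total genes {total_genes}")
        out[m] = round(g / total_genes, 4)
    return out


# ---------------------------------------------------------------------------
# Positional density
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Hit counts binned by distance to the ATG: bin k covers
    ((k-1)*bin_width, k*bin_width] bp from the start codon."""

    motif: str
    bin_width: int
    bins: dict[int, int] = field(default_factory=dict)
    anchor: str = "3prime"
    ragged_last_bin: bool = False

    def total(self) -> int:
        return sum(self.bins.values())


def density_profile(
    table: MotifHitTable,
    motifs: Sequence[MotifDefinition] | None = None,
    bin_width: int = 50,
    anchor: str = "3prime",
    promoter_length: int = 1000,
) -> dict[str, DensityProfile]:
    """Per-motif positional density over complete promoters.

    The distance of a hit to the ATG is measured from the motif's 3' end
    by default (``anchor="3prime"``: a motif ending on the last promoter
    base has distance 1); ``anchor="5prime"`` measures from the window's
    first base instead.
    """
    if anchor not in ("3prime", "5prime"):
        raise ValueError("anchor must be '3prime' or '5prime'")
    if motifs is None:
        motifs = builtin_motifs()
    lengths = {m.name: m.length for m in motifs}
    ragged = promoter_length % bin_width != 0
    profiles = {
        m.name: DensityProfile(m.name, bin_width, {}, anchor, ragged)
        for m in motifs
    }
    for hit in table.hits:
        prom = table.promoters[hit.gene_id]
        if not prom.complete or hit.motif not in lengths:
            continue
        n = lengths[hit.motif]
        if anchor == "3prime":
            dist = prom.length - hit.offset - n + 2
        else:
            dist = prom.length - hit.offset + 1
        k = (dist + bin_width - 1) // bin_width
        bins = profiles[hit.motif].bins
        bins[k] = bins.get(k, 0) + 1
    return profiles


def density_frame(profiles: Mapping[str, DensityProfile]) -> pd.DataFrame:
    rows = []
    for name, prof in profiles.items():
        for k in sorted(prof.bins):
            rows.append({
                "motif": name,
                "bin_start": (k - 1) * prof.bin_width + 1,
                "bin_end": k * prof.bin_width,
                "count": prof.bins[k],
            })
    return pd.DataFrame(rows, columns=["motif", "bin_start", "bin_end", "count"])


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def stats_report(
    table: MotifHitTable,
    promoters: Sequence[Promoter],
    motifs: Sequence[MotifDefinition] | None = None,
    total_genes: int | None = None,
    strand_factor: int = 1,
) -> pd.DataFrame:
    """One row per motif with every occurrence statistic."""
    if motifs is None:
        motifs = builtin_motifs()
    occ = {m.name: table.total_occurrences(m.name) for m in motifs}
    car = {m.name: table.promoters_with(m.name) for m in motifs}
    T = total_genes if total_genes is not None else len(promoters)
    rel = relative_content(occ)
    mean = mean_per_positive(occ, car)
    rare = rarity_factor(car, T)
    rows = []
    for m in motifs:
        enr = enrichment_factor(table, promoters, m, strand_factor=strand_factor)
        rows.append({
            "motif": m.name,
            "occurrences": occ[m.name],
            "promoters_with_element": car[m.name],
            "relative_content_pct": rel[m.name],
            "mean_per_positive": mean.get(m.name, float("nan")),
            "rarity_factor": rare[m.name],
            "probability": enr.probability,
            "expected_occurrences": enr.expected_occurrences,
            "occurrence_enrichment": enr.occurrence_enrichment,
            "gene_enrichment": enr.gene_enrichment,
            "total_genes": T,
        })
    return pd.DataFrame(rows)
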