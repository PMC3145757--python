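"""Exact scanning of IUPAC-degenerate elements in promoter sets.

A motif is a short literal pattern over the IUPAC nucleotide alphabet
(e.g. the dehydration-responsive element RCCGAC, where R = A or G).
Matching is exact over the expansion set: no mismatches, no position
weight matrices. Overlapping occurrences are all reported, and windows
containing N never match.

The three built-in elements:

=====  ========  =======================================
name   pattern   meaning
=====  ========  =======================================
ABRE   ACGTGTC   abscisic-acid-responsive element
DRE    RCCGAC    dehydration-responsive element (CRT)
ERE    AGCCGCC   ethylene-responsive element (GCC-box)
=====  ========  =======================================
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .promoters import Promoter, reverse_complement

# Pattern N expands to {A,C,G,T}; an unknown residue (N) on the sequence
# side is never a member of any expansion, so windows containing N never
# match regardless of the pattern.
_IUPAC = {c: "".join(sorted(v)) for c, v in ambiguous_dna_values.items()
          if c != "X"}

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    iupac_pattern: str
    length: int
    expansion: frozenset[str]

    def degeneracy(self) -> int:
        return len(self.expansion)


def compile_motif(name: str, iupac_pattern: str) -> MotifDefinition:
    """Compile an IUPAC pattern, enumerating its concrete-word expansion."""
    pattern = iupac_pattern.upper()
    if not pattern:
        raise ValueError("empty motif pattern")
    for i, c in enumerate(pattern):
        if c not in _IUPAC:
            raise ValueError(
                f"motif {name!r}: invalid IUPAC code {c!r} at position {i + 1}")
    words = frozenset(
        "".join(w) for w in itertools.product(*(_IUPAC[c] for c in pattern)))
    return MotifDefinition(
        name=name, iupac_pattern=pattern, length=len(pattern), expansion=words)


BUILTIN_MOTIFS: dict[str, MotifDefinition] = {
    "ABRE": compile_motif("ABRE", "ACGTGTC"),
    "DRE": compile_motif("DRE", "RCCGAC"),
    "ERE": compile_motif("ERE", "AGCCGCC"),
}


def builtin_motifs() -> list[MotifDefinition]:
    return list(BUILTIN_MOTIFS.values())


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; offset is the 1-based position of the window's
    first base on the promoter's sense coordinate system."""

    gene_id: str
    motif: str
    offset: int
    strand: str = SENSE


def _regex(motif: MotifDefinition) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all found
    body = "".join(
        c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]"
        for c in motif.iupac_pattern)
    return re.compile(f"(?=({body}))")


def scan_promoter(
    promoter: Promoter,
    motifs: Sequence[MotifDefinition],
    strands: str = SENSE,
) -> list[MotifHit]:
    """All occurrences of each motif in one promoter.

    With ``strands="both"`` the reverse complement is also scanned and
    antisense hits are reported at the sense offset of the window's
    first base.
    """
    if strands not in (SENSE, "both"):
        raise ValueError(f"strands must be 'sense' or 'both', got {strands!r}")
    seq = promoter.sequence
    L = len(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        if L < motif.length:
            continue
        rx = _regex(motif)
        for m in rx.finditer(seq):
            hits.append(MotifHit(promoter.gene_id, motif.name, m.start() + 1))
        if strands == "both":
            rc = reverse_complement(seq)
            for m in rx.finditer(rc):
                offset = L - m.start() - motif.length + 1
                hits.append(MotifHit(
                    promoter.gene_id, motif.name, offset, ANTISENSE))
    hits.sort(key=lambda h: (h.motif, h.offset, h.strand))
    return hits


@dataclass
class MotifHitTable:
    """All occurrences across a promoter set plus per-gene count marginals."""

    hits: list[MotifHit]
    counts: pd.DataFrame  # index gene_id, columns motif names, int counts
    promoters: dict[str, Promoter] = field(default_factory=dict)
    strands: str = SENSE

    def total_occurrences(self, motif: str) -> int:
        return int(self.counts[motif].sum())

    def promoters_with(self, motif: str) -> int:
        """Number of promoters with at least one occurrence of the motif."""
        return int((self.counts[motif] > 0).sum())

    def occurrence_totals(self) -> dict[str, int]:
        return {m: self.total_occurrences(m) for m in self.counts.columns}

    def presence_sets(self) -> dict[str, frozenset[str]]:
        """gene_id -> set of motif names present in its promoter."""
        return {
            gene: frozenset(
                m for m in self.counts.columns if self.counts.at[gene, m] > 0)
            for gene in self.counts.index
        }

    def validate(self) -> None:
        tally: dict[tuple[str, str], int] = {}
        for h in self.hits:
            tally[h.gene_id, h.motif] = tally.get((h.gene_id, h.motif), 0) + 1
        for gene in self.counts.index:
            for m in self.counts.columns:
                if self.counts.at[gene, m] != tally.get((gene, m), 0):
                    raise ValueError(
                        f"count matrix disagrees with hit list at ({gene},{m})")


def scan_all(
    promoters: Sequence[Promoter],
    motifs: Sequence[MotifDefinition] | None = None,
    strands: str = SENSE,
) -> MotifHitTable:
    """Scan a promoter set; result carries hits and count-matrix marginals."""
    if motifs is None:
        motifs = builtin_motifs()
    ids = [p.gene_id for p in promoters]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate promoter ids: {dup[:5]}")
    all_hits: list[MotifHit] = []
    names = [m.name for m in motifs]
    rows = []
    for p in promoters:
        hits = scan_promoter(p, motifs, strands)
        all_hits.extend(hits)
        row = {n: 0 for n in names}
        for h in hits:
            row[h.motif] += 1
        rows.append(row)
    counts = pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"),
                          columns=names, dtype=int)
    return MotifHitTable(
        hits=all_hits, counts=counts,
        promoters={p.gene_id: p for p in promoters}, strands=strands)


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def hits_frame(table: MotifHitTable, motif_lengths: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Hit list as a DataFrame with distance of the window's 3' end to the ATG."""
    if motif_lengths is None:
        motif_lengths = {m.name: m.length for m in builtin_motifs()}
    rows = []
    for h in table.hits:
        L = table.promoters[h.gene_id].length
        n = motif_lengths.get(h.motif)
        dist = L - h.offset - n + 2 if n is not None else None
        rows.append({
            "gene_id": h.gene_id, "motif": h.motif, "offset": h.offset,
            "strand": h.strand, "distance_to_atg": dist,
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "motif", "offset", "strand", "distance_to_atg"])


def write_hits(table: MotifHitTable, path: str | Path,
               metadata: Mapping[str, object] | None = None) -> None:
    from .io_formats import write_report
    write_report(hits_frame(table), path, metadata)


def write_counts(table: MotifHitTable, path: str | Path,
                 metadata: Mapping[str, object] | None = None) -> None:
    from .io_formats import write_report
    write_report(table.counts.reset_index(), path, metadata)
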