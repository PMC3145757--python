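"""Promoter extraction: the window immediately 5' of each gene's ATG.

The promoter is defined relative to the translation start (the 'A' of
the ATG), not a transcription start site: the sequence returned is the
``promoter_length`` bases upstream of the start codon, oriented 5'->3'
toward the ATG. For a '-'-strand gene this is the reverse complement of
the genomic slice downstream of ``cds_start``. Promoters truncated by a
contig edge are retained and flagged ``complete=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from .io_formats import FormatError, GeneModel, GenomeSequences

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_LENGTH = 1000


@dataclass
class Promoter:
    """A strand-oriented upstream sequence ending at the base before the ATG."""

    gene_id: str
    sequence: str
    length: int
    complete: bool
    species: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError(
                f"promoter {self.gene_id}: sequence length {len(self.sequence)}"
                f" != declared length {self.length}"
            )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_promoters(
    genome: GenomeSequences,
    genes: Iterable[GeneModel],
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    include_truncated: bool = True,
) -> list[Promoter]:
    """Extract the upstream window of every gene.

    '+' gene with translation start at s: genomic slice [s-L, s-1].
    '-' gene: genomic slice [s+1, s+L], reverse-complemented.
    Slices are truncated at contig edges; a gene whose ATG sits at the
    contig edge (no upstream base at all) is excluded with a warning, as
    is a gene on a missing contig.
    """
    if promoter_length < 1:
        raise ValueError("promoter_length must be >= 1")
    out: list[Promoter] = []
    for gene in genes:
        if gene.contig_id not in genome:
            logger.warning(
                "gene %s: contig %s missing from genome; skipped",
                gene.gene_id, gene.contig_id)
            continue
        contig = genome[gene.contig_id]
        s = gene.cds_start
        if not 1 <= s <= len(contig):
            logger.warning(
                "gene %s: cds_start %d outside contig bounds; skipped",
                gene.gene_id, s)
            continue
        if gene.strand == "+":
            start = max(1, s - promoter_length)
            seq = contig[start - 1: s - 1]
        else:
            end = min(len(contig), s + promoter_length)
            seq = reverse_complement(contig[s: end])
        if not seq:
            logger.warning(
                "gene %s: no upstream sequence at contig edge; excluded",
                gene.gene_id)
            continue
        out.append(Promoter(
            gene_id=gene.gene_id,
            sequence=seq,
            length=len(seq),
            complete=len(seq) == promoter_length,
            species=gene.species,
        ))
    return out


def promoter_interval(
    gene: GeneModel, contig_length: int,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
) -> tuple[int, int] | None:
    """Genomic 1-based inclusive interval of the promoter window, or None."""
    s = gene.cds_start
    if gene.strand == "+":
        start, end = max(1, s - promoter_length), s - 1
    else:
        start, end = s + 1, min(contig_length, s + promoter_length)
    if end < start:
        return None
    return start, end


# ---------------------------------------------------------------------------
# FASTA round trip; headers carry gene_id|species|length|complete
# ---------------------------------------------------------------------------

def write_promoters_fasta(promoters: Iterable[Promoter], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            flag = "1" if p.complete else "0"
            fh.write(f">{p.gene_id}|{p.species or '.'}|{p.length}|{flag}\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i:i + 70] + "\n")


def read_promoters_fasta(path: str | Path) -> list[Promoter]:
    from Bio import SeqIO

    out: list[Promoter] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 4:
            raise FormatError(
                f"{path}: promoter header {rec.id!r} is not "
                "gene_id|species|length|complete")
        gene_id, species, length, flag = parts
        seq = str(rec.seq).upper()
        if int(length) != len(seq):
            raise FormatError(f"{path}: {gene_id}: header length != sequence")
        out.append(Promoter(
            gene_id=gene_id, sequence=seq, length=len(seq),
            complete=flag == "1",
            species=None if species == "." else species,
        ))
    return out
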