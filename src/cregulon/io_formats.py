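"""Readers and writers for the external formats the pipeline touches.

Every coordinate that enters or leaves this module is 1-based and
inclusive (the GFF3 convention). Python half-open slicing is an internal
detail and never leaks into a file.

Supported formats
-----------------
* FASTA for genomes and promoter sets (via Biopython).
* GFF3 (gene/mRNA/exon/CDS subset, via gffutils) or a 7-column TSV for
  gene models.
* Minimal VCF 4.x (REF/ALT only, via cyvcf2) or a 6-column TSV for
  variants.
* TSV for ortholog-group membership and GO-style functional annotations.

All report tables are written as TSV with a ``#``-prefixed metadata
preamble followed by a header line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRICT_ALPHABET = frozenset("ACGTN")
IUPAC_EXTRA = frozenset("MRWSYKVHDBX")
NAMESPACES = frozenset({"BP", "MF", "CC"})


class FormatError(ValueError):
    """Raised for malformed or invalid input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequences:
    """A set of contigs: contig_id -> uppercase sequence over {A,C,G,T,N}."""

    records: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, contig_id: str) -> str:
        return self.records[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.records.items()}

    def validate(self) -> None:
        for cid, seq in self.records.items():
            if not cid:
                raise FormatError("empty contig id")
            if not seq:
                raise FormatError(f"contig {cid!r} has an empty sequence")
            bad = set(seq) - STRICT_ALPHABET
            if bad:
                raise FormatError(
                    f"contig {cid!r} contains characters outside ACGTN: "
                    f"{sorted(bad)}"
                )


@dataclass
class GeneModel:
    """A gene with exon structure and a translation-start coordinate.

    ``cds_start`` is the genomic coordinate of the 'A' of the ATG: the
    lowest CDS coordinate for '+' genes and the highest for '-' genes,
    which makes "upstream" well defined per strand.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_start: int
    exons: list[tuple[int, int]]
    species: str | None = None

    def validate(self, contig_length: int | None = None) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: empty exon list")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise FormatError(
                    f"gene {self.gene_id}: bad exon interval [{start},{end}]"
                )
            if start <= prev_end:
                raise FormatError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if not any(s <= self.cds_start <= e for s, e in self.exons):
            raise FormatError(
                f"gene {self.gene_id}: cds_start {self.cds_start} "
                "lies outside every exon"
            )
        if contig_length is not None and self.exons[-1][1] > contig_length:
            raise FormatError(
                f"gene {self.gene_id}: exon end {self.exons[-1][1]} exceeds "
                f"contig length {contig_length}"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval covered by the gene body (first to last exon)."""
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class VariantRecord:
    """A SNP, insertion or deletion in empty-allele representation.

    After stripping VCF anchor bases, an insertion has an empty
    ``ref_allele`` and a deletion an empty ``alt_allele``, so that
    ``indel_length`` equals the length of the non-empty allele.
    ``position`` is the 1-based coordinate of the first affected
    reference base (for insertions: the reference base immediately after
    the insertion point).
    """

    contig_id: str
    position: int
    vtype: str  # SNP | INS | DEL
    ref_allele: str
    alt_allele: str
    indel_length: int = 0

    def validate(self) -> None:
        if self.vtype == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise FormatError(f"SNP at {self.position}: alleles must be 1 bp")
            if self.ref_allele == self.alt_allele:
                raise FormatError(f"SNP at {self.position}: ref == alt")
            if self.indel_length != 0:
                raise FormatError("SNP with nonzero indel_length")
        elif self.vtype == "INS":
            if self.ref_allele or not self.alt_allele:
                raise FormatError(f"INS at {self.position}: need empty ref, non-empty alt")
            if self.indel_length != len(self.alt_allele):
                raise FormatError("INS indel_length != |alt|")
        elif self.vtype == "DEL":
            if self.alt_allele or not self.ref_allele:
                raise FormatError(f"DEL at {self.position}: need empty alt, non-empty ref")
            if self.indel_length != len(self.ref_allele):
                raise FormatError("DEL indel_length != |ref|")
        else:
            raise FormatError(f"unknown variant type {self.vtype!r}")


@dataclass
class OrthologGroupTable:
    """group_id -> species_id -> member gene ids."""

    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def species(self) -> set[str]:
        out: set[str] = set()
        for members in self.groups.values():
            out.update(members)
        return out

    def is_complete(self, group_id: str, species_set: Iterable[str]) -> bool:
        """A group is complete if it has >=1 gene of every listed species."""
        members = self.groups[group_id]
        return all(members.get(sp) for sp in species_set)

    def complete_groups(self, species_set: Iterable[str]) -> set[str]:
        sps = list(species_set)
        return {g for g in self.groups if self.is_complete(g, sps)}

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for gid, members in self.groups.items():
            for sp, genes in members.items():
                for gene in genes:
                    if gene in seen and seen[gene] != gid:
                        raise FormatError(
                            f"gene {gene} appears in groups {seen[gene]} and {gid}"
                        )
                    seen[gene] = gid


@dataclass
class FunctionalGroupTable:
    """gene_id -> set of (namespace, category_id, category_name)."""

    assignments: dict[str, set[tuple[str, str, str]]] = field(default_factory=dict)

    def categories(self) -> set[tuple[str, str, str]]:
        out: set[tuple[str, str, str]] = set()
        for cats in self.assignments.values():
            out.update(cats)
        return out

    def genes_in(self, namespace: str, category_id: str) -> set[str]:
        return {
            g for g, cats in self.assignments.items()
            if any(ns == namespace and cid == category_id for ns, cid, _ in cats)
        }

    def validate(self) -> None:
        for gene, cats in self.assignments.items():
            for ns, _cid, _name in cats:
                if ns not in NAMESPACES:
                    raise FormatError(
                        f"gene {gene}: namespace {ns!r} not in {sorted(NAMESPACES)}"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, permissive: bool = False) -> GenomeSequences:
    """Read a FASTA file into :class:`GenomeSequences`.

    Sequences are uppercased. With ``permissive=False`` any residue
    outside {A,C,G,T,N} is a :class:`FormatError`; with
    ``permissive=True`` other IUPAC codes are converted to N.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if rec.id in records:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: contig {rec.id!r} is empty")
        bad = set(seq) - STRICT_ALPHABET
        if bad:
            if permissive and bad <= IUPAC_EXTRA:
                seq = "".join(c if c in STRICT_ALPHABET else "N" for c in seq)
                logger.warning(
                    "%s: contig %s: converted ambiguous codes %s to N",
                    path, rec.id, sorted(bad),
                )
            else:
                raise FormatError(
                    f"{path}: contig {rec.id!r} contains invalid characters "
                    f"{sorted(bad)}"
                )
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequences(records)


def write_fasta(genome: GenomeSequences | Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    records = genome.records if isinstance(genome, GenomeSequences) else genome
    seqs = [SeqRecord(Seq(s), id=cid, description="") for cid, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_TSV_GENE_COLUMNS = [
    "gene_id", "contig", "strand", "cds_start",
    "exon_starts", "exon_ends", "species",
]


def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 or the 7-column TSV dialect.

    Genes violating the structural invariants are skipped with a logged
    warning rather than aborting the whole read.
    """
    if format == "gff3":
        genes = _read_gene_models_gff3(path)
    elif format == "tsv":
        genes = _read_gene_models_tsv(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    valid: list[GeneModel] = []
    for g in genes:
        try:
            g.validate()
        except FormatError as exc:
            logger.warning("%s: skipping gene: %s", path, exc)
            continue
        valid.append(g)
    return valid


def _read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene {gene.id}: unknown strand {gene.strand!r}"
            )
        exons = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="CDS")
        )
        if not exons:
            exons = cds
        if not cds:
            logger.warning("%s: gene %s has no CDS feature; skipped", path, gene.id)
            continue
        cds_start = cds[0][0] if gene.strand == "+" else cds[-1][1]
        species = gene.attributes.get("species", [None])[0]
        genes.append(GeneModel(
            gene_id=gene.id, contig_id=gene.seqid, strand=gene.strand,
            cds_start=cds_start, exons=exons, species=species,
        ))
    return genes


def _read_gene_models_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_TSV_GENE_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    genes: list[GeneModel] = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene {row.gene_id}: unknown strand {row.strand!r}"
            )
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        if len(starts) != len(ends):
            raise FormatError(f"{path}: gene {row.gene_id}: exon list mismatch")
        species = getattr(row, "species", None)
        if pd.isna(species) or species == ".":
            species = None
        genes.append(GeneModel(
            gene_id=row.gene_id, contig_id=row.contig, strand=row.strand,
            cds_start=int(row.cds_start),
            exons=list(zip(starts, ends)), species=species,
        ))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path,
                      format: str = "gff3") -> None:
    if format == "gff3":
        _write_gene_models_gff3(genes, path)
    elif format == "tsv":
        _write_gene_models_tsv(genes, path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")


def _write_gene_models_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            attrs = f"ID={g.gene_id}"
            if g.species:
                attrs += f";species={g.species}"
            fh.write("\t".join([
                g.contig_id, "cregulon", "gene", str(span[0]), str(span[1]),
                ".", g.strand, ".", attrs,
            ]) + "\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write("\t".join([
                    g.contig_id, "cregulon", "exon", str(s), str(e),
                    ".", g.strand, ".",
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                ]) + "\n")
            # a single CDS anchoring the translation start, clipped to the
            # exon that contains it, so the strand-wise first CDS base
            # round-trips to cds_start
            host = next((s, e) for s, e in g.exons if s <= g.cds_start <= e)
            if g.strand == "+":
                cs, ce = g.cds_start, host[1]
            else:
                cs, ce = host[0], g.cds_start
            fh.write("\t".join([
                g.contig_id, "cregulon", "CDS", str(cs), str(ce),
                ".", g.strand, "0",
                f"ID={g.gene_id}.cds;Parent={g.gene_id}",
            ]) + "\n")


def _write_gene_models_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id,
            "contig": g.contig_id,
            "strand": g.strand,
            "cds_start": g.cds_start,
            "exon_starts": ",".join(str(s) for s, _ in g.exons),
            "exon_ends": ",".join(str(e) for _, e in g.exons),
            "species": g.species or ".",
        })
    pd.DataFrame(rows, columns=_TSV_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_TSV_VARIANT_COLUMNS = ["contig", "position", "vtype", "ref", "alt", "indel_length"]


def read_variant_table(path: str | Path, format: str = "tsv") -> list[VariantRecord]:
    if format == "tsv":
        variants = _read_variants_tsv(path)
    elif format == "vcf":
        variants = _read_variants_vcf(path)
    else:
        raise ValueError(f"unknown variant format {format!r}")
    for v in variants:
        v.validate()
    return variants


def _read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_TSV_VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        ref = "" if pd.isna(row.ref) or row.ref == "." else row.ref
        alt = "" if pd.isna(row.alt) or row.alt == "." else row.alt
        out.append(VariantRecord(
            contig_id=row.contig, position=int(row.position), vtype=row.vtype,
            ref_allele=ref, alt_allele=alt, indel_length=int(row.indel_length),
        ))
    return out


def _read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    import cyvcf2

    out: list[VariantRecord] = []
    for v in cyvcf2.VCF(str(path)):
        for alt in v.ALT:
            if alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
                logger.warning(
                    "%s:%d symbolic ALT %r rejected", v.CHROM, v.POS, alt
                )
                continue
            rec = _vcf_to_record(v.CHROM, v.POS, v.REF.upper(), alt.upper())
            if rec is not None:
                out.append(rec)
    return out


def _vcf_to_record(chrom: str, pos: int, ref: str, alt: str) -> VariantRecord | None:
    """Convert a VCF REF/ALT pair to the empty-allele convention."""
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt:
            return None
        return VariantRecord(chrom, pos, "SNP", ref, alt, 0)
    # strip the longest common left anchor
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    ref_t, alt_t = ref[k:], alt[k:]
    if ref_t and alt_t:
        logger.warning("%s:%d complex allele %s>%s rejected", chrom, pos, ref, alt)
        return None
    if alt_t:
        return VariantRecord(chrom, pos + k, "INS", "", alt_t, len(alt_t))
    if ref_t:
        return VariantRecord(chrom, pos + k, "DEL", ref_t, "", len(ref_t))
    return None


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [{
        "contig": v.contig_id, "position": v.position, "vtype": v.vtype,
        "ref": v.ref_allele or ".", "alt": v.alt_allele or ".",
        "indel_length": v.indel_length,
    } for v in variants]
    pd.DataFrame(rows, columns=_TSV_VARIANT_COLUMNS).to_csv(
        path, sep="\t", index=False)


def write_vcf(variants: Iterable[VariantRecord], genome: GenomeSequences,
              path: str | Path) -> None:
    """Write minimal VCF 4.2; INDELs are re-anchored on the preceding base."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for cid, length in genome.lengths.items():
            fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            if v.vtype == "SNP":
                pos, ref, alt = v.position, v.ref_allele, v.alt_allele
            else:
                anchor_pos = v.position - 1
                if anchor_pos < 1:
                    logger.warning(
                        "%s:%d INDEL at contig start has no anchor base; skipped",
                        v.contig_id, v.position)
                    continue
                anchor = genome[v.contig_id][anchor_pos - 1]
                pos = anchor_pos
                if v.vtype == "INS":
                    ref, alt = anchor, anchor + v.alt_allele
                else:
                    ref, alt = anchor + v.ref_allele, anchor
            fh.write(f"{v.contig_id}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Ortholog groups and functional annotations
# ---------------------------------------------------------------------------

def read_ortholog_groups(path: str | Path) -> OrthologGroupTable:
    """Read a TSV with columns group_id, species_id, gene_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"group_id", "species_id", "gene_id"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(needed)}")
    ndup = df.duplicated().sum()
    if ndup:
        logger.info("%s: deduplicated %d repeated membership rows", path, ndup)
        df = df.drop_duplicates()
    table = OrthologGroupTable()
    for row in df.itertuples(index=False):
        table.groups.setdefault(row.group_id, {}).setdefault(
            row.species_id, []).append(row.gene_id)
    table.validate()
    return table


def write_ortholog_groups(table: OrthologGroupTable, path: str | Path) -> None:
    rows = [
        {"group_id": gid, "species_id": sp, "gene_id": gene}
        for gid, members in table.groups.items()
        for sp, genes in members.items()
        for gene in genes
    ]
    pd.DataFrame(rows, columns=["group_id", "species_id", "gene_id"]).to_csv(
        path, sep="\t", index=False)


def read_gene_annotations(path: str | Path) -> FunctionalGroupTable:
    """Read a TSV with columns gene_id, namespace, category_id, category_name."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"gene_id", "namespace", "category_id"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(needed)}")
    if "category_name" not in df.columns:
        df["category_name"] = df["category_id"]
    table = FunctionalGroupTable()
    for row in df.itertuples(index=False):
        table.assignments.setdefault(row.gene_id, set()).add(
            (row.namespace, row.category_id, row.category_name))
    table.validate()
    return table


def write_gene_annotations(table: FunctionalGroupTable, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "namespace": ns, "category_id": cid, "category_name": name}
        for g, cats in table.assignments.items()
        for ns, cid, name in sorted(cats)
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "namespace", "category_id", "category_name"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def write_report(df: pd.DataFrame, path: str | Path,
                 metadata: Mapping[str, object] | None = None) -> None:
    """Write a report TSV with a '#'-prefixed metadata preamble."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Pairwise-aligned contig pairs (2 records per contig, gapped FASTA)
# ---------------------------------------------------------------------------

def write_aligned_pairs(pairs: Mapping[str, tuple[str, str]],
                        path: str | Path) -> None:
    """Write gapped reference/query pairs; headers are contig|ref, contig|qry."""
    with open(path, "w") as fh:
        for cid, (ref, qry) in pairs.items():
            for tag, seq in (("ref", ref), ("qry", qry)):
                fh.write(f">{cid}|{tag}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")


def read_aligned_pairs(path: str | Path) -> dict[str, tuple[str, str]]:
    halves: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            cid, tag = rec.id.rsplit("|", 1)
        except ValueError:
            raise FormatError(f"{path}: header {rec.id!r} is not contig|ref|qry")
        if tag not in ("ref", "qry"):
            raise FormatError(f"{path}: header {rec.id!r} must end in ref or qry")
        halves.setdefault(cid, {})[tag] = str(rec.seq).upper()
    out = {}
    for cid, d in halves.items():
        if set(d) != {"ref", "qry"}:
            raise FormatError(f"{path}: contig {cid} lacks a ref/qry pair")
        if len(d["ref"]) != len(d["qry"]):
            raise FormatError(f"{path}: contig {cid}: unequal aligned lengths")
        out[cid] = (d["ref"], d["qry"])
    return out
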