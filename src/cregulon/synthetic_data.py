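"""Synthetic genomes, promoters, ortholog sets and variant pairs.

Every pipeline stage is testable without real assemblies: the generator
emits the exact formats the readers consume, together with ground truth
that is *recomputed from the emitted sequences* by a brute-force oracle
(never trusted from planting intent alone), so incidental background
motif matches are part of the truth.

Defaults emulate the study system the package was built around: contigs
at 36.6% GC; genes with ~5 exons of ~200 bp separated by ~440 bp
introns; 1,000-bp promoters; motif planting rates of a few occurrences
per hundred promoters with a 3x positional bias within 300 bp of the
ATG; five mock species with per-species element retention; and variant
rates (SNPs ~15/kb in promoters vs ~4.6/kb in gene bodies, deletions
twice as frequent as insertions, mostly 1-2 bp) matching the promoter
vs gene-body contrast the analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, GenomeSequences, OrthologGroupTable, VariantRecord
from .motif_scan import ANTISENSE, SENSE, MotifDefinition, builtin_motifs
from .polymorphism import LABEL_NAMES, annotate_regions
from .promoters import Promoter, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def naive_scan(seq: str, motif: MotifDefinition,
               strands: str = SENSE) -> list[tuple[int, str]]:
    """Exhaustive window enumeration: every offset whose window is in the
    motif's expansion set. Independent of the production scanner."""
    hits = [
        (i + 1, SENSE)
        for i in range(len(seq) - motif.length + 1)
        if seq[i:i + motif.length] in motif.expansion
    ]
    if strands == "both":
        rc = reverse_complement(seq)
        L = len(seq)
        for i in range(len(rc) - motif.length + 1):
            if rc[i:i + motif.length] in motif.expansion:
                hits.append((L - i - motif.length + 1, ANTISENSE))
    return sorted(hits)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

def _default_motif_rates() -> dict[str, float]:
    return {"ABRE": 0.03, "DRE": 0.02, "ERE": 0.01}


def _default_bias() -> tuple[float, ...]:
    # 3x planting weight in the six 50-bp bins closest to the ATG
    return (3.0,) * 6 + (1.0,) * 14


def _default_snp_rates() -> dict[str, float]:
    return {"promoter": 14.89, "exon": 4.60, "intron": 4.60, "intergenic": 4.22}


def _default_indel_rates() -> dict[str, float]:
    return {"promoter": 3.87, "exon": 1.34, "intron": 1.34, "intergenic": 2.53}


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome structure
    n_genes: int = 100
    genes_per_contig: int = 20
    gc_content: float = 0.366
    promoter_length: int = 1000
    exons_per_gene: int = 5
    exon_length: int = 201
    intron_length: int = 436
    intergenic_length: int = 1000
    # motif planting: mean planted occurrences per promoter (Poisson)
    motif_rates: dict[str, float] = field(default_factory=_default_motif_rates)
    positional_bias: Sequence[float] = field(default_factory=_default_bias)
    # ortholog-set simulation
    n_species: int = 5
    n_groups: int = 100
    complement_prob: float = 0.5
    retention: float | Mapping[str, float] = 0.85
    # variant simulation (rates per kb by region label)
    snp_per_kb: dict[str, float] = field(default_factory=_default_snp_rates)
    indel_per_kb: dict[str, float] = field(default_factory=_default_indel_rates)
    insertion_fraction: float = 1.0 / 3.0
    ins_class_probs: Sequence[float] = (0.60, 0.25, 0.14, 0.01)
    del_class_probs: Sequence[float] = (0.85, 0.10, 0.045, 0.005)

    def validate(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0,1]")
        if any(r < 0 for r in self.motif_rates.values()):
            raise ValueError("motif rates must be >= 0")
        if any(w < 0 for w in self.positional_bias):
            raise ValueError("positional bias weights must be >= 0")
        for probs in (self.ins_class_probs, self.del_class_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("INDEL class probabilities must sum to 1")
        if not 0.0 <= self.insertion_fraction <= 1.0:
            raise ValueError("insertion_fraction must be in [0,1]")

    def base_probs(self) -> np.ndarray:
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def retention_prob(self, species: str, motif: str) -> float:
        """Retention may be a scalar, a per-motif mapping, or a per-motif
        mapping of per-species mappings; unlisted motifs/species retain
        with probability 1."""
        r = self.retention
        if isinstance(r, Mapping):
            val = r.get(motif, 1.0)
            if isinstance(val, Mapping):
                val = val.get(species, 1.0)
            return float(val)
        return float(r)


@dataclass
class GroundTruth:
    """Truth recomputed from emitted artifacts by the brute-force oracle."""

    # gene_id -> sorted (motif, offset) pairs found by naive_scan (sense)
    promoter_hits: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    # gene_id -> (motif, offset) pairs the generator intended to plant
    planted_hits: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    # gene_id -> (contig, start, end, strand) of the promoter window
    promoter_regions: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    # species -> gene_id -> presence set (ortholog simulation)
    presence: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    # planted variant edit script (variant simulation)
    edit_script: list[VariantRecord] = field(default_factory=list)

    def occurrence_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for hits in self.promoter_hits.values():
            for motif, _off in hits:
                out[motif] = out.get(motif, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def random_sequence(rng: np.random.Generator, n: int,
                    base_probs: np.ndarray) -> str:
    idx = rng.choice(4, size=n, p=base_probs)
    return _BASES[idx].tobytes().decode("ascii")


def _sample_plant_offset(
    rng: np.random.Generator, length: int, motif_len: int,
    bias: Sequence[float], bin_width: int = 50,
) -> int:
    """Sample a planting offset honoring the distance-to-ATG bias bins."""
    max_dist = length - motif_len + 1
    n_bins = (max_dist + bin_width - 1) // bin_width
    weights = np.array([
        bias[k] if k < len(bias) else 1.0 for k in range(n_bins)])
    if weights.sum() == 0:
        weights[:] = 1.0
    k = rng.choice(n_bins, p=weights / weights.sum())
    lo = k * bin_width + 1
    hi = min((k + 1) * bin_width, max_dist)
    dist = int(rng.integers(lo, hi + 1))
    # distance is measured from the motif's 3' end to the ATG
    return length - dist - motif_len + 2


def plant_motifs(
    rng: np.random.Generator,
    sequence: str,
    motifs: Sequence[MotifDefinition],
    rates: Mapping[str, float],
    bias: Sequence[float],
    max_tries: int = 50,
    poisson: bool = True,
) -> tuple[str, list[tuple[str, int]]]:
    """Overwrite background bases with sampled motif words (length kept).

    With ``poisson=True`` the number of plants per motif is
    Poisson(rate); otherwise the rate is taken as an exact count.
    Overlapping plants are re-sampled; a plant that cannot be placed
    after ``max_tries`` attempts is dropped.
    """
    seq = list(sequence)
    occupied: list[tuple[int, int]] = []
    planted: list[tuple[str, int]] = []
    for motif in motifs:
        lam = rates.get(motif.name, 0.0)
        if lam <= 0 or len(sequence) < motif.length:
            continue
        words = sorted(motif.expansion)
        n_plants = rng.poisson(lam) if poisson else int(round(lam))
        for _ in range(n_plants):
            for _try in range(max_tries):
                off = _sample_plant_offset(
                    rng, len(sequence), motif.length, bias)
                span = (off, off + motif.length - 1)
                if all(span[1] < s or span[0] > e for s, e in occupied):
                    word = words[rng.integers(len(words))]
                    seq[off - 1: off - 1 + motif.length] = word
                    occupied.append(span)
                    planted.append((motif.name, off))
                    break
    return "".join(seq), planted


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig,
    motifs: Sequence[MotifDefinition] | None = None,
) -> tuple[GenomeSequences, list[GeneModel], GroundTruth]:
    """Simulate contigs carrying genes with planted promoter motifs.

    Each gene occupies a slot [intergenic pad][promoter][gene body] (the
    body precedes the promoter for '-' genes, whose promoter is embedded
    reverse-complemented). Ground-truth occurrences are enumerated by
    ``naive_scan`` on promoter windows sliced back out of the final
    contigs, so incidental background matches are included.
    """
    config.validate()
    if motifs is None:
        motifs = builtin_motifs()
    min_len = min(m.length for m in motifs)
    if config.promoter_length < min_len:
        raise ValueError("promoter shorter than the shortest motif")
    rng = np.random.default_rng(config.seed)
    probs = config.base_probs()
    truth = GroundTruth()
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []

    n_contigs = -(-config.n_genes // config.genes_per_contig)
    gene_no = 0
    for ci in range(n_contigs):
        cid = f"ctg{ci + 1:03d}"
        parts: list[str] = []
        pos = 0  # genomic length so far
        n_here = min(config.genes_per_contig, config.n_genes - gene_no)
        for _ in range(n_here):
            gene_no += 1
            gid = f"g{gene_no:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            pad = random_sequence(rng, config.intergenic_length, probs)
            promoter_seq, planted = plant_motifs(
                rng, random_sequence(rng, config.promoter_length, probs),
                motifs, config.motif_rates, config.positional_bias)
            n_ex = max(1, config.exons_per_gene)
            ex_lens = [
                int(rng.integers(config.exon_length // 2,
                                 config.exon_length * 3 // 2 + 1))
                for _ in range(n_ex)]
            in_lens = [
                int(rng.integers(config.intron_length // 2,
                                 config.intron_length * 3 // 2 + 1))
                for _ in range(n_ex - 1)]
            body_len = sum(ex_lens) + sum(in_lens)
            body = random_sequence(rng, body_len, probs)

            if strand == "+":
                parts.extend([pad, promoter_seq, body])
                prom_start = pos + len(pad) + 1
                prom_end = prom_start + config.promoter_length - 1
                body_start = prom_end + 1
                cds_start = body_start
            else:
                parts.extend([pad, body, reverse_complement(promoter_seq)])
                body_start = pos + len(pad) + 1
                prom_start = body_start + body_len
                prom_end = prom_start + config.promoter_length - 1
                cds_start = body_start + body_len - 1  # last body base

            exons = []
            cursor = body_start
            for k, el in enumerate(ex_lens):
                exons.append((cursor, cursor + el - 1))
                cursor += el
                if k < len(in_lens):
                    cursor += in_lens[k]
            genes.append(GeneModel(
                gene_id=gid, contig_id=cid, strand=strand,
                cds_start=cds_start, exons=exons))
            truth.planted_hits[gid] = sorted(planted)
            truth.promoter_regions[gid] = (cid, prom_start, prom_end, strand)
            pos += len(pad) + config.promoter_length + body_len
        parts.append(random_sequence(rng, config.intergenic_length, probs))
        contigs[cid] = "".join(parts)

    genome = GenomeSequences(contigs)
    # recount ground truth from the emitted contigs
    for gid, (cid, start, end, strand) in truth.promoter_regions.items():
        window = genome[cid][start - 1: end]
        if strand == "-":
            window = reverse_complement(window)
        hits: list[tuple[str, int]] = []
        for motif in motifs:
            hits.extend((motif.name, off) for off, _s in naive_scan(window, motif))
        truth.promoter_hits[gid] = sorted(hits)
    return genome, genes, truth


# ---------------------------------------------------------------------------
# Ortholog-set simulation (element retention across mock species)
# ---------------------------------------------------------------------------

def simulate_ortholog_set(
    config: SimulationConfig,
    motifs: Sequence[MotifDefinition] | None = None,
) -> tuple[dict[str, list[Promoter]], OrthologGroupTable, GroundTruth]:
    """Mock species sharing ortholog groups with per-species CRE retention.

    Each group is seeded with a motif complement; every species
    independently retains each complement motif with its retention
    probability and gets one member gene whose promoter carries the
    retained motifs. Presence ground truth is recomputed by the oracle,
    so background matches can add presence beyond the planted set.
    """
    config.validate()
    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    if motifs is None:
        motifs = builtin_motifs()
    rng = np.random.default_rng(config.seed)
    probs = config.base_probs()
    species = [f"sp{k + 1}" for k in range(config.n_species)]
    truth = GroundTruth(presence={sp: {} for sp in species})
    table = OrthologGroupTable()
    promoters: dict[str, list[Promoter]] = {sp: [] for sp in species}
    flat_bias = (1.0,)  # retention planting is positionally uniform

    for gi in range(config.n_groups):
        group_id = f"OG{gi + 1:05d}"
        complement = [m for m in motifs if rng.random() < config.complement_prob]
        table.groups[group_id] = {}
        for sp in species:
            gene_id = f"{sp}_g{gi + 1:05d}"
            table.groups[group_id][sp] = [gene_id]
            retained = {
                m.name: 1.0 for m in complement
                if rng.random() < config.retention_prob(sp, m.name)
            }
            seq, planted = plant_motifs(
                rng, random_sequence(rng, config.promoter_length, probs),
                motifs, retained, flat_bias, poisson=False)
            prom = Promoter(
                gene_id=gene_id, sequence=seq, length=len(seq),
                complete=True, species=sp)
            promoters[sp].append(prom)
            truth.planted_hits[gene_id] = sorted(planted)
            present = frozenset(
                m.name for m in motifs if naive_scan(seq, m))
            truth.presence[sp][gene_id] = present
    return promoters, table, truth


# ---------------------------------------------------------------------------
# Variant-pair simulation
# ---------------------------------------------------------------------------

_CLASS_RANGES = ((1, 2), (3, 10), (11, 50), (51, 100))


def simulate_variant_pair(
    config: SimulationConfig,
    genome: GenomeSequences,
    genes: Sequence[GeneModel],
) -> tuple[GenomeSequences, dict[str, tuple[str, str]], GroundTruth]:
    """Mutate a genome copy at region-specific per-kb rates.

    Returns the mutated genome, per-contig gapped alignment pairs that
    reflect the exact edit script, and the script itself (positions on
    the reference line; polarity named from the reference). Edits keep
    at least one untouched reference base between INDELs so the planted
    script and a column-walk call on the emitted alignment agree record
    for record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    regions = annotate_regions(
        genes, genome.lengths, promoter_length=config.promoter_length)
    label_to_name = LABEL_NAMES
    snp_p = np.array([
        config.snp_per_kb.get(label_to_name[code], 0.0) / 1000.0
        for code in range(4)])
    indel_p = np.array([
        config.indel_per_kb.get(label_to_name[code], 0.0) / 1000.0
        for code in range(4)])

    script: list[VariantRecord] = []
    mutated: dict[str, str] = {}
    aligned: dict[str, tuple[str, str]] = {}
    base_list = "ACGT"

    for cid, seq in genome.records.items():
        labels = regions.labels[cid]
        n = len(seq)
        snp_hits = np.nonzero(rng.random(n) < snp_p[labels])[0] + 1
        indel_hits = np.nonzero(rng.random(n) < indel_p[labels])[0] + 1
        events = sorted(
            [(int(p), "SNP") for p in snp_hits] +
            [(int(p), "INDEL") for p in indel_hits])
        contig_script: list[VariantRecord] = []
        next_free = 2  # leave base 1 as an anchor
        for pos, kind in events:
            if pos < next_free:
                continue
            if kind == "SNP":
                ref = seq[pos - 1]
                if ref == "N":
                    continue
                alt = base_list[rng.integers(4)]
                while alt == ref:
                    alt = base_list[rng.integers(4)]
                contig_script.append(VariantRecord(cid, pos, "SNP", ref, alt, 0))
                next_free = pos + 1
            else:
                is_ins = rng.random() < config.insertion_fraction
                probs_cls = (config.ins_class_probs if is_ins
                             else config.del_class_probs)
                lo, hi = _CLASS_RANGES[rng.choice(4, p=np.asarray(probs_cls))]
                length = int(rng.integers(lo, hi + 1))
                if is_ins:
                    alt = "".join(
                        base_list[i] for i in rng.integers(0, 4, size=length))
                    contig_script.append(
                        VariantRecord(cid, pos, "INS", "", alt, length))
                    next_free = pos + 2
                else:
                    if pos + length - 1 > n - 1:
                        continue  # keep the final base intact
                    ref_run = seq[pos - 1: pos - 1 + length]
                    if "N" in ref_run:
                        continue
                    contig_script.append(
                        VariantRecord(cid, pos, "DEL", ref_run, "", length))
                    next_free = pos + length + 2
        # build the gapped pair by walking the reference
        ref_parts: list[str] = []
        qry_parts: list[str] = []
        cursor = 1
        for v in contig_script:
            ref_parts.append(seq[cursor - 1: v.position - 1])
            qry_parts.append(seq[cursor - 1: v.position - 1])
            if v.vtype == "SNP":
                ref_parts.append(v.ref_allele)
                qry_parts.append(v.alt_allele)
                cursor = v.position + 1
            elif v.vtype == "INS":
                ref_parts.append("-" * v.indel_length)
                qry_parts.append(v.alt_allele)
                cursor = v.position
            else:
                ref_parts.append(v.ref_allele)
                qry_parts.append("-" * v.indel_length)
                cursor = v.position + v.indel_length
        ref_parts.append(seq[cursor - 1:])
        qry_parts.append(seq[cursor - 1:])
        ref_aln = "".join(ref_parts)
        qry_aln = "".join(qry_parts)
        aligned[cid] = (ref_aln, qry_aln)
        mutated[cid] = qry_aln.replace("-", "")
        script.extend(contig_script)

    truth = GroundTruth(edit_script=script)
    return GenomeSequences(mutated), aligned, truth
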