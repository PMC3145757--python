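"""Variant calling from pairwise alignments and region-stratified rates.

Variants between two assemblies are called by a column walk over a
pairwise alignment: mismatch columns become SNPs and maximal gap runs
become insertions (gaps on the reference line) or deletions (gaps on
the query line), with polarity named from the reference's perspective.
Each genomic position receives exactly one finest region label with
precedence exon > intron > promoter > intergenic, and per-region
frequencies are reported both per kb and as "1 per N bp". INDELs are
additionally classified by length: ultra (1-2 bp), micro (3-10 bp),
mini (11-50 bp), midi (51-100 bp); longer events are tallied but
excluded from the class shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel, VariantRecord
from .promoters import promoter_interval

logger = logging.getLogger(__name__)

# region label codes, in increasing precedence
INTERGENIC, PROMOTER, INTRON, EXON = 0, 1, 2, 3
LABEL_NAMES = {INTERGENIC: "intergenic", PROMOTER: "promoter",
               INTRON: "intron", EXON: "exon"}

INDEL_CLASSES = (("ultra", 1, 2), ("micro", 3, 10),
                 ("mini", 11, 50), ("midi", 51, 100))


class AlignmentError(ValueError):
    pass


def call_variants_from_alignment(
    ref_aligned: str,
    qry_aligned: str,
    contig_id: str = "ref",
    ref_offset: int = 0,
) -> list[VariantRecord]:
    """Column walk over a gapped pair of equal-length strings.

    Positions are 1-based reference coordinates (plus ``ref_offset``).
    A deletion is reported at its first deleted reference base; an
    insertion at the reference base immediately after the run (i.e. the
    base before the run, plus one). Columns containing N emit nothing,
    and a gap run containing N on its non-gap side is dropped whole.
    """
    if len(ref_aligned) != len(qry_aligned):
        raise AlignmentError(
            f"aligned strings differ in length: {len(ref_aligned)} vs "
            f"{len(qry_aligned)}")
    ref_aligned = ref_aligned.upper()
    qry_aligned = qry_aligned.upper()
    out: list[VariantRecord] = []
    rp = ref_offset  # last consumed reference coordinate
    i, n = 0, len(ref_aligned)
    while i < n:
        r, q = ref_aligned[i], qry_aligned[i]
        if r == "-" and q == "-":
            raise AlignmentError(f"column {i + 1}: gap in both sequences")
        if r == "-":
            j = i
            while j < n and ref_aligned[j] == "-":
                j += 1
            inserted = qry_aligned[i:j]
            if "-" in inserted:
                raise AlignmentError(f"column {i + 1}: gap in both sequences")
            if "N" not in inserted:
                out.append(VariantRecord(
                    contig_id, rp + 1, "INS", "", inserted, len(inserted)))
            i = j
        elif q == "-":
            j = i
            while j < n and qry_aligned[j] == "-":
                j += 1
            deleted = ref_aligned[i:j]
            if "-" in deleted:
                raise AlignmentError(f"column {i + 1}: gap in both sequences")
            if "N" not in deleted:
                out.append(VariantRecord(
                    contig_id, rp + 1, "DEL", deleted, "", len(deleted)))
            rp += j - i
            i = j
        else:
            rp += 1
            if r != q and r != "N" and q != "N":
                out.append(VariantRecord(contig_id, rp, "SNP", r, q, 0))
            i += 1
    return out


def apply_variants(reference: str, variants: Sequence[VariantRecord]) -> str:
    """Reconstruct the query sequence from the reference and a variant set."""
    ordered = sorted(variants, key=lambda v: (v.position, v.vtype != "INS"))
    parts: list[str] = []
    cursor = 1
    for v in ordered:
        parts.append(reference[cursor - 1: v.position - 1])
        if v.vtype == "SNP":
            parts.append(v.alt_allele)
            cursor = v.position + 1
        elif v.vtype == "INS":
            parts.append(v.alt_allele)
            cursor = v.position
        else:
            cursor = v.position + v.indel_length
    parts.append(reference[cursor - 1:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

@dataclass
class RegionAnnotation:
    """Per-contig finest region label for every base.

    ``labels[contig]`` is an int8 array of length contig_length where
    index i holds the label of position i+1.
    """

    labels: dict[str, np.ndarray] = field(default_factory=dict)
    promoter_length: int = 1000

    def label_of(self, contig_id: str, position: int) -> str:
        arr = self.labels[contig_id]
        if not 1 <= position <= len(arr):
            raise IndexError(f"{contig_id}:{position} outside contig")
        return LABEL_NAMES[int(arr[position - 1])]

    def bp_totals(self) -> dict[str, int]:
        """bp per finest label plus the composites 'gene' and 'genome'."""
        counts = np.zeros(4, dtype=np.int64)
        for arr in self.labels.values():
            counts += np.bincount(arr, minlength=4)
        out = {LABEL_NAMES[code]: int(counts[code]) for code in LABEL_NAMES}
        out["gene"] = out["exon"] + out["intron"]
        out["genome"] = int(counts.sum())
        return out


def annotate_regions(
    genes: Iterable[GeneModel],
    contig_lengths: Mapping[str, int],
    promoter_length: int = 1000,
) -> RegionAnnotation:
    """Label every position: exon > intron > promoter > intergenic.

    Promoters are the same upstream windows the extraction step uses;
    where a promoter overlaps an annotated exon or intron of another
    gene the higher-precedence label wins.
    """
    labels = {
        cid: np.zeros(length, dtype=np.int8)
        for cid, length in contig_lengths.items()
    }
    gene_list = [g for g in genes if g.contig_id in labels]
    # paint in increasing precedence so later layers overwrite
    for g in gene_list:
        iv = promoter_interval(g, len(labels[g.contig_id]), promoter_length)
        if iv is not None:
            labels[g.contig_id][iv[0] - 1: iv[1]] = PROMOTER
    for g in gene_list:
        arr = labels[g.contig_id]
        for (s1, e1), (s2, _e2) in zip(g.exons, g.exons[1:]):
            arr[e1: s2 - 1] = INTRON
    for g in gene_list:
        arr = labels[g.contig_id]
        for s, e in g.exons:
            arr[s - 1: min(e, len(arr))] = EXON
    return RegionAnnotation(labels=labels, promoter_length=promoter_length)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

REPORT_REGIONS = ("promoter", "exon", "intron", "gene", "intergenic", "genome")
VARIANT_CLASSES = ("SNP", "INS", "DEL", "INDEL")


@dataclass
class PolymorphismReport:
    frame: pd.DataFrame
    indel_classes: pd.DataFrame | None = None

    def rate(self, region: str, vclass: str) -> float:
        sel = self.frame[(self.frame.region == region) &
                         (self.frame.vclass == vclass)]
        return float(sel["per_kb"].iloc[0])

    def count(self, region: str, vclass: str) -> int:
        sel = self.frame[(self.frame.region == region) &
                         (self.frame.vclass == vclass)]
        return int(sel["count"].iloc[0])


def polymorphism_frequencies(
    variants: Sequence[VariantRecord],
    regions: RegionAnnotation,
) -> PolymorphismReport:
    """Per-region, per-class counts and frequencies.

    A variant is assigned to the label of its (first) reference base.
    Rates are reported per kb and as "1 per N bp" (N = bp/count, inf
    when the count is zero).
    """
    totals = regions.bp_totals()
    counts = {(r, c): 0 for r in REPORT_REGIONS for c in VARIANT_CLASSES}
    kept: list[VariantRecord] = []
    for v in variants:
        if v.contig_id not in regions.labels:
            logger.warning("variant on unannotated contig %s skipped", v.contig_id)
            continue
        arr = regions.labels[v.contig_id]
        if not 1 <= v.position <= len(arr):
            logger.warning("variant %s:%d off contig; skipped",
                           v.contig_id, v.position)
            continue
        kept.append(v)
        label = LABEL_NAMES[int(arr[v.position - 1])]
        targets = {label, "genome"}
        if label in ("exon", "intron"):
            targets.add("gene")
        classes = [v.vtype] + (["INDEL"] if v.vtype in ("INS", "DEL") else [])
        for r in targets:
            for c in classes:
                counts[r, c] += 1
    rows = []
    for region in REPORT_REGIONS:
        bp = totals[region]
        for vclass in VARIANT_CLASSES:
            n = counts[region, vclass]
            per_kb = 1000.0 * n / bp if bp else float("nan")
            one_per = bp / n if n else float("inf")
            rows.append({
                "region": region, "vclass": vclass, "count": n, "bp": bp,
                "per_kb": per_kb, "one_per_n_bp": one_per,
            })
    frame = pd.DataFrame(rows)
    indels = [v for v in kept if v.vtype in ("INS", "DEL")]
    classes = indel_length_classes(indels) if indels else None
    return PolymorphismReport(frame=frame, indel_classes=classes)


def indel_length_classes(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Length-class shares per polarity: ultra/micro/mini/midi.

    Lengths above 100 bp are counted in an ``over_100`` row but excluded
    from the percentage shares, which sum to 100 per polarity.
    """
    for v in variants:
        if v.vtype not in ("INS", "DEL"):
            raise ValueError(f"non-INDEL record of type {v.vtype}")
    rows = []
    for polarity in ("INS", "DEL"):
        lengths = [v.indel_length for v in variants if v.vtype == polarity]
        in_class = [x for x in lengths if 1 <= x <= 100]
        over = len(lengths) - len(in_class)
        denom = len(in_class)
        for name, lo, hi in INDEL_CLASSES:
            n = sum(1 for x in in_class if lo <= x <= hi)
            rows.append({
                "polarity": polarity, "length_class": name,
                "min_bp": lo, "max_bp": hi, "count": n,
                "share_pct": round(100.0 * n / denom, 1) if denom else float("nan"),
            })
        rows.append({
            "polarity": polarity, "length_class": "over_100",
            "min_bp": 101, "max_bp": None, "count": over,
            "share_pct": float("nan"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-gene promoter vs gene-body contrast
# ---------------------------------------------------------------------------

def per_gene_rates(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    promoter_length: int = 1000,
    classes: Iterable[str] = ("SNP",),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mutation rates (per kb) in the promoter and the gene body.

    The gene body spans first-exon start to last-exon end (introns and
    exons together). Returns two aligned arrays over the gene list.
    """
    wanted = set(classes)
    if "INDEL" in wanted:
        wanted |= {"INS", "DEL"}
    by_contig: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.vtype in wanted:
            by_contig.setdefault(v.contig_id, []).append(v)
    prom_rates = np.zeros(len(genes))
    body_rates = np.zeros(len(genes))
    for idx, g in enumerate(genes):
        clen = contig_lengths.get(g.contig_id)
        if clen is None:
            continue
        iv = promoter_interval(g, clen, promoter_length)
        span = g.span
        contig_vars = by_contig.get(g.contig_id, [])
        if iv is not None:
            n = sum(1 for v in contig_vars if iv[0] <= v.position <= iv[1])
            prom_rates[idx] = 1000.0 * n / (iv[1] - iv[0] + 1)
        n = sum(1 for v in contig_vars if span[0] <= v.position <= span[1])
        body_rates[idx] = 1000.0 * n / (span[1] - span[0] + 1)
    return prom_rates, body_rates


def compare_region_rates(
    rates_promoter: Sequence[float],
    rates_genebody: Sequence[float],
) -> tuple[float, float]:
    """Two-sided Welch t-test on per-gene per-kb rates -> (t, p)."""
    a = np.asarray(rates_promoter, dtype=float)
    b = np.asarray(rates_genebody, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 genes per arm")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero variance in both arms with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
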