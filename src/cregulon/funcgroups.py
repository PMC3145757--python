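"""Per-functional-group CRE composition and two-genotype fold filtering.

Percentages are always within-genotype: the denominator for a GO-style
category is the number of that genotype's annotated genes with analyzed
promoters, so genotypes with different gene universes remain comparable
on the percent scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .combos_ortho import CREPresenceProfile, all_combos, combo_label
from .io_formats import FunctionalGroupTable

logger = logging.getLogger(__name__)


def group_cre_percentages(
    profile: CREPresenceProfile,
    annotations: FunctionalGroupTable,
    motifs: Sequence[str] = ("ABRE", "DRE", "ERE"),
    combos: Sequence[Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Percent of each category's analyzed genes carrying each combination.

    A category's denominator is the number of its genes that appear in
    the presence profile; empty categories are omitted with a log note.
    """
    if combos is None:
        combos = all_combos(list(motifs))
    combos = [frozenset(c) for c in combos]
    categories: dict[tuple[str, str, str], set[str]] = {}
    for gene, cats in annotations.assignments.items():
        if gene not in profile.genes:
            continue
        for cat in cats:
            categories.setdefault(cat, set()).add(gene)
    rows = []
    for (ns, cid, name), genes in sorted(categories.items()):
        if not genes:
            logger.info("category %s/%s empty after promoter filter; omitted",
                        ns, cid)
            continue
        for combo in combos:
            carriers = sum(1 for g in genes if combo <= profile.genes[g])
            rows.append({
                "namespace": ns,
                "category_id": cid,
                "category_name": name,
                "combination": combo_label(combo),
                "genes_in_category": len(genes),
                "carriers": carriers,
                "percent": round(100.0 * carriers / len(genes), 1),
            })
    return pd.DataFrame(rows, columns=[
        "namespace", "category_id", "category_name", "combination",
        "genes_in_category", "carriers", "percent"])


@dataclass
class FoldDifferenceReport:
    frame: pd.DataFrame
    threshold: float
    min_total: int

    def flagged(self) -> pd.DataFrame:
        return self.frame[self.frame["flagged"]]


def fold_difference_filter(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    threshold: float = 2.0,
    min_total: int = 3,
    label_a: str = "A",
    label_b: str = "B",
) -> FoldDifferenceReport:
    """Flag categories with a >= threshold-fold gene-count difference.

    fold = max(a,b)/min(a,b); a zero on one side gives an infinite fold.
    Categories with fewer than ``min_total`` genes in both genotypes
    combined are never flagged (noise suppression for tiny categories).
    """
    rows = []
    for cat in sorted(set(counts_a) | set(counts_b)):
        a = counts_a.get(cat, 0)
        b = counts_b.get(cat, 0)
        if a < 0 or b < 0:
            raise ValueError(f"category {cat}: negative count")
        if a == b:
            fold, direction = 1.0 if a else float("nan"), "equal"
        else:
            hi, lo = max(a, b), min(a, b)
            fold = math.inf if lo == 0 else hi / lo
            direction = label_a if a > b else label_b
        flagged = (
            not math.isnan(fold)
            and fold >= threshold
            and (a + b) >= min_total
        )
        rows.append({
            "category": cat, f"count_{label_a}": a, f"count_{label_b}": b,
            "fold": fold, "direction": direction, "flagged": flagged,
        })
    frame = pd.DataFrame(rows)
    return FoldDifferenceReport(frame=frame, threshold=threshold,
                                min_total=min_total)


def gene_family_cre_fraction(
    family_genes: Iterable[str],
    profile: CREPresenceProfile,
    motifs: Sequence[str] = ("ABRE", "DRE", "ERE"),
) -> pd.DataFrame:
    """Per-motif carrier count and percent within a gene family.

    The denominator is the full (deduplicated) family size; family
    members missing from the profile are reported in the ``missing``
    count and necessarily count as non-carriers.
    """
    family = list(dict.fromkeys(family_genes))
    if not family:
        raise ValueError("empty gene family")
    missing = [g for g in family if g not in profile.genes]
    if missing:
        logger.warning("%d family genes absent from profile: %s",
                       len(missing), missing[:5])
    rows = []
    for m in motifs:
        carriers = sum(
            1 for g in family if m in profile.genes.get(g, frozenset()))
        rows.append({
            "motif": m,
            "family_size": len(family),
            "carriers": carriers,
            "missing_from_profile": len(missing),
            "percent": round(100.0 * carriers / len(family), 1),
        })
    return pd.DataFrame(rows, columns=[
        "motif", "family_size", "carriers", "missing_from_profile", "percent"])
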