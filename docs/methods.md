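# Methods

## Promoter definition and extraction

The promoter is the window of `promoter_length` (default 1,000) bp
immediately 5′ of the translation start — the 'A' of the ATG — not of a
transcription start site, since the gene models carry no TSS
annotation. The 5′UTR is therefore inside the window. For a '+' gene
with translation start *s* the window is the genomic slice
[s−L, s−1]; for a '−' gene it is [s+1, s+L] reverse-complemented.
Windows truncated at a contig edge are retained and flagged incomplete;
they participate in scanning and occurrence totals but are excluded
wherever completeness is required (positional density profiles,
ortholog-group selection). Promoters overlapping a neighbouring gene
are deliberately **not** clipped — the analysis treats the upstream
window as a fixed-width feature of the gene, and clipping would make
windows incomparable across genes.

## Motif model

Elements are short literal IUPAC patterns; a pattern compiles to its
full expansion set (e.g. `RCCGAC` → {ACCGAC, GCCGAC}), and scanning is
exact membership of each window in that set. Consequences that the
statistics rely on:

- overlapping occurrences are all counted (occurrence totals can exceed
  carrier-promoter counts, which is what makes the mean-per-positive
  statistic informative);
- an unknown residue (N) is never a member of any expansion, so windows
  containing N cannot match, for any pattern including pattern-side N;
- matching is mismatch-free; there is no score threshold to choose.

The default scan is **sense-strand only**. The built-in elements are
defined as literal coding-strand sequences, and sense-only scanning
gives the most conservative per-promoter bookkeeping; `strands="both"`
reports antisense hits at the sense offset of the window's first base.
Neither mode is claimed to be "the" convention used in any particular
published scan — double-strand counting roughly doubles expected
occurrences and is exposed both in the scanner and as
`strand_factor` in the enrichment null.

## Occurrence statistics

With O_e occurrences in G_e of T promoters: relative content
100·O_e/ΣO_f, mean per positive O_e/G_e, rarity G_e/T. The null model
is i.i.d. bases at the frequencies measured on the scanned promoter set
itself (N bases excluded from numerator and denominator); the element
probability is the product over pattern positions of summed allowed-
base frequencies, which equals the sum over expansion words of
per-word probabilities. Expected occurrences are
E_e = Σ_promoters (len − N + 1)·p_e·strand_factor and the primary
enrichment figure is occurrence-level O_e/E_e. A gene-level variant
divides carriers by the binomially expected number of promoters with at
least one hit; in the rare-element regime (p_e·L ≪ 1) the two agree,
and both are always reported, labelled. No analytical p-values are
attached to enrichment and no multiple-testing correction is applied —
the statistic is descriptive.

Display rounding follows the conventional table layout: percentages to
1 decimal, per-carrier means and fractions to 4 decimals. Rounding is
applied in the reporting functions, so the documented worked examples
are exact.

## Positional density

Hits over complete promoters are binned by distance to the ATG in
`bin_width` = 50 bp bins, bin k covering ((k−1)·50, k·50]. Distance is
measured from the motif's **3′ end** (a motif ending on the last
promoter base has distance 1): the proximal edge is where boundary
effects matter most, and anchoring there keeps the first bin exact. A
5′-end mode is available. A bin width that does not divide the promoter
length leaves a ragged last bin, which is flagged on the profile.

## Combinations and ortholog groups

A promoter's presence set is the set of elements with ≥1 occurrence.
Combination counts are reported both *inclusively* (a triple-carrier
counts toward every pair and the triple) and *exclusively* (the 2³−1
partition by exact presence set). A combination is a property of a
single promoter: elements split across paralogs never make a
combination.

Ortholog groups are compared over the groups complete for the profiled
species set (≥1 gene of every species), with member genes restricted to
those having analyzed complete promoters. The default multi-copy rule
is **any_gene** (a group is present in a species if at least one member
gene there carries the target); `all_genes` is the strict alternative.
any_gene is the weakest reading of "groups with promoters containing
the element" and is configurable precisely because it is an assumption.
The Venn partition classifies each group by the exact subset of species
where it is present; "common" is the full-subset count.

## Variant calling and region stratification

Variants come from a column walk over a pairwise alignment of contig
pairs: mismatch columns → SNPs; maximal gap runs on the reference line
→ insertions; on the query line → deletions. Polarity is named from the
reference's perspective. Positions are 1-based reference coordinates;
an INDEL sits at its first affected reference base (for insertions, the
base after the run). After stripping VCF anchor bases the allele
representation is empty-sided (INS: ref="", DEL: alt=""), so
`indel_length` equals the non-empty allele length and feeds the length
classes directly: ultra 1–2, micro 3–10, mini 11–50, midi 51–100 bp.
Events longer than 100 bp are tallied separately and excluded from the
class shares. Columns containing N emit nothing.

Every genomic position gets exactly one finest label with precedence
**exon > intron > promoter > intergenic** (a base inside an annotated
exon is most specifically exonic, even where a neighbour's promoter
window overlaps it); "gene" is exon ∪ intron. Rates are reported per kb
and as "1 per N bp" (N = bp/count; infinite sentinel at zero counts).
The promoter vs gene-body contrast uses per-gene per-kb rates and a
two-sided **Welch** (unequal-variance) t-test: promoter and gene-body
rate variances have no reason to be equal, so the pooled-variance test
flavor is not used.

## The simulator and what passing tests mean

`synthetic_data` emits the exact formats the readers consume. Ground
truth is always *recomputed from the emitted sequences* by a
brute-force window-enumeration oracle — never trusted from planting
intent — so incidental background matches are part of the truth and
statistics tests see realistic nulls.

Defaults, with the reasoning:

- background composition 36.6% GC, the measured composition of the
  cucumber assembly the analysis was designed around;
- gene structure ~5 exons of ~200 bp with ~440-bp introns and ~1–2 kb
  intergenic pads (lengths drawn uniformly within ±50% of the mean),
  matching typical compact plant gene models;
- motif planting rates λ = 0.03/0.02/0.01 per promoter for
  ABRE/DRE/ERE: together with the expected background at 36.6% GC
  (≈0.036 ABRE, ≈0.18 DRE, ≈0.012 ERE per 994-window promoter) these
  give per-promoter totals of the order observed in real cucumber
  promoter sets. Note that DRE is *background-dominated* at this
  composition — which is exactly why its real-data enrichment sits near
  1 while ERE's sits near 2;
- positional bias: 3× planting weight in the six 50-bp bins nearest the
  ATG, the qualitative proximal clustering real profiles show;
- ortholog sets: each group seeded with a motif complement
  (each element included with probability 0.5), each of 5 mock species
  independently retaining each complement motif with probability 0.85 —
  an element-shuffling model in which expected common-to-all counts
  follow the product of retention probabilities;
- variant rates per kb: SNPs 14.89 (promoter) / 4.60 (exon, intron) /
  4.22 (intergenic); INDELs 3.87 / 1.34 / 2.53 — the promoter:gene-body
  contrast of roughly 3:1 the analysis is meant to detect; deletions
  twice as frequent as insertions; length classes drawn at
  60/25/14/1% (insertions) and 85/10/4.5/0.5% (deletions) across
  ultra/micro/mini/midi, dominated by 1–2-bp events. Planted INDELs
  keep ≥1 untouched reference base between events so the planted script
  and the column-walk caller agree record for record.

Motif plants overwrite background bases (promoter length never
changes); overlapping plants are re-sampled up to 50 times and then
dropped. Identical configuration and seed reproduce byte-identical
artifacts.

What the simulator does **not** emulate: repeat and SSR landscapes,
rearrangements, phylogenetic sequence evolution along a tree (species
are independent given the complement), linkage between neighbouring
variants, alignment error. Passing recovery tests therefore
demonstrates the correctness of the bookkeeping and the statistics
under the stated generative model — not robustness to assembly
artifacts or alignment noise in real genome comparisons.

## Numerical and edge-case conventions

- Coordinates 1-based inclusive everywhere at module boundaries.
- Degenerate inputs: empty promoter sets and all-zero occurrence tables
  raise; zero-carrier motifs are omitted from per-carrier means; zero
  variant counts report an infinite "1 per N bp" sentinel; identical
  rate vectors give t = 0, p = 1.
- Readers warn and skip structurally invalid genes and off-contig
  variants rather than aborting a whole file; duplicate ortholog
  membership rows are deduplicated with a log entry, while a gene in
  two *different* groups is an error.
- The two-genotype fold filter treats a zero count as infinite fold but
  suppresses flags for categories with fewer than 3 genes combined
  (configurable) — tiny categories otherwise flag on noise.

## Problem sizes used in the checks

The statistical checks run at sizes where 3-standard-error bands are
decisive: 1,000 promoters for scanner/oracle equivalence, 5,000 for
null calibration and positional-bias recovery, 150 five-species groups
for retention, and a ~2.4-Mb / 500-gene genome (≥100 kb for the exact
round-trip check) for variant-rate recovery and the promoter contrast.

## Known limitations

- Exact-match scanning cannot represent degenerate binding beyond IUPAC
  codes; no PWM support by design.
- The enrichment null is i.i.d. at global promoter composition; local
  composition heterogeneity (e.g. TATA-proximal AT-richness) is not
  modelled, so real-data enrichment factors carry that caveat.
- The column-walk caller requires a given pairwise alignment; it does
  not align, and ambiguous gap placement in the input propagates to
  variant coordinates.
- Ortholog groups are an input; no orthology inference is performed.
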