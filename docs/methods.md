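# Methods

## Scope and model

`exocnv` post-processes per-sample CNV segment calls from an exome
read-depth caller and classifies assembled events with a point-based
dosage framework. It does not infer copy number from reads (the caller's
QS and CN are inputs), does not compute in-silico deleteriousness scores
(ingested as annotations when present), and does not curate gene-disease
validity (ingested as a dosage table).

## Coordinates and overlap primitives

Internal coordinates are 0-based half-open; GFF3 and VCF (1-based) are
converted at the I/O boundary and human-readable output is 1-based
inclusive (`chr1:197438450-197439442` style). Reciprocal overlap is
`min(overlap/len(a), overlap/len(b))`: symmetric, 1 only for identical
intervals, 0 across chromosomes. Array probes are treated as points (their
BED start); a probe is "within" a CNV when that point falls in the CNV's
half-open span. The probe-boundary convention is configurable in
principle but point-probes are the default because CGH probes assay an
effectively point-like locus relative to CNV scale.

## Same-allele matching and in-cohort frequency

Two calls (or a call and a population-panel SV) represent the same allele
when they have the same SV type and reciprocal overlap of at least 50%
(both > 5 kb) or 10% (either ≤ 5 kb; a mixed-size pair takes the
permissive threshold, since the size classes are defined per SV and a
mixed pair is otherwise unspecified). Cohort allele clusters are the
transitive closure (single linkage) under this rule, computed with a
per-chromosome sweep and union-find; carrier frequency is distinct
carriers / cohort size. Clustered frequency is used rather than
exact-coordinate matching because read-depth breakpoints are exon-grid
estimates and recurrent alleles rarely reproduce coordinates exactly.

**Small-cohort frequency filtering.** The mode-of-inheritance filters
retain calls strictly below 0.1% (dominant) or 1% (recessive). Those
limits presuppose a cohort of thousands: at n = 100 a singleton already
sits at 1/n = 0.01 and would be discarded by the very filter it should
survive. The pipeline therefore feeds the filter the carrier fraction
among the *other* samples (leave-proband-out), which converges to the
full-cohort frequency as n grows, while the high-confidence flag keeps
the full-cohort frequency with its inclusive ≤ 0.01 comparison. Both
frequencies are available on the `Callset` API.

## Filters

QS gates use greater-or-equal comparisons at 50 (duplication), 100
(heterozygous deletion) and 400 (homozygous deletion, CN = 0); the
"QS>50"-style shorthand common in the field denotes these thresholds, and
the equal-or-greater reading is used because the high-confidence
definition spells it out. A `--no-qs-filter` mode retains low-quality
calls for the second-pass analysis style in which phenotype or an
in-trans variant justifies rescuing a weak call. A sample is high-quality
with ≤ 200 autosomal raw calls of which ≥ 35 have QS > 20 (strict, as
printed). The high-confidence flag requires all four of: high-quality
sample, cluster frequency ≤ 0.01, ≥ 3 exons overlapped, QS gate passed.

## Event assembly

Read-depth callers fragment large CNVs. In practice fragments are
rejoined by eye on the copy-number plot; `exocnv` substitutes a
reproducible rule: same-sample, same-chromosome, same-type calls merge
transitively when consecutive calls are ≤ `max_gap_bp` apart (default
1 Mb) and no opposite-direction call lies in the gap. The default gap is
deliberately conservative — intra-arm fragmented events in exome data are
separated by uncovered intervals far below 1 Mb, while unrelated events
on one chromosome are typically much farther apart. Merging is
order-independent and idempotent; an event's span is the union of its
components and its QS the component maximum.

Two or more events within 2 Mb on one chromosome in one sample
(del/dup or a paired same-type pattern) are flagged as suspected complex
SVs. No quantitative criterion separates a true complex rearrangement
from coincidental nearby calls; the window is a heuristic and is
configurable. Orthogonal validation records (method, resolved type,
optional breakpoints) overwrite an event's resolved type — covering the
observed failure modes where a read-depth "deletion" is really a
mobile-element insertion or part of a paired deletion–inversion.

## Annotation

Protein-coding gene counts are recorded per annotation source, and events
whose counts differ between sources are flagged discordant. Scoring uses
the most conservative (lowest-count) source by default — curated
databases undercount relative to comprehensive genome annotations, and a
conservative count avoids awarding gene-number points on annotation
noise; the source is overridable per run. An event is intragenic when it
overlaps exactly one gene and both endpoints fall within that gene's
span. Microarray detectability requires ≥ 5 probes within the event span
(union span for complex events). `threshold_metrics` evaluates an
ingested deleteriousness score at a cutoff (strictly-greater calls):
TPR/FPR and per-class medians, with empty classes reported as missing.
For fragmented events an externally supplied score should describe the
merged span; failing that the component maximum is used, since fragment
scores systematically understate the full event.

## Classification engine

Evidence strengths map to points (0.90/0.45/0.30/0.15); items sum to a
total classified as P ≥ 0.99, LP ≥ 0.90, B ≤ −0.99, LB ≤ −0.90, else
VUS (float comparisons carry a 1e-9 guard). All constants, caps, ranges
and the X-linked branch table are one `ScoringScheme` dataclass,
YAML round-trippable.

* **Gene number**: binned points as in the README. The printed deletion
  bins leave exactly 35 unassigned ("25–34", "more than 35"); 35 scores
  0.9 here to keep the bins contiguous, and the bins are configurable.
* **LoF (PVS1-style)**: deletions always LoF-eligible; insertions when
  they land in an exon; inversions when exactly one breakpoint is inside
  the gene, or both are and ≥ 1 exon is spanned (an inversion enclosing a
  whole gene leaves it intact); duplications only when explicitly
  configured as disruptive, since an intragenic in-frame duplication may
  be rescued. Strength: full-gene removal, or a frameshifting loss whose
  premature stop lies > 50 nt upstream of the last exon–exon junction
  (NMD predicted), earns the full 0.90; NMD-escaping losses step down by
  removed coding fraction (> 10% strong, > 5% moderate, else supporting).
  The premature stop is approximated at the first affected coding
  position in translation order, which is exact for contiguous deletions
  in fully annotated transcripts.
* **Recessive cases**: the adapted in-trans table with its caps
  (homozygous aggregate ≤ 0.30, in-trans-VUS aggregate ≤ 0.16,
  phase-unknown VUS = 0). Proband-derived points are capped at 0.90 —
  one full "strong" of case evidence, consistent with how in-trans
  evidence aggregates for sequence variants — and the once-per-variant
  phenotype bonus is added after that cap, so a richly phenotyped series
  can reach at most 0.90 + 0.30. Phenotype and functional points may
  co-occur on one observation; nothing in the framework forbids it and
  they measure different things.
* **X-linked cases**: a branch table over proband sex × inheritance ×
  carrier-parent affected status, each case adjusted by phenotype
  specificity and capped at 0.45. The published framework gives no branch
  values, so the defaults (e.g. 0.45 for a confirmed de novo hemizygous
  male, stepping down with weaker segregation) are this package's own
  explicitly non-anchored calibration; the table ships as configuration.
* **De novo**: confirmed 0.45, assumed 0.30 (configurable).
* **Complex events** are classified per canonical component and take the
  most deleterious component classification (B < LB < VUS < LP < P);
  the rule is associative and order-independent.

## Synthetic data

The generator emulates the structure of a rare-disease exome callset on a
~48-Mb five-contig toy genome: up to 400 non-overlapping genes (10 exons
of 160/161 bp, 840-bp introns, fully coding), two annotation sources that
disagree (the curated-like source omits every 10th gene of each dominant
block: 36 vs 40), a Poisson probe set at 0.1 probes/kb, a 100-entry
population panel mixing common and rare alleles, and a dosage table of
established recessive and X-linked genes. Per sample it draws 60–140
autosomal artifact calls at recurrent hotspot loci — below the analysis
QS gate, with ≥ 40 above QS 20 so samples pass QC, acquiring high cohort
frequencies exactly as systematically noisy read-depth loci do — plus
Poisson-distributed rare high-quality benign CNVs calibrated (mean 3.0,
before allele-cluster collisions remove multi-carrier loci) so the
per-sample count of rare high-confidence calls has median ≈ 2.

Implants: de novo deletions over family-specific 40-gene blocks (a
configurable fraction fragmented into 2–6 pieces with ≤ 5-kb gaps),
intragenic frameshifting three-exon deletions in established recessive
genes paired with an in-trans pathogenic point variant, hemizygous
deletions in male probands of the X-linked gene, and one common deletion
carried by 5% of samples that the frequency filters must remove.
Exon-length placement makes every implant's LoF strength deterministic
(frameshift + NMD → 0.90), so expected classifications are exact:
dominant 0.90 + 0.45 = 1.35 → P; recessive 0.90 + 0.30 = 1.20 → P;
X-linked 0.90 + 0.45 = 1.35 → P. Each implant occupies its own locus:
in a 15,000-sample cohort a recurrent causal allele sits far below the
frequency limits, but in a 100-sample emulation allele-sharing across
families would misrepresent exactly the frequencies under test.

What the generator does not emulate — and what passing tests therefore do
not show about real data: breakpoint uncertainty and exon-grid coordinate
error, batch/coverage structure, overlapping genes and partial-coding
transcripts, population stratification in the panel, and artifact loci
that overlap real genes. Recovery results on this cohort validate the
plumbing and the arithmetic of the engine, not caller performance.

## Problem sizes and numerics

Default test/demo cohorts use 100 samples (~10,000 raw calls), a size at
which the full pipeline runs in seconds while still exercising every
filter, the clustering sweep and fragment reassembly. Clustering equals
an all-pairs transitive-closure oracle on instances of ≤ 200 calls;
overlap and probe counting equal brute-force oracles on 1,000 random
instances. Ties and degenerate inputs: zero-length intervals are
rejected at construction; duplicate probe positions count once;
classification totals are rounded to 10 decimals before thresholding;
empty evidence lists classify VUS; empty score classes report missing
medians rather than NaN.

## Known limitations

The merge and complex-SV rules are reproducible surrogates for manual
copy-number-plot review, not validated breakpoint logic. LoF strength for
inversions is coarse (qualifying inversions score as full LoF). Ploidy is
assumed diploid when reading segment files; hemizygous male chrX losses
must be encoded as CN 0. The X-linked point table is configuration, not
literature. Benign-direction evidence beyond frequency filtering (e.g.
population-panel overlap as formal benign points) is annotation only.
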