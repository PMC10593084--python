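# exocnv

Post-processing, filtering and quantitative pathogenicity classification of
germline copy-number variants (CNVs) called from exome read-depth data.

Read-depth callers such as GATK-gCNV emit per-sample segment calls — an
interval, a copy number (CN) and a quality score (QS) — across a cohort.
Turning that raw callset into clinically interpretable events requires a
chain of standard but fiddly steps: per-sample QC, in-cohort allele
clustering and frequency filtering by mode of inheritance, reassembly of
large CNVs fragmented into multiple calls, gene/exon annotation against
one or more gene models, matching against a population SV panel,
microarray-detectability assessment, and finally a point-based
ACMG/ClinGen-style classification. `exocnv` implements that chain for
analysts of rare-disease exome cohorts, with extensions the published
dosage framework does not cover: case-evidence scoring for
autosomal-recessive (an adapted in-trans/PM3-style table) and X-linked
conditions, functional-evidence points, loss-of-function (PVS1-style)
evaluation of deletions, insertions and inversions, and a
most-deleterious-component rule for complex rearrangements.

## The scoring model

Evidence lines carry points on the familiar strength scale — very strong
0.90, strong 0.45, moderate 0.30, supporting 0.15 — and sum to a total
classified on the five-tier scale: total ≥ 0.99 pathogenic (P), ≥ 0.90
likely pathogenic (LP), ≤ −0.99 benign (B), ≤ −0.90 likely benign (LB),
otherwise a variant of uncertain significance (VUS). The shipped defaults
encode, among others:

* **gene number** — deletions: 0 points for 0–24 protein-coding genes,
  0.45 for 25–34, 0.9 for ≥ 35; duplications: 0 for 0–34, 0.45 for 35–49,
  0.9 for ≥ 50;
* **recessive case evidence** (per proband) — 0.30 for a confirmed
  in-trans P/LP second variant; 0.15 / 0.08 for phase-unknown P / LP;
  0.15 per homozygous occurrence (capped at 0.30); 0.08 for an in-trans
  VUS (capped at 0.16); plus a once-per-variant phenotype-specificity
  bonus of 0.15 (0.30 when particularly strong);
* **functional evidence** — 0.15 / 0.30 / 0.45 for supporting / moderate /
  strong;
* **filters** — QS gates of 50 (duplication), 100 (heterozygous deletion)
  and 400 (homozygous deletion); same-allele matching at 50% reciprocal
  overlap for SVs > 5 kb and 10% below; frequency limits of 0.1%
  (dominant) and 1% (recessive); the four-part high-confidence flag
  (high-quality sample, frequency ≤ 0.01, ≥ 3 exons, QS gate); ≥ 5 array
  probes for microarray detectability.

All point values, caps, classification ranges and the X-linked branch
table live in a single editable `ScoringScheme` (YAML-serializable).

## Worked example

A de novo ~857-kb duplication whose protein-coding gene count depends on
which annotation database you ask (28 under a curated source, 35 under a
comprehensive one):

```python
from exocnv import SVType, aggregate, score_gene_number
from exocnv.classify import EvidenceItem

for n_genes in (28, 35):
    items = [
        score_gene_number(SVType.DUP, n_genes),
        EvidenceItem("5-de-novo", 0.45, "confirmed", "trio-confirmed de novo"),
    ]
    res = aggregate(items)
    print(f"{n_genes} protein-coding genes: total = {res.total:.2f} -> {res.classification.value}")
```

prints

```
28 protein-coding genes: total = 0.45 -> VUS
35 protein-coding genes: total = 0.90 -> LP
```

— with 28 genes the duplication earns no gene-number points and the de
novo observation alone leaves it a VUS; at 35 genes the 0.45-point
gene-number line moves it into the likely-pathogenic band. This is why
`exocnv` records gene counts per annotation source and flags
source-discordant events rather than silently picking one number.

## Command line

```bash
# write a fully synthetic reference + cohort with a truth table
exocnv simulate --seed 1 --n-samples 100 --outdir demo/

# run the whole pipeline: QC, cluster, filter, merge, annotate, classify
exocnv run \
  --segments demo/segments.tsv \
  --gene-model demo/genes_curated.gff3 gff3 curated \
  --gene-model demo/genes_comprehensive.gff3 gff3 comprehensive \
  --probes demo/probes.bed --panel demo/panel.bed \
  --dosage demo/dosage.tsv --observations demo/observations.json \
  --outdir demo/out
```

Outputs: `events.bed`/`events.json` (assembled events with component
provenance), `classified.tsv` (one row per event with gene content,
population-panel match, probe counts and classification),
`evidence.tsv` (one row per evidence line), summary count tables and a
`report.json` with stage counters and the settings used.

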