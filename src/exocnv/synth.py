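"""Synthetic references and cohorts with known truth.

Generates everything the pipeline consumes — gene models from two
annotation sources that disagree on gene counts, an array probe set, a
population SV panel, a dosage/disease-gene table, per-sample CNV segment
calls with realistic quality-score structure, a pedigree and per-proband
case observations — plus a truth table tying each implanted event to its
expected downstream fate.

The cohort emulates the structure of a rare-disease exome callset: every
sample carries a raw-call burden dominated by low-quality artifacts (kept
below the per-sample QC ceiling, with enough QS>20 calls to pass sample
QC), a couple of rare high-quality benign CNVs per sample, and a small
number of families carry implanted causal events: multi-gene de novo
deletions (dominant), intragenic frameshifting deletions in trans with a
pathogenic point variant (recessive), hemizygous deletions in male
probands (X-linked), and a common deletion present in 5% of samples that
the mode-of-inheritance frequency filters must reject. A configurable
fraction of the large dominant deletions is deliberately fragmented into
2-6 pieces to exercise event reassembly.

Causal implants are placed at family-specific loci (each dominant family
has its own multi-gene block; recessive and X-linked families take
non-overlapping exon runs or separate genes), reflecting that in the
source cohort a rare causal allele is far below the frequency limits —
at 100 samples an allele shared across families would not be.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .annotate import PopulationSV, write_dosage_table, write_population_panel
from .callset import Callset, CNVCall, SVType, write_segments_tsv, write_segments_vcf
from .classify import CaseObservation, DosageRecord
from .genome import (
    Biotype,
    GeneModel,
    GenomicInterval,
    ProbeSet,
    Transcript,
    write_gene_model,
    write_probes,
)

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "Reference",
    "Cohort",
    "generate_reference",
    "generate_cohort",
    "write_reference",
    "write_cohort",
    "read_truth",
    "read_observations",
]

# Gene architecture: 10 exons, 840-bp introns; exons 2 and 6 are 161 bp
# (others 160), so any deletion run containing one of them shifts the
# reading frame. Two disjoint frameshifting exon runs (exons 2-4 and 6-8)
# are available per gene for non-clustering recessive/X-linked implants.
N_EXONS = 10
EXON_LEN = 160
ODD_EXON_INDICES = (1, 5)
ODD_EXON_LEN = 161
INTRON_LEN = 840
EXON_RUNS = ((1, 3), (5, 7))  # 0-based inclusive; both frameshift + NMD
GENE_SPACING = 50_000
GENE_SPAN = (N_EXONS - 2) * EXON_LEN + 2 * ODD_EXON_LEN + (N_EXONS - 1) * INTRON_LEN

AD_BLOCK_GENES = 40  # curated source annotates 36 of them
AD_BLOCK_SPACING = 2_000_000
MAX_AD_FAMILIES = 3
MAX_AR_FAMILIES = 4
MAX_XL_FAMILIES = 2

CONTIGS = {
    "chr1": 12_000_000,
    "chr2": 8_000_000,
    "chr3": 8_000_000,
    "chr4": 8_000_000,
    "chrX": 8_000_000,
}


@dataclass
class SynthConfig:
    seed: int = 1
    n_samples: int = 100
    n_genes: int = 400  # total including the three 40-gene dominant blocks
    probe_density_per_kb: float = 0.1
    panel_size: int = 100
    # implant plan
    n_ad_families: int = 3
    n_ar_families: int = 3
    n_xl_families: int = 2
    benign_carriers: int = 5  # 5% carrier frequency at the default cohort size
    # noise model
    fragmentation_prob: float = 0.5
    fragment_range: tuple[int, int] = (2, 6)
    # drawn so the per-sample count of rare high-confidence calls has median
    # ~2 after allele clustering removes multi-carrier collisions
    rare_benign_mean_per_sample: float = 3.0
    noise: bool = True

    def __post_init__(self) -> None:
        if not 130 <= self.n_genes <= 400:
            raise ValueError("gene layout supports 130-400 genes on the fixed contigs")
        if not 0.0 <= self.fragmentation_prob <= 1.0:
            raise ValueError("fragmentation probability must be in [0,1]")
        if self.probe_density_per_kb <= 0 or self.probe_density_per_kb > 5:
            raise ValueError("infeasible probe density")
        if self.n_ad_families > MAX_AD_FAMILIES:
            raise ValueError(f"at most {MAX_AD_FAMILIES} dominant blocks in the reference")
        if self.n_ar_families > MAX_AR_FAMILIES:
            raise ValueError(f"at most {MAX_AR_FAMILIES} recessive implant loci")
        if self.n_xl_families > MAX_XL_FAMILIES:
            raise ValueError(f"at most {MAX_XL_FAMILIES} X-linked implant loci")


@dataclass
class TruthRecord:
    sample_id: str
    iv: GenomicInterval
    svtype: SVType
    moi: str  # AD | AR | XL | benign
    n_fragments: int
    expected_high_confidence: bool
    expected_classification: Optional[str]  # None: expected to be filtered out


@dataclass
class Reference:
    models: list[GeneModel]  # [conservative curated-like, comprehensive]
    probes: ProbeSet
    panel: list[PopulationSV]
    dosage: dict[str, DosageRecord]
    contig_lengths: dict[str, int]
    ad_blocks: list[GenomicInterval] = field(default_factory=list)
    ar_genes: list[str] = field(default_factory=list)
    xl_gene: str = ""
    benign_gene: str = ""
    background_genes: list[str] = field(default_factory=list)


@dataclass
class Cohort:
    callset: Callset
    ped: list[tuple[str, str, str, str, int, int]]  # fam, id, father, mother, sex, aff
    observations: list[CaseObservation]
    truth: list[TruthRecord]


def _make_gene(gene_id: str, chrom: str, start: int) -> Transcript:
    exons = []
    pos = start
    for i in range(N_EXONS):
        length = ODD_EXON_LEN if i in ODD_EXON_INDICES else EXON_LEN
        exons.append(GenomicInterval(chrom, pos, pos + length))
        pos += length + INTRON_LEN
    span = GenomicInterval(chrom, exons[0].start, exons[-1].end)
    return Transcript(
        gene_id=gene_id,
        gene_name=gene_id,
        biotype=Biotype.protein_coding,
        strand="+",
        exons=exons,
        cds=span,  # fully coding: keeps frame arithmetic transparent
    )


def generate_reference(cfg: SynthConfig) -> Reference:
    """Deterministic reference: gene models, probes, panel, dosage table.

    Layout (disease loci kept >2 Mb from background genes so clustered-call
    heuristics never touch them):

    * chr1 0.1-6.1 Mb — three 40-gene dominant blocks, one per dominant
      family; the curated-like source omits every 10th block gene (36 vs 40
      protein-coding genes, so the sources disagree); chr1 background genes
      start at 8.5 Mb;
    * chr2/chr3/chr4 — background genes from 0.1 Mb; two established
      recessive disease genes at 6 Mb on chr2, the designated benign-locus
      gene at 6 Mb on chr3;
    * chrX — the established X-linked gene at 0.2 Mb, X background genes
      from 2.5 Mb.
    """
    rng = np.random.default_rng(cfg.seed)

    curated: list[Transcript] = []
    comprehensive: list[Transcript] = []
    background: list[str] = []
    gid = 0

    def next_gene(chrom: str, start: int, in_curated: bool = True) -> Transcript:
        nonlocal gid
        gid += 1
        t = _make_gene(f"GENE{gid:04d}", chrom, start)
        comprehensive.append(t)
        if in_curated:
            curated.append(t)
        return t

    ad_blocks = []
    for b in range(MAX_AD_FAMILIES):
        block_start = 100_000 + b * AD_BLOCK_SPACING
        block_genes = [
            next_gene("chr1", block_start + i * GENE_SPACING, in_curated=(i % 10 != 9))
            for i in range(AD_BLOCK_GENES)
        ]
        ad_blocks.append(
            GenomicInterval("chr1", block_genes[0].span.start, block_genes[-1].span.end)
        )

    n_background = max(cfg.n_genes - (MAX_AD_FAMILIES * AD_BLOCK_GENES + 4), 16)
    per_chrom = {
        "chr1": n_background // 4,
        "chr2": n_background // 4,
        "chr3": n_background // 4,
        "chr4": n_background - 3 * (n_background // 4),
    }
    offsets = {"chr1": 8_500_000, "chr2": 100_000, "chr3": 100_000, "chr4": 100_000}
    for chrom, count in per_chrom.items():
        for i in range(count):
            t = next_gene(chrom, offsets[chrom] + i * GENE_SPACING)
            background.append(t.gene_id)

    ar_genes = [next_gene("chr2", 6_000_000 + i * GENE_SPACING).gene_id for i in range(2)]
    benign_gene = next_gene("chr3", 6_000_000)
    xl_gene = next_gene("chrX", 200_000)
    for i in range(5):  # X background (not autosomal: excluded from sample QC burden)
        t = next_gene("chrX", 2_500_000 + i * GENE_SPACING)
        background.append(t.gene_id)

    models = [
        GeneModel(transcripts=curated, source_label="curated"),
        GeneModel(transcripts=comprehensive, source_label="comprehensive"),
    ]

    # probes: Poisson process at the configured density per contig
    probes = []
    for chrom, length in CONTIGS.items():
        n = rng.poisson(cfg.probe_density_per_kb * length / 1_000)
        starts = np.sort(rng.integers(0, length, size=n))
        probes.extend(GenomicInterval(chrom, int(s), int(s) + 1) for s in starts)
    probe_set = ProbeSet(probes=probes, platform_label="synthetic-cgh")

    # population panel: the benign locus as a common allele, plus common and
    # rare entries over background genes
    panel: list[PopulationSV] = [
        PopulationSV(
            iv=_benign_locus(benign_gene),
            svtype=SVType.DEL,
            af=cfg.benign_carriers / cfg.n_samples,
            panel_label="synthetic-panel",
        )
    ]
    all_by_id = {t.gene_id: t for t in comprehensive}
    bg_choices = rng.choice(background, size=cfg.panel_size - 1, replace=True)
    for i, g in enumerate(bg_choices):
        t = all_by_id[str(g)]
        af = float(rng.uniform(0.01, 0.10)) if i % 5 == 0 else float(10 ** rng.uniform(-4.5, -2.5))
        svtype = SVType.DEL if rng.random() < 0.6 else SVType.DUP
        jitter = int(rng.integers(-400, 400))
        start = max(0, t.span.start - 400 + jitter)
        panel.append(
            PopulationSV(
                iv=GenomicInterval(t.chrom, start, t.span.end + 400 + jitter),
                svtype=svtype,
                af=af,
                panel_label="synthetic-panel",
            )
        )

    dosage = {g: DosageRecord(g, "AR", established=True) for g in ar_genes}
    dosage[xl_gene.gene_id] = DosageRecord(xl_gene.gene_id, "XL", established=True)

    return Reference(
        models=models,
        probes=probe_set,
        panel=panel,
        dosage=dosage,
        contig_lengths=dict(CONTIGS),
        ad_blocks=ad_blocks,
        ar_genes=ar_genes,
        xl_gene=xl_gene.gene_id,
        benign_gene=benign_gene.gene_id,
        background_genes=background,
    )


def _benign_locus(t: Transcript) -> GenomicInterval:
    return GenomicInterval(t.chrom, t.span.start - 400, t.span.end + 400)


def _exon_run_span(t: Transcript, first: int, last: int, margin: int = 200) -> GenomicInterval:
    return GenomicInterval(t.chrom, t.exons[first].start - margin, t.exons[last].end + margin)


def generate_cohort(ref: Reference, cfg: SynthConfig) -> Cohort:
    """Generate per-sample calls, pedigree, observations and truth records."""
    rng = np.random.default_rng(cfg.seed + 1)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    sexes = {s: (1 if i % 2 == 0 else 2) for i, s in enumerate(samples)}  # PED codes

    need = cfg.n_ad_families + cfg.n_ar_families + cfg.n_xl_families + cfg.benign_carriers
    if need > cfg.n_samples:
        raise ValueError("implant plan exceeds cohort size")
    if cfg.n_ad_families > len(ref.ad_blocks):
        raise ValueError("implant plan exceeds reference dominant blocks")

    comprehensive = ref.models[1]
    by_id = {t.gene_id: t for t in comprehensive.transcripts}
    xl_t, benign_t = by_id[ref.xl_gene], by_id[ref.benign_gene]

    calls: list[CNVCall] = []
    truth: list[TruthRecord] = []
    observations: list[CaseObservation] = []
    ped: list[tuple[str, str, str, str, int, int]] = []
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        chosen = samples[cursor : cursor + n]
        cursor += n
        return chosen

    # --- dominant: de novo multi-gene deletion, one block per family
    for i, s in enumerate(take(cfg.n_ad_families)):
        block = ref.ad_blocks[i]
        span = GenomicInterval(block.chrom, block.start - 5_000, block.end + 5_000)
        qs = int(rng.integers(500, 3000))
        n_frag = 1
        if cfg.noise and rng.random() < cfg.fragmentation_prob:
            n_frag = int(rng.integers(cfg.fragment_range[0], cfg.fragment_range[1] + 1))
        for frag in _fragment(span, n_frag, rng):
            calls.append(CNVCall(s, frag, SVType.DEL, cn=1, qs=qs))
        truth.append(TruthRecord(s, span, SVType.DEL, "AD", n_frag, True, "P"))
        observations.append(
            CaseObservation(proband_id=s, sex="M" if sexes[s] == 1 else "F", de_novo="confirmed")
        )
        ped.append((f"F_{s}", s, f"{s}_fa", f"{s}_mo", sexes[s], 2))

    # --- recessive: intragenic frameshifting deletion in trans with a
    # pathogenic point variant; each family takes its own locus (gene x run)
    for j, s in enumerate(take(cfg.n_ar_families)):
        gene = ref.ar_genes[j // len(EXON_RUNS)]
        run = EXON_RUNS[j % len(EXON_RUNS)]
        span = _exon_run_span(by_id[gene], *run)
        qs = int(rng.integers(150, 1000))
        calls.append(CNVCall(s, span, SVType.DEL, cn=1, qs=qs))
        truth.append(TruthRecord(s, span, SVType.DEL, "AR", 1, True, "P"))
        observations.append(
            CaseObservation(
                proband_id=s,
                gene=gene,
                zygosity="het",
                phase="in_trans_confirmed",
                second_variant_class="P",
                sex="M" if sexes[s] == 1 else "F",
                de_novo="inherited_unaffected",
            )
        )
        ped.append((f"F_{s}", s, f"{s}_fa", f"{s}_mo", sexes[s], 2))

    # --- X-linked: hemizygous de novo deletion in a male proband
    for j, s in enumerate(take(cfg.n_xl_families)):
        sexes[s] = 1  # hemizygous male by design
        span = _exon_run_span(xl_t, *EXON_RUNS[j % len(EXON_RUNS)])
        qs = int(rng.integers(450, 1500))
        calls.append(CNVCall(s, span, SVType.DEL, cn=0, qs=qs))
        truth.append(TruthRecord(s, span, SVType.DEL, "XL", 1, True, "P"))
        observations.append(
            CaseObservation(
                proband_id=s, gene=ref.xl_gene, zygosity="hemi", sex="M", de_novo="confirmed"
            )
        )
        ped.append((f"F_{s}", s, f"{s}_fa", f"{s}_mo", 1, 2))

    # --- common benign deletion shared by several carriers
    benign_span = _benign_locus(benign_t)
    for s in take(cfg.benign_carriers):
        qs = int(rng.integers(200, 900))
        calls.append(CNVCall(s, benign_span, SVType.DEL, cn=1, qs=qs))
        truth.append(TruthRecord(s, benign_span, SVType.DEL, "benign", 1, False, None))

    probands = {row[1] for row in ped}
    for s in samples:
        if s not in probands:
            ped.append((f"F_{s}", s, "0", "0", sexes[s], 2))

    # --- per-sample background: artifacts below the QS gate plus a couple of
    # rare high-quality benign CNVs (the exome raw-call burden). Artifacts
    # recur at systematically noisy hotspot loci — as read-depth artifacts
    # do — so they acquire high cohort frequencies and never contaminate
    # the allele clusters of genuine rare gene-level CNVs.
    if cfg.noise:
        bg = [g for g in ref.background_genes if by_id[g].chrom != "chrX"]
        hotspots = [
            GenomicInterval(t.chrom, t.span.end + 10_000, t.span.end + 12_000)
            for t in (by_id[g] for g in bg)
        ]
        for s in samples:
            n_mid = int(rng.integers(40, 80))  # QS>20 but below the analysis gate
            n_low = int(rng.integers(20, 60))
            for qs_lo, qs_hi, count in ((21, 49, n_mid), (1, 20, n_low)):
                for k in rng.integers(0, len(hotspots), size=count):
                    h = hotspots[int(k)]
                    jitter = int(rng.integers(-300, 300))
                    length = int(rng.integers(1_500, 3_000))
                    span = GenomicInterval(h.chrom, h.start + jitter, h.start + jitter + length)
                    svtype = SVType.DEL if rng.random() < 0.5 else SVType.DUP
                    cn = 1 if svtype is SVType.DEL else 3
                    calls.append(
                        CNVCall(s, span, svtype, cn=cn, qs=float(rng.integers(qs_lo, qs_hi + 1)))
                    )
            for _ in range(rng.poisson(cfg.rare_benign_mean_per_sample)):
                t = by_id[str(rng.choice(bg))]
                first = int(rng.integers(0, N_EXONS - 3))
                span = _exon_run_span(t, first, first + 2, margin=int(rng.integers(50, 200)))
                svtype = SVType.DEL if rng.random() < 0.5 else SVType.DUP
                if svtype is SVType.DEL:
                    cn, qs = 1, float(rng.integers(120, 600))
                else:
                    cn, qs = 3, float(rng.integers(60, 600))
                calls.append(CNVCall(s, span, svtype, cn=cn, qs=qs))

    callset = Callset(calls=calls, samples=samples)
    return Cohort(callset=callset, ped=ped, observations=observations, truth=truth)


def _fragment(span: GenomicInterval, k: int, rng: np.random.Generator) -> list[GenomicInterval]:
    """Split a span into k pieces separated by small gaps; union span kept."""
    if k <= 1:
        return [span]
    cuts = np.sort(rng.choice(np.arange(1, 20), size=k - 1, replace=False)) / 20
    edges = [span.start] + [int(span.start + c * span.length) for c in cuts] + [span.end]
    pieces = []
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        gap = min(5_000, (b - a) // 4)
        lo = a + (gap if i > 0 else 0)
        pieces.append(GenomicInterval(span.chrom, lo, b))
    return pieces


# ---------------------------------------------------------------------------
# Writers / readers for the full on-disk bundle


def write_reference(ref: Reference, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_curated": outdir / "genes_curated.gff3",
        "genes_comprehensive": outdir / "genes_comprehensive.gff3",
        "probes": outdir / "probes.bed",
        "panel": outdir / "panel.bed",
        "dosage": outdir / "dosage.tsv",
    }
    write_gene_model(ref.models[0], paths["genes_curated"], format="gff3")
    write_gene_model(ref.models[1], paths["genes_comprehensive"], format="gff3")
    write_probes(ref.probes, paths["probes"])
    write_population_panel(ref.panel, paths["panel"])
    write_dosage_table(ref.dosage, paths["dosage"])
    return paths


def write_cohort(
    cohort: Cohort,
    outdir: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
    segments_format: str = "tsv",
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg_ext = "vcf" if segments_format == "sv_vcf" else "tsv"
    paths = {
        "segments": outdir / f"segments.{seg_ext}",
        "ped": outdir / "cohort.ped",
        "observations": outdir / "observations.json",
        "truth": outdir / "truth.tsv",
    }
    if segments_format == "sv_vcf":
        write_segments_vcf(cohort.callset, paths["segments"], contig_lengths or CONTIGS)
    else:
        write_segments_tsv(cohort.callset, paths["segments"])
    with open(paths["ped"], "w") as fh:
        for row in cohort.ped:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(paths["observations"], "w") as fh:
        json.dump([o.__dict__ for o in cohort.observations], fh, indent=2)
        fh.write("\n")
    with open(paths["truth"], "w") as fh:
        fh.write(
            "sample_id\tchrom\tstart\tend\tsvtype\tmoi\tn_fragments\t"
            "expected_high_confidence\texpected_classification\n"
        )
        for t in cohort.truth:
            fh.write(
                f"{t.sample_id}\t{t.iv.chrom}\t{t.iv.start}\t{t.iv.end}\t"
                f"{t.svtype.value}\t{t.moi}\t{t.n_fragments}\t"
                f"{int(t.expected_high_confidence)}\t{t.expected_classification or 'NA'}\n"
            )
    return paths


def read_truth(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    sample_id=f[0],
                    iv=GenomicInterval(f[1], int(f[2]), int(f[3])),
                    svtype=SVType(f[4]),
                    moi=f[5],
                    n_fragments=int(f[6]),
                    expected_high_confidence=bool(int(f[7])),
                    expected_classification=None if f[8] == "NA" else f[8],
                )
            )
    return records


def read_observations(path: str | Path) -> list[CaseObservation]:
    with open(path) as fh:
        data = json.load(fh)
    return [CaseObservation(**d) for d in data]
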