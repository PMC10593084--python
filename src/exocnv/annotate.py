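"""Event annotation: gene content, population SV matching, microarray
detectability and deleteriousness-score threshold metrics.

Gene-number evidence depends on the annotation source — curated databases
count fewer genes than comprehensive ones — so protein-coding counts are
recorded per source and discordance between sources is flagged. Population
matching applies the same-allele rule (same type, sufficient reciprocal
overlap) against a reference SV panel. Microarray detectability follows the
probe-count criterion: at least five probes within the CNV coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Optional, Sequence

from .callset import SVType, calls_match
from .events import CNVEvent
from .genome import (
    GeneModel,
    GenomicInterval,
    ProbeSet,
    count_overlapping_probes,
    exons_overlapped,
    normalize_chrom,
)

__all__ = [
    "GeneContent",
    "PopulationSV",
    "CMAReport",
    "annotate_gene_content",
    "match_population_sv",
    "cma_detectable",
    "threshold_metrics",
    "read_population_panel",
    "write_population_panel",
    "read_dosage_table",
    "write_dosage_table",
    "CMA_MIN_PROBES",
]

CMA_MIN_PROBES = 5


@dataclass
class GeneContent:
    """Gene/exon content of one event across annotation sources."""

    n_protein_coding: dict[str, int]
    genes: dict[str, list[str]]  # source -> overlapped protein-coding gene ids
    disease_genes: list[str]
    intragenic: bool
    exon_counts: dict[str, int]  # gene id -> exons overlapped (primary source)
    discordant_sources: bool

    def count_for_scoring(self, source: Optional[str] = None) -> int:
        """Protein-coding gene count used for dosage scoring.

        Defaults to the most conservative (lowest-count) source, mirroring
        curated-database practice; pass ``source`` to override.
        """
        if source is not None:
            return self.n_protein_coding[source]
        return min(self.n_protein_coding.values())


@dataclass(frozen=True)
class PopulationSV:
    iv: GenomicInterval
    svtype: SVType
    af: float
    panel_label: str = "panel"

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValueError("allele frequency must be in [0,1]")


@dataclass(frozen=True)
class CMAReport:
    n_probes: int

    @property
    def detectable(self) -> bool:
        return self.n_probes >= CMA_MIN_PROBES


def annotate_gene_content(
    e: CNVEvent,
    models: Sequence[GeneModel],
    dosage: Optional[dict[str, "DosageRecord"]] = None,
) -> GeneContent:
    """Gene and exon content of an event against one or more gene models.

    The first model is the primary source used for exon counts and the
    intragenic determination; all models contribute protein-coding counts.
    """
    if not models:
        raise ValueError("at least one gene model required")
    for m in models:
        if not m.transcripts:
            raise ValueError(f"gene model {m.source_label!r} is empty")
    span = e.span
    n_pc: dict[str, int] = {}
    genes: dict[str, list[str]] = {}
    for m in models:
        pc = sorted(
            {t.gene_id for t in m.query(span) if t.biotype.value == "protein_coding"}
        )
        n_pc[m.source_label] = len(pc)
        genes[m.source_label] = pc

    primary = models[0]
    hits = primary.query(span)
    exon_counts: dict[str, int] = {}
    for t in hits:
        count, _ = exons_overlapped(span, t)
        exon_counts[t.gene_id] = max(exon_counts.get(t.gene_id, 0), count)
    overlapped_gene_ids = sorted({t.gene_id for t in hits})
    intragenic = False
    if len(overlapped_gene_ids) == 1:
        g = overlapped_gene_ids[0]
        intragenic = any(t.span.contains(span) for t in primary.by_gene(g))

    disease = []
    if dosage:
        all_genes = set().union(*genes.values()) if genes else set()
        disease = sorted(g for g in all_genes if g in dosage)

    counts = list(n_pc.values())
    return GeneContent(
        n_protein_coding=n_pc,
        genes=genes,
        disease_genes=disease,
        intragenic=intragenic,
        exon_counts=exon_counts,
        discordant_sources=len(set(counts)) > 1,
    )


def match_population_sv(
    e: CNVEvent, panel: Sequence[PopulationSV]
) -> tuple[list[PopulationSV], float]:
    """Same-allele matches of an event in a population SV panel.

    A panel entry matches when it has the same SV type and reciprocal
    overlap at or above the size-class threshold (50% for pairs >5 kb, 10%
    otherwise). Returns the matches and the maximum allele frequency among
    them (0 when there is no match).
    """
    span = e.span
    matches = [
        p
        for p in panel
        if calls_match(span, e.resolved_type, p.iv, p.svtype)
    ]
    max_af = max((p.af for p in matches), default=0.0)
    return matches, max_af


def cma_detectable(e: CNVEvent, probes: ProbeSet) -> CMAReport:
    """Microarray detectability of an event: >=5 probes within its span.

    Complex events are assessed on the union span of their components.
    """
    return CMAReport(n_probes=count_overlapping_probes(e.span, probes))


def threshold_metrics(
    records: Sequence[tuple[float, bool]], cutoff: float
) -> dict[str, Optional[float]]:
    """TPR/FPR and per-class medians of a deleteriousness score at a cutoff.

    ``records`` pairs a score in [0,1] with a causal/non-causal label; a
    record counts as called when its score is strictly above the cutoff.
    An empty class yields a missing (None) median and rate.
    """
    causal = [s for s, c in records if c]
    noncausal = [s for s, c in records if not c]
    tpr = sum(s > cutoff for s in causal) / len(causal) if causal else None
    fpr = sum(s > cutoff for s in noncausal) / len(noncausal) if noncausal else None
    return {
        "tpr": tpr,
        "fpr": fpr,
        "median_causal": median(causal) if causal else None,
        "median_noncausal": median(noncausal) if noncausal else None,
    }


# ---------------------------------------------------------------------------
# I/O: population panel (BED + svtype + af), dosage table (TSV)

from .classify import DosageRecord  # noqa: E402  (I/O helpers only)


def read_population_panel(path: str | Path, panel_label: str = "panel") -> list[PopulationSV]:
    """Read a BED+2 panel: chrom, start, end, svtype, allele frequency."""
    panel = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            panel.append(
                PopulationSV(
                    iv=GenomicInterval(normalize_chrom(f[0]), int(f[1]), int(f[2])),
                    svtype=SVType(f[3]),
                    af=float(f[4]),
                    panel_label=panel_label,
                )
            )
    return panel


def write_population_panel(panel: Iterable[PopulationSV], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in panel:
            fh.write(
                f"{p.iv.chrom}\t{p.iv.start}\t{p.iv.end}\t{p.svtype.value}\t{p.af:g}\n"
            )


DOSAGE_COLUMNS = ["gene", "moi", "established", "haploinsufficient", "triplosensitive"]


def read_dosage_table(path: str | Path) -> dict[str, DosageRecord]:
    records: dict[str, DosageRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != DOSAGE_COLUMNS:
            raise ValueError(f"{path}: expected columns {DOSAGE_COLUMNS}, got {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, moi, est, hi, ts = line.split("\t")
            records[gene] = DosageRecord(
                gene_or_region=gene,
                moi=moi,
                established=est == "1",
                haploinsufficient=hi == "1",
                triplosensitive=ts == "1",
            )
    return records


def write_dosage_table(records: dict[str, DosageRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DOSAGE_COLUMNS) + "\n")
        for gene, r in sorted(records.items()):
            fh.write(
                f"{gene}\t{r.moi}\t{int(r.established)}\t"
                f"{int(r.haploinsufficient)}\t{int(r.triplosensitive)}\n"
            )
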