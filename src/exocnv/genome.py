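"""Genomic interval arithmetic, gene models and array probe sets.

All coordinates are held internally as 0-based half-open ``[start, end)``.
1-based inclusive conventions (GFF3, VCF POS, human-readable reports such
as ``chr1:197438450-197439442``) are converted at the I/O boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence
import warnings

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "ProbeSet",
    "Biotype",
    "reciprocal_overlap",
    "count_overlapping_probes",
    "exons_overlapped",
    "read_gene_model",
    "write_gene_model",
    "read_probes",
    "write_probes",
    "normalize_chrom",
    "is_autosome",
]

AUTOSOMES = {f"chr{i}" for i in range(1, 23)}


def normalize_chrom(name: str, prefix: bool = True) -> str:
    """Normalize a chromosome name to one dialect (default "chr"-prefixed)."""
    name = name.strip()
    bare = name[3:] if name.lower().startswith("chr") else name
    if bare == "MT":
        bare = "M"
    return f"chr{bare}" if prefix else bare


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot span intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )

    def to_1based(self) -> str:
        """Render in the 1-based inclusive style used in clinical reports."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


class Biotype(str, Enum):
    protein_coding = "protein_coding"
    other = "other"


@dataclass
class Transcript:
    """Exon-resolved transcript annotation.

    Exons must be non-overlapping, sorted by start, and on one chromosome.
    ``cds`` (when present) is the genomic span of the coding region; exon
    portions inside it count as coding sequence for LoF evaluation.
    """

    gene_id: str
    gene_name: str
    biotype: Biotype
    strand: str
    exons: list[GenomicInterval]
    cds: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.gene_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.gene_id} spans chromosomes {chroms}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.gene_id} has overlapping exons")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def coding_exon_parts(self) -> list[GenomicInterval]:
        """Exon pieces intersected with the CDS span, in genomic order."""
        if self.cds is None:
            return []
        parts = []
        for e in self.exons:
            bp = e.overlap_bp(self.cds)
            if bp > 0:
                parts.append(
                    GenomicInterval(
                        e.chrom, max(e.start, self.cds.start), min(e.end, self.cds.end)
                    )
                )
        return parts


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap of two intervals.

    Returns ``min(overlap / len(a), overlap / len(b))`` — the symmetric
    similarity used for SV same-allele matching; 0 when the intervals are on
    different chromosomes or do not intersect.
    """
    bp = a.overlap_bp(b)
    if bp == 0:
        return 0.0
    return min(bp / a.length, bp / b.length)


def exons_overlapped(iv: GenomicInterval, t: Transcript) -> tuple[int, list[int]]:
    """Count exons of ``t`` with >=1 bp overlap with ``iv``.

    Returns ``(count, indices)`` with indices in transcript (genomic) order.
    """
    idx = [i for i, e in enumerate(t.exons) if e.overlaps(iv)]
    return len(idx), idx


@dataclass
class GeneModel:
    """A queryable collection of transcripts from one annotation source."""

    transcripts: list[Transcript]
    source_label: str = "unknown"
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._trees = {}
        for t in self.transcripts:
            s = t.span
            self._trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, t)

    def query(self, iv: GenomicInterval) -> list[Transcript]:
        """Transcripts with >=1 bp overlap with ``iv``, sorted by start."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        return sorted(hits, key=lambda t: (t.span.start, t.gene_id))

    def genes(self) -> list[str]:
        return sorted({t.gene_id for t in self.transcripts})

    def by_gene(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.gene_id == gene_id]


@dataclass
class ProbeSet:
    """Array probes treated as points (BED start coordinate).

    A probe lies within a CNV when its start position falls in the CNV's
    half-open interval. Duplicate positions are counted once.
    """

    probes: list[GenomicInterval]
    platform_label: str = "array"
    _starts: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.probes = sorted(self.probes, key=lambda p: (p.chrom, p.start))
        self._starts = {}
        for p in self.probes:
            self._starts.setdefault(p.chrom, []).append(p.start)
        # dedupe per position: one assay per locus
        for chrom, starts in self._starts.items():
            self._starts[chrom] = sorted(set(starts))

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())


def count_overlapping_probes(iv: GenomicInterval, probes: ProbeSet) -> int:
    """Number of probes whose position falls inside ``iv`` (binary search)."""
    starts = probes._starts.get(iv.chrom, [])
    lo = bisect.bisect_left(starts, iv.start)
    hi = bisect.bisect_left(starts, iv.end)
    return hi - lo


# ---------------------------------------------------------------------------
# I/O: GFF3, BED12, BED3


class ParseError(ValueError):
    pass


def _parse_gff3(path: Path, chr_prefix: bool) -> Iterator[Transcript]:
    # Minimal gene/mRNA/exon/CDS reader for the annotation subset this
    # package consumes; GFF3 is 1-based inclusive.
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            chrom = normalize_chrom(chrom, prefix=chr_prefix)
            if ftype == "gene":
                gid = attr.get("ID", f"gene{lineno}")
                biotype = attr.get("biotype", attr.get("gene_biotype", "protein_coding"))
                if biotype not in {b.value for b in Biotype}:
                    if biotype != "other":
                        warnings.warn(
                            f"{path}:{lineno}: unknown biotype {biotype!r}, "
                            "classified 'other'"
                        )
                    biotype = "other"
                genes[gid] = {
                    "gene_id": gid,
                    "gene_name": attr.get("Name", gid),
                    "biotype": Biotype(biotype),
                    "strand": strand,
                    "exons": [],
                    "cds": None,
                    "chrom": chrom,
                }
            elif ftype == "exon":
                parent = attr.get("Parent", "").split(",")[0].replace("_t1", "")
                if parent in genes:
                    genes[parent]["exons"].append(GenomicInterval(chrom, start_i, end_i))
            elif ftype == "CDS":
                parent = attr.get("Parent", "").split(",")[0].replace("_t1", "")
                if parent in genes:
                    prev = genes[parent]["cds"]
                    cur = GenomicInterval(chrom, start_i, end_i)
                    genes[parent]["cds"] = cur if prev is None else prev.union_span(cur)
    for g in genes.values():
        g.pop("chrom")
        yield Transcript(**g)


def _parse_bed12(path: Path, chr_prefix: bool) -> Iterator[Transcript]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom = normalize_chrom(f[0], prefix=chr_prefix)
            chrom_start = int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = [
                GenomicInterval(chrom, chrom_start + o, chrom_start + o + s)
                for o, s in zip(offsets, sizes)
            ]
            cds = (
                GenomicInterval(chrom, thick_start, thick_end)
                if thick_end > thick_start
                else None
            )
            yield Transcript(
                gene_id=name,
                gene_name=name,
                biotype=Biotype.protein_coding,
                strand=strand if strand in {"+", "-"} else "+",
                exons=exons,
                cds=cds,
            )


def read_gene_model(
    path: str | Path,
    format: str = "gff3",
    source_label: str = "unknown",
    chr_prefix: bool = True,
) -> GeneModel:
    """Read a gene model from GFF3 or BED12.

    GFF3 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention; BED12 is already 0-based half-open.
    """
    path = Path(path)
    if format == "gff3":
        transcripts = list(_parse_gff3(path, chr_prefix))
    elif format == "bed12":
        transcripts = list(_parse_bed12(path, chr_prefix))
    else:
        raise ValueError(f"unknown gene model format {format!r}")
    return GeneModel(transcripts=transcripts, source_label=source_label)


def write_gene_model(gm: GeneModel, path: str | Path, format: str = "gff3") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for t in gm.transcripts:
                s = t.span
                fh.write(
                    f"{s.chrom}\t{gm.source_label}\tgene\t{s.start + 1}\t{s.end}\t.\t"
                    f"{t.strand}\t.\tID={t.gene_id};Name={t.gene_name};"
                    f"biotype={t.biotype.value}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\t{gm.source_label}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\tParent={t.gene_id}\n"
                    )
                if t.cds is not None:
                    c = t.cds
                    fh.write(
                        f"{c.chrom}\t{gm.source_label}\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{t.strand}\t0\tParent={t.gene_id}\n"
                    )
        elif format == "bed12":
            for t in gm.transcripts:
                s = t.span
                sizes = ",".join(str(e.length) for e in t.exons)
                offsets = ",".join(str(e.start - s.start) for e in t.exons)
                cds = t.cds or s
                fh.write(
                    f"{s.chrom}\t{s.start}\t{s.end}\t{t.gene_id}\t0\t{t.strand}\t"
                    f"{cds.start}\t{cds.end}\t0\t{len(t.exons)}\t{sizes}\t{offsets}\n"
                )
        else:
            raise ValueError(f"unknown gene model format {format!r}")


def read_probes(
    path: str | Path, platform_label: str = "array", chr_prefix: bool = True
) -> ProbeSet:
    """Read a BED3 probe file (0-based half-open)."""
    probes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: BED3 needs 3 columns")
            try:
                probes.append(
                    GenomicInterval(
                        normalize_chrom(f[0], prefix=chr_prefix), int(f[1]), int(f[2])
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return ProbeSet(probes=probes, platform_label=platform_label)


def write_probes(ps: ProbeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in ps.probes:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def write_bed(intervals: Iterable[tuple[GenomicInterval, Sequence[str]]], path: str | Path) -> None:
    """Write intervals plus extra columns as BED."""
    with open(path, "w") as fh:
        for iv, extra in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), *extra]
            fh.write("\t".join(cols) + "\n")
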