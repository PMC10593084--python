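"""Per-sample CNV segment calls, in-cohort allele frequencies and sample QC.

Raw read-depth CNV calls arrive one segment per sample with a copy number
(CN) and a caller quality score (QS). Calls from different samples that
represent the same underlying allele are grouped by single-linkage
clustering under the same-allele rule used for population SV matching:
same SV type and sufficient reciprocal overlap (50% when both calls exceed
5 kb, 10% otherwise). Cluster carrier frequencies feed the downstream
mode-of-inheritance filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import pysam

from .genome import GenomicInterval, is_autosome, normalize_chrom, reciprocal_overlap

__all__ = [
    "SVType",
    "CNVCall",
    "SampleQC",
    "Callset",
    "read_segments",
    "write_segments_tsv",
    "write_segments_vcf",
    "cluster_alleles",
    "sample_qc",
    "same_allele_threshold",
    "SIZE_RULE_BOUNDARY_BP",
    "LARGE_SV_RECIPROCAL_OVERLAP",
    "SMALL_SV_RECIPROCAL_OVERLAP",
]

log = logging.getLogger(__name__)

# Same-allele matching: 50% reciprocal overlap for SVs >5 kb, 10% below.
SIZE_RULE_BOUNDARY_BP = 5_000
LARGE_SV_RECIPROCAL_OVERLAP = 0.50
SMALL_SV_RECIPROCAL_OVERLAP = 0.10

# Per-sample quality: <=200 autosomal raw calls, >=35 of them with QS>20.
MAX_AUTOSOMAL_RAW_CALLS = 200
MIN_CALLS_QS_GT20 = 35
SAMPLE_QC_QS = 20

TSV_COLUMNS = ["sample_id", "chrom", "start", "end", "svtype", "cn", "qs"]


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    CPX = "CPX"
    SUSPECTED_CPX = "SUSPECTED_CPX"


@dataclass
class CNVCall:
    """One raw per-sample CNV segment call."""

    sample_id: str
    iv: GenomicInterval
    svtype: SVType
    cn: int
    qs: float
    n_exons: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError("copy number must be >= 0")
        if self.qs < 0:
            raise ValueError("QS must be >= 0")

    @property
    def is_homozygous_deletion(self) -> bool:
        return self.svtype is SVType.DEL and self.cn == 0


@dataclass
class SampleQC:
    sample_id: str
    n_autosomal_raw_calls: int
    n_calls_qs_gt20: int

    @property
    def is_high_quality(self) -> bool:
        return (
            self.n_autosomal_raw_calls <= MAX_AUTOSOMAL_RAW_CALLS
            and self.n_calls_qs_gt20 >= MIN_CALLS_QS_GT20
        )


def same_allele_threshold(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal-overlap threshold for a pair of SVs by size class.

    50% when both exceed 5 kb; the permissive 10% when either is <=5 kb
    (mixed-size pairs take the small-SV threshold).
    """
    if a.length > SIZE_RULE_BOUNDARY_BP and b.length > SIZE_RULE_BOUNDARY_BP:
        return LARGE_SV_RECIPROCAL_OVERLAP
    return SMALL_SV_RECIPROCAL_OVERLAP


def calls_match(a_iv: GenomicInterval, a_type: SVType, b_iv: GenomicInterval, b_type: SVType) -> bool:
    """Same-allele rule: same SV type and sufficient reciprocal overlap."""
    if a_type is not b_type:
        return False
    return reciprocal_overlap(a_iv, b_iv) >= same_allele_threshold(a_iv, b_iv)


@dataclass
class Callset:
    """A collection of calls across samples with allele-cluster frequencies."""

    calls: list[CNVCall]
    samples: list[str]
    cluster_of: dict[int, int] = field(default_factory=dict)  # call index -> cluster id
    frequencies: dict[int, float] = field(default_factory=dict)  # cluster id -> carrier frac

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def frequency_of(self, call_index: int, exclude_self: bool = False) -> float:
        """Carrier frequency of the allele cluster containing a call.

        With ``exclude_self`` the proband's own contribution is removed
        (carriers among the *other* samples), the quantity an analyst uses
        as a population prior when the cohort is small.
        """
        if not self.cluster_of:
            raise ValueError("cluster_alleles() has not been run")
        cid = self.cluster_of[call_index]
        if not exclude_self:
            return self.frequencies[cid]
        carriers = {
            self.calls[i].sample_id
            for i, c in self.cluster_of.items()
            if c == cid
        }
        carriers.discard(self.calls[call_index].sample_id)
        return len(carriers) / self.n_samples


def cluster_alleles(cs: Callset) -> Callset:
    """Single-linkage clustering of calls under the same-allele rule.

    Two calls link iff they have the same SV type and reciprocal overlap at
    or above the size-class threshold; clusters are the transitive closure.
    Frequencies are distinct-carrier fractions over the callset's samples.
    """
    n = len(cs.calls)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # sweep per (chrom, svtype): only overlapping pairs can link
    by_group: dict[tuple[str, SVType], list[int]] = {}
    for i, c in enumerate(cs.calls):
        by_group.setdefault((c.iv.chrom, c.svtype), []).append(i)
    for idxs in by_group.values():
        idxs.sort(key=lambda i: cs.calls[i].iv.start)
        active: list[int] = []
        for i in idxs:
            ci = cs.calls[i]
            active = [j for j in active if cs.calls[j].iv.end > ci.iv.start]
            for j in active:
                cj = cs.calls[j]
                if calls_match(ci.iv, ci.svtype, cj.iv, cj.svtype):
                    union(i, j)
            active.append(i)

    roots: dict[int, int] = {}
    cluster_of: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        cluster_of[i] = roots.setdefault(r, len(roots))
    carriers: dict[int, set[str]] = {}
    for i, cid in cluster_of.items():
        carriers.setdefault(cid, set()).add(cs.calls[i].sample_id)
    frequencies = {
        cid: len(s) / cs.n_samples for cid, s in carriers.items()
    }
    cs.cluster_of = cluster_of
    cs.frequencies = frequencies
    return cs


def sample_qc(cs: Callset) -> list[SampleQC]:
    """Per-sample counts of autosomal raw calls and calls with QS>20."""
    counts: dict[str, list[int]] = {s: [0, 0] for s in cs.samples}
    for c in cs.calls:
        if c.sample_id not in counts:
            counts[c.sample_id] = [0, 0]
        if is_autosome(c.iv.chrom):
            counts[c.sample_id][0] += 1
            if c.qs > SAMPLE_QC_QS:
                counts[c.sample_id][1] += 1
    return [
        SampleQC(sample_id=s, n_autosomal_raw_calls=a, n_calls_qs_gt20=q)
        for s, (a, q) in sorted(counts.items())
    ]


# ---------------------------------------------------------------------------
# I/O


def _ploidy(chrom: str) -> int:
    # Autosomal default; sex-chromosome ploidy depends on sample sex, which
    # segment files do not carry — diploid is assumed and callers encode
    # hemizygous loss as CN below 2.
    return 2


def read_segments(path: str | Path, dialect: str = "sv_vcf") -> Callset:
    """Read per-sample CNV segment calls.

    ``sv_vcf``: VCF with INFO SVTYPE/END and per-sample FORMAT CN/QS; one
    call is emitted per sample x record with non-reference copy number.
    ``tsv``: 7 columns (sample_id, chrom, start, end, svtype, cn, qs) with
    0-based half-open coordinates.
    """
    path = Path(path)
    if dialect == "sv_vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown segment dialect {dialect!r}")


def _read_vcf(path: Path) -> Callset:
    calls: list[CNVCall] = []
    n_bad = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf.fetch() if vf.index is not None else vf:
            svtype = rec.info.get("SVTYPE")
            end = rec.stop  # pysam resolves INFO/END
            if svtype is None or end is None:
                n_bad += 1
                continue
            if svtype not in ("DEL", "DUP"):
                n_bad += 1
                continue
            chrom = normalize_chrom(rec.chrom)
            iv = GenomicInterval(chrom, rec.start, end)
            for sample in samples:
                fmt = rec.samples[sample]
                cn = fmt.get("CN")
                qs = fmt.get("QS")
                if cn is None:
                    continue
                if cn == _ploidy(chrom):
                    continue  # reference copy number: no call for this sample
                calls.append(
                    CNVCall(
                        sample_id=sample,
                        iv=iv,
                        svtype=SVType(svtype),
                        cn=int(cn),
                        qs=float(qs if qs is not None else 0),
                    )
                )
    if n_bad:
        log.warning("%s: skipped %d records lacking SVTYPE/END or non-CNV type", path, n_bad)
    return Callset(calls=calls, samples=samples)


def _read_tsv(path: Path) -> Callset:
    calls: list[CNVCall] = []
    samples: list[str] = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(
                f"{path}: expected columns {TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            sample, chrom, start, end, svtype, cn, qs = f
            chrom = normalize_chrom(chrom)
            if int(cn) == _ploidy(chrom):
                log.warning("%s:%d: CN equals ploidy, skipped", path, lineno)
                continue
            calls.append(
                CNVCall(
                    sample_id=sample,
                    iv=GenomicInterval(chrom, int(start), int(end)),
                    svtype=SVType(svtype),
                    cn=int(cn),
                    qs=float(qs),
                )
            )
            if sample not in seen:
                seen.add(sample)
                samples.append(sample)
    return Callset(calls=calls, samples=samples)


def write_segments_tsv(cs: Callset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for c in cs.calls:
            fh.write(
                f"{c.sample_id}\t{c.iv.chrom}\t{c.iv.start}\t{c.iv.end}\t"
                f"{c.svtype.value}\t{c.cn}\t{c.qs:g}\n"
            )


def write_segments_vcf(cs: Callset, path: str | Path, contig_lengths: dict[str, int]) -> None:
    """Write calls as a minimal SV-VCF (INFO SVTYPE/END, FORMAT CN/QS).

    Calls sharing (interval, svtype) collapse to one record with per-sample
    genotype columns; samples without the call get reference CN.
    """
    sites: dict[tuple[GenomicInterval, SVType], list[CNVCall]] = {}
    for c in cs.calls:
        sites.setdefault((c.iv, c.svtype), []).append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">\n')
        fh.write('##FORMAT=<ID=QS,Number=1,Type=Integer,Description="Quality score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cs.samples) + "\n")
        for (iv, svtype), site_calls in sorted(
            sites.items(), key=lambda kv: (kv[0][0].chrom, kv[0][0].start, kv[0][1].value)
        ):
            by_sample = {c.sample_id: c for c in site_calls}
            cols = [
                iv.chrom,
                str(iv.start + 1),
                ".",
                "N",
                f"<{svtype.value}>",
                ".",
                ".",
                f"SVTYPE={svtype.value};END={iv.end}",
                "GT:CN:QS",
            ]
            for s in cs.samples:
                c = by_sample.get(s)
                if c is None:
                    cols.append(f"0/0:{_ploidy(iv.chrom)}:0")
                else:
                    gt = "1/1" if c.cn == 0 else "0/1"
                    cols.append(f"{gt}:{c.cn}:{int(c.qs)}")
            fh.write("\t".join(cols) + "\n")
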