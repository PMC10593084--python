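"""Assembly of per-sample calls into biological events.

Read-depth callers fragment large CNVs into several smaller segment calls.
Same-sample, same-chromosome, same-type calls separated by no more than a
gap limit — with no opposite-direction call in between — are merged into a
single event whose span is the union of its components. Nearby events of
mixed type (del/dup, paired dup) in one sample are flagged as suspected
complex SVs; orthogonal validation can overwrite the resolved type
(e.g. a deletion call revealed to be a mobile-element insertion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .callset import CNVCall, SVType
from .genome import GeneModel, GenomicInterval

__all__ = [
    "Inheritance",
    "ValidationMethod",
    "ValidationRecord",
    "CNVEvent",
    "merge_fragments",
    "flag_complex_candidate",
    "resolve_with_validation",
    "write_events_bed",
    "write_events_json",
    "DEFAULT_MERGE_GAP_BP",
    "DEFAULT_COMPLEX_WINDOW_BP",
]

# Rule-based surrogate for manual copy-number-plot review of fragmented calls.
DEFAULT_MERGE_GAP_BP = 1_000_000
DEFAULT_COMPLEX_WINDOW_BP = 2_000_000


class Inheritance(str, Enum):
    de_novo_confirmed = "de_novo_confirmed"
    inherited_affected_parent = "inherited_affected_parent"
    inherited_unaffected_parent = "inherited_unaffected_parent"
    unknown = "unknown"


class ValidationMethod(str, Enum):
    FISH = "FISH"
    karyotype = "karyotype"
    CMA = "CMA"
    MLPA = "MLPA"
    Sanger = "Sanger"
    qPCR = "qPCR"
    ddPCR = "ddPCR"
    genome_short = "genome_short"
    genome_long = "genome_long"
    long_range_PCR = "long_range_PCR"


@dataclass
class ValidationRecord:
    method: ValidationMethod
    resolved_type: SVType
    breakpoints: Optional[list[GenomicInterval]] = None
    notes: str = ""


@dataclass
class CNVEvent:
    """One biological event per sample: merged components and resolved type."""

    sample_id: str
    components: list[CNVCall]
    resolved_type: SVType
    inheritance: Inheritance = Inheritance.unknown
    validation: Optional[ValidationRecord] = None
    event_id: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("event needs at least one component call")
        if len({c.sample_id for c in self.components}) != 1:
            raise ValueError("components must share one sample")
        if len({c.iv.chrom for c in self.components}) != 1:
            raise ValueError("components must share one chromosome")

    @property
    def span(self) -> GenomicInterval:
        ivs = [c.iv for c in self.components]
        return GenomicInterval(
            ivs[0].chrom, min(i.start for i in ivs), max(i.end for i in ivs)
        )

    @property
    def qs(self) -> float:
        return max(c.qs for c in self.components)

    @property
    def estimated_size(self) -> int:
        return self.span.length

    @property
    def n_exons(self) -> Optional[int]:
        counts = [c.n_exons for c in self.components]
        if any(c is None for c in counts):
            return None
        return sum(counts)  # components are disjoint segments


def merge_fragments(
    calls_for_sample: Sequence[CNVCall],
    gm: Optional[GeneModel] = None,
    max_gap_bp: int = DEFAULT_MERGE_GAP_BP,
    same_type_only: bool = True,
) -> list[CNVEvent]:
    """Merge fragmented same-type calls of one sample into events.

    Calls on one chromosome with the same SV type merge transitively when
    consecutive calls (in position order) are separated by at most
    ``max_gap_bp`` and no call of the opposite direction lies in the gap.
    The result is independent of input order and idempotent.
    """
    samples = {c.sample_id for c in calls_for_sample}
    if len(samples) > 1:
        raise ValueError("merge_fragments operates on one sample at a time")
    calls = sorted(calls_for_sample, key=lambda c: (c.iv.chrom, c.iv.start, c.iv.end))
    events: list[CNVEvent] = []
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.iv.chrom, []).append(c)

    for chrom, chrom_calls in by_chrom.items():
        for svtype in sorted({c.svtype for c in chrom_calls}, key=lambda s: s.value):
            group = [c for c in chrom_calls if c.svtype is svtype]
            others = [c for c in chrom_calls if c.svtype is not svtype]
            current: list[CNVCall] = []
            for c in group:
                if not current:
                    current = [c]
                    continue
                prev_end = max(x.iv.end for x in current)
                gap_ok = c.iv.start - prev_end <= max_gap_bp
                blocked = same_type_only and any(
                    o.iv.end > prev_end and o.iv.start < c.iv.start for o in others
                )
                if gap_ok and not blocked:
                    current.append(c)
                else:
                    events.append(
                        CNVEvent(
                            sample_id=current[0].sample_id,
                            components=current,
                            resolved_type=svtype,
                        )
                    )
                    current = [c]
            if current:
                events.append(
                    CNVEvent(
                        sample_id=current[0].sample_id,
                        components=current,
                        resolved_type=svtype,
                    )
                )
    events.sort(key=lambda e: (e.span.chrom, e.span.start, e.span.end))
    for i, e in enumerate(events):
        if not e.event_id:
            e.event_id = f"{e.sample_id}_ev{i}"
    return events


def flag_complex_candidate(
    events_for_sample: Sequence[CNVEvent],
    window_bp: int = DEFAULT_COMPLEX_WINDOW_BP,
) -> list[CNVEvent]:
    """Flag clustered events in one sample as suspected complex SVs.

    Two or more events on one chromosome whose spans lie within
    ``window_bp`` of each other — differing types (del/dup) or a paired
    same-type pattern flanking a gap — are jointly marked SUSPECTED_CPX.
    Events already resolved by validation are left untouched.
    """
    flagged = list(events_for_sample)
    by_chrom: dict[str, list[int]] = {}
    for i, e in enumerate(flagged):
        by_chrom.setdefault(e.span.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: flagged[i].span.start)
        for a, b in zip(idxs, idxs[1:]):
            ea, eb = flagged[a], flagged[b]
            gap = eb.span.start - ea.span.end
            if gap <= window_bp:
                for i in (a, b):
                    if flagged[i].validation is None:
                        flagged[i].resolved_type = SVType.SUSPECTED_CPX
    return flagged


def resolve_with_validation(e: CNVEvent, v: ValidationRecord) -> CNVEvent:
    """Adopt an orthogonal validation result for an event.

    The resolved type is replaced; validated breakpoints are adopted as new
    component coordinates while the original read-depth calls remain
    available through the validation record's provenance.
    """
    if v.breakpoints:
        chroms = {bp.chrom for bp in v.breakpoints}
        if chroms != {e.span.chrom}:
            raise ValueError(
                f"validation breakpoints on {sorted(chroms)} do not match event "
                f"chromosome {e.span.chrom}"
            )
    e.resolved_type = v.resolved_type
    e.validation = v
    return e


# ---------------------------------------------------------------------------
# Writers


def write_events_bed(events: Iterable[CNVEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in events:
            s = e.span
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t"
                f"{e.event_id}|{e.sample_id}|{e.resolved_type.value}\n"
            )


def write_events_json(events: Iterable[CNVEvent], path: str | Path) -> None:
    payload = []
    for e in events:
        payload.append(
            {
                "event_id": e.event_id,
                "sample_id": e.sample_id,
                "span": e.span.to_1based(),
                "resolved_type": e.resolved_type.value,
                "inheritance": e.inheritance.value,
                "qs": e.qs,
                "components": [
                    {
                        "interval": c.iv.to_1based(),
                        "svtype": c.svtype.value,
                        "cn": c.cn,
                        "qs": c.qs,
                    }
                    for c in e.components
                ],
                "validation": (
                    None
                    if e.validation is None
                    else {
                        "method": e.validation.method.value,
                        "resolved_type": e.validation.resolved_type.value,
                        "notes": e.validation.notes,
                    }
                ),
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
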