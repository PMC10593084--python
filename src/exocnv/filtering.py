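"""Call-level filters: QS gates, high-confidence flag, MOI frequency filters.

The read-depth caller's developer-recommended quality-score gates are
QS >= 50 for duplications, >= 100 for heterozygous deletions and >= 400 for
homozygous deletions ("QS>n" shorthand in the field; the comparison is
greater-or-equal). A call is high-confidence when it comes from a
high-quality sample, has cohort carrier frequency <= 0.01, overlaps at
least 3 exons and passes its QS gate. Mode-of-inheritance frequency
filters retain calls strictly below 0.1% (dominant) or 1% (recessive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .callset import CNVCall, SampleQC, SVType

__all__ = [
    "QSThresholds",
    "MOIFrequencyLimits",
    "passes_qs_gate",
    "flag_high_confidence",
    "filter_by_moi",
    "HIGH_CONFIDENCE_MAX_FREQ",
    "HIGH_CONFIDENCE_MIN_EXONS",
]

HIGH_CONFIDENCE_MAX_FREQ = 0.01
HIGH_CONFIDENCE_MIN_EXONS = 3


@dataclass(frozen=True)
class QSThresholds:
    dup_min: float = 50.0
    del_min: float = 100.0
    homdel_min: float = 400.0
    analysis_min: float = 50.0  # initial per-analysis screen across all types

    def __post_init__(self) -> None:
        if not (self.homdel_min >= self.del_min >= self.analysis_min):
            raise ValueError("require homdel_min >= del_min >= analysis_min")


@dataclass(frozen=True)
class MOIFrequencyLimits:
    dominant_max: float = 0.001
    recessive_max: float = 0.01

    def __post_init__(self) -> None:
        if not self.dominant_max < self.recessive_max:
            raise ValueError("dominant limit must be below recessive limit")


def passes_qs_gate(call: CNVCall, t: QSThresholds = QSThresholds()) -> bool:
    """Type-specific QS gate (greater-or-equal comparison)."""
    if call.svtype is SVType.DUP:
        return call.qs >= t.dup_min
    if call.svtype is SVType.DEL:
        if call.cn == 0:
            return call.qs >= t.homdel_min
        return call.qs >= t.del_min
    # other SV types only arise post-validation; screen at the analysis gate
    return call.qs >= t.analysis_min


def flag_high_confidence(
    call: CNVCall,
    qc: SampleQC,
    freq: float,
    t: QSThresholds = QSThresholds(),
) -> bool:
    """All four high-confidence criteria.

    Sample is high quality, cohort carrier frequency <= 0.01, >= 3 exons
    overlapped, and the type-specific QS gate passes.
    """
    if call.n_exons is None:
        raise ValueError("call has no exon annotation; annotate first")
    return (
        qc.is_high_quality
        and freq <= HIGH_CONFIDENCE_MAX_FREQ
        and call.n_exons >= HIGH_CONFIDENCE_MIN_EXONS
        and passes_qs_gate(call, t)
    )


def filter_by_moi(
    calls: Iterable[tuple[CNVCall, float]],
    moi: str,
    limits: MOIFrequencyLimits = MOIFrequencyLimits(),
) -> list[CNVCall]:
    """Retain calls with frequency strictly below the MOI-specific limit.

    ``calls`` pairs each call with the frequency to test (cluster carrier
    frequency, or its leave-proband-out variant for small cohorts).
    """
    if moi == "dominant":
        limit = limits.dominant_max
    elif moi == "recessive":
        limit = limits.recessive_max
    else:
        raise ValueError(f"unknown mode of inheritance {moi!r}")
    return [c for c, f in calls if f < limit]
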