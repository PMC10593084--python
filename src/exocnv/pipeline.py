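"""End-to-end orchestration: read -> QC -> filter -> merge -> annotate -> classify.

The stages mirror how an analyst works through a read-depth CNV callset:
sample-level QC and in-cohort allele clustering first, then per-call
quality-score and mode-of-inheritance frequency filters, reassembly of
fragmented calls into events, annotation against gene models / population
panel / array probes, and finally the quantitative pathogenicity engine.

Frequency handling: the high-confidence flag uses the full cohort carrier
frequency (<= 0.01 as printed); the mode-of-inheritance filter uses the
carrier fraction among the *other* samples. In a large cohort the two are
indistinguishable, but at a few hundred samples a singleton already sits
at 1/n and would otherwise be discarded by the strict frequency limits it
is meant to survive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .annotate import (
    CMAReport,
    GeneContent,
    annotate_gene_content,
    cma_detectable,
    match_population_sv,
    read_dosage_table,
    read_population_panel,
)
from .callset import Callset, CNVCall, SVType, cluster_alleles, read_segments, sample_qc
from .classify import (
    CaseObservation,
    ClassificationResult,
    DosageRecord,
    ScoringScheme,
    classify_event,
)
from .events import CNVEvent, Inheritance, flag_complex_candidate, merge_fragments, write_events_bed, write_events_json
from .filtering import MOIFrequencyLimits, QSThresholds, flag_high_confidence, passes_qs_gate
from .genome import GeneModel, ProbeSet, read_gene_model, read_probes
from .synth import read_observations

__all__ = ["RunConfig", "PipelineResult", "ClassifiedEvent", "run_pipeline", "run_pipeline_in_memory"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    segments: Path
    gene_models: list[tuple[Path, str, str]]  # (path, format, source_label); first = primary
    probes: Optional[Path] = None
    panel: Optional[Path] = None
    dosage: Optional[Path] = None
    observations: Optional[Path] = None
    scheme: Optional[Path] = None
    outdir: Path = Path("exocnv_out")
    segments_dialect: str = ""  # inferred from extension when empty
    qs_thresholds: QSThresholds = field(default_factory=QSThresholds)
    moi_limits: MOIFrequencyLimits = field(default_factory=MOIFrequencyLimits)
    apply_qs_filter: bool = True
    moi: str = "recessive"  # retention mode for the frequency filter
    max_gap_bp: int = 1_000_000
    complex_window_bp: int = 2_000_000

    def __post_init__(self) -> None:
        self.segments = Path(self.segments)
        self.outdir = Path(self.outdir)
        if not self.segments_dialect:
            self.segments_dialect = "sv_vcf" if self.segments.suffix == ".vcf" else "tsv"


@dataclass
class ClassifiedEvent:
    event: CNVEvent
    gene_content: GeneContent
    cma: Optional[CMAReport]
    panel_max_af: float
    high_confidence: bool
    result: ClassificationResult


@dataclass
class PipelineResult:
    callset: Callset
    events: list[ClassifiedEvent]
    n_raw_calls: int
    n_retained_calls: int


def _load_stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"[{name}] {exc}") from exc


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run all stages from files and persist every stage's output."""
    models = [
        _load_stage("gene-model", read_gene_model, p, format=fmt, source_label=lbl)
        for p, fmt, lbl in cfg.gene_models
    ]
    probes = _load_stage("probes", read_probes, cfg.probes) if cfg.probes else None
    panel = _load_stage("panel", read_population_panel, cfg.panel) if cfg.panel else []
    dosage = _load_stage("dosage", read_dosage_table, cfg.dosage) if cfg.dosage else {}
    observations = (
        _load_stage("observations", read_observations, cfg.observations)
        if cfg.observations
        else []
    )
    scheme = (
        ScoringScheme.from_yaml(cfg.scheme) if cfg.scheme else ScoringScheme()
    )
    cs = _load_stage("segments", read_segments, cfg.segments, dialect=cfg.segments_dialect)
    result = run_pipeline_in_memory(
        cs, models, probes, panel, dosage, observations, scheme, cfg
    )
    _write_outputs(result, cfg)
    return result


def run_pipeline_in_memory(
    cs: Callset,
    models: list[GeneModel],
    probes: Optional[ProbeSet],
    panel,
    dosage: dict[str, DosageRecord],
    observations: list[CaseObservation],
    scheme: ScoringScheme,
    cfg: RunConfig,
) -> PipelineResult:
    n_raw = len(cs.calls)
    qc = {q.sample_id: q for q in sample_qc(cs)}
    cluster_alleles(cs)
    primary = models[0]

    # call-level exon annotation (total exons overlapped across genes)
    for c in cs.calls:
        c.n_exons = sum(
            len([e for e in t.exons if e.overlaps(c.iv)]) for t in primary.query(c.iv)
        )

    retained: list[CNVCall] = []
    hc_flags: dict[int, bool] = {}
    limit = (
        cfg.moi_limits.recessive_max
        if cfg.moi == "recessive"
        else cfg.moi_limits.dominant_max
    )
    for i, c in enumerate(cs.calls):
        if cfg.apply_qs_filter and not passes_qs_gate(c, cfg.qs_thresholds):
            continue
        if cs.frequency_of(i, exclude_self=True) >= limit:
            continue
        hc_flags[id(c)] = flag_high_confidence(
            c, qc[c.sample_id], cs.frequency_of(i), cfg.qs_thresholds
        )
        retained.append(c)
    log.info("retained %d/%d calls after QS and frequency filters", len(retained), n_raw)

    by_sample: dict[str, list[CNVCall]] = {}
    for c in retained:
        by_sample.setdefault(c.sample_id, []).append(c)

    obs_by_sample: dict[str, list[CaseObservation]] = {}
    for o in observations:
        obs_by_sample.setdefault(o.proband_id, []).append(o)

    transcripts = {
        g: primary.by_gene(g)[0] for g in dosage if primary.by_gene(g)
    }

    classified: list[ClassifiedEvent] = []
    for sample in cs.samples:
        calls = by_sample.get(sample, [])
        if not calls:
            continue
        events = merge_fragments(calls, primary, max_gap_bp=cfg.max_gap_bp)
        events = flag_complex_candidate(events, window_bp=cfg.complex_window_bp)
        for e in events:
            gc = annotate_gene_content(e, models, dosage)
            component_gcs = None
            if e.resolved_type in (SVType.CPX, SVType.SUSPECTED_CPX) and len(e.components) > 1:
                component_gcs = [
                    annotate_gene_content(
                        CNVEvent(sample_id=sample, components=[c], resolved_type=c.svtype),
                        models,
                        dosage,
                    )
                    for c in e.components
                ]
            _, max_af = match_population_sv(e, panel) if panel else ([], 0.0)
            cma = cma_detectable(e, probes) if probes is not None else None

            event_genes = set(gc.disease_genes) | set().union(*gc.genes.values())
            obs = [
                o
                for o in obs_by_sample.get(sample, [])
                if not o.gene or o.gene in event_genes
            ]
            if any(o.de_novo == "confirmed" for o in obs):
                e.inheritance = Inheritance.de_novo_confirmed
            res = classify_event(
                e,
                gc,
                dosage,
                observations=obs,
                transcripts=transcripts,
                scheme=scheme,
                component_gcs=component_gcs,
            )
            classified.append(
                ClassifiedEvent(
                    event=e,
                    gene_content=gc,
                    cma=cma,
                    panel_max_af=max_af,
                    high_confidence=any(hc_flags.get(id(c), False) for c in e.components),
                    result=res,
                )
            )
    return PipelineResult(
        callset=cs,
        events=classified,
        n_raw_calls=n_raw,
        n_retained_calls=len(retained),
    )


def _write_outputs(result: PipelineResult, cfg: RunConfig) -> None:
    from .report import events_table, summarize

    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    write_events_bed((ce.event for ce in result.events), out / "events.bed")
    write_events_json((ce.event for ce in result.events), out / "events.json")

    df = events_table(result.events)
    df.to_csv(out / "classified.tsv", sep="\t", index=False)

    with open(out / "evidence.tsv", "w") as fh:
        fh.write("event_id\tcategory\tpoints\tstrength\trationale\tcap_applied\n")
        for ce in result.events:
            for item in ce.result.items:
                fh.write(
                    f"{ce.result.event_id}\t{item.category}\t{item.points:g}\t"
                    f"{item.strength_label}\t{item.rationale}\t{int(item.cap_applied)}\n"
                )

    for name, table in summarize(df).items():
        table.to_csv(out / f"summary_{name}.tsv", sep="\t")

    report = {
        "n_raw_calls": result.n_raw_calls,
        "n_retained_calls": result.n_retained_calls,
        "n_events": len(result.events),
        "n_high_confidence": int(sum(ce.high_confidence for ce in result.events)),
        "classification_counts": df["classification"].value_counts().to_dict() if len(df) else {},
        "settings": {
            "qs_thresholds": cfg.qs_thresholds.__dict__,
            "moi_limits": cfg.moi_limits.__dict__,
            "moi": cfg.moi,
            "apply_qs_filter": cfg.apply_qs_filter,
            "max_gap_bp": cfg.max_gap_bp,
            "complex_window_bp": cfg.complex_window_bp,
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
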