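"""Quantitative CNV pathogenicity engine.

Implements the point-based ACMG/ClinGen dosage framework for copy-number
loss and gain, extended with case-evidence scoring for autosomal-recessive
and X-linked conditions, functional-evidence points, phenotype-specificity
points, loss-of-function (PVS1-style) strength evaluation for deletions,
insertions and inversions, and a most-deleterious-component rule for
complex rearrangements.

Evidence strengths map onto the familiar point scale (very strong 0.90,
strong 0.45, moderate 0.30, supporting 0.15); evidence items sum to a total
that is thresholded into the five-tier scale B / LB / VUS / LP / P
(pathogenic at >=0.99, likely pathogenic at 0.90, mirrored for benign).

Point values printed in the source framework are shipped as editable
configuration (:class:`ScoringScheme`); the X-linked branch table has no
published values and its defaults are explicit package choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import yaml

from .callset import SVType
from .events import CNVEvent, Inheritance
from .genome import GenomicInterval, Transcript

__all__ = [
    "DosageRecord",
    "CaseObservation",
    "EvidenceItem",
    "Tier",
    "ClassificationResult",
    "ScoringScheme",
    "DEFAULT_SCHEME",
    "pvs1_strength",
    "strength_to_points",
    "score_gene_number",
    "score_ar_cases",
    "score_xl_cases",
    "score_de_novo",
    "score_functional",
    "score_phenotype",
    "aggregate",
    "classify_complex",
    "classify_event",
]

_EPS = 1e-9


class Tier(str, Enum):
    B = "B"
    LB = "LB"
    VUS = "VUS"
    LP = "LP"
    P = "P"

    @property
    def rank(self) -> int:
        return ["B", "LB", "VUS", "LP", "P"].index(self.value)


@dataclass(frozen=True)
class DosageRecord:
    """Established gene-disease / dosage-sensitivity knowledge for one gene."""

    gene_or_region: str
    moi: str  # AD | AR | XL
    established: bool
    haploinsufficient: bool = False
    triplosensitive: bool = False

    def __post_init__(self) -> None:
        if self.moi not in {"AD", "AR", "XL"}:
            raise ValueError(f"unknown mode of inheritance {self.moi!r}")


@dataclass
class CaseObservation:
    """Per-proband evidence for one variant.

    ``phase`` and ``second_variant_class`` drive recessive case scoring;
    ``sex``/``de_novo``/``maternal_carrier_affected`` drive the X-linked
    branch table; phenotype specificity and functional evidence add fixed
    bonuses. Observations recorded in cis contribute no points.
    """

    proband_id: str
    zygosity: str = "het"  # het | hom | hemi
    phase: str = "unknown"  # in_trans_confirmed | unknown | in_cis
    second_variant_class: str = "none"  # P | LP | VUS | none
    phenotype_specificity: str = "none"  # none | unique | unique_strong
    sex: str = ""  # M | F
    de_novo: str = "unknown"  # confirmed|assumed|inherited_affected|inherited_unaffected|unknown
    maternal_carrier_affected: Optional[bool] = None
    functional_evidence: str = "none"  # none | supporting | moderate | strong
    gene: str = ""


@dataclass
class EvidenceItem:
    category: str
    points: float
    strength_label: str = ""
    rationale: str = ""
    cap_applied: bool = False


@dataclass
class ClassificationResult:
    event_id: str
    items: list[EvidenceItem]
    total: float
    classification: Tier
    component_results: Optional[list["ClassificationResult"]] = None


# ---------------------------------------------------------------------------
# Configuration


def _default_strength_points() -> dict[str, float]:
    return {"PVS1": 0.90, "strong": 0.45, "moderate": 0.30, "supporting": 0.15, "none": 0.0}


def _default_xl_table() -> dict[str, float]:
    # Branch values for the X-linked flowchart (sex x inheritance x carrier
    # parent status). These defaults are this package's own calibration —
    # strong for a confirmed de novo hemizygote, stepped down with weaker
    # segregation — and are NOT anchored to published numbers; edit freely.
    return {
        "M|confirmed": 0.45,
        "M|assumed": 0.30,
        "M|inherited_affected": 0.30,
        "M|inherited_unaffected": 0.15,
        "M|unknown": 0.15,
        "F|confirmed": 0.30,
        "F|assumed": 0.15,
        "F|inherited_affected": 0.15,
        "F|inherited_unaffected": 0.0,
        "F|unknown": 0.0,
    }


@dataclass
class ScoringScheme:
    """All point values, caps and classification ranges in one place."""

    strength_points: dict[str, float] = field(default_factory=_default_strength_points)

    # Gene-number (section-3 style) bins: (lower bound inclusive, points),
    # evaluated top-down. 35-gene deletions take the 0.9 bin (the printed
    # 25-34 / "more than 35" bins leave 35 unassigned; contiguous bins kept).
    del_gene_bins: list[tuple[int, float]] = field(
        default_factory=lambda: [(35, 0.90), (25, 0.45), (0, 0.0)]
    )
    dup_gene_bins: list[tuple[int, float]] = field(
        default_factory=lambda: [(50, 0.90), (35, 0.45), (0, 0.0)]
    )

    # Recessive case-evidence table (points per proband).
    ar_in_trans_p: float = 0.30
    ar_in_trans_lp: float = 0.30
    ar_phase_unknown_p: float = 0.15
    ar_phase_unknown_lp: float = 0.08
    ar_homozygous: float = 0.15
    ar_homozygous_cap: float = 0.30
    ar_in_trans_vus: float = 0.08
    ar_in_trans_vus_cap: float = 0.16
    ar_case_cap: float = 0.90  # aggregate cap across probands (one "strong")

    phenotype_unique: float = 0.15
    phenotype_unique_strong: float = 0.30

    functional_points: dict[str, float] = field(
        default_factory=lambda: {"none": 0.0, "supporting": 0.15, "moderate": 0.30, "strong": 0.45}
    )

    de_novo_points: dict[str, float] = field(
        default_factory=lambda: {
            "confirmed": 0.45,
            "assumed": 0.30,
            "inherited_affected": 0.0,
            "inherited_unaffected": 0.0,
            "unknown": 0.0,
        }
    )

    xl_table: dict[str, float] = field(default_factory=_default_xl_table)
    xl_case_cap: float = 0.45  # any single X-linked case, after phenotype adjustment

    established_region_points: float = 1.0  # full overlap of an established HI/TS region

    # Classification ranges on the evidence total.
    pathogenic_min: float = 0.99
    likely_pathogenic_min: float = 0.90
    likely_benign_max: float = -0.90
    benign_max: float = -0.99

    # LoF evaluation knobs.
    dup_lof_eligible: bool = False  # intragenic duplications assumed rescued by default
    nmd_last_junction_nt: int = 50  # the 50-nt rule
    lof_strong_removed_fraction: float = 0.10
    lof_moderate_removed_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (
            self.pathogenic_min
            > self.likely_pathogenic_min
            > self.likely_benign_max
            > self.benign_max
        ):
            raise ValueError("classification ranges overlap or are out of order")

    def classify_total(self, total: float) -> Tier:
        if total >= self.pathogenic_min - _EPS:
            return Tier.P
        if total >= self.likely_pathogenic_min - _EPS:
            return Tier.LP
        if total <= self.benign_max + _EPS:
            return Tier.B
        if total <= self.likely_benign_max + _EPS:
            return Tier.LB
        return Tier.VUS

    def to_yaml(self, path) -> None:
        data = {
            k: (list(map(list, v)) if isinstance(v, list) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScoringScheme":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("del_gene_bins", "dup_gene_bins"):
            if key in data:
                data[key] = [tuple(x) for x in data[key]]
        return cls(**data)


DEFAULT_SCHEME = ScoringScheme()


def strength_to_points(s: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Map an evidence strength tier to points (0.90/0.45/0.30/0.15/0)."""
    try:
        return scheme.strength_points[s]
    except KeyError:
        raise ValueError(f"unknown strength {s!r}") from None


# ---------------------------------------------------------------------------
# LoF (PVS1-style) evaluation


def _coding_disruption(
    span: GenomicInterval, t: Transcript, scheme: ScoringScheme
) -> tuple[int, bool, bool]:
    """(removed coding bp, frameshift, NMD predicted) for a deletion span.

    NMD is predicted when the resulting premature stop — approximated at the
    first affected coding position in translation order — lies more than the
    50-nt boundary upstream of the last exon-exon junction.
    """
    parts = t.coding_exon_parts()
    if not parts:
        return 0, False, False
    if t.strand == "-":
        parts = list(reversed(parts))
    total = sum(p.length for p in parts)
    removed = 0
    first_affected: Optional[int] = None
    pos = 0
    for p in parts:
        bp = p.overlap_bp(span)
        if bp > 0:
            if t.strand == "+":
                offset = max(0, span.start - p.start)
            else:
                offset = max(0, p.end - span.end)
            if first_affected is None:
                first_affected = pos + offset
            else:
                first_affected = min(first_affected, pos + offset)
            removed += bp
        pos += p.length
    if removed == 0:
        return 0, False, False
    frameshift = removed % 3 != 0
    if len(parts) < 2:
        nmd = False  # single coding exon: no junction, no NMD
    else:
        last_junction = total - parts[-1].length
        boundary = last_junction - scheme.nmd_last_junction_nt
        nmd = first_affected is not None and first_affected < boundary
    return removed, frameshift, nmd


def _inversion_is_lof(span: GenomicInterval, t: Transcript) -> bool:
    """Inversion LoF rule: exactly one breakpoint inside the gene, or both
    inside the same gene with at least one exon spanned."""
    gene_span = t.span
    bp1_in = gene_span.start <= span.start < gene_span.end
    bp2_in = gene_span.start < span.end <= gene_span.end
    if bp1_in != bp2_in:
        return True
    if bp1_in and bp2_in:
        return any(span.contains(e) for e in t.exons)
    return False


def _insertion_in_exon(span: GenomicInterval, t: Transcript) -> bool:
    parts = t.coding_exon_parts() or t.exons
    return any(p.overlap_bp(span) > 0 for p in parts)


def pvs1_strength(
    e: CNVEvent,
    gc: "GeneContent",
    d: DosageRecord,
    transcript: Optional[Transcript] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> str:
    """LoF evidence strength of an event in an established disease gene.

    Returns one of PVS1 / strong / moderate / supporting / none:

    * deletions are LoF-eligible; full-gene removal or a frameshifting loss
      predicted to trigger NMD earns PVS1; NMD-escaping losses step down by
      removed coding fraction (> 10% strong, > 5% moderate, else supporting);
    * insertions are LoF-eligible when they land within an exon;
    * inversions are LoF-eligible when exactly one breakpoint falls within
      the gene, or both fall within it and at least one exon is spanned (an
      inversion enclosing the whole gene leaves it intact);
    * duplications are not LoF-eligible unless configured as disruptive.
    """
    if not d.established:
        raise ValueError(
            f"{d.gene_or_region}: gene-disease relationship not established; "
            "use the case-evidence path"
        )
    span = e.span
    svtype = e.resolved_type

    if svtype is SVType.DUP and not scheme.dup_lof_eligible:
        return "none"
    if svtype is SVType.INV:
        if transcript is None or not _inversion_is_lof(span, transcript):
            return "none"
        return "PVS1"  # gene disrupted by an inverted breakpoint
    if svtype is SVType.INS:
        if transcript is not None and not _insertion_in_exon(span, transcript):
            return "none"
        # exonic insertion: frame-disrupting by assumption, NMD per position
        if transcript is None:
            return "PVS1"
        _, _, nmd = _coding_disruption(
            GenomicInterval(span.chrom, span.start, span.start + 1), transcript, scheme
        )
        return "PVS1" if nmd else "strong"
    if svtype not in (SVType.DEL, SVType.DUP):
        return "none"

    # deletions (and opted-in duplications)
    if transcript is None:
        return "PVS1" if gc.intragenic or svtype is SVType.DEL else "none"
    if span.contains(transcript.span):
        return "PVS1"
    removed, frameshift, nmd = _coding_disruption(span, transcript, scheme)
    if removed == 0:
        return "none"
    if frameshift and nmd:
        return "PVS1"
    total = sum(p.length for p in transcript.coding_exon_parts())
    fraction = removed / total if total else 0.0
    if fraction > scheme.lof_strong_removed_fraction:
        return "strong"
    if fraction > scheme.lof_moderate_removed_fraction:
        return "moderate"
    return "supporting"


# ---------------------------------------------------------------------------
# Evidence scorers


def score_gene_number(
    svtype: SVType, n_genes: int, scheme: ScoringScheme = DEFAULT_SCHEME
) -> EvidenceItem:
    """Gene-number evidence: binned points by protein-coding gene count."""
    if n_genes < 0:
        raise ValueError("gene count must be >= 0")
    if svtype is SVType.DEL:
        bins = scheme.del_gene_bins
    elif svtype is SVType.DUP:
        bins = scheme.dup_gene_bins
    else:
        raise ValueError("gene-number scoring applies to DEL/DUP only")
    points = 0.0
    for lower, pts in sorted(bins, reverse=True):
        if n_genes >= lower:
            points = pts
            break
    return EvidenceItem(
        category="3-gene-count",
        points=points,
        rationale=f"{svtype.value} spanning {n_genes} protein-coding genes",
    )


def score_phenotype(
    observations: Sequence[CaseObservation], scheme: ScoringScheme = DEFAULT_SCHEME
) -> EvidenceItem:
    """Phenotype-specificity bonus, used at most once per variant.

    0.15 points when at least one reported individual has a phenotype highly
    specific to the disease; 0.30 when the evidence is particularly strong
    (unique phenotype plus high-sensitivity clinical testing and consistent
    family history).
    """
    levels = {o.phenotype_specificity for o in observations if o.phase != "in_cis"}
    if "unique_strong" in levels:
        pts, label = scheme.phenotype_unique_strong, "unique_strong"
    elif "unique" in levels:
        pts, label = scheme.phenotype_unique, "unique"
    else:
        pts, label = 0.0, "none"
    return EvidenceItem(
        category="PP4-like",
        points=pts,
        strength_label=label,
        rationale="phenotype specificity bonus (applied once per variant)",
    )


def score_ar_cases(
    observations: Sequence[CaseObservation], scheme: ScoringScheme = DEFAULT_SCHEME
) -> EvidenceItem:
    """Recessive case evidence per the adapted in-trans (PM3-style) table.

    Per proband: 0.30 for a confirmed in-trans pathogenic or likely
    pathogenic second variant; 0.15 / 0.08 when phase is unknown (P / LP);
    0.15 per homozygous occurrence capped at 0.30 in aggregate; 0.08 for a
    VUS confirmed in trans capped at 0.16 (phase-unknown VUS scores 0).
    The aggregate of proband points is capped (default 0.90); the
    once-per-variant phenotype bonus is then added on top.
    """
    case_points = 0.0
    hom_points = 0.0
    vus_points = 0.0
    cap_applied = False
    notes = []
    for o in observations:
        if o.phase == "in_cis":
            continue
        if o.zygosity == "hom":
            hom_points += scheme.ar_homozygous
            continue
        if o.phase == "in_trans_confirmed":
            if o.second_variant_class == "P":
                case_points += scheme.ar_in_trans_p
            elif o.second_variant_class == "LP":
                case_points += scheme.ar_in_trans_lp
            elif o.second_variant_class == "VUS":
                vus_points += scheme.ar_in_trans_vus
        elif o.phase == "unknown":
            if o.second_variant_class == "P":
                case_points += scheme.ar_phase_unknown_p
            elif o.second_variant_class == "LP":
                case_points += scheme.ar_phase_unknown_lp
            # phase-unknown VUS: 0
    if hom_points > scheme.ar_homozygous_cap:
        hom_points = scheme.ar_homozygous_cap
        cap_applied = True
        notes.append("homozygous-occurrence cap")
    if vus_points > scheme.ar_in_trans_vus_cap:
        vus_points = scheme.ar_in_trans_vus_cap
        cap_applied = True
        notes.append("VUS-in-trans cap")
    total = case_points + hom_points + vus_points
    if total > scheme.ar_case_cap:
        total = scheme.ar_case_cap
        cap_applied = True
        notes.append("aggregate case cap")
    phenotype = score_phenotype(observations, scheme)
    total += phenotype.points
    if phenotype.points:
        notes.append(f"phenotype bonus {phenotype.points:g}")
    return EvidenceItem(
        category="4-AR-case",
        points=round(total, 10),
        rationale="; ".join(notes) or f"{len(observations)} observation(s)",
        cap_applied=cap_applied,
    )


def score_xl_cases(
    observations: Sequence[CaseObservation], scheme: ScoringScheme = DEFAULT_SCHEME
) -> EvidenceItem:
    """X-linked case evidence from the sex x inheritance branch table.

    Each observation looks up its branch (proband sex, de novo status /
    parental genotype, carrier-parent affected status), is adjusted by
    phenotype specificity, and contributes at most 0.45 points. Branch
    values come from the configured table (defaults are package choices,
    not published numbers).
    """
    total = 0.0
    cap_applied = False
    for o in observations:
        if o.phase == "in_cis":
            continue
        if not o.sex:
            raise ValueError(f"observation {o.proband_id}: proband sex required for X-linked scoring")
        branch = o.de_novo
        if branch in ("inherited_affected", "inherited_unaffected") and o.maternal_carrier_affected is not None:
            branch = "inherited_affected" if o.maternal_carrier_affected else "inherited_unaffected"
        key = f"{o.sex}|{branch}"
        if key not in scheme.xl_table:
            raise ValueError(f"no X-linked branch configured for {key!r}")
        pts = scheme.xl_table[key]
        if o.phenotype_specificity == "unique":
            pts += scheme.phenotype_unique
        elif o.phenotype_specificity == "unique_strong":
            pts += scheme.phenotype_unique_strong
        if pts > scheme.xl_case_cap:
            pts = scheme.xl_case_cap
            cap_applied = True
        total += max(pts, 0.0)
    return EvidenceItem(
        category="4-XL-case",
        points=round(total, 10),
        rationale=f"{len(observations)} X-linked observation(s)",
        cap_applied=cap_applied,
    )


def score_de_novo(obs: CaseObservation, scheme: ScoringScheme = DEFAULT_SCHEME) -> EvidenceItem:
    """De novo occurrence evidence (confirmed 0.45, assumed 0.30)."""
    pts = scheme.de_novo_points.get(obs.de_novo)
    if pts is None:
        raise ValueError(f"unknown de novo status {obs.de_novo!r}")
    return EvidenceItem(
        category="5-de-novo",
        points=pts,
        strength_label=obs.de_novo,
        rationale="de novo occurrence in the proband",
    )


def score_functional(obs: CaseObservation, scheme: ScoringScheme = DEFAULT_SCHEME) -> EvidenceItem:
    """Functional-evidence points: supporting 0.15, moderate 0.30, strong 0.45."""
    pts = scheme.functional_points.get(obs.functional_evidence)
    if pts is None:
        raise ValueError(f"unknown functional evidence level {obs.functional_evidence!r}")
    return EvidenceItem(
        category="FUNC",
        points=pts,
        strength_label=obs.functional_evidence,
        rationale="functional evidence of pathogenicity",
    )


# ---------------------------------------------------------------------------
# Aggregation


def aggregate(
    items: Sequence[EvidenceItem],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    event_id: str = "",
) -> ClassificationResult:
    """Sum evidence points and classify by the configured ranges."""
    total = round(sum(i.points for i in items), 10)
    return ClassificationResult(
        event_id=event_id,
        items=list(items),
        total=total,
        classification=scheme.classify_total(total),
    )


def classify_complex(
    component_results: Sequence[ClassificationResult],
    event_id: str = "",
) -> ClassificationResult:
    """Most-deleterious-component rule for complex rearrangements.

    Each canonical component is classified separately; the overall event
    takes the most deleterious classification (B < LB < VUS < LP < P).
    """
    if not component_results:
        raise ValueError("complex event has no component results")
    worst = max(component_results, key=lambda r: r.classification.rank)
    return ClassificationResult(
        event_id=event_id or worst.event_id,
        items=[i for r in component_results for i in r.items],
        total=worst.total,
        classification=worst.classification,
        component_results=list(component_results),
    )


# ---------------------------------------------------------------------------
# Event-level orchestration


def classify_event(
    e: CNVEvent,
    gc: "GeneContent",
    dosage: dict[str, DosageRecord],
    observations: Sequence[CaseObservation] = (),
    transcripts: Optional[dict[str, Transcript]] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    gene_count_source: Optional[str] = None,
    component_gcs: Optional[Sequence["GeneContent"]] = None,
) -> ClassificationResult:
    """Assemble and aggregate all evidence lines for one event.

    Complex events (or suspected ones) are classified per canonical
    component and combined with the most-deleterious rule. For simple
    events the evidence lines are: gene-number points, LoF (2E/PVS1)
    strength in the first established overlapped disease gene, de novo
    points (dominant/unknown inheritance), recessive or X-linked case
    evidence according to the gene's inheritance mode, phenotype
    specificity (outside the recessive path, which includes it), and
    functional evidence.
    """
    if e.resolved_type in (SVType.CPX, SVType.SUSPECTED_CPX) and len(e.components) > 1:
        parts = []
        for i, c in enumerate(e.components):
            sub = CNVEvent(
                sample_id=e.sample_id,
                components=[c],
                resolved_type=c.svtype,
                inheritance=e.inheritance,
                event_id=f"{e.event_id}.c{i}",
            )
            sub_gc = component_gcs[i] if component_gcs is not None else gc
            parts.append(
                classify_event(
                    sub, sub_gc, dosage, observations, transcripts, scheme, gene_count_source
                )
            )
        return classify_complex(parts, event_id=e.event_id)

    items: list[EvidenceItem] = []
    svtype = e.resolved_type
    if svtype in (SVType.DEL, SVType.DUP):
        items.append(
            score_gene_number(svtype, gc.count_for_scoring(gene_count_source), scheme)
        )

    established = [
        dosage[g] for g in gc.disease_genes if g in dosage and dosage[g].established
    ]
    moi = established[0].moi if established else None
    if established:
        d = established[0]
        t = (transcripts or {}).get(d.gene_or_region)
        strength = pvs1_strength(e, gc, d, transcript=t, scheme=scheme)
        if strength != "none":
            items.append(
                EvidenceItem(
                    category="2E-PVS1",
                    points=strength_to_points(strength, scheme),
                    strength_label=strength,
                    rationale=f"LoF in established gene {d.gene_or_region} ({strength})",
                )
            )

    if moi == "AR":
        if observations:
            items.append(score_ar_cases(observations, scheme))
    elif moi == "XL":
        if observations:
            items.append(score_xl_cases(observations, scheme))
    else:
        # dominant / unassigned: de novo occurrence plus phenotype bonus
        dn = None
        if observations:
            dn = max(
                (score_de_novo(o, scheme) for o in observations),
                key=lambda i: i.points,
            )
        elif e.inheritance is Inheritance.de_novo_confirmed:
            dn = EvidenceItem(
                category="5-de-novo",
                points=scheme.de_novo_points["confirmed"],
                strength_label="confirmed",
                rationale="de novo occurrence (trio-confirmed)",
            )
        if dn is not None and dn.points > 0:
            items.append(dn)
        if observations:
            ph = score_phenotype(observations, scheme)
            if ph.points > 0:
                items.append(ph)

    if observations:
        func = max(
            (score_functional(o, scheme) for o in observations),
            key=lambda i: i.points,
        )
        if func.points > 0:
            items.append(func)

    return aggregate(items, scheme, event_id=e.event_id)


# imported late to avoid a module cycle; re-exported for type checkers
from .annotate import GeneContent  # noqa: E402,F401
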