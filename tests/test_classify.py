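"""The quantitative pathogenicity engine: point tables, caps, LoF logic,
aggregation and the complex-SV rule."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exocnv.annotate import GeneContent
from exocnv.callset import CNVCall, SVType
from exocnv.classify import (
    CaseObservation,
    DosageRecord,
    EvidenceItem,
    ScoringScheme,
    Tier,
    aggregate,
    classify_complex,
    pvs1_strength,
    score_ar_cases,
    score_de_novo,
    score_functional,
    score_gene_number,
    score_phenotype,
    score_xl_cases,
    strength_to_points,
)
from exocnv.events import CNVEvent
from exocnv.genome import Biotype, GenomicInterval, Transcript


def make_event(start, end, svtype="DEL", cn=1, chrom="chr1"):
    return CNVEvent(
        sample_id="S0",
        components=[CNVCall("S0", GenomicInterval(chrom, start, end), SVType(svtype), cn, 500.0)],
        resolved_type=SVType(svtype),
    )


def make_gc(intragenic=True, genes=("G1",)):
    return GeneContent(
        n_protein_coding={"src": len(genes)},
        genes={"src": list(genes)},
        disease_genes=list(genes),
        intragenic=intragenic,
        exon_counts={g: 1 for g in genes},
        discordant_sources=False,
    )


def obs(**kw):
    kw.setdefault("proband_id", "P1")
    return CaseObservation(**kw)


AR_GENE = DosageRecord("G1", "AR", established=True)


@pytest.fixture
def transcript():
    # 10 exons, 100 bp each except exon 2 (101 bp), fully coding, 400-bp introns
    exons = []
    pos = 10_000
    for i in range(10):
        length = 101 if i == 1 else 100
        exons.append(GenomicInterval("chr1", pos, pos + length))
        pos += length + 400
    span = GenomicInterval("chr1", exons[0].start, exons[-1].end)
    return Transcript("G1", "G1", Biotype.protein_coding, "+", exons, cds=span)


class TestStrengthPoints:
    @pytest.mark.parametrize(
        "strength,points",
        [("PVS1", 0.90), ("strong", 0.45), ("moderate", 0.30), ("supporting", 0.15), ("none", 0.0)],
    )
    def test_tier_mapping(self, strength, points):
        assert strength_to_points(strength) == points

    def test_unknown_strength_rejected(self):
        with pytest.raises(ValueError):
            strength_to_points("very strong")


class TestPVS1:
    def test_frameshifting_exon_deletion_with_nmd_is_pvs1(self, transcript):
        # deleting exons 2-4 removes 301 coding bp (frameshift), stop well
        # upstream of the last-junction boundary
        e = make_event(transcript.exons[1].start - 50, transcript.exons[3].end + 50)
        assert pvs1_strength(e, make_gc(), AR_GENE, transcript) == "PVS1"

    def test_full_gene_deletion_is_pvs1(self, transcript):
        e = make_event(transcript.span.start - 1_000, transcript.span.end + 1_000)
        assert pvs1_strength(e, make_gc(intragenic=False), AR_GENE, transcript) == "PVS1"

    def test_inframe_last_exon_deletion_steps_down(self, transcript):
        # removing only the final exon (100 bp, ~10% of coding) escapes NMD
        e = make_event(transcript.exons[9].start - 50, transcript.exons[9].end + 50)
        strength = pvs1_strength(e, make_gc(), AR_GENE, transcript)
        assert strength in {"moderate", "supporting"}

    def test_intronic_deletion_is_not_lof(self, transcript):
        e = make_event(transcript.exons[0].end + 10, transcript.exons[1].start - 10)
        assert pvs1_strength(e, make_gc(), AR_GENE, transcript) == "none"

    def test_inversion_enclosing_whole_gene_not_lof(self, transcript):
        e = make_event(transcript.span.start - 5_000, transcript.span.end + 5_000, svtype="INV")
        assert pvs1_strength(e, make_gc(intragenic=False), AR_GENE, transcript) == "none"

    def test_inversion_with_one_breakpoint_in_gene_is_lof(self, transcript):
        e = make_event(transcript.exons[2].start, transcript.span.end + 50_000, svtype="INV")
        assert pvs1_strength(e, make_gc(intragenic=False), AR_GENE, transcript) == "PVS1"

    def test_insertion_within_coding_exon_is_lof(self, transcript):
        mid = transcript.exons[2].start + 50
        e = make_event(mid, mid + 300, svtype="INS")
        assert pvs1_strength(e, make_gc(), AR_GENE, transcript) != "none"

    def test_insertion_in_intron_not_lof(self, transcript):
        mid = transcript.exons[2].end + 100
        e = make_event(mid, mid + 50, svtype="INS")
        assert pvs1_strength(e, make_gc(), AR_GENE, transcript) == "none"

    def test_duplication_not_lof_by_default(self, transcript):
        e = make_event(transcript.exons[1].start - 50, transcript.exons[3].end + 50,
                       svtype="DUP", cn=3)
        assert pvs1_strength(e, make_gc(), AR_GENE, transcript) == "none"

    def test_unestablished_gene_rejected(self, transcript):
        novel = DosageRecord("G1", "AR", established=False)
        e = make_event(transcript.exons[1].start, transcript.exons[3].end)
        with pytest.raises(ValueError, match="case-evidence"):
            pvs1_strength(e, make_gc(), novel, transcript)


class TestGeneNumber:
    @pytest.mark.parametrize(
        "svtype,n,expected",
        [
            ("DEL", 10, 0.0),
            ("DEL", 24, 0.0),
            ("DEL", 25, 0.45),
            ("DEL", 30, 0.45),
            ("DEL", 34, 0.45),
            ("DEL", 35, 0.90),  # contiguous-bin choice for the unprinted value
            ("DEL", 60, 0.90),
            ("DUP", 34, 0.0),
            ("DUP", 35, 0.45),
            ("DUP", 40, 0.45),
            ("DUP", 49, 0.45),
            ("DUP", 50, 0.90),
        ],
    )
    def test_bins(self, svtype, n, expected):
        assert score_gene_number(SVType(svtype), n).points == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            score_gene_number(SVType.DEL, -1)


class TestARCases:
    def test_in_trans_pathogenic(self):
        item = score_ar_cases([obs(phase="in_trans_confirmed", second_variant_class="P")])
        assert item.points == pytest.approx(0.30)

    def test_phase_unknown_by_second_variant(self):
        assert score_ar_cases(
            [obs(phase="unknown", second_variant_class="P")]
        ).points == pytest.approx(0.15)
        assert score_ar_cases(
            [obs(phase="unknown", second_variant_class="LP")]
        ).points == pytest.approx(0.08)

    def test_homozygous_single_and_cap(self):
        assert score_ar_cases([obs(zygosity="hom")]).points == pytest.approx(0.15)
        three = score_ar_cases([obs(zygosity="hom", proband_id=f"P{i}") for i in range(3)])
        assert three.points == pytest.approx(0.30)
        assert three.cap_applied

    def test_vus_in_trans_and_cap(self):
        one = score_ar_cases([obs(phase="in_trans_confirmed", second_variant_class="VUS")])
        assert one.points == pytest.approx(0.08)
        many = score_ar_cases(
            [obs(phase="in_trans_confirmed", second_variant_class="VUS", proband_id=f"P{i}")
             for i in range(4)]
        )
        assert many.points == pytest.approx(0.16)
        assert many.cap_applied

    def test_phase_unknown_vus_scores_nothing(self):
        assert score_ar_cases([obs(phase="unknown", second_variant_class="VUS")]).points == 0.0

    def test_in_cis_scores_nothing(self):
        assert score_ar_cases([obs(phase="in_cis", second_variant_class="P")]).points == 0.0

    def test_aggregate_case_cap(self):
        many = score_ar_cases(
            [obs(phase="in_trans_confirmed", second_variant_class="P", proband_id=f"P{i}")
             for i in range(5)]
        )
        assert many.points == pytest.approx(0.90)
        assert many.cap_applied

    def test_phenotype_bonus_applied_once(self):
        item = score_ar_cases(
            [
                obs(phase="in_trans_confirmed", second_variant_class="P",
                    phenotype_specificity="unique"),
                obs(phase="in_trans_confirmed", second_variant_class="P",
                    phenotype_specificity="unique", proband_id="P2"),
            ]
        )
        assert item.points == pytest.approx(0.30 + 0.30 + 0.15)


class TestPhenotypeAndFunctional:
    def test_phenotype_levels(self):
        assert score_phenotype([obs(phenotype_specificity="unique")]).points == 0.15
        assert score_phenotype([obs(phenotype_specificity="unique_strong")]).points == 0.30
        assert score_phenotype([obs()]).points == 0.0

    @pytest.mark.parametrize(
        "level,points", [("supporting", 0.15), ("moderate", 0.30), ("strong", 0.45), ("none", 0.0)]
    )
    def test_functional_levels(self, level, points):
        assert score_functional(obs(functional_evidence=level)).points == points

    def test_de_novo_levels(self):
        assert score_de_novo(obs(de_novo="confirmed")).points == 0.45
        assert score_de_novo(obs(de_novo="assumed")).points == 0.30
        assert score_de_novo(obs(de_novo="inherited_unaffected")).points == 0.0


class TestXLCases:
    def test_branch_lookup_matches_configured_table(self):
        scheme = ScoringScheme()
        item = score_xl_cases([obs(sex="M", de_novo="confirmed")], scheme)
        assert item.points == scheme.xl_table["M|confirmed"]

    def test_single_case_capped_after_phenotype_upgrade(self):
        item = score_xl_cases(
            [obs(sex="M", de_novo="confirmed", phenotype_specificity="unique_strong")]
        )
        assert item.points <= 0.45

    def test_in_cis_scores_nothing(self):
        assert score_xl_cases([obs(sex="M", de_novo="confirmed", phase="in_cis")]).points == 0.0

    def test_missing_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            score_xl_cases([obs(de_novo="confirmed")])

    def test_carrier_mother_status_selects_branch(self):
        scheme = ScoringScheme()
        affected = score_xl_cases(
            [obs(sex="M", de_novo="inherited_unaffected", maternal_carrier_affected=True)],
            scheme,
        )
        assert affected.points == scheme.xl_table["M|inherited_affected"]


class TestAggregation:
    def test_single_de_novo_is_vus(self):
        res = aggregate([EvidenceItem("5-de-novo", 0.45)])
        assert res.total == pytest.approx(0.45)
        assert res.classification is Tier.VUS

    def test_pvs1_plus_ar_case_is_pathogenic(self):
        res = aggregate([EvidenceItem("2E-PVS1", 0.90), EvidenceItem("4-AR-case", 0.30)])
        assert res.total == pytest.approx(1.20)
        assert res.classification is Tier.P

    def test_empty_items_is_vus(self):
        res = aggregate([])
        assert res.total == 0.0 and res.classification is Tier.VUS

    def test_likely_pathogenic_band(self):
        assert aggregate([EvidenceItem("x", 0.90)]).classification is Tier.LP
        assert aggregate([EvidenceItem("x", 0.98)]).classification is Tier.LP
        assert aggregate([EvidenceItem("x", 0.99)]).classification is Tier.P

    def test_benign_direction(self):
        assert aggregate([EvidenceItem("x", -0.95)]).classification is Tier.LB
        assert aggregate([EvidenceItem("x", -1.0)]).classification is Tier.B

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(pathogenic_min=0.8, likely_pathogenic_min=0.9)

    @settings(max_examples=200, derandomize=True)
    @given(
        base=st.lists(st.floats(-1.5, 1.5), max_size=5),
        extra=st.floats(0, 1.0),
    )
    def test_monotone_under_added_nonnegative_evidence(self, base, extra):
        items = [EvidenceItem("x", p) for p in base]
        before = aggregate(items).classification
        after = aggregate(items + [EvidenceItem("y", extra)]).classification
        assert after.rank >= before.rank


class TestComplexRule:
    def _res(self, tier):
        return aggregate([EvidenceItem("x", {"P": 1.2, "LP": 0.9, "VUS": 0.0,
                                             "LB": -0.95, "B": -1.2}[tier])])

    def test_pathogenic_component_dominates(self):
        overall = classify_complex([self._res("P"), self._res("VUS")])
        assert overall.classification is Tier.P

    def test_all_vus_stays_vus(self):
        assert classify_complex([self._res("VUS"), self._res("VUS")]).classification is Tier.VUS

    def test_ordering_lb_lp(self):
        assert classify_complex([self._res("LB"), self._res("LP")]).classification is Tier.LP

    def test_order_independent_and_associative(self):
        parts = [self._res(t) for t in ("LB", "VUS", "LP")]
        a = classify_complex(parts).classification
        b = classify_complex(list(reversed(parts))).classification
        nested = classify_complex([classify_complex(parts[:2]), parts[2]]).classification
        assert a == b == nested

    def test_empty_components_rejected(self):
        with pytest.raises(ValueError):
            classify_complex([])


class TestWorkedDuplicationExample:
    """A de novo ~857-kb duplication whose gene count depends on the source:
    28 protein-coding genes under the curated database, 35 under the
    comprehensive one — the classification moves from VUS toward
    pathogenic purely on the gene-number evidence."""

    def _classify(self, n_genes):
        items = [
            score_gene_number(SVType.DUP, n_genes),
            EvidenceItem("5-de-novo", 0.45, "confirmed"),
        ]
        return aggregate(items)

    def test_28_genes_is_vus(self):
        assert self._classify(28).classification is Tier.VUS

    def test_35_genes_reaches_likely_pathogenic(self):
        res = self._classify(35)
        assert res.classification.rank >= Tier.LP.rank


def test_scheme_yaml_roundtrip(tmp_path):
    scheme = ScoringScheme(ar_case_cap=0.75)
    path = tmp_path / "scheme.yaml"
    scheme.to_yaml(path)
    back = ScoringScheme.from_yaml(path)
    assert back.ar_case_cap == 0.75
    assert back.del_gene_bins == scheme.del_gene_bins
    assert back.xl_table == scheme.xl_table
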