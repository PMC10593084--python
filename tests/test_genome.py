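"""Interval arithmetic, gene-model containers and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exocnv.genome import (
    Biotype,
    GeneModel,
    GenomicInterval,
    ProbeSet,
    Transcript,
    count_overlapping_probes,
    exons_overlapped,
    normalize_chrom,
    read_gene_model,
    read_probes,
    reciprocal_overlap,
    write_gene_model,
    write_probes,
)


def brute_force_reciprocal(a: GenomicInterval, b: GenomicInterval) -> float:
    """Per-base oracle: count shared positions, take min fraction."""
    if a.chrom != b.chrom:
        return 0.0
    shared = len(set(range(a.start, a.end)) & set(range(b.start, b.end)))
    if shared == 0:
        return 0.0
    return min(shared / a.length, shared / b.length)


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 100), (0, 100), 1.0),
            ((0, 100), (50, 150), 0.5),
            ((0, 1000), (900, 910), 0.01),
            ((0, 100), (100, 200), 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        ia = GenomicInterval("chr1", *a)
        ib = GenomicInterval("chr1", *b)
        assert reciprocal_overlap(ia, ib) == pytest.approx(expected)
        assert reciprocal_overlap(ia, ib) == pytest.approx(brute_force_reciprocal(ia, ib))

    def test_different_chromosomes(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr2", 0, 100)
        assert reciprocal_overlap(a, b) == 0.0

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)

    @settings(max_examples=200, derandomize=True)
    @given(
        s1=st.integers(0, 10_000),
        l1=st.integers(1, 5_000),
        s2=st.integers(0, 10_000),
        l2=st.integers(1, 5_000),
    )
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        r = reciprocal_overlap(a, b)
        assert r == reciprocal_overlap(b, a)
        assert 0.0 <= r <= 1.0
        # identity iff intervals identical
        assert (r == 1.0) == (a == b)

    def test_monotone_under_shift(self):
        a = GenomicInterval("chr1", 0, 1000)
        values = [
            reciprocal_overlap(a, GenomicInterval("chr1", shift, shift + 1000))
            for shift in range(0, 1500, 100)
        ]
        assert values == sorted(values, reverse=True)


class TestProbeCounting:
    def test_probes_inside(self):
        ps = ProbeSet([GenomicInterval("chr1", p, p + 1) for p in (110, 150, 190)])
        assert count_overlapping_probes(GenomicInterval("chr1", 100, 200), ps) == 3

    def test_half_open_boundaries(self):
        ps = ProbeSet([GenomicInterval("chr1", p, p + 1) for p in (99, 200)])
        assert count_overlapping_probes(GenomicInterval("chr1", 100, 200), ps) == 0

    def test_duplicate_positions_counted_once(self):
        ps = ProbeSet([GenomicInterval("chr1", 150, 151)] * 3)
        assert count_overlapping_probes(GenomicInterval("chr1", 100, 200), ps) == 1

    def test_matches_linear_scan_on_random_cases(self):
        rng = np.random.default_rng(42)
        positions = sorted(int(p) for p in rng.integers(0, 100_000, size=1_000))
        ps = ProbeSet([GenomicInterval("chr1", p, p + 1) for p in positions])
        unique = sorted(set(positions))
        for _ in range(1_000):
            start = int(rng.integers(0, 99_000))
            end = start + int(rng.integers(1, 5_000))
            iv = GenomicInterval("chr1", start, end)
            oracle = sum(start <= p < end for p in unique)
            assert count_overlapping_probes(iv, ps) == oracle


@pytest.fixture
def transcript():
    # 5 exons of 100 bp separated by 400-bp introns on chr1 starting at 1000
    exons = [GenomicInterval("chr1", 1000 + i * 500, 1100 + i * 500) for i in range(5)]
    return Transcript(
        gene_id="G1", gene_name="G1", biotype=Biotype.protein_coding, strand="+", exons=exons
    )


class TestExonsOverlapped:
    def test_full_transcript(self, transcript):
        count, idx = exons_overlapped(GenomicInterval("chr1", 0, 10_000), transcript)
        assert count == 5 and idx == [0, 1, 2, 3, 4]

    def test_strictly_intronic(self, transcript):
        count, idx = exons_overlapped(GenomicInterval("chr1", 1150, 1450), transcript)
        assert count == 0 and idx == []

    def test_partial_upstream_exon_plus_full_exon(self, transcript):
        # a deletion removing exon 2 and the tail of exon 1 touches 2 exons
        iv = GenomicInterval("chr1", 1050, 1650)
        count, idx = exons_overlapped(iv, transcript)
        assert count == 2 and idx == [0, 1]


class TestGeneModelIO:
    def test_bed12_roundtrip(self, transcript, tmp_path):
        gm = GeneModel([transcript], source_label="test")
        path = tmp_path / "genes.bed12"
        write_gene_model(gm, path, format="bed12")
        back = read_gene_model(path, format="bed12", source_label="test")
        assert len(back.transcripts) == 1
        assert back.transcripts[0].exons == transcript.exons

    def test_gff3_roundtrip_and_coordinate_conversion(self, transcript, tmp_path):
        gm = GeneModel([transcript], source_label="test")
        path = tmp_path / "genes.gff3"
        write_gene_model(gm, path, format="gff3")
        text = path.read_text()
        # 1-based inclusive on disk: first exon written as 1001..1100
        assert "\t1001\t1100\t" in text
        back = read_gene_model(path, format="gff3", source_label="test")
        assert back.transcripts[0].exons == transcript.exons
        assert back.transcripts[0].biotype is Biotype.protein_coding

    def test_gff3_unknown_biotype_becomes_other(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t101\t200\t.\t+\t.\tID=G1;biotype=weird_rna\n"
            "chr1\tx\texon\t101\t200\t.\t+\t.\tParent=G1\n"
        )
        with pytest.warns(UserWarning, match="biotype"):
            gm = read_gene_model(path, format="gff3")
        t = gm.transcripts[0]
        assert t.biotype is Biotype.other
        assert t.exons[0] == GenomicInterval("chr1", 100, 200)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchr1\tonly\tthree\n")
        with pytest.raises(ValueError, match=":2"):
            read_gene_model(path, format="gff3")

    def test_probe_bed3_roundtrip(self, tmp_path):
        ps = ProbeSet([GenomicInterval("chr1", p, p + 1) for p in (5, 10, 20)])
        path = tmp_path / "probes.bed"
        write_probes(ps, path)
        back = read_probes(path)
        assert len(back) == 3
        assert back.probes == ps.probes

    def test_query_returns_overlapping_transcripts(self, transcript):
        gm = GeneModel([transcript], source_label="test")
        assert gm.query(GenomicInterval("chr1", 1050, 1060)) == [transcript]
        assert gm.query(GenomicInterval("chr1", 5000, 6000)) == []
        assert gm.query(GenomicInterval("chr2", 1000, 2000)) == []


def test_chromosome_dialect_normalization():
    assert normalize_chrom("1") == "chr1"
    assert normalize_chrom("chrX") == "chrX"
    assert normalize_chrom("chr5", prefix=False) == "5"
    assert normalize_chrom("MT") == "chrM"
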