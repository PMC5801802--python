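import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastiq import (
    GeneFeature,
    Plastome,
    canonicalize,
    extract_cds,
    load_coverage,
    load_features,
    load_plastome,
    revcomp,
)
from plastiq.irdetect import QuadripartiteStructure
from plastiq.model import write_features, write_plastome

from conftest import random_seq


class TestLoadPlastome:
    def test_case_and_rna_normalization(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">rec1\natgcaugcat\n")
        plastome = load_plastome(p)
        assert plastome.length == 10
        assert plastome.sequence == "ATGCATGCAT"

    def test_multi_record_rejected(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="expected 1 record, found 2"):
            load_plastome(p)

    def test_illegal_characters_listed(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nATGX\n")
        with pytest.raises(ValueError, match="X"):
            load_plastome(p)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Plastome("x", "")

    def test_roundtrip(self, tmp_path, rng):
        plastome = Plastome("g1", random_seq(rng, 500))
        fp = tmp_path / "g.fasta"
        write_plastome(plastome, fp)
        again = load_plastome(fp)
        assert again.sequence == plastome.sequence
        assert again.id == plastome.id


class TestLoadFeatures:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("ndhA\tprotein\t+\t100-639,1740-2292\n")
        feats = load_features(p, 3000)
        assert feats[0].exons == [(99, 639), (1739, 2292)]
        assert feats[0].strand == "+"

    def test_short_protein_exon_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("tiny\tprotein\t+\t5-6\n")
        with pytest.raises(ValueError):
            load_features(p, 100)

    def test_trna_row(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("trnH\ttRNA\t-\t5-80\n")
        feats = load_features(p, 100)
        assert feats[0].feature_class == "tRNA"
        assert feats[0].strand == "-"

    def test_beyond_length_without_wrap_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("g\tprotein\t+\t90-120\n")
        with pytest.raises(ValueError, match="wrap"):
            load_features(p, 100)

    def test_wrap_declared_allowed(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("g\tprotein\t+\t90-120\twrap\n")
        feats = load_features(p, 100)
        assert feats[0].exons == [(89, 120)]
        assert feats[0].wraps_origin

    def test_unknown_class_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("g\tmystery\t+\t1-30\n")
        with pytest.raises(ValueError, match="class"):
            load_features(p, 100)

    def test_roundtrip(self, tmp_path):
        feats = [
            GeneFeature("ndhA", "protein", [(99, 639), (1739, 2292)], "+"),
            GeneFeature("trnH", "tRNA", [(4, 80)], "-"),
        ]
        fp = tmp_path / "rt.tsv"
        write_features(feats, fp)
        again = load_features(fp, 3000)
        assert [(f.name, f.feature_class, f.strand, f.exons) for f in again] \
            == [("trnH", "tRNA", "-", [(4, 80)]),
                ("ndhA", "protein", "+", [(99, 639), (1739, 2292)])]

    def test_gff3(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr\t.\tCDS\t100\t639\t.\t+\t0\tID=cds1;gene=ndhA\n"
            "chr\t.\tCDS\t1740\t2292\t.\t+\t0\tID=cds2;gene=ndhA\n"
            "chr\t.\ttRNA\t5\t80\t.\t-\t.\tID=t1;gene=trnH\n"
        )
        feats = load_features(p, 3000)
        by = {f.name: f for f in feats}
        assert by["ndhA"].exons == [(99, 639), (1739, 2292)]
        assert by["trnH"].feature_class == "tRNA"


def _toy_structure(n=400, ir=(100, 180), irb=(240, 320)):
    return QuadripartiteStructure(
        genome_length=n, lsc=(irb[1], irb[1] + (n - irb[1]) + ir[0]),
        ir_a=ir, ssc=(ir[1], irb[0]), ir_b=irb,
    )


class TestCanonicalize:
    def test_identity(self, rng):
        seq = random_seq(rng, 400)
        plastome = Plastome("g", seq)
        struct = QuadripartiteStructure(
            genome_length=400, lsc=(0, 180), ir_a=(180, 260),
            ssc=(260, 320), ir_b=(320, 400),
        )
        rotated, offset = canonicalize(plastome, struct)
        assert offset == 0
        assert rotated.sequence == seq

    def test_rotation_roundtrip(self, rng):
        seq = random_seq(rng, 400)
        canonical = Plastome("g", seq)
        shifted = canonical.rotated(-37)  # rotate away from canonical
        # in the shifted genome the LSC starts at 37, so canonicalizing
        # rotates by 37 and restores the original presentation
        struct = QuadripartiteStructure(
            genome_length=400, lsc=(37, 217), ir_a=(217, 297),
            ssc=(297, 357), ir_b=(357, 437),
        )
        rotated, offset = canonicalize(shifted, struct)
        assert offset == 37
        assert rotated.sequence == shifted.rotated(37).sequence
        # applying the offset twice round-trips
        assert rotated.rotated(-offset).sequence == shifted.sequence

    def test_length_and_composition_preserved(self, rng):
        seq = random_seq(rng, 400)
        plastome = Plastome("g", seq)
        struct = QuadripartiteStructure(
            genome_length=400, lsc=(100, 280), ir_a=(280, 360),
            ssc=(360, 420), ir_b=(20, 100),
        )
        rotated, _ = canonicalize(plastome, struct)
        assert rotated.length == 400
        assert sorted(rotated.sequence) == sorted(seq)


class TestFeatureGeometry:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.integers(-400, 400))
    def test_rotation_preserves_pairwise_distance(self, offset):
        n = 400
        f1 = GeneFeature("a", "protein", [(10, 40)], "+")
        f2 = GeneFeature("b", "protein", [(200, 260)], "+")
        d0 = (f2.start - f1.start) % n
        g1, g2 = f1.shifted(offset, n), f2.shifted(offset, n)
        assert (g2.start - g1.start) % n == d0
        assert g1.total_exon_len == f1.total_exon_len

    def test_extract_cds_minus_strand(self):
        seq = "AAAA" + "TTACAT" + "GGGG"  # revcomp(ATGTAA) = TTACAT
        plastome = Plastome("g", seq)
        f = GeneFeature("x", "protein", [(4, 10)], "-")
        assert extract_cds(plastome, f) == "ATGTAA"

    def test_extract_cds_wrapping(self):
        seq = "GTAACCCCCCAT"  # ATG at 10..12 wraps, then TAA
        plastome = Plastome("g", seq)
        f = GeneFeature("x", "protein", [(10, 16)], "+", wraps_origin=True)
        assert extract_cds(plastome, f) == "ATGTAA"


class TestCoverage:
    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "cov.tsv"
        p.write_text("1\t30\n2\t31\n3\t29\n")
        track = load_coverage(p)
        assert list(track.depths) == [30.0, 31.0, 29.0]

    def test_bedgraph(self, tmp_path):
        p = tmp_path / "cov.bg"
        p.write_text("chr\t0\t2\t30\nchr\t2\t3\t60\n")
        track = load_coverage(p)
        assert list(track.depths) == [30.0, 30.0, 60.0]

    def test_negative_depth_rejected(self):
        from plastiq import CoverageTrack

        with pytest.raises(ValueError):
            CoverageTrack(np.array([1.0, -2.0]))
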