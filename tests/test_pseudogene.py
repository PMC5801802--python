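import numpy as np
import pytest

from plastiq import (
    GeneFeature,
    align_cds,
    call_status,
    scan_frameshifts,
    scan_stops,
    tabulate_gene_content,
)
from plastiq.pseudogene import GeneStatus

from conftest import random_cds


def aligned(tgt, ref, gene="g", species="s"):
    return align_cds(tgt, ref, gene=gene, species=species)


class TestScanFrameshifts:
    def test_single_base_deletion_in_codon_two(self):
        ref = "ATGAAACCCGGGTGA"
        tgt = "ATGAACCCGGGTGA"  # one A of codon 2 deleted
        aln = aligned(tgt, ref)
        fs = scan_frameshifts(aln)
        assert len(fs) == 1
        assert fs[0].aa_ref == 2
        assert fs[0].change == "del1@4"
        assert fs[0].kind == "FS"

    def test_in_frame_deletion_emits_nothing(self):
        ref = "ATGAAACCCGGGTGA"
        tgt = "ATGAAAGGGTGA"  # codon 3 (CCC) cleanly removed
        aln = aligned(tgt, ref)
        assert scan_frameshifts(aln) == []

    def test_compensating_indels_restore_frame(self, rng):
        ref = random_cds(rng, 20, no_adjacent_repeat=True)
        # +1 nt inside codon 5, -1 nt inside codon 9
        ins_at = 4 * 3
        del_at = 8 * 3
        tgt = ref[:ins_at] + "A" if ref[ins_at - 1] != "A" else ref[:ins_at] + "C"
        ins_base = tgt[-1]
        tgt = tgt + ref[ins_at:del_at] + ref[del_at + 1:]
        aln = aligned(tgt, ref)
        fs = scan_frameshifts(aln)
        assert [m.aa_ref for m in fs] == [5, 9]
        assert fs[0].change.startswith(f"ins1:{ins_base}@")
        assert fs[0].frame_state_at_site == 0
        assert fs[1].frame_state_at_site == 1  # shifted until second indel

    def test_planted_indel_grid_small(self, rng):
        """FS emitted iff indel length is not 0 mod 3, at the planted
        codon (repeat-free gene so the placement is unambiguous)."""
        from conftest import leftmost_del

        ref = random_cds(rng, 30, no_adjacent_repeat=True)
        for L in (1, 2, 3):
            for k in (2, 11, 25):
                o = (k - 1) * 3
                tgt = ref[:o] + ref[o + L:]
                fs = scan_frameshifts(aligned(tgt, ref))
                if L % 3 == 0:
                    assert fs == []
                else:
                    no = leftmost_del(ref, o, L)
                    assert [(m.aa_ref, m.change) for m in fs] \
                        == [(1 + no // 3, f"del{L}@{no + 1}")]


class TestScanStops:
    def test_simple_stop_gain(self):
        ref = "ATGGAAGAATGA"
        tgt = "ATGTAAGAATGA"
        aln = aligned(tgt, ref)
        sc = scan_stops(aln)
        assert len(sc) == 1
        assert (sc[0].aa_ref, sc[0].aa_target) == (2, 2)
        assert sc[0].frameshift_induced is False
        assert sc[0].change == "TAA@4"

    def test_identity_has_no_stops(self, rng):
        ref = random_cds(rng, 60)
        assert scan_stops(aligned(ref, ref)) == []

    def test_terminal_stop_never_premature(self):
        ref = "ATGGAATGA"
        tgt = "ATGGAGTGA"  # synonymous change, terminal TGA kept
        assert scan_stops(aligned(tgt, ref)) == []

    def test_frameshift_induced_stop_flagged(self):
        # deleting one base of codon 2 shifts the frame; the TGA that
        # then appears downstream in the target's running frame is a
        # consequence of the frameshift, not an independent stop gain
        ref = "ATGAACTTGACCTGA"  # ATG AAC TTG ACC TGA, no premature stop
        tgt = "ATGACTTGACCTGA"   # -1 nt in codon 2 -> ATG ACT TGA CCT GA
        aln = aligned(tgt, ref)
        fs = scan_frameshifts(aln)
        assert len(fs) == 1 and fs[0].aa_ref == 2
        sc = scan_stops(aln, fs)
        assert len(sc) == 1
        assert sc[0].aa_target == 3
        assert sc[0].frameshift_induced is True

    def test_every_stop_after_uncompensated_fs_is_induced(self, rng):
        ref = random_cds(rng, 50, no_adjacent_repeat=True)
        tgt = ref[:30] + ref[31:]  # -1 nt at codon 11, never compensated
        aln = aligned(tgt, ref)
        fs = scan_frameshifts(aln)
        sc = scan_stops(aln, fs)
        assert all(m.frameshift_induced for m in sc if m.aa_ref > 11)


class TestCallStatus:
    def test_absent_on_empty_target(self, rng):
        ref = random_cds(rng, 50)
        st = call_status("g", "s", align_cds("", ref))
        assert st.status == "absent"

    def test_partial_on_missing_exon(self, rng):
        ref = random_cds(rng, 100)
        exon_map = [(0, 150), (150, 300)]
        tgt = ref[:150]  # second exon gone
        aln = aligned(tgt, ref)
        st = call_status("g", "s", aln, exon_map=exon_map)
        assert st.status == "partial"
        assert st.missing_exons == [2]

    def test_single_fs_makes_pseudogene(self, rng):
        ref = random_cds(rng, 100, no_adjacent_repeat=True)
        tgt = ref[:90] + ref[91:]
        st = call_status("g", "s", aligned(tgt, ref))
        assert st.status == "potential_pseudogene"
        assert any(m.kind == "FS" for m in st.mutations)

    def test_intact(self, rng):
        ref = random_cds(rng, 100)
        st = call_status("g", "s", aligned(ref, ref))
        assert st.status == "intact"
        assert st.mutations == []


class TestTabulate:
    def test_arithmetic_shape(self):
        """79 single-copy protein genes plus 6 genes duplicated in the
        IR (12 copies), 30 tRNA and 4 rRNA types tally as 91 (12) — the
        shape of an autotrophic outgroup genome's content row."""
        feats = []
        for i in range(79):
            feats.append(GeneFeature(f"p{i}", "protein", [(i * 40, i * 40 + 30)],
                                     "+", copy_number=1))
        for i in range(6):
            feats.append(GeneFeature(f"d{i}", "protein",
                                     [(4000 + i * 40, 4000 + i * 40 + 30)],
                                     "+", copy_number=2))
        for i in range(30):
            feats.append(GeneFeature(f"trn{i}", "tRNA",
                                     [(6000 + i * 40, 6000 + i * 40 + 30)], "+"))
        for i in range(4):
            feats.append(GeneFeature(f"rrn{i}", "rRNA",
                                     [(8000 + i * 40, 8000 + i * 40 + 30)], "+"))
        statuses = [GeneStatus(f"p{i}", "sp", "intact") for i in range(79)]
        df = tabulate_gene_content(statuses, {"sp": feats})
        row = df.iloc[0]
        assert row.total_protein_genes == 91
        assert row["duplicated"] == 12
        assert row.potential_pseudogenes == 0
        assert row.tRNA_types == 30
        assert row.rRNA_types == 4

    def test_pseudogene_count(self):
        feats = [GeneFeature(f"g{i}", "protein", [(i * 40, i * 40 + 30)], "+")
                 for i in range(5)]
        statuses = [
            GeneStatus("g0", "sp", "potential_pseudogene"),
            GeneStatus("g1", "sp", "partial"),
            GeneStatus("g2", "sp", "intact"),
        ]
        df = tabulate_gene_content(statuses, {"sp": feats})
        assert df.iloc[0].potential_pseudogenes == 2
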