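import numpy as np
import pytest

from plastiq import (
    CoverageTrack,
    Plastome,
    detect_ir_from_coverage,
    find_inverted_repeat,
    partition_quadripartite,
    revcomp,
)

from conftest import random_seq
from oracles import brute_force_inverted_repeat


def planted_ir_sequence(rng, a_len=100, r_len=80, b_len=60, c_len=80,
                        mutate=None):
    """A + R + B + revcomp(R) + C with mismatch guards so that chance
    single-base extension beyond the planted arms is impossible."""
    A, R, B, C = (random_seq(rng, n) for n in (a_len, r_len, b_len, c_len))
    # guards: bases flanking each arm must not complement each other
    A = A[:-1] + "A"
    B = "A" + B[1:-1] + "A"
    C = "A" + C[1:]
    seq = A + R + B + revcomp(R) + C
    if mutate is not None:
        i = a_len + mutate
        old = seq[i]
        seq = seq[:i] + ("C" if old != "C" else "G") + seq[i + 1:]
    return seq


class TestFindInvertedRepeat:
    def test_planted_exact(self, rng):
        seq = planted_ir_sequence(rng)
        hit = find_inverted_repeat(Plastome("t", seq), min_len=50,
                                   max_mismatch_frac=0.0)
        assert hit == ((100, 180), (240, 320), 0)

    def test_planted_one_mismatch(self, rng):
        seq = planted_ir_sequence(rng, mutate=40)
        hit = find_inverted_repeat(Plastome("t", seq), min_len=50,
                                   max_mismatch_frac=0.02)
        a, b, mism = hit
        assert (a, b) == ((100, 180), (240, 320))
        assert mism == 1

    def test_no_repeat_in_random_sequence(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 500)
        assert brute_force_inverted_repeat(seq, 50, 0.0) is None
        assert find_inverted_repeat(Plastome("t", seq), min_len=50,
                                    max_mismatch_frac=0.0) is None

    def test_matches_bruteforce_on_small_batch(self):
        """Quick oracle agreement; the full 100-sequence sweep is an
        acceptance criterion."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            seq = planted_ir_sequence(rng, a_len=40, r_len=60, b_len=30,
                                      c_len=40)
            oracle = brute_force_inverted_repeat(seq, 50, 0.0)
            hit = find_inverted_repeat(Plastome("t", seq), min_len=50,
                                       max_mismatch_frac=0.0)
            assert oracle is not None and hit is not None
            a, b, _ = hit
            assert b[0] - b[1] == a[0] - a[1]
            assert (b[1] - b[0]) == oracle[0]
            assert (a[0], b[0]) in oracle[1]

    def test_rotation_invariance(self, rng):
        seq = planted_ir_sequence(rng)
        n = len(seq)
        base = find_inverted_repeat(Plastome("t", seq), min_len=50,
                                    max_mismatch_frac=0.0)
        for k in (37, 150, 333):
            rot = Plastome("t", seq).rotated(k)
            hit = find_inverted_repeat(rot, min_len=50, max_mismatch_frac=0.0)
            a, b, mism = hit
            back = sorted(
                [((a[0] + k) % n, (a[0] + k) % n + (a[1] - a[0])),
                 ((b[0] + k) % n, (b[0] + k) % n + (b[1] - b[0]))]
            )
            assert back == sorted([base[0], base[1]])
            assert mism == base[2]

    def test_precondition_validation(self, rng):
        p = Plastome("t", random_seq(rng, 200))
        with pytest.raises(ValueError):
            find_inverted_repeat(p, min_len=10)
        with pytest.raises(ValueError):
            find_inverted_repeat(p, max_mismatch_frac=0.5)


class TestPartition:
    def test_longer_arc_is_lsc(self, rng):
        seq = planted_ir_sequence(rng)  # n=400, IRs [100,180) & [240,320)
        struct = partition_quadripartite(
            Plastome("t", seq), ((100, 180), (240, 320))
        )
        assert struct.ssc == (180, 240)
        assert struct.lsc == (320, 500)  # wraps: 180 bp
        assert struct.lsc_len == 180 and struct.ssc_len == 60
        assert struct.lsc_len + struct.ssc_len + 2 * struct.ir_len \
            == struct.genome_length
        # IRa follows the LSC
        assert struct.ir_a == (100, 180)

    def test_equal_arcs_tie_breaks_to_origin_arc(self, rng):
        # arms [50,130) and [230,310) on a 360 bp genome: both arcs are
        # 100 bp — the arc containing coordinate 0 becomes the LSC
        A, R = random_seq(rng, 50), random_seq(rng, 80)
        seq = A + R + random_seq(rng, 100) + revcomp(R) + random_seq(rng, 50)
        with pytest.warns(UserWarning, match="equal length"):
            struct = partition_quadripartite(
                Plastome("t", seq), ((50, 130), (230, 310))
            )
        assert struct.lsc == (310, 410)

    def test_overlapping_arms_rejected(self, rng):
        p = Plastome("t", random_seq(rng, 400))
        with pytest.raises(ValueError, match="overlap"):
            partition_quadripartite(p, ((100, 200), (150, 250)))


class TestCoverageDetection:
    def test_exact_doubling(self):
        depths = np.full(200, 30.0)
        depths[50:100] = 60.0
        runs = detect_ir_from_coverage(CoverageTrack(depths), window=5)
        assert runs == [(50, 100)]

    def test_uniform_track_yields_nothing(self):
        runs = detect_ir_from_coverage(CoverageTrack(np.full(200, 30.0)),
                                       window=5)
        assert runs == []

    def test_all_zero_track_rejected(self):
        with pytest.raises(ValueError, match="no coverage"):
            detect_ir_from_coverage(CoverageTrack(np.zeros(100)), window=5)

    def test_wrapping_run(self):
        depths = np.full(200, 30.0)
        depths[180:] = 60.0
        depths[:20] = 60.0
        runs = detect_ir_from_coverage(CoverageTrack(depths), window=5)
        assert runs == [(180, 220)]

    def test_short_runs_discarded(self):
        depths = np.full(200, 30.0)
        depths[50:54] = 60.0
        runs = detect_ir_from_coverage(CoverageTrack(depths), window=10)
        assert runs == []
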