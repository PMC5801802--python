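import json

import numpy as np
import pytest

from plastiq import (
    SimulationConfig,
    detect_ir_from_coverage,
    extract_cds,
    find_inverted_repeat,
    load_coverage,
    load_features,
    load_plastome,
    simulate,
    simulate_coverage,
)
from plastiq.simulate import EngineeredEvent, write_bundle


class TestDeterminism:
    def test_same_seed_identical_genomes(self):
        r1 = simulate(SimulationConfig(seed=11))
        r2 = simulate(SimulationConfig(seed=11))
        for name in r1.leaves:
            assert r1.leaves[name][0].sequence == r2.leaves[name][0].sequence

    def test_different_seed_differs(self):
        r1 = simulate(SimulationConfig(seed=11))
        r2 = simulate(SimulationConfig(seed=12))
        assert any(
            r1.leaves[n][0].sequence != r2.leaves[n][0].sequence
            for n in r1.leaves
        )

    def test_coverage_deterministic(self, sim_result):
        struct = sim_result.leaves["Avir"][2]
        t1 = simulate_coverage(struct, 40, seed=3)
        t2 = simulate_coverage(struct, 40, seed=3)
        assert (t1.depths == t2.depths).all()


class TestAncestor:
    def test_structure_identity(self, sim_result):
        _, _, s = sim_result.ancestor
        assert s.lsc_len + s.ssc_len + 2 * s.ir_len == s.genome_length

    def test_ir_detection_recovers_planted_arms_exactly(self, sim_result):
        plastome, _, s = sim_result.ancestor
        hit = find_inverted_repeat(plastome, min_len=1000,
                                   max_mismatch_frac=0.0)
        assert (hit[0], hit[1]) == (s.ir_a, s.ir_b)
        assert hit[2] == 0

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate(SimulationConfig(seed=0, lsc_len=2000))


class TestEvolution:
    def test_no_events_zero_rate_reproduces_ancestor(self):
        cfg = SimulationConfig(seed=3, sub_rate=0.0, events=[])
        res = simulate(cfg)
        anc = res.ancestor[0].sequence
        for name, (p, _, _) in res.leaves.items():
            assert p.sequence == anc

    def test_engineered_fs_inherited_by_clade_only(self, sim_result):
        """The ndhB deletion planted on the (Sher,Sasp) stem appears in
        both descendants at the same position and nowhere else."""
        lengths = {}
        for name, (p, feats, _) in sim_result.leaves.items():
            f = next(x for x in feats if x.name == "ndhB")
            lengths[name] = len(extract_cds(p, f))
        ref_len = lengths["Lphil"]
        assert lengths["Sher"] == lengths["Sasp"] == ref_len - 1
        for other in ("Avir", "Bam", "Sfor"):
            assert lengths[other] == ref_len

    def test_deleted_gene_absent_from_clade_annotation(self, sim_result):
        for name, (_, feats, _) in sim_result.leaves.items():
            names = {f.name for f in feats}
            if name in ("Sher", "Sasp"):
                assert "ndhG" not in names
            else:
                assert "ndhG" in names

    def test_leaf_structural_identity(self, sim_result):
        for name, (p, _, s) in sim_result.leaves.items():
            assert s.lsc_len + s.ssc_len + 2 * s.ir_len == p.length

    def test_ledger_events_map_to_descendant_leaves(self, sim_result):
        expected = {
            "n4": ["Sasp", "Sfor", "Sher"],
            "n5": ["Sasp", "Sher"],
            "Sher": ["Sher"],
        }
        for ev in sim_result.ledger.events:
            assert ev["affected_leaves"] == expected[ev["branch"]]

    def test_event_on_unknown_branch_rejected(self):
        cfg = SimulationConfig(
            seed=0,
            events=[EngineeredEvent(branch="nope", kind="delete_gene",
                                    gene="ndhG")],
        )
        with pytest.raises(ValueError, match="unknown branch"):
            simulate(cfg)

    def test_event_on_deleted_gene_rejected(self):
        cfg = SimulationConfig(
            seed=0,
            events=[
                EngineeredEvent(branch="n4", kind="delete_gene", gene="ndhG"),
                EngineeredEvent(branch="n5", kind="stop_gain", gene="ndhG",
                                codon=5),
            ],
        )
        with pytest.raises(ValueError, match="ndhG"):
            simulate(cfg)


class TestCoverageSimulation:
    def test_ir_depth_doubled_on_average(self, sim_result):
        struct = sim_result.leaves["Avir"][2]
        track = simulate_coverage(struct, 40, seed=9)
        n = struct.genome_length
        ir_positions = np.concatenate([
            np.arange(*struct.ir_a) % n, np.arange(*struct.ir_b) % n
        ])
        sc_positions = np.arange(*struct.lsc) % n
        ir_mean = track.depths[ir_positions].mean()
        sc_mean = track.depths[sc_positions].mean()
        assert abs(ir_mean - 80) < 3 * np.sqrt(80 / len(ir_positions))
        assert abs(sc_mean - 40) < 3 * np.sqrt(40 / len(sc_positions))

    def test_detection_recovers_arm_within_window(self, sim_result):
        struct = sim_result.leaves["Avir"][2]
        track = simulate_coverage(struct, 40, seed=21)
        window = 100
        runs = detect_ir_from_coverage(track, window=window)
        assert len(runs) == 2
        truth = sorted([struct.ir_a, struct.ir_b])
        for got, want in zip(sorted(runs), truth):
            assert abs(got[0] - want[0]) <= window
            assert abs(got[1] - want[1]) <= window


class TestBundle:
    def test_write_bundle_roundtrip(self, sim_result, tmp_path):
        write_bundle(sim_result, tmp_path)
        for name, (p, feats, _) in sim_result.leaves.items():
            again = load_plastome(tmp_path / f"{name}.fasta")
            assert again.sequence == p.sequence
            feats2 = load_features(tmp_path / f"{name}.features.tsv", p.length)
            assert len(feats2) == len(feats)
            track = load_coverage(tmp_path / f"{name}.coverage.tsv", p.length)
            assert len(track) == p.length
        ledger = json.loads((tmp_path / "ledger.json").read_text())
        assert len(ledger["events"]) == len(sim_result.ledger.events)
        assert set(ledger["structures"]) == set(sim_result.leaves)
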