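"""Tests of the synthetic read-pair generator and folding trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from spetfold.sim import (
    SimConfig,
    build_trajectory,
    decile_state_table,
    demo_sequestration_trajectory,
    sample_stop_events,
    simulate_read_pairs,
    write_fixture,
    STATE_PAIRED,
    STATE_UNPAIRED,
)


class TestBuildTrajectory:
    def test_cooperative_hairpin_appears_when_3prime_side_covered(self, hairpin_trajectory):
        # helix closes at position 60: paired in all intermediates >= 60
        for L in hairpin_trajectory.intermediate_lengths():
            mask = hairpin_trajectory.paired_mask(L)
            if L >= 60:
                assert mask[40:48].all() and mask[52:60].all()
            else:
                assert not mask[: L].any()

    def test_transient_sequestration_state_sequence(self):
        # the published geometry: emergence, decoy pairing, release, true pairing
        seq = list("GT" * 50)
        for p in (20, 21, 22, 60, 61, 62):
            seq[p - 1] = "C"
        for p in (35, 36, 37, 80, 81, 82):
            seq[p - 1] = "G"
        traj = build_trajectory("".join(seq), "transient_sequestration",
                                block=(20, 22), decoy=(35, 37),
                                competitor=(60, 62), true_partner=(80, 82))
        states = []
        for L in (30, 40, 70, 90):
            paired = traj.paired_mask(L)[19:22]
            assert paired.all() or not paired.any()
            states.append(bool(paired.all()))
        assert states == [False, True, False, True]
        # decoy is handed from the block to the competitor
        assert traj.paired_mask(40)[34:37].all()
        assert traj.paired_mask(90)[34:37].all()

    def test_user_supplied_identical_structures_have_no_transitions(self):
        structures = {L: "." * L for L in (10, 20, 30, 40)}
        traj = build_trajectory("ACGT" * 10, "user_supplied", structures=structures)
        assert traj.planted_transitions == []

    def test_unbalanced_user_structure_names_intermediate(self):
        with pytest.raises(ValueError, match="intermediate 4"):
            build_trajectory("ACGTACGT", "user_supplied", structures={4: "((.."})

    def test_scenario_does_not_fit(self):
        with pytest.raises(ValueError, match="does not fit"):
            build_trajectory("ACGT" * 5, "cooperative_hairpin", helices=[(1, 18, 5)])
        with pytest.raises(ValueError, match="no A/C"):
            build_trajectory("GGUU" * 5, "cooperative_hairpin", helices=[])

    def test_planted_transition_derivation(self, seq_trajectory):
        flips = [(t.state_prev, t.state_next) for t in seq_trajectory.planted_transitions
                 if (t.start, t.end) == (20, 22)]
        assert flips == [(STATE_UNPAIRED, STATE_PAIRED),
                         (STATE_PAIRED, STATE_UNPAIRED),
                         (STATE_UNPAIRED, STATE_PAIRED)]


class TestSimulateReadPairs:
    def test_zero_rates_give_full_length_pairs_only(self, seq_trajectory):
        config = SimConfig(coverage_per_intermediate=50, p_mod_unpaired=0.0,
                           p_mod_paired=0.0, seed=3)
        records, truth = simulate_read_pairs(seq_trajectory, config)
        assert truth["stop_pos"].isna().all()
        assert all(r.fwd_pos == 1 for r in records)

    def test_single_unpaired_base_forces_stop(self):
        seq = "G" * 40 + "A" + "G" * 39
        traj = build_trajectory(seq, "user_supplied",
                                structures={80: "." * 80}, intermediate_lengths=[80])
        config = SimConfig(coverage_per_intermediate=200, p_mod_unpaired=1.0,
                           p_mod_paired=0.0, seed=4)
        _, truth = simulate_read_pairs(traj, config)
        assert (truth["stop_pos"] == 41).all()
        assert truth["mappable"].all()

    def test_stop_position_law(self):
        # all-unpaired poly-A: P(stop=m) = p (1-p)^(L-m), P(full) = (1-p)^L
        L, p, n = 100, 0.1, 10_000
        traj = build_trajectory("A" * L, "user_supplied",
                                structures={L: "." * L}, intermediate_lengths=[L])
        config = SimConfig(coverage_per_intermediate=n, p_mod_unpaired=p, seed=5)
        L_arr, stops = sample_stop_events(traj, config, np.random.default_rng(5))
        observed = np.bincount(stops, minlength=L + 1)
        expected = np.array([(1 - p) ** L] + [p * (1 - p) ** (L - m) for m in range(1, L + 1)])
        expected *= n
        # pool low-expectation bins for a valid chi-square test
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        stat, p_value = scipy_stats.chisquare(obs, exp)
        assert p_value > 0.01

    def test_signal_contrast_unpaired_exceeds_paired(self, seq_trajectory):
        config = SimConfig(coverage_per_intermediate=500, seed=6)
        L_arr, stops = sample_stop_events(seq_trajectory, config, np.random.default_rng(6))
        per_base = {}
        for L, m in zip(L_arr, stops):
            if m > 0:
                per_base.setdefault(int(m), []).append(int(L))
        paired_counts, unpaired_counts = [], []
        for pos, hits in per_base.items():
            for L in set(hits):
                n_hits = sum(1 for x in hits if x == L)
                bucket = paired_counts if seq_trajectory.paired_mask(L)[pos - 1] else unpaired_counts
                bucket.append(n_hits)
        assert np.mean(unpaired_counts) > np.mean(paired_counts)

    def test_blind_region_flagged_unmappable(self, sim_fixture):
        truth = sim_fixture["truth"]
        config = sim_fixture["config"]
        stops = truth["stop_pos"].astype("Int64").fillna(0).astype(int)
        cdna_len = truth["intermediate_len"] - stops
        assert ((cdna_len >= config.min_read_len) == truth["mappable"]).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(p_mod_unpaired=0.1, p_mod_paired=0.2)
        with pytest.raises(ValueError):
            SimConfig(min_read_len=0)


class TestWriteFixture:
    def test_record_and_truth_conservation(self, sim_fixture):
        assert len(sim_fixture["records"]) == len(sim_fixture["truth"])

    def test_round_trip_against_truth(self, sim_fixture):
        from spetfold.align_io import assignments_from_sam, load_transcripts

        paths = sim_fixture["paths"]
        transcripts = load_transcripts(paths["fasta"])
        assignments, stats = assignments_from_sam(paths["fwd_sam"], paths["rev_sam"], transcripts)
        truth = sim_fixture["truth"]
        mappable = truth[truth["mappable"]]
        assert len(assignments) == len(mappable)
        got = sorted((a.intermediate_len, a.stop_pos or 0) for a in assignments)
        want = sorted(zip(mappable["intermediate_len"],
                          mappable["stop_pos"].astype("Int64").fillna(0).astype(int)))
        assert got == want
        assert stats.orphans == (~truth["mappable"]).sum()

    def test_fixed_seed_reproduces_identical_bytes(self, tmp_path, seq_trajectory):
        config = SimConfig(coverage_per_intermediate=40, seed=11)
        outputs = []
        for sub in ("a", "b"):
            records, truth = simulate_read_pairs(seq_trajectory, config)
            paths = write_fixture([seq_trajectory], records, truth, tmp_path / sub)
            outputs.append({k: open(v, "rb").read() for k, v in paths.items()})
        assert outputs[0] == outputs[1]

    def test_zero_reads_gives_header_only_sam(self, tmp_path, seq_trajectory):
        truth = pd.DataFrame(columns=["read_id", "transcript", "intermediate_len",
                                      "stop_pos", "mappable"])
        paths = write_fixture([seq_trajectory], [], truth, tmp_path)
        lines = open(paths["fwd_sam"]).read().splitlines()
        assert all(ln.startswith("@") for ln in lines) and len(lines) == 2


def test_decile_state_table_definite_states(seq_trajectory):
    states = decile_state_table(seq_trajectory)
    assert states.shape == (10, seq_trajectory.length)
    # block positions 20-22: unpaired in decile 4, paired in decile 5
    assert (states[3, 19:22] == STATE_UNPAIRED).all()
    assert (states[4, 19:22] == STATE_PAIRED).all()
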