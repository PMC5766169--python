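"""Shared fixtures: small simulated datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from spetfold.align_io import annotate_transcript
from spetfold.sim import (
    SimConfig,
    build_trajectory,
    demo_sequestration_trajectory,
    sample_stop_events,
    simulate_read_pairs,
    write_fixture,
)


@pytest.fixture(scope="session")
def seq_trajectory():
    return demo_sequestration_trajectory()


@pytest.fixture(scope="session")
def hairpin_trajectory():
    """A 120-nt transcript with one cooperative hairpin closing at position 60."""
    rng = np.random.default_rng(20)
    seq = "".join(rng.choice(list("ACGT"), size=120))
    # helix 41..48 paired with 53..60 (closes at 60), loop 49..52
    return build_trajectory(seq, "cooperative_hairpin", transcript_id="hp",
                            helices=[(41, 53, 8)])


@pytest.fixture(scope="session")
def sim_fixture(tmp_path_factory, seq_trajectory):
    """Simulated dataset written to disk: FASTA + fwd/rev SAM + truth."""
    config = SimConfig(coverage_per_intermediate=300, seed=7)
    records, truth = simulate_read_pairs(seq_trajectory, config)
    outdir = tmp_path_factory.mktemp("sim_fixture")
    paths = write_fixture([seq_trajectory], records, truth, outdir)
    return {"config": config, "records": records, "truth": truth,
            "trajectory": seq_trajectory, "paths": paths}


@pytest.fixture(scope="session")
def demo_matrix(seq_trajectory):
    """Stop-count matrix built from truth-level simulated assignments."""
    from spetfold.counting import StopCountMatrix

    config = SimConfig(coverage_per_intermediate=2000, seed=1)
    rng = np.random.default_rng(1)
    L, S = sample_stop_events(seq_trajectory, config, rng)
    keep = (L - S) >= config.min_read_len
    matrix = StopCountMatrix(seq_trajectory.transcript_id, seq_trajectory.length)
    matrix.add_arrays(L[keep], S[keep])
    return matrix


@pytest.fixture(scope="session")
def demo_annotation(seq_trajectory):
    return annotate_transcript(seq_trajectory.transcript_id, seq_trajectory.sequence)
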