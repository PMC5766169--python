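"""Synthetic cotranscriptional probing datasets with known ground truth.

The generator emulates the statistical structure of a paired-end
structure-probing experiment on elongating transcripts:

* each gene exists as a mixture of transcription intermediates whose
  3' end marks the polymerase position;
* DMS modifies unpaired A/C residues with a much higher probability than
  paired A/C, and never touches G/U;
* reverse transcription runs 3' to 5' and halts at the 3'-most modified
  base, so the sequenced cDNA covers (stop+1 .. intermediate 3' end);
* the reverse mate is anchored at the intermediate's 3' end (ligated
  adapter) and the forward mate's 5' end sits one base downstream of the
  modified residue;
* forward reads shorter than a minimum mappable length are lost, which
  creates a blind region near each intermediate's 3' end.

Molecules may carry several modifications, but only the 3'-most one is
reported (single-hit RT-stop chemistry), which keeps the generative model
exactly invertible and gives the stop position the closed-form law
``P(stop = m) = p_m * prod_{j > m} (1 - p_j)`` over modifiable positions.

Everything is driven by a single integer seed; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import parse_dotbracket

__all__ = [
    "SimConfig",
    "PlantedTransition",
    "FoldingTrajectory",
    "ReadPairRecord",
    "build_trajectory",
    "simulate_read_pairs",
    "sample_stop_events",
    "write_fixture",
    "default_intermediate_grid",
    "decile_state_table",
    "STATE_UNPAIRED",
    "STATE_PAIRED",
    "STATE_MIXED",
    "STATE_UNTRANSCRIBED",
]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

# per-decile pairing states used by decile_state_table
STATE_UNTRANSCRIBED = -1
STATE_UNPAIRED = 0
STATE_PAIRED = 1
STATE_MIXED = 2


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet output)."""
    return seq.translate(_COMPLEMENT)[::-1]


def default_intermediate_grid(length: int, step: int = 10) -> list[int]:
    """Uniform grid of intermediate lengths: {step, 2*step, ...} plus the full length."""
    grid = list(range(step, length + 1, step))
    if not grid or grid[-1] != length:
        grid.append(length)
    return grid


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the read-pair generator.

    ``coverage_per_intermediate`` is the expected number of read pairs
    drawn for each sampled intermediate length; with the default uniform
    sampling over ~10 intermediates per transcription decile this yields
    roughly ``10 x coverage_per_intermediate`` pairs per decile.

    ``p_mod_unpaired`` / ``p_mod_paired`` are per-base Bernoulli
    modification probabilities for unpaired and paired A/C residues;
    G and U are never modified.
    """

    n_transcripts: int = 1
    length_range: tuple[int, int] = (900, 1100)
    coverage_per_intermediate: int = 200
    p_mod_unpaired: float = 0.15
    p_mod_paired: float = 0.01
    min_read_len: int = 15
    read_len: int = 35
    seed: int = 0
    intermediate_sampling: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_mod_paired <= self.p_mod_unpaired <= 1.0):
            raise ValueError(
                "require 0 <= p_mod_paired <= p_mod_unpaired <= 1, got "
                f"{self.p_mod_paired} / {self.p_mod_unpaired}"
            )
        if self.min_read_len < 1:
            raise ValueError("min_read_len must be >= 1")
        if self.read_len < self.min_read_len:
            raise ValueError("read_len must be >= min_read_len")
        if self.coverage_per_intermediate < 0:
            raise ValueError("coverage_per_intermediate must be >= 0")
        if self.intermediate_sampling is not None:
            w = np.asarray(list(self.intermediate_sampling.values()), dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("intermediate_sampling weights must be non-negative with positive sum")


@dataclass(frozen=True)
class PlantedTransition:
    """An A/C interval whose pairing state differs between two consecutive deciles."""

    start: int
    end: int
    decile_prev: int
    decile_next: int
    state_prev: int
    state_next: int


@dataclass(eq=False)
class FoldingTrajectory:
    """Per-intermediate secondary structures of one transcript.

    ``structures`` maps an intermediate length L (1-based nucleotide
    count) to a dot-bracket string of exactly that length.
    ``planted_transitions`` lists the A/C intervals whose pairing state
    flips between consecutive transcription deciles, derived from the
    structures themselves.
    """

    transcript_id: str
    sequence: str
    structures: dict[int, str]
    planted_transitions: list[PlantedTransition] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.structures:
            raise ValueError(f"{self.transcript_id}: trajectory has no structures")
        for L, db in self.structures.items():
            if not 1 <= L <= len(self.sequence):
                raise ValueError(
                    f"{self.transcript_id}: intermediate length {L} outside transcript"
                )
            if len(db) != L:
                raise ValueError(
                    f"{self.transcript_id}: dot-bracket for intermediate {L} has length "
                    f"{len(db)}, expected {L}"
                )
            try:
                parse_dotbracket(db)
            except ValueError as exc:
                raise ValueError(
                    f"{self.transcript_id}: invalid structure for intermediate {L}: {exc}"
                ) from exc
        for t in self.planted_transitions:
            if not 1 <= t.start <= t.end <= len(self.sequence):
                raise ValueError(
                    f"{self.transcript_id}: planted transition {t} outside [1, {len(self.sequence)}]"
                )
        self._state_cache: dict[int, np.ndarray] = {}

    @property
    def length(self) -> int:
        return len(self.sequence)

    def intermediate_lengths(self) -> list[int]:
        return sorted(self.structures)

    def paired_mask(self, L: int) -> np.ndarray:
        """Boolean array (length L): True where the base is paired at intermediate L."""
        cached = self._state_cache.get(L)
        if cached is None:
            db = self.structures[L]
            cached = np.frombuffer(db.encode(), dtype="S1") != b"."
            self._state_cache[L] = cached
        return cached

    def ac_mask(self) -> np.ndarray:
        arr = np.frombuffer(self.sequence.encode(), dtype="S1")
        return (arr == b"A") | (arr == b"C")


def _pairs_to_dotbracket(length: int, pairs: Sequence[tuple[int, int]]) -> str:
    """Render non-crossing 1-based pairs as a dot-bracket string."""
    chars = ["."] * length
    seen: set[int] = set()
    ordered = sorted((min(i, j), max(i, j)) for i, j in pairs)
    for idx, (i, j) in enumerate(ordered):
        if i == j or i < 1 or j > length:
            raise ValueError(f"invalid pair ({i}, {j}) for length {length}")
        if i in seen or j in seen:
            raise ValueError(f"position reused by pair ({i}, {j})")
        seen.update((i, j))
        for a, b in ordered[idx + 1:]:
            if i < a <= j < b:
                raise ValueError(f"crossing pairs ({i},{j}) and ({a},{b}) are not representable")
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def _helix_pairs(five_start: int, three_start: int, n: int) -> list[tuple[int, int]]:
    """Pairs of a helix: 5' strand [five_start, five_start+n) against
    3' strand [three_start, three_start+n), antiparallel."""
    return [(five_start + k, three_start + n - 1 - k) for k in range(n)]


def _span_pairs(five_span: tuple[int, int], three_span: tuple[int, int]) -> list[tuple[int, int]]:
    (fs, fe), (ts, te) = five_span, three_span
    if fe - fs != te - ts:
        raise ValueError(f"spans {five_span} and {three_span} have different lengths")
    return _helix_pairs(fs, ts, fe - fs + 1)


def decile_state_table(trajectory: FoldingTrajectory, n_deciles: int = 10) -> np.ndarray:
    """Pooled per-decile pairing state of every position.

    For decile d, a position is PAIRED (UNPAIRED) when it has that state
    in every sampled intermediate of the decile that has transcribed it,
    MIXED when the state varies within the decile, and UNTRANSCRIBED when
    no intermediate of the decile reaches it.

    Returns an int8 array of shape (n_deciles, transcript length).
    """
    from .counting import split_deciles

    L_total = trajectory.length
    intervals = split_deciles(L_total, n_deciles)
    states = np.full((n_deciles, L_total), STATE_UNTRANSCRIBED, dtype=np.int8)
    lengths = trajectory.intermediate_lengths()
    for d, (start, end) in enumerate(intervals):
        Ls = [L for L in lengths if start <= L <= end]
        if not Ls:
            continue
        n_seen = np.zeros(L_total, dtype=int)
        n_paired = np.zeros(L_total, dtype=int)
        for L in Ls:
            mask = trajectory.paired_mask(L)
            n_seen[:L] += 1
            n_paired[:L] += mask
        seen = n_seen > 0
        states[d, seen & (n_paired == 0)] = STATE_UNPAIRED
        states[d, seen & (n_paired == n_seen)] = STATE_PAIRED
        states[d, seen & (n_paired > 0) & (n_paired < n_seen)] = STATE_MIXED
    return states


def _derive_transitions(trajectory: FoldingTrajectory, n_deciles: int = 10) -> list[PlantedTransition]:
    """A/C intervals with a clean pairing-state flip between consecutive deciles."""
    states = decile_state_table(trajectory, n_deciles)
    ac = trajectory.ac_mask()
    transitions: list[PlantedTransition] = []
    for d in range(n_deciles - 1):
        prev, nxt = states[d], states[d + 1]
        definite = np.isin(prev, (STATE_PAIRED, STATE_UNPAIRED)) & np.isin(
            nxt, (STATE_PAIRED, STATE_UNPAIRED)
        )
        flip = definite & (prev != nxt) & ac
        idx = np.flatnonzero(flip)
        if idx.size == 0:
            continue
        run_start = idx[0]
        prev_i = idx[0]
        for i in list(idx[1:]) + [None]:  # type: ignore[list-item]
            if i is not None and i == prev_i + 1:
                prev_i = i
                continue
            transitions.append(
                PlantedTransition(
                    start=int(run_start) + 1,
                    end=int(prev_i) + 1,
                    decile_prev=d + 1,
                    decile_next=d + 2,
                    state_prev=int(prev[run_start]),
                    state_next=int(nxt[run_start]),
                )
            )
            if i is not None:
                run_start = i
                prev_i = i
    return transitions


def build_trajectory(sequence: str,
                     scenario: str,
                     *,
                     transcript_id: str = "sim",
                     intermediate_lengths: Sequence[int] | None = None,
                     helices: Sequence[tuple[int, int, int]] | None = None,
                     block: tuple[int, int] | None = None,
                     decoy: tuple[int, int] | None = None,
                     competitor: tuple[int, int] | None = None,
                     true_partner: tuple[int, int] | None = None,
                     structures: Mapping[int, str] | None = None,
                     n_deciles: int = 10) -> FoldingTrajectory:
    """Build a :class:`FoldingTrajectory` for one of three folding scenarios.

    ``cooperative_hairpin``
        ``helices`` is a list of ``(five_start, three_start, n_pairs)``
        tuples.  Every helix appears in the first intermediate whose
        length covers its 3' strand and persists thereafter — local
        elements fold as soon as they are transcribed.

    ``transient_sequestration``
        A 5' ``block`` is unpaired when it emerges, pairs with a
        ``decoy`` once the decoy is transcribed, is released when a
        ``competitor`` sequesters the decoy, and finally pairs with its
        ``true_partner`` — the canonical non-cooperative long-range
        pattern (state sequence unpaired, paired, unpaired, paired).
        ``helices`` may add cooperative background elements.

    ``user_supplied``
        ``structures`` (length -> dot-bracket) are validated and passed
        through.

    Planted transitions are derived from the resulting structures in all
    scenarios.
    """
    sequence = sequence.upper().replace("U", "T")
    length = len(sequence)
    if not any(b in "AC" for b in sequence):
        raise ValueError("sequence contains no A/C residues; nothing can be probed")
    if intermediate_lengths is None:
        intermediate_lengths = default_intermediate_grid(length)
    intermediate_lengths = sorted(set(int(L) for L in intermediate_lengths))
    if intermediate_lengths[0] < 1 or intermediate_lengths[-1] > length:
        raise ValueError("intermediate lengths must lie in [1, transcript length]")

    if scenario == "user_supplied":
        if structures is None:
            raise ValueError("user_supplied scenario requires structures")
        structs = {int(L): db for L, db in structures.items()}
    elif scenario in ("cooperative_hairpin", "transient_sequestration"):
        # each background helix folds cooperatively: all of its pairs
        # appear in the first intermediate covering its 3' strand
        base_helices: list[tuple[int, list[tuple[int, int]]]] = []
        for fs, ts, n in (helices or ()):
            if ts <= fs + n - 1:
                raise ValueError(f"helix ({fs}, {ts}, {n}) strands overlap or are misordered")
            three_end = ts + n - 1
            if three_end > length:
                raise ValueError(f"helix ({fs}, {ts}, {n}) does not fit transcript of length {length}")
            base_helices.append((three_end, _helix_pairs(fs, ts, n)))
        seq_pairs: dict[str, list[tuple[int, int]]] = {}
        if scenario == "transient_sequestration":
            if block is None or decoy is None or true_partner is None:
                raise ValueError(
                    "transient_sequestration requires block, decoy and true_partner spans"
                )
            spans = {"block": block, "decoy": decoy, "true_partner": true_partner}
            if competitor is not None:
                spans["competitor"] = competitor
            for name, (s, e) in spans.items():
                if not 1 <= s <= e <= length:
                    raise ValueError(f"{name} span {s}-{e} does not fit transcript of length {length}")
            seq_pairs["block_decoy"] = _span_pairs(block, decoy)
            seq_pairs["block_true"] = _span_pairs(block, true_partner)
            if competitor is not None:
                seq_pairs["decoy_competitor"] = _span_pairs(decoy, competitor)

        structs = {}
        for L in intermediate_lengths:
            pairs = [p for three_end, hp in base_helices if three_end <= L for p in hp]
            if scenario == "transient_sequestration":
                decoy_taken = competitor is not None and competitor[1] <= L
                if true_partner[1] <= L:
                    pairs += seq_pairs["block_true"]
                elif decoy[1] <= L and not decoy_taken:
                    pairs += seq_pairs["block_decoy"]
                if decoy_taken:
                    pairs += seq_pairs["decoy_competitor"]
            try:
                structs[L] = _pairs_to_dotbracket(L, pairs)
            except ValueError as exc:
                raise ValueError(f"intermediate {L}: {exc}") from exc
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    traj = FoldingTrajectory(
        transcript_id=transcript_id, sequence=sequence, structures=structs
    )
    traj.planted_transitions = _derive_transitions(traj, n_deciles)
    return traj


def demo_sequestration_trajectory(transcript_id: str = "seqdemo") -> FoldingTrajectory:
    """A small transient-sequestration fixture with observable phases.

    A 110-nt transcript in which a C-triplet block (positions 20-22) is
    unpaired on emergence, pairs with a decoy G-triplet (48-50), is
    released when a competitor C-triplet (76-78) sequesters the decoy,
    and finally pairs with its true partner (95-97).  The spans are
    spaced so that every phase of the high/low reactivity alternation is
    observable outside the minimum-read-length blind region near each
    intermediate's 3' end.  Background A residues provide unpaired
    normalization anchors in every sliding window.
    """
    length = 110
    seq = ["G", "T"] * (length // 2)
    # unpaired background A anchors: at least two per 50-nt normalization
    # window, but sparse 3' of the block so RT attrition between the
    # block and the polymerase stays mild
    for p in (5, 10, 15, 33, 44, 58, 66, 85, 90, 100, 105):
        seq[p - 1] = "A"
    for p in (20, 21, 22):
        seq[p - 1] = "C"
    for p in (48, 49, 50):
        seq[p - 1] = "G"
    for p in (76, 77, 78):
        seq[p - 1] = "C"
    for p in (95, 96, 97):
        seq[p - 1] = "G"
    return build_trajectory(
        "".join(seq),
        "transient_sequestration",
        transcript_id=transcript_id,
        block=(20, 22),
        decoy=(48, 50),
        competitor=(76, 78),
        true_partner=(95, 97),
    )


@dataclass(frozen=True)
class ReadPairRecord:
    """One emitted read pair, in transcript coordinates (1-based, closed)."""

    read_id: str
    transcript_id: str
    intermediate_len: int
    stop_pos: int | None          # modified base; None = full-length cDNA
    mappable: bool
    fwd_pos: int                  # forward mate 5'-most position
    fwd_len: int
    rev_pos: int                  # reverse mate leftmost position
    rev_len: int


def sample_stop_events(trajectory: FoldingTrajectory,
                       config: SimConfig,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised core of the generator.

    Draws read pairs for every sampled intermediate and returns
    ``(intermediate_len, stop_pos)`` int arrays, one entry per pair;
    ``stop_pos == 0`` encodes a full-length (unmodified) molecule.

    Each A/C base of the length-L structure is modified independently
    (Bernoulli, rate by pairing state) and the reported stop is the
    3'-most modified position.
    """
    lengths = trajectory.intermediate_lengths()
    if config.intermediate_sampling is not None:
        missing = [L for L in config.intermediate_sampling if L not in trajectory.structures]
        if missing:
            raise ValueError(f"sampled intermediate lengths {missing} missing from trajectory")
        lengths = sorted(config.intermediate_sampling)
        weights = np.asarray([config.intermediate_sampling[L] for L in lengths], dtype=float)
    else:
        weights = np.ones(len(lengths), dtype=float)
    weights = weights / weights.sum()
    total = config.coverage_per_intermediate * len(lengths)
    n_per_L = rng.multinomial(total, weights)

    seq_arr = np.frombuffer(trajectory.sequence.encode(), dtype="S1")
    ac_all = np.flatnonzero((seq_arr == b"A") | (seq_arr == b"C")) + 1  # 1-based

    out_L = np.empty(total, dtype=np.int64)
    out_stop = np.empty(total, dtype=np.int64)
    cursor = 0
    for L, n in zip(lengths, n_per_L):
        if n == 0:
            continue
        ac = ac_all[ac_all <= L]
        if ac.size == 0:
            stops = np.zeros(n, dtype=np.int64)
        else:
            paired = trajectory.paired_mask(L)[ac - 1]
            p = np.where(paired, config.p_mod_paired, config.p_mod_unpaired)
            hits = rng.random((n, ac.size)) < p
            stops = np.max(np.where(hits, ac[None, :], 0), axis=1)
        out_L[cursor:cursor + n] = L
        out_stop[cursor:cursor + n] = stops
        cursor += n
    return out_L[:cursor], out_stop[:cursor]


def simulate_read_pairs(trajectory: FoldingTrajectory,
                        config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[ReadPairRecord], pd.DataFrame]:
    """Generate read pairs and the matching ground-truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per emitted
    pair: ``read_id``, ``transcript``, ``intermediate_len``, ``stop_pos``
    (NA for full-length molecules) and ``mappable`` (False when the
    forward mate would be shorter than ``min_read_len`` — the blind
    region near each intermediate's 3' end).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L_arr, stop_arr = sample_stop_events(trajectory, config, rng)
    records: list[ReadPairRecord] = []
    rows = []
    for i, (L, m) in enumerate(zip(L_arr.tolist(), stop_arr.tolist())):
        fwd_pos = m + 1
        cdna_len = L - m
        fwd_len = min(config.read_len, cdna_len)
        mappable = cdna_len >= config.min_read_len
        rev_pos = max(fwd_pos, L - config.read_len + 1)
        rev_len = L - rev_pos + 1
        read_id = f"{trajectory.transcript_id}:{i:07d}"
        stop: int | None = m if m > 0 else None
        records.append(ReadPairRecord(
            read_id=read_id,
            transcript_id=trajectory.transcript_id,
            intermediate_len=L,
            stop_pos=stop,
            mappable=mappable,
            fwd_pos=fwd_pos,
            fwd_len=fwd_len,
            rev_pos=rev_pos,
            rev_len=rev_len,
        ))
        rows.append((read_id, trajectory.transcript_id, L,
                     stop if stop is not None else pd.NA, mappable))
    truth = pd.DataFrame(
        rows, columns=["read_id", "transcript", "intermediate_len", "stop_pos", "mappable"]
    )
    return records, truth


def _sam_header_lines(transcripts: Sequence[tuple[str, str]]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in transcripts:
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    return lines


def write_fixture(trajectories: Sequence[FoldingTrajectory],
                  records: Sequence[ReadPairRecord],
                  truth: pd.DataFrame,
                  outdir) -> dict[str, str]:
    """Write FASTA + forward/reverse SAM + truth TSV + trajectory JSON.

    The forward mate is emitted sense (FLAG 0x1|0x40) and the reverse
    mate antisense (FLAG 0x1|0x80|0x10), mirroring independently mapped
    and re-paired mates.  Unmappable forward mates (blind region) are
    written as unmapped records (FLAG 0x4 set) so a consumer sees exactly
    what an aligner would report.  Output is byte-deterministic for a
    fixed simulation.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "transcripts.fa"),
        "fwd_sam": os.path.join(outdir, "fwd.sam"),
        "rev_sam": os.path.join(outdir, "rev.sam"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "trajectories": os.path.join(outdir, "trajectories.json"),
    }
    seqs = {t.transcript_id: t.sequence for t in trajectories}
    try:
        with open(paths["fasta"], "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        header = _sam_header_lines(list(seqs.items()))
        with open(paths["fwd_sam"], "w") as ffwd, open(paths["rev_sam"], "w") as frev:
            for line in header:
                ffwd.write(line + "\n")
                frev.write(line + "\n")
            for rec in records:
                seq = seqs[rec.transcript_id]
                fwd_seq = seq[rec.fwd_pos - 1: rec.fwd_pos - 1 + rec.fwd_len]
                rev_seq = revcomp(seq[rec.rev_pos - 1: rec.rev_pos - 1 + rec.rev_len])
                if rec.mappable:
                    ffwd.write("\t".join((
                        rec.read_id, "65", rec.transcript_id, str(rec.fwd_pos), "255",
                        f"{rec.fwd_len}M", "=", str(rec.rev_pos), "0",
                        fwd_seq, "I" * rec.fwd_len)) + "\n")
                else:
                    ffwd.write("\t".join((
                        rec.read_id, "69", "*", "0", "0", "*",
                        rec.transcript_id, str(rec.rev_pos), "0",
                        fwd_seq if fwd_seq else "*",
                        "I" * rec.fwd_len if fwd_seq else "*")) + "\n")
                frev.write("\t".join((
                    rec.read_id, "145", rec.transcript_id, str(rec.rev_pos), "255",
                    f"{rec.rev_len}M", "=",
                    str(rec.fwd_pos) if rec.mappable else str(rec.rev_pos), "0",
                    rev_seq, "I" * rec.rev_len)) + "\n")
        truth_out = truth.copy()
        truth_out["mappable"] = truth_out["mappable"].astype(int)
        truth_out.to_csv(paths["truth"], sep="\t", index=False, na_rep="NA")
        meta = {
            t.transcript_id: {
                "sequence": t.sequence,
                "structures": {str(L): db for L, db in sorted(t.structures.items())},
                "planted_transitions": [
                    {
                        "start": tr.start, "end": tr.end,
                        "decile_prev": tr.decile_prev, "decile_next": tr.decile_next,
                        "state_prev": tr.state_prev, "state_next": tr.state_next,
                    }
                    for tr in t.planted_transitions
                ],
            }
            for t in trajectories
        }
        with open(paths["trajectories"], "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {outdir}: {exc}") from exc
    return paths
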