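"""End-to-end planted-transition benchmark on synthetic transcripts.

Builds transcripts (~1 kb) whose folding trajectories mix the two modes
the method is meant to distinguish:

* a tiling of short hairpin modules that close as soon as their 3'
  strand is transcribed — short-range, cooperative background that is
  stable across pooled deciles once formed;
* planted long-range helices whose 5' block (a run of 8 A/C residues)
  sits in the middle of a transcription decile while the 3' partner (a
  G/T-only octamer, so it adds no probing signal of its own) begins
  exactly at the next decile's first position.  The block is therefore
  unpaired in every intermediate of its own decile and paired in every
  intermediate of the next — a clean, pooled-state structural
  transition between consecutive deciles.

Blocks are placed so that their A/C residues sit clear of the analysis
window grid boundaries: every planted event is fully contained in the
windows that cover it, which makes the per-window ground truth
unambiguous.  The benchmark then runs the full counting / pooling /
windowed-comparison pipeline and scores CHANGED calls against the
planted truth (sensitivity) and STABLE calls against planted-stable
windows (specificity), and pools a long-range-base enrichment test over
the structure-changing windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align_io import annotate_transcript
from .counting import StopCountMatrix, pool_deciles, split_deciles
from .deciles import (
    STATUS_CHANGED,
    STATUS_FILTERED,
    STATUS_STABLE,
    WindowParams,
    WindowRecord,
    analyze_transcript,
)
from .metrics import hypergeom_upper_tail
from .sim import (
    STATE_PAIRED,
    STATE_UNPAIRED,
    FoldingTrajectory,
    SimConfig,
    build_trajectory,
    decile_state_table,
    revcomp,
    sample_stop_events,
)
from .structure import CATEGORY_LONG, classify_pairs, parse_dotbracket

__all__ = [
    "TransitionBenchmarkConfig",
    "BenchmarkResult",
    "make_transition_trajectory",
    "window_truth",
    "run_seed",
    "run_transition_benchmark",
]

_STEM5 = "GCAGCAGC"
_LOOP = "GTAC"                 # two unpaired A/C per module: stable hot anchors
_SPACER = "GTGT"
_MODULE = _STEM5 + _LOOP + revcomp(_STEM5) + _SPACER  # 24 nt, helix span 20 nt
_BLOCK = "ACACACACACAC"        # planted 5' block: 12 A/C residues
_PARTNER = revcomp(_BLOCK)     # GTGTGT...: no A/C, silent 3' partner


@dataclass(frozen=True)
class TransitionBenchmarkConfig:
    """Study conditions of the planted-transition benchmark."""

    n_transcripts: int = 20
    length_choices: tuple[int, ...] = tuple(range(960, 1050, 10))
    transitions_per_transcript: int = 3
    candidate_boundaries: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    min_boundary_gap: int = 2
    coverage_per_intermediate: int = 500
    p_mod_unpaired: float = 0.15
    p_mod_paired: float = 0.01
    min_read_len: int = 15


def _carve(seq: np.ndarray, start: int, letters: str) -> None:
    seq[start - 1: start - 1 + len(letters)] = np.frombuffer(letters.encode(), dtype="S1")


def _intersects(span: tuple[int, int], carves: list[tuple[int, int]]) -> bool:
    s, e = span
    return any(not (e < cs or s > ce) for cs, ce in carves)


def make_transition_trajectory(transcript_id: str,
                               length: int,
                               boundaries: list[int],
                               rng: np.random.Generator,
                               ac_per_window: int = 40,
                               ac_offset: int = 20) -> FoldingTrajectory:
    """One benchmark transcript with planted transitions at the given
    decile boundaries (a boundary d plants a flip between deciles d and
    d+1).

    Each transition decile is turned into a G/T-only quiet zone holding
    just the planted block, so the pooled pairing state of every A/C
    residue in the surrounding analysis windows is definite (the stable
    background modules all fold in earlier deciles).  The quiet zone is
    extended 5' base by base until the block's last A/C residue lands
    exactly on a window-grid boundary, so exactly one analysis window —
    fully inside the positional filter band — ends at the block.
    """
    intervals = split_deciles(length)
    seq = np.frombuffer((_MODULE * (length // len(_MODULE) + 1)).encode(), dtype="S1")[:length].copy()
    # background hairpin helices from the module tiling
    module_helices = []
    p = 1
    while p + len(_MODULE) - 1 <= length:
        module_helices.append((p, p + 12, 8))       # pairs (p+i, p+19-i)
        p += len(_MODULE)

    gt = np.frombuffer(b"GT" * (length // 2 + 1), dtype="S1")
    quiet_spans: list[tuple[int, int]] = []
    dead_spans: list[tuple[int, int]] = []           # regions where modules must not pair
    partner_starts: dict[int, int] = {}
    for d in sorted(boundaries):
        ds, de = intervals[d - 1]
        seq[ds - 1: de] = gt[: de - ds + 1]
        quiet_spans.append((ds, de))
        # the partner ends just before the first sampled intermediate of
        # decile d+1 (grid step 10), so the helix is formed in every
        # pooled intermediate of that decile
        ps = intervals[d][0] + 10 - len(_PARTNER)
        partner_starts[d] = ps
        _carve(seq, ps, _PARTNER)
        dead_spans.append((ps, ps + len(_PARTNER) - 1))

    long_helices = []
    ac_mask = (seq == b"A") | (seq == b"C")
    for d in sorted(boundaries):
        ds, de = intervals[d - 1]
        # early in the quiet decile: most Prev-decile intermediates are
        # long enough to observe the block's stops outside the blind region
        s = ds + 5 + int(rng.integers(0, 11))
        _carve(seq, s, _BLOCK)
        ac_mask = (seq == b"A") | (seq == b"C")
        # extend the quiet zone 5' until the A/C index of the block start
        # is ac_offset - len(_BLOCK) (mod ac_offset): the block then fills
        # the tail of one analysis window exactly
        i0 = int(ac_mask[: ds - 1].sum())
        want = (ac_offset - len(_BLOCK)) % ac_offset
        pos = ds - 1
        ext_start = ds
        while i0 % ac_offset != want and pos >= 1:
            if ac_mask[pos - 1]:
                i0 -= 1
                seq[pos - 1] = b"G"
                ac_mask[pos - 1] = False
            ext_start = pos
            pos -= 1
        for i, span in enumerate(quiet_spans):
            if span[0] == ds:
                quiet_spans[i] = (min(ext_start, ds), span[1])
        long_helices.append((s, partner_starts[d], len(_BLOCK)))

    kept_modules = [
        h for h in module_helices
        if not _intersects((h[0], h[0] + 19), quiet_spans + dead_spans)
    ]
    return build_trajectory(
        seq.tobytes().decode(),
        "cooperative_hairpin",
        transcript_id=transcript_id,
        helices=kept_modules + long_helices,
    )


def sample_boundaries(rng: np.random.Generator,
                      config: TransitionBenchmarkConfig) -> list[int]:
    """Transition boundaries with a minimum gap, so quiet-zone extensions
    never collide with a neighbouring planted block."""
    while True:
        picks = sorted(
            int(b) for b in rng.choice(
                config.candidate_boundaries,
                size=config.transitions_per_transcript, replace=False,
            )
        )
        if all(b - a >= config.min_boundary_gap for a, b in zip(picks, picks[1:])):
            return picks


def window_truth(states: np.ndarray, record: WindowRecord) -> str | None:
    """Ground-truth label of a scored window for its decile pair.

    ``changed`` when at least one A/C position flips cleanly between the
    pooled states of the two deciles, ``stable`` when every position has
    the same definite state in both, None when any position is mixed
    within a decile (no unambiguous truth exists).
    """
    d_prev, d_next = record.decile_pair
    idx = np.asarray(record.window.ac_positions) - 1
    s1 = states[d_prev - 1, idx]
    s2 = states[d_next - 1, idx]
    definite = np.isin(s1, (STATE_PAIRED, STATE_UNPAIRED)) & np.isin(
        s2, (STATE_PAIRED, STATE_UNPAIRED)
    )
    if not definite.all():
        return None
    return "changed" if (s1 != s2).any() else "stable"


@dataclass
class BenchmarkResult:
    """Aggregated planted-transition recovery over one or more seeds."""

    true_changed_called_changed: int = 0
    true_changed_scored: int = 0
    true_stable_called_stable: int = 0
    true_stable_scored: int = 0
    scored_windows: int = 0
    filtered_windows: int = 0
    status_counts: dict = field(default_factory=dict)
    # pooled enrichment counts: population / long-range successes / draws / observed
    enrich_N: int = 0
    enrich_K: int = 0
    enrich_n: int = 0
    enrich_k: int = 0

    @property
    def sensitivity(self) -> float:
        return (self.true_changed_called_changed / self.true_changed_scored
                if self.true_changed_scored else float("nan"))

    @property
    def specificity(self) -> float:
        return (self.true_stable_called_stable / self.true_stable_scored
                if self.true_stable_scored else float("nan"))

    @property
    def enrichment_p(self) -> float:
        if self.enrich_N == 0:
            return float("nan")
        return hypergeom_upper_tail(self.enrich_k, self.enrich_N, self.enrich_K, self.enrich_n)

    def merge(self, other: "BenchmarkResult") -> None:
        self.true_changed_called_changed += other.true_changed_called_changed
        self.true_changed_scored += other.true_changed_scored
        self.true_stable_called_stable += other.true_stable_called_stable
        self.true_stable_scored += other.true_stable_scored
        self.scored_windows += other.scored_windows
        self.filtered_windows += other.filtered_windows
        for k, v in other.status_counts.items():
            self.status_counts[k] = self.status_counts.get(k, 0) + v
        self.enrich_N += other.enrich_N
        self.enrich_K += other.enrich_K
        self.enrich_n += other.enrich_n
        self.enrich_k += other.enrich_k


def run_seed(seed: int,
             config: TransitionBenchmarkConfig = TransitionBenchmarkConfig(),
             params: WindowParams = WindowParams()) -> BenchmarkResult:
    """Simulate one replicate and score recovery against the planted truth."""
    rng = np.random.default_rng(seed)
    sim_config = SimConfig(
        coverage_per_intermediate=config.coverage_per_intermediate,
        p_mod_unpaired=config.p_mod_unpaired,
        p_mod_paired=config.p_mod_paired,
        min_read_len=config.min_read_len,
        seed=seed,
    )
    result = BenchmarkResult()
    for t in range(config.n_transcripts):
        length = int(rng.choice(config.length_choices))
        boundaries = sample_boundaries(rng, config)
        traj = make_transition_trajectory(f"tx{t:02d}", length, boundaries, rng,
                                          ac_per_window=params.ac_per_window,
                                          ac_offset=params.ac_offset)
        L_arr, stop_arr = sample_stop_events(traj, sim_config, rng)
        mappable = (L_arr - stop_arr) >= config.min_read_len
        matrix = StopCountMatrix(traj.transcript_id, length)
        matrix.add_arrays(L_arr[mappable], stop_arr[mappable])
        intervals = split_deciles(length)
        pooled = pool_deciles(matrix, intervals)
        ann = annotate_transcript(traj.transcript_id, traj.sequence)
        records = analyze_transcript(ann, pooled, params)
        states = decile_state_table(traj)

        universe: set[int] = set()
        changed_positions: set[int] = set()
        for rec in records:
            if rec.status == STATUS_FILTERED:
                result.filtered_windows += 1
                continue
            result.scored_windows += 1
            result.status_counts[rec.status] = result.status_counts.get(rec.status, 0) + 1
            universe.update(rec.window.ac_positions)
            if rec.status == STATUS_CHANGED:
                changed_positions.update(rec.window.ac_positions)
            truth = window_truth(states, rec)
            if truth == "changed":
                result.true_changed_scored += 1
                if rec.status == STATUS_CHANGED:
                    result.true_changed_called_changed += 1
            elif truth == "stable":
                result.true_stable_scored += 1
                if rec.status == STATUS_STABLE:
                    result.true_stable_called_stable += 1

        if universe:
            mature = parse_dotbracket(traj.structures[length], traj.transcript_id)
            table = classify_pairs(mature, intervals, sorted(universe))
            cats = dict(zip(table["position"].astype(int), table["category"]))
            result.enrich_N += len(universe)
            result.enrich_K += sum(1 for p in universe if cats[p] == CATEGORY_LONG)
            result.enrich_n += len(changed_positions)
            result.enrich_k += sum(1 for p in changed_positions if cats[p] == CATEGORY_LONG)
    return result


def run_transition_benchmark(n_seeds: int = 20,
                             base_seed: int = 0,
                             config: TransitionBenchmarkConfig = TransitionBenchmarkConfig(),
                             params: WindowParams = WindowParams()) -> BenchmarkResult:
    """Aggregate planted-transition recovery over independent replicates."""
    total = BenchmarkResult()
    child_seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31)
    for s in child_seeds:
        total.merge(run_seed(int(s), config, params))
    return total
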