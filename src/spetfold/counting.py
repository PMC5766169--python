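"""RT-stop count accumulation, decile pooling and polymerase occupancy.

The central container is the per-transcript stop-count matrix indexed by
(intermediate length, position).  Coverage is inferred from each pair's
implied cDNA extent — the cDNA runs from one base past the stop to the
intermediate's 3' end — so coverage within an intermediate is
non-decreasing toward the 3' end (RT attrition).  Internally each
intermediate row stores a histogram of cDNA 5' starts; the coverage row
is its running sum, which keeps storage sparse in intermediate length
while giving exact per-position coverage.

Transcription deciles follow the floor rule: decile d of a length-L
gene spans positions floor((d-1)L/10)+1 .. floor(dL/10), giving ten
contiguous intervals that differ in size by at most one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .align_io import PairedAssignment

__all__ = [
    "split_deciles",
    "StopCountMatrix",
    "DecileCounts",
    "build_stop_matrix",
    "pool_deciles",
    "pol_occupancy",
]


def split_deciles(length: int, n: int = 10) -> list[tuple[int, int]]:
    """Ten contiguous equally sized position intervals (1-based, closed)."""
    if length < n:
        raise ValueError(f"transcript length {length} shorter than {n} deciles")
    bounds = [(d * length) // n for d in range(n + 1)]
    return [(bounds[d] + 1, bounds[d + 1]) for d in range(n)]


class StopCountMatrix:
    """Per-transcript RT-stop counts and coverage by (intermediate, position).

    ``stops[L]`` is a length-L float array of summed stop weights;
    ``coverage_row(L)`` the matching coverage; ``full_length[L]`` the
    summed weight of pairs whose cDNA reached position 1.
    """

    def __init__(self, transcript_id: str, length: int):
        self.transcript_id = transcript_id
        self.length = length
        self.stops: dict[int, np.ndarray] = {}
        self._start_hist: dict[int, np.ndarray] = {}
        self.full_length: dict[int, float] = {}

    def _ensure(self, L: int) -> None:
        if not 1 <= L <= self.length:
            raise ValueError(
                f"{self.transcript_id}: intermediate length {L} outside [1, {self.length}]"
            )
        if L not in self.stops:
            self.stops[L] = np.zeros(L)
            self._start_hist[L] = np.zeros(L)
            self.full_length.setdefault(L, 0.0)

    def add(self, a: PairedAssignment) -> None:
        if a.transcript_id != self.transcript_id:
            raise ValueError(f"assignment for {a.transcript_id!r} added to {self.transcript_id!r}")
        L = a.intermediate_len
        self._ensure(L)
        if a.stop_pos is not None:
            if not 1 <= a.stop_pos < L:
                raise ValueError(f"stop {a.stop_pos} outside [1, {L})")
            self.stops[L][a.stop_pos - 1] += a.weight
        elif a.full_length:
            self.full_length[L] += a.weight
        self._start_hist[L][a.cdna_start - 1] += a.weight

    def add_arrays(self, L_arr, stop_arr, weight=None) -> None:
        """Bulk accumulation; ``stop_arr == 0`` encodes full-length pairs."""
        L_arr = np.asarray(L_arr, dtype=np.int64)
        stop_arr = np.asarray(stop_arr, dtype=np.int64)
        w = np.ones_like(L_arr, dtype=float) if weight is None else np.asarray(weight, float)
        for L in np.unique(L_arr):
            Li = int(L)
            self._ensure(Li)
            sel = L_arr == L
            stops = stop_arr[sel]
            ws = w[sel]
            hit = stops > 0
            np.add.at(self.stops[Li], stops[hit] - 1, ws[hit])
            self.full_length[Li] += float(ws[~hit].sum())
            starts = np.where(hit, stops + 1, 1)
            np.add.at(self._start_hist[Li], starts - 1, ws)

    def intermediates(self) -> list[int]:
        return sorted(self.stops)

    def coverage_row(self, L: int) -> np.ndarray:
        """Coverage at positions 1..L (weights of cDNAs spanning each position)."""
        return np.cumsum(self._start_hist[L])

    def stop_total(self) -> float:
        return float(sum(row.sum() for row in self.stops.values()))

    def pair_total(self) -> float:
        return float(sum(h.sum() for h in self._start_hist.values()))


def build_stop_matrix(assignments: Iterable[PairedAssignment],
                      transcript_id: str,
                      length: int) -> StopCountMatrix:
    """Accumulate assignments of one transcript into a stop-count matrix."""
    m = StopCountMatrix(transcript_id, length)
    for a in assignments:
        if a.transcript_id != transcript_id:
            continue
        m.add(a)
    return m


@dataclass(eq=False)
class DecileCounts:
    """Pooled stop and coverage vectors of one transcription decile.

    Vectors run over positions 1..interval end; intermediates whose
    length falls inside the decile's interval contribute.
    """

    transcript_id: str
    decile: int                       # 1-based index
    interval: tuple[int, int]
    stops: np.ndarray = field(repr=False)
    coverage: np.ndarray = field(repr=False)
    n_pairs: float = 0.0


def pool_deciles(matrix: StopCountMatrix,
                 intervals: Sequence[tuple[int, int]] | None = None) -> list[DecileCounts]:
    """Pool intermediate rows into one count set per transcription decile."""
    if intervals is None:
        intervals = split_deciles(matrix.length)
    out: list[DecileCounts] = []
    for d, (start, end) in enumerate(intervals, start=1):
        stops = np.zeros(end)
        coverage = np.zeros(end)
        n_pairs = 0.0
        for L in matrix.intermediates():
            if not start <= L <= end:
                continue
            stops[:L] += matrix.stops[L]
            coverage[:L] += matrix.coverage_row(L)
            n_pairs += float(matrix._start_hist[L].sum())
        out.append(DecileCounts(
            transcript_id=matrix.transcript_id, decile=d, interval=(start, end),
            stops=stops, coverage=coverage, n_pairs=n_pairs,
        ))
    return out


def write_rc_tables(matrix: StopCountMatrix, outdir) -> dict[str, str]:
    """Write a matrix as the tool's RC-table dialect: one stops TSV and
    one coverage twin per transcript (rows = intermediate length,
    columns = positions 1..transcript length)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "stops": os.path.join(outdir, f"{matrix.transcript_id}.stops.tsv"),
        "coverage": os.path.join(outdir, f"{matrix.transcript_id}.coverage.tsv"),
    }
    header = "intermediate_len\t" + "\t".join(str(p) for p in range(1, matrix.length + 1))
    for kind, path in paths.items():
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for L in matrix.intermediates():
                row = matrix.stops[L] if kind == "stops" else matrix.coverage_row(L)
                padded = np.zeros(matrix.length)
                padded[:L] = row
                fh.write(str(L) + "\t" + "\t".join(f"{v:g}" for v in padded) + "\n")
    return paths


def read_rc_tables(stops_path, coverage_path, transcript_id: str) -> StopCountMatrix:
    """Rebuild a :class:`StopCountMatrix` from its RC tables.

    The cDNA-start histogram is recovered as the first difference of each
    coverage row (coverage is its running sum, exactly).
    """
    stops_df = _read_rc(stops_path)
    cov_df = _read_rc(coverage_path)
    if list(stops_df.index) != list(cov_df.index):
        raise ValueError(f"{stops_path} and {coverage_path} list different intermediates")
    length = stops_df.shape[1]
    m = StopCountMatrix(transcript_id, length)
    for L in stops_df.index:
        Li = int(L)
        m._ensure(Li)
        m.stops[Li] = stops_df.loc[L].to_numpy(dtype=float)[:Li]
        cov = cov_df.loc[L].to_numpy(dtype=float)[:Li]
        hist = np.diff(cov, prepend=0.0)
        m._start_hist[Li] = hist
        m.full_length[Li] = float(cov[0]) if Li else 0.0
    return m


def _read_rc(path):
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: malformed RC table (missing cells)")
    return df


def pol_occupancy(assignments: Iterable[PairedAssignment], length: int) -> np.ndarray:
    """Per-position nascent 3'-end count profile (polymerase occupancy).

    Expects duplicate-collapsed assignments; each distinct assignment
    contributes one count at its intermediate length.
    """
    profile = np.zeros(length)
    for a in assignments:
        if not 1 <= a.intermediate_len <= length:
            raise ValueError(f"intermediate length {a.intermediate_len} outside [1, {length}]")
        profile[a.intermediate_len - 1] += 1
    return profile
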