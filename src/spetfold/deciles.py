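"""Decile-wise structural-change detection over dynamic A/C windows.

A dynamically sized window is slid along each transcript to collect
successive groups of 40 A/C residues (offset 20 A/C), and every window
is scored on each pair of consecutive transcription deciles (Prev,
Next) it is eligible for:

1. filters — median coverage >= 100 in both deciles, >= 1 RT stop per
   A/C base on average in both deciles, and a positional rule relative
   to the Prev decile (window end no more than 200 nt before the
   decile's start and at least 25 nt before its end) that avoids
   low-coverage edges;
2. half-normalization — the 40 A/C values are split into two chunks of
   20 A/C residues, each independently 90%-Winsorised, which smooths
   the RT-attrition coverage decrease toward the 5' end;
3. metrics — Pearson r between the normalized Prev/Next vectors and the
   Gini index of each, giving a Gini difference.

Windows with r < 0.8 are called CHANGED (structural rearrangement);
windows with r > 0.8 and |dGini| < 0.1 are STABLE; everything else —
high correlation with redistributed signal, degenerate halves, or too
few shared values — is AMBIGUOUS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align_io import TranscriptAnnotation
from .counting import DecileCounts
from .metrics import gini, pearson
from .reactivity import MISSING, ReactivityProfile, winsorise

__all__ = [
    "STATUS_STABLE",
    "STATUS_CHANGED",
    "STATUS_AMBIGUOUS",
    "STATUS_FILTERED",
    "Window",
    "WindowRecord",
    "WindowParams",
    "enumerate_windows",
    "filter_window",
    "window_values",
    "half_normalize",
    "compare_deciles",
    "analyze_transcript",
    "transcriptome_summary",
    "residue_trajectory",
]

STATUS_STABLE = "STABLE"
STATUS_CHANGED = "CHANGED"
STATUS_AMBIGUOUS = "AMBIGUOUS"
STATUS_FILTERED = "FILTERED"


@dataclass(frozen=True)
class Window:
    """A group of consecutive A/C residues and its nucleotide span."""

    transcript_id: str
    index: int
    ac_positions: tuple[int, ...]

    @property
    def nt_start(self) -> int:
        return self.ac_positions[0]

    @property
    def nt_end(self) -> int:
        return self.ac_positions[-1]


@dataclass(frozen=True)
class WindowRecord:
    """A scored (window, consecutive-decile pair) comparison."""

    window: Window
    decile_pair: tuple[int, int]
    status: str
    r: float = MISSING
    gini_prev: float = MISSING
    gini_next: float = MISSING
    filter_reason: str | None = None

    @property
    def dgini(self) -> float:
        return self.gini_next - self.gini_prev


@dataclass(frozen=True)
class WindowParams:
    """Tunable thresholds of the windowed analysis (defaults as published
    for deeply sequenced bacterial libraries)."""

    ac_per_window: int = 40
    ac_offset: int = 20
    min_median_coverage: float = 100.0
    min_stops_per_ac: float = 1.0
    max_nt_before_start: int = 200
    min_nt_from_end: int = 25
    r_cutoff: float = 0.8
    dgini_cutoff: float = 0.1
    min_shared_values: int = 10


def enumerate_windows(annotation: TranscriptAnnotation,
                      ac_per_window: int = 40,
                      ac_offset: int = 20) -> list[Window]:
    """Slide a dynamic window of ``ac_per_window`` A/C residues with an
    offset of ``ac_offset`` A/C residues; enumeration stops when fewer
    than a full window of residues remains."""
    ac = [int(p) for p in annotation.ac_positions]
    out = []
    k = 0
    start = 0
    while start + ac_per_window <= len(ac):
        out.append(Window(
            transcript_id=annotation.id,
            index=k,
            ac_positions=tuple(ac[start:start + ac_per_window]),
        ))
        k += 1
        start += ac_offset
    return out


def filter_window(window: Window,
                  prev: DecileCounts,
                  nxt: DecileCounts,
                  params: WindowParams = WindowParams()) -> str | None:
    """Return a rejection reason or None if the window is analyzable.

    The positional rule is anchored on the Prev decile, whose 3'
    boundary truncates the coverage of the comparison.
    """
    d_start, d_end = prev.interval
    if window.nt_end < d_start - params.max_nt_before_start:
        return "positional"
    if window.nt_end > d_end - params.min_nt_from_end:
        return "positional"
    span = slice(window.nt_start - 1, window.nt_end)
    for dec in (prev, nxt):
        if float(np.median(dec.coverage[span])) < params.min_median_coverage:
            return "low_coverage"
    ac_idx = np.asarray(window.ac_positions) - 1
    for dec in (prev, nxt):
        if float(dec.stops[ac_idx].sum()) / len(window.ac_positions) < params.min_stops_per_ac:
            return "low_signal"
    return None


def window_values(window: Window, dec: DecileCounts) -> np.ndarray:
    """Raw stop weights at the window's A/C positions (missing where uncovered)."""
    idx = np.asarray(window.ac_positions) - 1
    vals = dec.stops[idx].astype(float)
    vals[dec.coverage[idx] <= 0] = MISSING
    return vals


def half_normalize(values: np.ndarray, ac_per_chunk: int | None = None) -> tuple[np.ndarray, bool]:
    """Winsorise the first and second half of a window independently.

    The window is defined by its A/C residues, so the two chunks are the
    first and last half of those residues (20 each at defaults).
    Returns ``(normalized, degenerate)`` where ``degenerate`` flags an
    all-zero or under-populated half.
    """
    values = np.asarray(values, dtype=float)
    half = values.size // 2 if ac_per_chunk is None else ac_per_chunk
    first, first_flag = winsorise(values[:half])
    second, second_flag = winsorise(values[half:])
    degenerate = first_flag is not None or second_flag is not None
    return np.concatenate([first, second]), degenerate


def compare_deciles(window: Window,
                    decile_pair: tuple[int, int],
                    prev_values: np.ndarray,
                    next_values: np.ndarray,
                    params: WindowParams = WindowParams()) -> WindowRecord:
    """Score one (window, consecutive-decile pair) from raw stop values.

    Both vectors are half-normalized; Pearson r and the two Gini indices
    are computed over the positions non-missing in both.
    """
    prev_norm, prev_deg = half_normalize(prev_values)
    next_norm, next_deg = half_normalize(next_values)
    shared = np.isfinite(prev_norm) & np.isfinite(next_norm)
    if prev_deg or next_deg or int(shared.sum()) < params.min_shared_values:
        return WindowRecord(window=window, decile_pair=decile_pair, status=STATUS_AMBIGUOUS)
    p, q = prev_norm[shared], next_norm[shared]
    r = pearson(p, q)
    g_prev = gini(p)
    g_next = gini(q)
    if not np.isfinite(r) or not np.isfinite(g_prev) or not np.isfinite(g_next):
        return WindowRecord(window=window, decile_pair=decile_pair, status=STATUS_AMBIGUOUS,
                            r=r, gini_prev=g_prev, gini_next=g_next)
    if r < params.r_cutoff:
        status = STATUS_CHANGED
    elif r > params.r_cutoff and abs(g_next - g_prev) < params.dgini_cutoff:
        status = STATUS_STABLE
    else:
        status = STATUS_AMBIGUOUS
    return WindowRecord(window=window, decile_pair=decile_pair, status=status,
                        r=r, gini_prev=g_prev, gini_next=g_next)


def analyze_transcript(annotation: TranscriptAnnotation,
                       pooled: Sequence[DecileCounts],
                       params: WindowParams = WindowParams()) -> list[WindowRecord]:
    """Score every window against every eligible consecutive-decile pair."""
    records: list[WindowRecord] = []
    windows = enumerate_windows(annotation, params.ac_per_window, params.ac_offset)
    for d in range(len(pooled) - 1):
        prev, nxt = pooled[d], pooled[d + 1]
        for window in windows:
            reason = filter_window(window, prev, nxt, params)
            if reason is not None:
                records.append(WindowRecord(
                    window=window, decile_pair=(prev.decile, nxt.decile),
                    status=STATUS_FILTERED, filter_reason=reason,
                ))
                continue
            records.append(compare_deciles(
                window, (prev.decile, nxt.decile),
                window_values(window, prev), window_values(window, nxt), params,
            ))
    return records


def transcriptome_summary(records: Iterable[WindowRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-transcript and overall counts/fractions of window calls.

    Returns ``(table, scatter)``: the summary table and the per-window
    (r, dGini) scatter data of scored windows for plotting.
    """
    rows = []
    scatter = []
    for rec in records:
        rows.append((rec.window.transcript_id, rec.status))
        if rec.status in (STATUS_STABLE, STATUS_CHANGED, STATUS_AMBIGUOUS):
            scatter.append((
                rec.window.transcript_id, rec.window.index,
                rec.decile_pair[0], rec.decile_pair[1],
                rec.r, rec.gini_prev, rec.gini_next, rec.dgini, rec.status,
            ))
    df = pd.DataFrame(rows, columns=["transcript", "status"])
    statuses = [STATUS_STABLE, STATUS_CHANGED, STATUS_AMBIGUOUS, STATUS_FILTERED]
    table = (
        df.groupby(["transcript", "status"]).size().unstack(fill_value=0)
        .reindex(columns=statuses, fill_value=0)
    )
    total = pd.DataFrame(table.sum(axis=0)).T
    total.index = ["ALL"]
    table = pd.concat([table, total])
    scored = table[[STATUS_STABLE, STATUS_CHANGED, STATUS_AMBIGUOUS]].sum(axis=1)
    for status in (STATUS_STABLE, STATUS_CHANGED, STATUS_AMBIGUOUS):
        with np.errstate(invalid="ignore", divide="ignore"):
            table[f"frac_{status.lower()}"] = np.where(
                scored > 0, table[status] / scored, np.nan
            )
    scatter_df = pd.DataFrame(scatter, columns=[
        "transcript", "window", "decile_prev", "decile_next",
        "r", "gini_prev", "gini_next", "dgini", "status",
    ])
    return table, scatter_df


def residue_trajectory(profiles: Mapping[int, ReactivityProfile],
                       positions: Sequence[int],
                       annotation: TranscriptAnnotation) -> pd.Series:
    """Mean reactivity of a residue group across transcription intermediates.

    For each intermediate long enough to contain all requested positions,
    the series holds the mean reactivity over those positions (missing
    values excluded); ordered by intermediate length.
    """
    positions = [int(p) for p in positions]
    ac_set = set(int(p) for p in annotation.ac_positions)
    bad = [p for p in positions if p not in ac_set]
    if bad:
        raise ValueError(f"positions {bad} are not A/C residues of {annotation.id}")
    idx = np.asarray(positions) - 1
    out = {}
    for L in sorted(profiles):
        if L < max(positions):
            continue
        vals = profiles[L].values[idx]
        finite = vals[np.isfinite(vals)]
        out[L] = float(finite.mean()) if finite.size else MISSING
    return pd.Series(out, name="mean_reactivity")
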