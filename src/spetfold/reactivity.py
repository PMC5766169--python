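"""Normalized per-base DMS reactivities from RT-stop counts.

Scoring is treated-only: the raw score of an A/C position is its pooled
stop weight (no untreated-control subtraction), and G/U or uncovered
positions are missing.  Normalization caps each value at the nearest-rank
95th percentile of its window and divides by it (90% Winsorising), so
reactivities land in [0, 1] and are invariant under rescaling of the raw
counts.  Whole profiles are normalized in 50-nt sliding windows with a
25-nt offset; a position covered by two windows receives the mean of its
two normalized values.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .align_io import TranscriptAnnotation
from .counting import DecileCounts, StopCountMatrix
from .metrics import nearest_rank_percentile

__all__ = [
    "MISSING",
    "WinsorResult",
    "winsorise",
    "score_profile",
    "normalize_sliding",
    "ReactivityProfile",
    "profiles_per_intermediate",
    "profiles_per_decile",
    "reactivity_heatmap",
    "MASK_OK",
    "MASK_BLIND",
    "MASK_UNTRANSCRIBED",
]

MISSING = float("nan")

MASK_OK = 0
MASK_BLIND = 1
MASK_UNTRANSCRIBED = 2


class WinsorResult(NamedTuple):
    values: np.ndarray
    flag: str | None          # None | "degenerate" | "too_few"


def winsorise(values, upper_pct: float = 95.0) -> WinsorResult:
    """Scale values to the nearest-rank ``upper_pct`` percentile, capped at 1.

    Missing (NaN) entries propagate.  An all-zero input returns all
    zeros with the ``degenerate`` flag (no division); fewer than two
    non-missing values return all-missing with the ``too_few`` flag.
    """
    v = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(v)
    n = int(finite.sum())
    if n < 2:
        out = np.full_like(v, MISSING)
        return WinsorResult(out, "too_few")
    if np.all(v[finite] == 0):
        return WinsorResult(v, "degenerate")
    p = nearest_rank_percentile(v[finite], upper_pct)
    if p <= 0:
        # all mass above the percentile rank (possible with many zeros);
        # fall back to the max so outputs stay in [0, 1]
        p = float(np.max(v[finite]))
    out = np.where(finite, np.minimum(v, p) / p, MISSING)
    return WinsorResult(out, None)


def score_profile(stops, coverage, ac_positions, length: int | None = None) -> np.ndarray:
    """Raw treated-only score vector: stop weight at covered A/C positions.

    Positions that are not A/C, have zero coverage, or lie beyond the
    count vectors are missing.
    """
    stops = np.asarray(stops, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if length is None:
        length = stops.size
    out = np.full(length, MISSING)
    ac = np.asarray(ac_positions, dtype=int)
    ac = ac[(ac >= 1) & (ac <= min(length, stops.size, coverage.size))]
    covered = ac[coverage[ac - 1] > 0]
    out[covered - 1] = stops[covered - 1]
    return out


def normalize_sliding(raw, window: int = 50, offset: int = 25) -> np.ndarray:
    """Winsorise a raw score vector in sliding windows and blend overlaps.

    Each window is normalized independently over its non-missing values;
    a position covered by several windows receives the mean of its
    normalized values.  A transcript shorter than one window is treated
    as a single whole-length window; terminal partial windows are
    normalized as-is when they hold at least two values.
    """
    if window < 1 or offset < 1:
        raise ValueError("window and offset must be positive")
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    acc = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    starts = range(0, n, offset) if n > window else [0]
    for s in starts:
        e = min(s + window, n)
        res = winsorise(raw[s:e])
        if res.flag == "too_few":
            continue
        ok = np.isfinite(res.values)
        acc[s:e][ok] += res.values[ok]
        cnt[s:e][ok] += 1
    out = np.full(n, MISSING)
    covered = cnt > 0
    out[covered] = acc[covered] / cnt[covered]
    return out


@dataclass(eq=False)
class ReactivityProfile:
    """Per-position reactivity in [0, 1] for one analysis context.

    ``context`` is an intermediate length (int), a decile index tagged
    ``("decile", d)``, or the string ``"MATURE"``.
    """

    transcript_id: str
    context: object
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1.0 + 1e-12):
            raise ValueError("reactivities must lie in [0, 1]")
        self.values = v


def profiles_per_intermediate(matrix: StopCountMatrix,
                              annotation: TranscriptAnnotation,
                              window: int = 50, offset: int = 25) -> dict[int, ReactivityProfile]:
    """One normalized reactivity profile per intermediate length."""
    out: dict[int, ReactivityProfile] = {}
    for L in matrix.intermediates():
        raw = score_profile(matrix.stops[L], matrix.coverage_row(L),
                            annotation.ac_positions, L)
        out[L] = ReactivityProfile(
            transcript_id=matrix.transcript_id, context=L,
            values=normalize_sliding(raw, window, offset),
        )
    return out


def profiles_per_decile(pooled: Sequence[DecileCounts],
                        annotation: TranscriptAnnotation,
                        window: int = 50, offset: int = 25) -> list[ReactivityProfile]:
    """One normalized reactivity profile per transcription decile pool."""
    out = []
    for dec in pooled:
        raw = score_profile(dec.stops, dec.coverage, annotation.ac_positions, dec.stops.size)
        out.append(ReactivityProfile(
            transcript_id=dec.transcript_id, context=("decile", dec.decile),
            values=normalize_sliding(raw, window, offset),
        ))
    return out


def reactivity_heatmap(profiles: Mapping[int, ReactivityProfile],
                       length: int,
                       min_read_len: int = 15) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Assemble per-intermediate profiles into a renderable matrix.

    Rows are ordered by intermediate length; columns are transcript
    positions.  The companion mask distinguishes the blind region
    (positions within ``min_read_len`` of a row's 3' end, where stops
    cannot be observed) from the untranscribed region (positions past
    the row's 3' end).

    Returns ``(values, mask, row_lengths)``; empty inputs give empty
    arrays.
    """
    rows = sorted(profiles)
    values = np.full((len(rows), length), MISSING)
    mask = np.full((len(rows), length), MASK_OK, dtype=np.int8)
    for i, L in enumerate(rows):
        v = profiles[L].values
        values[i, :v.size] = v
        blind_start = max(L - min_read_len, 0)
        mask[i, blind_start:L] = MASK_BLIND
        mask[i, L:] = MASK_UNTRANSCRIBED
    return values, mask, rows


def render_heatmap(values: np.ndarray, mask: np.ndarray, row_lengths: Sequence[int],
                   path, title: str = "") -> None:
    """Optional PNG rendering of a reactivity heatmap (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.ma.masked_invalid(values)
    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(shown, aspect="auto", origin="lower", cmap="viridis",
                   vmin=0.0, vmax=1.0, interpolation="nearest")
    blind = np.ma.masked_where(mask != MASK_BLIND, np.ones_like(values))
    ax.imshow(blind, aspect="auto", origin="lower", cmap="autumn",
              alpha=0.4, interpolation="nearest")
    ax.set_xlabel("position (nt)")
    ax.set_ylabel("intermediate (row index)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="DMS reactivity")
    fig.savefig(path, dpi=150)
    plt.close(fig)
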