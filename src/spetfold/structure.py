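"""Secondary-structure handling and base-pair range classification.

A mature RNA secondary structure (dot-bracket / Vienna notation) is turned
into a symmetric pair table, and each base is labelled by whether it is
unpaired, or paired within a single transcription decile (short-range), or
paired across decile boundaries (long-range).  On top of the labels the
module computes the enrichment of long-range bases inside
structure-changing windows (hypergeometric upper tail), nascent-versus-
mature grouped reactivity comparisons (one-way ANOVA), and an averaged
reactivity metaprofile over minimal hairpin elements.

Only plain, pseudoknot-free dot-brackets (characters ``().``) are
accepted; crossing bracket layers are rejected rather than silently
flattened, because flattening corrupts the pair-range labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .metrics import hypergeom_upper_tail

__all__ = [
    "UNPAIRED",
    "SecondaryStructure",
    "parse_dotbracket",
    "read_vienna",
    "write_vienna",
    "classify_pairs",
    "EnrichmentResult",
    "enrichment_test",
    "category_reactivity",
    "element_metaprofile",
    "hairpin_elements",
]

UNPAIRED = 0

CATEGORY_UNPAIRED = "UNPAIRED"
CATEGORY_SHORT = "SHORT_RANGE"
CATEGORY_LONG = "LONG_RANGE"


@dataclass(eq=False)
class SecondaryStructure:
    """A parsed dot-bracket structure with its symmetric pair table.

    ``pair_table`` is a 1-based int array of length ``len(dotbracket)+1``;
    entry ``p`` holds the partner of position ``p`` or 0 if unpaired
    (index 0 is unused).
    """

    transcript_id: str
    dotbracket: str
    pair_table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pt = np.asarray(self.pair_table, dtype=int)
        if pt.size != len(self.dotbracket) + 1:
            raise ValueError("pair table length must be structure length + 1")
        for p in range(1, pt.size):
            q = pt[p]
            if q and pt[q] != p:
                raise ValueError(f"pair table not symmetric at position {p}")
        self.pair_table = pt

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    def partner(self, position: int) -> int:
        """Partner of a 1-based position, or 0 if unpaired."""
        return int(self.pair_table[position])

    def pairs(self) -> list[tuple[int, int]]:
        """All base pairs as (5'-side, 3'-side) 1-based tuples."""
        out = []
        for p in range(1, self.length + 1):
            q = int(self.pair_table[p])
            if q > p:
                out.append((p, q))
        return out


def parse_dotbracket(dotbracket: str, transcript_id: str = "") -> SecondaryStructure:
    """Parse a plain dot-bracket string into a :class:`SecondaryStructure`.

    Raises ``ValueError`` naming the first offending 1-based offset for
    characters outside ``().``, an unmatched ``)``, or an unclosed ``(``.
    """
    n = len(dotbracket)
    table = np.zeros(n + 1, dtype=int)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(
                    f"{transcript_id or 'structure'}: unmatched ')' at offset {i}"
                )
            j = stack.pop()
            table[j] = i
            table[i] = j
        elif ch != ".":
            raise ValueError(
                f"{transcript_id or 'structure'}: invalid character {ch!r} at offset {i}"
                " (only '().' are supported; pseudoknot layers are rejected)"
            )
    if stack:
        raise ValueError(
            f"{transcript_id or 'structure'}: unclosed '(' at offset {stack[0]}"
        )
    return SecondaryStructure(transcript_id=transcript_id, dotbracket=dotbracket, pair_table=table)


def read_vienna(path) -> dict[str, SecondaryStructure]:
    """Read a Vienna file (``>id`` / sequence / dot-bracket triplets).

    The sequence line is optional: records may also be ``>id`` followed
    directly by a dot-bracket line.
    """
    structures: dict[str, SecondaryStructure] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        i += 1
        block = []
        while i < len(lines) and not lines[i].startswith(">"):
            block.append(lines[i])
            i += 1
        db = next((ln for ln in block if set(ln) <= set("().")), None)
        if db is None:
            raise ValueError(f"{path}: no dot-bracket line for record {name!r}")
        if name in structures:
            raise ValueError(f"{path}: duplicate record {name!r}")
        structures[name] = parse_dotbracket(db, transcript_id=name)
    return structures


def write_vienna(structures: Mapping[str, SecondaryStructure], path,
                 sequences: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, struct in structures.items():
            fh.write(f">{name}\n")
            if sequences and name in sequences:
                fh.write(sequences[name] + "\n")
            fh.write(struct.dotbracket + "\n")


def _decile_of(position: int, intervals: Sequence[tuple[int, int]]) -> int:
    for d, (start, end) in enumerate(intervals, start=1):
        if start <= position <= end:
            return d
    raise ValueError(f"position {position} outside decile intervals")


def classify_pairs(structure: SecondaryStructure,
                   decile_intervals: Sequence[tuple[int, int]],
                   ac_positions: Iterable[int]) -> pd.DataFrame:
    """Label every A/C position as unpaired / short-range / long-range.

    A paired base is short-range when its partner lies in the same
    transcription decile and long-range when the pair spans two deciles
    (boundary-spanning pairs are long-range).  The lower-coordinate
    partner of a helix is the 5' side.

    Returns a DataFrame with columns ``position``, ``category``,
    ``helix_side`` (``FIVE_PRIME`` / ``THREE_PRIME`` / ``NA``) covering
    each A/C position exactly once.
    """
    rows = []
    for p in sorted(set(int(x) for x in ac_positions)):
        if not 1 <= p <= structure.length:
            raise ValueError(f"A/C position {p} outside structure of length {structure.length}")
        q = structure.partner(p)
        if q == UNPAIRED:
            rows.append((p, CATEGORY_UNPAIRED, "NA"))
            continue
        same = _decile_of(p, decile_intervals) == _decile_of(q, decile_intervals)
        category = CATEGORY_SHORT if same else CATEGORY_LONG
        side = "FIVE_PRIME" if p < q else "THREE_PRIME"
        rows.append((p, category, side))
    return pd.DataFrame(rows, columns=["position", "category", "helix_side"])


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of long-range bases in changed windows."""

    population: int          # N: A/C bases in all analyzed (filter-passing) windows
    successes: int           # K: long-range bases in the population
    draws: int               # n: A/C bases inside CHANGED windows
    observed: int            # k: long-range bases among the draws
    p_value: float
    expected_fraction: dict[str, float]
    observed_fraction: dict[str, float]


def enrichment_test(category_table: pd.DataFrame,
                    changed_positions: Iterable[int],
                    universe_positions: Iterable[int],
                    category: str = CATEGORY_LONG) -> EnrichmentResult:
    """Upper-tail hypergeometric test for category enrichment.

    Parameters
    ----------
    category_table : DataFrame
        Output of :func:`classify_pairs` (columns ``position``,
        ``category``).
    changed_positions : iterable of int
        A/C positions inside structure-changing (CHANGED) windows.
    universe_positions : iterable of int
        A/C positions inside all analyzed (non-filtered) windows.
    category : str
        The category tested for enrichment (default long-range).

    Also reports expected versus observed per-category fractions among
    the drawn positions, for bar-plot style summaries.
    """
    universe = set(int(p) for p in universe_positions)
    draws_set = set(int(p) for p in changed_positions)
    if not draws_set <= universe:
        raise ValueError("changed positions must be a subset of the universe")
    cats = dict(zip(category_table["position"].astype(int), category_table["category"]))
    missing = universe - set(cats)
    if missing:
        raise ValueError(f"{len(missing)} universe positions lack a category label")
    N = len(universe)
    n = len(draws_set)
    K = sum(1 for p in universe if cats[p] == category)
    k = sum(1 for p in draws_set if cats[p] == category)
    p_value = hypergeom_upper_tail(k, N, K, n)
    all_cats = (CATEGORY_UNPAIRED, CATEGORY_SHORT, CATEGORY_LONG)
    expected = {
        c: (sum(1 for p in universe if cats[p] == c) / N if N else float("nan"))
        for c in all_cats
    }
    observed = {
        c: (sum(1 for p in draws_set if cats[p] == c) / n if n else float("nan"))
        for c in all_cats
    }
    return EnrichmentResult(N, K, n, k, p_value, expected, observed)


def category_reactivity(nascent_decile_profiles: Sequence[np.ndarray],
                        mature_profile: np.ndarray,
                        category_table: pd.DataFrame,
                        decile_intervals: Sequence[tuple[int, int]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group reactivities by pairing category in nascent and mature RNA.

    The nascent value of a base is taken from the profile of its own
    transcription decile (the decile whose interval contains the base);
    the mature value from the mature profile.  For paired bases only the
    5'-side of each helix enters the short-/long-range groups, since the
    3' side of a nascent helix is close to the polymerase and generally
    unresolved.

    Returns
    -------
    (values, tests)
        ``values``: long DataFrame with ``position``, ``category``,
        ``source`` (nascent/mature), ``reactivity``.
        ``tests``: one-way ANOVA F and p per category comparing nascent
        versus mature reactivities; empty groups are omitted.
    """
    mature = np.asarray(mature_profile, dtype=float)
    rows = []
    for _, rec in category_table.iterrows():
        p = int(rec["position"])
        cat = rec["category"]
        if cat != CATEGORY_UNPAIRED and rec["helix_side"] != "FIVE_PRIME":
            continue
        d = _decile_of(p, decile_intervals)
        nas_profile = nascent_decile_profiles[d - 1]
        nas = float(nas_profile[p - 1]) if p - 1 < len(nas_profile) else float("nan")
        mat = float(mature[p - 1]) if p - 1 < mature.size else float("nan")
        if np.isfinite(nas):
            rows.append((p, cat, "nascent", nas))
        if np.isfinite(mat):
            rows.append((p, cat, "mature", mat))
    values = pd.DataFrame(rows, columns=["position", "category", "source", "reactivity"])
    tests = []
    for cat, grp in values.groupby("category"):
        nas = grp.loc[grp["source"] == "nascent", "reactivity"].to_numpy()
        mat = grp.loc[grp["source"] == "mature", "reactivity"].to_numpy()
        if nas.size < 2 or mat.size < 2:
            continue
        f, p = _scipy_stats.f_oneway(nas, mat)
        tests.append((cat, nas.size, mat.size, float(f), float(p)))
    tests_df = pd.DataFrame(tests, columns=["category", "n_nascent", "n_mature", "F", "p_value"])
    return values, tests_df


def hairpin_elements(structure: SecondaryStructure) -> list[tuple[int, int]]:
    """Minimal structural elements: maximal single-branch hairpin spans.

    An element is grown from each hairpin-closing pair outward through
    enclosing pairs as long as the enclosing pair contains no other
    branch (stacked pairs, bulges and internal loops are absorbed;
    multiloops stop the growth).  Returns (start, end) 1-based spans of
    the outermost pair of each element.
    """
    pt = structure.pair_table
    n = structure.length
    # hairpin-closing pairs: no paired position strictly inside
    closings = []
    for i, j in structure.pairs():
        if all(pt[x] == 0 for x in range(i + 1, j)):
            closings.append((i, j))
    elements = []
    for i, j in closings:
        while True:
            # find nearest enclosing pair (a, b) with only this branch inside
            a = i - 1
            while a >= 1 and pt[a] == 0:
                a -= 1
            if a < 1 or pt[a] <= j:
                break
            b = int(pt[a])
            # region (j, b) must be unpaired for (a,b) to enclose a single branch
            if any(pt[x] != 0 for x in range(j + 1, b)):
                break
            i, j = a, b
        elements.append((i, j))
    # deduplicate (several closings cannot merge, but be safe) and sort
    return sorted(set(elements))


def element_metaprofile(structure: SecondaryStructure,
                        nascent_decile_profiles: Sequence[np.ndarray],
                        mature_profile: np.ndarray,
                        decile_intervals: Sequence[tuple[int, int]],
                        category_table: pd.DataFrame | None = None,
                        ac_positions: Iterable[int] | None = None,
                        n_bins: int = 21) -> pd.DataFrame:
    """Average nascent and mature reactivity over minimal hairpin elements.

    Each qualifying element (a maximal single-branch hairpin whose pairs
    are all short-range) is rescaled to ``n_bins`` relative-coordinate
    bins.  The nascent curve of an element is taken from the decile in
    which the element was transcribed (the decile of its 3' end).

    Returns a DataFrame with ``bin``, ``rel_pos``, ``nascent_mean``,
    ``mature_mean``, ``n_nascent``, ``n_mature``; empty when no element
    qualifies.
    """
    if category_table is None:
        if ac_positions is None:
            raise ValueError("provide either category_table or ac_positions")
        category_table = classify_pairs(structure, decile_intervals, ac_positions)
    cats = dict(zip(category_table["position"].astype(int), category_table["category"]))
    mature = np.asarray(mature_profile, dtype=float)
    nas_sum = np.zeros(n_bins)
    nas_n = np.zeros(n_bins, dtype=int)
    mat_sum = np.zeros(n_bins)
    mat_n = np.zeros(n_bins, dtype=int)
    for start, end in hairpin_elements(structure):
        paired = [p for p in range(start, end + 1) if structure.partner(p)]
        if any(cats.get(p) == CATEGORY_LONG for p in paired):
            continue
        d = _decile_of(end, decile_intervals)
        nas_profile = np.asarray(nascent_decile_profiles[d - 1], dtype=float)
        span = end - start
        for p in range(start, end + 1):
            rel = 0.0 if span == 0 else (p - start) / span
            b = int(round(rel * (n_bins - 1)))
            if p - 1 < nas_profile.size and np.isfinite(nas_profile[p - 1]):
                nas_sum[b] += nas_profile[p - 1]
                nas_n[b] += 1
            if p - 1 < mature.size and np.isfinite(mature[p - 1]):
                mat_sum[b] += mature[p - 1]
                mat_n[b] += 1
    with np.errstate(invalid="ignore"):
        nas_mean = np.where(nas_n > 0, nas_sum / np.maximum(nas_n, 1), np.nan)
        mat_mean = np.where(mat_n > 0, mat_sum / np.maximum(mat_n, 1), np.nan)
    return pd.DataFrame({
        "bin": np.arange(n_bins),
        "rel_pos": np.linspace(0.0, 1.0, n_bins),
        "nascent_mean": nas_mean,
        "mature_mean": mat_mean,
        "n_nascent": nas_n,
        "n_mature": mat_n,
    })
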