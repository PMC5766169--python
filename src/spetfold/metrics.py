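"""Scalar statistics shared across the pipeline.

The two window-comparison metrics (Pearson correlation and the Gini index
of a reactivity vector) and the enrichment tail probability live here so
that the windowed analysis and the structure classification modules use
one definition each, tested against brute-force oracles.

Conventions
-----------
* Missing values are ``numpy.nan`` and are dropped pairwise (Pearson) or
  listwise (Gini, percentile) before computation.
* The Gini index of a non-negative vector ``x`` of length ``n`` with mean
  ``mu`` is ``sum_ij |x_i - x_j| / (2 n^2 mu)``, which ranges over
  ``[0, 1 - 1/n]`` and is invariant under positive rescaling.
* Percentiles use the nearest-rank definition: the p-th percentile of
  ``n`` sorted values is the value at rank ``ceil(p/100 * n)``.  This is
  deterministic and ecosystem-independent (no interpolation).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "nearest_rank_percentile",
    "gini",
    "pearson",
    "hypergeom_upper_tail",
]


def _finite(values) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    return v[np.isfinite(v)]


def nearest_rank_percentile(values, pct: float) -> float:
    """Nearest-rank percentile of the non-missing values.

    Parameters
    ----------
    values : array-like
        Input values; NaN entries are ignored.
    pct : float
        Percentile in (0, 100].

    Returns
    -------
    float
        The value at sorted rank ``ceil(pct/100 * n)`` (1-based).
    """
    if not 0.0 < pct <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {pct}")
    v = _finite(values)
    n = v.size
    if n == 0:
        raise ValueError("no non-missing values")
    rank = max(1, math.ceil(pct / 100.0 * n))
    return float(np.partition(v, rank - 1)[rank - 1])


def gini(values) -> float:
    """Gini index ``sum_ij |x_i - x_j| / (2 n^2 mu)`` of a vector.

    Computed through the sorted-rank identity
    ``sum_i (2 i - n - 1) x_(i) / (n^2 mu)`` which is O(n log n) and
    algebraically equal to the double-sum definition.

    Returns NaN for an empty or zero-mean vector (the index is undefined
    when there is no signal to distribute).
    """
    v = _finite(values)
    n = v.size
    if n == 0:
        return float("nan")
    mu = v.mean()
    if mu == 0:
        return float("nan")
    vs = np.sort(v)
    ranks = np.arange(1, n + 1, dtype=float)
    return float(np.sum((2.0 * ranks - n - 1.0) * vs) / (n * n * mu))


def pearson(x, y) -> float:
    """Pearson correlation over positions non-missing in both vectors.

    Returns NaN when fewer than two shared values remain or either side
    has zero variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[mask], y[mask]
    if xs.size < 2:
        return float("nan")
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    denom = math.sqrt(float(np.dot(xc, xc)) * float(np.dot(yc, yc)))
    if denom == 0.0:
        return float("nan")
    return float(np.dot(xc, yc) / denom)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts successes among ``n`` draws without replacement from a
    population of ``N`` items of which ``K`` are successes.

    Raises ``ValueError`` on inconsistent inputs (``k > min(K, n)`` or
    negative/overflowing counts).
    """
    for name, val in (("k", k), ("N", N), ("K", K), ("n", n)):
        if val < 0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(
            f"observed successes k={k} exceed min(K={K}, n={n}); inconsistent inputs"
        )
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(_scipy_stats.hypergeom.sf(k - 1, N, K, n))
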