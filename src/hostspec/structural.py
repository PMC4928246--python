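"""Structural specialization indices for weighted bipartite networks.

Community level: H2', the standardized two-dimensional Shannon entropy of
the interaction matrix.  With p_ij = a_ij / m,

    H2 = -sum_{ij: a_ij>0} p_ij ln p_ij
    H2' = (H2_max - H2) / (H2_max - H2_min)

where H2_min / H2_max are the extreme entropies over non-negative integer
tables sharing the observed row and column totals.  H2' is 0 for the most
generalist community (interactions proportional to marginal totals) and 1
for the most specialist one.

Species level: d', the standardized Kullback-Leibler divergence of a
species' host-use distribution from overall host availability.  For row i
with p'_ij = a_ij / A_i and availability q_j = A_j / m,

    d_i   = sum_j p'_ij ln(p'_ij / q_j)
    d_max = ln(m / A_i)
    d_min = min of d over integer allocations of A_i across hosts
    d'    = (d - d_min) / (d_max - d_min)

All entropies are in nats.  Extrema are found by exhaustive enumeration for
small problems and by deterministic greedy/largest-remainder heuristics for
large ones; the small-problem route is exact by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

from .records import BipartiteMatrix

# Problem-size bounds below which extrema are computed by exhaustive
# enumeration when method="auto".
EXACT_MAX_CELLS = 10
EXACT_MAX_M = 12
#: Max number of integer allocations enumerated for d_min under "auto".
EXACT_MAX_ALLOCATIONS = 5000


@dataclass(frozen=True)
class H2Result:
    """Community-level specialization: entropy, its extrema, and H2' in [0, 1]."""

    H2: float
    H2_min: float
    H2_max: float
    H2_prime: float
    degenerate: bool = False


@dataclass(frozen=True)
class DPrimeResult:
    """Species-level specialization for one tick row."""

    tick_species: str
    d: float
    d_min: float
    d_max: float
    d_prime: float
    degenerate: bool = False


def _entropy_counts(a: np.ndarray) -> float:
    """Shannon entropy (nats) of counts a, H = ln m - (1/m) sum a ln a."""
    a = np.asarray(a, dtype=np.float64)
    m = a.sum()
    pos = a[a > 0]
    return float(np.log(m) - (pos * np.log(pos)).sum() / m)


def shannon_H2(M: BipartiteMatrix) -> float:
    """Two-dimensional Shannon entropy of the interaction frequencies (nats)."""
    return _entropy_counts(M.counts)


def _compositions_bounded(total: int, bounds: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
    if len(bounds) == 1:
        if total <= bounds[0]:
            yield (total,)
        return
    for v in range(min(total, bounds[0]), -1, -1):
        for rest in _compositions_bounded(total - v, bounds[1:]):
            yield (v,) + rest


def enumerate_tables(row_totals: Sequence[int],
                     col_totals: Sequence[int]) -> Iterator[np.ndarray]:
    """All non-negative integer tables with the given margins (small problems)."""
    r = [int(x) for x in row_totals]
    c = [int(x) for x in col_totals]

    def rec(i: int, colrem: tuple[int, ...]):
        if i == len(r):
            yield []
            return
        for comp in _compositions_bounded(r[i], colrem):
            new = tuple(cr - v for cr, v in zip(colrem, comp))
            for rest in rec(i + 1, new):
                yield [comp] + rest

    for rows in rec(0, tuple(c)):
        yield np.array(rows, dtype=np.int64)


def _check_margins(row_totals, col_totals) -> tuple[np.ndarray, np.ndarray, int]:
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    if (r < 0).any() or (c < 0).any():
        raise ValueError("margins must be non-negative")
    m = int(r.sum())
    if m != int(c.sum()):
        raise ValueError(
            f"inconsistent margins: row sum {m} != column sum {int(c.sum())}"
        )
    if m == 0:
        raise ValueError("margins sum to zero")
    return r, c, m


def _h2_extrema_exact(r: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    lo = math.inf
    hi = -math.inf
    for table in enumerate_tables(r, c):
        h = _entropy_counts(table)
        lo = min(lo, h)
        hi = max(hi, h)
    return lo, hi


def _h2_min_greedy(r: np.ndarray, c: np.ndarray) -> float:
    """Concentrate mass: place min(remaining row, remaining column) into the
    cell of the two largest remaining margins until exhausted."""
    r = r.astype(np.int64).copy()
    c = c.astype(np.int64).copy()
    cells: list[int] = []
    total = int(r.sum())
    while total > 0:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        v = int(min(r[i], c[j]))
        cells.append(v)
        r[i] -= v
        c[j] -= v
        total -= v
    return _entropy_counts(np.array(cells, dtype=np.int64))


def _h2_max_greedy(r: np.ndarray, c: np.ndarray) -> float:
    """Even out mass: largest-remainder integer allocation toward the
    margin-proportional table a_ij = A_i A_j / m, respecting the margins."""
    m = int(r.sum())
    expected = np.outer(r, c) / m
    base = np.floor(expected).astype(np.int64)
    rdef = r - base.sum(axis=1)
    cdef = c - base.sum(axis=0)
    frac = (expected - base).ravel()
    order = np.argsort(-frac, kind="stable")
    ncols = len(c)
    remaining = int(rdef.sum())
    a = base
    while remaining > 0:
        for idx in order:
            i, j = divmod(int(idx), ncols)
            if rdef[i] > 0 and cdef[j] > 0:
                a[i, j] += 1
                rdef[i] -= 1
                cdef[j] -= 1
                remaining -= 1
                if remaining == 0:
                    break
    return _entropy_counts(a)


def h2_extrema(row_totals: Sequence[int], col_totals: Sequence[int],
               method: str = "auto") -> tuple[float, float]:
    """(H2_min, H2_max) over integer tables with the given margins.

    method="exact" enumerates every table; "greedy" uses the deterministic
    heuristics; "auto" picks exact for small problems (cells <= 10 or
    m <= 12) and greedy otherwise.
    """
    r, c, m = _check_margins(row_totals, col_totals)
    if method == "auto":
        method = "exact" if (r.size * c.size <= EXACT_MAX_CELLS or m <= EXACT_MAX_M) \
            else "greedy"
    if method == "exact":
        return _h2_extrema_exact(r, c)
    if method == "greedy":
        return _h2_min_greedy(r, c), _h2_max_greedy(r, c)
    raise ValueError(f"unknown method {method!r}")


def h2_prime(M: BipartiteMatrix, method: str = "auto",
             extrema: tuple[float, float] | None = None) -> H2Result:
    """Standardized two-dimensional Shannon entropy H2' of the whole network.

    ``extrema`` allows reusing (H2_min, H2_max) when margins are known fixed
    (e.g. across fixed-margin null replicates).
    """
    h2 = shannon_H2(M)
    if extrema is None:
        extrema = h2_extrema(M.row_totals, M.col_totals, method=method)
    h2_min, h2_max = extrema
    span = h2_max - h2_min
    if span <= 1e-12:
        return H2Result(h2, h2_min, h2_max, 0.0, degenerate=True)
    prime = (h2_max - h2) / span
    return H2Result(h2, h2_min, h2_max, float(min(1.0, max(0.0, prime))))


# ---------------------------------------------------------------------------
# species-level d'


def _kl_counts(x: np.ndarray, total: float, q: np.ndarray) -> float:
    """KL divergence (nats) of allocation x/total from availability q."""
    pos = x > 0
    p = x[pos] / total
    return float((p * (np.log(p) - np.log(q[pos]))).sum())


@lru_cache(maxsize=512)
def _compositions(total: int, parts: int) -> np.ndarray:
    """All non-negative integer compositions of ``total`` into ``parts`` parts."""
    if parts == 1:
        return np.array([[total]], dtype=np.int64)
    blocks = []
    for v in range(total, -1, -1):
        rest = _compositions(total - v, parts - 1)
        first = np.full((rest.shape[0], 1), v, dtype=np.int64)
        blocks.append(np.hstack([first, rest]))
    return np.vstack(blocks)


def n_allocations(total: int, parts: int) -> int:
    return math.comb(total + parts - 1, parts - 1)


def _d_min_exact(A: int, q: np.ndarray) -> float:
    X = _compositions(A, len(q))
    P = X / A
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(X > 0, P * (np.log(P) - np.log(q)[None, :]), 0.0)
    return float(terms.sum(axis=1).min())


def _d_min_largest_remainder(A: int, q: np.ndarray) -> float:
    """Largest-remainder integer allocation of A proportional to q."""
    target = A * q
    x = np.floor(target).astype(np.int64)
    deficit = A - int(x.sum())
    if deficit > 0:
        order = np.argsort(-(target - x), kind="stable")
        x[order[:deficit]] += 1
    return _kl_counts(x, A, q)


def species_d(M: BipartiteMatrix, tick: str, method: str = "auto",
              bounds: tuple[float, float] | None = None) -> DPrimeResult:
    """Standardized Kullback-Leibler host-use divergence d' for one tick species.

    Availability q_j = A_j / m is taken from the full matrix (including the
    focal row's own contribution).  ``bounds`` allows reusing (d_min, d_max)
    across fixed-margin null replicates.
    """
    i = M.row_index(tick)
    row = M.counts[i].astype(np.float64)
    A = int(row.sum())
    m = M.m
    q = M.col_totals / m
    d = _kl_counts(row, A, q)
    if bounds is not None:
        d_min, d_max = bounds
    else:
        d_max = math.log(m / A)
        if method == "auto":
            method = "exact" if n_allocations(A, q.size) <= EXACT_MAX_ALLOCATIONS \
                else "heuristic"
        if method == "exact":
            d_min = _d_min_exact(A, q)
        elif method == "heuristic":
            # the observed row is itself a valid allocation, so d_min <= d
            d_min = min(_d_min_largest_remainder(A, q), d)
        else:
            raise ValueError(f"unknown method {method!r}")
    span = d_max - d_min
    if span <= 1e-12:
        return DPrimeResult(tick, d, d_min, d_max, 0.0, degenerate=True)
    prime = (d - d_min) / span
    return DPrimeResult(tick, d, d_min, d_max, float(min(1.0, max(0.0, prime))))


def species_d_all(M: BipartiteMatrix, method: str = "auto") -> list[DPrimeResult]:
    """d' for every tick row of the matrix."""
    return [species_d(M, t, method=method) for t in M.row_names]


def d_bounds(M: BipartiteMatrix, tick: str, method: str = "auto") -> tuple[float, float]:
    """(d_min, d_max) for a row, reusable across fixed-margin null replicates."""
    i = M.row_index(tick)
    A = int(M.counts[i].sum())
    q = M.col_totals / M.m
    d_max = math.log(M.m / A)
    if method == "auto":
        method = "exact" if n_allocations(A, q.size) <= EXACT_MAX_ALLOCATIONS \
            else "heuristic"
    if method == "exact":
        d_min = _d_min_exact(A, q)
    else:
        d_min = _d_min_largest_remainder(A, q)
    return d_min, d_max
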