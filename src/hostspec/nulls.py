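"""Null models for weighted bipartite matrices and empirical significance.

Two randomization schemes are provided:

* ``patefield`` (null model I): redistributes all interaction events while
  keeping row and column totals exactly fixed — the permutation
  (multivariate hypergeometric) distribution of contingency tables.
  Sampled through scipy's fixed-margin table sampler using the token-pairing
  ("boyett") scheme: pair the m row tokens with m shuffled column tokens and
  tabulate.
* ``vaznull`` (null model II): redistributes events while keeping the number
  of realized links (connectance) and the grand total fixed, and forcing
  every tick and host to retain at least one interaction.  Cells are filled
  sequentially with probability proportional to the product of the observed
  marginal frequencies.

Observed index values are compared against replicate ensembles by the
empirical proportion of null values at least as extreme as the observation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import random_table

from .records import BipartiteMatrix
from .structural import d_bounds, h2_extrema, h2_prime, species_d

DEFAULT_REPLICATES = 1000

NULL_MODELS = ("patefield", "vaznull")
METRICS = ("H2_prime", "d_prime")


def patefield_sample(row_totals: Sequence[int], col_totals: Sequence[int],
                     rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Sample table(s) uniformly-at-random over event pairings with fixed margins.

    Returns one (R x C) table, or (size x R x C) when ``size`` is given.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    if int(r.sum()) != int(c.sum()):
        raise ValueError("inconsistent margins: row and column sums differ")
    if int(r.sum()) == 0:
        raise ValueError("margins sum to zero")
    dist = random_table(r, c)
    out = dist.rvs(size=size if size is not None else 1,
                   method="boyett", random_state=rng)
    out = np.asarray(out, dtype=np.int64)
    return out if size is not None else out[0]


def patefield_matrix(M: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    """One fixed-margins replicate of M (row/column names preserved)."""
    a = patefield_sample(M.row_totals, M.col_totals, rng)
    return BipartiteMatrix(a, M.row_names, M.col_names)


def vaznull_sample(M: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    """One connectance-preserving replicate of M.

    Exactly ``M.n_links`` cells are non-zero and the grand total is ``M.m``;
    every row and column keeps at least one interaction.  Link positions are
    drawn sequentially with probability proportional to (A_i/m)(A_j/m) among
    cells that leave enough remaining links to cover all rows and columns;
    the remaining events are then distributed multinomially over the chosen
    cells with the same probabilities.
    """
    R, C = M.shape
    L = M.n_links
    m = M.m
    if L < max(R, C):
        raise ValueError(
            f"infeasible: {L} links cannot cover {R} rows and {C} columns"
        )
    P = np.outer(M.row_totals, M.col_totals).astype(np.float64)
    filled = np.zeros((R, C), dtype=bool)
    row_cov = np.zeros(R, dtype=bool)
    col_cov = np.zeros(C, dtype=bool)
    for step in range(L):
        rem = L - step
        nur = int((~row_cov).sum())
        nuc = int((~col_cov).sum())
        # feasibility: after placing a cell, the links left must still be able
        # to cover every so-far-uncovered row and column
        nur_after = nur - (~row_cov).astype(int)[:, None]
        nuc_after = nuc - (~col_cov).astype(int)[None, :]
        allowed = (~filled) & (rem - 1 >= np.maximum(nur_after, nuc_after))
        w = np.where(allowed, P, 0.0).ravel()
        total = w.sum()
        if total <= 0:  # pragma: no cover - excluded by the feasibility check
            raise RuntimeError("no feasible cell available")
        idx = rng.choice(R * C, p=w / total)
        i, j = divmod(int(idx), C)
        filled[i, j] = True
        row_cov[i] = True
        col_cov[j] = True
    probs = P[filled]
    probs = probs / probs.sum()
    a = filled.astype(np.int64)
    if m > L:
        a[filled] += rng.multinomial(m - L, probs)
    return BipartiteMatrix(a, M.row_names, M.col_names)


def empirical_p(observed: float, null_values: Sequence[float], tail: str = "ge",
                corrected: bool = False) -> float:
    """Proportion of null values as or more extreme than the observation.

    tail="ge" counts null values >= observed (larger metric = more
    specialized); tail="le" counts null values <= observed.  With
    ``corrected`` the (k+1)/(N+1) continuity-corrected estimate is returned.
    """
    vals = np.asarray(null_values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("null_values must be non-empty")
    if tail == "ge":
        k = int((vals >= observed).sum())
    elif tail == "le":
        k = int((vals <= observed).sum())
    else:
        raise ValueError(f"tail must be 'ge' or 'le', got {tail!r}")
    if corrected:
        return (k + 1) / (vals.size + 1)
    return k / vals.size


@dataclass(frozen=True)
class NullEnsemble:
    """Replicate metric values under a named null model, with empirical p."""

    model: str
    metric: str
    observed: float
    values: np.ndarray
    p_value: float
    n_replicates: int
    rng_seed: int
    species: str | None = None
    tail: str = "ge"

    def summary(self) -> dict:
        return {
            "model": self.model,
            "metric": self.metric,
            "species": self.species,
            "observed": self.observed,
            "mean_null": float(np.mean(self.values)),
            "sd_null": float(np.std(self.values, ddof=1)) if self.n_replicates > 1 else 0.0,
            "p_value": self.p_value,
            "tail": self.tail,
            "n": self.n_replicates,
            "seed": self.rng_seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("replicate\tvalue\n")
            for i, v in enumerate(self.values):
                fh.write(f"{i}\t{v:.10g}\n")


def _null_matrices(M: BipartiteMatrix, model: str, n: int,
                   rng: np.random.Generator):
    if model == "patefield":
        tables = patefield_sample(M.row_totals, M.col_totals, rng, size=n)
        for t in tables:
            yield BipartiteMatrix(t, M.row_names, M.col_names)
    elif model == "vaznull":
        for _ in range(n):
            yield vaznull_sample(M, rng)
    else:
        raise ValueError(f"unknown null model {model!r}; choose from {NULL_MODELS}")


def null_ensemble(M: BipartiteMatrix, metric: str, model: str,
                  n: int = DEFAULT_REPLICATES, rng_seed: int = None,
                  species: str | None = None,
                  corrected: bool = False) -> NullEnsemble:
    """Replicate a specialization metric under a null model.

    metric is "H2_prime" or "d_prime" (the latter needs ``species``).
    A seed is mandatory for reproducibility.  Specificity indices grow with
    specialization, so significance uses tail="ge".
    """
    if rng_seed is None:
        raise ValueError("rng_seed is required for reproducible null ensembles")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "d_prime" and species is None:
        raise ValueError("metric 'd_prime' requires a species")
    rng = np.random.default_rng(rng_seed)

    if metric == "H2_prime":
        observed = h2_prime(M).H2_prime
        if model == "patefield":
            # margins are invariant under this null: reuse the extrema
            extrema = h2_extrema(M.row_totals, M.col_totals)
            fn: Callable[[BipartiteMatrix], float] = \
                lambda Mr: h2_prime(Mr, extrema=extrema).H2_prime
        else:
            fn = lambda Mr: h2_prime(Mr).H2_prime
    else:
        observed = species_d(M, species).d_prime
        if model == "patefield":
            bounds = d_bounds(M, species)
            fn = lambda Mr: species_d(Mr, species, bounds=bounds).d_prime
        else:
            fn = lambda Mr: species_d(Mr, species).d_prime

    values = np.array([fn(Mr) for Mr in _null_matrices(M, model, n, rng)])
    p = empirical_p(observed, values, tail="ge", corrected=corrected)
    return NullEnsemble(model=model, metric=metric, observed=float(observed),
                        values=values, p_value=p, n_replicates=n,
                        rng_seed=rng_seed, species=species)


def species_null_pvalues(M: BipartiteMatrix, model: str,
                         n: int = DEFAULT_REPLICATES, rng_seed: int = None,
                         corrected: bool = False) -> dict[str, float]:
    """Empirical p-values of d' for every tick row from one shared ensemble."""
    if rng_seed is None:
        raise ValueError("rng_seed is required for reproducible null ensembles")
    rng = np.random.default_rng(rng_seed)
    observed = {t: species_d(M, t).d_prime for t in M.row_names}
    if model == "patefield":
        bounds = {t: d_bounds(M, t) for t in M.row_names}
        nulls = {t: [] for t in M.row_names}
        for Mr in _null_matrices(M, model, n, rng):
            for t in M.row_names:
                nulls[t].append(species_d(Mr, t, bounds=bounds[t]).d_prime)
    else:
        nulls = {t: [] for t in M.row_names}
        for Mr in _null_matrices(M, model, n, rng):
            for t in M.row_names:
                nulls[t].append(species_d(Mr, t).d_prime)
    return {
        t: empirical_p(observed[t], nulls[t], tail="ge", corrected=corrected)
        for t in M.row_names
    }
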