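"""Genus-level host richness: Chao1 estimation and rank correlations.

If tick species specialize on different hosts, species-rich tick genera
should collectively parasitize more host species than species-poor genera.
Observed host richness underestimates true richness under finite sampling,
so the asymptotic host-species richness of each tick genus is estimated
with Chao1 from the genus-pooled host abundance vector:

    classic:        S_chao1 = S_obs + F1^2 / (2 F2)
    bias-corrected: S_chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1))

with F1/F2 the numbers of singleton/doubleton hosts.  Relationships between
generic tick richness and host-use metrics are tested with Spearman's rho;
for small samples the two-sided p-value is exact, from full enumeration of
rank permutations.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import HostTaxonomy, weighted_mpd
from .records import BipartiteMatrix
from .structural import species_d

#: Largest n for which the exact permutation null of Spearman's rho is used.
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class Chao1Result:
    s_obs: int
    F1: int
    F2: int
    estimate: float
    corrected: bool
    fallback: bool = False


def chao1_result(abundances: Sequence[int], corrected: bool = True) -> Chao1Result:
    """Chao1 asymptotic species richness from an abundance vector.

    The bias-corrected form is always defined; the classic form falls back
    to the corrected one when there are no doubletons (flagged).
    """
    ab = np.asarray(abundances)
    if ab.size == 0 or (ab < 0).any():
        raise ValueError("abundances must be non-negative with at least one entry")
    if not np.issubdtype(ab.dtype, np.integer):
        if not np.allclose(ab, np.round(ab)):
            raise ValueError("abundances must be integers")
        ab = np.round(ab).astype(np.int64)
    pos = ab[ab > 0]
    if pos.size == 0:
        raise ValueError("at least one abundance must be positive")
    s_obs = int(pos.size)
    F1 = int((pos == 1).sum())
    F2 = int((pos == 2).sum())
    fallback = False
    if corrected:
        est = s_obs + F1 * (F1 - 1) / (2 * (F2 + 1))
    elif F2 == 0:
        fallback = True
        warnings.warn("no doubletons: classic Chao1 undefined, "
                      "falling back to the bias-corrected form", stacklevel=2)
        est = s_obs + F1 * (F1 - 1) / 2.0
    else:
        est = s_obs + F1 ** 2 / (2 * F2)
    return Chao1Result(s_obs, F1, F2, float(est), corrected, fallback)


def chao1(abundances: Sequence[int], corrected: bool = True) -> float:
    """Chao1 point estimate (see :func:`chao1_result`)."""
    return chao1_result(abundances, corrected=corrected).estimate


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with an exact permutation p for small n.

    Ties get average ranks.  For n <= 9 the two-sided p-value is the exact
    proportion of rank permutations with |rho| at least as large as
    observed; larger samples use the t approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho is undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt(float((cx ** 2).sum() * (cy ** 2).sum()))
    rho = float((cx * cy).sum() / denom)
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(itertools.permutations(cy)))
        rhos = perms @ cx / denom
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
        return CorrelationResult(rho, p, n, "exact_permutation")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho, float(res.pvalue), n, "t_approximation")


def genus_aggregate(M: BipartiteMatrix,
                    tick_to_genus: Mapping[str, str]) -> BipartiteMatrix:
    """Sum tick rows within genus; columns are unchanged."""
    unmapped = [t for t in M.row_names if t not in tick_to_genus]
    if unmapped:
        raise KeyError(f"tick species without a genus mapping: {unmapped}")
    genera = sorted({tick_to_genus[t] for t in M.row_names})
    gi = {g: i for i, g in enumerate(genera)}
    a = np.zeros((len(genera), len(M.col_names)), dtype=np.int64)
    for i, t in enumerate(M.row_names):
        a[gi[tick_to_genus[t]]] += M.counts[i]
    return BipartiteMatrix(a, tuple(genera), M.col_names)


def genus_specificity(M: BipartiteMatrix, tick_to_genus: Mapping[str, str],
                      taxonomy: HostTaxonomy,
                      mode: str = "pooled") -> pd.DataFrame:
    """Genus-level d' and weighted MPD.

    mode="pooled" (default) computes both indices on the genus-pooled row of
    the aggregated matrix; mode="averaged" instead takes the
    abundance-weighted mean of the member species' values.
    """
    if mode not in ("pooled", "averaged"):
        raise ValueError(f"mode must be 'pooled' or 'averaged', got {mode!r}")
    D = taxonomy.distance_matrix(M.col_names)
    G = genus_aggregate(M, tick_to_genus)
    rows = {}
    if mode == "pooled":
        for g in G.row_names:
            rows[g] = {
                "d_prime": species_d(G, g).d_prime,
                "mpd": weighted_mpd(G.row(g), D),
            }
    else:
        for g in G.row_names:
            members = [t for t in M.row_names if tick_to_genus[t] == g]
            weights = np.array([M.row(t).sum() for t in members], dtype=np.float64)
            dvals = np.array([species_d(M, t).d_prime for t in members])
            mvals = np.array([weighted_mpd(M.row(t), D) for t in members])
            rows[g] = {
                "d_prime": float(np.average(dvals, weights=weights)),
                "mpd": float(np.average(mvals, weights=weights)),
            }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("tick_genus")


def genus_richness_table(M: BipartiteMatrix, tick_to_genus: Mapping[str, str],
                         taxonomy: HostTaxonomy | None = None,
                         corrected: bool = True,
                         mode: str = "pooled") -> pd.DataFrame:
    """Per-genus richness and specificity table.

    Columns: number of member tick species, observed host richness,
    singleton/doubleton counts, Chao1 estimate, and (when a taxonomy is
    given) genus-level d' and weighted MPD.
    """
    G = genus_aggregate(M, tick_to_genus)
    spec = (genus_specificity(M, tick_to_genus, taxonomy, mode=mode)
            if taxonomy is not None else None)
    rows = {}
    for g in G.row_names:
        members = [t for t in M.row_names if tick_to_genus[t] == g]
        res = chao1_result(G.row(g), corrected=corrected)
        row = {
            "n_tick_species": len(members),
            "s_obs": res.s_obs,
            "F1": res.F1,
            "F2": res.F2,
            "chao1": res.estimate,
        }
        if spec is not None:
            row["d_prime"] = spec.loc[g, "d_prime"]
            row["mpd"] = spec.loc[g, "mpd"]
        rows[g] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("tick_genus")


def richness_correlations(table: pd.DataFrame) -> dict[str, CorrelationResult]:
    """Spearman correlations of generic tick richness with host-use metrics."""
    out = {"richness_vs_chao1": spearman(table["n_tick_species"], table["chao1"])}
    if "d_prime" in table.columns:
        out["richness_vs_d_prime"] = spearman(table["n_tick_species"],
                                              table["d_prime"])
    if "mpd" in table.columns:
        out["richness_vs_mpd"] = spearman(table["n_tick_species"], table["mpd"])
    return out
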