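"""Cross-scale rarefaction of weighted interaction matrices.

Nested spatial subsetting makes the per-scale matrices additive: the larger
the scale, the more interaction events.  For a fair comparison of
specialization across scales, the larger matrices are rarefied down to the
event total of the smallest one by resampling interaction events with
probability proportional to link strength (cell probability p_ij = a_ij/m),
and the specialization indices are recomputed on every replicate.

Resampling is multinomial (with replacement) by default, which matches the
stated per-link probabilities exactly; a without-replacement (multivariate
hypergeometric) mode is available.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .records import BipartiteMatrix
from .structural import h2_prime, species_d_all

DEFAULT_REPLICATES = 1000


def rarefy_matrix(M: BipartiteMatrix, target_m: int, rng: np.random.Generator,
                  with_replacement: bool = True) -> BipartiteMatrix:
    """Resample ``target_m`` interaction events from the matrix.

    Cells that are zero in the source stay zero; rows/columns receiving no
    events are dropped from the replicate.
    """
    if not (0 < target_m <= M.m):
        raise ValueError(f"target_m must be in (0, {M.m}], got {target_m}")
    flat = M.counts.ravel()
    if with_replacement:
        drawn = rng.multinomial(target_m, flat / flat.sum())
    else:
        drawn = rng.multivariate_hypergeometric(flat, target_m)
    a = drawn.reshape(M.shape)
    rk = a.sum(axis=1) > 0
    ck = a.sum(axis=0) > 0
    return BipartiteMatrix(
        a[np.ix_(rk, ck)],
        tuple(n for n, k in zip(M.row_names, rk) if k),
        tuple(n for n, k in zip(M.col_names, ck) if k),
    )


@dataclass(frozen=True)
class RarefactionResult:
    """Per-scale rarefaction summary.

    ``h2_values`` holds the replicate H2' values (a single observed value for
    the unrarefied smallest scale).  ``d_summary`` is a per-species frame
    with the replicate mean, 2.5/97.5 percentiles and the fraction of
    replicates in which the species survived resampling.
    """

    scale: str
    target_m: int
    n_replicates: int
    h2_values: np.ndarray
    d_summary: pd.DataFrame
    rarefied: bool
    rng_seed: int

    @property
    def h2_mean(self) -> float:
        return float(np.mean(self.h2_values))

    @property
    def h2_interval(self) -> tuple[float, float]:
        return (float(np.percentile(self.h2_values, 2.5)),
                float(np.percentile(self.h2_values, 97.5)))

    def to_tsv(self, path) -> None:
        self.d_summary.to_csv(path, sep="\t")


def _d_summary_point(M: BipartiteMatrix) -> pd.DataFrame:
    rows = {r.tick_species: {"mean": r.d_prime, "q2.5": r.d_prime,
                             "q97.5": r.d_prime, "presence": 1.0}
            for r in species_d_all(M)}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("tick_species")


def cross_scale_compare(matrices: Mapping[str, BipartiteMatrix],
                        n: int = DEFAULT_REPLICATES, rng_seed: int = None,
                        with_replacement: bool = True) -> dict[str, RarefactionResult]:
    """Rarefy every larger scale to the event total of the smallest scale.

    The smallest scale (minimal m) is reported unrarefied; each larger scale
    is resampled ``n`` times to that total, with H2' and every d' recomputed
    per replicate.
    """
    if rng_seed is None:
        raise ValueError("rng_seed is required for reproducible rarefaction")
    if len(matrices) < 2:
        raise ValueError("need at least two scales to compare")
    for scale, M in matrices.items():
        if M.m == 0:
            raise ValueError(f"scale {scale!r} has an empty matrix")
    target = min(M.m for M in matrices.values())
    # ties on m resolve toward the nominally innermost scale
    nesting = {"small": 0, "intermediate": 1, "large": 2}
    smallest = min(matrices,
                   key=lambda s: (matrices[s].m, nesting.get(s, len(nesting))))
    seeds = np.random.SeedSequence(rng_seed).spawn(len(matrices))
    out: dict[str, RarefactionResult] = {}
    for (scale, M), ss in zip(matrices.items(), seeds):
        if scale == smallest:
            out[scale] = RarefactionResult(
                scale=scale, target_m=target, n_replicates=1,
                h2_values=np.array([h2_prime(M).H2_prime]),
                d_summary=_d_summary_point(M), rarefied=False,
                rng_seed=rng_seed)
            continue
        rng = np.random.default_rng(int(ss.generate_state(1)[0] % (2 ** 31)))
        h2_vals = np.empty(n)
        d_vals: dict[str, list[float]] = {t: [] for t in M.row_names}
        for r in range(n):
            Mr = rarefy_matrix(M, target, rng, with_replacement=with_replacement)
            h2_vals[r] = h2_prime(Mr).H2_prime
            for res in species_d_all(Mr):
                d_vals[res.tick_species].append(res.d_prime)
        rows = {}
        for t in M.row_names:
            vals = np.asarray(d_vals[t])
            if vals.size:
                rows[t] = {"mean": float(vals.mean()),
                           "q2.5": float(np.percentile(vals, 2.5)),
                           "q97.5": float(np.percentile(vals, 97.5)),
                           "presence": vals.size / n}
            else:
                rows[t] = {"mean": np.nan, "q2.5": np.nan, "q97.5": np.nan,
                           "presence": 0.0}
        out[scale] = RarefactionResult(
            scale=scale, target_m=target, n_replicates=n, h2_values=h2_vals,
            d_summary=pd.DataFrame.from_dict(rows, orient="index")
            .rename_axis("tick_species"),
            rarefied=True, rng_seed=rng_seed)
    return out
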