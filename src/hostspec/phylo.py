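"""Taxonomy-based phylogenetic specificity: weighted MPD and SES_MPD.

Host relatedness is measured on the tree induced by a hierarchical
taxonomic classification (up to 19 ranks above species) with every branch
length set to one: the distance between two host species is the number of
edges on the tip-to-tip path.  For a tick with per-host association counts
w, the abundance-weighted mean pairwise distance is

    MPD = sum_{j<k} w_j w_k d_jk / sum_{j<k} w_j w_k

over hosts with w > 0.  Significance uses a tip-label-shuffle null: host
names are permuted on the tips of the taxonomy (the branch-length
distribution is untouched) and MPD recomputed with the observed weights.

    SES_MPD = (MPD_obs - mean_null) / sd_null

which equals -1 times the Net Relatedness Index (NRI).  Negative SES values
mean the hosts used are more closely related than a random draw from the
available pool, i.e. high phylogenetic specificity; the empirical p-value
is accordingly left-tailed.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nulls import empirical_p
from .records import BipartiteMatrix

MAX_LEVELS = 19


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class HostTaxonomy:
    """Hierarchical classification of host species.

    ``levels`` are rank names ordered from highest to lowest; ``lineages``
    maps each species to its tuple of taxon names along those ranks (highest
    first).  Lineage tuples share prefixes exactly when taxa are shared, so
    the classification induces a tree whose tips are the species.
    """

    levels: tuple[str, ...]
    lineages: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) > MAX_LEVELS:
            raise TaxonomyError(
                f"at most {MAX_LEVELS} ranks above species are supported, "
                f"got {len(self.levels)}"
            )
        lineages = {sp: tuple(lin) for sp, lin in self.lineages.items()}
        parent: dict[tuple[str, ...], tuple[str, ...]] = {}
        for sp, lin in lineages.items():
            if len(lin) > len(self.levels):
                raise TaxonomyError(
                    f"species {sp!r} has a lineage of {len(lin)} ranks but only "
                    f"{len(self.levels)} levels are declared"
                )
            # a taxon name must always appear under the same parent chain,
            # otherwise shared names would not mean shared taxa
            for depth, taxon in enumerate(lin):
                key = (taxon, self.levels[depth] if depth < len(self.levels) else depth)
                prefix = lin[:depth]
                prev = parent.setdefault(key, prefix)
                if prev != prefix:
                    raise TaxonomyError(
                        f"taxon {taxon!r} appears under two different parent "
                        f"chains: {prev} and {prefix}"
                    )
        object.__setattr__(self, "lineages", lineages)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.lineages))

    def _path(self, sp: str) -> tuple[str, ...]:
        try:
            return self.lineages[sp] + (sp,)
        except KeyError:
            raise TaxonomyError(f"species {sp!r} not in taxonomy") from None

    def distance(self, sp1: str, sp2: str) -> int:
        """Edges on the tip-to-tip path with unit branch lengths (0 iff equal)."""
        p1 = self._path(sp1)
        p2 = self._path(sp2)
        if sp1 == sp2:
            return 0
        shared = 0
        for a, b in zip(p1, p2):
            if a != b:
                break
            shared += 1
        return (len(p1) - shared) + (len(p2) - shared)

    def distance_matrix(self, species: Sequence[str]) -> np.ndarray:
        """Symmetric zero-diagonal pairwise distance matrix over ``species``."""
        paths = [self._path(sp) for sp in species]
        n = len(paths)
        D = np.zeros((n, n), dtype=np.float64)
        for j in range(n):
            for k in range(j + 1, n):
                pj, pk = paths[j], paths[k]
                shared = 0
                for a, b in zip(pj, pk):
                    if a != b:
                        break
                    shared += 1
                D[j, k] = D[k, j] = (len(pj) - shared) + (len(pk) - shared)
        return D

    def collapse_unary(self) -> "HostTaxonomy":
        """Drop uninformative ranks: levels at which every node is a unary
        pass-through (exactly one child).

        Removing such a level shortens every tip path by one, so absolute
        distances change but the relative ordering of tip pairs does not.
        Ranks where only some nodes are unary are kept, because collapsing
        them would make tip depths ragged and could reorder distances.
        """
        children: dict[tuple[str, ...], set[str]] = {}
        for sp, lin in self.lineages.items():
            full = lin + (sp,)
            for depth in range(len(full)):
                children.setdefault(full[:depth], set()).add(full[depth])
        depth_max = max((len(lin) for lin in self.lineages.values()), default=0)
        droppable = []
        for d in range(depth_max):
            if not all(len(lin) > d for lin in self.lineages.values()):
                continue
            nodes = {lin[:d + 1] for lin in self.lineages.values()}
            if all(len(children[p]) == 1 for p in nodes):
                droppable.append(d)
        new_lineages = {
            sp: tuple(t for d, t in enumerate(lin) if d not in droppable)
            for sp, lin in self.lineages.items()
        }
        new_depth = max((len(v) for v in new_lineages.values()), default=0)
        levels = tuple(f"level_{i + 1}" for i in range(new_depth))
        return HostTaxonomy(levels, new_lineages)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "HostTaxonomy":
        """Read a taxonomy table: one column per rank plus a ``species`` column."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "species" not in df.columns:
            raise TaxonomyError(f"{path}: missing 'species' column")
        levels = tuple(c for c in df.columns if c != "species")
        lineages = {}
        for _, row in df.iterrows():
            lin = tuple(str(row[c]).strip() for c in levels if str(row[c]).strip())
            lineages[str(row["species"]).strip()] = lin
        return cls(levels, lineages)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for sp in self.species:
            lin = self.lineages[sp]
            row = {lev: (lin[i] if i < len(lin) else "")
                   for i, lev in enumerate(self.levels)}
            row["species"] = sp
            rows.append(row)
        pd.DataFrame(rows, columns=list(self.levels) + ["species"]).to_csv(
            path, sep="\t", index=False)

    def to_newick(self) -> str:
        """Newick string of the induced tree with unit branch lengths."""
        import dendropy

        tree = dendropy.Tree()
        nodes: dict[tuple[str, ...], "dendropy.Node"] = {(): tree.seed_node}
        for sp in self.species:
            full = self.lineages[sp] + (sp,)
            for depth in range(1, len(full) + 1):
                prefix = full[:depth]
                if prefix not in nodes:
                    child = nodes[prefix[:-1]].new_child(edge_length=1.0)
                    child.label = prefix[-1]
                    nodes[prefix] = child
        taxa = dendropy.TaxonNamespace()
        for prefix, node in nodes.items():
            if prefix and node.is_leaf():
                node.taxon = taxa.new_taxon(prefix[-1])
        tree.taxon_namespace = taxa
        return tree.as_string(schema="newick").strip()


@dataclass(frozen=True)
class PhyloSpecResult:
    """Abundance-weighted MPD with its tip-shuffle standardized effect size."""

    tick_species: str
    mpd_obs: float
    null_mean: float
    null_sd: float
    ses_mpd: float
    p_value: float
    n_hosts: int
    degenerate: bool = False


def weighted_mpd(weights: Sequence[float], D: np.ndarray) -> float:
    """Abundance-weighted mean pairwise distance over hosts with weight > 0.

    Returns 0 by convention when fewer than two hosts carry positive weight.
    """
    w = np.asarray(weights, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if D.shape != (w.size, w.size):
        raise ValueError("distance matrix shape does not match weights")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if int((w > 0).sum()) < 2:
        return 0.0
    num = float(w @ D @ w)           # = 2 * sum_{j<k} w_j w_k d_jk
    den = float(w.sum() ** 2 - (w ** 2).sum())
    return num / den


def ses_mpd(M: BipartiteMatrix, tick: str, taxonomy: HostTaxonomy,
            n: int = 1000, rng_seed: int = None,
            method: str = "sample",
            D: np.ndarray | None = None) -> PhyloSpecResult:
    """SES of the weighted MPD for one tick against the tip-label-shuffle null.

    The null pool is every host species present in the matrix (the available
    hosts at that scale).  method="exact" enumerates all label permutations
    of the pool instead of sampling ``n`` of them.
    """
    i = M.row_index(tick)
    w = M.counts[i].astype(np.float64)
    pool = M.col_names
    if D is None:
        D = taxonomy.distance_matrix(pool)
    n_hosts = int((w > 0).sum())
    if n_hosts < 2:
        return PhyloSpecResult(tick, 0.0, 0.0, 0.0, 0.0, math.nan,
                               n_hosts, degenerate=True)
    obs = weighted_mpd(w, D)
    if method == "exact":
        perms = itertools.permutations(range(len(pool)))
        nulls = np.array([weighted_mpd(w[list(p)], D) for p in perms])
    elif method == "sample":
        if rng_seed is None:
            raise ValueError("rng_seed is required when sampling the null")
        if n < 2:
            raise ValueError("need at least 2 null replicates")
        rng = np.random.default_rng(rng_seed)
        nulls = np.array([weighted_mpd(w[rng.permutation(len(pool))], D)
                          for _ in range(n)])
    else:
        raise ValueError(f"unknown method {method!r}")
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd <= 1e-12:
        return PhyloSpecResult(tick, obs, mean, sd, 0.0, math.nan,
                               n_hosts, degenerate=True)
    ses = (obs - mean) / sd
    p = empirical_p(obs, nulls, tail="le")
    return PhyloSpecResult(tick, obs, mean, sd, float(ses), p, n_hosts)


def ses_mpd_all(M: BipartiteMatrix, taxonomy: HostTaxonomy, n: int = 1000,
                rng_seed: int = None) -> list[PhyloSpecResult]:
    """SES_MPD for every tick row, with independent per-row null streams."""
    if rng_seed is None:
        raise ValueError("rng_seed is required")
    D = taxonomy.distance_matrix(M.col_names)
    seeds = np.random.SeedSequence(rng_seed).spawn(len(M.row_names))
    out = []
    for tick, ss in zip(M.row_names, seeds):
        seed = int(ss.generate_state(1)[0] % (2 ** 31))
        out.append(ses_mpd(M, tick, taxonomy, n=n, rng_seed=seed, D=D))
    return out


def phylo_table(results: Sequence[PhyloSpecResult]) -> pd.DataFrame:
    """Tabular per-species summary (one row per tick)."""
    return pd.DataFrame(
        [
            {
                "tick_species": r.tick_species,
                "n_hosts": r.n_hosts,
                "mpd_obs": r.mpd_obs,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "ses_mpd": r.ses_mpd,
                "p_value": r.p_value,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
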