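"""Synthetic tick-host communities with known specialization.

The generator emulates the statistical structure of a field dataset of
adult tick-host association records: a ticks x hosts count matrix with
heterogeneous marginal totals, hosts embedded in a multi-level taxonomy,
and nested spatial scales.  Each tick species i has a focal host f_i and a
concentration lambda_i >= 0; it chooses hosts with probability

    P(host j | tick i)  proportional to  availability_j * exp(-lambda_i * d(f_i, j))

where d is the unit-branch taxonomy distance.  lambda = 0 reduces exactly
to proportional host use (the null models' generalist assumption); large
lambda collapses all mass onto the focal host (exclusive use).  The truth
(focal hosts, lambdas, availability, taxonomy) is retained so parameter-
recovery tests can check that the specificity indices respond to it.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .phylo import HostTaxonomy
from .records import InteractionRecord, RecordSet, merge_duplicates

_DISTRIBUTIONS = ("lognormal", "gamma", "poisson", "fixed")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults describe a moderately specialized Neotropical-like community:
    20 tick species in 8 genera on 30 host species, a 4-level host taxonomy
    with 3-way branching, lognormal host availability and per-tick record
    totals in the tens-to-hundreds, and nested scale retention of 80 %
    (large -> intermediate) and 50 % (intermediate -> small) of events.
    """

    n_ticks: int = 20
    n_hosts: int = 30
    taxonomy_depth: int = 4
    branching: int = 3
    host_availability: tuple[str, dict] = ("lognormal", {"mu": 0.0, "sigma": 1.0})
    records_per_tick: tuple[str, dict] = ("lognormal", {"mu": 3.0, "sigma": 1.0})
    lam: float | Sequence[float] = 2.0
    n_genera: int = 8
    p_intermediate: float = 0.8
    p_small: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hosts < 2:
            raise ValueError("n_hosts must be >= 2")
        if self.taxonomy_depth < 1:
            raise ValueError("taxonomy_depth must be >= 1")
        if self.taxonomy_depth > 19:
            raise ValueError("taxonomy_depth must be <= 19")
        if self.n_ticks < 1 or self.n_genera < 1:
            raise ValueError("n_ticks and n_genera must be >= 1")
        lam = np.atleast_1d(np.asarray(self.lam, dtype=np.float64))
        if (lam < 0).any():
            raise ValueError("lambda must be >= 0")
        if lam.size not in (1, self.n_ticks):
            raise ValueError("lam must be a scalar or have one value per tick")
        for name, (dist, _) in (("host_availability", self.host_availability),
                                ("records_per_tick", self.records_per_tick)):
            if dist not in _DISTRIBUTIONS:
                raise ValueError(f"{name}: unknown distribution {dist!r}")
        if not (0 <= self.p_small <= 1 and 0 <= self.p_intermediate <= 1):
            raise ValueError("scale retention probabilities must be in [0, 1]")

    def lambdas(self) -> np.ndarray:
        lam = np.atleast_1d(np.asarray(self.lam, dtype=np.float64))
        return np.full(self.n_ticks, lam[0]) if lam.size == 1 else lam.copy()


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters retained for parameter-recovery tests."""

    focal_host: Mapping[str, str]
    lam: Mapping[str, float]
    taxonomy: HostTaxonomy
    availability: Mapping[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "focal_host": dict(self.focal_host),
            "lambda": {k: float(v) for k, v in self.lam.items()},
            "availability": {k: float(v) for k, v in self.availability.items()},
            "taxonomy_levels": list(self.taxonomy.levels),
            "lineages": {sp: list(lin) for sp, lin in self.taxonomy.lineages.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _draw(dist: tuple[str, dict], rng: np.random.Generator, size: int) -> np.ndarray:
    name, params = dist
    if name == "lognormal":
        return rng.lognormal(mean=params.get("mu", 0.0),
                             sigma=params.get("sigma", 1.0), size=size)
    if name == "gamma":
        return rng.gamma(shape=params.get("shape", 2.0),
                         scale=params.get("scale", 1.0), size=size)
    if name == "poisson":
        return rng.poisson(lam=params.get("lam", 10.0), size=size).astype(float)
    if name == "fixed":
        return np.full(size, float(params.get("value", 1.0)))
    raise ValueError(f"unknown distribution {name!r}")


def generate_taxonomy(cfg: SyntheticConfig, rng: np.random.Generator) -> HostTaxonomy:
    """Balanced host taxonomy with ``taxonomy_depth`` ranks above species.

    Hosts are grouped ``branching`` per lowest-level taxon, those taxa
    ``branching`` per next level up, and so on; the host-to-leaf assignment
    is shuffled so taxonomic structure is random with respect to host names.
    """
    n, b, D = cfg.n_hosts, cfg.branching, cfg.taxonomy_depth
    if n > b ** (D + 1):
        raise ValueError(
            f"branching {b} with depth {D} holds at most {b ** (D + 1)} hosts, "
            f"got {n}"
        )
    hosts = [f"host_{i:03d}" for i in range(n)]
    slots = rng.permutation(n)
    levels = tuple(f"L{k}" for k in range(1, D + 1))
    lineages: dict[str, tuple[str, ...]] = {}
    for host, slot in zip(hosts, slots):
        idx = int(slot)
        chain = []
        node = idx // b  # parent taxon index at the lowest level
        for level in range(D, 0, -1):
            chain.append(f"L{level}_{node:03d}")
            node //= b
        lineages[host] = tuple(reversed(chain))
    return HostTaxonomy(levels, lineages)


def _genus_sizes(n_ticks: int, n_genera: int) -> list[int]:
    """Skewed genus sizes (largest-remainder split of weights 1/(g+1))."""
    n_genera = min(n_genera, n_ticks)
    w = np.array([1.0 / (g + 1) for g in range(n_genera)])
    target = n_ticks * w / w.sum()
    sizes = np.floor(target).astype(int)
    sizes = np.maximum(sizes, 1)
    while sizes.sum() > n_ticks:
        sizes[int(np.argmax(sizes))] -= 1
    rem = n_ticks - int(sizes.sum())
    if rem > 0:
        order = np.argsort(-(target - sizes), kind="stable")
        for k in range(rem):
            sizes[order[k % n_genera]] += 1
    return sizes.tolist()


def generate_network(cfg: SyntheticConfig,
                     rng: np.random.Generator) -> tuple[RecordSet, SyntheticTruth]:
    """Generate a record set with nested scale tags and its ground truth."""
    taxonomy = generate_taxonomy(cfg, rng)
    hosts = list(taxonomy.species)
    D = taxonomy.distance_matrix(hosts)
    avail = _draw(cfg.host_availability, rng, cfg.n_hosts)
    if not (avail > 0).any():
        raise ValueError("degenerate host availability: all zero")
    avail = avail / avail.sum()

    sizes = _genus_sizes(cfg.n_ticks, cfg.n_genera)
    tick_names: list[str] = []
    tick_genus: dict[str, str] = {}
    for g, sz in enumerate(sizes):
        genus = f"genus_{g:02d}"
        for s in range(sz):
            name = f"tick_{g:02d}_{s:02d}"
            tick_names.append(name)
            tick_genus[name] = genus

    lambdas = cfg.lambdas()
    totals = np.maximum(1, np.round(_draw(cfg.records_per_tick, rng,
                                          cfg.n_ticks))).astype(int)
    focal_idx = rng.choice(cfg.n_hosts, size=cfg.n_ticks, p=avail)

    records: list[InteractionRecord] = []
    focal: dict[str, str] = {}
    lam_map: dict[str, float] = {}
    for i, tick in enumerate(tick_names):
        f = int(focal_idx[i])
        focal[tick] = hosts[f]
        lam_map[tick] = float(lambdas[i])
        weights = avail * np.exp(-lambdas[i] * D[f])
        probs = weights / weights.sum()
        counts = rng.multinomial(int(totals[i]), probs)
        for j in np.nonzero(counts)[0]:
            n_large = int(counts[j])
            n_int = int(rng.binomial(n_large, cfg.p_intermediate))
            n_small = int(rng.binomial(n_int, cfg.p_small))
            for cnt, tags in (
                (n_large - n_int, {"large"}),
                (n_int - n_small, {"large", "intermediate"}),
                (n_small, {"large", "intermediate", "small"}),
            ):
                if cnt > 0:
                    records.append(InteractionRecord(
                        tick_species=tick, tick_genus=tick_genus[tick],
                        host_species=hosts[j], count=cnt,
                        scale_tags=frozenset(tags), source="synthetic"))
    rs = RecordSet(merge_duplicates(records))
    truth = SyntheticTruth(
        focal_host=focal, lam=lam_map, taxonomy=taxonomy,
        availability={h: float(a) for h, a in zip(hosts, avail)})
    return rs, truth
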