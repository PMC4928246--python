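"""Interaction records, spatial-scale subsetting and bipartite count matrices.

The raw unit of data is one observed association event set: a tick species
found attached to a host species, with a count of attached adults and a set
of nested spatial-scale tags.  Everything downstream (specialization
indices, null models, rarefaction, richness estimation) consumes the
ticks x hosts count matrix derived from a record set.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Nested spatial scales, outermost first.  "small" is contained in
#: "intermediate", which is contained in "large".
SCALES = ("large", "intermediate", "small")

REQUIRED_COLUMNS = ("tick_species", "tick_genus", "host_species", "count", "scale_tags")


class RecordValidationError(ValueError):
    """A record or record table violates an input invariant."""


def _close_scale_tags(tags: Iterable[str]) -> frozenset[str]:
    """Validate scale tags and close them under scale nesting.

    A record observed at the small scale is by construction also part of the
    intermediate and large datasets, so ``small`` implies ``intermediate``
    implies ``large``.
    """
    tags = set(tags)
    unknown = tags - set(SCALES)
    if unknown:
        raise RecordValidationError(
            f"unknown scale tag(s) {sorted(unknown)}; valid scales are {SCALES}"
        )
    if not tags:
        raise RecordValidationError("scale_tags must be non-empty")
    if "small" in tags:
        tags.add("intermediate")
    if "intermediate" in tags:
        tags.add("large")
    return frozenset(tags)


@dataclass(frozen=True)
class InteractionRecord:
    """One tick-host association event set with a count of attached adults."""

    tick_species: str
    tick_genus: str
    host_species: str
    count: int
    scale_tags: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.count, (int, np.integer)) or isinstance(self.count, bool):
            raise RecordValidationError(
                f"count must be an integer, got {self.count!r} "
                f"for ({self.tick_species}, {self.host_species})"
            )
        if self.count < 1:
            raise RecordValidationError(
                f"count must be >= 1, got {self.count} "
                f"for ({self.tick_species}, {self.host_species})"
            )
        object.__setattr__(self, "count", int(self.count))
        object.__setattr__(self, "scale_tags", _close_scale_tags(self.scale_tags))


@dataclass(frozen=True)
class RecordSet:
    """An ordered collection of interaction records with a consistent tick taxonomy."""

    records: tuple[InteractionRecord, ...]
    tick_to_genus: Mapping[str, str] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        mapping: dict[str, str] = {}
        for r in self.records:
            prev = mapping.setdefault(r.tick_species, r.tick_genus)
            if prev != r.tick_genus:
                raise RecordValidationError(
                    f"tick species {r.tick_species!r} mapped to two genera: "
                    f"{prev!r} and {r.tick_genus!r}"
                )
        object.__setattr__(self, "tick_to_genus", mapping)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.records)

    def host_species(self) -> tuple[str, ...]:
        return tuple(sorted({r.host_species for r in self.records}))

    def tick_species(self) -> tuple[str, ...]:
        return tuple(sorted({r.tick_species for r in self.records}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tick_species": r.tick_species,
                "tick_genus": r.tick_genus,
                "host_species": r.host_species,
                "count": r.count,
                "scale_tags": ";".join(s for s in SCALES if s in r.scale_tags),
                "source": r.source,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["source"])


def merge_duplicates(records: Iterable[InteractionRecord]) -> tuple[InteractionRecord, ...]:
    """Sum counts of records sharing (tick, host, scale-tag set).

    Field-collected and literature-sourced observations of the same
    association legitimately co-occur; their counts add.
    """
    merged: dict[tuple, InteractionRecord] = {}
    order: list[tuple] = []
    for r in records:
        key = (r.tick_species, r.host_species, r.scale_tags)
        if key in merged:
            old = merged[key]
            source = old.source if old.source == r.source else ";".join(
                s for s in (old.source, r.source) if s
            )
            merged[key] = InteractionRecord(
                r.tick_species, r.tick_genus, r.host_species,
                old.count + r.count, r.scale_tags, source,
            )
        else:
            merged[key] = r
            order.append(key)
    return tuple(merged[k] for k in order)


def read_records(path: str | Path, format: str = "tsv") -> RecordSet:
    """Read a record table (TSV or CSV, UTF-8, header required) into a RecordSet.

    Duplicate (tick, host, scale) rows are summed.  Counts must be positive
    base-10 integers; scale tags are semicolon-separated tokens.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(
            f"{path}: missing required column(s) {missing}; header must contain "
            f"{list(REQUIRED_COLUMNS)}"
        )
    records: list[InteractionRecord] = []
    for idx, row in df.iterrows():
        raw = str(row["count"]).strip()
        try:
            count = int(raw)
        except ValueError:
            raise RecordValidationError(
                f"{path}: row {idx + 2}: count {raw!r} is not an integer"
            ) from None
        if count < 1:
            raise RecordValidationError(
                f"{path}: row {idx + 2}: count must be >= 1, got {count}"
            )
        tags = [t.strip() for t in str(row["scale_tags"]).split(";") if t.strip()]
        try:
            rec = InteractionRecord(
                tick_species=str(row["tick_species"]).strip(),
                tick_genus=str(row["tick_genus"]).strip(),
                host_species=str(row["host_species"]).strip(),
                count=count,
                scale_tags=frozenset(tags),
                source=str(row.get("source", "")).strip(),
            )
        except RecordValidationError as e:
            raise RecordValidationError(f"{path}: row {idx + 2}: {e}") from None
        records.append(rec)
    return RecordSet(merge_duplicates(records))


def write_records(rs: RecordSet, path: str | Path) -> None:
    """Write a RecordSet as the TSV format consumed by :func:`read_records`."""
    rs.to_frame().to_csv(path, sep="\t", index=False)


def subset_scale(rs: RecordSet, scale: str) -> RecordSet:
    """Records belonging to the given spatial scale (nested subsetting)."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; valid scales are {SCALES}")
    return RecordSet(tuple(r for r in rs if scale in r.scale_tags))


@dataclass(frozen=True)
class BipartiteMatrix:
    """Ticks x hosts non-negative integer count matrix with cached margins.

    Rows are tick species, columns host species, cell ``a[i, j]`` the number
    of association events.  No all-zero row or column survives construction.
    """

    counts: np.ndarray
    row_names: tuple[str, ...]
    col_names: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.counts)
        if a.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.allclose(a, np.round(a)):
                raise ValueError("counts must be integers")
            a = np.round(a).astype(np.int64)
        else:
            a = a.astype(np.int64)
        if (a < 0).any():
            raise ValueError("counts must be non-negative")
        if a.shape != (len(self.row_names), len(self.col_names)):
            raise ValueError("counts shape does not match names")
        if a.sum() == 0:
            raise ValueError("matrix has zero total")
        if (a.sum(axis=1) == 0).any() or (a.sum(axis=0) == 0).any():
            raise ValueError("matrix has an all-zero row or column")
        a.setflags(write=False)
        object.__setattr__(self, "counts", a)
        object.__setattr__(self, "row_names", tuple(self.row_names))
        object.__setattr__(self, "col_names", tuple(self.col_names))

    # -- cached-margin accessors ------------------------------------------
    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def m(self) -> int:
        """Grand total number of interaction events."""
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_links(self) -> int:
        """Number of realized (non-zero) tick-host links, i.e. connectance count."""
        return int((self.counts > 0).sum())

    def row_index(self, tick: str) -> int:
        try:
            return self.row_names.index(tick)
        except ValueError:
            raise KeyError(f"tick species {tick!r} not in matrix") from None

    def row(self, tick: str) -> np.ndarray:
        return self.counts[self.row_index(tick)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_names),
                            columns=list(self.col_names))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BipartiteMatrix":
        return cls(df.to_numpy(), tuple(df.index), tuple(df.columns))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def drop_empty(self) -> "BipartiteMatrix":
        """Return a copy without all-zero rows/columns (identity if already clean)."""
        a = self.counts
        rk = a.sum(axis=1) > 0
        ck = a.sum(axis=0) > 0
        return BipartiteMatrix(
            a[np.ix_(rk, ck)],
            tuple(n for n, k in zip(self.row_names, rk) if k),
            tuple(n for n, k in zip(self.col_names, ck) if k),
        )


def build_matrix(rs: RecordSet) -> BipartiteMatrix:
    """Aggregate a RecordSet into a count matrix with lexicographic name order."""
    if len(rs) == 0:
        raise ValueError("cannot build a matrix from an empty RecordSet")
    ticks = rs.tick_species()
    hosts = rs.host_species()
    ti = {t: i for i, t in enumerate(ticks)}
    hi = {h: j for j, h in enumerate(hosts)}
    a = np.zeros((len(ticks), len(hosts)), dtype=np.int64)
    for r in rs:
        a[ti[r.tick_species], hi[r.host_species]] += r.count
    return BipartiteMatrix(a, ticks, hosts)
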