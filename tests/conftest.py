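import numpy as np
import pytest

from hostspec import (
    BipartiteMatrix,
    HostTaxonomy,
    InteractionRecord,
    RecordSet,
    SyntheticConfig,
    generate_network,
)


@pytest.fixture
def diag_matrix():
    """Perfectly specialized 2x2 community."""
    return BipartiteMatrix(np.array([[2, 0], [0, 2]]), ("t1", "t2"), ("h1", "h2"))


@pytest.fixture
def even_matrix():
    """Most generalist 2x2 community (margin-proportional)."""
    return BipartiteMatrix(np.array([[1, 1], [1, 1]]), ("t1", "t2"), ("h1", "h2"))


@pytest.fixture
def small_recordset():
    recs = [
        InteractionRecord("t1", "g1", "h1", 2, frozenset({"small"})),
        InteractionRecord("t1", "g1", "h2", 1, frozenset({"intermediate"})),
        InteractionRecord("t2", "g1", "h1", 3, frozenset({"large"})),
        InteractionRecord("t2", "g1", "h2", 4, frozenset({"small"})),
        InteractionRecord("t3", "g2", "h3", 5, frozenset({"large"})),
    ]
    return RecordSet(tuple(recs))


@pytest.fixture
def four_host_taxonomy():
    """Two genera of two species each: within-genus distance 2, between 4."""
    return HostTaxonomy(
        ("genus",),
        {
            "a1": ("A",),
            "a2": ("A",),
            "b1": ("B",),
            "b2": ("B",),
        },
    )


@pytest.fixture
def synthetic_community():
    """Default study conditions with a lambda grid from 0 to 5, seed 1."""
    cfg = SyntheticConfig(lam=np.linspace(0.0, 5.0, 20), seed=1)
    rs, truth = generate_network(cfg, np.random.default_rng(cfg.seed))
    return rs, truth


def random_matrix(rng, max_rows=4, max_cols=4, max_count=6):
    """A random valid BipartiteMatrix (no empty rows/columns)."""
    while True:
        r = rng.integers(1, max_rows + 1)
        c = rng.integers(1, max_cols + 1)
        a = rng.integers(0, max_count + 1, size=(r, c))
        if a.sum() == 0:
            continue
        a = a[a.sum(axis=1) > 0][:, a[a.sum(axis=1) > 0].sum(axis=0) > 0]
        if a.size == 0 or a.sum() == 0:
            continue
        rows = tuple(f"t{i}" for i in range(a.shape[0]))
        cols = tuple(f"h{j}" for j in range(a.shape[1]))
        return BipartiteMatrix(a, rows, cols)
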