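"""Taxonomy distances, weighted MPD and SES_MPD against enumeration oracles."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hostspec import (
    BipartiteMatrix,
    HostTaxonomy,
    SyntheticConfig,
    generate_taxonomy,
    ses_mpd,
    weighted_mpd,
)
from hostspec.phylo import TaxonomyError


class TestTaxonomyDistance:
    def test_same_species_zero(self, four_host_taxonomy):
        assert four_host_taxonomy.distance("a1", "a1") == 0

    def test_congeners_distance_two(self, four_host_taxonomy):
        assert four_host_taxonomy.distance("a1", "a2") == 2

    def test_cross_genus_distance_four(self, four_host_taxonomy):
        assert four_host_taxonomy.distance("a1", "b2") == 4

    def test_symmetry(self, four_host_taxonomy):
        for s1, s2 in itertools.combinations(four_host_taxonomy.species, 2):
            assert four_host_taxonomy.distance(s1, s2) == \
                four_host_taxonomy.distance(s2, s1)

    def test_unknown_species(self, four_host_taxonomy):
        with pytest.raises(TaxonomyError):
            four_host_taxonomy.distance("a1", "zz")

    def test_deeper_ranks(self):
        tax = HostTaxonomy(
            ("order", "family", "genus"),
            {
                "s1": ("O1", "F1", "G1"),
                "s2": ("O1", "F1", "G2"),
                "s3": ("O1", "F2", "G3"),
                "s4": ("O2", "F3", "G4"),
            },
        )
        assert tax.distance("s1", "s2") == 4   # same family, different genus
        assert tax.distance("s1", "s3") == 6   # same order, different family
        assert tax.distance("s1", "s4") == 8   # different order

    def test_inconsistent_parentage_rejected(self):
        with pytest.raises(TaxonomyError, match="parent"):
            HostTaxonomy(("family", "genus"),
                         {"s1": ("F1", "G1"), "s2": ("F2", "G1")})

    def test_tsv_roundtrip(self, tmp_path, four_host_taxonomy):
        p = tmp_path / "tax.tsv"
        four_host_taxonomy.to_tsv(p)
        back = HostTaxonomy.from_tsv(p)
        assert back.lineages == dict(four_host_taxonomy.lineages)

    def test_newick_export_parses(self, four_host_taxonomy):
        import dendropy

        nwk = four_host_taxonomy.to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tips = {t.taxon.label for t in tree.leaf_node_iter()}
        assert tips == set(four_host_taxonomy.species)

    def test_collapse_preserves_distance_order(self):
        cfg = SyntheticConfig(n_hosts=20, taxonomy_depth=6, branching=2)
        tax = generate_taxonomy(cfg, np.random.default_rng(0))
        collapsed = tax.collapse_unary()
        sp = tax.species
        D1 = tax.distance_matrix(sp)
        D2 = collapsed.distance_matrix(sp)
        iu = np.triu_indices(len(sp), 1)
        rho = stats.spearmanr(D1[iu], D2[iu]).statistic
        assert rho == pytest.approx(1.0)
        # 20 hosts under 2-way branching leave the top ranks unary
        assert max(len(v) for v in collapsed.lineages.values()) < 6


class TestWeightedMPD:
    def test_worked_example(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        assert weighted_mpd([2, 1, 1], D) == pytest.approx(3.2)

    def test_two_hosts_weights_cancel(self):
        D = np.array([[0, 6], [6, 0]], float)
        assert weighted_mpd([5, 1], D) == pytest.approx(6.0)
        assert weighted_mpd([1, 9], D) == pytest.approx(6.0)

    def test_single_host_degenerate_zero(self):
        D = np.array([[0, 2], [2, 0]], float)
        assert weighted_mpd([3, 0], D) == 0.0

    def test_negative_weight_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError):
            weighted_mpd([1, -1], D)

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(0)
        D = rng.integers(1, 9, size=(5, 5)).astype(float)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        w = rng.integers(0, 5, size=5).astype(float)
        w[0] = 2
        w[1] = 1
        assert weighted_mpd(w, D) == pytest.approx(weighted_mpd(7 * w, D))


class TestSesMpd:
    def _matrix(self, counts, hosts):
        counts = np.atleast_2d(counts)
        return BipartiteMatrix(counts, tuple(f"t{i}" for i in range(len(counts))),
                               tuple(hosts))

    def test_star_taxonomy_sd_zero_flagged(self):
        tax = HostTaxonomy(("g",), {f"h{i}": ("G",) for i in range(4)})
        M = self._matrix([[1, 1, 1, 1]], [f"h{i}" for i in range(4)])
        res = ses_mpd(M, "t0", tax, method="exact")
        assert res.degenerate
        assert res.ses_mpd == 0.0

    def test_congeneric_hosts_negative_ses(self, four_host_taxonomy):
        M = self._matrix([[3, 2, 0, 1], [1, 1, 3, 4]], ["a1", "a2", "b1", "b2"])
        res = ses_mpd(M, "t0", four_host_taxonomy, method="exact")
        assert res.ses_mpd < 0  # hosts mostly congeneric vs distant pool

    def test_exact_enumeration_matches_manual(self, four_host_taxonomy):
        M = self._matrix([[2, 1, 1, 0], [1, 1, 1, 1]], ["a1", "a2", "b1", "b2"])
        D = four_host_taxonomy.distance_matrix(M.col_names)
        w = M.row("t0").astype(float)
        nulls = [weighted_mpd(w[list(p)], D)
                 for p in itertools.permutations(range(4))]
        obs = weighted_mpd(w, D)
        exp_ses = (obs - np.mean(nulls)) / np.std(nulls, ddof=1)
        res = ses_mpd(M, "t0", four_host_taxonomy, method="exact")
        assert res.ses_mpd == pytest.approx(exp_ses)
        assert res.p_value == pytest.approx(
            np.mean(np.array(nulls) <= obs))

    def test_equals_minus_nri(self, four_host_taxonomy):
        # NRI = (mean_null - obs) / sd_null, so SES_MPD must equal -NRI
        M = self._matrix([[2, 1, 1, 0], [1, 1, 1, 1]], ["a1", "a2", "b1", "b2"])
        res = ses_mpd(M, "t0", four_host_taxonomy, method="exact")
        nri = (res.null_mean - res.mpd_obs) / res.null_sd
        assert res.ses_mpd == pytest.approx(-nri)

    def test_single_host_row_degenerate(self, four_host_taxonomy):
        M = self._matrix([[4, 0, 0, 0], [1, 1, 1, 1]], ["a1", "a2", "b1", "b2"])
        res = ses_mpd(M, "t0", four_host_taxonomy, n=100, rng_seed=0)
        assert res.degenerate
        assert res.ses_mpd == 0.0
        assert math.isnan(res.p_value)

    def test_sampled_reproducible(self, four_host_taxonomy):
        M = self._matrix([[2, 1, 1, 0], [1, 1, 1, 1]], ["a1", "a2", "b1", "b2"])
        a = ses_mpd(M, "t0", four_host_taxonomy, n=200, rng_seed=9)
        b = ses_mpd(M, "t0", four_host_taxonomy, n=200, rng_seed=9)
        assert a.ses_mpd == b.ses_mpd


def test_ses_approximately_standard_normal_under_null():
    """When the observed weights are themselves a random labeling, SES across
    datasets is centred near 0 with spread near 1."""
    cfg = SyntheticConfig(n_hosts=8, taxonomy_depth=3, branching=2)
    tax = generate_taxonomy(cfg, np.random.default_rng(1))
    hosts = tax.species
    D = tax.distance_matrix(hosts)
    rng = np.random.default_rng(2)
    ses_vals = []
    for i in range(300):
        w = np.zeros(8)
        chosen = rng.choice(8, size=4, replace=False)
        w[chosen] = rng.integers(1, 6, size=4)
        M = BipartiteMatrix(np.vstack([w, np.ones(8)]).astype(int),
                            ("t0", "t1"), hosts)
        res = ses_mpd(M, "t0", tax, n=200, rng_seed=3000 + i)
        if not res.degenerate:
            ses_vals.append(res.ses_mpd)
    ses_vals = np.array(ses_vals)
    assert abs(ses_vals.mean()) < 0.2
    assert 0.7 < ses_vals.std() < 1.4
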