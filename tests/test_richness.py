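"""Chao1 estimation, exact Spearman correlation, and genus aggregation."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hostspec import (
    BipartiteMatrix,
    HostTaxonomy,
    chao1,
    chao1_result,
    genus_aggregate,
    genus_richness_table,
    genus_specificity,
    richness_correlations,
    spearman,
    species_d,
    weighted_mpd,
)


class TestChao1:
    def test_worked_example(self):
        assert chao1([5, 3, 2, 1, 1], corrected=False) == pytest.approx(7.0)
        assert chao1([5, 3, 2, 1, 1], corrected=True) == pytest.approx(5.5)

    def test_no_singletons_equals_observed(self):
        assert chao1([3, 2, 2], corrected=False) == 3.0
        assert chao1([3, 2, 2], corrected=True) == 3.0

    def test_no_doubletons_corrected(self):
        assert chao1([1, 1, 3]) == pytest.approx(4.0)

    def test_classic_falls_back_without_doubletons(self):
        with pytest.warns(UserWarning, match="falling back"):
            res = chao1_result([1, 1, 3], corrected=False)
        assert res.fallback
        assert res.estimate == pytest.approx(4.0)

    def test_never_below_observed(self):
        import warnings

        rng = np.random.default_rng(0)
        for _ in range(50):
            ab = rng.integers(0, 6, size=10)
            if (ab > 0).sum() == 0:
                continue
            for corrected in (True, False):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = chao1_result(ab, corrected=corrected)
                assert res.estimate >= res.s_obs - 1e-12
                if res.F1 == 0:
                    assert res.estimate == res.s_obs

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chao1([0, 0])


class TestSpearman:
    def test_identity_exact_p(self):
        res = spearman([1, 2, 3], [1, 2, 3])
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "exact_permutation"

    def test_antimonotone(self):
        res = spearman([1, 2, 3, 4], [10, 7, 5, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_rank_formula_vs_enumeration(self):
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)
        # brute-force p over all 24 permutations
        rx = np.array([1, 2, 3, 4], float)
        count = 0
        for p in itertools.permutations([2, 1, 4, 3]):
            r = stats.spearmanr(rx, p).statistic
            if abs(r) >= 0.6 - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / 24)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_bruteforce_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        x = rng.normal(size=n)
        y = rng.integers(0, 4, size=n).astype(float)
        if np.ptp(y) == 0:
            y[0] += 1
        res = spearman(x, y)
        obs = stats.spearmanr(x, y).statistic
        assert res.rho == pytest.approx(obs)
        count = sum(
            abs(stats.spearmanr(x, p).statistic) >= abs(obs) - 1e-12
            for p in itertools.permutations(y)
        )
        assert res.p_value == pytest.approx(count / math.factorial(n))

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        res = spearman(x, y)
        assert res.method == "t_approximation"
        assert res.p_value == pytest.approx(stats.spearmanr(x, y).pvalue)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [5, 5, 5])


class TestGenusAggregate:
    def test_congeneric_rows_summed(self):
        M = BipartiteMatrix(np.array([[2, 0], [0, 2]]), ("t1", "t2"), ("h1", "h2"))
        G = genus_aggregate(M, {"t1": "g", "t2": "g"})
        assert G.counts.tolist() == [[2, 2]]
        assert G.m == M.m

    def test_single_species_genus_unchanged(self):
        M = BipartiteMatrix(np.array([[2, 1], [1, 3]]), ("t1", "t2"), ("h1", "h2"))
        G = genus_aggregate(M, {"t1": "ga", "t2": "gb"})
        assert G.counts.tolist() == M.counts.tolist()

    def test_unmapped_row_rejected(self):
        M = BipartiteMatrix(np.array([[1, 1]]), ("t1",), ("h1", "h2"))
        with pytest.raises(KeyError):
            genus_aggregate(M, {})


class TestGenusSpecificity:
    def _setup(self):
        tax = HostTaxonomy(("genus",), {"h1": ("A",), "h2": ("B",)})
        M = BipartiteMatrix(np.array([[4, 0], [0, 4]]), ("t1", "t2"), ("h1", "h2"))
        t2g = {"t1": "g", "t2": "g"}
        return M, t2g, tax

    def test_single_species_genus_equals_species_values(self):
        tax = HostTaxonomy(("genus",), {"h1": ("A",), "h2": ("B",)})
        M = BipartiteMatrix(np.array([[3, 1], [1, 3]]), ("t1", "t2"), ("h1", "h2"))
        t2g = {"t1": "ga", "t2": "gb"}
        spec = genus_specificity(M, t2g, tax)
        D = tax.distance_matrix(M.col_names)
        assert spec.loc["ga", "d_prime"] == pytest.approx(species_d(M, "t1").d_prime)
        assert spec.loc["ga", "mpd"] == pytest.approx(weighted_mpd(M.row("t1"), D))

    def test_pooling_two_exclusive_congeners_raises_mpd(self):
        M, t2g, tax = self._setup()
        pooled = genus_specificity(M, t2g, tax, mode="pooled")
        D = tax.distance_matrix(M.col_names)
        species_mpds = [weighted_mpd(M.row(t), D) for t in M.row_names]
        assert pooled.loc["g", "mpd"] > max(species_mpds)  # 4 > 0, 0

    def test_pooled_d_not_above_member_max(self):
        M, t2g, tax = self._setup()
        pooled = genus_specificity(M, t2g, tax, mode="pooled")
        member_max = max(species_d(M, t).d_prime for t in M.row_names)
        assert pooled.loc["g", "d_prime"] <= member_max + 1e-12

    def test_averaged_mode_weighted_mean(self):
        M, t2g, tax = self._setup()
        avg = genus_specificity(M, t2g, tax, mode="averaged")
        dvals = [species_d(M, t).d_prime for t in M.row_names]
        assert avg.loc["g", "d_prime"] == pytest.approx(np.mean(dvals))


class TestRichnessTable:
    def test_table_and_correlation_recover_positive_relationship(self):
        """Genera built to parasitize more hosts with more member species must
        yield a positive richness-Chao1 rank correlation."""
        rng = np.random.default_rng(3)
        n_hosts = 24
        hosts = tuple(f"h{j:02d}" for j in range(n_hosts))
        tax = HostTaxonomy(("g",), {h: (f"G{j // 3}",) for j, h in enumerate(hosts)})
        rows = []
        names = []
        t2g = {}
        # genus k has k+1 member species, each using ~3 distinct hosts
        for g in range(5):
            for s in range(g + 1):
                name = f"t{g}_{s}"
                names.append(name)
                t2g[name] = f"genus{g}"
                row = np.zeros(n_hosts, dtype=int)
                chosen = rng.choice(n_hosts, size=3, replace=False)
                row[chosen] = rng.integers(1, 6, size=3)
                rows.append(row)
        counts = np.array(rows)
        used = counts.sum(axis=0) > 0
        M = BipartiteMatrix(counts[:, used], tuple(names),
                            tuple(h for h, u in zip(hosts, used) if u))
        table = genus_richness_table(M, t2g, tax)
        assert (table["chao1"] >= table["s_obs"]).all()
        corr = richness_correlations(table)["richness_vs_chao1"]
        assert corr.rho > 0
        assert corr.p_value < 0.05
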