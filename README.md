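# hostspec

Quantitative host-specificity analysis for weighted parasite–host
interaction networks, built for tick–host association data but applicable
to any bipartite count matrix of parasites on hosts.

Field surveys of ticks attached to vertebrate hosts yield a ticks × hosts
count matrix. Three complementary questions follow. Does a tick use hosts
out of proportion to their availability (*structural specificity*)? Are the
hosts it uses more closely related than a random draw from the available
pool (*phylogenetic specificity*)? And do these patterns persist across
nested spatial scales once sampling effort is equalized (*geographical
specificity*)? `hostspec` answers all three, plus the genus-level question
of whether species-rich parasite genera collectively exploit more host
species.

## What it computes

**Structural specialization.** With cell counts `a_ij`, margins `A_i`,
`A_j` and grand total `m`:

- community level *H₂′* — the standardized two-dimensional Shannon entropy
  `H2 = −Σ p_ij ln p_ij` with `p_ij = a_ij/m`, rescaled between the extreme
  entropies of integer tables with the observed margins:
  `H2' = (H2_max − H2)/(H2_max − H2_min)` ∈ [0, 1], 0 for the most
  generalist community and 1 for the most specialist.
- species level *dᵢ′* — the standardized Kullback–Leibler divergence of the
  row's host use `p'_ij = a_ij/A_i` from availability `q_j = A_j/m`:
  `d_i = Σ p'_ij ln(p'_ij/q_j)`, rescaled by `d_max = ln(m/A_i)` and the
  minimum over integer allocations of `A_i`. Extrema are exact (full
  enumeration) for small problems and deterministic heuristics otherwise.

**Null models.** Significance of the indices is the empirical proportion of
null replicates at least as specialized as the observation, under
(I) a fixed-margins permutation null (Patefield / multivariate
hypergeometric) and (II) a connectance-preserving null that keeps the
number of realized links and forces every species to retain interactions
(the vaznull scheme).

**Phylogenetic specificity.** Host relatedness comes from a hierarchical
taxonomy (up to 19 ranks above species) with unit branch lengths; the
abundance-weighted mean pairwise distance
`MPD = Σ_{j<k} w_j w_k δ_jk / Σ_{j<k} w_j w_k` is standardized against a
tip-label-shuffle null: `SES_MPD = (MPD_obs − mean_null)/sd_null`, equal to
−1 × the Net Relatedness Index. Negative values mean phylogenetically
clustered host use.

**Geographical specificity.** Nested scale subsets are rarefied to the
smallest scale's event total by link-strength-proportional resampling, with
H₂′ and d′ recomputed per replicate.

**Richness relationships.** Genus-pooled host abundance vectors feed the
Chao1 asymptotic richness estimator
(`S_obs + F1²/2F2` classic, `S_obs + F1(F1−1)/(2(F2+1))` bias-corrected),
and Spearman's ρ (exact permutation p-value at small n) tests whether
species-rich tick genera parasitize more host species.

A synthetic-community generator with known ground truth (per-tick focal
host and concentration λ) makes the entire pipeline testable without any
field data.

## Worked example

```python
import numpy as np
from hostspec import (SyntheticConfig, generate_network, build_matrix,
                      subset_scale, h2_prime, species_d, null_ensemble,
                      ses_mpd_all)

cfg = SyntheticConfig(lam=np.linspace(0.0, 5.0, 20), seed=1)
records, truth = generate_network(cfg, np.random.default_rng(1))
M = build_matrix(subset_scale(records, "large"))
print(f"matrix: {M.shape[0]} ticks x {M.shape[1]} hosts, m = {M.m} events")

res = h2_prime(M)
print(f"H2' = {res.H2_prime:.3f}  (H2 = {res.H2:.3f} in [{res.H2_min:.3f}, {res.H2_max:.3f}])")

ens = null_ensemble(M, "H2_prime", "patefield", n=1000, rng_seed=2)
print(f"fixed-margins null: mean H2' = {np.mean(ens.values):.3f}, p = {ens.p_value:.3f}")

generalist = species_d(M, "tick_00_00")   # lambda = 0
specialist = species_d(M, "tick_07_00")   # high lambda
print(f"d'(lambda=0 tick)    = {generalist.d_prime:.3f}")
print(f"d'(high-lambda tick) = {specialist.d_prime:.3f}")

ses = ses_mpd_all(M, truth.taxonomy, n=1000, rng_seed=3)
sig = [r for r in ses if not r.degenerate and r.p_value < 0.05]
print(f"phylogenetically specific ticks: {len(sig)} of "
      f"{sum(not r.degenerate for r in ses)} testable")
```

Output:

```
matrix: 20 ticks x 27 hosts, m = 490 events
H2' = 0.791  (H2 = 3.379 in [2.925, 5.105])
fixed-margins null: mean H2' = 0.081, p = 0.000
d'(lambda=0 tick)    = 0.297
d'(high-lambda tick) = 0.557
phylogenetically specific ticks: 4 of 9 testable
```

The simulated community is strongly specialized overall (H₂′ = 0.79, far
above the null mean of 0.08, empirical p = 0 over 1,000 fixed-margin
replicates). The λ = 0 tick, which uses hosts in proportion to
availability, gets a low d′; the high-λ tick scores higher — d′ measures
*reciprocal* exclusiveness, so sharing its focal host with other ticks
keeps it below 1. Ticks found on a single host are flagged degenerate and
excluded from the SES_MPD count.

## Command line

```sh
specificity simulate --out data/ --seed 1 --lambda 2.5
specificity run-all --records data/records.tsv --taxonomy data/taxonomy.tsv \
    --reps 1000 --seed 1 --out results/
```

Subcommands `structural`, `phylo`, `rarefy` and `richness` run each
analysis separately; all stochastic commands require `--seed` and write
TSV/JSON outputs plus a log with the seed and a config hash.

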