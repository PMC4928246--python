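# Methods

This note documents the models, numerical choices and limitations of
`hostspec`. It records design decisions in the package's own terms; every
empirical statement here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Data model

The canonical input is the *record*, not the matrix: one observed
association of a tick species with a host species, a count of attached
adults (≥ 1), and a set of nested spatial-scale tags
(`small ⊂ intermediate ⊂ large`; tags are closed under this nesting at
construction, so a record observed at the small scale automatically belongs
to the larger scales). Matrices are always derived from records, which
makes scale subsetting and genus aggregation consistent by construction:
the per-scale matrices are additive and `m(small) ≤ m(intermediate) ≤
m(large)` holds for any record set. Duplicate (tick, host, scale) rows are
summed, since field-collected and literature-sourced observations of the
same association legitimately co-occur. Row and column order is
lexicographic for determinism; matrices never retain all-zero rows or
columns.

## Structural specialization

All entropies are natural-log (nats).

* `H2 = −Σ_{a_ij>0} p_ij ln p_ij`, `p_ij = a_ij/m`.
* `H2' = (H2_max − H2)/(H2_max − H2_min)` where the extrema range over
  non-negative **integer** tables with the observed margins.
* `d_i = Σ_j p'_ij ln(p'_ij / q_j)` with `p'_ij = a_ij/A_i`,
  `q_j = A_j/m`; `d_max = ln(m/A_i)`;
  `d_min = min` of `d` over integer allocations of `A_i` across hosts;
  `d'_i = (d_i − d_min)/(d_max − d_min)`, clamped to [0, 1].

Availability `q_j` includes the focal row's own contribution — the simplest
reading of "overall partner availability"; excluding it is a defensible
alternative that would change values in the low digits for dominant rows.

**Extrema.** For small problems (≤ 10 cells or `m ≤ 12` for the table
extrema; ≤ 5,000 candidate allocations for `d_min`) the extrema are exact by
exhaustive enumeration. Above that, deterministic heuristics are used:
`H2_min` by repeatedly placing `min(remaining row, remaining column)` mass
in the cell of the two largest remaining margins; `H2_max` and `d_min` by
largest-remainder integer allocation toward the margin-proportional table
(`a_ij = A_i A_j / m`) and toward `A_i · q_j` respectively. The observed
row is itself a valid allocation, so `d_min` is additionally capped at the
observed `d`, guaranteeing `d' ≤ 1` before clamping. The heuristics are
reproducible and tested never to cross the true extrema on enumerable
problems, but may differ from other implementations in the last digits on
large matrices.

**Degenerate denominators** (`max = min`, e.g. a 1×1 matrix or a tick that
is the only one in the network) yield index 0 with a `degenerate` flag
rather than NaN, so result tables stay complete.

## Null models and significance

* **Fixed margins (`patefield`).** The permutation distribution of
  contingency tables with both margin vectors fixed, sampled through
  scipy's fixed-margin sampler with the token-pairing ("boyett") scheme —
  pair the m row tokens with m shuffled column tokens and tabulate — which
  is distributionally identical to Patefield's algorithm and directly
  checkable against the closed-form hypergeometric law on 2×2 margins.
  Because margins are invariant under this null, the index extrema are
  computed once per ensemble and reused.
* **Connectance-preserving (`vaznull`).** Exactly L = observed link count
  cells become non-zero; cells are chosen sequentially with probability
  ∝ (A_i/m)(A_j/m) among cells that leave enough remaining links to cover
  every row and column (a feasibility mask, equivalent to rejecting dead
  ends), then the remaining m − L events are placed multinomially on the
  chosen cells with the same probabilities. Margins are therefore
  approximate — only their expectation matches — which is the behaviour of
  the source algorithm this scheme follows.

Significance is the raw empirical proportion of null values at least as
specialized as the observation (`tail="ge"` for H₂′ and d′, `tail="le"` for
MPD). The uncorrected proportion is the default to match the convention
the indices are usually reported with; the safer `(k+1)/(N+1)` continuity
correction is available via a flag. Default replicate count is 1,000 and a
seed is mandatory.

## Phylogenetic specificity

Host relatedness is taxonomic: each species carries a lineage of up to 19
ranks; the induced tree has unit branch lengths and the distance between
two tips is the edge count of their path (2 for congeners, 4 for
confamilial species in different genera, …). Unary pass-through ranks are
kept by default — they are part of the stated classification — and an
optional `collapse_unary()` drops only ranks at which *every* node is an
only child, which changes absolute distances but provably not their
ordering (per-node collapse would make tip depths ragged and can reorder
pairs, so it is not offered).

Weighted MPD uses unordered host pairs `j < k` with `w_j w_k` weights and
excludes self-pairs. The null shuffles host labels uniformly over the host
pool observed in the matrix at that scale (not over all species in the
taxonomy): the question is non-randomness with respect to *available*
hosts. SES uses the sample standard deviation (ddof = 1) of the null MPDs.
Single-host ticks have no pairwise distances: MPD = 0, SES = 0, p = NaN,
all flagged degenerate. How significance could be assigned to such ticks
is not defined by the method, so the package only flags them; downstream
summaries exclude them.

## Rarefaction

Larger scales are resampled down to the smallest scale's event total with
cell probabilities `p_ij = a_ij/m` — multinomial by default, which matches
the stated per-link probabilities exactly and has testable moments
(`E[cell] = target · p_ij`); a without-replacement multivariate
hypergeometric mode is available, and is the mode under which resampling
the full total reproduces the matrix exactly. Species that receive no
events drop out of a replicate; indices are computed on the realized
replicate matrix and per-species summaries report the fraction of
replicates in which the species survived. Note that H₂′ of a rarefied
replicate is upward-biased relative to the source matrix (subsampling
concentrates frequencies), which is precisely why cross-scale comparisons
must compare rarefied values with rarefied-or-equal-effort values, never
with raw larger-scale values.

## Richness

Chao1 is computed on genus-pooled host abundance vectors; the
bias-corrected form is the default because it is always defined, with the
classic form available (falling back, with a warning, when there are no
doubletons). Genus-level d′ and MPD are computed on the pooled genus row
by default — consistent with Chao1 being computed on pooled abundances — or
as abundance-weighted means of member-species values behind a flag.
Spearman's ρ uses average ranks for ties; for n ≤ 9 the two-sided p-value
is exact by full enumeration of rank permutations (at eight genera an
asymptotic p would be meaningless), above that the t approximation.

## Synthetic communities

The generator emulates the structure the pipeline assumes: heterogeneous
margins, a multi-level host taxonomy, nested scales, and a *known* degree
of specialization. Tick i with focal host `f_i` and concentration
`λ_i ≥ 0` chooses hosts with probability
∝ `availability_j · exp(−λ_i · δ(f_i, j))`. The exponential
taxonomic-distance kernel is the simplest monotone family that spans
proportional use (λ = 0, exactly the null models' generalist assumption,
because availability enters multiplicatively) to exclusive single-host use
(large λ). Defaults, chosen once as the study conditions: 20 tick species
in 8 genera (sizes skewed by a 1/(g+1) largest-remainder split, echoing
the strongly uneven genus sizes of real tick communities), 30 host
species, taxonomy depth 4 with 3-way branching (deep enough for
within-genus versus cross-order contrasts), lognormal host availability
(σ = 1), lognormal per-tick record totals (μ = 3, σ = 1 on the log scale;
median ≈ 20 records per tick, community totals in the hundreds), and
nested scale retention of 80 % (large → intermediate) and 50 %
(intermediate → small) per event, drawn binomially per cell so the scale
matrices are additive.

What the generator does **not** emulate: spatial autocorrelation of
sampling, life-stage structure, seasonality, observation error in species
identification, and literature-versus-field source heterogeneity. Passing
tests therefore demonstrate the estimators' correctness and their ability
to recover a specialization gradient under idealized sampling — not
robustness to those real-data complications.

A consequence of exclusive specialization worth noting: ticks with large λ
typically end on a single host, where SES_MPD is undefined (degenerate).
Parameter-recovery checks for the λ–SES relationship therefore pool the
non-degenerate ticks of several replicate communities generated under the
same conditions, which gives the rank correlation adequate power without
altering any per-community condition.

## Problem sizes used in the shipped checks

Exhaustive-enumeration checks cover every margin configuration realizable
by matrices up to 3×3 with m ≤ 10. Distributional checks use 10,000
fixed-margin draws (2×2) and 1,000 connectance-preserving draws (6×8).
Pipeline-level checks run 20 × 30 communities with 200–1,000 null or
rarefaction replicates, and recovery correlations pool five such
communities. These sizes were chosen so each check is decisive at its
stated tolerance while the whole suite stays quick to run.

## Known limitations

* The extrema heuristics (hence H₂′ and d′ on large matrices) are one
  defensible choice among several; other implementations may differ in low
  digits.
* Empirical p-values without continuity correction can be exactly 0;
  report them as `p < 1/N` when publishing.
* Taxonomic distances are a coarse proxy for phylogenetic distance; all
  branches are unit length by construction.
* vaznull requires at least as many links as max(#rows, #cols); sparser
  matrices are infeasible for that null and raise an error.
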