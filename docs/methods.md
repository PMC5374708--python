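# Methods

## Cell proliferation models

Each tumor biopsy or normal cell type is modeled as a map from target
subsets φ ⊆ {0, …, T−1} to a kill sensitivity in [0, 1], monotone under
inclusion (all targets are treated as oncogenes).  Two representations:

* **Circuit**: an ordered series of parallel blocks.  Block *b* carries a
  member set T_b and a score S_b ∈ [0, 1]; its effective inhibition is
  λ_b(φ) = min_{t ∈ T_b} φ_t, i.e. 1 iff every member is inhibited.
  Assuming independence between series blocks,
  `Sensitivity(φ) = 1 − Π_b (1 − S_b λ_b(φ))`.  The empty inhibition always
  scores 0, and the map is monotone by construction.
* **Lookup table**: an explicit subset → sensitivity map (e.g. inferred from
  a drug screen).  Tables may be partial; search entry points reject partial
  tables because subtree pruning needs every visited subset to be evaluable.
  Monotonicity is validated on load — immediate (one-extra-target) pairs for
  complete tables, all comparable stored pairs for partial ones — and
  violations are reported as warnings rather than errors, since screen-derived
  tables may carry noise.

Conventions: targets are 0-indexed; the 01-string position i is target i
("1100" inhibits targets 0 and 1); internally subsets are uint32 bit masks
with target i on bit i.  Scores round-trip through JSON at full IEEE-double
precision.

## Objectives

With k tumor models and p normal models sharing one target universe:
WCO maximizes min_i O(MT_i, φ) subject to max_j O(MN_j, φ) ≤ θ;
BEO maximizes the means on both sides subject to mean ≤ θ.  The boundary is
feasible (≤), and pruning triggers on strict excess (>), keeping the two
consistent.  Both aggregates of monotone maps are monotone in φ, which is
the soundness condition for superset pruning in either mode.  θ defaults to
0.1 — one normal-cell model may lose at most 10% of its proliferation
(WCO), or the organ-average may (BEO).

## Exact search

The subset lattice is spanned by the tree in which a node's children set one
bit at an index strictly greater than the node's highest set index; every
subset is generated exactly once and parents precede children.  A node whose
toxicity exceeds θ is evaluated but not expanded, removing its whole subtree.
The implementation is an explicit level-order frontier, expanded in bulk with
numpy (child generation by ragged aranges over bit positions; toxicity and
tumor objectives evaluated on mask arrays in chunks of 2^19 to bound peak
memory).  The visited-node set — and hence the reported evaluation count,
which includes the empty root — is identical to the recursive depth-first
formulation, because pruning depends only on the node itself.  Recursion
depth therefore never limits correctness.

Tie-breaking among equally optimal feasible sets: fewer inhibited targets
first, then the lexicographically smallest 01-string.  Smaller therapies are
practically preferable and the rule makes results reproducible bit for bit.

`lex_search_prefixes` exploits that pruning depends only on the normal
models: one traversal scores the tumor objective for every leading tumor
prefix (nTumor = 1..k), so a whole benchmark-table column costs one search.
Results are exactly those of the per-cell searches (tested).

The exhaustive oracle enumerates all 2^T subsets (capped at T ≤ 20) and
backs the equivalence tests; the pruned search is capped by default at
T ≤ 30 and refuses larger universes unless the caller raises the cap.

## GACT (genetic algorithm)

Chromosome = therapy bit string.  Fitness is the pair (tumor score,
toxicity score) for the active mode.  Per generation: the non-dominated
front of the population breeds `clamp(2·|front|, 1000, 15000)` offspring —
two parents drawn uniformly with replacement from the front, uniform
per-gene crossover applied with probability rate_c (otherwise the first
parent is cloned), then independent per-bit mutation at rate_m — and the
merged pool is reduced to the best N by (front layer from repeated peeling,
tumor score descending, toxicity ascending).  Defaults rate_m = 0.2,
rate_c = 0.6, totalG = 400 follow the parameter sweeps; N = 100 is this
package's choice (population size is otherwise unconstrained and is exposed
in `GactParams`).

Two survivor-selection details are this package's own design, adopted after
the plain (layer, tumor, toxicity) cut proved degenerate:

* duplicate genomes are collapsed before the cut — copies never strictly
  dominate each other, so they flood the top layer and the sort then keeps N
  copies of the single best-tumor genotype, collapsing diversity;
* the pool's best *feasible* point is always retained, so the best feasible
  tumor score of the population is nondecreasing across generations — the
  elitism the final selection step (max tumor on the final front subject to
  toxicity ≤ θ) relies on.

The stopping rule "offspring greater than the maximum" is ambiguous between
per-generation and cumulative counting; the per-generation demand is always
clamped at off_max, and by default the loop additionally stops once the
cumulative offspring count would pass off_max (`cumulative_offspring_stop`
turns this off, letting all totalG generations run).

## Hill climbing

Starts are Latin-hypercube points in [0, 1]^T thresholded at 0.5 (scipy's
`qmc.LatinHypercube`, drawn in batches of 64).  One iteration is one sweep
over all T single-flip neighbors.  Over-ceiling states descend toxicity
(least-toxic neighbor); feasible states ascend the tumor objective among
feasible neighbors; moves happen only on strict improvement, ties go to the
lowest flipped index, and a stall triggers a restart, which is charged one
iteration against max_iter (default 15000, past which returns diminish).
The best feasible therapy seen anywhere — including evaluated neighbors that
were never moved to — is returned, so the best-so-far trace is nondecreasing.

## Search-cost theory

`f(l, θ)` is estimated by drawing `reps` uniform l-subsets per level
(default 300 000, reducible for tests), evaluating every supplied normal
model, and pooling the values into one empirical CDF on a uniform
1001-point θ grid.  Pooling across the P cell models, combined with the
independence assumption behind `g = f^P`, treats the cells as i.i.d. — an
approximation, since the models differ.  For BEO, the grid density
(first differences of f, with the mass at 0 kept in the first cell) is
self-convolved P−1 times; the CDF of the mean at grid point θ_j is the sum
CDF at index P·j, exact on a uniform grid with integer P.

Stop-level probabilities are `P(L_i) = g(i−1, θ) − g(i, θ)` with the
convention g(0, θ) = 1 (the empty inhibition is never toxic for circuits);
Monte-Carlo noise occasionally makes g non-monotone in l, in which case
negative differences are floored at zero with a warning.  Expected searches
`Σ_i P(L_i) Σ_{j≤i} C(T, j) + g(T, θ) 2^T` and expected savings are exact
complements: they sum to 2^T.  The level-stopping model ignores that real
pruning happens branch by branch at mixed levels, so it is an approximation
of the pruned-tree cost; on the synthetic benchmark it lands within ~10% of
the observed mean (the tests assert 50%).

## Synthetic benchmark generator

Defaults reproduce the benchmark conditions: T = 25 targets; five blocks
per circuit; block sizes uniform on {1..5} (only the upper bound is pinned
down, so the least-informative uniform law is used and exposed in
`GeneratorConfig` — this is the main tolerance driver when comparing table
values); members drawn uniformly without replacement within a block, freely
repeating across blocks, so all targets are equiprobable; scores uniform on
[0.5, 1]; 100 groups of 5 tumor + 5 normal circuits (1000 models).  Group i
is generated from the i-th spawned child of `SeedSequence(seed)`, so groups
are reproducible in isolation and prefixes are stable as n_groups grows.

What the generator does *not* emulate: correlations between tumor and normal
circuits of one patient, organ-specific normal responses, inference noise in
screen-derived PTIMs, and non-binary (partial) inhibition.  Passing tests
show the algorithms are correct and well-calibrated on monotone circuit
ensembles, not that the sensitivity values transfer to any particular
biological dataset; lookup-table input exists precisely so users can supply
screen-derived maps.

## Benchmark harness

A cell (nTumor, nNormal) uses the deterministic leading prefix of each
group's models, keeping nested cells comparable, and averages best values
and evaluation counts over groups.  Searches with randomness are seeded per
(experiment seed, group index).  Identical config and seed give bit-identical
CSVs.

## Problem sizes used by the shipped checks

The test suite runs the exact search on a 30-group benchmark (corner cells
of both modes), oracle-equivalence on 210 random instances with T ∈ 4..12,
heuristic comparisons on 30 T = 10 instances, and table-structure checks at
T = 25 (3 groups, for the per-group-deterministic properties) and T = 10
(1200 groups, for the properties that hold in expectation).  The acceptance
script runs the full 100-group benchmark.  Mean-value monotonicity of BEO
tables along nTumor holds only in expectation — a favorable extra tumor
model can raise one group's constrained mean — which is why that property is
checked at the many-group scale.

## Known limitations

* The pruned search is exponential in the worst case (θ → 1 degenerates to
  exhaustive enumeration); the T ≤ 30 cap guards against accidental misuse.
* GACT offers no convergence guarantee; it is a baseline, not the optimizer.
* The cost theory assumes i.i.d. normal models and level-wise stopping.
* Lookup-table groups evaluate through dense 2^T arrays per model, which is
  memory-bound beyond T ≈ 24.
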