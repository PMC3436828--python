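# Methods

## Model and problem

A metabolic network is a stoichiometric matrix `S ∈ ℝ^{m×n}` (m metabolites,
n reactions) with a reversibility flag per reaction and an internal/external
flag per metabolite. External (boundary) metabolites are not balanced; they
represent the environment, reached through drain/exchange reactions. An
**elementary flux mode** (EM) is a flux vector `e` with `S_int · e = 0`,
`e_i ≥ 0` for irreversible `i`, and minimal support: no other steady-state,
sign-feasible vector uses a strict subset of its nonzero reactions.
Equivalently, `rank(S_int[:, support(e)]) = |support(e)| − 1`, which is the
test used throughout ("rank test").

## Canonical-basis tableau with random filtering

The tableau starts as `T = [S_intᵀ | Iₙ]`. For each internal metabolite, all
rows with a nonzero entry in its column are removed and replaced by all
pairwise combinations that cancel the entry. Orientation rules: a row may be
negated only if it is *reversible* (every reaction in its support is
reversible); a pair is combinable only if the oriented entries have opposite
signs. A candidate whose oriented parents share a reversible reaction with
opposite signs would run that reaction in both directions at once and is
discarded outright. Surviving candidates must pass the rank test restricted
to the metabolites processed so far (including the current one). When all
internal metabolites are processed, the reaction parts of the remaining rows
are exactly the EMs.

The sampling contribution is one extra step: after each metabolite's batch of
new candidates is assembled and deduplicated, each candidate is kept
independently with probability `P = min(1, K/N)` (N = batch size), so the
expected number of survivors is `min(N, K)`. Uniformity of P within a batch
is what keeps the sample unbiased; K is the only tuning knob. Selected
survivors remain subject to all subsequent eliminations, so everything that
reaches the end is a true EM — sampling can only *omit* modes, never invent
them. A second selection mode (`exact_size`) draws exactly `min(N, ⌈K⌉)`
survivors without replacement, for the reading of K as a hard cap rather
than an expected bound; the binomial mode is the default. Deduplication runs
before filtering so the uniform probability is over distinct candidates.

Independent trials use seeds `seed + t` and are merged with
normalization-aware deduplication; every merged mode is re-verified against
the full internal stoichiometry (steady state, signs, rank test) as a
guarantee, not a correction.

## Numerical choices

- Floating point with absolute zero tolerance `1e−9` on tableau entries;
  rows are rescaled after every combination so the largest reaction
  coefficient is 1, bounding coefficient growth.
- Rank from singular values with relative tolerance `1e−9`; steady-state
  residual tolerance `1e−6` on normalized modes.
- Modes are canonicalized by max-|coefficient| = 1 scaling; fully reversible
  modes are additionally oriented so their first nonzero coefficient is
  positive, giving one representative per reversible direction pair.
  Deduplication keys round coefficients to 9 decimals.
- An exact rational tableau (`exact=True`, Fractions + exact rank) is
  available for small fixtures where floating-point behaviour itself is
  under test.
- Metabolite processing order defaults to input order; a
  fewest-combinations-first heuristic (`order="fewest"`) is available. The
  enumerated set is order-independent (tested); the heuristic only affects
  intermediate batch sizes.
- The per-candidate rank is computed from scratch; incremental rank updating
  is a known optimization deliberately left out for clarity, since the
  package targets desk-scale networks and correctness validation.

## Preprocessing

Blocked reactions (zero flux range under steady state and bounds) are found
by FVA — two LPs per reaction via `scipy.optimize.linprog`/HiGHS — using
`|flux| ≤ 1e−9` at both extremes as the blocked criterion (LP solver
precision). Removal drops blocked reactions and any metabolite left without
reactions; the operation is idempotent and preserves the EM set (tested
against the oracle). Files without explicit bounds get `[0, 1000]` for
irreversible and `[−1000, 1000]` for reversible reactions, the conventional
"effectively unbounded" magnitudes. Growth-medium choices (e.g. a single
carbon source) are expressed as exchange-reaction bounds on the input model.

## Strain design

`apply_knockouts` removes every mode with flux through a knocked reaction;
`production_counts` reports total / target-producing / biomass-viable counts.
The knockout search maximizes `producing − λ·non_producing` survivors
(λ = 1) subject to at least one biomass-viable survivor, over sets of at most
`max_ko` internal reactions — exhaustively when the subset count fits a
budget (default 20 000), otherwise by greedy forward selection with
lexicographic tie-breaks. This scalarized objective is a design choice: it
captures "eliminate the maximum number of competing pathways while keeping
production and viability" as a single deterministic criterion; other
published knockout-scoring schemes could be substituted behind the same
interface.

MOMA predicts mutant fluxes by minimizing `‖v − v_wt‖²` subject to
`S_int v = 0`, bounds, and `v_ko = 0`. The minimizer is computed exactly by
least squares on the nullspace of the constrained stoichiometry; when a box
bound binds, the solver falls back to SLSQP with explicit bounds. The
wild-type reference defaults to the FBA biomass-maximal flux, standard
practice when no measured distribution is given.

## Synthetic data: what the fixtures emulate and what they do not

- **Toys** (chain, diamond, reversible cycle, dead end, branched) exercise
  each structural case: single pathway, alternative routes, a fully
  reversible cycle mode, a blocked reaction, and competing branches.
- **Layered networks** model cascades with parallel isozymes and optional
  bypass ("skip") reactions. Their EM count and pathway-length histogram
  have closed forms by path counting, giving an algorithm-independent truth
  for fixtures too large to brute-force (the 5473-mode fixture used for
  scaling tests). Branch symmetry makes per-mode inclusion probabilities
  provably equal, which is what the chi-square uniformity test relies on.
- **Random networks** are seeded sparse single-substrate conversion graphs
  with a spanning chain, drains, occasional stoichiometric coefficient 2 and
  a tunable reversible fraction, calibrated so 5-metabolite/10-reaction
  instances stay within oracle-tractable EM counts (≤ ~200).

None of these reproduce the features of curated genome-scale
reconstructions — cofactor coupling, highly connected currency metabolites,
compartments, or realistic degree distributions. Passing tests demonstrate
algorithmic correctness and the statistical behaviour of the sampler (subset
soundness, uniform inclusion, linear size-in-K scaling, short-pathway bias
shrinking with K); they do not certify sampling quality on any particular
real network, where connectivity determines how large K must be for a given
coverage.

## Problem sizes used in tests and the acceptance script

Enumeration/oracle cross-validation runs on networks of up to 12 reactions
(30 seeds); uniformity uses 2000 runs at K=2 on a 20-mode fixture; scaling
and length-bias statistics use 3 replicates of 10 merged trials per
K ∈ {10, 30, 100, 300} on the 5473-mode fixture; participation correlations
use the enumerable 305-mode fixture. These sizes make the whole suite run in
well under a minute per statistic while leaving each test's expected effect
far above its noise floor.

## Known limitations

- The canonical-basis approach is inherently slower than nullspace/bit-
  pattern-tree enumerators; this package trades speed for the filtering hook
  and transparency. Genome-scale sampling is possible in principle but slow.
- The rank test per candidate dominates runtime (one SVD per candidate).
- Small K biases samples towards shorter pathways (longer modes survive more
  filtering rounds); the bias shrinks as K grows and is quantified by the
  length-gap statistics. No length-compensating selection probability is
  implemented.
- SBML support covers Level 2/3 stoichiometry, reversibility, boundary
  species and FBC flux bounds; gene rules, compartments beyond the
  internal/external flag, and SBML writing are out of scope.
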