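# Methods

This note documents the models, conventions, and numerical choices behind
`connectocore`, in the order a typical analysis uses them.

## Graph model and conventions

A connectome is a simple directed graph: nodes are neurons (opaque string
ids, never silently reindexed), edges carry positive integer synapse
counts aggregated over parallel records. Self-loops are dropped by default
and counted, because the density, rich-club, and type-matrix denominators
all assume ordered pairs with i ≠ j; a flag keeps them. Binarization sets
every weight to 1 and changes nothing else, so density is invariant under
it. The minimum synapse count for an edge defaults to 1 (any synapse makes
a connection) and is exposed as a parameter. Nodes missing from the
annotation table, or annotated with an empty label, belong to the explicit
`"unassigned"` type, which participates in composition profiles like any
other type.

## Synthetic study conditions

The generator's defaults define the conditions under which the package's
guarantees are tested:

* **Planted core** — 200 neurons, a 20-neuron core wired internally at
  probability 0.6, core↔periphery 0.05, periphery 0.01, all edges
  independent Bernoulli draws. The core carries one cell type; periphery
  labels are i.i.d. from a 4-type frequency vector. The overall density
  (~0.02) is of the order of a dense juvenile network; lowering the
  periphery probability toward 0.0002 gives an adult-like sparse regime.
  Independent-edge blocks (rather than degree-corrected blocks) suffice
  because frontier-core extraction depends only on the minimum in/out
  degrees inside the block.
* **Degree models** — discrete Weibull with λ = 0.025, β = 1.3 at
  n = 3000, and discrete power law with α = 2.5, x_min = 5 at n = 10000.
  Sequences are drawn by inverse CDF on the normalized mass over
  x_min … k_cap, with k_cap defaulting to n − 1 since a simple graph's
  degree cannot exceed that.
* **Configuration graphs** — stub matching; self-loops and parallel edges
  are dropped (not rewired) and counted, the standard surrogate
  convention, so callers can bound the distortion.

The generator makes no attempt to reproduce a real connectome's joint
in/out-degree correlation, reciprocity, spatial embedding, or synapse-type
structure. Passing tests therefore demonstrate that the *methods* recover
known structure under their stated assumptions — not that any particular
biological claim holds.

## Core decompositions

All three decompositions share one worklist-peeling kernel. Feasible node
sets are closed under union, so iterative deletion of violating nodes
reaches the unique maximal subgraph regardless of processing order (tested
by shuffled runs and by exhaustive subset search on small graphs). The
D-core matrix is filled exploiting nesting — each cell is pruned from a
neighboring cell's membership rather than from scratch — and spans
0 ≤ k ≤ k_max + 1, 0 ≤ l ≤ l_max + 1 where k_max is the last k with
D-core(k, 0) non-empty (similarly l_max), so the final row and column are
identically zero.

**Frontier rule.** The frontier is formalized as the Pareto-maximal
skyline: non-empty cells (k, l) such that no other non-empty cell
dominates them in both coordinates. This reproduces a staircase when no
single cell dominates and collapses to one innermost cell when one does;
the union of frontier members is the structural core.

**s-core sweep.** Thresholds are the sorted observed node strengths rather
than a continuous sweep — finite, exact, and sufficient for ranking nodes
or cell types by core depth. A node's level is the largest threshold it
survives; with unit weights the ranking coincides with k-core numbers (the
levels are a monotone transform).

## Degree-distribution fitting

Degrees are integers, so discrete likelihoods are used throughout.

* **Power law.** p(k) = k^(−α) / ζ(α, x_min) with the Hurwitz zeta
  normalization. α is estimated per candidate x_min by bounded scalar
  minimization of the negative log-likelihood (tolerance 1e−8); the
  returned fit minimizes the KS distance between the empirical and model
  tail CDFs over the scanned x_min values. The scan is restricted to
  candidates keeping at least 50 tail points, because KS minimization
  overfits tiny tails; if no candidate qualifies the smallest positive
  degree is used. A continuous closed-form estimator
  α = 1 + n / Σ ln(x_i/x_min) is exposed as a cross-check utility.
* **Discrete Weibull.** p(k) ∝ k^(β−1) e^(−λk^β) normalized by a finite
  sum over x_min … k_cap with k_cap = max(2·max(data), 1000); the omitted
  mass is negligible anywhere the optimizer goes on such data. (λ, β) are
  optimized in log-parameter space by Nelder–Mead from six starts with β
  spanning 0.4–2.5 and λ at the exponential moment heuristic 1/mean;
  convergence tolerance 1e−8 on the log-likelihood. The default x_min is
  the smallest positive degree, i.e. the whole range is fitted. Zero
  degrees are excluded and counted before any fit.
* **KS distance** is the supremum over observed tail values of
  |ECDF − model CDF|, both evaluated at the data points (where the ECDF
  moves; the model CDF is monotone between them).

**Family comparison.** The power law is the boundary limit of the Weibull
family (β → 0, λ → ∞ with λβ fixed), so on power-law data the
unconstrained Weibull MLE collapses onto that boundary and *ties* the KS
distance and log-likelihood — raw in-sample criteria cannot choose between
a model and its own limit. The comparison therefore reports three things:
the raw KS preference, the raw likelihood preference, and a headline
`preferred` field that applies an AIC-style penalty (Weibull must gain
more than one nat of log-likelihood for its extra parameter) together with
a boundary check: a fitted β below 0.2 means e^(−λk^β) varies too slowly
over any realistic degree range to be distinguishable from a pure power
correction, and the fit is reported as the power law it is. Under the
synthetic study conditions this selects the generating family 20/20 in
both directions.

## Rich-club analysis

Club membership is strictly greater than the threshold (> k), matching the
coefficient's denominator N_{>k}(N_{>k}−1). Null graphs are produced by
three-edge directed swaps (via networkx's `directed_edge_swap`), which
preserve both degree sequences exactly and introduce no self-loops or
parallel edges; the default budget is 10·E attempted swaps per sample, a
standard mixing heuristic recorded in the curve object. If a graph is too
rigid to complete the budget, the partially mixed surrogate is returned
with a warning rather than an error. Normalized points where the null mean
is zero are reported as missing (NaN), never as 0 or ∞.

Membership rules: `above_first_crossing` takes all nodes whose
direction-degree exceeds the smallest k with normalized RCC > 1 (the club
fraction is an *outcome*, not an input); `top_fraction` takes the ⌈fN⌉
highest-degree nodes with ties broken by eigenvector centrality (right
eigenvector of the directed graph, power iteration tolerance 1e−10).

## Whole-graph statistics

* **Clustering** defaults to the standard directed (Fagiolo-style)
  definition implemented by networkx; the literal ratio
  L_i/(k_i(k_i−1)) with k_i = k_in + k_out is kept as an auditable
  variant. The mean is over all nodes, zeros included — note this means
  removing an isolated node *raises* the mean by N/(N−1) without touching
  any surviving node's value.
* **Efficiency and betweenness** are computed on the largest strongly
  connected component; betweenness enters only as a ratio (set mean over
  SCC mean), so any common normalization cancels.
* **Consensus communities**: n seeded Louvain runs, a pair co-occurrence
  matrix, pairs below 50% co-occurrence cut (majority rule, recorded in
  the result), then a final Louvain pass on the weighted co-occurrence
  graph. Louvain runs directly on the directed graph; the reported
  modularity uses the directed formula with the 2m² null-term denominator
  by default and the common m² convention behind a flag, with the variant
  named in reports.
* **Normalized** clustering and modularity are ratios of means: observed
  value over the mean across degree-preserving null graphs.
* **Targeted attack** removes a node set simultaneously; the clustering
  ratio uses the entire graph, the efficiency ratio the largest SCC before
  and after.

## Composition and diversity

Neighbor sets use distinct-neuron (set) semantics — the profiles describe
neighbor *populations*, not synapse weights — with seeds excluded from
their own neighborhoods by default; order 2 is the order-1 step applied
twice. Shannon diversity is normalized by ln n and Simpson diversity is
reported in two forms: the concentration form n·Σp_i² (≥ 1, decreasing in
diversity) and its inverse 1/(n·Σp_i²) ∈ (0, 1], the default, which is the
only monotone-increasing-in-diversity variant consistent with reading
higher values as greater diversity. The vocabulary size n defaults to the
types present in the profiled set and can be fixed to the dataset's full
annotation vocabulary.

## Pipeline reproducibility

Per-stage seeds derive from the global seed through fixed stage
identifiers via `numpy.random.SeedSequence`, so toggling or adding stages
never shifts another stage's stream; every run writes a manifest with the
config digest and all stage seeds, and identical configs produce
byte-identical deterministic artifacts. Stage failures are isolated,
logged, and reported without aborting independent stages. Stages that need
the structural core (composition, attack) recompute it internally so that
disabling the D-core stage never changes their output.

## Problem sizes and limitations

Tests and the acceptance script run on 200-node planted-core graphs,
degree samples of 3,000–10,000, and null ensembles of 8–20 surrogates —
sizes chosen so the full suite completes in about a minute while keeping
Monte-Carlo error well inside the asserted tolerances; the library itself
has no such limits, and the pipeline defaults (e.g. 100 nulls for
published-quality curves) are set per run. Known limitations: no weighted
rich-club variant; no bootstrap plausibility p-value for the power-law
fit; no multi-resolution consensus sweep (a single resolution per run);
the s-core threshold sweep visits only observed strengths; and the
synthetic generator's independence assumptions understate the reciprocity
and degree correlations of real connectomes.
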