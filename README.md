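# connectocore

Core–periphery, rich-club, and degree-distribution analysis of directed
connectomes.

`connectocore` is a Python library for comparing the mesoscale structure of
directed neuronal networks — for example a young, dense brain network
against a mature, sparse one. It is aimed at researchers who have synapse
tables (pre-neuron, post-neuron, synapse count) plus cell-type annotations
and want reproducible, null-model-controlled answers to questions like:
*which neurons form the structural core? do high-degree neurons form a rich
club beyond what their degrees force? is the degree distribution
stretched-exponential or scale-free? what happens when the core is
removed?*

## What it computes

**D-cores and the frontier core.** For a directed graph, the D-core(k, l)
is the maximal subgraph in which every node has in-degree ≥ k and
out-degree ≥ l within the subgraph. Scanning all (k, l) yields the D-core
matrix A_G(k, l) = (dc_{k,l}); its Pareto-maximal non-empty cells are the
*frontier D-cores*, and the union of their members is taken as the
structural core. One peeling kernel also provides classical k-cores (total
degree) and s-cores (total strength) for weighted and type-level graphs.

**Rich clubs against degree-preserving nulls.** The directed rich-club
coefficient at threshold k is

```
RCC(k) = M_{>k} / ( N_{>k} (N_{>k} − 1) )
```

where N_{>k} counts nodes with in- (or out-) degree > k and M_{>k} the
directed edges among them. The raw curve is normalized by its mean over an
ensemble of three-edge directed swaps that preserve every node's in- and
out-degree exactly; normalized values above 1 indicate rich-club
organization.

**Degree-distribution fitting.** Discrete maximum-likelihood fits of a
power law P(k) ∝ k^(−α) (Hurwitz-zeta normalization, x_min chosen by
Kolmogorov–Smirnov minimization over the observed values) and of a discrete
Weibull / stretched exponential P(k) ∝ k^(β−1) e^(−λk^β), which is
exponential at β = 1 and heavier-tailed otherwise. A penalized comparison
reports which family the data prefer.

**Whole-graph statistics and experiments.** Density, directed clustering
(standard and literal-ratio variants), consensus Louvain communities with
directed modularity Q = Σ_c [L_c/m − γ k_c^in k_c^out / (2m²)], global
efficiency and betweenness on the largest strongly connected component,
degree–strength Spearman correlation, targeted-attack before/after ratios,
neighbor-set cell-type profiles with normalized Shannon and Simpson
diversity, and the type-to-type connection-probability matrix
P_ij = E_ij/(N_i N_j) (diagonal E_ii/(N_i(N_i−1))).

A synthetic generator (planted dense core confined to one cell type,
heavy-tailed degree sequences, directed configuration graphs) makes every
stage testable without any dataset download.

## Worked example

```python
from connectocore import (SyntheticSpec, generate_planted_core,
                          dcore_matrix, planted_core_nodes)

spec = SyntheticSpec(seed=1)          # 200 neurons, 20-neuron planted core
c = generate_planted_core(spec)
m = dcore_matrix(c)
print(m.frontier_cells(), len(m.frontier_core()))
```

Running `python examples/simulate_and_core.py` prints:

```
graph: 200 neurons, 919 connections, density 0.0231
D-core matrix spans k = 0..10, l = 0..9
frontier cells (Pareto-maximal non-empty): [(9, 8)]
frontier core: 19 neurons; Jaccard with planted core 0.95
```

The frontier sits at a single cell (k, l) = (9, 8): every one of the 19
core neurons keeps at least 9 inputs and 8 outputs inside the core, and no
deeper non-empty D-core exists. A Jaccard of 0.95 with the planted 20-node
block means the decomposition recovered the true core almost exactly.
`examples/degree_fitting.py` likewise recovers generating parameters
(fitted λ = 0.0256, β = 1.295 from λ = 0.025, β = 1.3; α = 2.500 from
α = 2.5) and picks the generating family in both directions; the other
examples cover rich clubs, composition/diversity, and the end-to-end
pipeline (`connectocore run config.yaml` from the shell).

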