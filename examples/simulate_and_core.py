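"""Generate a planted-core connectome and recover its core by D-cores.

Builds a 200-neuron directed graph with a 20-neuron densely wired core
(all one cell type), computes the full D-core matrix, and checks how
well the frontier D-cores recover the planted core.
"""

from connectocore import (
    SyntheticSpec,
    dcore_matrix,
    generate_planted_core,
    planted_core_nodes,
)

spec = SyntheticSpec(seed=1)  # 200 nodes, 20-node core at 0.6 density
c = generate_planted_core(spec)
print(f"graph: {c.n_nodes} neurons, {c.n_edges} connections, "
      f"density {c.density():.4f}")

m = dcore_matrix(c)
print(f"D-core matrix spans k = 0..{m.k_max + 1}, l = 0..{m.l_max + 1}")
print(f"frontier cells (Pareto-maximal non-empty): {m.frontier_cells()}")

core = m.frontier_core()
truth = planted_core_nodes(spec)
jaccard = len(core & truth) / len(core | truth)
print(f"frontier core: {len(core)} neurons; Jaccard with planted core "
      f"{jaccard:.2f}")
# A Jaccard near 1 means the innermost D-cores are exactly the planted
# dense block: the decomposition finds the structural core.
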