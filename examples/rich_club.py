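"""Rich-club analysis of a planted-core graph against degree-preserving
nulls, and the density hierarchy core > rich club > whole graph.
"""

from connectocore import (
    SyntheticSpec,
    dcore_matrix,
    generate_planted_core,
    normalized_rcc,
    rc_membership,
    subgraph_density,
)

c = generate_planted_core(SyntheticSpec(seed=1))
curve = normalized_rcc(c, direction="in", n_nulls=20, seed=0)
k0 = curve.first_crossing()
print(f"normalized in-degree RCC first exceeds 1 at k = {k0}")

members = rc_membership(curve, c)  # nodes with in-degree > k0
print(f"rich club: {len(members)} neurons "
      f"({100 * len(members) / c.n_nodes:.0f}% of the network)")

core = dcore_matrix(c).frontier_core()
print(f"density: core {subgraph_density(c, core):.3f} > "
      f"rich club {subgraph_density(c, members):.3f} > "
      f"graph {c.density():.3f}")
# The structural core is denser than the rich club containing it: a
# "rich club of the rich club" hierarchy of connectivity.
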