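"""Edge crossings grow with the square of the connection density.

On a 49-node jittered-grid layout, counts the crossings of the complete
graph (Ec_max) and compares Monte-Carlo means over uniform L-edge subsets
with the exact combinatorial expectation Ec_max * L(L-1)/(Lmax(Lmax-1))
and its large-L limit Ec_max * rho**2.
"""

import numpy as np

from econet import (
    complete_graph_edges,
    count_crossings,
    exact_subset_expectation,
    expected_crossings,
    netviz_layout,
)

rng = np.random.default_rng(0)
layout = netviz_layout(seed=0)
edges = complete_graph_edges(49)
ec_max = count_crossings(layout, edges)
l_max = len(edges)
print(f"complete graph: {l_max} edges, Ec_max = {ec_max} crossings")

for L in (100, 300, 600):
    mc = np.mean(
        [
            count_crossings(layout, edges[rng.choice(l_max, L, replace=False)])
            for _ in range(50)
        ]
    )
    exact = exact_subset_expectation(L, l_max, ec_max)
    law = expected_crossings(L / l_max, ec_max)
    print(f"L={L:4d}  MC mean={mc:9.1f}  exact={exact:9.1f}  Ec_max*rho^2={law:9.1f}")

print()
print("the Monte-Carlo means track the exact subset expectation, which")
print("approaches Ec_max * rho**2 — the scaling that lets crossing counts be")
print("predicted from the complete-graph maximum alone.")
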