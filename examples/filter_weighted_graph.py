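"""Filter a weighted geometric graph to its optimal edge prefix.

Builds a complete 60-node graph whose weights are independent of edge
lengths (the "random" regime), ranks the edges by descending weight, and
keeps the prefix that maximises J = rho**alpha (1 - delta)**beta.
At alpha = 1 the theory predicts an optimal connection density near 0.5.
"""

from econet import FunctionalParams, filter_graph, weight_length_correlation
from econet.synth import geometric_graph

graph = geometric_graph(60, regime="random", seed=7)
result = filter_graph(graph, "weight_desc", FunctionalParams(alpha=1.0))

print(f"nodes: {graph.n_nodes}, candidate edges: {graph.n_edges}")
print(f"weight-length Spearman correlation: {weight_length_correlation(graph):+.3f}")
print(f"optimal prefix: L* = {result.l_star} edges (rho* = {result.rho_star:.3f})")
print(f"removed fraction: {result.removed_fraction:.1%}")
print()
print("rho* near 0.5 is the closed-form optimum alpha/(alpha+1) for")
print("uncorrelated weights and lengths at alpha = 1; the near-zero Spearman")
print("correlation confirms the graph really is in that regime.")
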