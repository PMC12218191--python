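"""Edge ranking, optimal graph filtering, and the least-squares fit of alpha.

Filtering keeps a prefix of a total order over the edges — by descending
weight (the usual "show the strongest connections" criterion), by length
(ascending = short-range emphasis, descending = long-range emphasis), or in
random order — with the prefix size chosen by maximising the benefit-cost
functional ``J`` or by its closed-form optimum for an asserted regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .graph import (
    FunctionalParams,
    SpatialGraph,
    empirical_density_curve,
    functional_J,
    maximize_J_empirical,
    optimal_density,
    phi_from_alpha,
)

__all__ = [
    "EdgeRanking",
    "FilterResult",
    "AlphaFit",
    "rank_edges",
    "filter_graph",
    "fit_alpha",
    "weight_length_correlation",
]

CRITERIA = ("weight_desc", "length_asc", "length_desc", "random")

#: closed-form regime implied by each deterministic ranking criterion
CRITERION_REGIME = {"length_asc": "short", "length_desc": "long", "random": "random"}


@dataclass(frozen=True)
class EdgeRanking:
    """A total order over a graph's edges.

    ``ordered_edges`` is a tuple of canonical ``(node_id, node_id)`` pairs;
    deterministic given ``(graph, criterion, seed)``.
    """

    ordered_edges: tuple
    criterion: str
    seed: int | None = None

    def __len__(self):
        return len(self.ordered_edges)


@dataclass(frozen=True)
class FilterResult:
    params: FunctionalParams
    ranking: EdgeRanking
    alpha: float
    rho_star: float
    l_star: int
    retained_edges: tuple
    removed_fraction: float
    rho_curve: np.ndarray
    delta_curve: np.ndarray
    j_curve: np.ndarray

    def retained_graph(self, graph: SpatialGraph) -> SpatialGraph:
        """The filtered graph (retained edges only, same node set)."""
        keep = {frozenset(e) for e in self.retained_edges}
        edges = [
            (u, v, w)
            for (u, v), w in zip(graph.edge_pairs(), graph.weights)
            if frozenset((u, v)) in keep
        ]
        coords = {u: graph.coords[k] for k, u in enumerate(graph.node_ids)}
        return SpatialGraph.from_edges(coords, edges, metric=graph.metric)


@dataclass(frozen=True)
class AlphaFit:
    alpha_star: float
    phi_star: float | None
    residual: float
    observed_densities: Mapping[str, float]


def rank_edges(graph: SpatialGraph, criterion: str, seed: int | None = None) -> EdgeRanking:
    """Total order over the edges by the given criterion.

    Weight/length ties break by lexicographic (i, j) node-pair order so the
    ranking is reproducible; the random criterion requires a seed.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges to rank")
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
    idx = graph.edge_index
    if criterion == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(graph.n_edges)
    else:
        if criterion == "weight_desc":
            key = -graph.weights
        elif criterion == "length_asc":
            key = graph.edge_lengths()
        else:  # length_desc
            key = -graph.edge_lengths()
        order = np.lexsort((idx[:, 1], idx[:, 0], key))
    pairs = tuple(
        (graph.node_ids[i], graph.node_ids[j]) for i, j in idx[order]
    )
    return EdgeRanking(pairs, criterion, seed)


def weight_length_correlation(graph: SpatialGraph) -> float:
    """Spearman correlation between edge weights and lengths.

    Diagnostic for choosing a closed-form regime: strongly negative means
    short-range (strong edges are short), strongly positive long-range.
    """
    if graph.n_edges < 2:
        raise ValueError("need at least 2 edges")
    return float(stats.spearmanr(graph.weights, graph.edge_lengths()).statistic)


def filter_graph(
    graph: SpatialGraph,
    criterion: str | EdgeRanking,
    params: FunctionalParams,
    mode: str = "empirical",
    seed: int | None = None,
) -> FilterResult:
    """Choose the optimal number of edges to keep along a ranking.

    ``mode="empirical"`` scans every ranking prefix for the exact argmax of
    ``J``; ``mode="closed_form:<regime>"`` uses the regime's analytic optimum
    ``rho*`` and keeps ``round(rho* N(N-1)/2)`` edges (clipped to the edges
    the graph actually has).  The caller asserts the regime; see
    :func:`weight_length_correlation` for a diagnostic.
    """
    if graph.n_edges == 0:
        raise ValueError("cannot filter an empty graph")
    ranking = (
        criterion
        if isinstance(criterion, EdgeRanking)
        else rank_edges(graph, criterion, seed=seed)
    )
    alpha = params.resolve_alpha(graph.n_nodes, graph.s)
    rho_curve, delta_curve = empirical_density_curve(graph, ranking)
    j_curve = functional_J(rho_curve, delta_curve, alpha=alpha, beta=params.beta)
    if mode == "empirical":
        l_star, rho_star = maximize_J_empirical(graph, ranking, params)
    elif mode.startswith("closed_form"):
        try:
            regime = mode.split(":", 1)[1]
        except IndexError:
            raise ValueError("closed_form mode must specify a regime, e.g. 'closed_form:random'")
        rho_star = optimal_density(alpha, regime)
        l_star = int(np.clip(round(rho_star * graph.n_pairs), 0, graph.n_edges))
        rho_star = l_star / graph.n_pairs
    else:
        raise ValueError(f"unknown mode {mode!r}")
    retained = tuple(ranking.ordered_edges[:l_star])
    return FilterResult(
        params=params,
        ranking=ranking,
        alpha=alpha,
        rho_star=rho_star,
        l_star=l_star,
        retained_edges=retained,
        removed_fraction=1.0 - l_star / graph.n_edges,
        rho_curve=rho_curve,
        delta_curve=delta_curve,
        j_curve=j_curve,
    )


def fit_alpha(
    observed: Mapping[str, float],
    bounds: tuple[float, float] = (0.0, 1.0),
    tol: float = 1e-6,
    n_nodes: int | None = None,
    s: int | None = None,
) -> AlphaFit:
    """Bounded least-squares fit of alpha to observed mean densities.

    Minimises ``sum_k (rho_theo,k(alpha) - rho_obs,k)**2`` over the three
    regimes with a bounded scalar minimiser at tolerance ``tol``; a 1e-4-step
    grid refinement guards against local minima.  ``phi_star`` is reported
    when ``n_nodes`` and ``s`` are supplied.
    """
    missing = {"short", "random", "long"} - set(observed)
    if missing:
        raise ValueError(f"observed densities missing regimes: {sorted(missing)}")
    obs = {k: float(observed[k]) for k in ("short", "random", "long")}
    if any(not 0 <= v <= 1 for v in obs.values()):
        raise ValueError("observed densities must lie in [0, 1]")

    def residual(a):
        return sum((optimal_density(a, k) - obs[k]) ** 2 for k in obs)

    res = optimize.minimize_scalar(
        residual, bounds=bounds, method="bounded", options={"xatol": tol}
    )
    grid = np.arange(bounds[0], bounds[1] + 1e-12, 1e-4)
    grid_res = np.array([residual(a) for a in grid])
    a_grid = float(grid[np.argmin(grid_res)])
    alpha_star = float(res.x) if residual(res.x) <= residual(a_grid) else a_grid
    phi_star = (
        phi_from_alpha(alpha_star, n_nodes, s)
        if (n_nodes is not None and s is not None and alpha_star > 0)
        else None
    )
    return AlphaFit(alpha_star, phi_star, float(residual(alpha_star)), obs)
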