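"""Core data model for weighted geometric graphs and the benefit-cost functional.

A spatial network is an undirected, positively weighted graph whose nodes carry
positions in a Euclidean ``s``-dimensional space.  Two densities summarise it:

* the connection density ``rho = 2L / (N(N-1))`` — the fraction of realised
  edges out of all node pairs, and
* the spatial density ``delta`` — the cumulative Euclidean length of the
  present edges divided by the cumulative length of *all* node pairs.

The benefit-cost functional ``J = rho**alpha * (1 - delta)**beta`` trades the
benefit of showing many connections against the progressive cost of their
cumulative length; maximising ``J`` over how many edges to keep is the
filtering criterion implemented in :mod:`econet.filtering`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "DegenerateGeometryError",
    "SpatialGraph",
    "FunctionalParams",
    "connection_density",
    "spatial_density",
    "functional_J",
    "expected_delta",
    "optimal_density",
    "scaled_alpha",
    "phi_from_alpha",
    "empirical_density_curve",
    "maximize_J_empirical",
]

REGIMES = ("random", "short", "long")

_EARTH_RADIUS_KM = 6371.0


class DegenerateGeometryError(ValueError):
    """Raised when a geometric computation is undefined for the given layout."""


def _haversine_pairs(lonlat: np.ndarray) -> np.ndarray:
    """Condensed great-circle distance matrix (km) for (lon, lat) rows in degrees."""
    rad = np.radians(lonlat)
    lon, lat = rad[:, 0], rad[:, 1]
    i, j = np.triu_indices(len(lonlat), 1)
    dlat = lat[j] - lat[i]
    dlon = lon[j] - lon[i]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat[i]) * np.cos(lat[j]) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass(frozen=True)
class SpatialGraph:
    """Undirected weighted graph with node positions.

    Parameters
    ----------
    node_ids
        Opaque node identifiers (stored as strings).
    coords
        Array of shape ``(N, s)`` with one position per node.
    edge_index
        Integer array of shape ``(L, 2)``, each row ``(i, j)`` with ``i < j``
        indexing into ``node_ids``.
    weights
        Strictly positive edge weights, shape ``(L,)``.
    metric
        ``"euclidean"`` (default) or ``"geodesic"``; the latter treats
        coordinates as (longitude, latitude) in degrees and measures
        great-circle distances.
    """

    node_ids: tuple
    coords: np.ndarray
    edge_index: np.ndarray
    weights: np.ndarray
    metric: str = "euclidean"
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[0] != len(self.node_ids):
            raise ValueError("coords must be (N, s) with one row per node")
        if coords.shape[1] < 1:
            raise ValueError("embedding dimension s must be >= 1")
        if not np.all(np.isfinite(coords)):
            raise ValueError("all coordinates must be finite")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")
        if self.metric not in ("euclidean", "geodesic"):
            raise ValueError(f"unknown metric {self.metric!r}")
        edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(edge_index) != len(weights):
            raise ValueError("edge_index and weights length mismatch")
        if len(edge_index):
            if edge_index.min() < 0 or edge_index.max() >= len(self.node_ids):
                raise ValueError("edge references unknown node")
            if np.any(edge_index[:, 0] == edge_index[:, 1]):
                raise ValueError("self-loops are not allowed")
            if np.any(edge_index[:, 0] > edge_index[:, 1]):
                raise ValueError("edges must be canonically ordered i < j")
            key = edge_index[:, 0] * len(self.node_ids) + edge_index[:, 1]
            if len(np.unique(key)) != len(key):
                raise ValueError("duplicate edges")
            if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
                raise ValueError("weights must be strictly positive and finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "edge_index", edge_index)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(
            self, "_index", {u: k for k, u in enumerate(self.node_ids)}
        )

    @classmethod
    def from_edges(
        cls,
        coords: Mapping[str, Sequence[float]],
        edges: Iterable[tuple],
        metric: str = "euclidean",
    ) -> "SpatialGraph":
        """Build from a mapping ``node -> position`` and ``(u, v, w)`` triples.

        Reciprocal/duplicate pairs are merged by summing their weights
        (symmetrisation, as for directed route tables).
        """
        node_ids = tuple(str(u) for u in coords)
        index = {u: k for k, u in enumerate(node_ids)}
        xy = np.asarray([coords[u] for u in coords], dtype=float)
        if xy.ndim == 1:
            xy = xy[:, None]
        merged: dict = {}
        for item in edges:
            u, v, w = item[0], item[1], (item[2] if len(item) > 2 else 1.0)
            i, j = index[str(u)], index[str(v)]
            if i == j:
                raise ValueError(f"self-loop on node {u!r}")
            if i > j:
                i, j = j, i
            merged[(i, j)] = merged.get((i, j), 0.0) + float(w)
        if merged:
            pairs = np.array(sorted(merged), dtype=np.int64)
            ws = np.array([merged[tuple(p)] for p in pairs])
        else:
            pairs = np.empty((0, 2), dtype=np.int64)
            ws = np.empty(0)
        return cls(node_ids, xy, pairs, ws, metric=metric)

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    @property
    def s(self) -> int:
        return self.coords.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def node_index(self, u) -> int:
        return self._index[str(u)]

    def edge_pairs(self) -> list:
        """Edges as (node_id, node_id) tuples in canonical order."""
        return [
            (self.node_ids[i], self.node_ids[j]) for i, j in self.edge_index
        ]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edge_index[:, 0], 1)
            np.add.at(deg, self.edge_index[:, 1], 1)
        return deg

    # -------------------------------------------------------------- geometry
    def pairwise_lengths(self) -> np.ndarray:
        """Condensed distance vector over all node pairs (scipy ordering)."""
        if self.metric == "geodesic":
            return _haversine_pairs(self.coords)
        return pdist(self.coords)

    def _pair_position(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Index of pair (i < j) in the condensed distance vector."""
        n = self.n_nodes
        return (i * (2 * n - i - 1)) // 2 + (j - i - 1)

    def edge_lengths(self, edge_index: np.ndarray | None = None) -> np.ndarray:
        idx = self.edge_index if edge_index is None else np.asarray(edge_index)
        if len(idx) == 0:
            return np.empty(0)
        if self.metric == "geodesic":
            lengths = _haversine_pairs(self.coords)
            return lengths[self._pair_position(idx[:, 0], idx[:, 1])]
        d = self.coords[idx[:, 0]] - self.coords[idx[:, 1]]
        return np.sqrt((d**2).sum(axis=1))

    def total_pairwise_length(self) -> float:
        total = float(self.pairwise_lengths().sum())
        if total == 0.0:
            raise DegenerateGeometryError(
                "all node positions coincide; spatial density undefined"
            )
        return total

    def resolve_pairs(self, pairs: Iterable[tuple]) -> np.ndarray:
        """Convert (u, v) node-id pairs to a canonical (K, 2) index array."""
        out = []
        for u, v in pairs:
            try:
                i, j = self._index[str(u)], self._index[str(v)]
            except KeyError as exc:
                raise ValueError(f"unknown node in pair ({u!r}, {v!r})") from exc
            if i == j:
                raise ValueError(f"pair ({u!r}, {v!r}) is a self-loop")
            out.append((i, j) if i < j else (j, i))
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)


@dataclass(frozen=True)
class FunctionalParams:
    """Exponents of the benefit-cost functional ``J = rho**alpha (1-delta)**beta``.

    ``alpha`` scales the benefit of connection density, ``beta`` the cost of
    cumulative edge length.  ``phi`` is the size-free filtering constant tied
    to ``alpha`` through ``alpha = phi * N**(-1/s)``; supply either ``alpha``
    directly or ``phi`` (resolved against a graph's ``N`` and ``s``).
    """

    alpha: float | None = None
    beta: float = 1.0
    phi: float | None = None

    def __post_init__(self):
        if self.alpha is None and self.phi is None:
            raise ValueError("provide alpha or phi")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.phi is not None and self.phi <= 0:
            raise ValueError("phi must be > 0")

    def resolve_alpha(self, n_nodes: int | None = None, s: int | None = None) -> float:
        if self.alpha is not None:
            return float(self.alpha)
        if n_nodes is None or s is None:
            raise ValueError("resolving phi to alpha requires N and s")
        return scaled_alpha(self.phi, n_nodes, s)


# ---------------------------------------------------------------- densities

def connection_density(graph: SpatialGraph) -> float:
    """Fraction of realised edges: ``rho = 2L / (N(N-1))``."""
    if graph.n_nodes < 2:
        raise ValueError("connection density requires at least 2 nodes")
    return 2 * graph.n_edges / (graph.n_nodes * (graph.n_nodes - 1))


def spatial_density(graph: SpatialGraph, edges: Iterable[tuple] | None = None) -> float:
    """Cumulative length of ``edges`` over the cumulative length of all pairs.

    ``edges`` may be any subset of node pairs (defaults to the graph's own
    edge set).  Equals 1 for the complete pair set and 0 for the empty one.
    """
    if graph.n_nodes < 2:
        raise ValueError("spatial density requires at least 2 nodes")
    total = graph.total_pairwise_length()
    if edges is None:
        idx = graph.edge_index
    else:
        idx = graph.resolve_pairs(edges)
    if len(idx) == 0:
        return 0.0
    return float(graph.edge_lengths(idx).sum() / total)


# --------------------------------------------------------------- functional

def functional_J(rho, delta, params: FunctionalParams | None = None, *,
                 alpha: float | None = None, beta: float | None = None):
    """Benefit-cost functional ``J = rho**alpha * (1 - delta)**beta``.

    Convention ``0**0 = 1`` so that ``alpha = 0`` degrades continuously to a
    pure cost term.  Accepts scalars or arrays.
    """
    if params is not None:
        alpha, beta = params.resolve_alpha(), params.beta
    if alpha is None or beta is None:
        raise ValueError("provide params or alpha/beta")
    rho = np.asarray(rho, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1) or np.any(delta < 0) or np.any(delta > 1):
        raise ValueError("rho and delta must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        benefit = np.where(rho == 0, 0.0 if alpha > 0 else 1.0, rho**alpha)
        comp = 1.0 - delta
        cost = np.where(comp == 0, 0.0 if beta > 0 else 1.0, comp**beta)
    out = benefit * cost
    return float(out) if out.ndim == 0 else out


def expected_delta(rho, regime: str):
    """Expected spatial density at connection density ``rho``.

    ``random``: edge lengths are sampled uniformly at random, so
    ``delta = rho``.  ``short`` / ``long``: perfect (anti)correlation between
    weight and length selects the shortest / longest lengths first; for a
    uniform length spectrum order statistics give ``delta = rho**2`` and
    ``delta = 2 rho - rho**2`` respectively.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    if regime == "random":
        out = rho
    elif regime == "short":
        out = rho**2
    elif regime == "long":
        out = 2 * rho - rho**2
    else:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    return float(out) if out.ndim == 0 else out


def optimal_density(alpha: float, regime: str) -> float:
    """Closed-form density maximising ``J`` at ``beta = 1``.

    Obtained from ``dJ/drho = 0`` after substituting the regime's
    ``delta(rho)`` relation:

    * random: ``rho* = alpha / (alpha + 1)``
    * long:   ``rho* = alpha / (alpha + 2)``
    * short:  ``rho* = sqrt(alpha / (alpha + 2))``

    For every ``alpha > 0`` these are ordered ``long <= random <= short``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if regime == "random":
        return alpha / (alpha + 1.0)
    if regime == "long":
        return alpha / (alpha + 2.0)
    if regime == "short":
        return math.sqrt(alpha / (alpha + 2.0))
    raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")


def scaled_alpha(phi: float, n_nodes: int, s: int) -> float:
    """Size-scaled filtering exponent ``alpha = phi * N**(-1/s)``."""
    if phi <= 0:
        raise ValueError("phi must be > 0")
    if n_nodes < 1 or s < 1:
        raise ValueError("require N >= 1 and s >= 1")
    return phi * n_nodes ** (-1.0 / s)


def phi_from_alpha(alpha: float, n_nodes: int, s: int) -> float:
    """Inverse conversion ``phi = alpha * N**(1/s)``."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if n_nodes < 1 or s < 1:
        raise ValueError("require N >= 1 and s >= 1")
    return alpha * n_nodes ** (1.0 / s)


# ---------------------------------------------------- empirical density curve

def empirical_density_curve(graph: SpatialGraph, ranking) -> tuple[np.ndarray, np.ndarray]:
    """``(rho, delta)`` along the prefixes of an edge ranking.

    Entry ``k`` corresponds to keeping the first ``k`` ranked edges,
    ``k = 0 .. L``.  ``delta`` is nondecreasing by construction.
    """
    idx = _ranking_index(graph, ranking)
    total = graph.total_pairwise_length()
    lengths = graph.edge_lengths(idx)
    delta = np.concatenate([[0.0], np.cumsum(lengths)]) / total
    rho = np.arange(len(idx) + 1) / graph.n_pairs
    return rho, np.clip(delta, 0.0, 1.0)


def _ranking_index(graph: SpatialGraph, ranking) -> np.ndarray:
    """Validate a ranking against the graph and return its (L, 2) index array."""
    ordered = getattr(ranking, "ordered_edges", ranking)
    idx = graph.resolve_pairs(ordered)
    if len(idx) != graph.n_edges:
        raise ValueError("ranking must cover exactly the graph's edges")
    n = graph.n_nodes
    if set(map(tuple, idx)) != set(map(tuple, graph.edge_index)):
        raise ValueError("ranking edges do not match the graph's edge set")
    del n
    return idx


def maximize_J_empirical(
    graph: SpatialGraph, ranking, params: FunctionalParams
) -> tuple[int, float]:
    """Prefix length (and its density) maximising ``J`` along a ranking.

    Scans every prefix ``L = 0 .. L_total`` exactly; ties break toward the
    smallest ``L`` (the sparser representation).
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    alpha = params.resolve_alpha(graph.n_nodes, graph.s)
    rho, delta = empirical_density_curve(graph, ranking)
    J = functional_J(rho, delta, alpha=alpha, beta=params.beta)
    l_star = int(np.argmax(J))
    return l_star, float(rho[l_star])
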