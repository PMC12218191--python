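"""Edge-crossing counting and the density-squared scaling law.

A crossing is a *proper* interior intersection of two straight edges drawn on
a 2D layout: the segments cross transversally at a point interior to both.
Pairs sharing an endpoint never count; configurations that merely touch
(an endpoint on another edge's interior, or collinear overlap) are degenerate
for a drawing "in general position" and raise
:class:`~econet.graph.DegenerateGeometryError` — callers may jitter the
layout instead of silently resolving ties.

For a uniformly random subset of ``L`` of the ``L_max`` complete-graph edges,
each complete-graph crossing survives with probability
``L(L-1) / (L_max(L_max-1))``, so the expected crossing count is
``Ec_max * L(L-1)/(L_max(L_max-1)) -> Ec_max * rho**2`` for large layouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import DegenerateGeometryError

__all__ = [
    "count_crossings",
    "count_crossings_brute",
    "crossing_pairs",
    "expected_crossings",
    "exact_subset_expectation",
    "complete_graph_edges",
    "crossing_profile",
    "CrossingProfile",
]

_EPS = 1e-12

#: brute force is used below this edge count, the plane sweep above
SWEEP_THRESHOLD = 200


def _validate(coords: np.ndarray, edges: np.ndarray):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("crossing counts require 2D coordinates")
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if len(edges) and (edges.min() < 0 or edges.max() >= len(coords)):
        raise ValueError("edge references unknown node")
    if len(edges) and np.any(edges[:, 0] == edges[:, 1]):
        raise ValueError("self-loops are not valid edges")
    return coords, edges


def _pair_status(P, Q, R, S, scale):
    """Classify segment pairs (P-Q vs R-S): 1 = proper crossing, -1 = degenerate.

    Vectorised orientation predicate with a relative epsilon; assumes no pair
    shares an endpoint (filtered by the callers on node identity).
    """
    def cross(o, a, b):
        return (a[:, 0] - o[:, 0]) * (b[:, 1] - o[:, 1]) - (a[:, 1] - o[:, 1]) * (
            b[:, 0] - o[:, 0]
        )

    eps = _EPS * max(scale * scale, 1.0)
    o1 = cross(P, Q, R)
    o2 = cross(P, Q, S)
    o3 = cross(R, S, P)
    o4 = cross(R, S, Q)
    near_zero = (
        (np.abs(o1) <= eps)
        | (np.abs(o2) <= eps)
        | (np.abs(o3) <= eps)
        | (np.abs(o4) <= eps)
    )
    # bounding boxes must interact for a near-zero orientation to mean contact
    def boxes_touch():
        lo1 = np.minimum(P, Q) - eps
        hi1 = np.maximum(P, Q) + eps
        lo2 = np.minimum(R, S) - eps
        hi2 = np.maximum(R, S) + eps
        return np.all((lo1 <= hi2) & (lo2 <= hi1), axis=1)

    degenerate = near_zero & boxes_touch()
    proper = (~near_zero) & (o1 * o2 < 0) & (o3 * o4 < 0)
    status = np.zeros(len(P), dtype=np.int8)
    status[proper] = 1
    status[degenerate] = -1
    return status


def count_crossings_brute(coords, edges) -> int:
    """O(L^2) pairwise crossing count; oracle for the sweep-line path."""
    return len(crossing_pairs(coords, edges, method="brute"))


def count_crossings(coords, edges) -> int:
    """Number of properly crossing edge pairs on a 2D layout.

    Dispatches to the brute-force path below ``SWEEP_THRESHOLD`` edges and to
    the plane sweep above it; the two agree exactly by contract.
    """
    return len(crossing_pairs(coords, edges))


def crossing_pairs(coords, edges, method: str | None = None) -> np.ndarray:
    """Indices ``(a, b)`` of edge pairs that properly cross (a < b)."""
    coords, edges = _validate(coords, edges)
    L = len(edges)
    if L < 2:
        return np.empty((0, 2), dtype=np.int64)
    if method is None:
        method = "brute" if L < SWEEP_THRESHOLD else "sweep"
    scale = float(np.abs(coords).max())
    if method == "brute":
        a, b = np.triu_indices(L, 1)
        mask = ~_shares_endpoint(edges[a], edges[b])
        a, b = a[mask], b[mask]
        status = _pair_status(
            coords[edges[a, 0]], coords[edges[a, 1]],
            coords[edges[b, 0]], coords[edges[b, 1]], scale,
        )
        _raise_if_degenerate(status)
        keep = status == 1
        return np.column_stack([a[keep], b[keep]])
    if method != "sweep":
        raise ValueError(f"unknown method {method!r}")
    return _sweep_pairs(coords, edges, scale)


def _shares_endpoint(e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    return (
        (e1[:, 0] == e2[:, 0])
        | (e1[:, 0] == e2[:, 1])
        | (e1[:, 1] == e2[:, 0])
        | (e1[:, 1] == e2[:, 1])
    )


def _raise_if_degenerate(status: np.ndarray):
    if np.any(status == -1):
        raise DegenerateGeometryError(
            "layout is not in general position (touching or collinear "
            "overlapping edges); jitter the coordinates to resolve"
        )


def _sweep_pairs(coords, edges, scale) -> np.ndarray:
    """Plane sweep over x: test each segment against the segments whose
    x-interval overlaps it.  Exact (same predicate as brute force)."""
    x = coords[:, 0][edges]
    xmin = x.min(axis=1)
    xmax = x.max(axis=1)
    order = np.argsort(xmin, kind="stable")
    active: list[int] = []
    out_a: list[np.ndarray] = []
    out_b: list[np.ndarray] = []
    for e in order:
        lo = xmin[e]
        if active:
            act = np.asarray(active)
            alive = xmax[act] >= lo
            act = act[alive]
            active = act.tolist()
            if len(act):
                mask = ~_shares_endpoint(edges[act], np.broadcast_to(edges[e], (len(act), 2)))
                cand = act[mask]
                if len(cand):
                    status = _pair_status(
                        coords[edges[cand, 0]], coords[edges[cand, 1]],
                        np.broadcast_to(coords[edges[e, 0]], (len(cand), 2)),
                        np.broadcast_to(coords[edges[e, 1]], (len(cand), 2)),
                        scale,
                    )
                    _raise_if_degenerate(status)
                    hit = cand[status == 1]
                    if len(hit):
                        out_a.append(np.minimum(hit, e))
                        out_b.append(np.maximum(hit, e))
        active.append(int(e))
    if not out_a:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.column_stack([np.concatenate(out_a), np.concatenate(out_b)])
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def expected_crossings(rho: float, ec_max: float) -> float:
    """Density-squared scaling law ``Ec = Ec_max * rho**2``."""
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    if ec_max < 0:
        raise ValueError("ec_max must be >= 0")
    return ec_max * rho * rho


def exact_subset_expectation(l_edges: int, l_max: int, ec_max: float) -> float:
    """Exact expected crossings of a uniform ``l_edges``-subset of ``l_max`` edges.

    Each complete-layout crossing pair survives with probability
    ``L(L-1) / (L_max(L_max-1))``.
    """
    if l_max < 2 or not 0 <= l_edges <= l_max:
        raise ValueError("require 0 <= L <= L_max and L_max >= 2")
    return ec_max * l_edges * (l_edges - 1) / (l_max * (l_max - 1))


def complete_graph_edges(n: int) -> np.ndarray:
    """All node pairs (i < j) of an n-node layout."""
    i, j = np.triu_indices(n, 1)
    return np.column_stack([i, j]).astype(np.int64)


@dataclass(frozen=True)
class CrossingProfile:
    """Mean crossing count as a function of the number of displayed edges."""

    regime: str
    per_l_mean: np.ndarray
    n_samples: int
    ec_max: float
    seed: int | None = None


def crossing_profile(
    layout,
    regime: str,
    n_samples: int = 100,
    seed: int | None = None,
) -> CrossingProfile:
    """Per-L mean crossing counts along a ranking regime.

    ``layout`` is either a fixed ``(N, 2)`` coordinate array or a callable
    ``layout(rng) -> coords`` sampling a fresh (e.g. jittered) layout per
    repetition.  The ranking orders all ``N(N-1)/2`` edges by length
    (``short`` = ascending, ``long`` = descending) or uniformly at random;
    entry ``L`` of the profile is the mean crossing count of the first ``L``
    ranked edges over ``n_samples`` repetitions.
    """
    if regime not in ("short", "long", "random"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    fixed = None if callable(layout) else np.asarray(layout, dtype=float)
    fixed_pairs = None
    per_l = None
    for _ in range(n_samples):
        coords = layout(rng) if callable(layout) else fixed
        edges = complete_graph_edges(len(coords))
        if callable(layout) or fixed_pairs is None:
            pairs = crossing_pairs(coords, edges)
            if not callable(layout):
                fixed_pairs = pairs
        else:
            pairs = fixed_pairs
        if regime == "random":
            order = rng.permutation(len(edges))
        else:
            d = coords[edges[:, 0]] - coords[edges[:, 1]]
            lengths = (d**2).sum(axis=1)
            order = np.argsort(lengths if regime == "short" else -lengths, kind="stable")
        pos = np.empty(len(edges), dtype=np.int64)
        pos[order] = np.arange(len(edges))
        counts = np.zeros(len(edges) + 1)
        if len(pairs):
            # a crossing appears once both its edges are displayed
            born = np.maximum(pos[pairs[:, 0]], pos[pairs[:, 1]]) + 1
            counts[1:] = np.cumsum(np.bincount(born, minlength=len(edges) + 1))[1:]
        per_l = counts if per_l is None else per_l + counts
    per_l /= n_samples
    return CrossingProfile(regime, per_l, n_samples, float(per_l[-1]), seed)
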