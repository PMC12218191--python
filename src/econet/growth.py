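"""Benefit-cost spatial growth models.

A newcomer ``i`` attaches to an existing node ``j`` with probability

    pi_ij = k_hat_j**alpha * (1 - d_hat_ij)**beta

where ``k_hat_j`` is ``j``'s degree and ``d_hat_ij`` the internode distance,
each normalised by its current maximum in the existing network.  To first
order ``pi ~ k_hat - k_hat * beta * d_hat``: the cost per length unit grows
with the target's degree, the growth analogue of the progressive cost in the
filtering functional.

Two constructions are provided:

* **plain** — each arrival places ``m`` edges to distinct targets drawn
  without replacement with probability proportional to ``pi``; the edge count
  is deterministic, ``L = N0(N0-1)/2 + m (N - N0)``.  ``alpha = beta = 0``
  recovers uniform attachment, ``alpha = 1, beta = 0`` linear preferential
  attachment.
* **accelerated** — nodes arrive on a prescribed schedule with fixed
  positions and *hidden* target degrees (e.g. a connectome's adult-stage
  degrees); each newcomer links to every existing node by an independent
  Bernoulli draw with probability ``pi``, so the final edge count is a random
  variable (the quantity the first calibration stage targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .graph import SpatialGraph

__all__ = [
    "GrowthConfig",
    "GrownNetwork",
    "attachment_probability",
    "grow_network",
    "grow_accelerated",
    "unit_disk_sampler",
    "disk_distance_pdf",
    "distance_distribution_reference",
]


def unit_disk_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """``n`` points uniform on the 2D unit disk."""
    r = np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of the growth process.

    Plain mode requires ``m``, ``n_nodes``, ``n0``; accelerated mode requires
    ``positions`` (arrival order = row order), ``hidden_degrees`` and ignores
    ``m``/``n0``/``space_sampler``.
    """

    alpha: float
    beta: float
    mode: str = "plain"
    m: int = 5
    n_nodes: int = 2000
    n0: int = 6
    space_sampler: Callable[[np.random.Generator, int], np.ndarray] = field(
        default=unit_disk_sampler
    )
    positions: np.ndarray | None = None
    hidden_degrees: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.mode not in ("plain", "accelerated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "plain":
            if self.n0 < 2:
                raise ValueError("seed size n0 must be >= 2")
            if self.m > self.n0:
                raise ValueError("m must not exceed the seed size n0")
            if self.n_nodes <= self.n0:
                raise ValueError("final size N must exceed n0")
        else:
            if self.positions is None or self.hidden_degrees is None:
                raise ValueError(
                    "accelerated mode requires positions and hidden_degrees"
                )
            k = np.asarray(self.hidden_degrees, dtype=float)
            if len(k) != len(np.asarray(self.positions)):
                raise ValueError("one hidden degree per node required")
            if np.any(k <= 0) or not np.all(np.isfinite(k)):
                raise ValueError("hidden degrees must be positive and finite")


@dataclass(frozen=True)
class GrownNetwork:
    graph: SpatialGraph
    arrival_index: np.ndarray
    config: GrowthConfig

    def degrees(self) -> np.ndarray:
        return self.graph.degrees()

    def edge_lengths(self) -> np.ndarray:
        return self.graph.edge_lengths()


def attachment_probability(k_hat, d_hat, alpha: float, beta: float):
    """``pi = k_hat**alpha * (1 - d_hat)**beta`` with the 0**0 = 1 convention."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    k_hat = np.asarray(k_hat, dtype=float)
    d_hat = np.asarray(d_hat, dtype=float)
    if np.any(k_hat < 0) or np.any(k_hat > 1) or np.any(d_hat < 0) or np.any(d_hat > 1):
        raise ValueError("k_hat and d_hat must lie in [0, 1]")
    benefit = np.where(k_hat == 0, 0.0 if alpha > 0 else 1.0, k_hat**alpha)
    comp = 1.0 - d_hat
    cost = np.where(comp == 0, 0.0 if beta > 0 else 1.0, comp**beta)
    out = benefit * cost
    return float(out) if out.ndim == 0 else out


def _as_grown(coords: np.ndarray, edges: list, n: int, config: GrowthConfig,
              node_ids: Sequence[str] | None = None) -> GrownNetwork:
    ids = tuple(node_ids) if node_ids is not None else tuple(str(k) for k in range(n))
    pairs = np.asarray(
        [(i, j) if i < j else (j, i) for i, j in edges], dtype=np.int64
    ).reshape(-1, 2)
    graph = SpatialGraph(ids, coords, pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))],
                         np.ones(len(pairs)))
    return GrownNetwork(graph, np.arange(n), config)


def grow_network(config: GrowthConfig) -> GrownNetwork:
    """Plain fixed-``m`` growth from a fully connected seed."""
    if config.mode != "plain":
        raise ValueError("grow_network requires mode='plain'")
    rng = np.random.default_rng(config.seed)
    n, n0, m = config.n_nodes, config.n0, config.m
    coords = np.empty((n, 2))
    coords[:n0] = config.space_sampler(rng, n0)
    deg = np.zeros(n, dtype=np.int64)
    deg[:n0] = n0 - 1
    edges = [(i, j) for i in range(n0) for j in range(i + 1, n0)]
    max_dist = float(pdist(coords[:n0]).max()) if n0 > 1 else 0.0
    for t in range(n0, n):
        pos = config.space_sampler(rng, 1)[0]
        coords[t] = pos
        diff = coords[:t] - pos
        dists = np.sqrt((diff**2).sum(axis=1))
        d_hat = np.minimum(dists / max_dist, 1.0) if max_dist > 0 else np.zeros(t)
        k_hat = deg[:t] / deg[:t].max()
        pi = attachment_probability(k_hat, d_hat, config.alpha, config.beta)
        nonzero = np.count_nonzero(pi)
        if nonzero >= m:
            targets = rng.choice(t, size=m, replace=False, p=pi / pi.sum())
        elif nonzero == 0:
            # all candidates at zero probability: fall back to uniform
            targets = rng.choice(t, size=m, replace=False)
        else:
            # keep every positive-probability target, fill the rest uniformly
            pos = np.nonzero(pi)[0]
            rest = np.setdiff1d(np.arange(t), pos)
            fill = rng.choice(rest, size=m - nonzero, replace=False)
            targets = np.concatenate([pos, fill])
        for j in targets:
            edges.append((int(j), t))
        deg[targets] += 1
        deg[t] = m
        max_dist = max(max_dist, float(dists.max()))
    return _as_grown(coords, edges, n, config)


def grow_accelerated(config: GrowthConfig, node_ids: Sequence[str] | None = None) -> GrownNetwork:
    """Hidden-variable accelerated growth on a prescribed arrival schedule."""
    if config.mode != "accelerated":
        raise ValueError("grow_accelerated requires mode='accelerated'")
    rng = np.random.default_rng(config.seed)
    coords = np.asarray(config.positions, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    k = np.asarray(config.hidden_degrees, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    edges: list = []
    max_dist = 0.0
    for t in range(1, n):
        diff = coords[:t] - coords[t]
        dists = np.sqrt((diff**2).sum(axis=1))
        # normalise by the max pairwise distance among already-placed nodes,
        # clipping when the newcomer exceeds it
        d_hat = np.minimum(dists / max_dist, 1.0) if max_dist > 0 else np.zeros(t)
        max_dist = max(max_dist, float(dists.max()))
        k_hat = k[:t] / k[:t].max()
        pi = attachment_probability(k_hat, d_hat, config.alpha, config.beta)
        hit = np.nonzero(rng.random(t) < pi)[0]
        edges.extend((int(j), t) for j in hit)
    return _as_grown(coords, edges, n, config, node_ids)


# ------------------------------------------------------------ disk reference

def disk_distance_pdf(d, radius: float = 1.0):
    """Density of the distance between two uniform points on a disk.

    ``f(d) = (2d/R^2) * (2/pi) * (acos(d/2R) - (d/2R) sqrt(1 - d^2/4R^2))``
    on ``[0, 2R]``.
    """
    d = np.asarray(d, dtype=float)
    x = np.clip(d / (2 * radius), 0.0, 1.0)
    f = (2 * d / radius**2) * (2 / np.pi) * (np.arccos(x) - x * np.sqrt(1 - x**2))
    out = np.where((d < 0) | (d > 2 * radius), 0.0, f)
    return float(out) if out.ndim == 0 else out


def distance_distribution_reference(
    bin_edges: np.ndarray, domain: str = "unit_disk"
) -> np.ndarray:
    """Reference pairwise-distance probability mass per histogram bin.

    Integrates the closed-form density over each bin (Simpson on a fine grid)
    so it can be compared directly with a normalised empirical histogram.
    """
    if domain != "unit_disk":
        raise ValueError(f"unsupported domain {domain!r}")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least 2 entries")
    from scipy.integrate import quad

    mass = np.array(
        [quad(disk_distance_pdf, lo, hi, limit=100)[0] for lo, hi in zip(edges[:-1], edges[1:])]
    )
    return mass
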