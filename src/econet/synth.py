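"""Synthetic geometric graphs and layouts for experiments and tests.

Three weight-length regimes are supported, mirroring the characteristic
scenarios of the filtering theory:

* ``random`` — weights independent of lengths,
* ``short``  — perfect anticorrelation (strongest edges are shortest),
* ``long``   — perfect correlation (strongest edges are longest).

The closed-form density relations ``delta = rho**2`` and
``delta = 2 rho - rho**2`` are order-statistics results that hold when the
pairwise-distance spectrum is uniform; :func:`uniform_distance_layout`
constructs genuine 2D point sets with that property (by quantile-matching
the sorted distances during a quasi-Newton adjustment of the positions), so
that simulations can be run under exactly the assumption the theory makes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

from .graph import SpatialGraph

__all__ = [
    "uniform_points",
    "geometric_graph",
    "uniform_distance_layout",
    "toy_connectome",
]


def uniform_points(
    n: int, domain: str = "square", s: int = 2, seed: int | None = None
) -> np.ndarray:
    """IID uniform points on the unit square/cube (any ``s``) or the 2D unit disk."""
    rng = np.random.default_rng(seed)
    if domain == "square":
        return rng.random((n, s))
    if domain == "disk":
        if s != 2:
            raise ValueError("the disk domain is two-dimensional")
        r = np.sqrt(rng.random(n))
        th = rng.random(n) * 2 * np.pi
        return np.column_stack([r * np.cos(th), r * np.sin(th)])
    raise ValueError(f"unknown domain {domain!r}")


def geometric_graph(
    coords: np.ndarray | int,
    regime: str = "random",
    seed: int | None = None,
    domain: str = "square",
) -> SpatialGraph:
    """Complete weighted graph on a point set with a chosen weight-length regime.

    ``coords`` may be an ``(N, s)`` array or a node count (points then drawn
    uniformly from ``domain``).  Weights are strictly positive and, in the
    short/long regimes, a strictly monotone function of edge length; in the
    random regime they are iid uniform, independent of geometry.
    """
    rng = np.random.default_rng(seed)
    if isinstance(coords, (int, np.integer)):
        coords = uniform_points(int(coords), domain=domain,
                                seed=int(rng.integers(2**31)))
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    i, j = np.triu_indices(n, 1)
    d = pdist(coords)
    if regime == "random":
        w = rng.random(len(d)) + 1e-9
    elif regime == "short":
        w = d.max() - d + 1e-9 * d.max() + 1e-12
    elif regime == "long":
        w = d.copy()
    else:
        raise ValueError(f"unknown regime {regime!r}")
    ids = {str(k): coords[k] for k in range(n)}
    return SpatialGraph.from_edges(
        ids, zip(map(str, i), map(str, j), w)
    )


def _uniform_spectrum_objective(flat, n, target):
    X = flat.reshape(n, 2)
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, 1)
    dv = d[iu]
    order = np.argsort(dv, kind="stable")
    t = np.empty_like(dv)
    t[order] = target
    r = dv - t
    f = np.sum(r**2)
    w = np.zeros((n, n))
    w[iu] = 2 * r / np.maximum(dv, 1e-12)
    w = w + w.T
    g = (w[:, :, None] * diff).sum(axis=1)
    return f, g.ravel()


def uniform_distance_layout(
    n: int, seed: int | None = None, max_iter: int = 3000
) -> np.ndarray:
    """2D point set whose pairwise-distance spectrum is ~uniform on (0, 1).

    Starting from iid uniform points, positions are adjusted by L-BFGS so the
    sorted distances match the uniform quantiles ``k / (M + 1)``,
    ``M = N(N-1)/2``.  Residual deviations are O(1e-2) in sup norm on the
    distance CDF for moderate ``n``.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    x0 = rng.random((n, 2))
    m = n * (n - 1) // 2
    target = np.arange(1, m + 1) / (m + 1)
    res = minimize(
        _uniform_spectrum_objective, x0.ravel(), args=(n, target), jac=True,
        method="L-BFGS-B", options={"maxiter": max_iter},
    )
    return res.x.reshape(n, 2)


def toy_connectome(
    n: int = 200,
    degree_exponent: float = 2.5,
    k_min: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic arrival schedule for the accelerated growth model.

    Emulates the shape of a small connectome's growth inputs: 1D positions
    uniform on [0, 1] (a worm-like longitudinal axis), power-law hidden
    (adult-stage) degrees with exponent ``degree_exponent``, and a random
    birth order.  Columns: ``node_id, birth_order, x, hidden_degree``.
    """
    rng = np.random.default_rng(seed)
    x = rng.random(n)
    # discrete power-law degrees via inverse transform, capped at n - 1
    u = rng.random(n)
    k = np.floor(k_min * (1 - u) ** (-1.0 / (degree_exponent - 1.0))).astype(int)
    k = np.clip(k, k_min, n - 1)
    order = rng.permutation(n)
    df = pd.DataFrame(
        {
            "node_id": [f"n{i}" for i in range(n)],
            "birth_order": np.argsort(order),
            "x": x,
            "hidden_degree": k,
        }
    )
    return df.sort_values("birth_order").reset_index(drop=True)
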