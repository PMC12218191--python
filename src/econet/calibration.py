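"""Two-step calibration of the growth model against a reference network.

Stage 1 scans an ``(alpha, beta)`` grid (log-spaced over [1e-3, 1e3] by
default) and keeps the combinations whose ensemble-mean edge count matches
the reference within a relative error ``eps_dif = |<L_sim> - L| / L < 0.05``.
Stage 2 refines inside the bounding box of that feasible set with a
global-best particle swarm, minimising
``eps_div = max(JS(P(k)), JS(P(d)))`` — the larger of the Jensen-Shannon
divergences between ensemble-averaged simulated and reference degree and
edge-length distributions (log base 2, so ``eps_div`` is bounded by 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.spatial.distance import jensenshannon

from .growth import GrowthConfig, grow_accelerated, grow_network

__all__ = [
    "Histogram",
    "degree_histogram",
    "length_histogram",
    "simulate_mean_histograms",
    "epsilon_dif",
    "grid_search",
    "js_divergence",
    "epsilon_div",
    "pso_optimize",
    "calibrate",
    "CalibrationResult",
    "PSOResult",
]


@dataclass(frozen=True)
class Histogram:
    """Counts (or masses) over explicit bin edges."""

    counts: np.ndarray
    edges: np.ndarray

    def probabilities(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        total = c.sum()
        if total <= 0:
            raise ValueError("histogram has no mass")
        return c / total


def degree_histogram(degrees, k_max: int) -> Histogram:
    """Unit-width integer bins ``0 .. k_max`` (values above clip into the top bin)."""
    d = np.clip(np.asarray(degrees, dtype=int), 0, k_max)
    counts = np.bincount(d, minlength=k_max + 1).astype(float)
    return Histogram(counts, np.arange(k_max + 2) - 0.5)


def length_histogram(lengths, edges: np.ndarray) -> Histogram:
    counts, _ = np.histogram(lengths, bins=edges)
    return Histogram(counts.astype(float), np.asarray(edges, dtype=float))


def _run(config: GrowthConfig):
    return grow_network(config) if config.mode == "plain" else grow_accelerated(config)


def simulate_mean_histograms(
    config: GrowthConfig,
    k_max: int,
    length_edges: np.ndarray,
    n_rep: int,
    seed: int | None,
) -> tuple[Histogram, Histogram, float]:
    """Ensemble-averaged degree and edge-length histograms and the mean L."""
    rng = np.random.default_rng(seed)
    deg_acc = np.zeros(k_max + 1)
    len_acc = np.zeros(len(length_edges) - 1)
    l_acc = 0.0
    for _ in range(n_rep):
        net = _run(replace(config, seed=int(rng.integers(2**31))))
        deg_acc += degree_histogram(net.degrees(), k_max).counts
        len_acc += length_histogram(net.edge_lengths(), length_edges).counts
        l_acc += net.graph.n_edges
    return (
        Histogram(deg_acc / n_rep, np.arange(k_max + 2) - 0.5),
        Histogram(len_acc / n_rep, np.asarray(length_edges, dtype=float)),
        l_acc / n_rep,
    )


def epsilon_dif(
    config: GrowthConfig, target_l: int, n_rep: int = 30, seed: int | None = None
) -> float:
    """Relative edge-count error ``|<L_sim> - L| / L`` over ``n_rep`` runs."""
    if target_l <= 0:
        raise ValueError("target_l must be positive")
    rng = np.random.default_rng(seed)
    mean_l = np.mean(
        [_run(replace(config, seed=int(rng.integers(2**31)))).graph.n_edges
         for _ in range(n_rep)]
    )
    return abs(mean_l - target_l) / target_l


def grid_search(
    base_config: GrowthConfig,
    target_l: int,
    bounds: tuple[float, float] = (1e-3, 1e3),
    n_grid: int = 50,
    threshold: float = 0.05,
    n_rep: int = 30,
    seed: int | None = None,
) -> "CalibrationGrid":
    """Stage 1: log-spaced ``(alpha, beta)`` scan of ``eps_dif``.

    Returns the full error surface plus the feasible set
    ``eps_dif < threshold`` (empty feasible sets are returned as such, with a
    warning — not an error).
    """
    if n_grid < 2:
        raise ValueError("need at least 2 grid points per axis")
    values = np.logspace(np.log10(bounds[0]), np.log10(bounds[1]), n_grid)
    rng = np.random.default_rng(seed)
    eps = np.empty((n_grid, n_grid))
    for ia, a in enumerate(values):
        for ib, b in enumerate(values):
            cfg = replace(base_config, alpha=float(a), beta=float(b))
            eps[ia, ib] = epsilon_dif(cfg, target_l, n_rep=n_rep,
                                      seed=int(rng.integers(2**31)))
    feasible = np.argwhere(eps < threshold)
    if len(feasible) == 0:
        import warnings

        warnings.warn("no parameter combination met the edge-count threshold")
    pairs = np.column_stack([values[feasible[:, 0]], values[feasible[:, 1]]]) \
        if len(feasible) else np.empty((0, 2))
    return CalibrationGrid(values, eps, pairs, threshold)


@dataclass(frozen=True)
class CalibrationGrid:
    values: np.ndarray
    epsilon: np.ndarray
    feasible_pairs: np.ndarray
    threshold: float

    def feasible_box(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Bounding box of the feasible set: ((alpha_lo, alpha_hi), (beta_lo, beta_hi))."""
        if len(self.feasible_pairs) == 0:
            raise ValueError("feasible set is empty")
        a, b = self.feasible_pairs[:, 0], self.feasible_pairs[:, 1]
        return (float(a.min()), float(a.max())), (float(b.min()), float(b.max()))


def js_divergence(p, q, base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two histograms on the same bins.

    Symmetric, ``0`` iff the normalised histograms coincide, and bounded by 1
    in log base 2.
    """
    if isinstance(p, Histogram) and isinstance(q, Histogram):
        if len(p.edges) != len(q.edges) or not np.allclose(p.edges, q.edges):
            raise ValueError("histograms use incompatible bins")
        p, q = p.probabilities(), q.probabilities()
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms use incompatible bins")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("histograms must have positive mass")
    p = p / p.sum()
    q = q / q.sum()
    # subnormal masses underflow inside the mixture term; they carry no
    # information at histogram scale, so drop them
    tiny = np.finfo(float).tiny
    p = np.where(p < tiny, 0.0, p)
    q = np.where(q < tiny, 0.0, q)
    return float(jensenshannon(p / p.sum(), q / q.sum(), base=base) ** 2)


def epsilon_div(
    config: GrowthConfig,
    ref_degree: Histogram,
    ref_length: Histogram,
    n_rep: int = 100,
    seed: int | None = None,
) -> float:
    """``max(JS(P(k)), JS(P(d)))`` of ensemble means against the references."""
    k_max = len(ref_degree.counts) - 1
    deg, lng, _ = simulate_mean_histograms(
        config, k_max, ref_length.edges, n_rep=n_rep, seed=seed
    )
    return max(js_divergence(deg, ref_degree), js_divergence(lng, ref_length))


@dataclass(frozen=True)
class PSOResult:
    best_x: np.ndarray
    best_f: float
    n_iter: int
    trajectory: np.ndarray  # best objective value per iteration


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    n_particles: int = 20,
    max_iter: int = 400,
    tol: float = 0.001,
    patience: int = 20,
    seed: int | None = None,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
) -> PSOResult:
    """Global-best particle swarm minimisation on a box.

    Velocities are clamped to 20% of each bound range; the run stops when the
    incumbent has improved by less than ``tol`` over ``patience`` consecutive
    iterations, or at ``max_iter``.  Deterministic given ``seed``.
    """
    bounds = np.asarray(bounds, dtype=float).reshape(-1, 2)
    if np.any(bounds[:, 1] < bounds[:, 0]):
        raise ValueError("invalid bounds")
    if np.all(bounds[:, 1] == bounds[:, 0]):
        x = bounds[:, 0]
        return PSOResult(x, float(objective(x)), 0, np.array([float(objective(x))]))
    rng = np.random.default_rng(seed)
    dim = len(bounds)
    span = bounds[:, 1] - bounds[:, 0]
    x = bounds[:, 0] + rng.random((n_particles, dim)) * span
    v = (rng.random((n_particles, dim)) - 0.5) * 0.2 * span
    f = np.array([objective(xi) for xi in x])
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])
    vmax = 0.2 * span
    trajectory = [gbest_f]
    stagnant = 0
    it = 0
    for it in range(1, max_iter + 1):
        r1 = rng.random((n_particles, dim))
        r2 = rng.random((n_particles, dim))
        v = inertia * v + cognitive * r1 * (pbest_x - x) + social * r2 * (gbest_x - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, bounds[:, 0], bounds[:, 1])
        f = np.array([objective(xi) for xi in x])
        better = f < pbest_f
        pbest_x[better], pbest_f[better] = x[better], f[better]
        g = int(np.argmin(pbest_f))
        improvement = gbest_f - float(pbest_f[g])
        if improvement > 0:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        stagnant = stagnant + 1 if improvement < tol else 0
        trajectory.append(gbest_f)
        if stagnant >= patience:
            break
    return PSOResult(gbest_x, gbest_f, it, np.asarray(trajectory))


@dataclass(frozen=True)
class CalibrationResult:
    grid: CalibrationGrid
    best_alpha: float
    best_beta: float
    epsilon_div: float
    pso: PSOResult
    n_rep_stage1: int
    n_rep_stage2: int


def calibrate(
    base_config: GrowthConfig,
    target_l: int,
    ref_degree: Histogram,
    ref_length: Histogram,
    bounds: tuple[float, float] = (1e-3, 1e3),
    n_grid: int = 50,
    threshold: float = 0.05,
    n_rep_stage1: int = 30,
    n_rep_stage2: int = 100,
    n_particles: int = 20,
    max_iter: int = 400,
    tol: float = 0.001,
    seed: int | None = None,
) -> CalibrationResult:
    """Full two-step pipeline: eps_dif grid, then PSO on eps_div.

    The swarm searches log10-parameter space over the bounding box of the
    stage-1 feasible set.
    """
    rng = np.random.default_rng(seed)
    grid = grid_search(
        base_config, target_l, bounds=bounds, n_grid=n_grid,
        threshold=threshold, n_rep=n_rep_stage1, seed=int(rng.integers(2**31)),
    )
    (a_lo, a_hi), (b_lo, b_hi) = grid.feasible_box()
    log_bounds = np.log10([[a_lo, a_hi], [b_lo, b_hi]])
    eval_seed = int(rng.integers(2**31))

    def objective(log_ab):
        cfg = replace(base_config, alpha=float(10 ** log_ab[0]),
                      beta=float(10 ** log_ab[1]))
        return epsilon_div(cfg, ref_degree, ref_length, n_rep=n_rep_stage2,
                           seed=eval_seed)

    pso = pso_optimize(
        objective, log_bounds, n_particles=n_particles, max_iter=max_iter,
        tol=tol, seed=int(rng.integers(2**31)),
    )
    return CalibrationResult(
        grid=grid,
        best_alpha=float(10 ** pso.best_x[0]),
        best_beta=float(10 ** pso.best_x[1]),
        epsilon_div=pso.best_f,
        pso=pso,
        n_rep_stage1=n_rep_stage1,
        n_rep_stage2=n_rep_stage2,
    )
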