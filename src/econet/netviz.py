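"""Jittered-grid layouts, trial records, and overdispersed count modelling.

Emulates the structure of slider experiments in which participants add edges
to a fixed 49-node layout until the drawing becomes confusing: per-condition
(short / random / long) selected-edge counts are overdispersed relative to a
Poisson, and are modelled as a Gamma-Poisson (negative binomial) process with
mean ``lambda`` and scale ``gamma``, variance ``lambda * (1 + gamma)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "netviz_layout",
    "TrialRecord",
    "apply_exclusion_filters",
    "GammaPoissonFit",
    "gamma_poisson_fit",
    "cohens_d",
    "simulate_trials",
    "condition_mean_densities",
]

GRID_SIDE = 7
N_NODES = GRID_SIDE * GRID_SIDE
N_PAIRS = N_NODES * (N_NODES - 1) // 2  # 1176

#: inclusive retention bounds on edge count and elapsed seconds
L_RANGE = (2, N_PAIRS - 1)
T_RANGE = (1.0, 3600.0)

CONDITIONS = ("short", "random", "long")


def netviz_layout(seed: int | None = None, jitter: float = 0.08) -> np.ndarray:
    """49 nodes on a 7x7 unit grid, jittered per axis by ``jitter * U(0,1)``
    with an independent random sign (i.e. uniform on ``[-jitter, jitter]``).

    ``jitter=0`` returns the exact regular grid — a degenerate layout with
    many collinear triples that the crossing counter will reject.
    """
    base = np.stack(
        np.meshgrid(np.arange(GRID_SIDE), np.arange(GRID_SIDE), indexing="ij"), -1
    ).reshape(-1, 2) / (GRID_SIDE - 1)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(N_NODES, 2))
    disp = signs * jitter * rng.random((N_NODES, 2))
    return base + disp


@dataclass(frozen=True)
class TrialRecord:
    condition: str
    l_selected: int
    elapsed_seconds: float

    def __post_init__(self):
        if self.l_selected < 0 or self.elapsed_seconds < 0:
            raise ValueError("counts and times must be nonnegative")


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "l_selected": r.l_selected,
                "elapsed_seconds": r.elapsed_seconds,
            }
            for r in records
        ]
    )


def apply_exclusion_filters(records) -> pd.DataFrame:
    """Drop unreliable trials: keeps ``2 <= L <= 1175`` and ``1 <= t <= 3600`` s
    (inclusive bounds).  Malformed rows are reported and skipped."""
    df = _records_frame(records)
    required = {"condition", "l_selected", "elapsed_seconds"}
    if not required <= set(df.columns):
        raise ValueError(f"records must provide columns {sorted(required)}")
    l_col = pd.to_numeric(df["l_selected"], errors="coerce")
    t_col = pd.to_numeric(df["elapsed_seconds"], errors="coerce")
    malformed = l_col.isna() | t_col.isna()
    if malformed.any():
        warnings.warn(f"skipped {int(malformed.sum())} malformed record(s)")
    keep = (
        ~malformed
        & l_col.between(*L_RANGE)
        & t_col.between(*T_RANGE)
    )
    return df.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class GammaPoissonFit:
    """Maximum-likelihood Gamma-Poisson (negative binomial) parameters.

    ``lam`` is the count mean, ``gamma`` the overdispersion scale: the
    variance is ``lam * (1 + gamma)``; ``gamma -> 0`` recovers the Poisson.
    """

    lam: float
    gamma: float
    loglik: float

    def variance(self) -> float:
        return self.lam * (1.0 + self.gamma)


def _nb_loglik(counts: np.ndarray, lam: float, gamma: float) -> float:
    # mean lam, variance lam (1 + gamma)  <=>  nbinom(r = lam/gamma, p = 1/(1+gamma))
    r = lam / gamma
    p = 1.0 / (1.0 + gamma)
    return float(stats.nbinom.logpmf(counts, r, p).sum())


def gamma_poisson_fit(counts, min_gamma: float = 1e-8) -> GammaPoissonFit:
    """Fit the Gamma-Poisson by maximum likelihood.

    Underdispersed samples (variance <= mean) cannot be represented; the fit
    then degenerates toward the Poisson limit ``gamma -> 0`` with a warning.
    """
    counts = np.asarray(counts)
    if len(counts) < 10:
        raise ValueError("need at least 10 counts")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(float)
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be nonnegative integers")
        counts = counts.astype(int)
    mean = counts.mean()
    var = counts.var(ddof=1)
    if mean <= 0:
        raise ValueError("counts are all zero; mean parameter undefined")
    if var <= mean:
        warnings.warn("data are not overdispersed; returning the Poisson limit")
        lam = float(mean)
        return GammaPoissonFit(lam, min_gamma, _nb_loglik(counts, lam, min_gamma))
    # moment start: gamma0 = var/mean - 1
    x0 = np.log([mean, var / mean - 1.0])

    def nll(logs):
        lam, gamma = np.exp(logs)
        return -_nb_loglik(counts, lam, max(gamma, min_gamma))

    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-8})
    lam, gamma = np.exp(res.x)
    gamma = max(float(gamma), min_gamma)
    return GammaPoissonFit(float(lam), gamma, _nb_loglik(counts, float(lam), gamma))


def cohens_d(x, y) -> float:
    """Standardised mean difference with the df-weighted pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    nx, ny = len(x), len(y)
    pooled = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance; effect size undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled))


def simulate_trials(
    lam: float,
    gamma: float,
    n_per_condition: int,
    condition_means: dict | None = None,
    seed: int | None = None,
    elapsed_log_mean: float = 4.0,
    elapsed_log_sd: float = 0.8,
) -> pd.DataFrame:
    """Synthetic trial records with Gamma-Poisson selected-edge counts.

    ``condition_means`` maps condition to its count mean (default: ``lam``
    for every condition); the scale ``gamma`` is shared.  Elapsed times are
    log-normal.  Deterministic given ``seed``.
    """
    if lam <= 0 or gamma <= 0 or n_per_condition <= 0:
        raise ValueError("lam, gamma and n_per_condition must be positive")
    means = {c: float(lam) for c in CONDITIONS}
    if condition_means:
        unknown = set(condition_means) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        means.update({c: float(v) for c, v in condition_means.items()})
    rng = np.random.default_rng(seed)
    frames = []
    for cond in CONDITIONS:
        mu = means[cond]
        r = mu / gamma
        p = 1.0 / (1.0 + gamma)
        counts = stats.nbinom.rvs(r, p, size=n_per_condition, random_state=rng)
        elapsed = rng.lognormal(elapsed_log_mean, elapsed_log_sd, n_per_condition)
        frames.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "l_selected": counts,
                    "elapsed_seconds": elapsed,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def condition_mean_densities(records, n_pairs: int = N_PAIRS) -> dict:
    """Mean connection density per condition: ``<L> / (N(N-1)/2)``."""
    df = _records_frame(records)
    out = {}
    for cond, grp in df.groupby("condition"):
        out[str(cond)] = float(grp["l_selected"].mean()) / n_pairs
    return out
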