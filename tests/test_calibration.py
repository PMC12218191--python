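"""Jensen-Shannon divergence, the two calibration errors, and the PSO."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from econet import (
    GrowthConfig,
    Histogram,
    degree_histogram,
    epsilon_dif,
    epsilon_div,
    grid_search,
    js_divergence,
    length_histogram,
    pso_optimize,
    simulate_mean_histograms,
)
from econet.synth import toy_connectome


@pytest.fixture(scope="module")
def toy_config():
    tc = toy_connectome(n=100, seed=5)
    return GrowthConfig(
        alpha=2.0, beta=0.3, mode="accelerated",
        positions=tc["x"].to_numpy()[:, None],
        hidden_degrees=tc["hidden_degree"].to_numpy(dtype=float),
    )


class TestJSDivergence:
    def test_identical_is_zero(self):
        assert js_divergence([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == pytest.approx(0.0)

    def test_disjoint_support_is_one(self):
        assert js_divergence([1, 0, 0], [0, 0, 1]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # p=(1/2,1/2), q=(1,0): H(m) - (H(p)+H(q))/2 with m=(3/4,1/4)
        assert js_divergence([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.3113, abs=1e-4)

    def test_incompatible_bins_rejected(self):
        a = Histogram(np.ones(3), np.arange(4.0))
        b = Histogram(np.ones(3), np.arange(4.0) * 2)
        with pytest.raises(ValueError):
            js_divergence(a, b)

    @given(
        st.lists(st.floats(0.0, 10.0), min_size=4, max_size=4).filter(
            lambda v: sum(v) > 0
        ),
        st.lists(st.floats(0.0, 10.0), min_size=4, max_size=4).filter(
            lambda v: sum(v) > 0
        ),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, p, q):
        d = js_divergence(p, q)
        assert d == pytest.approx(js_divergence(q, p), abs=1e-12)
        assert -1e-12 <= d <= 1 + 1e-12

    def test_sqrt_js_triangle_inequality(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p, q, r = rng.random((3, 6)) + 1e-3
            a = np.sqrt(js_divergence(p, q))
            b = np.sqrt(js_divergence(q, r))
            c = np.sqrt(js_divergence(p, r))
            assert c <= a + b + 1e-9


class TestEpsilonDif:
    def test_deterministic_plain_mode_is_zero(self):
        cfg = GrowthConfig(alpha=1.0, beta=0.0, m=3, n_nodes=50, n0=4, seed=0)
        target = 4 * 3 // 2 + 3 * 46
        assert epsilon_dif(cfg, target, n_rep=2, seed=0) == 0.0

    def test_doubled_target_gives_half(self):
        cfg = GrowthConfig(alpha=1.0, beta=0.0, m=3, n_nodes=50, n0=4, seed=0)
        target = 2 * (4 * 3 // 2 + 3 * 46)
        assert epsilon_dif(cfg, target, n_rep=2, seed=0) == pytest.approx(0.5)

    def test_invalid_target_rejected(self, toy_config):
        with pytest.raises(ValueError):
            epsilon_dif(toy_config, 0, n_rep=2, seed=0)


class TestGridSearch:
    def test_infinite_threshold_keeps_whole_grid(self, toy_config):
        grid = grid_search(toy_config, target_l=100, n_grid=3, threshold=np.inf,
                           n_rep=2, seed=0)
        assert len(grid.feasible_pairs) == 9

    def test_zero_threshold_warns_empty(self, toy_config):
        with pytest.warns(UserWarning):
            grid = grid_search(toy_config, target_l=100, n_grid=3, threshold=0.0,
                               n_rep=2, seed=0)
        assert len(grid.feasible_pairs) == 0
        with pytest.raises(ValueError):
            grid.feasible_box()

    def test_feasible_band_contiguous_in_alpha(self, toy_config):
        """Mean L grows monotonically with alpha at fixed small beta, so the
        feasible set projects onto a contiguous alpha band."""
        grid = grid_search(
            replace(toy_config, beta=0.01), target_l=250,
            bounds=(0.3, 30.0), n_grid=8, threshold=0.25, n_rep=5, seed=1,
        )
        rows = np.unique(
            [np.searchsorted(grid.values, a) for a in grid.feasible_pairs[:, 0]]
        )
        assert len(rows) > 0
        assert np.array_equal(rows, np.arange(rows.min(), rows.max() + 1))


class TestEpsilonDiv:
    def test_self_recovery_is_small(self, toy_config):
        ref_deg, ref_len, _ = simulate_mean_histograms(
            toy_config, 40, np.linspace(0, 1, 31), n_rep=60, seed=3
        )
        assert epsilon_div(toy_config, ref_deg, ref_len, n_rep=60, seed=4) < 0.05

    def test_degenerate_reference_far(self, toy_config):
        deg = Histogram(np.eye(41)[0], np.arange(42) - 0.5)
        lng = Histogram(np.eye(30)[0], np.linspace(0, 1, 31))
        assert epsilon_div(toy_config, deg, lng, n_rep=5, seed=0) > 0.5

    def test_perturbed_parameters_are_worse(self, toy_config):
        ref_deg, ref_len, _ = simulate_mean_histograms(
            toy_config, 40, np.linspace(0, 1, 31), n_rep=60, seed=3
        )
        good = epsilon_div(toy_config, ref_deg, ref_len, n_rep=30, seed=5)
        bad = epsilon_div(
            replace(toy_config, alpha=toy_config.alpha * 10,
                    beta=toy_config.beta * 10),
            ref_deg, ref_len, n_rep=30, seed=5,
        )
        assert bad > good


class TestPSO:
    def test_sphere_benchmark(self):
        res = pso_optimize(
            lambda x: float(np.sum(x**2)), [[-1, 1], [-1, 1]],
            n_particles=20, max_iter=200, tol=1e-9, patience=40, seed=0,
        )
        assert np.all(np.abs(res.best_x) < 1e-2)
        assert res.best_f < 1e-4

    def test_deterministic_given_seed(self):
        runs = [
            pso_optimize(
                lambda x: float(np.sum((x - 0.3) ** 2)), [[-1, 1], [-1, 1]],
                n_particles=10, max_iter=50, seed=9,
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].trajectory, runs[1].trajectory)
        assert np.array_equal(runs[0].best_x, runs[1].best_x)

    def test_degenerate_bounds_return_the_point(self):
        res = pso_optimize(lambda x: float(x[0] ** 2), [[2.0, 2.0]], seed=0)
        assert res.best_x[0] == 2.0

    def test_never_worse_than_initial_swarm(self):
        rng = np.random.default_rng(1)

        def rastrigin(x):
            return float(10 * len(x) + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))

        res = pso_optimize(rastrigin, [[-5, 5]] * 2, n_particles=15, max_iter=60,
                           seed=int(rng.integers(1000)))
        assert res.best_f <= res.trajectory[0]
        assert np.all(np.diff(res.trajectory) <= 0)


class TestHistograms:
    def test_degree_histogram_clips_into_top_bin(self):
        h = degree_histogram([0, 1, 1, 7], k_max=3)
        assert h.counts.tolist() == [1, 2, 0, 1]

    def test_length_histogram_binning(self):
        h = length_histogram([0.1, 0.9, 0.5], np.linspace(0, 1, 3))
        assert h.counts.tolist() == [1, 2]  # 0.5 falls in the upper bin

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            Histogram(np.zeros(3), np.arange(4.0)).probabilities()
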