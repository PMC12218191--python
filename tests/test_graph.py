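"""Densities, the benefit-cost functional, and its closed-form optima."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from econet import (
    DegenerateGeometryError,
    FunctionalParams,
    SpatialGraph,
    connection_density,
    empirical_density_curve,
    expected_delta,
    functional_J,
    maximize_J_empirical,
    optimal_density,
    phi_from_alpha,
    scaled_alpha,
    spatial_density,
)
from econet.filtering import rank_edges
from econet.synth import geometric_graph, uniform_distance_layout


class TestConnectionDensity:
    def test_complete_graph_is_one(self, complete_k4):
        assert connection_density(complete_k4) == 1.0

    def test_empty_edge_set_is_zero(self):
        coords = {str(k): (k, 0.0) for k in range(10)}
        g = SpatialGraph.from_edges(coords, [])
        assert connection_density(g) == 0.0

    def test_netviz_mean_count_density(self):
        # 49-node layout: 150.27 mean edges over 1176 possible pairs
        assert 150.27 / 1176 == pytest.approx(0.1278, abs=5e-5)

    def test_requires_two_nodes(self):
        g = SpatialGraph.from_edges({"a": (0.0, 0.0)}, [])
        with pytest.raises(ValueError):
            connection_density(g)


class TestSpatialDensity:
    def test_full_pair_set_is_one(self, complete_k4):
        pairs = [(u, v) for u, v in complete_k4.edge_pairs()]
        assert spatial_density(complete_k4, pairs) == pytest.approx(1.0)

    def test_empty_subset_is_zero(self, complete_k4):
        assert spatial_density(complete_k4, []) == 0.0

    def test_two_short_edges_of_collinear_triple(self, triangle_graph):
        # lengths 1 + 1 over 1 + 1 + 2
        assert spatial_density(triangle_graph) == pytest.approx(0.5)

    def test_coincident_nodes_degenerate(self):
        g = SpatialGraph.from_edges({"a": (0, 0), "b": (0, 0)}, [("a", "b", 1.0)])
        with pytest.raises(DegenerateGeometryError):
            spatial_density(g)


class TestFunctionalJ:
    @pytest.mark.parametrize(
        "rho,delta,alpha,beta,expected",
        [
            (0.5, 0.5, 1, 1, 0.25),
            (0.3, 1.0, 2, 1, 0.0),  # zero cost-complement
            (0.5, 0.25, 1, 1, 0.375),
            (0.0, 0.3, 0, 1, 0.7),  # 0**0 = 1
            (0.0, 0.0, 0, 0, 1.0),
        ],
    )
    def test_values(self, rho, delta, alpha, beta, expected):
        assert functional_J(rho, delta, alpha=alpha, beta=beta) == pytest.approx(expected)

    def test_peak_matches_short_regime_maximum(self):
        # max of rho (1 - rho^2) over [0, 1] is at rho = 1/sqrt(3), J = 0.3849
        r = np.linspace(0, 1, 200001)
        j = functional_J(r, expected_delta(r, "short"), alpha=1, beta=1)
        assert r[np.argmax(j)] == pytest.approx(optimal_density(1, "short"), abs=1e-4)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            functional_J(1.2, 0.5, alpha=1, beta=1)

    @given(
        rho=st.floats(0, 1), delta=st.floats(0, 1),
        alpha=st.floats(0, 10), beta=st.floats(0, 10),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_unit_interval(self, rho, delta, alpha, beta):
        assert 0.0 <= functional_J(rho, delta, alpha=alpha, beta=beta) <= 1.0

    def test_binomial_approximation_first_order(self):
        # J ~ rho**a - rho**a * b * delta with O(delta^2) error
        rho, alpha, beta = 0.6, 1.5, 2.0
        deltas = np.array([1e-1, 1e-2, 1e-3, 1e-4])
        exact = functional_J(rho, deltas, alpha=alpha, beta=beta)
        approx = rho**alpha - rho**alpha * beta * deltas
        err = np.abs(exact - approx)
        assert np.all(err <= 2.0 * beta**2 * deltas**2)


class TestExpectedDelta:
    @pytest.mark.parametrize(
        "rho,regime,expected",
        [
            (0.5, "random", 0.5),
            (0.3, "short", 0.09),
            (0.3, "long", 0.51),
            (1.0, "random", 1.0),
            (1.0, "short", 1.0),
            (1.0, "long", 1.0),
        ],
    )
    def test_values(self, rho, regime, expected):
        assert expected_delta(rho, regime) == pytest.approx(expected)

    def test_unknown_regime(self):
        with pytest.raises(ValueError):
            expected_delta(0.5, "medium")

    def test_short_oracle_on_uniform_length_spectra(self):
        """Monte-Carlo over sorted uniform length samples reproduces rho**2."""
        rng = np.random.default_rng(0)
        acc = np.zeros(11)
        rhos = np.linspace(0, 1, 11)
        reps = 300
        for _ in range(reps):
            d = np.sort(rng.random(435))
            cs = np.concatenate([[0.0], np.cumsum(d)]) / d.sum()
            acc += cs[np.round(rhos * 435).astype(int)]
        assert np.abs(acc / reps - rhos**2).max() < 0.01


class TestOptimalDensity:
    @pytest.mark.parametrize(
        "alpha,regime,expected",
        [
            (1.0, "random", 0.5),
            (0.0, "random", 0.0),
            (0.0, "short", 0.0),
            (0.0, "long", 0.0),
            (1.0, "long", 1 / 3),
            (1.0, "short", np.sqrt(1 / 3)),
        ],
    )
    def test_values(self, alpha, regime, expected):
        assert optimal_density(alpha, regime) == pytest.approx(expected)

    @pytest.mark.parametrize("regime,delta_fn", [
        ("random", lambda r: r),
        ("short", lambda r: r**2),
        ("long", lambda r: 2 * r - r**2),
    ])
    @pytest.mark.parametrize("alpha", [0.146, 0.5, 1.0, 2.7])
    def test_matches_grid_maximisation(self, regime, delta_fn, alpha):
        """The closed forms agree with direct maximisation of J on a fine grid."""
        r = np.linspace(0, 1, 400001)
        j = functional_J(r, delta_fn(r), alpha=alpha, beta=1.0)
        assert r[np.argmax(j)] == pytest.approx(optimal_density(alpha, regime), abs=1e-4)

    def test_ordering_and_monotonicity(self):
        alphas = np.linspace(0.01, 50, 300)
        for regime in ("long", "random", "short"):
            vals = np.array([optimal_density(a, regime) for a in alphas])
            assert np.all(np.diff(vals) > 0)
            assert vals[-1] > 0.9  # -> 1 as alpha -> inf
        longs = [optimal_density(a, "long") for a in alphas]
        rands = [optimal_density(a, "random") for a in alphas]
        shorts = [optimal_density(a, "short") for a in alphas]
        assert np.all(np.asarray(longs) <= np.asarray(rands))
        assert np.all(np.asarray(rands) <= np.asarray(shorts))

    def test_small_alpha_size_scaling(self):
        # alpha = phi N**(-1/s):  rho_long N^(1/s) -> phi/2, rho_rand N^(1/s) -> phi,
        # rho_short N^(1/(2s)) -> sqrt(phi/2)
        phi, s = 1.3, 2
        for n in (10**6, 10**8):
            a = scaled_alpha(phi, n, s)
            assert optimal_density(a, "long") * n ** (1 / s) == pytest.approx(phi / 2, rel=1e-2)
            assert optimal_density(a, "random") * n ** (1 / s) == pytest.approx(phi, rel=1e-2)
            assert optimal_density(a, "short") * n ** (1 / (2 * s)) == pytest.approx(
                np.sqrt(phi / 2), rel=1e-2
            )

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            optimal_density(-0.1, "random")


class TestScaledAlpha:
    def test_netviz_setting(self):
        assert scaled_alpha(1.026, 49, 2) == pytest.approx(1.026 / 7)

    def test_trivial_and_airline_cases(self):
        assert scaled_alpha(1.0, 1, 1) == 1.0
        assert scaled_alpha(1.0, 3214, 3) == pytest.approx(3214 ** (-1 / 3))

    def test_inverse_roundtrip(self):
        assert phi_from_alpha(scaled_alpha(1.7, 200, 3), 200, 3) == pytest.approx(1.7)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            scaled_alpha(0.0, 10, 2)


class TestEmpiricalCurve:
    def test_single_edge_graph(self):
        g = SpatialGraph.from_edges(
            {"a": (0, 0), "b": (1, 0), "c": (0, 1)}, [("a", "b", 2.0)]
        )
        ranking = rank_edges(g, "weight_desc")
        rho, delta = empirical_density_curve(g, ranking)
        assert rho.tolist() == [0.0, pytest.approx(1 / 3)]
        assert delta[1] == pytest.approx(spatial_density(g))

    def test_delta_nondecreasing(self, random_regime_graph):
        _, delta = empirical_density_curve(
            random_regime_graph, rank_edges(random_regime_graph, "random", seed=0)
        )
        assert np.all(np.diff(delta) >= 0)

    def test_length_descending_dominates_random_expectation(self, random_regime_graph):
        rho, delta = empirical_density_curve(
            random_regime_graph, rank_edges(random_regime_graph, "length_desc")
        )
        interior = (rho > 0) & (rho < 1)
        assert np.all(delta[interior] > rho[interior])

    def test_ranking_mismatch_rejected(self, complete_k4, triangle_graph):
        ranking = rank_edges(triangle_graph, "weight_desc")
        with pytest.raises(ValueError):
            empirical_density_curve(complete_k4, ranking)


class TestMaximizeJEmpirical:
    def test_large_alpha_keeps_everything(self, random_regime_graph):
        # non-complete subgraph so that delta < 1 at the full prefix
        ranking = rank_edges(random_regime_graph, "weight_desc")
        keep = ranking.ordered_edges[: random_regime_graph.n_edges // 2]
        weights = dict(zip(random_regime_graph.edge_pairs(), random_regime_graph.weights))
        coords = {u: random_regime_graph.coords[k]
                  for k, u in enumerate(random_regime_graph.node_ids)}
        sub = SpatialGraph.from_edges(
            coords, [(u, v, weights[(u, v)]) for u, v in keep]
        )
        l_star, _ = maximize_J_empirical(
            sub, rank_edges(sub, "weight_desc"), FunctionalParams(alpha=1e3)
        )
        assert l_star == sub.n_edges

    def test_zero_alpha_keeps_nothing(self, random_regime_graph):
        l_star, rho_star = maximize_J_empirical(
            random_regime_graph,
            rank_edges(random_regime_graph, "weight_desc"),
            FunctionalParams(alpha=0.0),
        )
        assert (l_star, rho_star) == (0, 0.0)

    def test_random_regime_matches_closed_form(self):
        """Empirical argmax on a random-regime graph sits near alpha/(alpha+1)."""
        rng_devs = []
        for seed in range(5):
            g = geometric_graph(45, regime="random", seed=seed)
            _, rho_star = maximize_J_empirical(
                g, rank_edges(g, "weight_desc"), FunctionalParams(alpha=1.0)
            )
            rng_devs.append(rho_star)
        assert np.mean(rng_devs) == pytest.approx(0.5, abs=0.05)

    def test_closed_forms_reproduced_on_uniform_spectrum_layout(self):
        """With a uniform distance spectrum, ranking by length reproduces the
        short/long closed-form optima within grid resolution."""
        coords = uniform_distance_layout(40, seed=3)
        g = geometric_graph(coords, regime="short", seed=3)
        for criterion, regime in (("length_asc", "short"), ("length_desc", "long")):
            _, rho_star = maximize_J_empirical(
                g, rank_edges(g, criterion), FunctionalParams(alpha=1.0)
            )
            assert rho_star == pytest.approx(optimal_density(1.0, regime), abs=0.03)


class TestSpatialGraphValidation:
    def test_rejects_self_loop(self):
        with pytest.raises(ValueError):
            SpatialGraph.from_edges({"a": (0, 0), "b": (1, 1)}, [("a", "a", 1.0)])

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError):
            SpatialGraph.from_edges({"a": (0, 0), "b": (1, 1)}, [("a", "b", 0.0)])

    def test_merges_reciprocated_pairs(self):
        g = SpatialGraph.from_edges(
            {"a": (0, 0), "b": (1, 1)}, [("a", "b", 2.0), ("b", "a", 3.0)]
        )
        assert g.n_edges == 1
        assert g.weights[0] == pytest.approx(5.0)

    def test_rejects_nonfinite_coordinates(self):
        with pytest.raises(ValueError):
            SpatialGraph.from_edges({"a": (np.nan, 0), "b": (1, 1)}, [("a", "b", 1.0)])
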