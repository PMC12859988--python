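import numpy as np
import pytest
from scipy.optimize import bisect

from tfdyn import (
    ACTIVATING,
    INHIBITING,
    DynamicModel,
    Edge,
    ExpressionSeries,
    Perturbation,
    SignedNetwork,
    ValidationError,
    rhs,
    scale_expression,
    simulate,
)
from tfdyn.dynamics import make_grid, rk4_batch


class TestScaleExpression:
    def test_endpoints_map_to_0_1_and_0_9(self):
        s = ExpressionSeries(np.array([0.0, 1, 2]), ["g"],
                             np.array([[0.0, 5.0, 10.0]]))
        np.testing.assert_allclose(scale_expression(s).values,
                                   [[0.1, 0.5, 0.9]])

    def test_constant_gene_maps_to_midpoint(self):
        s = ExpressionSeries(np.array([0.0, 1, 2]), ["g"],
                             np.array([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(scale_expression(s).values, [[0.5, 0.5, 0.5]])

    def test_idempotent_on_already_scaled_series(self):
        s = ExpressionSeries(np.array([0.0, 1, 2]), ["g"],
                             np.array([[0.1, 0.42, 0.9]]))
        np.testing.assert_allclose(scale_expression(s).values, s.values,
                                   atol=1e-12)


def _model(nodes, edges, weights, **kw):
    net = SignedNetwork(nodes, edges)
    idx = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for (s, t), w in weights.items():
        W[idx[t], idx[s]] = w
    return DynamicModel(net, W, **kw)


def _isolated_pair():
    """Two nodes joined by a zero-weight edge: effectively isolated."""
    return _model(["a", "b"], [Edge("a", "b", ACTIVATING, 1.0)], {})


class TestRhs:
    def test_pure_decay_without_inputs(self):
        m = _isolated_pair()
        d = rhs(np.array([0.5, 0.0]), m)
        assert d[0] == pytest.approx(-0.5)

    def test_saturated_single_activator_equilibrium(self):
        # x* solves x = w x_j^n / (1 + w x_j^n) with x_j = 1, w = 1 -> 0.5
        m = _model(["j", "i"], [Edge("j", "i", ACTIVATING, 1.0)],
                   {("j", "i"): 1.0})
        d = rhs(np.array([1.0, 0.5]), m)
        assert d[1] == pytest.approx(0.0, abs=1e-12)

    def test_perturbed_isolated_node_equilibrium_three_quarters(self):
        m = _isolated_pair()
        d = rhs(np.array([0.75, 0.0]), m, Perturbation("a", 3.0))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_negative_weight_rejected_at_model_construction(self):
        with pytest.raises(ValidationError):
            _model(["a", "b"], [Edge("a", "b", ACTIVATING, 1.0)],
                   {("a", "b"): -1.0})


class TestSimulate:
    def test_zero_weights_decay_matches_closed_form(self):
        m = _isolated_pair()
        t = np.linspace(0, 3, 7)
        traj = simulate(m, np.array([0.5, 0.5]), t, rtol=1e-9, atol=1e-9)
        expected = np.tile(0.5 * np.exp(-t), (2, 1))
        np.testing.assert_allclose(traj.states, expected, rtol=1e-5)

    def test_two_node_mutual_activation_reaches_fixed_point(self):
        w = 10.0  # strong enough for a nonzero symmetric fixed point
        m = _model(["a", "b"],
                   [Edge("a", "b", ACTIVATING, 1.0), Edge("b", "a", ACTIVATING, 1.0)],
                   {("a", "b"): w, ("b", "a"): w})
        traj = simulate(m, np.array([0.9, 0.9]), [0.0, 60.0])
        # independent oracle: symmetric steady state solves
        # x = w x^3 / (1 + w x^3) by bisection on [0.6, 0.95]
        x_star = bisect(lambda x: w * x**3 / (1 + w * x**3) - x, 0.6, 0.95,
                        xtol=1e-12)
        np.testing.assert_allclose(traj.final_state(), [x_star, x_star],
                                   atol=1e-5)

    def test_perturbation_zero_equals_unperturbed_exactly(self, sparse_dataset):
        sc = sparse_dataset.scenario
        m = sc.model()
        t = np.asarray(sc.spec.times)
        base = simulate(m, sc.x0, t)
        pert = simulate(m, sc.x0, t, Perturbation(m.nodes[0], 0.0))
        np.testing.assert_array_equal(base.states, pert.states)

    def test_perturbation_saturation_drives_node_toward_one(self):
        m = _isolated_pair()
        final = [simulate(m, np.array([0.5, 0.5]), [0, 40.0],
                          Perturbation("a", p)).final_state()[0]
                 for p in (3.0, 30.0, 3000.0)]
        assert final[0] == pytest.approx(0.75, abs=1e-4)
        assert final[0] < final[1] < final[2] < 1.0 + 1e-9

    def test_monotone_response_to_activating_weight(self):
        # u <-> j self-sustains the source; i's steady state is H(w j^3)
        finals = []
        for w in (0.5, 1.0, 2.0, 4.0):
            m = _model(["u", "j", "i"],
                       [Edge("u", "j", ACTIVATING, 1.0),
                        Edge("j", "u", ACTIVATING, 1.0),
                        Edge("j", "i", ACTIVATING, 1.0)],
                       {("u", "j"): 10.0, ("j", "u"): 10.0, ("j", "i"): w})
            finals.append(simulate(m, np.array([0.9, 0.9, 0.2]), [0, 50.0])
                          .final_state()[2])
        assert finals[0] > 0.05  # the motif is alive, not collapsed
        assert all(a <= b + 1e-9 for a, b in zip(finals, finals[1:]))

    def test_boundedness_over_random_models(self):
        """W >= 0 and x0 in [0,1]^N keep trajectories in [0,1]^N."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(25):
            n = int(rng.integers(3, 8))
            nodes = [f"n{i}" for i in range(n)]
            edges, weights = [], {}
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.5:
                        sign = ACTIVATING if rng.random() < 0.7 else INHIBITING
                        edges.append(Edge(nodes[i], nodes[j], sign, 1.0))
                        weights[(nodes[i], nodes[j])] = float(rng.uniform(0, 8))
            if not edges:
                continue
            m = _model(nodes, edges, weights)
            x0 = rng.uniform(0.1, 0.9, size=n)
            traj = simulate(m, x0, np.linspace(0, 9, 10))
            worst = max(worst, float(traj.states.max()),
                        float(-traj.states.min()))
        assert worst <= 1 + 1e-6

    def test_inhibition_lowers_steady_state(self):
        base = _model(["j", "i"],
                      [Edge("j", "i", ACTIVATING, 1.0),
                       Edge("i", "j", ACTIVATING, 1.0)],
                      {("j", "i"): 4.0, ("i", "j"): 4.0})
        inh = _model(["j", "i", "k"],
                     [Edge("j", "i", ACTIVATING, 1.0),
                      Edge("i", "j", ACTIVATING, 1.0),
                      Edge("j", "k", ACTIVATING, 1.0),
                      Edge("k", "i", INHIBITING, 1.0)],
                     {("j", "i"): 4.0, ("i", "j"): 4.0,
                      ("j", "k"): 4.0, ("k", "i"): 6.0})
        f_base = simulate(base, np.array([0.9, 0.9]), [0, 50.0]).final_state()
        f_inh = simulate(inh, np.array([0.9, 0.9, 0.9]), [0, 50.0]).final_state()
        assert f_inh[1] < f_base[1]


class TestFixedGrid:
    def test_grid_contains_data_times(self):
        times = np.array([0.0, 2.0, 3.0, 9.0])
        grid, idx = make_grid(times, dt_max=0.25)
        np.testing.assert_allclose(grid[idx], times)
        assert np.all(np.diff(grid) <= 0.25 + 1e-12)

    def test_rk4_matches_adaptive_solver(self, sparse_dataset):
        sc = sparse_dataset.scenario
        m = sc.model()
        t = np.asarray(sc.spec.times)
        ref = simulate(m, sc.x0, t, rtol=1e-9, atol=1e-9)
        w_act, w_inh = m.split_weights()
        grid, idx = make_grid(t, dt_max=0.1)
        states = rk4_batch(w_act, w_inh, sc.x0, grid, 1.0, 3.0, 1.0)
        np.testing.assert_allclose(states[idx].T, ref.states, atol=2e-5)

    def test_batched_perturbations_match_single_runs(self):
        m = _model(["j", "i"],
                   [Edge("j", "i", ACTIVATING, 1.0),
                    Edge("i", "j", ACTIVATING, 1.0)],
                   {("j", "i"): 3.0, ("i", "j"): 3.0})
        w_act, w_inh = m.split_weights()
        grid, _ = make_grid(np.array([0.0, 5.0]), 0.1)
        ps = np.array([-2.0, 0.0, 1.5])
        x0 = np.array([0.4, 0.6])
        batch = rk4_batch(w_act, w_inh, np.repeat(x0[:, None], 3, axis=1), grid,
                          1.0, 3.0, 1.0, pert_idx=0,
                          p_act=np.maximum(ps, 0), p_inh=np.maximum(-ps, 0))
        for k, p in enumerate(ps):
            single = rk4_batch(w_act, w_inh, x0, grid, 1.0, 3.0, 1.0,
                               pert_idx=0, p_act=max(p, 0), p_inh=max(-p, 0))
            np.testing.assert_allclose(batch[:, :, k], single, atol=1e-12)
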