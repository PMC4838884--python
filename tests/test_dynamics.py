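import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import endonet as en
from endonet import synthetic as syn
from endonet.dynamics import (CompiledDynamics, activation_term,
                              inhibition_term, integrate, jacobian, node_rate,
                              rhs)

unit = st.floats(0.0, 1.0)
hill_n = st.floats(1.0, 20.0)
hill_a = st.floats(0.01, 0.99)


@pytest.fixture(scope="module")
def iso_net():
    return en.Network(nodes=[en.Node("X")], edges=[], modules=["default"])


class TestRateTerms:
    def test_activation_zero_input(self):
        assert activation_term(0.0, 3, 0.5) == 0.0

    @pytest.mark.parametrize("n,a", [(3, 0.5), (2, 0.3), (7, 0.8)])
    def test_half_saturation_at_threshold(self, n, a):
        assert activation_term(a, n, a) == pytest.approx(0.5)
        assert inhibition_term(a, n, a) == pytest.approx(0.5)

    def test_steepness_saturates_above_threshold(self):
        assert activation_term(0.7, 20, 0.5) > activation_term(0.7, 2, 0.5)
        assert activation_term(0.7, 200, 0.5) == pytest.approx(1.0, abs=1e-6)

    def test_inhibition_full_generation_when_absent(self):
        assert inhibition_term(0.0, 3, 0.5) == 1.0

    @given(x=unit, n=hill_n, a=hill_a)
    @settings(max_examples=200, derandomize=True)
    def test_terms_complementary_and_bounded(self, x, n, a):
        act = activation_term(x, n, a)
        inh = inhibition_term(x, n, a)
        assert 0.0 <= act <= 1.0 and 0.0 <= inh <= 1.0
        assert act + inh == pytest.approx(1.0)

    @given(n=hill_n, a=hill_a)
    @settings(max_examples=50, derandomize=True)
    def test_activation_monotone(self, n, a):
        xs = np.linspace(0, 1, 50)
        vals = activation_term(xs, n, a)
        assert np.all(np.diff(vals) >= -1e-12)  # up to float rounding

    def test_parameters_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            activation_term(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            inhibition_term(0.5, 3, 1.5)
        with pytest.raises(ValueError):
            activation_term(1.5, 3, 0.5)


class TestNodeRate:
    def test_input_free_node_has_zero_generation(self, iso_net):
        assert node_rate(iso_net, None, "X", [0.7]) == 0.0

    def test_no_active_activator_means_no_generation(self):
        # one activator at 0 and one inhibitor at 0: activation gate closed
        net = en.parse_network(
            "NODE T\nNODE U\nNODE V\nEDGE U T +\nEDGE V T -\n")
        assert node_rate(net, None, "T", [0.9, 0.0, 0.0]) == 0.0

    def test_single_activator_reduces_to_activation_term(self):
        net = en.parse_network("NODE T\nNODE U\nEDGE U T +\n")
        for x in (0.2, 0.5, 0.9):
            assert node_rate(net, None, "T", [0.0, x]) == pytest.approx(
                float(activation_term(x, 3, 0.5)))

    def test_depends_only_on_in_neighbors(self, mini_net):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, mini_net.n_nodes)
        y = x.copy()
        y[mini_net.index("TgtB1")] = 0.99  # not an input of TgtA1
        assert node_rate(mini_net, None, "TgtA1", x) == pytest.approx(
            node_rate(mini_net, None, "TgtA1", y))

    def test_unknown_node_raises(self, toggle_net):
        with pytest.raises(en.network.NetworkReferenceError):
            node_rate(toggle_net, None, "nope", [0.5, 0.5])


class TestRhs:
    def test_fixed_point_gives_zero_vector(self, toggle_net):
        # the symmetric state of the plain toggle is a fixed point
        assert rhs(toggle_net, None, [0.5, 0.5]) == pytest.approx([0.0, 0.0])

    def test_isolated_node_pure_decay(self, iso_net):
        assert rhs(iso_net, None, [0.7])[0] == pytest.approx(-0.7)

    def test_toggle_symmetry(self, toggle_net):
        d = rhs(toggle_net, None, [0.3, 0.3])
        assert d[0] == pytest.approx(d[1])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_rhs_bounded_and_inward_on_boundary(self, seed):
        net = syn.make_random_signed_network(8, 2.0, 0.4, seed=seed % 100)
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 8)
        # push some coordinates onto the box boundary
        x[rng.random(8) < 0.3] = 0.0
        x[rng.random(8) < 0.3] = 1.0
        d = rhs(net, None, x)
        assert np.all(d >= -1 - 1e-12) and np.all(d <= 1 + 1e-12)
        assert np.all(d[x == 0.0] >= 0)
        assert np.all(d[x == 1.0] <= 0)

    def test_dimension_mismatch(self, toggle_net):
        with pytest.raises(ValueError):
            rhs(toggle_net, None, [0.5])


class TestJacobian:
    def test_no_edges_gives_minus_identity(self):
        net = en.parse_network("NODE A\nNODE B\nNODE C\n")
        J = jacobian(net, None, [0.2, 0.5, 0.9])
        assert J == pytest.approx(-np.eye(3))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_central_difference_agreement(self, seed):
        net = syn.make_random_signed_network(10, 2.5, 0.4, seed=seed)
        dyn = CompiledDynamics(net, None)
        x = np.random.default_rng(seed).uniform(0.05, 0.95, 10)
        J = dyn.jacobian(x)
        h = 1e-6
        for j in range(10):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            col = (dyn.rhs(xp) - dyn.rhs(xm)) / (2 * h)
            assert col == pytest.approx(J[:, j], abs=1e-6)

    def test_sparsity_matches_adjacency(self, mini_net):
        dyn = CompiledDynamics(mini_net, None)
        J = dyn.jacobian(np.full(mini_net.n_nodes, 0.37))
        regulated = {(mini_net.index(e.target), mini_net.index(e.source))
                     for e in mini_net.edges}
        for i in range(mini_net.n_nodes):
            for j in range(mini_net.n_nodes):
                if i != j and (i, j) not in regulated:
                    assert J[i, j] == 0.0

    def test_toggle_symmetric_state_is_a_saddle_spectrum(self, toggle_net):
        J = jacobian(toggle_net, None, [0.5, 0.5])
        eig = np.sort(np.linalg.eigvals(J).real)
        assert np.sum(eig > 0) == 1


class TestIntegrate:
    def test_exponential_decay_closed_form(self, iso_net):
        traj = integrate(iso_net, None, [1.0], 1.0)
        assert traj.final_state[0] == pytest.approx(np.exp(-1), abs=1e-6)

    def test_times_strictly_increasing(self, toggle_net):
        traj = integrate(toggle_net, None, [0.3, 0.8], 10.0)
        assert np.all(np.diff(traj.times) > 0)

    def test_toggle_basin_convergence(self, toggle_net):
        traj = integrate(toggle_net, None, [0.9, 0.1], 100.0,
                         converge_tol=1e-8)
        assert traj.final_state == pytest.approx([0.98807, 0.11472], abs=1e-4)

    def test_clamped_node_held_exactly(self, toggle_net):
        traj = integrate(toggle_net, None, [0.9, 0.1], 20.0,
                         clamps={"B": 1.0})
        assert np.all(traj.states[:, 1] == 1.0)
        # A relaxes toward its fully-inhibited level a^n/(a^n + 1) = 1/9
        assert traj.final_state[0] == pytest.approx(1 / 9, abs=1e-6)

    def test_trajectory_stays_in_unit_box(self, mini_net):
        rng = np.random.default_rng(5)
        for _ in range(10):
            traj = integrate(mini_net, None, rng.uniform(0, 1, 8), 30.0)
            assert traj.states.min() >= -1e-7
            assert traj.states.max() <= 1 + 1e-7

    def test_bad_inputs_rejected(self, toggle_net):
        with pytest.raises(ValueError):
            integrate(toggle_net, None, [0.5, 0.5], -1.0)
        with pytest.raises(en.dynamics.DynamicsError):
            integrate(toggle_net, None, [0.5, 0.5], 1.0, clamps={"Z": 1.0})
        with pytest.raises(en.dynamics.DynamicsError):
            integrate(toggle_net, None, [0.5, 0.5], 1.0, clamps={"A": 2.0})
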