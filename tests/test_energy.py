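"""Gramian, minimum-energy control, analytic gradient and OPGM."""

import numpy as np
import pytest
from scipy.linalg import expm

from netctrl import (
    LTISystem,
    OPGMConfig,
    build_B,
    cost_vs_longest_path,
    expected_cost,
    grad_cost,
    gramian,
    make_circle,
    make_stem,
    min_energy_control,
    opgm,
)
from netctrl.energy import (
    ControllabilityError,
    ControllabilityWarning,
    OPGMDivergenceError,
)

from conftest import quadrature_gramian, random_stable_matrix


def scalar_system(t_f=1.0):
    return LTISystem(np.array([[0.0]]), t_f=t_f)


class TestGramian:
    def test_integrator_gramian_is_linear_in_horizon(self):
        b = np.array([[1.0]])
        assert gramian(scalar_system(1.0), b) == pytest.approx(1.0)
        assert gramian(scalar_system(2.0), b) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed,n", [(0, 3), (1, 5), (2, 8)])
    def test_matches_quadrature_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        a = random_stable_matrix(n, rng)
        b = rng.standard_normal((n, 2))
        sys = LTISystem(a, t_f=1.5)
        w = gramian(sys, b)
        oracle = quadrature_gramian(a, b, 1.5)
        assert np.linalg.norm(w - oracle) / np.linalg.norm(oracle) < 1e-8
        assert np.allclose(w, w.T)

    def test_ill_conditioning_warns(self):
        net = make_stem(12)
        sys = LTISystem.from_network(net)
        b = build_B(net, ["1"])
        with pytest.warns(ControllabilityWarning):
            gramian(sys, b)

    def test_validation(self):
        with pytest.raises(ValueError):
            LTISystem(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            LTISystem(np.zeros((2, 2)), t_f=0.0)


class TestMinimumEnergyControl:
    def test_scalar_closed_form(self):
        ctrl = min_energy_control(scalar_system(), [[1.0]], [1.0])
        assert ctrl.cost == pytest.approx(1.0)
        for t in (0.0, 0.4, 1.0):
            assert ctrl.u(t) == pytest.approx(-1.0)
        assert abs(ctrl.terminal_state()[0]) < 1e-9

    def test_zero_initial_state_costs_nothing(self):
        ctrl = min_energy_control(scalar_system(), [[1.0]], [0.0])
        assert ctrl.cost == 0.0 and ctrl.u(0.5) == pytest.approx(0.0)

    def test_drives_stem_to_origin(self):
        net = make_stem(4)
        sys = LTISystem.from_network(net)
        b = build_B(net, ["1"])
        x0 = np.random.default_rng(0).standard_normal(4)
        ctrl = min_energy_control(sys, b, x0)
        assert np.linalg.norm(ctrl.terminal_state()) <= 1e-6 * np.linalg.norm(x0)
        assert ctrl.realized_cost() == pytest.approx(ctrl.cost, rel=1e-6)

    def test_uncontrollable_input_raises(self):
        net = make_stem(3)
        sys = LTISystem.from_network(net)
        b = build_B(net, ["3"])  # the tail cannot reach upstream nodes
        with pytest.warns(ControllabilityWarning):
            with pytest.raises(ControllabilityError):
                min_energy_control(sys, b, [1.0, 0.0, 0.0])

    def test_null_space_perturbation_raises_cost(self):
        """Adding an input component that leaves the terminal state
        untouched can only increase the energy."""
        net = make_stem(2)
        sys = LTISystem.from_network(net)
        b = build_B(net, ["1"])
        x0 = np.array([1.0, -0.5])
        ctrl = min_energy_control(sys, b, x0)

        def legendre2(t):  # orthogonal to {1, t} on [0, 1]
            x = 2 * t - 1
            return 0.5 * (3 * x * x - 1)

        from scipy.integrate import quad, solve_ivp

        for eps in (0.5, 2.0):
            u_pert = lambda t: ctrl.u(t) + eps * legendre2(t)
            sol = solve_ivp(
                lambda t, x: sys.A @ x + b @ u_pert(t),
                (0, 1.0),
                x0,
                rtol=1e-10,
                atol=1e-12,
            )
            assert np.linalg.norm(sol.y[:, -1]) < 1e-7  # still reaches origin
            cost_pert = quad(lambda t: float(u_pert(t) @ u_pert(t)), 0, 1.0)[0]
            assert cost_pert > ctrl.cost


class TestExpectedCost:
    def test_scalar_unit(self):
        assert expected_cost(scalar_system(), [[1.0]]) == pytest.approx(1.0)

    def test_nonnegative(self):
        rng = np.random.default_rng(7)
        a = random_stable_matrix(4, rng)
        b = rng.standard_normal((4, 2))
        assert expected_cost(LTISystem(a), b) >= 0.0

    def test_monte_carlo_identity(self):
        """The trace formula equals the mean realized cost over random
        unit-variance initial states (within Monte-Carlo error)."""
        net = make_stem(3)
        sys = LTISystem.from_network(net)
        b = build_B(net, ["1"])
        e = expected_cost(sys, b)
        w = gramian(sys, b)
        e_tf = expm(sys.A * sys.t_f)
        q = e_tf.T @ np.linalg.solve(w, e_tf)
        x = np.random.default_rng(1).standard_normal((10_000, 3))
        costs = np.einsum("ij,jk,ik->i", x, q, x)
        se = costs.std() / np.sqrt(len(costs))
        assert abs(costs.mean() - e) <= 3 * se

    def test_extended_precision_agrees_with_double(self):
        net = make_circle(8)
        sys = LTISystem.from_network(net)
        b = build_B(net, ["1", "5"])
        assert expected_cost(sys, b, precision=40) == pytest.approx(
            expected_cost(sys, b), rel=1e-8
        )


class TestGradient:
    def test_scalar_derivative(self):
        g = grad_cost(scalar_system(), [[1.0]])
        assert g[0, 0] == pytest.approx(-2.0)

    @pytest.mark.parametrize(
        "make",
        [
            # the stem input mixes all nodes so the Gramian stays well
            # conditioned and central differences remain trustworthy
            lambda rng: (
                make_stem(3).adjacency_matrix(),
                np.array([[0.9], [0.4], [0.2]]) / np.linalg.norm([0.9, 0.4, 0.2]),
            ),
            lambda rng: (
                random_stable_matrix(4, rng),
                np.linalg.qr(rng.standard_normal((4, 2)))[0],
            ),
        ],
    )
    def test_matches_finite_differences(self, make):
        rng = np.random.default_rng(11)
        a, b = make(rng)
        sys = LTISystem(a)
        g = grad_cost(sys, b)
        h = 1e-6
        fd = np.zeros_like(b)
        for i in range(b.shape[0]):
            for j in range(b.shape[1]):
                bp, bm = b.copy(), b.copy()
                bp[i, j] += h
                bm[i, j] -= h
                fd[i, j] = (expected_cost(sys, bp) - expected_cost(sys, bm)) / (2 * h)
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-4

    def test_scaling_homogeneity(self):
        """B -> cB scales W by c^2, E by c^-2 and the gradient by c^-3."""
        rng = np.random.default_rng(13)
        net = make_stem(3)
        sys = LTISystem.from_network(net)
        b, _ = np.linalg.qr(rng.standard_normal((3, 1)))
        c = 1.7
        assert expected_cost(sys, c * b) == pytest.approx(
            expected_cost(sys, b) / c**2, rel=1e-9
        )
        np.testing.assert_allclose(
            grad_cost(sys, c * b), grad_cost(sys, b) / c**3, rtol=1e-8
        )


class TestOPGM:
    def test_rescaling_enforces_trace_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            b_hat = rng.standard_normal((5, 2)) * rng.uniform(0.1, 10)
            t = b_hat.T @ b_hat
            b = np.sqrt(np.trace(t) / np.trace(t @ t)) * b_hat
            tb = b.T @ b
            assert abs(np.trace(tb @ tb) - np.trace(tb)) < 1e-10

    def test_identity_init_is_fixed_point(self):
        sys = LTISystem.from_network(make_stem(3))
        res = opgm(sys, 3, OPGMConfig(init=np.eye(3)))
        np.testing.assert_array_equal(res.B, np.eye(3))
        assert res.iterations == 1

    def test_cost_decreases_monotonically_for_small_eta(self):
        for net, eta in ((make_stem(3), 1e-5), (make_circle(4), 1e-8)):
            sys = LTISystem.from_network(net)
            res = opgm(sys, 1, OPGMConfig(eta=eta, max_iters=300, seed=1))
            diffs = np.diff(res.costs)
            assert np.all(diffs <= np.abs(res.costs[:-1]) * 1e-12)
            assert res.orthonormality_residual < 1e-10

    def test_converged_column_concentrates_on_path_head(self):
        sys = LTISystem.from_network(make_stem(3))
        res = opgm(sys, 1, OPGMConfig(eta=1e-5, max_iters=3000, seed=1, tol=1e-13))
        assert int(np.argmax(np.abs(res.B[:, 0]))) == 0
        assert res.costs[-1] < res.costs[0]

    def test_large_eta_reports_divergence(self):
        sys = LTISystem.from_network(make_circle(4))
        with pytest.raises(OPGMDivergenceError):
            opgm(sys, 1, OPGMConfig(eta=1e-2, max_iters=200, seed=2))

    def test_validation(self):
        sys = LTISystem.from_network(make_stem(3))
        with pytest.raises(ValueError):
            opgm(sys, 0)
        with pytest.raises(ValueError):
            OPGMConfig(eta=-1.0)


class TestCircleLayouts:
    def test_even_spacing_beats_clustering(self):
        even = cost_vs_longest_path(12, 6, layouts=[[1, 3, 5, 7, 9, 11]])
        clustered = cost_vs_longest_path(12, 6, layouts=[[1, 2, 3, 4, 5, 6]])
        assert even.cost[0] < clustered.cost[0]
        assert even.longest_segment[0] == 2
        assert clustered.longest_segment[0] == 7

    def test_full_coverage_is_cheapest(self):
        full = cost_vs_longest_path(12, 12, layouts=[list(range(1, 13))])
        assert full.longest_segment[0] == 1
        some = cost_vs_longest_path(12, 6, n_layouts=5, seed=0)
        assert full.cost[0] < some.cost.min()

    def test_equal_segments_have_comparable_costs(self):
        df = cost_vs_longest_path(
            12, 2, layouts=[[1, 7], [2, 8], [3, 9]]
        )
        assert df.longest_segment.nunique() == 1
        assert df.cost.max() / df.cost.min() < 1.5
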