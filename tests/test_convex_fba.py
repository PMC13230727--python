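"""Forward convex FBA: optima, duals, feasibility, and the solution map.

The independent oracle used here never touches the production solve
path: feasible points are harvested from vertex enumeration with random
linear objectives plus convex mixing, and the best candidate is refined
with SLSQP on the raw constrained formulation.
"""

import numpy as np
import pytest
from scipy.optimize import linprog, minimize

from celltarget.basis import evaluate_basis, sign_for
from celltarget.convex_fba import LowerConfig, solve_forward, solution_jacobian
from celltarget.datasets import random_network
from celltarget.network_io import MetabolicNetwork, ObjectiveSpec


def brute_objective(net, spec, seed=0, n_mix=400):
    """Independent optimum estimate: sampled polytope + SLSQP refinement."""
    rng = np.random.default_rng(seed)
    n = net.n_reactions
    verts = []
    for _ in range(30):
        c = rng.normal(size=n)
        res = linprog(c, A_eq=net.S, b_eq=np.zeros(net.n_metabolites),
                      bounds=list(zip(net.v_min, net.v_max)), method="highs")
        if res.status == 0:
            verts.append(res.x)
    verts = np.asarray(verts)
    pts = [verts[i] for i in range(len(verts))]
    for _ in range(n_mix):
        w = rng.dirichlet(np.ones(len(verts)))
        pts.append(w @ verts)
    O = list(spec.candidate_index)
    sgn = sign_for(spec.mode)

    def f(v):
        return sgn * evaluate_basis(spec.mode, spec.C, v[O])

    best = min(pts, key=f)
    res = minimize(f, best, method="SLSQP",
                   constraints={"type": "eq", "fun": lambda v: net.S @ v},
                   bounds=list(zip(net.v_min, net.v_max)),
                   options={"maxiter": 500, "ftol": 1e-14})
    cand = [f(best)] + ([f(res.x)] if res.success else [])
    return sgn * min(cand)


class TestForwardSolve:
    def test_toy_min_norm_matches_reference(self, toy_net):
        spec = ObjectiveSpec(tuple(range(5)), "norm", np.zeros(5))
        res = solve_forward(toy_net, spec)
        assert res.status == "optimal"
        v = res.v_opt
        assert v[1] == pytest.approx(-2.0, abs=1e-6)
        assert v[2] == pytest.approx(1.0, abs=1e-6)
        assert v[3] == pytest.approx(1.0, abs=1e-6)
        assert abs(v[0]) <= 1e-4 and abs(v[4]) <= 1e-4

    def test_single_reaction_closest_feasible_point(self):
        net = MetabolicNetwork(["M1"], ["r1"], [[0.0]], [1.0], [2.0])
        spec = ObjectiveSpec((0,), "sum_squares", np.zeros(1))
        res = solve_forward(net, spec)
        assert res.status == "optimal"
        assert res.v_opt[0] == pytest.approx(1.0, abs=1e-9)
        assert res.dual_lower[0] > 0  # lower bound is active and binding

    def test_empty_polytope_reported_infeasible(self):
        net = MetabolicNetwork(["M1"], ["r1", "r2"], [[1.0, 1.0]],
                               [1.0, 1.0], [2.0, 2.0])
        spec = ObjectiveSpec((0, 1), "sum_squares", np.zeros(2))
        res = solve_forward(net, spec)
        assert res.status == "infeasible"
        assert res.v_opt is None

    @pytest.mark.parametrize("mode", ["norm", "sum_squares", "logsumexp"])
    def test_feasibility_and_dual_signs(self, toy_net, mode, rng):
        for _ in range(3):
            spec = ObjectiveSpec(tuple(range(5)), mode, rng.normal(size=5))
            res = solve_forward(toy_net, spec)
            assert res.status == "optimal"
            assert np.all(res.v_opt >= toy_net.v_min - 1e-8)
            assert np.all(res.v_opt <= toy_net.v_max + 1e-8)
            assert np.abs(toy_net.S @ res.v_opt).max() <= 1e-8
            assert res.dual_upper.min() >= -1e-10
            assert res.dual_lower.min() >= -1e-10

    def test_relaxed_steady_state_band_and_duals(self, toy_net):
        cfg = LowerConfig(eps_ss=1e-2)
        spec = ObjectiveSpec(tuple(range(5)), "sum_squares", np.zeros(5))
        res = solve_forward(toy_net, spec, cfg)
        assert res.status == "optimal"
        assert np.abs(toy_net.S @ res.v_opt).max() <= 1e-2 + 1e-8
        # stationarity must hold with the signed combined equality duals
        from celltarget.kkt import compute_residuals
        rep = compute_residuals(toy_net, res, spec, cfg)
        assert rep.stationarity <= 1e-8

    def test_inverse_log_maximises_linear_form(self, toy_net):
        spec = ObjectiveSpec(tuple(range(5)), "inverse_log", np.zeros(5))
        res = solve_forward(toy_net, spec)
        assert res.status == "optimal"
        # the optimum maximises sum(C v); compare against the LP oracle
        lp = linprog(-spec.C, A_eq=toy_net.S, b_eq=np.zeros(2),
                     bounds=list(zip(toy_net.v_min, toy_net.v_max)),
                     method="highs")
        assert spec.C @ res.v_opt == pytest.approx(spec.C @ lp.x, rel=1e-8)

    @pytest.mark.parametrize("mode", ["norm", "sum_squares", "logsumexp"])
    def test_oracle_equivalence_small_networks(self, toy_net, mode):
        specs = [(toy_net, ObjectiveSpec(tuple(range(5)), mode,
                                         np.array([0.1, -0.2, 0.3, 0.0, -0.1])))]
        net6 = random_network(2, 5, seed=9)
        specs.append((net6, ObjectiveSpec(tuple(range(5)), mode,
                                          np.array([0.5, 0.0, -0.5, 0.2, 0.1]))))
        for net, spec in specs:
            res = solve_forward(net, spec)
            assert res.status == "optimal"
            oracle = brute_objective(net, spec, seed=1)
            assert res.objective_value <= oracle + 1e-3

    def test_deterministic_given_inputs(self, toy_net):
        spec = ObjectiveSpec(tuple(range(5)), "sum_squares",
                             np.array([0.3, -0.1, 0.2, 0.0, 0.1]))
        r1 = solve_forward(toy_net, spec)
        r2 = solve_forward(toy_net, spec)
        np.testing.assert_array_equal(r1.v_opt, r2.v_opt)
        np.testing.assert_array_equal(r1.dual_eq, r2.dual_eq)


class TestSolutionJacobian:
    @pytest.mark.parametrize("mode", ["norm", "sum_squares", "logsumexp"])
    def test_matches_central_finite_differences(self, toy_net, mode):
        rng = np.random.default_rng(3)
        spec = ObjectiveSpec(tuple(range(5)), mode, rng.normal(size=5) * 0.5)
        J, _ = solution_jacobian(toy_net, spec)
        C = spec.C
        h = 1e-5
        for j in range(5):
            Cp, Cm = C.copy(), C.copy()
            Cp[j] += h
            Cm[j] -= h
            vp = solve_forward(toy_net, ObjectiveSpec.from_C(
                range(5), mode, Cp / Cp.sum())).v_opt
            vm = solve_forward(toy_net, ObjectiveSpec.from_C(
                range(5), mode, Cm / Cm.sum())).v_opt
            fd = (vp - vm) / (2 * h)
            # simplex renormalisation perturbs along e_j - C
            model = J[:, j] - J @ C
            np.testing.assert_allclose(model, fd, atol=1e-3)

    def test_fixed_flux_row_is_zero(self):
        net = MetabolicNetwork(["M1"], ["r1", "r2"], [[0.0, 0.0]],
                               [1.0, -2.0], [1.0, 5.0])
        spec = ObjectiveSpec((0, 1), "sum_squares", np.zeros(2))
        J, _ = solution_jacobian(net, spec)
        np.testing.assert_allclose(J[0], 0.0, atol=1e-6)

    def test_vertex_optimum_flagged_degenerate_or_zero(self, toy_net):
        # the linear-forward mode sits at a vertex: dv/dC vanishes there
        spec = ObjectiveSpec(tuple(range(5)), "inverse_log", np.zeros(5))
        J, degenerate = solution_jacobian(toy_net, spec)
        assert degenerate or np.abs(J).max() < 1e-6
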