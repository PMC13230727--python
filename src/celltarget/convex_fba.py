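"""Lower-level parameterised convex FBA and its differentiable solution map.

The forward problem is

    min / max   f(C, v_O)                       (basis objective)
    subject to  S v = 0        (or  -eps <= S v <= eps  when relaxed)
                v_min <= v <= v_max

solved in two stages: a generic convex solve (HiGHS LP / trust-region
SQP) to locate the optimum and its active set, then a Newton polish of
the exact KKT system on that active set, which drives the residuals to
machine precision and yields the Lagrange multipliers reported to the
KKT verifier.

The same polished KKT matrix provides the sensitivity dv*/dC by implicit
differentiation, which is what makes the layer differentiable for the
upper-level objective-coefficient training.

Sign conventions follow the Lagrangian

    L = sgn f(v) + mu' (S v) + lam_up' (v - v_max) + lam_low' (v_min - v)

with sgn = +1 when minimising and -1 when maximising, so stationarity
reads  sgn grad f + S' mu + lam_up - lam_low = 0  with lam_up, lam_low
nonnegative and mu free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .basis import (
    basis_gradient,
    basis_hessian,
    basis_mixed_hessian,
    evaluate_basis,
    sign_for,
)
from .network_io import MetabolicNetwork, ObjectiveSpec

__all__ = ["LowerConfig", "SolveResult", "solve_forward", "solution_jacobian"]

# Steady-state relaxation: 0 (strict S v = 0) suits small and mid-size
# networks; 1e-2 / 1e-1 are the recommended tolerances for compact and
# genome-scale models respectively, where the strict equality can stall
# the solver.
_DEFAULT_EPS = 0.0


@dataclass(frozen=True)
class LowerConfig:
    """Numerical configuration of the lower convex programme."""

    eps_ss: float = _DEFAULT_EPS       # two-sided steady-state tolerance
    delta: float = 1e-6                # safeguard for inverse_log's logarithm
    solver_tolerance: float = 1e-9     # residual target of the generic solve
    active_tol: float = 1e-6           # active-set detection margin
    polish: bool = True                # Newton-polish the KKT system

    def __post_init__(self) -> None:
        if self.eps_ss < 0 or self.delta < 0 or self.solver_tolerance <= 0:
            raise ValueError("eps_ss, delta must be >= 0 and solver_tolerance > 0")


@dataclass
class SolveResult:
    """Optimal fluxes, duals and status of one forward solve."""

    v_opt: np.ndarray | None
    objective_value: float
    dual_eq: np.ndarray | None        # mu, length m, free sign
    dual_upper: np.ndarray | None     # lam_up >= 0, length n
    dual_lower: np.ndarray | None     # lam_low >= 0, length n
    status: str                       # optimal | inaccurate | infeasible | error
    degenerate: bool = False
    kkt_residual: float = np.nan      # inf-norm of the polished stationarity
    _cache: dict = field(default_factory=dict, repr=False)


def _embed(values: np.ndarray, index: tuple[int, ...], n: int) -> np.ndarray:
    out = np.zeros(n)
    out[list(index)] = values
    return out


def _feasible_point(network: MetabolicNetwork, eps: float):
    """Phase-1 LP: any point of the (relaxed) flux polytope, or None."""
    S, lb, ub = network.S, network.v_min, network.v_max
    kwargs = dict(c=np.zeros(network.n_reactions), bounds=list(zip(lb, ub)),
                  method="highs")
    if eps == 0.0:
        res = linprog(A_eq=S, b_eq=np.zeros(S.shape[0]), **kwargs)
    else:
        A = np.vstack([S, -S])
        res = linprog(A_ub=A, b_ub=np.full(2 * S.shape[0], eps), **kwargs)
    return res.x if res.status == 0 else None


def _objective_closures(network, spec, cfg):
    """Full-space objective/grad/hess (sgn-adjusted so we always minimise)."""
    O = list(spec.candidate_index)
    C = spec.C
    sgn = sign_for(spec.mode)
    n = network.n_reactions

    def fun(v):
        return sgn * evaluate_basis(spec.mode, C, v[O], cfg.delta)

    def grad(v):
        g, _ = basis_gradient(spec.mode, C, v[O], cfg.delta)
        return sgn * _embed(g, spec.candidate_index, n)

    def hess(v):
        H = np.zeros((n, n))
        H[np.ix_(O, O)] = sgn * basis_hessian(spec.mode, C, v[O], cfg.delta)
        return H

    return fun, grad, hess


def _generic_solve(network, spec, cfg, x0):
    """Stage 1: locate the optimum with a generic convex solver."""
    S, lb, ub = network.S, network.v_min, network.v_max
    m, n = S.shape
    O = list(spec.candidate_index)
    C = spec.C

    if spec.mode == "inverse_log":
        # maximising log(sum C_i v_i + delta) == maximising the linear form
        c = -_embed(C, spec.candidate_index, n)
        kwargs = dict(c=c, bounds=list(zip(lb, ub)), method="highs")
        if cfg.eps_ss == 0.0:
            res = linprog(A_eq=S, b_eq=np.zeros(m), **kwargs)
        else:
            A = np.vstack([S, -S])
            res = linprog(A_ub=A, b_ub=np.full(2 * m, cfg.eps_ss), **kwargs)
        if res.status != 0:
            return None
        return res.x

    if spec.mode == "norm":
        # ||x|| and ||x||^2 share their argmin; the squared form is smooth
        # everywhere, so stage 1 solves it and the polish restores the
        # norm-mode duals from the true gradient.
        spec = ObjectiveSpec(spec.candidate_index, "sum_squares", spec.theta)

    fun, grad, hess = _objective_closures(network, spec, cfg)
    if cfg.eps_ss == 0.0:
        cons = [LinearConstraint(S, 0.0, 0.0)]
    else:
        cons = [LinearConstraint(S, -cfg.eps_ss, cfg.eps_ss)]
    res = minimize(fun, x0, jac=grad, hess=hess, method="trust-constr",
                   constraints=cons, bounds=Bounds(lb, ub),
                   options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 500,
                            "verbose": 0})
    return res.x


def _detect_active(network, cfg, v):
    """Classify bounds and steady-state rows as active/inactive at v."""
    S, lb, ub = network.S, network.v_min, network.v_max
    tol = cfg.active_tol
    scale = 1.0 + np.maximum(np.abs(lb), np.abs(ub))
    scale[~np.isfinite(scale)] = 1.0
    low_act = (v - lb) <= tol * scale
    up_act = (ub - v) <= tol * scale
    fixed = (ub - lb) <= tol * scale
    Sv = S @ v
    if cfg.eps_ss == 0.0:
        ss_state = np.zeros(S.shape[0], dtype=int)  # 0 = equality
    else:
        ss_state = np.full(S.shape[0], 9, dtype=int)  # 9 = inactive
        ss_state[Sv >= cfg.eps_ss - tol] = 1          # at +eps
        ss_state[Sv <= -cfg.eps_ss + tol] = -1        # at -eps
    return low_act, up_act, fixed, ss_state


def _polish(network, spec, cfg, v0, max_rounds: int = 150):
    """Active-set refinement of the KKT system at a near-optimal point.

    Feasibility is preserved exactly throughout: the point is first
    projected onto the affine span of the active constraints, then a
    reduced-space (null-space) Newton method with backtracking line
    search minimises the objective within that span.  Steps that hit an
    inactive bound add it to the active set; multiplier sign violations
    drop a constraint; both trigger another round.  Duals are recovered
    from the stationarity system by least squares.

    Returns (v, mu, lam_up, lam_low, stationarity_residual, degenerate,
    cache).
    """
    from scipy.linalg import null_space

    S, lb, ub = network.S, network.v_min, network.v_max
    m, n = S.shape
    O = list(spec.candidate_index)
    C = spec.C
    sgn = sign_for(spec.mode)
    eps = cfg.eps_ss

    def objective(v):
        try:
            return sgn * evaluate_basis(spec.mode, C, v[O], cfg.delta)
        except Exception:
            return np.inf

    def gradient(v):
        g_O, deg = basis_gradient(spec.mode, C, v[O], cfg.delta)
        return sgn * _embed(g_O, spec.candidate_index, n), deg

    low_act, up_act, fixed, ss_state = _detect_active(network, cfg, v0)
    v = np.clip(v0, lb, ub)
    degenerate = False
    eye = np.eye(n)

    for _ in range(max_rounds):
        # --- assemble active constraint matrix G and targets h
        rows, targets, kinds = [], [], []
        for k in range(m):
            st = ss_state[k]
            if st == 9:
                continue
            rows.append(S[k])
            targets.append(0.0 if st == 0 else st * eps)
            kinds.append(("ss", k, st))
        for i in range(n):
            if fixed[i]:
                rows.append(eye[i]); targets.append(lb[i])
                kinds.append(("fix", i, 0))
            elif up_act[i]:
                rows.append(eye[i]); targets.append(ub[i])
                kinds.append(("up", i, 0))
            elif low_act[i]:
                rows.append(eye[i]); targets.append(lb[i])
                kinds.append(("low", i, 0))
        G = np.asarray(rows) if rows else np.zeros((0, n))
        h = np.asarray(targets)
        q = G.shape[0]

        # --- exact projection onto the active affine set
        if q:
            corr, *_ = np.linalg.lstsq(G, h - G @ v, rcond=None)
            v = v + corr
        Z = null_space(G) if q else eye

        # --- reduced Newton with backtracking; stop at a bound hit
        hit_bound = None
        if Z.size:
            for _ in range(60):
                g, deg_g = gradient(v)
                degenerate = degenerate or deg_g
                gz = Z.T @ g
                if np.abs(gz).max() < 1e-13:
                    break
                H = np.zeros((n, n))
                H[np.ix_(O, O)] = sgn * basis_hessian(spec.mode, C, v[O], cfg.delta)
                Hz = Z.T @ H @ Z
                with np.errstate(over="ignore", invalid="ignore"):
                    dw = -np.linalg.pinv(Hz, rcond=1e-12) @ gz
                    if not np.all(np.isfinite(dw)):
                        dw = -gz
                    # near-flat curvature can blow the Newton step up;
                    # cap it so the line search stays in float range
                    cap = 1e6 * (1.0 + np.abs(v).max())
                    nrm = float(np.sqrt(np.sum(np.minimum(np.abs(dw), 1e150) ** 2)))
                    if nrm > cap:
                        dw = np.clip(dw, -1e150, 1e150) * (cap / nrm)
                        nrm = cap
                    if gz @ dw > -1e-16 * np.linalg.norm(gz) * max(nrm, 1e-30):
                        dw = -gz  # fall back to steepest descent in the span
                dv = Z @ dw
                # largest step keeping inactive bounds and, under the
                # relaxed steady state, inactive +/-eps rows satisfied
                t_max, blocker = 1.0, None
                for i in range(n):
                    if fixed[i] or up_act[i] or low_act[i]:
                        continue
                    if dv[i] > 1e-14 and np.isfinite(ub[i]):
                        tb = (ub[i] - v[i]) / dv[i]
                        if tb < t_max:
                            t_max, blocker = tb, ("up", i)
                    elif dv[i] < -1e-14 and np.isfinite(lb[i]):
                        tb = (lb[i] - v[i]) / dv[i]
                        if tb < t_max:
                            t_max, blocker = tb, ("low", i)
                if eps > 0:
                    Sdv = S @ dv
                    Sv_cur = S @ v
                    for k in range(m):
                        if ss_state[k] != 9:
                            continue
                        if Sdv[k] > 1e-14:
                            tb = (eps - Sv_cur[k]) / Sdv[k]
                            if tb < t_max:
                                t_max, blocker = tb, ("ss+", k)
                        elif Sdv[k] < -1e-14:
                            tb = (-eps - Sv_cur[k]) / Sdv[k]
                            if tb < t_max:
                                t_max, blocker = tb, ("ss-", k)
                f0 = objective(v)
                t = t_max
                armijo = 1e-4 * (gz @ dw)
                for _ in range(50):
                    if objective(v + t * dv) <= f0 + t * armijo:
                        break
                    t *= 0.5
                else:
                    break  # no acceptable step: stationary to precision
                v = v + t * dv
                if blocker is not None and t >= t_max * (1 - 1e-12):
                    hit_bound = blocker
                    break
                if t * np.abs(dv).max() < 1e-16:
                    break
        if hit_bound is not None:
            kind, i = hit_bound
            if kind == "ss+":
                ss_state[i] = 1
            elif kind == "ss-":
                ss_state[i] = -1
            else:
                v[i] = ub[i] if kind == "up" else lb[i]
                (up_act if kind == "up" else low_act)[i] = True
            continue

        # --- duals by least squares on the stationarity system
        g, deg_g = gradient(v)
        degenerate = degenerate or deg_g
        y = (np.linalg.lstsq(G.T, -g, rcond=None)[0] if q else np.zeros(0))

        # --- dual sign check; drop the worst violator and re-polish
        worst, worst_idx = -1e-9, None
        for j, (kind, idx, st) in enumerate(kinds):
            if kind == "up" and y[j] < worst:
                worst, worst_idx = y[j], j
            elif kind == "low" and -y[j] < worst:
                worst, worst_idx = -y[j], j
            elif kind == "ss" and st == 1 and y[j] < worst:
                worst, worst_idx = y[j], j
            elif kind == "ss" and st == -1 and -y[j] < worst:
                worst, worst_idx = -y[j], j
        if worst_idx is None:
            break
        kind, idx, st = kinds[worst_idx]
        if kind == "up":
            up_act[idx] = False
        elif kind == "low":
            low_act[idx] = False
        else:
            ss_state[idx] = 9
    # --- unpack multipliers
    mu = np.zeros(m)
    lam_up = np.zeros(n)
    lam_low = np.zeros(n)
    for j, (kind, idx, st) in enumerate(kinds):
        if kind == "ss":
            mu[idx] = y[j]
        elif kind == "fix":
            lam_up[idx] = max(y[j], 0.0)
            lam_low[idx] = max(-y[j], 0.0)
        elif kind == "up":
            lam_up[idx] = max(y[j], 0.0)
        else:
            lam_low[idx] = max(-y[j], 0.0)

    g_O, deg_g = basis_gradient(spec.mode, C, v[O], cfg.delta)
    g = sgn * _embed(g_O, spec.candidate_index, n)
    stat = np.abs(g + S.T @ mu + lam_up - lam_low).max()
    cache = {"G": G, "kinds": kinds, "y": y}
    return v, mu, lam_up, lam_low, stat, degenerate or deg_g, cache


def solve_forward(network: MetabolicNetwork, spec: ObjectiveSpec,
                  cfg: LowerConfig | None = None) -> SolveResult:
    """Solve the forward FBA programme for the current coefficients.

    Returns the optimal flux vector with equality and bound-constraint
    multipliers; ``status`` is ``infeasible`` when the (relaxed) flux
    polytope is empty and ``inaccurate`` when the polished stationarity
    residual exceeds the solver tolerance.
    """
    cfg = cfg or LowerConfig()
    n = network.n_reactions
    if np.any(network.v_min > network.v_max):
        return SolveResult(None, np.nan, None, None, None, "infeasible")
    for i in spec.candidate_index:
        if not 0 <= i < n:
            raise ValueError(f"candidate index {i} outside network with n={n}")

    x0 = _feasible_point(network, cfg.eps_ss)
    if x0 is None:
        return SolveResult(None, np.nan, None, None, None, "infeasible")

    # The active-set refinement is itself a complete solver for the
    # smooth modes (reduced Newton + one-at-a-time pivoting converges
    # from any feasible point), so the generic solve only runs for the
    # linear-forward mode, when polishing is disabled, or as a fallback.
    try:
        if cfg.polish and spec.mode != "inverse_log":
            v = x0
        else:
            v = _generic_solve(network, spec, cfg, x0)
    except Exception:
        return SolveResult(None, np.nan, None, None, None, "error")
    if v is None:
        return SolveResult(None, np.nan, None, None, None, "infeasible")

    def finish(v):
        degenerate = False
        if cfg.polish:
            if spec.mode == "norm":
                # refine through the smooth squared surrogate first; at a
                # zero-norm optimum the kink admits only the 0 subgradient,
                # certified with all multipliers zero
                surrogate = ObjectiveSpec(spec.candidate_index, "sum_squares",
                                          spec.theta)
                v, *_, cache = _polish(network, surrogate, cfg, v)
                x = spec.C * v[list(spec.candidate_index)]
                if np.linalg.norm(x) <= 1e-9 * (1.0 + np.abs(v).max()):
                    return SolveResult(
                        np.clip(v, network.v_min, network.v_max),
                        float(np.linalg.norm(x)),
                        np.zeros(network.n_metabolites), np.zeros(n),
                        np.zeros(n), "optimal", degenerate=True,
                        kkt_residual=0.0, _cache=cache)
            v, mu, lam_up, lam_low, stat, degenerate, cache = _polish(
                network, spec, cfg, v)
        else:
            mu = np.zeros(network.n_metabolites)
            lam_up = np.zeros(n)
            lam_low = np.zeros(n)
            stat = np.nan
            cache = {}

        # clip solver fuzz off the box so feasibility invariants hold exactly
        v = np.clip(v, network.v_min, network.v_max)
        obj = evaluate_basis(spec.mode, spec.C,
                             v[list(spec.candidate_index)], cfg.delta)
        Sv = network.S @ v
        feas = np.abs(Sv).max() <= max(cfg.eps_ss, 0.0) + 1e-7 if Sv.size else True
        status = "optimal"
        if cfg.polish and (not feas or not np.isfinite(stat) or stat > 1e-4):
            status = "inaccurate"
        return SolveResult(v, obj, mu, lam_up, lam_low, status,
                           degenerate=degenerate, kkt_residual=stat,
                           _cache=cache)

    result = finish(v)
    if (result.status == "inaccurate" and cfg.polish
            and spec.mode != "inverse_log"):
        # pivoting stalled; fall back to the generic solver for a
        # near-optimal start and refine once more
        try:
            v2 = _generic_solve(network, spec, cfg, x0)
        except Exception:
            return result
        if v2 is not None:
            retry = finish(v2)
            if retry.status == "optimal" or (
                    np.isfinite(retry.kkt_residual)
                    and retry.kkt_residual < result.kkt_residual):
                return retry
    return result


def solution_jacobian(network: MetabolicNetwork, spec: ObjectiveSpec,
                      cfg: LowerConfig | None = None,
                      result: SolveResult | None = None) -> tuple[np.ndarray, bool]:
    """Sensitivity dv*/dC of the optimal fluxes to the coefficients.

    Implicit differentiation of the polished KKT system: with active
    constraint matrix G and Lagrangian Hessian H at the optimum,

        [ sgn H   G' ] [ dv/dC ]     [ -sgn d(grad f)/dC ]
        [   G     0  ] [ dy/dC ]  =  [         0         ]

    Entries of fluxes pinned by active bounds are exactly zero.  A
    singular KKT matrix (degenerate active set, e.g. vertex solutions of
    linear forward objectives) is solved in the least-squares sense and
    flagged via the returned ``degenerate`` boolean.
    """
    cfg = cfg or LowerConfig()
    if result is None or result.status not in ("optimal", "inaccurate"):
        result = solve_forward(network, spec, cfg)
    if result.status not in ("optimal", "inaccurate"):
        raise RuntimeError(f"forward solve failed with status {result.status}")

    n = network.n_reactions
    O = list(spec.candidate_index)
    d = len(O)
    sgn = sign_for(spec.mode)
    v = result.v_opt
    G = result._cache.get("G")
    if G is None:  # solved without polish; recover the active set now
        _, _, _, _, _, _, cache = _polish(network, spec, cfg, v.copy())
        G = cache["G"]
    q = G.shape[0]

    H = np.zeros((n, n))
    H[np.ix_(O, O)] = sgn * basis_hessian(spec.mode, spec.C, v[O], cfg.delta)
    M = np.zeros((n, d))
    M[O, :] = sgn * basis_mixed_hessian(spec.mode, spec.C, v[O], cfg.delta)

    K = np.block([[H, G.T], [G, np.zeros((q, q))]])
    rhs = np.vstack([-M, np.zeros((q, d))])
    degenerate = bool(result.degenerate)
    if np.linalg.matrix_rank(K, tol=1e-10) < K.shape[0]:
        degenerate = True
    sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    J = sol[:n, :]
    return J, degenerate
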