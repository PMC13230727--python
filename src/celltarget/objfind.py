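"""Single-level convex benchmark with partially enforced KKT conditions.

Instead of differentiating through the forward solve, this benchmark
optimises fluxes, objective coefficients and forward-problem duals
*jointly* in one convex programme:

    min   sum_{j in M} (v_j - v_j^exp)^2  +  rho_kkt * R_KKT
    s.t.  -eps_ss <= S v <= eps_ss
          v_min <= v <= v_max
          C + S' y_pos - S' y_neg - mu_lb + mu_ub = 0   (stationarity)
          C_j = 0 (j not in O),  C_j >= 0 (j in O),  sum_O C_j = 1
          y_pos, y_neg, mu_lb, mu_ub >= 0

Complementary slackness is *not* imposed; deviations from ideal KKT
behaviour are discouraged through the convex penalty

    R_KKT = (1/m)(||y_pos||_1 + ||y_neg||_1
                  + ||eps - S v||_1 + ||eps + S v||_1)
          + (1/n)(||mu_lb||_1 + ||mu_ub||_1
                  + ||v - v_min||_1 + ||v_max - v||_1)

which penalises both dual magnitudes and constraint slacks.  Within the
feasible set every absolute value resolves to a linear form, so the
whole problem is a convex QP.  Infinite bounds would make the slack
terms undefined; they are clipped to a +/-1e4 box (and the affected
reactions flagged) for both the penalty and the constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize

from .network_io import FluxDataset, MetabolicNetwork

__all__ = ["ObjFindVariables", "r_kkt", "solve_objfind", "BOUND_CLIP"]

BOUND_CLIP = 1e4  # finite box substituted for infinite bounds


@dataclass
class ObjFindVariables:
    """Joint variable block of the single-level programme."""

    v: np.ndarray        # fluxes, length n
    C: np.ndarray        # coefficients, length n, zero outside O
    y_pos: np.ndarray    # steady-state duals (>=0), length m
    y_neg: np.ndarray    # steady-state duals (>=0), length m
    mu_lb: np.ndarray    # lower-bound duals (>=0), length n
    mu_ub: np.ndarray    # upper-bound duals (>=0), length n
    rho_kkt: float = 1e-2

    def __post_init__(self) -> None:
        for name in ("v", "C", "y_pos", "y_neg", "mu_lb", "mu_ub"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.rho_kkt <= 0:
            raise ValueError("rho_kkt must be positive")


def _clipped_bounds(network: MetabolicNetwork):
    lb = np.maximum(network.v_min, -BOUND_CLIP)
    ub = np.minimum(network.v_max, BOUND_CLIP)
    clipped = [network.reaction_ids[i] for i in
               np.nonzero((lb != network.v_min) | (ub != network.v_max))[0]]
    return lb, ub, clipped


def r_kkt(vars: ObjFindVariables, network: MetabolicNetwork,
          eps_ss: float = 0.0) -> float:
    """Evaluate the KKT-deviation penalty exactly.

    Nonnegative whenever the relaxed constraints hold; linear in the
    dual magnitudes.  Infinite bounds are clipped to the +/-1e4 box.
    """
    m, n = network.S.shape
    lb, ub, _ = _clipped_bounds(network)
    Sv = network.S @ vars.v
    met = (np.abs(vars.y_pos).sum() + np.abs(vars.y_neg).sum()
           + np.abs(eps_ss - Sv).sum() + np.abs(eps_ss + Sv).sum()) / m
    rxn = (np.abs(vars.mu_lb).sum() + np.abs(vars.mu_ub).sum()
           + np.abs(vars.v - lb).sum() + np.abs(ub - vars.v).sum()) / n
    return float(met + rxn)


def solve_objfind(network: MetabolicNetwork, data: FluxDataset,
                  candidate_index=None, eps_ss: float = 0.0,
                  rho_kkt: float = 1e-2):
    """Solve the single-level convex programme.

    Returns ``(C_full, v, report)`` where ``C_full`` (length n, zero
    off the candidate set) lies on the simplex restricted to O and the
    report separates the data-fit term from the KKT penalty.  Status
    ``infeasible`` (in the report) means the stationarity system admits
    no simplex-constrained C.
    """
    S = network.S
    m, n = S.shape
    O = (tuple(range(n)) if candidate_index is None
         else tuple(int(i) for i in candidate_index))
    if not O or not data.measured_index:
        raise ValueError("candidate set O and measured set M must be nonempty")
    d = len(O)
    M_idx = list(data.measured_index)
    lb, ub, clipped = _clipped_bounds(network)

    # variable layout: [v (n) | C_O (d) | y_pos (m) | y_neg (m) | mu_lb (n) | mu_ub (n)]
    N = n + d + 2 * m + 2 * n
    sl_v = slice(0, n)
    sl_C = slice(n, n + d)
    sl_yp = slice(n + d, n + d + m)
    sl_yn = slice(n + d + m, n + d + 2 * m)
    sl_ml = slice(n + d + 2 * m, n + d + 2 * m + n)
    sl_mu = slice(n + d + 2 * m + n, N)

    # inside the feasible set the R_KKT slack terms are affine:
    # ||eps -+ S v||_1 sums to the constant 2 m eps, and the bound slacks
    # to sum(ub - lb); only the dual L1 norms vary.
    lin = np.zeros(N)
    lin[sl_yp] = rho_kkt / m
    lin[sl_yn] = rho_kkt / m
    lin[sl_ml] = rho_kkt / n
    lin[sl_mu] = rho_kkt / n
    const = rho_kkt * (2.0 * eps_ss + float((ub - lb).sum()) / n)

    Q = np.zeros(n)
    Q[M_idx] = 2.0  # fit term, measured fluxes only
    v_exp = np.zeros(n)
    v_exp[M_idx] = data.v_exp

    def fun(x):
        r = x[sl_v] - v_exp
        return float((r[M_idx] @ r[M_idx]) + lin @ x + const)

    def jac(x):
        g = lin.copy()
        g[sl_v] += Q * (x[sl_v] - v_exp)
        return g

    H = np.zeros((N, N))
    H[sl_v, sl_v] = np.diag(Q)

    def hess(x):
        return H

    # stationarity:  C + S' y_pos - S' y_neg - mu_lb + mu_ub = 0  (n rows)
    A_st = np.zeros((n, N))
    for k, j in enumerate(O):
        A_st[j, n + k] = 1.0
    A_st[:, sl_yp] = S.T
    A_st[:, sl_yn] = -S.T
    A_st[:, sl_ml] = -np.eye(n)
    A_st[:, sl_mu] = np.eye(n)
    cons = [LinearConstraint(A_st, 0.0, 0.0)]

    A_simplex = np.zeros((1, N))
    A_simplex[0, sl_C] = 1.0
    cons.append(LinearConstraint(A_simplex, 1.0, 1.0))

    if eps_ss == 0.0:
        A_ss = np.zeros((m, N))
        A_ss[:, sl_v] = S
        cons.append(LinearConstraint(A_ss, 0.0, 0.0))
    else:
        A_ss = np.zeros((m, N))
        A_ss[:, sl_v] = S
        cons.append(LinearConstraint(A_ss, -eps_ss, eps_ss))

    xlo = np.full(N, 0.0)
    xhi = np.full(N, np.inf)
    xlo[sl_v], xhi[sl_v] = lb, ub

    x0 = np.zeros(N)
    x0[sl_v] = np.clip((lb + ub) / 2.0, -BOUND_CLIP, BOUND_CLIP)
    x0[sl_C] = 1.0 / d

    res = minimize(fun, x0, jac=jac, hess=hess, method="trust-constr",
                   constraints=cons, bounds=Bounds(xlo, xhi),
                   options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000,
                            "verbose": 0})

    x = res.x
    v = x[sl_v]
    C_full = np.zeros(n)
    C_full[list(O)] = np.clip(x[sl_C], 0.0, None)
    s = C_full.sum()
    if s > 0:
        C_full /= s
    vars_ = ObjFindVariables(v, C_full, x[sl_yp], x[sl_yn],
                             x[sl_ml], x[sl_mu], rho_kkt)
    fit = float(sum((v[j] - v_exp[j]) ** 2 for j in M_idx))
    feas_ok = (res.constr_violation if hasattr(res, "constr_violation") else 0.0) < 1e-6
    report = {
        "status": "optimal" if (res.success or feas_ok) else "infeasible",
        "fit": fit,
        "r_kkt": r_kkt(vars_, network, eps_ss),
        "rho_kkt": rho_kkt,
        "clipped_reactions": clipped,
        "objective": float(res.fun),
    }
    return C_full, vars_, report
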