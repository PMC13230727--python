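"""KKT residual verification for forward-FBA solutions.

For a convex programme with affine constraints the KKT conditions are
necessary and sufficient, so small residuals at a candidate solution
certify (local = global) optimality.  With the Lagrangian

    L = sgn f(v) + mu' S v + lam_up' (v - v_max) + lam_low' (v_min - v)

the four condition blocks evaluated here are

* primal feasibility:   ||S v*||_inf and the fraction of fluxes inside
  their bounds (1 = all inside),
* dual feasibility:     lam_up, lam_low >= 0,
* stationarity:         ||sgn grad f(v*) + S' mu + lam_up - lam_low||_inf,
* complementary slackness:  max_i |lam_low,i (v_min,i - v*_i)| and
  max_i |lam_up,i (v*_i - v_max,i)|.

No optimisation happens here: the report is a pure function of the
solution and its multipliers.  When the steady state was relaxed to
|S v| <= eps, the relaxed violation max(|S v| - eps, 0) is reported
alongside the classical ||S v||_inf residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import basis_gradient, sign_for
from .convex_fba import LowerConfig, SolveResult
from .network_io import MetabolicNetwork, ObjectiveSpec

__all__ = ["KKTReport", "compute_residuals", "kkt_report_table"]

# Default certification thresholds; configuration, not semantics.
CERT_PRIMAL = 1e-8
CERT_STATIONARITY = 1e-4
CERT_COMPLEMENTARITY = 1e-5


@dataclass(frozen=True)
class KKTReport:
    """Residuals of the four KKT condition blocks at a candidate solution."""

    primal_feasibility: float       # ||S v*||_inf (classical, eps ignored)
    primal_feasibility_relaxed: float  # max(|S v*| - eps, 0)
    bounds_feasibility: float       # fraction of fluxes inside [v_min, v_max]
    max_bound_violation: float
    stationarity: float
    comp_slack_lower: float
    comp_slack_upper: float
    dual_feasibility: float         # most negative multiplier, 0 if none
    degenerate: bool = False

    def certified(self, primal: float = CERT_PRIMAL,
                  stationarity: float = CERT_STATIONARITY,
                  complementarity: float = CERT_COMPLEMENTARITY) -> bool:
        """True when every residual is below its certification threshold."""
        return (self.primal_feasibility_relaxed <= primal
                and self.bounds_feasibility == 1.0
                and self.stationarity <= stationarity
                and max(self.comp_slack_lower, self.comp_slack_upper) <= complementarity
                and self.dual_feasibility >= -primal)


def compute_residuals(network: MetabolicNetwork, result: SolveResult,
                      spec: ObjectiveSpec,
                      cfg: LowerConfig | None = None,
                      bound_tol: float = 1e-9) -> KKTReport:
    """Evaluate all KKT condition blocks for a solved forward problem.

    ``result`` must come from a solver run that exposed its duals
    (status optimal or inaccurate); fluxes within ``bound_tol`` of a
    bound (relative to the bound magnitude) count as inside it.
    """
    cfg = cfg or LowerConfig()
    if result.status not in ("optimal", "inaccurate"):
        raise ValueError(
            f"cannot verify a solve with status {result.status!r}")
    if result.dual_eq is None or result.dual_upper is None or result.dual_lower is None:
        raise ValueError(
            "solution carries no duals; re-solve with a solver that exposes them")

    v = np.asarray(result.v_opt, dtype=float)
    S, lb, ub = network.S, network.v_min, network.v_max
    mu = np.asarray(result.dual_eq, dtype=float)
    lam_up = np.asarray(result.dual_upper, dtype=float)
    lam_low = np.asarray(result.dual_lower, dtype=float)

    Sv = S @ v
    primal = float(np.abs(Sv).max()) if Sv.size else 0.0
    primal_rel = float(np.maximum(np.abs(Sv) - cfg.eps_ss, 0.0).max()) if Sv.size else 0.0

    scale = 1.0 + np.maximum(np.abs(lb), np.abs(ub))
    scale[~np.isfinite(scale)] = 1.0
    low_viol = np.maximum(lb - v, 0.0)
    up_viol = np.maximum(v - ub, 0.0)
    inside = (low_viol <= bound_tol * scale) & (up_viol <= bound_tol * scale)
    bounds_frac = float(np.mean(inside))
    max_viol = float(np.maximum(low_viol, up_viol).max())

    O = list(spec.candidate_index)
    g_O, degenerate = basis_gradient(spec.mode, spec.C, v[O], cfg.delta)
    g = np.zeros(v.size)
    g[O] = g_O
    sgn = sign_for(spec.mode)
    stat = float(np.abs(sgn * g + S.T @ mu + lam_up - lam_low).max())

    # complementarity: bound slacks enter with +inf slack treated as
    # inactive (their multiplier is necessarily 0 at an optimum)
    slack_low = np.where(np.isfinite(lb), lb - v, 0.0)
    slack_up = np.where(np.isfinite(ub), v - ub, 0.0)
    cs_low = float(np.abs(lam_low * slack_low).max())
    cs_up = float(np.abs(lam_up * slack_up).max())

    most_neg = float(min(lam_up.min(initial=0.0), lam_low.min(initial=0.0)))
    dual_feas = min(most_neg, 0.0)

    return KKTReport(primal, primal_rel, bounds_frac, max_viol, stat,
                     cs_low, cs_up, dual_feas,
                     degenerate=degenerate or result.degenerate)


def kkt_report_table(reports: dict[str, KKTReport]) -> pd.DataFrame:
    """One row per basis mode, in the standard report column layout.

    Comp. Slack Min / Max are the lower-bound-block and
    upper-bound-block complementarity maxima respectively.
    """
    rows = [
        {
            "Mode": mode,
            "Primal Feas.": r.primal_feasibility,
            "Bounds Feas.": r.bounds_feasibility,
            "Stationarity Resid.": r.stationarity,
            "Comp. Slack Min": r.comp_slack_lower,
            "Comp. Slack Max": r.comp_slack_upper,
        }
        for mode, r in reports.items()
    ]
    return pd.DataFrame(rows)
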