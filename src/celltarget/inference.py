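"""Upper level of the inverse-FBA method: coefficient training.

The unconstrained parameter vector theta is mapped onto the probability
simplex by a softmax, the forward convex FBA programme is solved at the
resulting coefficients C, and the mean squared error between predicted
and measured fluxes (optionally L2-regularised in C) is minimised over
theta with a limited-memory quasi-Newton method (L-BFGS with a
strong-Wolfe-style line search).  Gradients flow through the forward
solve via the implicit differentiation of its KKT system
(:func:`celltarget.convex_fba.solution_jacobian`) and through the
softmax by its analytic Jacobian.

A lambda grid search (short runs from fresh random starts) picks the
regularisation weight, and a multi-start wrapper trains several
independent initialisations and keeps the lowest-loss record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .convex_fba import LowerConfig, solve_forward, solution_jacobian
from .network_io import (
    FluxDataset,
    MetabolicNetwork,
    ObjectiveSpec,
    apply_observation_bounds,
)

__all__ = [
    "TrainConfig",
    "TrainRecord",
    "TrainStartError",
    "softmax_reparam",
    "softmax_jacobian",
    "prediction_loss",
    "regularised_loss",
    "train",
    "select_lambda",
    "multi_start",
    "random_initial_points",
]

logger = logging.getLogger(__name__)


class TrainStartError(RuntimeError):
    """A training start aborted (infeasible lower problem or NaN gradient)."""


def softmax_reparam(theta: np.ndarray) -> np.ndarray:
    """Map unconstrained theta onto the probability simplex, C = softmax(theta)."""
    z = np.asarray(theta, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def softmax_jacobian(C: np.ndarray) -> np.ndarray:
    """dC/dtheta = diag(C) - C C' for C = softmax(theta)."""
    C = np.asarray(C, dtype=float)
    return np.diag(C) - np.outer(C, C)


def prediction_loss(v_pred: np.ndarray, data: FluxDataset,
                    eval_index=None) -> float:
    """Mean squared residual between predicted and measured fluxes.

    ``eval_index`` selects which measured reactions enter the loss
    (default: all of them); it must be a subset of the measured set.
    """
    idx, targets = _eval_targets(data, eval_index)
    r = np.asarray(v_pred, dtype=float)[idx] - targets
    return float(np.mean(r * r))


def _eval_targets(data: FluxDataset, eval_index):
    if eval_index is None:
        eval_index = data.measured_index
    eval_index = tuple(int(i) for i in eval_index)
    if not eval_index:
        raise ValueError("eval_index is empty: the loss needs at least one flux")
    pos = {r: k for k, r in enumerate(data.measured_index)}
    try:
        targets = np.array([data.v_exp[pos[i]] for i in eval_index])
    except KeyError as exc:
        raise ValueError(f"eval_index contains unmeasured reaction {exc}") from exc
    return list(eval_index), targets


def regularised_loss(loss: float, C: np.ndarray, lambda_reg: float) -> float:
    """loss + lambda * ||C||_2^2."""
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    C = np.asarray(C, dtype=float)
    return float(loss + lambda_reg * (C @ C))


@dataclass(frozen=True)
class TrainConfig:
    """Quasi-Newton training configuration.

    ``epochs`` counts recorded quasi-Newton steps; ``max_inner_iter``
    caps line-search evaluations per step; ``initial_step`` is an
    initial step-size guess only (the strong-Wolfe-style line search
    adapts it).  ``tune_epochs`` is the short-run budget of the lambda
    grid search.  ``eval_index`` restricts the loss to a subset of the
    measured fluxes (None = all measured).
    """

    epochs: int = 50
    initial_step: float = 1e-3
    max_inner_iter: int = 20
    history_size: int = 100
    lambda_grid: tuple[float, ...] = (1e-6, 1e-5, 1e-4)
    lambda_reg: float = 0.0
    tune_epochs: int = 10
    n_starts: int = 5
    seed: int = 0
    eval_index: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.n_starts < 1 or self.tune_epochs < 1:
            raise ValueError("epochs, n_starts, tune_epochs must be positive")
        if self.lambda_reg < 0 or any(l < 0 for l in self.lambda_grid):
            raise ValueError("regularisation weights must be >= 0")


@dataclass
class TrainRecord:
    """Outcome of one training start."""

    loss_history: list[float]
    final_theta: np.ndarray
    final_C: np.ndarray
    final_loss: float            # regularised objective at the end
    final_prediction_loss: float  # data-fit term alone
    lambda_used: float
    start_id: int = 0
    converged: bool = False      # stopped before the epoch budget

    @property
    def early_stop(self) -> bool:
        return self.converged


def _loss_and_grad(theta, network, data, spec, lower_cfg, lambda_reg, eval_index):
    """Regularised loss and its theta-gradient through the convex layer."""
    C = softmax_reparam(theta)
    sp = ObjectiveSpec(spec.candidate_index, spec.mode, np.asarray(theta, float))
    res = solve_forward(network, sp, lower_cfg)
    if res.status in ("infeasible", "error"):
        raise TrainStartError(f"lower problem returned status {res.status}")
    v = res.v_opt
    idx, targets = _eval_targets(data, eval_index)
    r = v[idx] - targets
    fit = float(np.mean(r * r))
    total = regularised_loss(fit, C, lambda_reg)

    J, _ = solution_jacobian(network, sp, lower_cfg, result=res)
    dLdv = np.zeros(network.n_reactions)
    dLdv[idx] = 2.0 * r / len(idx)
    dLdC = J.T @ dLdv + 2.0 * lambda_reg * C
    g = softmax_jacobian(C) @ dLdC
    if not np.all(np.isfinite(g)):
        raise TrainStartError("NaN/inf gradient in theta")
    return total, fit, g, v


def train(network: MetabolicNetwork, data: FluxDataset, spec: ObjectiveSpec,
          cfg: TrainConfig | None = None,
          lower_cfg: LowerConfig | None = None,
          epochs: int | None = None, start_id: int = 0) -> TrainRecord:
    """Train theta for ``cfg.epochs`` quasi-Newton steps.

    The network bounds are first tightened with the dataset's
    measurement-derived overrides (the forward solver sees the bounds;
    the loss sees the medians).  The recorded loss history is monotone
    up to line-search tolerance; runs that converge before the budget
    return a shorter history with ``converged=True``.
    """
    cfg = cfg or TrainConfig()
    lower_cfg = lower_cfg or LowerConfig()
    n_epochs = epochs if epochs is not None else cfg.epochs
    net = apply_observation_bounds(network, data)
    data.validate_against(net)

    history: list[float] = []
    cache: dict[bytes, tuple[float, float, np.ndarray]] = {}

    def fun(theta):
        key = np.asarray(theta).tobytes()
        if key not in cache:
            total, fit, g, _ = _loss_and_grad(
                theta, net, data, spec, lower_cfg, cfg.lambda_reg, cfg.eval_index)
            cache[key] = (total, fit, g)
            if len(cache) > 4096:
                cache.clear()
        total, fit, g = cache[key]
        return total, g

    def record(theta):
        total, _ = fun(theta)
        history.append(float(total))

    theta0 = np.asarray(spec.theta, dtype=float)
    res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                   callback=record,
                   options={"maxiter": n_epochs,
                            "maxcor": min(cfg.history_size, max(2, theta0.size)),
                            "maxls": cfg.max_inner_iter,
                            "ftol": 1e-15, "gtol": 1e-12})
    theta_f = np.asarray(res.x, dtype=float)
    total_f, fit_f, _ = cache.get(theta_f.tobytes()) or _loss_and_grad(
        theta_f, net, data, spec, lower_cfg, cfg.lambda_reg, cfg.eval_index)[:3]
    if not history or history[-1] > total_f:
        history.append(float(total_f))
    converged = len(history) < n_epochs
    logger.info("start %d: %d epochs, final loss %.3e (fit %.3e, lambda %.1e)",
                start_id, len(history), total_f, fit_f, cfg.lambda_reg)
    return TrainRecord(history, theta_f, softmax_reparam(theta_f),
                       float(total_f), float(fit_f), cfg.lambda_reg,
                       start_id=start_id, converged=converged)


def random_initial_points(d: int, n: int, seed: int) -> list[np.ndarray]:
    """n random coefficient points, coordinates uniform on [0, 1]."""
    rng = np.random.default_rng(seed)
    return [rng.uniform(size=d) for _ in range(n)]


def _theta_from_point(C0: np.ndarray) -> np.ndarray:
    """Map a [0,1]^d point to theta = log C (after simplex normalisation)."""
    C0 = np.clip(np.asarray(C0, dtype=float), 1e-9, None)
    C0 = C0 / C0.sum()
    return np.log(C0)


def select_lambda(network: MetabolicNetwork, data: FluxDataset,
                  spec: ObjectiveSpec, cfg: TrainConfig | None = None,
                  lower_cfg: LowerConfig | None = None) -> float:
    """Pick the regularisation weight by short-run grid search.

    Each candidate lambda gets a fresh random initialisation trained for
    ``cfg.tune_epochs`` steps; the smallest final regularised loss wins,
    ties broken toward the smaller lambda.
    """
    cfg = cfg or TrainConfig()
    if not cfg.lambda_grid:
        raise ValueError("lambda_grid is empty")
    d = len(spec.candidate_index)
    scores: list[tuple[float, float]] = []
    failures: list[str] = []
    for k, lam in enumerate(sorted(cfg.lambda_grid)):
        rng = np.random.default_rng([cfg.seed, 7, k])
        theta0 = _theta_from_point(rng.uniform(size=d))
        sp = ObjectiveSpec(spec.candidate_index, spec.mode, theta0)
        try:
            rec = train(network, data, sp, replace(cfg, lambda_reg=lam),
                        lower_cfg, epochs=cfg.tune_epochs)
            scores.append((lam, rec.final_loss))
            logger.info("lambda %.1e -> tuning loss %.3e", lam, rec.final_loss)
        except TrainStartError as exc:
            failures.append(f"lambda={lam:g}: {exc}")
    if not scores:
        raise RuntimeError("all lambda tuning runs failed: " + "; ".join(failures))
    best = min(scores, key=lambda t: (t[1], t[0]))
    return float(best[0])


def multi_start(network: MetabolicNetwork, data: FluxDataset,
                spec: ObjectiveSpec, cfg: TrainConfig | None = None,
                initial_points=None, lower_cfg: LowerConfig | None = None,
                return_all: bool = False):
    """Train ``cfg.n_starts`` independent initialisations, keep the best.

    ``initial_points`` (list of coefficient vectors in [0,1]^d, e.g.
    from the Bayesian-optimisation initialiser) defaults to uniform
    random draws.  Starts share no mutable state and are trained in a
    fixed order, so the selection is order-independent and
    reproducible: the minimal final loss wins, ties broken by the
    lowest start id.
    """
    cfg = cfg or TrainConfig()
    d = len(spec.candidate_index)
    if initial_points is None:
        initial_points = random_initial_points(d, cfg.n_starts, cfg.seed)
    if len(initial_points) != cfg.n_starts:
        raise ValueError(
            f"got {len(initial_points)} initial points for n_starts={cfg.n_starts}")

    records: list[TrainRecord] = []
    failures: list[str] = []
    for sid, C0 in enumerate(initial_points):
        sp = ObjectiveSpec(spec.candidate_index, spec.mode, _theta_from_point(C0))
        try:
            records.append(train(network, data, sp, cfg, lower_cfg, start_id=sid))
        except TrainStartError as exc:
            failures.append(f"start {sid}: {exc}")
            logger.warning("start %d aborted: %s", sid, exc)
    if not records:
        raise RuntimeError("all training starts failed: " + "; ".join(failures))
    best = min(records, key=lambda r: (r.final_loss, r.start_id))
    return (best, records) if return_all else best
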