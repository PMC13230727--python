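"""Bayesian-optimisation initialisation for the coefficient training.

Good starting coefficients matter under partial observability, where
the loss landscape has flat vertex regions.  The initialiser treats the
short-run training loss

    f(C) = loss after `inner_epochs` quasi-Newton steps started from C

as a black box over the unit box [0, 1]^d, models it with a Gaussian
process (constant mean, RBF kernel, fitted noise; hyperparameters by
marginal-likelihood maximisation), and proposes new candidates by
minimising the lower confidence bound

    LCB(C) = mu(C) - beta * sigma(C)

with a multi-restart quasi-Newton search from the box centre.  Points
live in the unit box and are renormalised onto the simplex only when a
training run consumes them.  All evaluated points, ranked by short-run
loss, seed the multi-start trainer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .convex_fba import LowerConfig
from .inference import TrainConfig, TrainStartError, _theta_from_point, train
from .network_io import FluxDataset, MetabolicNetwork, ObjectiveSpec

__all__ = [
    "BOConfig",
    "SurrogateModel",
    "sobol_candidates",
    "short_eval",
    "fit_gp",
    "propose_next",
    "bo_loop",
]

logger = logging.getLogger(__name__)

_FAIL_SENTINEL = 1e12  # capped loss recorded for failed short runs


@dataclass(frozen=True)
class BOConfig:
    """Budget and exploration settings of the BO initialiser."""

    n_init: int = 5          # Sobol design points
    n_iter: int = 10         # acquisition iterations
    inner_epochs: int = 10   # short-run training budget (5 for genome-scale)
    beta: float = 2.0        # LCB exploration weight
    seed: int = 0
    scramble: bool = True    # scrambled Sobol (off for exact replay)

    def __post_init__(self) -> None:
        if self.n_init < 1 or self.n_iter < 0 or self.inner_epochs < 0:
            raise ValueError("n_init >= 1, n_iter >= 0, inner_epochs >= 0 required")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class SurrogateModel:
    """Fitted GP surrogate of the short-run loss over [0, 1]^d."""

    gp: GaussianProcessRegressor
    train_X: np.ndarray
    train_y: np.ndarray
    mean: float          # constant prior mean (empirical, via y-centring)
    lengthscale: float
    variance: float      # RBF output scale
    noise: float         # fitted observation noise sigma^2

    def predict(self, X, return_std: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.gp.predict(X, return_std=return_std)


def sobol_candidates(d: int, n: int, seed: int = 0,
                     scramble: bool = True) -> np.ndarray:
    """n points of a (scrambled) Sobol sequence in [0, 1]^d."""
    if d < 1 or n < 1:
        raise ValueError("need d >= 1 and n >= 1")
    sampler = qmc.Sobol(d, scramble=scramble, seed=seed)
    with warnings.catch_warnings():
        # non-power-of-2 designs (e.g. the default 5 points) are intended
        warnings.simplefilter("ignore", UserWarning)
        return sampler.random(n)


def short_eval(C0: np.ndarray, network: MetabolicNetwork, data: FluxDataset,
               spec: ObjectiveSpec, inner_epochs: int,
               cfg: TrainConfig | None = None,
               lower_cfg: LowerConfig | None = None) -> float:
    """Training loss after ``inner_epochs`` steps started from C0.

    C0 lives in the unit box and is renormalised onto the simplex
    before use.  With ``inner_epochs=0`` the loss of the unoptimised
    start is returned.  Failures yield a capped sentinel so the
    surrogate can still learn from them.
    """
    cfg = cfg or TrainConfig()
    sp = ObjectiveSpec(spec.candidate_index, spec.mode, _theta_from_point(C0))
    try:
        if inner_epochs == 0:
            from .convex_fba import solve_forward
            from .inference import (apply_observation_bounds, prediction_loss,
                                    regularised_loss)
            net = apply_observation_bounds(network, data)
            res = solve_forward(net, sp, lower_cfg)
            if res.status in ("infeasible", "error"):
                raise TrainStartError(f"lower problem returned {res.status}")
            fit = prediction_loss(res.v_opt, data, cfg.eval_index)
            return regularised_loss(fit, sp.C, cfg.lambda_reg)
        rec = train(network, data, sp, cfg, lower_cfg, epochs=int(inner_epochs))
        return float(rec.final_loss)
    except TrainStartError as exc:
        logger.warning("short run from %s failed: %s", np.round(C0, 3), exc)
        return _FAIL_SENTINEL


def fit_gp(X: np.ndarray, y: np.ndarray) -> SurrogateModel:
    """Fit the constant-mean RBF GP by marginal-likelihood maximisation.

    Needs at least two points.  Ill-conditioned kernels get escalating
    jitter (1e-6 up to 1e-3).  Sentinel-capped y values are allowed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("fit_gp needs at least two evaluated points")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite (cap failures before fitting)")

    kernel = (ConstantKernel(1.0, (1e-4, 1e4))
              * RBF(length_scale=0.5, length_scale_bounds=(1e-3, 1e3))
              + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e1)))
    last_exc = None
    for jitter in (1e-10, 1e-6, 1e-3):
        try:
            gp = GaussianProcessRegressor(kernel=kernel, alpha=jitter,
                                          normalize_y=True,
                                          n_restarts_optimizer=2,
                                          random_state=0)
            with warnings.catch_warnings():
                # hyperparameters pinned at a bound are acceptable optima
                from sklearn.exceptions import ConvergenceWarning
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(X, y)
            break
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            last_exc = exc
            logger.warning("GP fit ill-conditioned, escalating jitter to %g", jitter)
    else:  # pragma: no cover
        raise RuntimeError("GP fit failed at maximal jitter") from last_exc

    k = gp.kernel_
    return SurrogateModel(
        gp=gp, train_X=X, train_y=y, mean=float(np.mean(y)),
        lengthscale=float(k.k1.k2.length_scale),
        variance=float(k.k1.k1.constant_value),
        noise=float(k.k2.noise_level),
    )


def lcb(model: SurrogateModel, X: np.ndarray, beta: float) -> np.ndarray:
    """Lower confidence bound mu(X) - beta * sigma(X)."""
    mean, std = model.predict(X, return_std=True)
    return mean - beta * std


def propose_next(model: SurrogateModel, beta: float = 2.0,
                 bounds: tuple[float, float] = (0.0, 1.0),
                 n_restarts: int = 4, seed: int = 0) -> np.ndarray:
    """Minimise the LCB over the box, restarting from the centre.

    Quasi-Newton descent from the box centre plus small perturbations;
    the best of all restarts (never worse than the centre itself) is
    returned, clipped to the box.
    """
    d = model.train_X.shape[1]
    lo, hi = bounds
    centre = np.full(d, 0.5 * (lo + hi))
    rng = np.random.default_rng(seed)

    def f(x):
        return float(lcb(model, x[None, :], beta)[0])

    best_x, best_val = centre, f(centre)
    starts = [centre] + [np.clip(centre + 0.1 * (hi - lo) * rng.standard_normal(d),
                                 lo, hi) for _ in range(n_restarts)]
    for x0 in starts:
        res = minimize(f, x0, method="L-BFGS-B", bounds=[(lo, hi)] * d,
                       options={"maxiter": 200, "ftol": 1e-15, "gtol": 1e-10})
        if np.all(np.isfinite(res.x)) and res.fun <= best_val:
            best_val, best_x = float(res.fun), np.clip(res.x, lo, hi)
    # derivative-free polish: quasi-Newton stalls when the surrogate's
    # dynamic range drops below its finite-difference resolution
    res = minimize(f, best_x, method="Powell", bounds=[(lo, hi)] * d,
                   options={"xtol": 1e-10, "ftol": 1e-15, "maxiter": 400})
    if np.all(np.isfinite(res.x)) and res.fun <= best_val:
        best_x = np.clip(res.x, lo, hi)
    return best_x


def bo_loop(network: MetabolicNetwork, data: FluxDataset, spec: ObjectiveSpec,
            bo_cfg: BOConfig | None = None,
            train_cfg: TrainConfig | None = None,
            lower_cfg: LowerConfig | None = None):
    """Run the Sobol + GP/LCB initialisation loop.

    Returns ``(points, losses)`` with all ``n_init + n_iter`` evaluated
    points sorted by short-run loss (best first).  If every evaluation
    fails, falls back to random points with a warning.
    """
    bo_cfg = bo_cfg or BOConfig()
    train_cfg = train_cfg or TrainConfig()
    d = len(spec.candidate_index)

    X = list(sobol_candidates(d, bo_cfg.n_init, bo_cfg.seed, bo_cfg.scramble))
    y = [short_eval(x, network, data, spec, bo_cfg.inner_epochs,
                    train_cfg, lower_cfg) for x in X]

    for it in range(bo_cfg.n_iter):
        model = fit_gp(np.asarray(X), np.minimum(y, _FAIL_SENTINEL))
        x_next = propose_next(model, bo_cfg.beta, seed=bo_cfg.seed + it + 1)
        loss = short_eval(x_next, network, data, spec, bo_cfg.inner_epochs,
                          train_cfg, lower_cfg)
        logger.info("BO iter %d: loss %.3e at %s", it, loss, np.round(x_next, 3))
        X.append(x_next)
        y.append(loss)

    if all(v >= _FAIL_SENTINEL for v in y):
        logger.warning("all BO evaluations failed; falling back to random points")
        rng = np.random.default_rng(bo_cfg.seed)
        X = [rng.uniform(size=d) for _ in range(len(X))]
        y = [_FAIL_SENTINEL] * len(X)
        return np.asarray(X), np.asarray(y)

    order = np.lexsort((np.arange(len(y)), np.asarray(y)))
    return np.asarray(X)[order], np.asarray(y)[order]
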