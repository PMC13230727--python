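"""Convex basis functions for the forward FBA objective.

Each mode combines the simplex coefficients ``C`` with the candidate
flux subvector ``v_O`` into a scalar surrogate objective:

===========  ========  ==================================
mode         type      objective
===========  ========  ==================================
norm         convex    minimise  ||C (.) v_O||_2
sum_squares  convex    minimise  sum_i (C_i v_i)^2
logsumexp    convex    minimise  log sum_i exp(C_i v_i)
inverse_log  concave   maximise  log(sum_i C_i v_i + delta)
===========  ========  ==================================

``delta`` is a small safeguard keeping the logarithm of ``inverse_log``
well-posed; the other modes ignore it.  ``logsumexp`` uses the standard
max-shift stabilisation.  Gradients and Hessians are with respect to
``v_O``; the mixed second derivative (d grad / d C) feeds the implicit
differentiation of the solver.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp as _lse, softmax as _softmax_w

__all__ = [
    "MINIMISED_MODES",
    "MAXIMISED_MODES",
    "sign_for",
    "evaluate_basis",
    "basis_gradient",
    "basis_hessian",
    "basis_mixed_hessian",
    "BasisDomainError",
]

MINIMISED_MODES = ("norm", "sum_squares", "logsumexp")
MAXIMISED_MODES = ("inverse_log",)


class BasisDomainError(ValueError):
    """Objective evaluated outside its domain (inverse_log nonpositive sum)."""


def sign_for(mode: str) -> int:
    """+1 if the mode is minimised, -1 if maximised."""
    if mode in MINIMISED_MODES:
        return 1
    if mode in MAXIMISED_MODES:
        return -1
    raise ValueError(f"unknown basis mode {mode!r}")


def _check(C: np.ndarray, v_O: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    C = np.asarray(C, dtype=float)
    v_O = np.asarray(v_O, dtype=float)
    if C.shape != v_O.shape:
        raise ValueError(f"C has shape {C.shape} but v_O has shape {v_O.shape}")
    return C, v_O


def evaluate_basis(mode: str, C, v_O, delta: float = 1e-6) -> float:
    """Evaluate the basis objective at (C, v_O).

    Returns the raw scalar; whether it is minimised or maximised is the
    caller's business (see :func:`sign_for`).
    """
    C, v_O = _check(C, v_O)
    x = C * v_O
    if mode == "norm":
        return float(np.linalg.norm(x))
    if mode == "sum_squares":
        return float(x @ x)
    if mode == "logsumexp":
        return float(_lse(x))
    if mode == "inverse_log":
        s = float(x.sum()) + delta
        if s <= 0:
            raise BasisDomainError(
                f"inverse_log needs sum(C_i v_i) + delta > 0, got {s:.3e}")
        return float(np.log(s))
    raise ValueError(f"unknown basis mode {mode!r}")


def basis_gradient(mode: str, C, v_O, delta: float = 1e-6):
    """Gradient of the basis objective with respect to v_O.

    Returns ``(grad, degenerate)``; ``degenerate`` is True only for the
    norm mode at ``C (.) v_O = 0``, where the subgradient 0 is returned.
    """
    C, v_O = _check(C, v_O)
    x = C * v_O
    if mode == "norm":
        r = np.linalg.norm(x)
        # below numerical resolution the only stable choice is the zero
        # subgradient (0 is in the subdifferential at the kink)
        if r <= 1e-10 * (1.0 + np.abs(v_O).max(initial=0.0)):
            return np.zeros_like(x), True
        return C * x / r, False
    if mode == "sum_squares":
        return 2.0 * C * x, False
    if mode == "logsumexp":
        p = _softmax_w(x)
        return C * p, False
    if mode == "inverse_log":
        s = float(x.sum()) + delta
        if s <= 0:
            raise BasisDomainError(
                f"inverse_log needs sum(C_i v_i) + delta > 0, got {s:.3e}")
        return C / s, False
    raise ValueError(f"unknown basis mode {mode!r}")


def basis_hessian(mode: str, C, v_O, delta: float = 1e-6) -> np.ndarray:
    """Hessian of the basis objective with respect to v_O (|O| x |O|)."""
    C, v_O = _check(C, v_O)
    x = C * v_O
    if mode == "sum_squares":
        return np.diag(2.0 * C * C)
    if mode == "norm":
        r = np.linalg.norm(x)
        if r == 0.0:  # subdifferential point; PSD surrogate curvature
            return np.diag(C * C)
        g = C * x  # unnormalised gradient
        return np.diag(C * C) / r - np.outer(g, g) / r**3
    if mode == "logsumexp":
        p = _softmax_w(x)
        return (np.diag(C * C * p) - np.outer(C * p, C * p))
    if mode == "inverse_log":
        s = float(x.sum()) + delta
        if s <= 0:
            raise BasisDomainError(
                f"inverse_log needs sum(C_i v_i) + delta > 0, got {s:.3e}")
        return -np.outer(C, C) / s**2
    raise ValueError(f"unknown basis mode {mode!r}")


def basis_mixed_hessian(mode: str, C, v_O, delta: float = 1e-6,
                        step: float = 1e-6) -> np.ndarray:
    """Mixed second derivative d(grad_v f)/dC, shape (|O|, |O|).

    Entry (i, j) = d^2 f / (d v_i d C_j).  Computed by central finite
    differences of the analytic gradient in C; the gradient itself is
    exact, so the differencing error is ~1e-10 at the default step.
    """
    C, v_O = _check(C, v_O)
    d = C.size
    out = np.empty((d, d))
    for j in range(d):
        Cp, Cm = C.copy(), C.copy()
        h = step * max(1.0, abs(C[j]))
        Cp[j] += h
        Cm[j] -= h
        gp, _ = basis_gradient(mode, Cp, v_O, delta)
        gm, _ = basis_gradient(mode, Cm, v_O, delta)
        out[:, j] = (gp - gm) / (2 * h)
    return out
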