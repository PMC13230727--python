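"""Packaged toy problem and synthetic-scenario generator.

The toy problem is a 5-reaction, 2-metabolite network whose reference
fluxes ("in silico data") are the minimum-Euclidean-norm flux vector of
the feasible polytope.  The synthetic generator produces random sparse
stoichiometric networks that are feasible *by construction* — a
null-space flux vector is sampled first and the bounds are widened
around it — together with observations generated by the forward solver
at a known ground-truth coefficient vector.  These scenarios stand in
for experimental datasets in recovery and scaling tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .convex_fba import LowerConfig, solve_forward
from .network_io import (
    FluxDataset,
    MetabolicNetwork,
    ObjectiveSpec,
    derive_bounds,
    read_network,
)

__all__ = [
    "toy_network",
    "toy_dataset",
    "toy_ground_truth",
    "random_network",
    "SyntheticScenario",
    "generate_observations",
]


def toy_network() -> MetabolicNetwork:
    """The packaged 2-metabolite, 5-reaction network.

    Reaction v1 is an uptake into M1; v2, v3, v4 interconvert M1 and M2;
    v5 secretes M2.  v2's bounds force at least 2 units of flux through
    it in the uptake (negative) direction.
    """
    ref = importlib.resources.files("celltarget") / "data" / "toy_network.json"
    with importlib.resources.as_file(ref) as path:
        return read_network(str(path), format="json")


def toy_ground_truth(cfg: LowerConfig | None = None) -> np.ndarray:
    """Reference fluxes of the toy problem: the min-||v||_2 feasible point.

    Computed by the forward solver with uniform coefficients over all
    reactions (uniform weights make the norm basis the plain Euclidean
    norm up to a constant).  Equals (0, -2, 1, 1, 0) up to solver noise:
    v2 is pinned at its upper bound -2; mass balance gives
    v1 = v5 = v3 + v4 - 2, and with v5 >= 0 the norm is minimised at
    v3 = v4 = 1 with v1 = v5 = 0.
    """
    net = toy_network()
    spec = ObjectiveSpec(tuple(range(net.n_reactions)), "norm",
                         np.zeros(net.n_reactions))
    res = solve_forward(net, spec, cfg or LowerConfig())
    if res.status != "optimal":
        raise RuntimeError(f"toy forward solve returned status {res.status}")
    return res.v_opt


def toy_dataset(cfg: LowerConfig | None = None) -> FluxDataset:
    """Full-observability observations of the toy problem (noise-free)."""
    v = toy_ground_truth(cfg)
    return FluxDataset(tuple(range(v.size)), v)


def random_network(m: int, n: int, density: float = 0.4,
                   seed: int = 0) -> MetabolicNetwork:
    """Random sparse integer stoichiometry with a strictly feasible interior.

    Every metabolite gets at least one exchange-like column (a single
    +/-1 entry, listed first) so partial-observability subsampling can
    prioritise exchange reactions.  Feasibility: a null-space vector v0
    is found by least squares and the bounds are set to an interval
    strictly containing v0.  The bounds of the largest-|v0| reaction
    exclude zero — a forced substrate uptake/secretion — so the zero
    flux vector is infeasible and minimising objectives are forced to
    distribute nontrivial flux (otherwise every norm-like objective
    would trivially return v = 0 and observations would carry no
    signal).
    """
    if not (n > m >= 1):
        raise ValueError("need n > m >= 1")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    S = np.zeros((m, n))
    # exchange-like columns: one per metabolite, single +/-1 entry
    for k in range(m):
        S[k, k] = rng.choice([-1.0, 1.0])
    # internal columns: sparse small-integer coefficients, >= 2 nonzeros
    for j in range(m, n):
        nnz = max(2, rng.binomial(m, density))
        rows = rng.choice(m, size=min(nnz, m), replace=False)
        coefs = rng.choice([-2, -1, 1, 2], size=rows.size)
        S[rows, j] = coefs
    # a nontrivial null-space point: least-squares solve S v = 0 pushing
    # towards a random target keeps v0 away from the origin
    target = rng.normal(scale=2.0, size=n)
    P = np.eye(n) - np.linalg.pinv(S) @ S     # projector onto null(S)
    v0 = P @ target
    if np.linalg.norm(v0) < 1e-6:             # pathological target; retry once
        v0 = P @ rng.normal(scale=5.0, size=n)
    v0 *= 2.0 / np.abs(v0).max()              # well-scaled driving flux
    width = 1.0 + np.abs(v0) + rng.uniform(0.5, 2.0, size=n)
    lb = v0 - width
    ub = v0 + width
    j = int(np.argmax(np.abs(v0)))            # forced flux: bounds exclude 0
    lo, hi = sorted((0.5 * v0[j], 1.5 * v0[j]))
    lb[j], ub[j] = lo, hi
    mets = [f"M{k+1}" for k in range(m)]
    rxns = [f"v{j+1}" for j in range(n)]
    return MetabolicNetwork(mets, rxns, S, lb, ub)


@dataclass(frozen=True)
class SyntheticScenario:
    """A network plus the ground-truth objective that generated its data."""

    network: MetabolicNetwork
    C_true: np.ndarray
    mode: str = "sum_squares"
    noise_sd: float = 0.0            # relative sd of Gaussian measurement noise
    observed_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.C_true, dtype=float)
        object.__setattr__(self, "C_true", C)
        if np.any(C < 0) or abs(C.sum() - 1.0) > 1e-9:
            raise ValueError("C_true must lie on the probability simplex")
        if not (0 < self.observed_fraction <= 1):
            raise ValueError("observed_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_observations(scenario: SyntheticScenario,
                          cfg: LowerConfig | None = None) -> FluxDataset:
    """Forward-simulate observations at the scenario's ground truth.

    Solves the forward problem at ``C_true``, corrupts each flux with
    zero-mean Gaussian noise of sd ``noise_sd * |v|``, keeps an
    ``observed_fraction`` of reactions (exchange-like reactions first,
    mirroring extracellular-first observability in real experiments),
    and derives bound overrides from the noisy replicate spread.
    """
    net = scenario.network
    n = net.n_reactions
    spec = ObjectiveSpec.from_C(tuple(range(n)), scenario.mode, scenario.C_true)
    res = solve_forward(net, spec, cfg or LowerConfig())
    if res.status != "optimal":
        raise RuntimeError(f"forward solve at C_true returned {res.status}")
    v = res.v_opt

    rng = np.random.default_rng(scenario.seed)
    noisy = v + rng.normal(scale=scenario.noise_sd * np.abs(v), size=n) \
        if scenario.noise_sd > 0 else v.copy()

    n_obs = max(1, int(round(scenario.observed_fraction * n)))
    # exchange-like columns (single nonzero) rank first in observability
    nnz = (net.S != 0).sum(axis=0)
    order = np.lexsort((np.arange(n), nnz))
    observed = tuple(sorted(order[:n_obs].tolist()))

    overrides = {}
    if scenario.noise_sd > 0:
        for i in observed:
            _, lo, hi = derive_bounds(noisy[i])
            overrides[i] = (lo, hi)
    return FluxDataset(observed, noisy[list(observed)], overrides)
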