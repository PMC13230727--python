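"""Network and observation data model, with JSON / TSV / SBML readers.

A metabolic network is the feasible-space definition shared by every
solver in this package: a stoichiometric matrix ``S`` (metabolites x
reactions) together with per-reaction flux bounds.  Flux observations are
per-reaction medians plus optional measurement-derived bound overrides
that tighten the network before inference.

Sign convention: uptake fluxes are negative, secretion positive.  No
automatic sign flipping is performed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MetabolicNetwork",
    "FluxDataset",
    "ObjectiveSpec",
    "NetworkFormatError",
    "read_network",
    "write_network",
    "read_flux_table",
    "apply_observation_bounds",
    "derive_bounds",
]

logger = logging.getLogger(__name__)


class NetworkFormatError(ValueError):
    """Structural problem in a network or flux file."""


def _softmax(theta: np.ndarray) -> np.ndarray:
    z = np.asarray(theta, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass(frozen=True)
class MetabolicNetwork:
    """Stoichiometric network with flux bounds.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Row / column labels of ``S``.
    S
        Dense stoichiometric matrix, shape ``(m, n)``.  Dimensionless.
    v_min, v_max
        Flux bounds, length ``n`` (e.g. mmol/gDW/h).
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: np.ndarray
    v_min: np.ndarray
    v_max: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        v_min = np.asarray(self.v_min, dtype=float)
        v_max = np.asarray(self.v_max, dtype=float)
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "v_min", v_min)
        object.__setattr__(self, "v_max", v_max)
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if S.shape != (m, n):
            raise NetworkFormatError(
                f"S has shape {S.shape}, expected ({m}, {n}) from the label lists"
            )
        if v_min.shape != (n,) or v_max.shape != (n,):
            raise NetworkFormatError("bound vectors must have one entry per reaction")
        if len(set(self.reaction_ids)) != n:
            raise NetworkFormatError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != m:
            raise NetworkFormatError("duplicate metabolite identifiers")
        if np.any(v_min > v_max):
            bad = [self.reaction_ids[i] for i in np.nonzero(v_min > v_max)[0]]
            raise NetworkFormatError(f"v_min > v_max for reactions {bad}")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def with_bounds(self, v_min: np.ndarray, v_max: np.ndarray) -> "MetabolicNetwork":
        return replace(self, v_min=np.asarray(v_min, float), v_max=np.asarray(v_max, float))


@dataclass(frozen=True)
class FluxDataset:
    """Measured flux medians over a subset of reactions.

    ``measured_index`` holds reaction indices (into the associated
    network) in a fixed order; ``v_exp`` the per-reaction medians; and
    ``bound_overrides`` optional measurement-derived (lower, upper)
    intervals used to tighten the network bounds.
    """

    measured_index: tuple[int, ...]
    v_exp: np.ndarray
    bound_overrides: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "measured_index", tuple(int(i) for i in self.measured_index))
        object.__setattr__(self, "v_exp", np.asarray(self.v_exp, dtype=float))
        if self.v_exp.shape != (len(self.measured_index),):
            raise ValueError("v_exp must have exactly one entry per measured reaction")
        if len(set(self.measured_index)) != len(self.measured_index):
            raise ValueError("duplicate measured reaction indices")
        for i, (lo, hi) in self.bound_overrides.items():
            if lo > hi:
                raise ValueError(f"override for reaction {i} has lower > upper")

    def validate_against(self, network: MetabolicNetwork) -> None:
        n = network.n_reactions
        for i in self.measured_index:
            if not 0 <= i < n:
                raise ValueError(f"measured index {i} outside network with n={n}")
        for i in self.bound_overrides:
            if not 0 <= i < n:
                raise ValueError(f"override index {i} outside network with n={n}")


@dataclass
class ObjectiveSpec:
    """Candidate objective: index set, basis mode, simplex coefficients.

    ``C`` always equals ``softmax(theta)``: coefficients are strictly
    positive and sum to one, preventing trivial rescaling of the
    inferred objective.
    """

    candidate_index: tuple[int, ...]
    mode: str
    theta: np.ndarray

    VALID_MODES = ("norm", "sum_squares", "logsumexp", "inverse_log")

    def __post_init__(self) -> None:
        self.candidate_index = tuple(int(i) for i in self.candidate_index)
        if len(set(self.candidate_index)) != len(self.candidate_index):
            raise ValueError("duplicate candidate reaction indices")
        if self.mode not in self.VALID_MODES:
            raise ValueError(f"unknown basis mode {self.mode!r}; valid: {self.VALID_MODES}")
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (len(self.candidate_index),):
            raise ValueError("theta must have one entry per candidate reaction")

    @property
    def C(self) -> np.ndarray:
        return _softmax(self.theta)

    @classmethod
    def from_C(cls, candidate_index, mode: str, C) -> "ObjectiveSpec":
        """Build a spec whose softmax(theta) reproduces ``C`` (up to simplex normalisation)."""
        C = np.asarray(C, dtype=float)
        if np.any(C <= 0):
            C = np.clip(C, 1e-12, None)
        return cls(tuple(candidate_index), mode, np.log(C / C.sum()))

    def with_theta(self, theta) -> "ObjectiveSpec":
        return ObjectiveSpec(self.candidate_index, self.mode, np.asarray(theta, float))


# ---------------------------------------------------------------------------
# readers / writers

def _network_from_dict(doc: dict) -> MetabolicNetwork:
    try:
        mets = list(doc["metabolites"])
        rxns = list(doc["reactions"])
        S = np.asarray(doc["S"], dtype=float)
        lb = np.asarray(doc["lb"], dtype=float)
        ub = np.asarray(doc["ub"], dtype=float)
    except KeyError as exc:
        raise NetworkFormatError(f"missing required key {exc} in network document") from exc
    return MetabolicNetwork(mets, rxns, S, lb, ub)


def _read_sbml(path: str, default_bound: float | None) -> MetabolicNetwork:
    import cobra.io

    model = cobra.io.read_sbml_model(path)
    rxns = [r.id for r in model.reactions]
    mets = [m.id for m in model.metabolites]
    S = np.zeros((len(mets), len(rxns)))
    met_pos = {m: i for i, m in enumerate(mets)}
    lb = np.empty(len(rxns))
    ub = np.empty(len(rxns))
    for j, r in enumerate(model.reactions):
        for met, coef in r.metabolites.items():
            S[met_pos[met.id], j] = coef
        rlb, rub = r.lower_bound, r.upper_bound
        if rlb is None or rub is None or not np.isfinite([rlb, rub]).all():
            if default_bound is None:
                raise NetworkFormatError(
                    f"reaction {r.id} lacks finite flux bounds and no default was supplied"
                )
            rlb = -default_bound if rlb is None or not np.isfinite(rlb) else rlb
            rub = default_bound if rub is None or not np.isfinite(rub) else rub
        lb[j], ub[j] = rlb, rub
    return MetabolicNetwork(mets, rxns, S, lb, ub)


def _read_tsv(path: str) -> MetabolicNetwork:
    # wide TSV: first column metabolite id, one column per reaction for S,
    # plus two special rows `_lb` / `_ub` carrying the bounds.
    df = pd.read_csv(path, sep="\t", index_col=0)
    rxns = list(df.columns)
    body = df.drop(index=[r for r in ("_lb", "_ub") if r in df.index])
    if "_lb" not in df.index or "_ub" not in df.index:
        raise NetworkFormatError("TSV network needs `_lb` and `_ub` rows")
    return MetabolicNetwork(
        list(body.index), rxns, body.to_numpy(float),
        df.loc["_lb"].to_numpy(float), df.loc["_ub"].to_numpy(float),
    )


def read_network(path: str, format: str | None = None,
                 default_bound: float | None = None) -> MetabolicNetwork:
    """Read a network from JSON (native schema), SBML, or TSV.

    The format is inferred from the extension when not given.  SBML
    models must carry finite flux bounds, or ``default_bound`` must be
    supplied to fill in missing/infinite ones.
    """
    if format is None:
        p = str(path).lower()
        format = "sbml" if p.endswith((".xml", ".sbml")) else (
            "tsv" if p.endswith((".tsv", ".txt")) else "json")
    if format == "json":
        with open(path) as fh:
            return _network_from_dict(json.load(fh))
    if format == "sbml":
        return _read_sbml(str(path), default_bound)
    if format == "tsv":
        return _read_tsv(str(path))
    raise ValueError(f"unknown network format {format!r}")


def write_network(network: MetabolicNetwork, path: str) -> None:
    """Write the native JSON schema (dense row-major S, explicit bounds)."""
    doc = {
        "metabolites": list(network.metabolite_ids),
        "reactions": list(network.reaction_ids),
        "S": network.S.tolist(),
        "lb": network.v_min.tolist(),
        "ub": network.v_max.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_flux_table(path: str, network: MetabolicNetwork) -> FluxDataset:
    """Read a TSV flux table: columns ``reaction_id``, ``median``, optional ``lb``, ``ub``."""
    df = pd.read_csv(path, sep="\t")
    if "reaction_id" not in df.columns or "median" not in df.columns:
        raise NetworkFormatError("flux table needs `reaction_id` and `median` columns")
    idx = [network.reaction_index(r) for r in df["reaction_id"]]
    overrides: dict[int, tuple[float, float]] = {}
    if "lb" in df.columns and "ub" in df.columns:
        for i, lo, hi in zip(idx, df["lb"], df["ub"]):
            if np.isfinite(lo) and np.isfinite(hi):
                overrides[i] = (float(lo), float(hi))
    ds = FluxDataset(tuple(idx), df["median"].to_numpy(float), overrides)
    ds.validate_against(network)
    return ds


# ---------------------------------------------------------------------------
# measurement-derived bounds

def derive_bounds(values, k_mad: float = 3.0, rtol: float = 0.05) -> tuple[float, float, float]:
    """Turn replicate measurements into (median, lower, upper).

    With replicates the interval is ``median +/- k_mad * MAD``; with a
    single value it is ``value +/- |value| * rtol``.  Smaller measurement
    spread therefore yields tighter flux bounds.
    """
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    med = float(np.median(vals))
    if vals.size > 1:
        mad = float(np.median(np.abs(vals - med)))
        half = k_mad * mad
    else:
        half = abs(med) * rtol
    return med, med - half, med + half


def apply_observation_bounds(network: MetabolicNetwork, data: FluxDataset) -> MetabolicNetwork:
    """Tighten network bounds with measurement-derived overrides.

    Each override interval is intersected with the model's original
    bounds; an override disjoint from the model interval is ignored
    (bounds stay as in the model) and a warning is recorded.  Bounds are
    never widened.
    """
    data.validate_against(network)
    lb = network.v_min.copy()
    ub = network.v_max.copy()
    for i, (lo, hi) in data.bound_overrides.items():
        new_lo, new_hi = max(lo, lb[i]), min(hi, ub[i])
        if new_lo > new_hi:
            msg = (f"override ({lo}, {hi}) for reaction {network.reaction_ids[i]} is "
                   f"disjoint from model bounds ({lb[i]}, {ub[i]}); keeping model bounds")
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        lb[i], ub[i] = new_lo, new_hi
    return network.with_bounds(lb, ub)
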