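"""FBA, FVA and the cross-condition flux envelope on the irreversible network.

Each condition carries measured exchange fluxes; FBA maximizes the model
objective (biomass) under those constraints, and FVA reports per-reaction
flux ranges while retaining a fraction ``p`` of the FBA optimum. The
element-wise min of FVA minima and max of FVA maxima across conditions form
the envelope that later places each flux on a [0, 1] scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gem import IrreversibleNetwork
from .milp import InfeasibleError, Model

__all__ = [
    "ConditionSpec",
    "FVAResult",
    "FluxEnvelope",
    "solve_fba",
    "run_fva",
    "build_envelope",
    "condition_bounds",
    "read_conditions",
    "DEFAULT_OMEGA_FLUX",
]

logger = logging.getLogger(__name__)

DEFAULT_OMEGA_FLUX = 0.001
#: numerical floor below which FVA bounds are rounded to suppress sign noise
_ROUND_TOL = 1e-9


@dataclass
class ConditionSpec:
    """One experimental condition: measured exchange fluxes and overrides.

    ``exchange_fluxes`` maps reaction ids (irreversible ids, or original ids
    resolved to their forward direction) to non-negative measured uptake
    values; this is the EXP set. ``exp_mode`` decides how the measurement
    constrains the flux: ``equality`` pins it inside a +-band, ``upper`` and
    ``lower`` apply one-sided literal bounds.
    """

    condition_id: str
    exchange_fluxes: dict[str, float] = field(default_factory=dict)
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for rid, v in self.exchange_fluxes.items():
            if v < 0:
                raise ValueError(
                    f"condition {self.condition_id!r}: measured flux for {rid!r} "
                    "must be non-negative on the irreversible model"
                )


@dataclass
class FVAResult:
    condition_id: str
    alpha: np.ndarray  # per-reaction minimum flux
    beta: np.ndarray  # per-reaction maximum flux
    f_star: float  # FBA optimum for the condition
    p: float  # objective-retention fraction

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.alpha > self.beta + 1e-7):
            raise ValueError("FVA minimum exceeds maximum")

    def to_frame(self, reaction_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"alpha": self.alpha, "beta": self.beta}, index=reaction_ids
        )


@dataclass
class FluxEnvelope:
    """Cross-condition min of FVA minima / max of maxima, per reaction."""

    vmin: np.ndarray
    vmax: np.ndarray
    degenerate: np.ndarray  # bool: range <= omega_flux
    omega_flux: float = DEFAULT_OMEGA_FLUX

    def __post_init__(self):
        self.vmin = np.asarray(self.vmin, dtype=float)
        self.vmax = np.asarray(self.vmax, dtype=float)
        if np.any(self.vmin > self.vmax + 1e-9):
            raise ValueError("envelope minimum exceeds maximum")


def _resolve_exp_reaction(net: IrreversibleNetwork, rid: str) -> int:
    """Resolve a measured reaction id onto the irreversible network.

    Accepts an irreversible column id directly, or an original id which maps
    to its single column or, for a split pair, to the forward direction
    (uptake measurements are non-negative by convention).
    """
    ids = net.reaction_ids
    if rid in ids:
        return ids.index(rid)
    for cand in (rid + "_f", rid + "_r"):
        if cand in ids:
            return ids.index(cand)
    raise KeyError(f"measured reaction {rid!r} not found in the network")


def condition_bounds(
    net: IrreversibleNetwork,
    cond: ConditionSpec,
    exp_mode: str = "equality",
    exp_band: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction bounds with the condition's EXP constraints applied.

    ``equality``: v in [v_exp (1 - band), v_exp (1 + band)] and, for split
    reactions, the opposite direction is closed. ``upper``: v <= v_exp.
    ``lower``: v >= v_exp.
    """
    if exp_mode not in ("equality", "upper", "lower"):
        raise ValueError(f"unknown exp_mode {exp_mode!r}")
    lower = net.lower.copy()
    upper = net.upper.copy()
    paired = {f: b for f, b in net.pairs} | {b: f for f, b in net.pairs}
    for rid, (lo, hi) in cond.bound_overrides.items():
        j = _resolve_exp_reaction(net, rid)
        lower[j], upper[j] = lo, hi
    for rid, v in cond.exchange_fluxes.items():
        j = _resolve_exp_reaction(net, rid)
        if exp_mode == "equality":
            lower[j] = v * (1 - exp_band)
            upper[j] = v * (1 + exp_band)
            if j in paired:
                other = paired[j]
                lower[other] = 0.0
                upper[other] = 0.0
        elif exp_mode == "upper":
            upper[j] = min(upper[j], v)
        else:  # lower
            lower[j] = max(lower[j], v)
    if np.any(lower > upper):
        bad = net.reaction_ids[int(np.argmax(lower > upper))]
        raise ValueError(
            f"condition {cond.condition_id!r}: contradictory bounds on {bad!r}"
        )
    return lower, upper


def _base_model(
    net: IrreversibleNetwork, lower: np.ndarray, upper: np.ndarray, name: str
) -> tuple[Model, list[int]]:
    model = Model(name=name)
    v = [
        model.add_var(rid, float(lower[j]), float(upper[j]))
        for j, rid in enumerate(net.reaction_ids)
    ]
    S = net.S
    for i, mid in enumerate(net.metabolite_ids):
        row = {v[j]: S[i, j] for j in range(net.n_reactions) if S[i, j] != 0}
        if row:
            model.add_constr(row, 0.0, 0.0, name=f"mass_{mid}")
    return model, v


def solve_fba(
    net: IrreversibleNetwork,
    cond: ConditionSpec | None = None,
    exp_mode: str = "equality",
    exp_band: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Maximize the model objective under steady state and condition bounds.

    Returns an optimal vertex flux vector and the optimum f*.
    """
    if cond is None:
        cond = ConditionSpec("default")
    lower, upper = condition_bounds(net, cond, exp_mode, exp_band)
    model, v = _base_model(net, lower, upper, f"fba_{cond.condition_id}")
    obj = {v[j]: -net.objective[j] for j in range(net.n_reactions) if net.objective[j] != 0}
    model.set_objective(obj)
    try:
        sol = model.solve()
    except InfeasibleError as exc:
        raise InfeasibleError(
            f"FBA infeasible for condition {cond.condition_id!r}; check measured "
            f"exchange fluxes against network capacity ({exc})"
        ) from exc
    return sol.x.copy(), -sol.objective


def run_fva(
    net: IrreversibleNetwork,
    cond: ConditionSpec | None = None,
    p: float = 1.0,
    exp_mode: str = "equality",
    exp_band: float = 0.01,
    retention: str = "equality",
) -> FVAResult:
    """Per-reaction flux minima/maxima retaining ``p`` of the FBA optimum.

    The retention constraint is sum(c_j v_j) = p f* (``retention="equality"``,
    the default) or >= p f* (``retention="inequality"``); 2n LP solves.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if cond is None:
        cond = ConditionSpec("default")
    _, f_star = solve_fba(net, cond, exp_mode, exp_band)
    lower, upper = condition_bounds(net, cond, exp_mode, exp_band)
    model, v = _base_model(net, lower, upper, f"fva_{cond.condition_id}")
    obj_row = {v[j]: net.objective[j] for j in range(net.n_reactions) if net.objective[j] != 0}
    if obj_row:
        target = p * f_star
        slack = max(1e-9, 1e-9 * abs(target))
        if retention == "equality":
            model.add_constr(obj_row, target - slack, target + slack, name="retention")
        else:
            model.add_constr(obj_row, target - slack, np.inf, name="retention")
    n = net.n_reactions
    alpha = np.empty(n)
    beta = np.empty(n)
    for j in range(n):
        model.set_objective({v[j]: 1.0})
        alpha[j] = model.solve().x[j]
        model.set_objective({v[j]: -1.0})
        beta[j] = model.solve().x[j]
    alpha[np.abs(alpha) < _ROUND_TOL] = 0.0
    beta[np.abs(beta) < _ROUND_TOL] = 0.0
    np.minimum(alpha, beta, out=alpha)  # guard against LP tolerance crossings
    return FVAResult(cond.condition_id, alpha, beta, f_star, p)


def build_envelope(
    results: list[FVAResult], omega_flux: float = DEFAULT_OMEGA_FLUX
) -> FluxEnvelope:
    """Element-wise min of alpha and max of beta across conditions."""
    if not results:
        raise ValueError("at least one FVA result is required")
    n = len(results[0].alpha)
    for r in results:
        if len(r.alpha) != n:
            raise ValueError("FVA results cover different reaction sets")
    vmin = np.min([r.alpha for r in results], axis=0)
    vmax = np.max([r.beta for r in results], axis=0)
    degenerate = (vmax - vmin) <= omega_flux
    return FluxEnvelope(vmin, vmax, degenerate, omega_flux)


def read_conditions(path: str) -> list[ConditionSpec]:
    """Read a long-format TSV/CSV: columns condition_id, reaction_id, value."""
    sep = "," if path.lower().endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    required = {"condition_id", "reaction_id", "value"}
    if not required <= set(frame.columns):
        raise ValueError(f"conditions table must have columns {sorted(required)}")
    out = []
    for cid, grp in frame.groupby("condition_id", sort=False):
        exchange = {
            str(r.reaction_id): float(r.value) for r in grp.itertuples(index=False)
        }
        out.append(ConditionSpec(str(cid), exchange))
    return out
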