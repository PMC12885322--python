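"""Accuracy statistics against measured fluxes, and flux-flexibility analysis.

Measured fluxes (typically from 13C metabolic flux analysis) rarely map
one-to-one onto model reactions: a measured flux through a linear pathway
corresponds to the minimum over its sequential steps, and a measured flux fed
by parallel routes to their sum. Mapping expressions are written in a tiny
language over model reaction ids: ``min(a, b, ...)`` for sequential steps,
``+`` for parallel routes, parentheses for grouping.

Accuracy is summarized by the uncentered Pearson correlation (cosine
similarity of the raw flux vectors) and by RMSE, normalized across an
explicit batch of runs to NRMSE.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gem import IrreversibleNetwork, collapse_fluxes
from .milp import Model

__all__ = [
    "MeasuredFluxMap",
    "AccuracyReport",
    "FlexibilityReport",
    "parse_mapping",
    "map_predicted",
    "uncentered_pearson",
    "rmse",
    "nrmse_batch",
    "accuracy_report",
    "flexibility",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Measured-flux mapping mini-language
# ---------------------------------------------------------------------------

_MAP_TOKEN = re.compile(r"\s*(min\(|\(|\)|,|\+|[^\s(),+]+)")


def parse_mapping(text: str):
    """Parse a mapping expression into a nested tuple AST.

    Grammar: expr := term ('+' term)*; term := 'min(' expr (',' expr)* ')'
    | '(' expr ')' | reaction_id. AST nodes: ('sum', [...]), ('min', [...]),
    ('rxn', id).
    """
    tokens = []
    pos = 0
    while pos < len(text):
        m = _MAP_TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def expr():
        nonlocal idx
        terms = [term()]
        while peek() == "+":
            idx += 1
            terms.append(term())
        return terms[0] if len(terms) == 1 else ("sum", terms)

    def term():
        nonlocal idx
        tok = peek()
        if tok is None:
            raise ValueError(f"unexpected end of mapping expression {text!r}")
        if tok == "min(":
            idx += 1
            args = [expr()]
            while peek() == ",":
                idx += 1
                args.append(expr())
            if peek() != ")":
                raise ValueError(f"expected ')' in mapping expression {text!r}")
            idx += 1
            return ("min", args)
        if tok == "(":
            idx += 1
            node = expr()
            if peek() != ")":
                raise ValueError(f"expected ')' in mapping expression {text!r}")
            idx += 1
            return node
        if tok in (")", ",", "+"):
            raise ValueError(f"unexpected {tok!r} in mapping expression {text!r}")
        idx += 1
        return ("rxn", tok)

    node = expr()
    if idx != len(tokens):
        raise ValueError(f"trailing tokens in mapping expression {text!r}")
    return node


def _eval_mapping(node, fluxes: dict[str, float]) -> float:
    kind = node[0]
    if kind == "rxn":
        if node[1] not in fluxes:
            raise KeyError(f"mapping references unknown reaction {node[1]!r}")
        return fluxes[node[1]]
    vals = [_eval_mapping(child, fluxes) for child in node[1]]
    return min(vals) if kind == "min" else sum(vals)


@dataclass
class MeasuredFluxMap:
    """Mapping expressions and measured values per condition.

    ``expressions`` maps a measured flux id to its mapping expression text;
    ``measured`` maps condition id -> {measured id -> value}.
    """

    expressions: dict[str, str]
    measured: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def read(cls, path: str) -> "MeasuredFluxMap":
        """TSV with columns measured_id, expression, then one column per condition."""
        sep = "," if path.lower().endswith(".csv") else "\t"
        frame = pd.read_csv(path, sep=sep)
        if not {"measured_id", "expression"} <= set(frame.columns):
            raise ValueError("mapping file needs measured_id and expression columns")
        expressions = dict(zip(frame["measured_id"].astype(str), frame["expression"].astype(str)))
        cond_cols = [c for c in frame.columns if c not in ("measured_id", "expression")]
        measured = {
            c: dict(zip(frame["measured_id"].astype(str), frame[c].astype(float)))
            for c in cond_cols
        }
        return cls(expressions, measured)


def map_predicted(
    mapping: MeasuredFluxMap,
    net: IrreversibleNetwork | None,
    flux: np.ndarray,
    signed: bool = False,
) -> dict[str, float]:
    """Evaluate each measured id's expression on predicted fluxes.

    ``flux`` is a vector on the irreversible network (collapsed internally)
    or, when ``net`` is None, already a net-flux vector whose mapping
    expressions use positional ids. Absolute values are taken by default.
    """
    if net is not None:
        if len(flux) == net.n_reactions:
            net_flux = collapse_fluxes(net, np.asarray(flux))
        else:
            net_flux = np.asarray(flux, dtype=float)
        ids = net.original_reaction_ids
    else:
        net_flux = np.asarray(flux, dtype=float)
        ids = [str(i) for i in range(len(net_flux))]
    values = net_flux if signed else np.abs(net_flux)
    table = dict(zip(ids, values.astype(float)))
    return {
        mid: _eval_mapping(parse_mapping(text), table)
        for mid, text in mapping.expressions.items()
    }


# ---------------------------------------------------------------------------
# Accuracy statistics
# ---------------------------------------------------------------------------


def uncentered_pearson(v_p, v_m) -> float:
    """Uncentered Pearson correlation: sum(p*m) / (||p|| ||m||)."""
    v_p = np.asarray(v_p, dtype=float)
    v_m = np.asarray(v_m, dtype=float)
    if v_p.shape != v_m.shape or v_p.ndim != 1 or len(v_p) < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    np_norm = np.linalg.norm(v_p)
    nm_norm = np.linalg.norm(v_m)
    if np_norm == 0 or nm_norm == 0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float(np.dot(v_p, v_m) / (np_norm * nm_norm))


def rmse(v_p, v_m, mode: str = "standard") -> float:
    """Root mean square error between predicted and measured fluxes.

    ``mode="as_printed"`` returns the raw sum of squared differences instead
    (a published variant that omits the root and the 1/t factor).
    """
    v_p = np.asarray(v_p, dtype=float)
    v_m = np.asarray(v_m, dtype=float)
    sq = float(np.sum((v_p - v_m) ** 2))
    if mode == "as_printed":
        return sq
    if mode != "standard":
        raise ValueError(f"unknown rmse mode {mode!r}")
    return float(np.sqrt(sq / len(v_p)))


def nrmse_batch(rmse_values: dict[str, float]) -> dict[str, float]:
    """Min-max normalize RMSE values over an explicit batch of runs."""
    if len(rmse_values) < 2:
        raise ValueError("NRMSE needs a batch of at least two runs")
    vals = np.array(list(rmse_values.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi - lo == 0:
        logger.warning("NRMSE batch is constant; all values set to 0")
        return {k: 0.0 for k in rmse_values}
    return {k: float((v - lo) / (hi - lo)) for k, v in rmse_values.items()}


@dataclass
class AccuracyReport:
    condition_id: str
    R: float
    rmse: float
    nrmse: float | None
    pairs: pd.DataFrame  # columns: predicted, measured; index: measured ids

    @property
    def n_compared(self) -> int:
        return len(self.pairs)


def accuracy_report(
    mapping: MeasuredFluxMap,
    net: IrreversibleNetwork,
    fluxes: dict[str, np.ndarray],
    rmse_mode: str = "standard",
) -> list[AccuracyReport]:
    """Per-condition accuracy of predicted vs measured fluxes, NRMSE over the
    set of conditions as the normalization batch."""
    reports = {}
    rmses = {}
    for cid, flux in fluxes.items():
        if cid not in mapping.measured:
            raise KeyError(f"no measured fluxes for condition {cid!r}")
        pred = map_predicted(mapping, net, flux)
        meas = mapping.measured[cid]
        ids = sorted(set(pred) & set(meas))
        v_p = np.array([pred[i] for i in ids])
        v_m = np.array([meas[i] for i in ids])
        rmses[cid] = rmse(v_p, v_m, rmse_mode)
        reports[cid] = AccuracyReport(
            condition_id=cid,
            R=uncentered_pearson(v_p, v_m),
            rmse=rmses[cid],
            nrmse=None,
            pairs=pd.DataFrame({"predicted": v_p, "measured": v_m}, index=ids),
        )
    if len(rmses) >= 2:
        for cid, val in nrmse_batch(rmses).items():
            reports[cid].nrmse = val
    return [reports[cid] for cid in fluxes]


# ---------------------------------------------------------------------------
# Flexibility
# ---------------------------------------------------------------------------


@dataclass
class FlexibilityReport:
    """Per-original-reaction flux ranges under a pinned stage-1 optimum."""

    reaction_ids: list[str]
    fr: np.ndarray  # |vmax - vmin| per original reaction
    subsystems: list[str]

    def subsystem_means(self) -> pd.Series:
        frame = pd.DataFrame({"subsystem": self.subsystems, "fr": self.fr})
        return frame.groupby("subsystem")["fr"].mean()


def _original_subsystems(net: IrreversibleNetwork) -> list[str]:
    by_orig = {}
    for j, rid in enumerate(net.reaction_ids):
        orig, _ = net.provenance[rid]
        by_orig.setdefault(orig, net.subsystems[j])
    return [by_orig[rid] for rid in net.original_reaction_ids]


def flexibility_from_model(
    model: Model,
    net: IrreversibleNetwork,
    v_idx: list[int],
    objective: dict[int, float],
    z_star: float,
    rel_tol: float = 1e-6,
    mip_gap: float = 1e-9,
) -> FlexibilityReport:
    """Min/max each collapsed net flux with the stage-1 objective pinned.

    Works on any assembled model (FBA LP or the integration MILP): the
    stage-1 objective expression is fixed within a relative tolerance and
    each original reaction's net flux (forward minus backward for split
    pairs) is independently minimized and maximized.
    """
    slack = rel_tol * max(1.0, abs(z_star))
    row = model.add_constr(dict(objective), z_star - slack, z_star + slack, name="stage1")
    saved_obj = dict(model._obj)
    cols_by_orig: dict[str, dict[int, float]] = {}
    for j, rid in enumerate(net.reaction_ids):
        orig, sign = net.provenance[rid]
        cols_by_orig.setdefault(orig, {})[v_idx[j]] = float(sign)
    fr = np.zeros(len(net.original_reaction_ids))
    try:
        for i, orig in enumerate(net.original_reaction_ids):
            coeffs = cols_by_orig[orig]
            model.set_objective(coeffs)
            vmin = sum(c * model.solve(mip_gap=mip_gap).x[k] for k, c in coeffs.items())
            model.set_objective({k: -c for k, c in coeffs.items()})
            vmax = sum(c * model.solve(mip_gap=mip_gap).x[k] for k, c in coeffs.items())
            fr[i] = abs(vmax - vmin)
    finally:
        model.set_objective(saved_obj)
        assert row == model.n_constraints - 1
        model._rows.pop()
        model._row_lb.pop()
        model._row_ub.pop()
        model._row_names.pop()
    return FlexibilityReport(
        reaction_ids=list(net.original_reaction_ids),
        fr=fr,
        subsystems=_original_subsystems(net),
    )


def flexibility_fba(
    net: IrreversibleNetwork,
    cond,
    exp_mode: str = "equality",
    exp_band: float = 0.01,
    rel_tol: float = 1e-6,
) -> FlexibilityReport:
    """Flexibility under plain FBA: pin the biomass optimum, range each flux."""
    from .cbm import condition_bounds, solve_fba

    _, f_star = solve_fba(net, cond, exp_mode, exp_band)
    lower, upper = condition_bounds(net, cond, exp_mode, exp_band)
    model = Model(name="flex_fba")
    v_idx = [
        model.add_var(rid, float(lower[j]), float(upper[j]))
        for j, rid in enumerate(net.reaction_ids)
    ]
    for i in range(net.n_metabolites):
        rowc = {v_idx[j]: net.S[i, j] for j in range(net.n_reactions) if net.S[i, j] != 0}
        if rowc:
            model.add_constr(rowc, 0.0, 0.0)
    objective = {v_idx[j]: -net.objective[j] for j in range(net.n_reactions) if net.objective[j] != 0}
    return flexibility_from_model(model, net, v_idx, objective, -f_star, rel_tol)


def flexibility_igm(problem, z_star: float, rel_tol: float = 1e-6) -> FlexibilityReport:
    """Flexibility under the integration MILP: pin z*, range each net flux."""
    return flexibility_from_model(
        problem.model,
        problem.net,
        problem.v_idx,
        problem.objective,
        z_star,
        rel_tol,
        problem.cfg.mip_gap,
    )
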