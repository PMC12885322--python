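"""The expression-integration MILP and its L1/L2 regularized variants.

Per condition, the model chooses a steady-state flux vector that maximizes
biomass while minimizing two deviation totals: per-gene distance between the
model's expression variable g_i and the observed relative expression, and
per-reaction distance between the envelope-scaled flux and the GPR-derived
reaction expression score. The full objective is

    minimize  -ctilde * v_biomass + sum_i (d1_i + d2_i) + sum_j (e1_j + e2_j)

subject to mass balance, flux bounds gated by reaction binaries, measured
exchange-flux constraints, one-direction-active coupling for split reversible
pairs, the scaled-flux matching rows, the GPR min/max encodings, and the
expression matching rows. The biomass weight ctilde defaults to
B = (2k + 2n) / v_biomass_max, which puts the biomass term on the same scale
as the deviation totals (whose maximum possible value is 2k + 2n).

The two-step variants re-solve with the step-1 optimum pinned as a constraint
and minimize total flux (L1, promotes sparse distributions) or the sum of
squared fluxes (L2, spreads flux evenly).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize

from .cbm import (
    DEFAULT_OMEGA_FLUX,
    ConditionSpec,
    FluxEnvelope,
    build_envelope,
    condition_bounds,
    run_fva,
    solve_fba,
)
from .expression import (
    DEFAULT_OMEGA,
    ExpressionMatrix,
    RelativeExpression,
    align_to_model,
    transform,
)
from .gem import IrreversibleNetwork, collapse_fluxes
from .gpr_milp import encode_rule
from .milp import InfeasibleError, Model

__all__ = [
    "IGMConfig",
    "IGMProblem",
    "IGMSolution",
    "compute_B",
    "resolve_ctilde",
    "build_igm",
    "solve_igm",
    "solve_igm_l1",
    "solve_igm_l2",
    "run_multi_condition",
    "CTILDE_SCHEDULE",
]

logger = logging.getLogger(__name__)

#: biomass-coefficient schedule explored in sensitivity analyses
CTILDE_SCHEDULE = ("1", "B/1000", "B/100", "B/10", "B", "2B")


@dataclass
class IGMConfig:
    """Tunables for the integration MILP.

    ``ctilde`` is the biomass weight: a float, or a string expression in B
    ("B", "2B", "B/10", "1"). ``exp_mode`` decides how measured exchange
    fluxes constrain the model (equality band by default). ``p`` is the
    FVA objective-retention fraction used to build the envelope.
    """

    ctilde: float | str = "B"
    transform_scheme: str = "mean_reference"
    eq18: str = "monotone"
    omega: float = DEFAULT_OMEGA
    omega_flux: float = DEFAULT_OMEGA_FLUX
    p: float = 1.0
    retention: str = "equality"
    u_default: float = 1000.0
    exp_mode: str = "equality"
    exp_band: float = 0.01
    or_mode: str = "max"
    variant: str = "base"
    mip_gap: float = 1e-9
    retention_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self):
        if self.u_default <= 0:
            raise ValueError("u_default must be positive")
        if isinstance(self.ctilde, (int, float)) and self.ctilde <= 0:
            raise ValueError("ctilde must be positive")
        if self.variant not in ("base", "l1", "l2"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class IGMProblem:
    """Assembled MILP plus the variable index maps needed to read it back."""

    model: Model
    net: IrreversibleNetwork
    cond: ConditionSpec
    cfg: IGMConfig
    ctilde: float
    v_idx: list[int]
    b_idx: dict[int, int]  # reaction -> binary (split pairs only)
    g_idx: dict[str, int]  # gene -> expression variable
    ghat_idx: dict[int, int]  # reaction -> GPR root variable
    delta_idx: dict[str, tuple[int, int]]  # measured gene -> (d1, d2)
    eps_idx: dict[int, tuple[int, int]]  # reaction -> (e1, e2)
    gpr_binaries: list[int] = field(default_factory=list)
    objective: dict[int, float] = field(default_factory=dict)


@dataclass
class IGMSolution:
    condition_id: str
    flux: np.ndarray  # on the irreversible network
    net_flux: np.ndarray  # collapsed onto original reaction ids
    biomass: float
    g: dict[str, float]
    ghat: dict[str, float]
    delta_total: float
    eps_total: float
    z_star: float
    status: str
    variant: str = "base"
    variant_objective: float | None = None


def compute_B(net: IrreversibleNetwork, v_biomass_max: float) -> float:
    """B = (2k + 2n) / v_biomass_max: the biomass weight that balances the
    biomass term against the maximum possible deviation total (2k + 2n)."""
    if v_biomass_max <= 0:
        raise ValueError(
            "maximum biomass flux is zero; the biomass weight B is undefined "
            "for a non-growing condition"
        )
    return (2 * net.n_genes + 2 * net.n_reactions) / v_biomass_max


_CTILDE_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s*\*?\s*)?B\s*(?:/\s*(\d+(?:\.\d+)?))?\s*$")


def resolve_ctilde(spec: float | str, B: float) -> float:
    """Resolve a ctilde spec ("B", "2B", "B/10", "1", or a float) to a number."""
    if isinstance(spec, (int, float)):
        return float(spec)
    m = _CTILDE_RE.match(spec)
    if m:
        mult = float(m.group(1)) if m.group(1) else 1.0
        div = float(m.group(2)) if m.group(2) else 1.0
        return mult * B / div
    try:
        return float(spec)
    except ValueError:
        raise ValueError(f"cannot parse ctilde specification {spec!r}") from None


def build_igm(
    net: IrreversibleNetwork,
    env: FluxEnvelope,
    rel: RelativeExpression,
    cond: ConditionSpec,
    cfg: IGMConfig,
    ctilde: float | None = None,
) -> IGMProblem:
    """Assemble the per-condition MILP against the shared envelope.

    Scaled-flux matching rows (and their deviation variables) are emitted only
    for reactions that carry a GPR rule and are non-degenerate in the
    envelope; expression matching rows only for genes present in the table.
    Binaries are created only for split reversible pairs (an unpaired
    reaction's activity indicator is fixed at 1, which is never restrictive).
    """
    if list(rel.gene_ids) != list(net.gene_ids):
        raise ValueError("relative expression is not aligned to the model gene list")
    if len(env.vmin) != net.n_reactions:
        raise ValueError("envelope does not cover the irreversible reaction set")
    if ctilde is None:
        if isinstance(cfg.ctilde, str):
            raise ValueError(
                "symbolic ctilde requires resolving B first; pass ctilde explicitly "
                "or use run_multi_condition"
            )
        ctilde = float(cfg.ctilde)

    lower, upper = condition_bounds(net, cond, cfg.exp_mode, cfg.exp_band)
    upper = np.where(np.isfinite(upper), upper, cfg.u_default)

    model = Model(name=f"igm_{cond.condition_id}")
    n = net.n_reactions
    biomass_j = net.biomass_index

    # flux variables and mass balance
    v_idx = [model.add_var(rid, float(lower[j]), float(upper[j])) for j, rid in enumerate(net.reaction_ids)]
    for i, mid in enumerate(net.metabolite_ids):
        row = {v_idx[j]: net.S[i, j] for j in range(n) if net.S[i, j] != 0}
        if row:
            model.add_constr(row, 0.0, 0.0, name=f"mass_{mid}")

    # one-direction-active coupling for split pairs: v <= U b, b_f + b_b = 1
    b_idx: dict[int, int] = {}
    for f, b in net.pairs:
        bf = model.add_binary(f"b_{net.reaction_ids[f]}")
        bb = model.add_binary(f"b_{net.reaction_ids[b]}")
        b_idx[f], b_idx[b] = bf, bb
        model.add_constr({v_idx[f]: 1.0, bf: -float(upper[f])}, -1e30, 0.0, name=f"gate_{net.reaction_ids[f]}")
        model.add_constr({v_idx[b]: 1.0, bb: -float(upper[b])}, -1e30, 0.0, name=f"gate_{net.reaction_ids[b]}")
        model.add_constr({bf: 1.0, bb: 1.0}, 1.0, 1.0, name=f"pair_{net.reaction_ids[f]}")

    # gene expression variables, and deviation rows for measured genes
    g_idx = {gid: model.add_var(f"g_{gid}", 0.0, 1.0) for gid in net.gene_ids}
    gtilde = rel.column(cond.condition_id)
    delta_idx: dict[str, tuple[int, int]] = {}
    objective: dict[int, float] = {v_idx[biomass_j]: -ctilde}
    for gid in net.gene_ids:
        if gid not in gtilde:
            continue  # unmeasured: g floats freely in [0, 1]
        d1 = model.add_var(f"d1_{gid}", 0.0, np.inf)
        d2 = model.add_var(f"d2_{gid}", 0.0, np.inf)
        delta_idx[gid] = (d1, d2)
        model.add_constr(
            {g_idx[gid]: 1.0, d1: -1.0, d2: 1.0}, gtilde[gid], gtilde[gid], name=f"match_{gid}"
        )
        objective[d1] = 1.0
        objective[d2] = 1.0

    # GPR encodings and scaled-flux matching for rule-bearing, non-degenerate reactions
    ghat_idx: dict[int, int] = {}
    eps_idx: dict[int, tuple[int, int]] = {}
    gpr_binaries: list[int] = []
    for j, rule in enumerate(net.rules):
        if rule is None or env.degenerate[j]:
            continue
        enc = encode_rule(model, rule, g_idx, tag=f"gpr_{net.reaction_ids[j]}", or_mode=cfg.or_mode)
        ghat_idx[j] = enc.root_var
        gpr_binaries.extend(enc.binaries)
        e1 = model.add_var(f"e1_{net.reaction_ids[j]}", 0.0, np.inf)
        e2 = model.add_var(f"e2_{net.reaction_ids[j]}", 0.0, np.inf)
        eps_idx[j] = (e1, e2)
        denom = env.vmax[j] - env.vmin[j]
        model.add_constr(
            {v_idx[j]: 1.0 / denom, enc.root_var: -1.0, e1: -1.0, e2: 1.0},
            env.vmin[j] / denom,
            env.vmin[j] / denom,
            name=f"scale_{net.reaction_ids[j]}",
        )
        objective[e1] = 1.0
        objective[e2] = 1.0

    model.set_objective(objective)
    return IGMProblem(
        model=model,
        net=net,
        cond=cond,
        cfg=cfg,
        ctilde=ctilde,
        v_idx=v_idx,
        b_idx=b_idx,
        g_idx=g_idx,
        ghat_idx=ghat_idx,
        delta_idx=delta_idx,
        eps_idx=eps_idx,
        gpr_binaries=gpr_binaries,
        objective=objective,
    )


def _extract_solution(
    problem: IGMProblem, x: np.ndarray, status: str, variant: str = "base",
    variant_objective: float | None = None,
) -> IGMSolution:
    net = problem.net
    flux = np.array([x[i] for i in problem.v_idx])
    z = sum(c * x[i] for i, c in problem.objective.items())
    delta_total = sum(x[d1] + x[d2] for d1, d2 in problem.delta_idx.values())
    eps_total = sum(x[e1] + x[e2] for e1, e2 in problem.eps_idx.values())
    return IGMSolution(
        condition_id=problem.cond.condition_id,
        flux=flux,
        net_flux=collapse_fluxes(net, flux),
        biomass=float(flux[net.biomass_index]),
        g={gid: float(x[i]) for gid, i in problem.g_idx.items()},
        ghat={net.reaction_ids[j]: float(x[i]) for j, i in problem.ghat_idx.items()},
        delta_total=float(delta_total),
        eps_total=float(eps_total),
        z_star=float(z),
        status=status,
        variant=variant,
        variant_objective=variant_objective,
    )


def solve_igm(problem: IGMProblem, cfg: IGMConfig | None = None) -> IGMSolution:
    """Solve the assembled MILP to optimality (within the MIP gap)."""
    cfg = cfg or problem.cfg
    sol = problem.model.solve(mip_gap=cfg.mip_gap)
    return _extract_solution(problem, sol.x, sol.status)


def _add_retention(problem: IGMProblem, z_star: float, slack: float) -> int:
    return problem.model.add_constr(
        dict(problem.objective), z_star - slack, z_star + slack, name="retention_z"
    )


def _pop_constraint(model: Model, row: int) -> None:
    # rows are appended; the retention row is always last when we remove it
    assert row == model.n_constraints - 1
    model._rows.pop()
    model._row_lb.pop()
    model._row_ub.pop()
    model._row_names.pop()


def solve_igm_l1(
    problem: IGMProblem,
    cfg: IGMConfig | None = None,
    base: IGMSolution | None = None,
) -> IGMSolution:
    """Two-step L1 variant: pin the step-1 optimum, minimize total flux."""
    cfg = cfg or problem.cfg
    if base is None:
        base = solve_igm(problem, cfg)
    saved_obj = dict(problem.model._obj)
    for slack in (max(cfg.retention_tol, 1e-9), 1e-6 * max(1.0, abs(base.z_star))):
        row = _add_retention(problem, base.z_star, slack)
        problem.model.set_objective({i: 1.0 for i in problem.v_idx})
        try:
            sol = problem.model.solve(mip_gap=cfg.mip_gap)
        except InfeasibleError:
            _pop_constraint(problem.model, row)
            continue
        finally:
            problem.model.set_objective(saved_obj)
        out = _extract_solution(
            problem, sol.x, sol.status, variant="l1", variant_objective=float(sol.objective)
        )
        _pop_constraint(problem.model, row)
        return out
    raise InfeasibleError("L1 step-2 infeasible even with relaxed retention tolerance")


def solve_igm_l2(
    problem: IGMProblem,
    cfg: IGMConfig | None = None,
    base: IGMSolution | None = None,
) -> IGMSolution:
    """Two-step L2 variant: pin the step-1 optimum, minimize sum of squared fluxes.

    The backend has no mixed-integer quadratic solver, so all binaries are
    fixed at their step-1 values and the remaining convex QP is solved with a
    trust-region method, warm-started at the step-1 point.
    """
    cfg = cfg or problem.cfg
    if base is None:
        base = solve_igm(problem, cfg)
    model = problem.model
    # re-solve step 1 to recover the full variable vector (binaries included)
    sol1 = model.solve(mip_gap=cfg.mip_gap)
    x1 = sol1.x

    saved_bounds = [(model._lb[i], model._ub[i]) for i in range(model.n_vars)]
    binaries = [i for i in range(model.n_vars) if model._integer[i]]
    for i in binaries:
        fixed = float(round(x1[i]))
        model.set_var_bounds(i, fixed, fixed)

    slack = 1e-6 * max(1.0, abs(base.z_star))
    row = _add_retention(problem, base.z_star, slack)
    try:
        A = model.constraint_matrix()
        lc = LinearConstraint(A, np.array(model._row_lb), np.array(model._row_ub))
        bounds = Bounds(np.array(model._lb), np.array(model._ub))
        flux_set = np.zeros(model.n_vars)
        flux_set[problem.v_idx] = 1.0

        def fun(x):
            return float(np.sum((x * flux_set) ** 2))

        def jac(x):
            return 2.0 * x * flux_set

        res = minimize(
            fun,
            np.clip(x1, bounds.lb, bounds.ub),
            jac=jac,
            hess=lambda x: np.diag(2.0 * flux_set),
            method="trust-constr",
            constraints=[lc],
            bounds=bounds,
            options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000, "verbose": 0},
        )
        if not res.success and res.constr_violation > 1e-6:
            raise InfeasibleError(f"L2 step-2 failed: {res.message}")
        out = _extract_solution(
            problem, res.x, "optimal", variant="l2", variant_objective=float(res.fun)
        )
    finally:
        _pop_constraint(model, row)
        for i, (lo, hi) in enumerate(saved_bounds):
            model._lb[i], model._ub[i] = lo, hi
    return out


def run_multi_condition(
    net: IrreversibleNetwork,
    expr: ExpressionMatrix,
    conditions: list[ConditionSpec],
    cfg: IGMConfig | None = None,
) -> list[IGMSolution]:
    """Full pipeline: per-condition FBA + FVA, shared envelope, one solve each.

    The envelope and the expression transformation are computed once over all
    conditions, which is what makes the per-condition solutions comparable.
    """
    cfg = cfg or IGMConfig()
    if not conditions:
        raise ValueError("at least one condition is required")
    cond_ids = {c.condition_id for c in conditions}
    missing = cond_ids - set(expr.condition_ids)
    if missing:
        raise ValueError(f"conditions missing from the expression table: {sorted(missing)}")

    fva_results = []
    f_stars = {}
    for cond in conditions:
        res = run_fva(net, cond, cfg.p, cfg.exp_mode, cfg.exp_band, cfg.retention)
        fva_results.append(res)
        f_stars[cond.condition_id] = res.f_star
    env = build_envelope(fva_results, cfg.omega_flux)

    rel = transform(expr, cfg.transform_scheme, cfg.omega, cfg.eq18)
    rel = align_to_model(rel, net)

    solutions = []
    for cond in conditions:
        B = compute_B(net, f_stars[cond.condition_id])
        ctilde = resolve_ctilde(cfg.ctilde, B)
        problem = build_igm(net, env, rel, cond, cfg, ctilde)
        logger.info(
            "condition %s: %d vars, %d constraints, %d binaries, ctilde=%.4g",
            cond.condition_id,
            problem.model.n_vars,
            problem.model.n_constraints,
            problem.model.n_binaries,
            ctilde,
        )
        base = solve_igm(problem, cfg)
        if cfg.variant == "l1":
            solutions.append(solve_igm_l1(problem, cfg, base))
        elif cfg.variant == "l2":
            solutions.append(solve_igm_l2(problem, cfg, base))
        else:
            solutions.append(base)
    return solutions
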