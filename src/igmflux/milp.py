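"""Thin linear/mixed-integer model builder on top of scipy's HiGHS interface.

Every optimization in this package (FBA, FVA, the expression-integration MILP
and its variants) is assembled against :class:`Model`. Keeping one builder
means one place for tolerances and one solution format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["Model", "Solution", "InfeasibleError", "UnboundedError", "SolverError"]

#: feasibility / optimality tolerance passed to HiGHS
FEASIBILITY_TOL = 1e-9


class SolverError(RuntimeError):
    """Solver terminated without an optimal solution."""


class InfeasibleError(SolverError):
    """The model admits no feasible point."""


class UnboundedError(SolverError):
    """The objective is unbounded over the feasible region."""


@dataclass
class Solution:
    status: str
    objective: float
    x: np.ndarray

    def value(self, var: int) -> float:
        return float(self.x[var])


@dataclass
class Model:
    """Incrementally built LP/MILP: variables, row constraints, linear objective.

    Variables are integer handles; constraints are rows ``lb <= a.x <= ub``.
    The objective sense is always *minimize*.
    """

    name: str = "model"
    _lb: list[float] = field(default_factory=list)
    _ub: list[float] = field(default_factory=list)
    _integer: list[bool] = field(default_factory=list)
    _names: list[str] = field(default_factory=list)
    _rows: list[dict[int, float]] = field(default_factory=list)
    _row_lb: list[float] = field(default_factory=list)
    _row_ub: list[float] = field(default_factory=list)
    _row_names: list[str] = field(default_factory=list)
    _obj: dict[int, float] = field(default_factory=dict)

    # -- construction ------------------------------------------------------
    def add_var(
        self,
        name: str,
        lb: float = 0.0,
        ub: float = np.inf,
        *,
        integer: bool = False,
    ) -> int:
        if lb > ub:
            raise ValueError(f"variable {name!r}: lower bound {lb} > upper bound {ub}")
        self._lb.append(float(lb))
        self._ub.append(float(ub))
        self._integer.append(bool(integer))
        self._names.append(name)
        return len(self._lb) - 1

    def add_binary(self, name: str) -> int:
        return self.add_var(name, 0.0, 1.0, integer=True)

    def add_constr(
        self,
        coeffs: dict[int, float],
        lb: float = -np.inf,
        ub: float = np.inf,
        name: str = "",
    ) -> int:
        """Add ``lb <= sum(coeffs[j] * x_j) <= ub``; equality when lb == ub."""
        for j in coeffs:
            if not 0 <= j < len(self._lb):
                raise IndexError(f"constraint {name!r} references unknown variable {j}")
        self._rows.append({int(j): float(c) for j, c in coeffs.items()})
        self._row_lb.append(float(lb))
        self._row_ub.append(float(ub))
        self._row_names.append(name)
        return len(self._rows) - 1

    def set_objective(self, coeffs: dict[int, float]) -> None:
        self._obj = {int(j): float(c) for j, c in coeffs.items()}

    def set_var_bounds(self, var: int, lb: float, ub: float) -> None:
        if lb > ub:
            raise ValueError(f"variable {self._names[var]!r}: lb {lb} > ub {ub}")
        self._lb[var] = float(lb)
        self._ub[var] = float(ub)

    # -- introspection -----------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self._lb)

    @property
    def n_constraints(self) -> int:
        return len(self._rows)

    @property
    def n_binaries(self) -> int:
        return sum(self._integer)

    def var_name(self, var: int) -> str:
        return self._names[var]

    def constraint_matrix(self) -> sparse.csr_matrix:
        n, m = self.n_vars, self.n_constraints
        data, ri, ci = [], [], []
        for i, row in enumerate(self._rows):
            for j, c in row.items():
                ri.append(i)
                ci.append(j)
                data.append(c)
        return sparse.csr_matrix((data, (ri, ci)), shape=(m, n))

    def to_lp_text(self) -> str:
        """Dump the model in a readable LP-like format (debugging aid)."""
        lines = [f"\\ model {self.name}", "Minimize"]
        obj = " + ".join(f"{c:g} {self._names[j]}" for j, c in sorted(self._obj.items()))
        lines.append(" obj: " + (obj or "0"))
        lines.append("Subject To")
        for i, row in enumerate(self._rows):
            expr = " + ".join(f"{c:g} {self._names[j]}" for j, c in sorted(row.items()))
            lo, hi = self._row_lb[i], self._row_ub[i]
            tag = self._row_names[i] or f"c{i}"
            if lo == hi:
                lines.append(f" {tag}: {expr} = {lo:g}")
            else:
                if np.isfinite(lo):
                    lines.append(f" {tag}.lo: {expr} >= {lo:g}")
                if np.isfinite(hi):
                    lines.append(f" {tag}.hi: {expr} <= {hi:g}")
        lines.append("Bounds")
        for j in range(self.n_vars):
            lines.append(f" {self._lb[j]:g} <= {self._names[j]} <= {self._ub[j]:g}")
        binaries = [self._names[j] for j in range(self.n_vars) if self._integer[j]]
        if binaries:
            lines.append("Binaries")
            lines.append(" " + " ".join(binaries))
        lines.append("End")
        return "\n".join(lines)

    # -- solving -----------------------------------------------------------
    def solve(self, *, mip_gap: float = 1e-9, time_limit: float | None = None) -> Solution:
        """Minimize the objective with HiGHS; raise on infeasible/unbounded."""
        n = self.n_vars
        c = np.zeros(n)
        for j, v in self._obj.items():
            c[j] = v
        integrality = np.array(self._integer, dtype=int)
        bounds = Bounds(np.array(self._lb), np.array(self._ub))
        constraints = []
        if self._rows:
            constraints.append(
                LinearConstraint(
                    self.constraint_matrix(),
                    np.array(self._row_lb),
                    np.array(self._row_ub),
                )
            )
        options: dict = {
            "mip_rel_gap": mip_gap,
            "presolve": True,
        }
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = milp(
            c,
            constraints=constraints,
            integrality=integrality,
            bounds=bounds,
            options=options,
        )
        # scipy.optimize.milp status codes: 0 optimal, 1 iteration/time limit,
        # 2 infeasible, 3 unbounded, 4 other
        if res.status == 2:
            raise InfeasibleError(f"{self.name}: infeasible ({res.message})")
        if res.status == 3:
            raise UnboundedError(f"{self.name}: unbounded ({res.message})")
        if res.x is None:
            raise SolverError(f"{self.name}: solver failed ({res.message})")
        status = "optimal" if res.status == 0 else "incumbent"
        return Solution(status=status, objective=float(res.fun), x=np.asarray(res.x))
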