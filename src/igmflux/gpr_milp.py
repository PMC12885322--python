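"""Mixed-integer encodings of min/max GPR aggregation, plus a direct evaluator.

An ``and`` rule (enzyme complex) contributes the minimum of its gene
expression variables; an ``or`` rule (isozymes) the maximum. Solvers cannot
take min/max directly, so each internal rule node is compiled into a big-M
block with one binary selector per child:

    min:  out <= g_i,  out >= g_i - M y_i,  sum(y_i) = k - 1
    max:  out >= g_i,  out <= g_i + M y_i,  sum(y_i) = k - 1

With every expression variable in [0, 1], M = 1 is sufficiently large and the
tightest valid constant. Nested rules are encoded recursively, one auxiliary
[0, 1] variable per internal AST node; the root auxiliary is the reaction's
expression score. :func:`evaluate_rule` is the solver-free reference
implementation used as the oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gem import GeneProteinRule
from .milp import Model

__all__ = [
    "RuleEncoding",
    "encode_min",
    "encode_max",
    "encode_rule",
    "evaluate_rule",
    "BIG_M",
]

BIG_M = 1.0


class EncodingError(ValueError):
    pass


@dataclass
class RuleEncoding:
    """Bookkeeping for one compiled rule: root variable, auxiliaries, binaries."""

    root_var: int
    aux_vars: list[int] = field(default_factory=list)
    binaries: list[int] = field(default_factory=list)
    n_constraints: int = 0


def _check_children(model: Model, child_vars: list[int]) -> None:
    for cv in child_vars:
        lo, hi = model._lb[cv], model._ub[cv]
        if not (lo >= -1e-12 and hi <= 1.0 + 1e-12):
            raise EncodingError(
                f"child variable {model.var_name(cv)!r} not bounded in [0, 1]; "
                "big-M encoding with M=1 requires the unit box"
            )


def encode_min(
    model: Model, child_vars: list[int], out_var: int, tag: str = "min"
) -> tuple[list[int], int]:
    """Constrain ``out_var`` to the minimum of ``child_vars`` (2k+1 rows, k binaries)."""
    if len(child_vars) == 1:
        model.add_constr({out_var: 1.0, child_vars[0]: -1.0}, 0.0, 0.0, name=f"{tag}_eq")
        return [], 1
    _check_children(model, child_vars)
    k = len(child_vars)
    ys = [model.add_binary(f"{tag}_y{i}") for i in range(k)]
    n_rows = 0
    for i, (cv, y) in enumerate(zip(child_vars, ys)):
        model.add_constr({out_var: 1.0, cv: -1.0}, -1e30, 0.0, name=f"{tag}_le{i}")
        model.add_constr({out_var: 1.0, cv: -1.0, y: BIG_M}, 0.0, 1e30, name=f"{tag}_ge{i}")
        n_rows += 2
    model.add_constr({y: 1.0 for y in ys}, k - 1, k - 1, name=f"{tag}_sel")
    return ys, n_rows + 1


def encode_max(
    model: Model, child_vars: list[int], out_var: int, tag: str = "max"
) -> tuple[list[int], int]:
    """Constrain ``out_var`` to the maximum of ``child_vars`` (2k+1 rows, k binaries)."""
    if len(child_vars) == 1:
        model.add_constr({out_var: 1.0, child_vars[0]: -1.0}, 0.0, 0.0, name=f"{tag}_eq")
        return [], 1
    _check_children(model, child_vars)
    k = len(child_vars)
    ys = [model.add_binary(f"{tag}_y{i}") for i in range(k)]
    n_rows = 0
    for i, (cv, y) in enumerate(zip(child_vars, ys)):
        model.add_constr({out_var: 1.0, cv: -1.0}, 0.0, 1e30, name=f"{tag}_ge{i}")
        model.add_constr({out_var: 1.0, cv: -1.0, y: -BIG_M}, -1e30, 0.0, name=f"{tag}_le{i}")
        n_rows += 2
    model.add_constr({y: 1.0 for y in ys}, k - 1, k - 1, name=f"{tag}_sel")
    return ys, n_rows + 1


def _encode_sum(
    model: Model, child_vars: list[int], out_var: int, tag: str
) -> tuple[list[int], int]:
    # summation variant of OR aggregation: no binaries; the output box is
    # widened to [0, k] since the sum of k unit-box children can exceed 1
    model.set_var_bounds(out_var, 0.0, float(len(child_vars)))
    row = {out_var: 1.0}
    for cv in child_vars:
        row[cv] = row.get(cv, 0.0) - 1.0
    model.add_constr(row, 0.0, 0.0, name=f"{tag}_sum")
    return [], 1


def encode_rule(
    model: Model,
    ast: GeneProteinRule,
    gene_vars: dict[str, int],
    tag: str = "gpr",
    or_mode: str = "max",
) -> RuleEncoding:
    """Recursively compile a GPR AST; returns the root variable's encoding.

    Each internal node gets an auxiliary variable in [0, 1]; a single-gene
    rule short-circuits to the gene's own variable.
    """
    if or_mode not in ("max", "sum"):
        raise ValueError(f"or_mode must be 'max' or 'sum', got {or_mode!r}")

    enc = RuleEncoding(root_var=-1)
    counter = [0]

    def visit(node: GeneProteinRule) -> int:
        if node.kind == "gene":
            if node.gene not in gene_vars:
                raise EncodingError(f"no variable for gene {node.gene!r}")
            return gene_vars[node.gene]
        child_vars = [visit(c) for c in node.children]
        counter[0] += 1
        aux = model.add_var(f"{tag}_n{counter[0]}", 0.0, 1.0)
        enc.aux_vars.append(aux)
        node_tag = f"{tag}_n{counter[0]}"
        if node.kind == "and":
            ys, rows = encode_min(model, child_vars, aux, node_tag)
        elif or_mode == "max":
            ys, rows = encode_max(model, child_vars, aux, node_tag)
        else:
            ys, rows = _encode_sum(model, child_vars, aux, node_tag)
        enc.binaries.extend(ys)
        enc.n_constraints += rows
        return aux

    root = visit(ast)
    if ast.kind == "gene":
        # single-gene rule: introduce a dedicated root tied by equality so the
        # caller always owns a distinct reaction-level variable
        aux = model.add_var(f"{tag}_root", 0.0, 1.0)
        model.add_constr({aux: 1.0, root: -1.0}, 0.0, 0.0, name=f"{tag}_eq")
        enc.aux_vars.append(aux)
        enc.n_constraints += 1
        root = aux
    enc.root_var = root
    return enc


def evaluate_rule(
    ast: GeneProteinRule, gene_values: dict[str, float], or_mode: str = "max"
) -> float:
    """Direct recursive evaluation: min over ``and``, max (or sum) over ``or``."""
    if ast.kind == "gene":
        try:
            return float(gene_values[ast.gene])  # type: ignore[index]
        except KeyError:
            raise KeyError(f"no expression value for gene {ast.gene!r}") from None
    vals = [evaluate_rule(c, gene_values, or_mode) for c in ast.children]
    if ast.kind == "and":
        return min(vals)
    return sum(vals) if or_mode == "sum" else max(vals)
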