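"""Deterministic toy fixtures: small networks with known ground-truth routing.

The generator stands in for a real genome-scale model plus multi-condition
transcriptome: it emits small irreversible-splittable networks (a reversible
step is always present), AND/OR gene rules, per-condition uptake rates, and
an expression table generated *from* designed flux patterns, so that recovery
of the designed routing is a checkable ground truth. All randomness is seeded
and all outputs are reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cbm import ConditionSpec
from .expression import ExpressionMatrix
from .gem import GeneProteinRule, MetabolicNetwork, parse_gpr

__all__ = ["ToyNetworkSpec", "make_network", "make_expression", "make_condition_set"]

MOTIFS = ("linear_chain", "parallel_branches", "branched_with_loop", "diamond_gpr")
GPR_SCHEMES = ("none", "single", "and-pair", "or-pair", "nested")

#: nominal expression level of a fully active gene (arbitrary platform units)
BASE_LEVEL = 100.0


@dataclass(frozen=True)
class ToyNetworkSpec:
    motif: str = "parallel_branches"
    n_branches: int = 2
    uptake: float = 10.0
    gpr_scheme: str = "single"
    seed: int = 0

    def __post_init__(self):
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}; expected one of {MOTIFS}")
        if self.gpr_scheme not in GPR_SCHEMES:
            raise ValueError(f"unknown gpr scheme {self.gpr_scheme!r}")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if self.uptake <= 0:
            raise ValueError("uptake must be positive")


def _branch_rule(scheme: str, i: int, genes: list[str]) -> str | None:
    """GPR text for branch i under the requested scheme; appends new gene ids."""
    if scheme == "none":
        return None
    if scheme == "single":
        g = f"g{i}"
        genes.append(g)
        return g
    if scheme == "and-pair":
        a, b = f"g{i}a", f"g{i}b"
        genes.extend([a, b])
        return f"{a} and {b}"
    if scheme == "or-pair":
        a, b = f"g{i}a", f"g{i}b"
        genes.extend([a, b])
        return f"{a} or {b}"
    # nested: (a and b) or c
    a, b, c = f"g{i}a", f"g{i}b", f"g{i}c"
    genes.extend([a, b, c])
    return f"({a} and {b}) or {c}"


def make_network(spec: ToyNetworkSpec) -> MetabolicNetwork:
    """Build the requested motif; FBA-feasible with positive biomass.

    Every motif contains one reversible step (so the irreversible split has a
    direction pair) and a biomass pseudo-reaction marked as the objective.
    """
    mets: list[str] = []
    rxn_ids: list[str] = []
    stoich: list[dict[str, float]] = []
    lower: list[float] = []
    upper: list[float] = []
    obj: list[float] = []
    rule_texts: list[str | None] = []
    subsystems: list[str] = []
    genes: list[str] = []

    def add_met(mid: str) -> str:
        if mid not in mets:
            mets.append(mid)
        return mid

    def add_rxn(rid, coeffs, lo, hi, subsystem, rule=None, objective=0.0):
        rxn_ids.append(rid)
        stoich.append(coeffs)
        lower.append(lo)
        upper.append(hi)
        obj.append(objective)
        rule_texts.append(rule)
        subsystems.append(subsystem)

    U = 1000.0
    u = spec.uptake
    A, P, Q = add_met("A"), add_met("P"), add_met("Q")
    add_rxn("EX_A", {A: 1.0}, 0.0, u, "exchange")

    if spec.motif == "linear_chain":
        B, C = add_met("B"), add_met("C")
        add_rxn("R1", {A: -1, B: 1}, 0.0, U, "chain", _branch_rule(spec.gpr_scheme, 1, genes))
        add_rxn("R2", {B: -1, C: 1}, -U, U, "chain")  # the reversible step
        add_rxn("R3", {C: -1, P: 1}, 0.0, U, "chain", _branch_rule(spec.gpr_scheme, 3, genes))
    elif spec.motif in ("parallel_branches", "branched_with_loop"):
        for i in range(1, spec.n_branches + 1):
            add_rxn(
                f"B{i}", {A: -1, P: 1}, 0.0, U, f"branch_{i}",
                _branch_rule(spec.gpr_scheme, i, genes),
            )
        if spec.motif == "branched_with_loop":
            L = add_met("Lm")
            add_rxn("LOOP1", {A: -1, L: 1}, 0.0, U, "loop")
            add_rxn("LOOP2", {L: -1, A: 1}, 0.0, U, "loop")
    else:  # diamond_gpr: two branches with nested / mixed rules
        a, b, c = "g1a", "g1b", "g1c"
        genes.extend([a, b, c])
        add_rxn("B1", {A: -1, P: 1}, 0.0, U, "branch_1", f"({a} and {b}) or {c}")
        d, e, f = "g2a", "g2b", "g2c"
        genes.extend([d, e, f])
        add_rxn("B2", {A: -1, P: 1}, 0.0, U, "branch_2", f"{d} and ({e} or {f})")

    add_rxn("TP", {P: -1, Q: 1}, -U, U, "transport")  # reversible step exercising RE
    add_rxn("BIOMASS", {Q: -1}, 0.0, U, "biomass", objective=1.0)

    met_index = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxn_ids)))
    for j, coeffs in enumerate(stoich):
        for mid, c in coeffs.items():
            S[met_index[mid], j] = c
    rules: list[GeneProteinRule | None] = [
        parse_gpr(t) if t is not None else None for t in rule_texts
    ]
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=rxn_ids,
        S=S,
        lower=np.array(lower),
        upper=np.array(upper),
        objective=np.array(obj),
        gene_ids=genes,
        rules=rules,
        subsystems=subsystems,
    )


def make_condition_set(
    net: MetabolicNetwork, D: int, seed: int = 0, uptake_id: str = "EX_A"
) -> tuple[list[ConditionSpec], dict[str, np.ndarray]]:
    """D conditions with distinct uptakes and distinct designed flux routings.

    Designed fluxes live on the *original* reaction ids, satisfy Sv = 0, and
    route each condition's carbon through a preferred branch (round-robin over
    branches for branched motifs; uptake level is the only designed difference
    for chains). Returns (conditions, {condition_id: designed flux vector}).
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(seed)
    j_up = net.reaction_index(uptake_id)
    max_uptake = net.upper[j_up]
    branch_js = [j for j, rid in enumerate(net.reaction_ids) if rid.startswith("B") and rid != "BIOMASS"]
    chain_js = [
        j
        for j, rid in enumerate(net.reaction_ids)
        if rid in ("R1", "R2", "R3", "TP", "BIOMASS")
    ]
    conditions: list[ConditionSpec] = []
    designed: dict[str, np.ndarray] = {}
    # distinct uptake levels in (0.4, 1.0] of the bound, shuffled deterministically
    levels = 0.4 + 0.6 * (np.arange(1, D + 1) / D)
    rng.shuffle(levels)
    for d in range(D):
        u = float(max_uptake * levels[d])
        v = np.zeros(net.n_reactions)
        v[j_up] = u
        if branch_js:
            v[branch_js[d % len(branch_js)]] = u
        for j in chain_js:
            if j != j_up:
                v[j] = u
        cid = f"C{d + 1}"
        conditions.append(ConditionSpec(cid, {uptake_id: u}))
        designed[cid] = v
        residual = np.abs(net.S @ v).max()
        assert residual < 1e-9, "designed flux violates mass balance"
    return conditions, designed


def make_expression(
    net: MetabolicNetwork,
    designed: dict[str, np.ndarray],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression table coupled to the designed flux patterns.

    Each reaction's target activity is its cross-condition relative |flux|;
    a gene's activity is the max over its reactions (setting every leaf of an
    AND/OR rule to the reaction's target reproduces it under min/max
    aggregation). Values are BASE_LEVEL * activity with multiplicative
    log-normal noise of the given sd; genes attached to no reaction get a
    constant baseline.
    """
    rng = np.random.default_rng(seed)
    cond_ids = list(designed.keys())
    V = np.column_stack([np.abs(designed[c]) for c in cond_ids])  # n0 x D
    vmax = V.max(axis=1)
    rel = np.divide(V, vmax[:, None], out=np.zeros_like(V), where=vmax[:, None] > 0)

    gene_rxns: dict[str, list[int]] = {g: [] for g in net.gene_ids}
    for j, rule in enumerate(net.rules):
        if rule is None:
            continue
        for g in rule.genes():
            gene_rxns[g].append(j)

    K, D = len(net.gene_ids), len(cond_ids)
    T = np.empty((K, D))
    for i, g in enumerate(net.gene_ids):
        js = gene_rxns[g]
        if not js:
            T[i] = BASE_LEVEL * 0.5
        else:
            T[i] = BASE_LEVEL * rel[js].max(axis=0)
        if noise_sd > 0:
            T[i] *= np.exp(rng.normal(0.0, noise_sd, size=D))
    return ExpressionMatrix(list(net.gene_ids), cond_ids, T)
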