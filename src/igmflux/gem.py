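"""Genome-scale metabolic model container, GPR parsing and irreversible split.

The model is held as plain numpy arrays plus per-reaction metadata. File I/O
(SBML Level 3 with fbc, and COBRA-style JSON) is delegated to :mod:`cobra`;
everything downstream of loading runs on the in-package representation.

Gene-protein-reaction (GPR) rules are Boolean expressions over gene ids where
``and`` encodes an enzyme complex (all subunits required) and ``or`` encodes
isozymes (any one suffices). They are parsed into a small AST that the MILP
encoder and the direct evaluator both consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeneProteinRule",
    "MetabolicNetwork",
    "IrreversibleNetwork",
    "GPRParseError",
    "NetworkIntegrityError",
    "parse_gpr",
    "load_network",
    "save_network",
    "to_cobra",
    "from_cobra",
    "to_irreversible",
    "collapse_fluxes",
    "expand_fluxes",
]


class GPRParseError(ValueError):
    """Malformed GPR string; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class NetworkIntegrityError(ValueError):
    """Structurally inconsistent network (dimensions, bounds, references)."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneProteinRule:
    """Node of a Boolean gene-protein-reaction rule.

    ``kind`` is one of ``"gene"`` (leaf), ``"and"`` or ``"or"`` (internal,
    >= 2 children). Same-operator children are flattened on construction by
    the parser, so an ``and`` node never has an ``and`` child.
    """

    kind: str
    gene: str | None = None
    children: tuple["GeneProteinRule", ...] = ()

    def __post_init__(self):
        if self.kind == "gene":
            if not self.gene or self.children:
                raise ValueError("gene leaf must carry a gene id and no children")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind}-node needs >= 2 children")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    def genes(self) -> set[str]:
        if self.kind == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def to_string(self) -> str:
        if self.kind == "gene":
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            text = child.to_string()
            # parenthesize an 'or' child under an 'and' parent (and any
            # internal child generally, to keep round-trips unambiguous)
            if child.kind != "gene":
                text = f"({text})"
            parts.append(text)
        return f" {self.kind} ".join(parts)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """Return (type, value, position) tokens; type in {lpar, rpar, and, or, id}."""
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tok = m.group(1)
        at = m.start(1)
        low = tok.lower()
        if tok == "(":
            tokens.append(("lpar", tok, at))
        elif tok == ")":
            tokens.append(("rpar", tok, at))
        elif low == "and" or tok == "&":
            tokens.append(("and", tok, at))
        elif low == "or" or tok == "|":
            tokens.append(("or", tok, at))
        else:
            tokens.append(("id", tok, at))
        pos = m.end()
    return tokens


def parse_gpr(rule_text: str) -> GeneProteinRule:
    """Parse a GPR string into an AST.

    ``and`` binds tighter than ``or``; parentheses override; runs of the same
    operator flatten into a single node with >= 2 children. ``and``/``or`` are
    matched case-insensitively, gene ids case-sensitively.
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        raise GPRParseError("empty GPR expression", 0)
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else ("eof", "", len(rule_text))

    def parse_or() -> GeneProteinRule:
        nonlocal idx
        terms = [parse_and()]
        while peek()[0] == "or":
            idx += 1
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        flat: list[GeneProteinRule] = []
        for t in terms:
            flat.extend(t.children if t.kind == "or" else (t,))
        return GeneProteinRule("or", children=tuple(flat))

    def parse_and() -> GeneProteinRule:
        nonlocal idx
        factors = [parse_atom()]
        while peek()[0] == "and":
            idx += 1
            factors.append(parse_atom())
        if len(factors) == 1:
            return factors[0]
        flat: list[GeneProteinRule] = []
        for f in factors:
            flat.extend(f.children if f.kind == "and" else (f,))
        return GeneProteinRule("and", children=tuple(flat))

    def parse_atom() -> GeneProteinRule:
        nonlocal idx
        kind, value, at = peek()
        if kind == "lpar":
            idx += 1
            node = parse_or()
            kind2, _, at2 = peek()
            if kind2 != "rpar":
                raise GPRParseError("expected ')'", at2)
            idx += 1
            return node
        if kind == "id":
            idx += 1
            return GeneProteinRule("gene", gene=value)
        raise GPRParseError(f"unexpected token {value!r}", at)

    root = parse_or()
    kind, value, at = peek()
    if kind != "eof":
        raise GPRParseError(f"unexpected trailing token {value!r}", at)
    return root


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


@dataclass
class MetabolicNetwork:
    """Stoichiometric model: S, bounds, objective, GPR rules, subsystems."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray  # m x n stoichiometric coefficients
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    gene_ids: list[str]
    rules: list[GeneProteinRule | None]
    subsystems: list[str]

    def __post_init__(self):
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        self.S = np.asarray(self.S, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        if self.S.shape != (m, n):
            raise NetworkIntegrityError(
                f"S has shape {self.S.shape}, expected ({m}, {n})"
            )
        for arr, label in ((self.lower, "lower"), (self.upper, "upper"), (self.objective, "objective")):
            if arr.shape != (n,):
                raise NetworkIntegrityError(f"{label} bounds length != n")
        if np.any(self.lower > self.upper):
            bad = self.reaction_ids[int(np.argmax(self.lower > self.upper))]
            raise NetworkIntegrityError(f"reaction {bad!r}: lower bound exceeds upper bound")
        if len(self.rules) != n or len(self.subsystems) != n:
            raise NetworkIntegrityError("rules/subsystems length != n")
        genes = set(self.gene_ids)
        for rid, rule in zip(self.reaction_ids, self.rules):
            if rule is not None:
                missing = rule.genes() - genes
                if missing:
                    raise NetworkIntegrityError(
                        f"reaction {rid!r}: GPR references unknown genes {sorted(missing)}"
                    )

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def reversible(self) -> np.ndarray:
        return self.lower < 0

    @property
    def biomass_index(self) -> int:
        nz = np.flatnonzero(self.objective)
        if len(nz) == 0:
            raise NetworkIntegrityError("no objective (biomass) reaction marked")
        return int(nz[np.argmax(np.abs(self.objective[nz]))])


@dataclass
class IrreversibleNetwork(MetabolicNetwork):
    """Network after splitting reversible reactions into forward/backward columns.

    ``pairs`` lists each split as (forward_index, backward_index); ``provenance``
    maps every column back to (original reaction id, direction sign).
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    provenance: dict[str, tuple[str, int]] = field(default_factory=dict)
    original_reaction_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.lower < 0):
            raise NetworkIntegrityError("irreversible network has a negative lower bound")
        for f, b in self.pairs:
            if not np.allclose(self.S[:, f], -self.S[:, b]):
                raise NetworkIntegrityError(
                    f"pair ({self.reaction_ids[f]}, {self.reaction_ids[b]}) columns are not negatives"
                )


def to_irreversible(net: MetabolicNetwork) -> IrreversibleNetwork:
    """Split every reversible reaction into non-negative forward/backward columns.

    Backward-only reactions (lower < 0, upper <= 0) are flipped rather than
    split, so the pair set stays minimal. Split columns inherit the GPR rule
    and subsystem of the parent reaction.
    """
    cols: list[np.ndarray] = []
    ids: list[str] = []
    lower: list[float] = []
    upper: list[float] = []
    objective: list[float] = []
    rules: list[GeneProteinRule | None] = []
    subsystems: list[str] = []
    provenance: dict[str, tuple[str, int]] = {}
    pairs: list[tuple[int, int]] = []

    for j, rid in enumerate(net.reaction_ids):
        lo, hi = net.lower[j], net.upper[j]
        col = net.S[:, j]
        if lo >= 0:
            cols.append(col)
            ids.append(rid)
            lower.append(lo)
            upper.append(hi)
            objective.append(net.objective[j])
            rules.append(net.rules[j])
            subsystems.append(net.subsystems[j])
            provenance[rid] = (rid, 1)
        elif hi <= 0:
            # backward-only: flip direction instead of splitting
            cols.append(-col)
            ids.append(rid + "_r")
            lower.append(-hi)
            upper.append(-lo)
            objective.append(net.objective[j])
            rules.append(net.rules[j])
            subsystems.append(net.subsystems[j])
            provenance[rid + "_r"] = (rid, -1)
        else:
            fwd, bwd = rid + "_f", rid + "_b"
            fi = len(ids)
            cols.append(col)
            ids.append(fwd)
            lower.append(0.0)
            upper.append(hi)
            objective.append(net.objective[j])
            rules.append(net.rules[j])
            subsystems.append(net.subsystems[j])
            provenance[fwd] = (rid, 1)
            cols.append(-col)
            ids.append(bwd)
            lower.append(0.0)
            upper.append(-lo)
            objective.append(0.0)
            rules.append(net.rules[j])
            subsystems.append(net.subsystems[j])
            provenance[bwd] = (rid, -1)
            pairs.append((fi, fi + 1))

    return IrreversibleNetwork(
        metabolite_ids=list(net.metabolite_ids),
        reaction_ids=ids,
        S=np.column_stack(cols) if cols else np.zeros((net.n_metabolites, 0)),
        lower=np.array(lower),
        upper=np.array(upper),
        objective=np.array(objective),
        gene_ids=list(net.gene_ids),
        rules=rules,
        subsystems=subsystems,
        pairs=pairs,
        provenance=provenance,
        original_reaction_ids=list(net.reaction_ids),
    )


def collapse_fluxes(net: IrreversibleNetwork, flux: np.ndarray) -> np.ndarray:
    """Map a flux vector on the split network back to net fluxes on original ids."""
    flux = np.asarray(flux, dtype=float)
    if flux.shape != (net.n_reactions,):
        raise ValueError(
            f"flux vector length {flux.shape} does not match n={net.n_reactions}"
        )
    orig_index = {rid: i for i, rid in enumerate(net.original_reaction_ids)}
    out = np.zeros(len(net.original_reaction_ids))
    for j, rid in enumerate(net.reaction_ids):
        orig, sign = net.provenance[rid]
        out[orig_index[orig]] += sign * flux[j]
    return out


def expand_fluxes(net: IrreversibleNetwork, net_flux: np.ndarray) -> np.ndarray:
    """Inverse of :func:`collapse_fluxes` on split-consistent vectors.

    A net flux is routed entirely through the matching direction of each pair
    (the other direction carries zero), which is the canonical split-consistent
    representative.
    """
    net_flux = np.asarray(net_flux, dtype=float)
    orig_index = {rid: i for i, rid in enumerate(net.original_reaction_ids)}
    out = np.zeros(net.n_reactions)
    for j, rid in enumerate(net.reaction_ids):
        orig, sign = net.provenance[rid]
        v = net_flux[orig_index[orig]]
        out[j] = max(sign * v, 0.0)
    return out


# ---------------------------------------------------------------------------
# File I/O via cobra
# ---------------------------------------------------------------------------


def from_cobra(model) -> MetabolicNetwork:
    """Convert a :class:`cobra.Model` into the package's array representation."""
    metabolite_ids = [m.id for m in model.metabolites]
    reaction_ids = [r.id for r in model.reactions]
    met_index = {mid: i for i, mid in enumerate(metabolite_ids)}
    m, n = len(metabolite_ids), len(reaction_ids)
    S = np.zeros((m, n))
    lower = np.zeros(n)
    upper = np.zeros(n)
    objective = np.zeros(n)
    rules: list[GeneProteinRule | None] = []
    subsystems: list[str] = []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            if met.id not in met_index:
                raise NetworkIntegrityError(
                    f"reaction {rxn.id!r} references unknown metabolite {met.id!r}"
                )
            S[met_index[met.id], j] = coef
        lower[j] = rxn.lower_bound
        upper[j] = rxn.upper_bound
        objective[j] = rxn.objective_coefficient
        text = rxn.gene_reaction_rule
        rules.append(parse_gpr(text) if text and text.strip() else None)
        subsystems.append(rxn.subsystem if rxn.subsystem else "unassigned")
    return MetabolicNetwork(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lower=lower,
        upper=upper,
        objective=objective,
        gene_ids=[g.id for g in model.genes],
        rules=rules,
        subsystems=subsystems,
    )


def to_cobra(net: MetabolicNetwork, model_id: str = "model"):
    """Build a :class:`cobra.Model` from the array representation."""
    import cobra

    model = cobra.Model(model_id)
    mets = [cobra.Metabolite(mid, compartment="c") for mid in net.metabolite_ids]
    model.add_metabolites(mets)
    rxns = []
    for j, rid in enumerate(net.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(net.lower[j])
        rxn.upper_bound = float(net.upper[j])
        rxn.subsystem = net.subsystems[j]
        rxns.append(rxn)
    model.add_reactions(rxns)
    for j, rxn in enumerate(model.reactions):
        coeffs = {
            mets[i]: float(net.S[i, j])
            for i in range(net.n_metabolites)
            if net.S[i, j] != 0
        }
        rxn.add_metabolites(coeffs)
        rule = net.rules[j]
        if rule is not None:
            rxn.gene_reaction_rule = rule.to_string()
    # genes with no rule still belong to the model's gene list
    existing = {g.id for g in model.genes}
    for gid in net.gene_ids:
        if gid not in existing:
            model.genes.append(cobra.Gene(gid))
    objective = {
        model.reactions[j]: float(net.objective[j])
        for j in range(net.n_reactions)
        if net.objective[j] != 0
    }
    if objective:
        model.objective = objective
    return model


def load_network(path: str, format: str | None = None) -> MetabolicNetwork:
    """Load an SBML (Level 3 / fbc) or COBRA-JSON model from ``path``.

    ``format`` is ``"sbml"`` or ``"json"``; inferred from the extension when
    omitted. Reactions without a GPR string get ``rule = None``; a missing
    subsystem becomes ``"unassigned"``.
    """
    import cobra.io

    if format is None:
        lowered = path.lower()
        if lowered.endswith(".json"):
            format = "json"
        elif lowered.endswith((".xml", ".sbml")):
            format = "sbml"
        else:
            raise ValueError(f"cannot infer model format from {path!r}")
    if format == "json":
        model = cobra.io.load_json_model(path)
    elif format == "sbml":
        model = cobra.io.read_sbml_model(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    return from_cobra(model)


def save_network(net: MetabolicNetwork, path: str, format: str | None = None) -> None:
    """Write the network as SBML or COBRA-JSON (inferred from extension)."""
    import cobra.io

    if format is None:
        format = "json" if path.lower().endswith(".json") else "sbml"
    model = to_cobra(net)
    if format == "json":
        cobra.io.save_json_model(model, path, sort=True, pretty=True)
    else:
        cobra.io.write_sbml_model(model, path)
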