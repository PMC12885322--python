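"""Shared fixtures: toy networks, conditions, and a brute-force MILP oracle."""

import itertools

import numpy as np
import pytest

from igmflux import (
    ConditionSpec,
    IGMConfig,
    to_irreversible,
)
from igmflux.milp import Model, SolverError
from igmflux.synthetic import ToyNetworkSpec, make_condition_set, make_expression, make_network


@pytest.fixture
def chain_net():
    """Linear chain with one reversible step and single-gene rules."""
    return make_network(ToyNetworkSpec(motif="linear_chain", gpr_scheme="single"))


@pytest.fixture
def chain_irrev(chain_net):
    return to_irreversible(chain_net)


@pytest.fixture
def branches_net():
    """Two parallel single-step branches, single-gene rules."""
    return make_network(ToyNetworkSpec(motif="parallel_branches", n_branches=2, gpr_scheme="single"))


@pytest.fixture
def branches_irrev(branches_net):
    return to_irreversible(branches_net)


@pytest.fixture
def loop_net():
    return make_network(ToyNetworkSpec(motif="branched_with_loop", n_branches=2, gpr_scheme="single"))


@pytest.fixture
def default_cfg():
    return IGMConfig(transform_scheme="max_reference")


def branch_setup(n_branches=2, gpr_scheme="single", n_conditions=3, seed=0, noise_sd=0.0,
                 motif="parallel_branches"):
    """One-call fixture bundle: network, irreversible form, conditions, expression."""
    spec = ToyNetworkSpec(motif=motif, n_branches=n_branches, gpr_scheme=gpr_scheme, seed=seed)
    net0 = make_network(spec)
    net = to_irreversible(net0)
    conds, designed = make_condition_set(net0, n_conditions, seed)
    expr = make_expression(net0, designed, noise_sd, seed)
    return net0, net, conds, designed, expr


def enumerate_milp_optimum(model: Model) -> float:
    """Independent MILP oracle: exhaust all binary assignments, LP-solve each.

    Returns the best objective over feasible assignments (+inf if none).
    """
    binaries = [i for i in range(model.n_vars) if model._integer[i]]
    assert len(binaries) <= 12, "oracle is exponential; keep fixtures small"
    saved = [(model._lb[i], model._ub[i]) for i in binaries]
    best = np.inf
    try:
        for bits in itertools.product((0.0, 1.0), repeat=len(binaries)):
            for i, b in zip(binaries, bits):
                model.set_var_bounds(i, b, b)
            try:
                sol = model.solve()
            except SolverError:
                continue
            best = min(best, sol.objective)
    finally:
        for i, (lo, hi) in zip(binaries, saved):
            model.set_var_bounds(i, lo, hi)
    return best
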