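"""The integration MILP: assembly census, oracle equivalence, variant contracts."""

import numpy as np
import pytest

from igmflux import (
    ConditionSpec,
    IGMConfig,
    align_to_model,
    build_envelope,
    build_igm,
    compute_B,
    resolve_ctilde,
    run_fva,
    run_multi_condition,
    solve_fba,
    solve_igm,
    solve_igm_l1,
    solve_igm_l2,
    transform,
    uncentered_pearson,
)
from igmflux.synthetic import ToyNetworkSpec, make_network

from conftest import branch_setup, enumerate_milp_optimum


def assemble(net0, net, conds, expr, cfg, cond=None, ctilde=None):
    """FVA -> envelope -> transform -> one assembled problem."""
    results = [run_fva(net, c, cfg.p, cfg.exp_mode, cfg.exp_band) for c in conds]
    env = build_envelope(results, cfg.omega_flux)
    rel = align_to_model(transform(expr, cfg.transform_scheme, cfg.omega, cfg.eq18), net)
    cond = cond or conds[0]
    f_star = next(r.f_star for r in results if r.condition_id == cond.condition_id)
    B = compute_B(net, f_star)
    if ctilde is None:
        ctilde = resolve_ctilde(cfg.ctilde, B)
    return build_igm(net, env, rel, cond, cfg, ctilde), B


class TestComputeB:
    def test_arithmetic(self, branches_irrev):
        # B = (2k + 2n) / v_biomass_max
        k, n = branches_irrev.n_genes, branches_irrev.n_reactions
        assert compute_B(branches_irrev, 10.0) == pytest.approx((2 * k + 2 * n) / 10.0)

    def test_doubling_biomass_halves_B(self, branches_irrev):
        assert compute_B(branches_irrev, 20.0) == pytest.approx(
            compute_B(branches_irrev, 10.0) / 2
        )

    def test_normalization_identity(self, branches_irrev):
        """B * v_biomass_max equals the maximum deviation total 2k + 2n."""
        k, n = branches_irrev.n_genes, branches_irrev.n_reactions
        v = 7.3
        assert compute_B(branches_irrev, v) * v == pytest.approx(2 * k + 2 * n)

    def test_zero_growth_rejected(self, branches_irrev):
        with pytest.raises(ValueError, match="biomass"):
            compute_B(branches_irrev, 0.0)


class TestResolveCtilde:
    @pytest.mark.parametrize(
        "spec,expected", [("B", 4.0), ("2B", 8.0), ("B/10", 0.4), ("B/1000", 0.004), ("1", 1.0), (2.5, 2.5)]
    )
    def test_schedule_specs(self, spec, expected):
        assert resolve_ctilde(spec, 4.0) == pytest.approx(expected)

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            resolve_ctilde("twoB", 4.0)


class TestBuildCensus:
    def test_variable_census(self, default_cfg):
        """1 split pair, 2 rule-bearing branches, 2 genes: expected variable counts."""
        net0, net, conds, designed, expr = branch_setup(n_branches=2, gpr_scheme="single")
        problem, _ = assemble(net0, net, conds, expr, default_cfg)
        n = net.n_reactions
        assert len(problem.v_idx) == n
        assert len(problem.b_idx) == 2  # one binary per direction of the single pair
        assert problem.model.n_binaries == 2  # single-gene rules add no selectors
        assert len(problem.g_idx) == 2
        assert len(problem.ghat_idx) == 2  # both branches rule-bearing, non-degenerate
        assert len(problem.delta_idx) == 2  # both genes measured: 4 deviation vars
        assert len(problem.eps_idx) == 2  # 4 epsilon vars

    def test_degenerate_reaction_skipped(self, default_cfg):
        net0, net, conds, designed, expr = branch_setup(n_branches=2, gpr_scheme="single")
        results = [run_fva(net, c) for c in conds]
        env = build_envelope(results)
        # force one branch degenerate in the envelope
        j = net.reaction_ids.index("B1")
        env.degenerate[j] = True
        rel = align_to_model(transform(expr, "max_reference"), net)
        problem = build_igm(net, env, rel, conds[0], default_cfg, ctilde=1.0)
        assert j not in problem.eps_idx and j not in problem.ghat_idx

    def test_unmeasured_gene_floats(self, default_cfg):
        net0, net, conds, designed, expr = branch_setup(n_branches=2, gpr_scheme="single")
        expr.gene_ids[0] = "unrelated_gene"  # drops g1 from the table
        problem, _ = assemble(net0, net, conds, expr, default_cfg)
        assert "g1" not in problem.delta_idx
        assert "g1" in problem.g_idx

    def test_misaligned_expression_rejected(self, default_cfg):
        net0, net, conds, designed, expr = branch_setup()
        rel = transform(expr, "max_reference")  # not aligned to the model
        rel.gene_ids = ["x", "y"]
        results = [run_fva(net, c) for c in conds]
        env = build_envelope(results)
        with pytest.raises(ValueError, match="aligned"):
            build_igm(net, env, rel, conds[0], default_cfg, ctilde=1.0)


class TestSolveIGM:
    def test_expression_routes_flux(self, default_cfg):
        """g-tilde 1.0 on branch 1 and 0.0 on branch 2 routes flux through branch 1."""
        net0, net, conds, designed, expr = branch_setup(n_conditions=2, seed=1)
        problem, _ = assemble(net0, net, conds, expr, default_cfg)
        sol = solve_igm(problem)
        rel = align_to_model(transform(expr, "max_reference"), net)
        g1 = rel.column(conds[0].condition_id)["g1"]
        total = sol.net_flux[net0.reaction_ids.index("B1")] + sol.net_flux[net0.reaction_ids.index("B2")]
        preferred = "B1" if g1 == 1.0 else "B2"
        other = "B2" if preferred == "B1" else "B1"
        assert sol.net_flux[net0.reaction_ids.index(preferred)] >= 0.9 * total
        assert sol.net_flux[net0.reaction_ids.index(other)] <= 0.1 * total

    def test_uniform_expression_large_ctilde_recovers_fba(self, default_cfg):
        """With flat expression and ctilde = 2B the biomass term dominates."""
        net0, net, conds, designed, expr = branch_setup()
        expr.values[:] = 50.0  # flat: all relative schemes give a constant
        cfg = IGMConfig(transform_scheme="max_reference", ctilde="2B")
        problem, _ = assemble(net0, net, conds, expr, cfg)
        sol = solve_igm(problem)
        _, f_star = solve_fba(net, conds[0], cfg.exp_mode, cfg.exp_band)
        assert sol.biomass == pytest.approx(f_star, abs=1e-6)

    def test_tiny_ctilde_biomass_approaches_zero(self):
        """With a negligible biomass weight the deviation terms dominate and
        predicted growth collapses (no measured uptake pinning flux)."""
        net0, net, conds, designed, expr = branch_setup(n_conditions=2)
        # expression 0 in the target condition (and positive elsewhere, so the
        # relative value is a true 0, not the flat-row fallback): zero flux
        # then zeroes every deviation term
        expr.values[:, 0] = 0.0
        expr.values[:, 1] = 100.0
        cfg = IGMConfig(transform_scheme="max_reference", exp_mode="upper")
        results = [run_fva(net, c, exp_mode="upper") for c in conds]
        env = build_envelope(results)
        rel = align_to_model(transform(expr, "max_reference"), net)
        f_star = results[0].f_star
        B = compute_B(net, f_star)
        problem = build_igm(net, env, rel, conds[0], cfg, ctilde=B / 1e6)
        sol = solve_igm(problem)
        assert sol.biomass < 0.01 * f_star

    def test_pair_exclusivity(self, default_cfg):
        """At most one direction of every split pair carries flux."""
        net0, net, conds, designed, expr = branch_setup(n_conditions=3, seed=2)
        problem, _ = assemble(net0, net, conds, expr, default_cfg)
        sol = solve_igm(problem)
        for f, b in net.pairs:
            assert min(sol.flux[f], sol.flux[b]) <= 1e-9

    def test_deviation_complementarity(self, default_cfg):
        """d1*d2 = 0 and e1*e2 = 0 at optimality (they share a row, both cost 1)."""
        net0, net, conds, designed, expr = branch_setup(n_conditions=3, seed=3)
        problem, _ = assemble(net0, net, conds, expr, default_cfg)
        sol = solve_igm(problem)
        x = problem.model.solve().x
        for d1, d2 in problem.delta_idx.values():
            assert x[d1] * x[d2] <= 1e-9
        for e1, e2 in problem.eps_idx.values():
            assert x[e1] * x[e2] <= 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed, default_cfg):
        """MILP optimum equals brute-force enumeration over binary assignments."""
        scheme = ["single", "and-pair", "or-pair"][seed % 3]
        net0, net, conds, designed, expr = branch_setup(
            n_branches=2, gpr_scheme=scheme, n_conditions=2, seed=seed
        )
        problem, _ = assemble(net0, net, conds, expr, default_cfg)
        z_milp = solve_igm(problem).z_star
        z_oracle = enumerate_milp_optimum(problem.model)
        assert z_milp == pytest.approx(z_oracle, abs=1e-6)

    def test_biomass_bounded_by_fba_and_monotone_in_ctilde(self, default_cfg):
        """Biomass never exceeds FBA and is non-decreasing over the weight schedule."""
        for seed in range(5):
            net0, net, conds, designed, expr = branch_setup(n_conditions=2, seed=seed)
            results = [run_fva(net, c) for c in conds]
            env = build_envelope(results)
            rel = align_to_model(transform(expr, "max_reference"), net)
            f_star = results[0].f_star
            B = compute_B(net, f_star)
            biomasses = []
            for spec in ("B/1000", "B/100", "B/10", "B", "2B"):
                problem = build_igm(net, env, rel, conds[0], default_cfg, resolve_ctilde(spec, B))
                sol = solve_igm(problem)
                assert sol.biomass <= f_star + 1e-6
                biomasses.append(sol.biomass)
            assert np.all(np.diff(biomasses) >= -1e-6)


class TestVariants:
    def test_l1_removes_futile_cycle(self, default_cfg):
        """A free internal loop is eliminated by total-flux minimization."""
        net0, net, conds, designed, expr = branch_setup(motif="branched_with_loop", n_conditions=2)
        problem, _ = assemble(net0, net, conds, expr, default_cfg)
        base = solve_igm(problem)
        l1 = solve_igm_l1(problem, base=base)
        j1 = net.reaction_ids.index("LOOP1")
        j2 = net.reaction_ids.index("LOOP2")
        assert l1.flux[j1] <= 1e-6 and l1.flux[j2] <= 1e-6
        assert l1.flux.sum() <= base.flux.sum() + 1e-6

    def test_l1_preserves_z_star(self, default_cfg):
        for seed in range(5):
            net0, net, conds, designed, expr = branch_setup(n_conditions=2, seed=seed)
            problem, _ = assemble(net0, net, conds, expr, default_cfg)
            base = solve_igm(problem)
            l1 = solve_igm_l1(problem, base=base)
            assert l1.z_star == pytest.approx(base.z_star, rel=1e-6, abs=1e-6)

    def test_l1_on_unique_optimum_is_identity(self, default_cfg):
        net0, net, conds, designed, expr = branch_setup(motif="linear_chain", n_conditions=2)
        problem, _ = assemble(net0, net, conds, expr, default_cfg)
        base = solve_igm(problem)
        l1 = solve_igm_l1(problem, base=base)
        np.testing.assert_allclose(l1.flux, base.flux, atol=1e-6)

    def test_l2_splits_symmetric_branches_evenly(self):
        """Two equivalent branches carrying total T split T/2, T/2 under L2
        (the closed-form minimum of x^2 + (T - x)^2)."""
        net0, net, conds, designed, expr = branch_setup(n_branches=2, gpr_scheme="none", n_conditions=1)
        cfg = IGMConfig(transform_scheme="max_reference", ctilde="2B")
        problem, _ = assemble(net0, net, conds, expr, cfg)
        base = solve_igm(problem)
        l2 = solve_igm_l2(problem, base=base)
        b1 = l2.flux[net.reaction_ids.index("B1")]
        b2 = l2.flux[net.reaction_ids.index("B2")]
        total = b1 + b2
        assert b1 == pytest.approx(total / 2, rel=1e-3)
        assert b2 == pytest.approx(total / 2, rel=1e-3)

    def test_l2_preserves_z_star_and_beats_l1_on_squares(self, default_cfg):
        for seed in range(5):
            net0, net, conds, designed, expr = branch_setup(
                n_branches=2, gpr_scheme="none", n_conditions=2, seed=seed
            )
            problem, _ = assemble(net0, net, conds, expr, default_cfg)
            base = solve_igm(problem)
            l1 = solve_igm_l1(problem, base=base)
            l2 = solve_igm_l2(problem, base=base)
            tol = 1e-6 * max(1.0, abs(base.z_star))
            assert abs(l2.z_star - base.z_star) <= 2 * tol
            assert np.sum(l2.flux**2) <= np.sum(l1.flux**2) + 1e-6

    def test_l2_single_path_identical_to_l1(self, default_cfg):
        net0, net, conds, designed, expr = branch_setup(motif="linear_chain", n_conditions=2)
        problem, _ = assemble(net0, net, conds, expr, default_cfg)
        base = solve_igm(problem)
        l1 = solve_igm_l1(problem, base=base)
        l2 = solve_igm_l2(problem, base=base)
        np.testing.assert_allclose(l1.flux, l2.flux, atol=1e-5)


class TestMultiCondition:
    def test_three_conditions_three_solutions(self, default_cfg):
        net0, net, conds, designed, expr = branch_setup(n_conditions=3)
        sols = run_multi_condition(net, expr, conds, default_cfg)
        assert [s.condition_id for s in sols] == [c.condition_id for c in conds]

    def test_condition_order_invariance(self, default_cfg):
        """Permuting the condition order leaves each condition's z* unchanged."""
        net0, net, conds, designed, expr = branch_setup(n_conditions=3, seed=4)
        sols_fwd = run_multi_condition(net, expr, conds, default_cfg)
        sols_rev = run_multi_condition(net, expr, conds[::-1], default_cfg)
        by_id = {s.condition_id: s for s in sols_rev}
        for s in sols_fwd:
            assert s.z_star == pytest.approx(by_id[s.condition_id].z_star, abs=1e-8)

    def test_designed_routing_recovered(self, default_cfg):
        """Noiseless expression coupled to designed fluxes is recovered per condition."""
        net0, net, conds, designed, expr = branch_setup(n_conditions=3, seed=5)
        sols = run_multi_condition(net, expr, conds, default_cfg)
        for s in sols:
            r = uncentered_pearson(s.net_flux, designed[s.condition_id])
            assert r >= 0.9

    def test_missing_condition_column_rejected(self, default_cfg):
        net0, net, conds, designed, expr = branch_setup(n_conditions=2)
        with pytest.raises(ValueError, match="missing"):
            run_multi_condition(
                net, expr, conds + [ConditionSpec("C99", {"EX_A": 5.0})], default_cfg
            )
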