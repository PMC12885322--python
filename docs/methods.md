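# Methods

## Model and assumptions

`igmflux` predicts per-condition steady-state flux distributions on a
genome-scale metabolic model by coupling fluxes to relative gene expression.
The network is first converted to irreversible form: every reversible
reaction (lower bound < 0) becomes a forward/backward column pair, recorded in
a pair set so that (a) exactly one direction may be active in any solution and
(b) results can be collapsed back to signed net fluxes on the original
reaction ids. Backward-only reactions (lower < 0, upper ≤ 0) are flipped
rather than split, keeping the pair set minimal.

The pipeline per run is:

1. **FBA per condition** — maximize the biomass objective under mass balance,
   bounds, and that condition's measured exchange fluxes.
2. **FVA per condition** — per-reaction flux minima `α` and maxima `β` while
   retaining a fraction `p` of the FBA optimum (equality retention
   `Σ c_j v_j = p·f*` by default, `p = 1`; an inequality mode `≥ p·f*` is
   available). 2n LP solves per condition.
3. **Cross-condition envelope** — element-wise `min_d α_j,d` and
   `max_d β_j,d`. The envelope, not the per-condition range, scales fluxes in
   the matching constraint; this shared scale is what makes the per-condition
   solutions comparable.
4. **Expression transformation** — the raw gene × condition table is mapped
   row-wise into [0, 1] (see below) and aligned to the model's gene list.
5. **One MILP per condition** — the integration program described in the
   README, sharing the envelope and the transformed table across conditions.

The formulation carries no condition index; multi-condition coherence enters
through the shared envelope and the cross-condition normalization of
expression. A literal joint MILP over all conditions would add nothing the
shared scaling does not already provide, and would multiply the binary count
by the number of conditions, so it is not implemented.

## Expression transformations

Three row-wise reference schemes produce relative expression `g̃ ∈ [0, 1]`
from non-negative raw values `T` (any platform units; inputs are assumed
already normalized across samples):

- **max_reference**: `g̃ = T / max`. The most-expressed condition maps to 1.
- **minmax**: `g̃ = (T − min) / (max − min)`.
- **mean_reference** (default): the row mean is anchored at 0.5. Above-mean
  values are min-max scaled between mean and max into (0.5, 1]; below-mean
  values between min and mean into [0, 0.5). The below-mean branch is
  implemented in its monotone form `(T − min) / (2(mean − min))` (row minimum
  → 0). A reflected variant of this branch, which maps the row minimum to 0.5
  and is non-monotone, is available as `eq18="as-printed"` for comparison;
  the monotone form is the default because a relative-expression scale should
  preserve within-gene ordering.

Rows too flat to scale are guarded by `ω = 0.001` (configurable): if the
relevant range is ≤ ω the row falls back to a neutral constant (0.5, or 1.0
for max_reference when the row max is positive), keeping every gene's
matching constraint well-posed instead of dropping genes. Duplicate gene rows
are averaged. Genes in the table but not the model are dropped; model genes
missing from the table are flagged unmeasured and their `g` variables float
freely in [0, 1] with no deviation term.

## GPR encoding

GPR rules are parsed into ASTs (AND binds tighter than OR; same-operator runs
flatten into one ≥2-child node; `and`/`or` match case-insensitively, gene ids
case-sensitively). Each internal node is compiled into a big-M block over its
children's variables:

- AND (min): `out ≤ g_i`, `out ≥ g_i − M·y_i`, `Σ y_i = k − 1`
- OR (max): `out ≥ g_i`, `out ≤ g_i + M·y_i`, `Σ y_i = k − 1`

with `y_i ∈ {0,1}`: exactly one selector is zero, pinning `out` to the
min/max. Every block contributes exactly `2k + 1` constraints and `k`
binaries. Since all expression variables and auxiliaries live in [0, 1],
`M = 1` is sufficiently large and the tightest valid constant. Nested rules
are encoded recursively with one auxiliary [0, 1] variable per internal node;
the root auxiliary is the reaction's expression score `ĝ_j`. A solver-free
recursive evaluator provides the independent oracle in the test suite
(equivalence asserted to 1e-6 on random rules and gene vectors).

OR aggregation by **summation** instead of max (isozymes acting additively)
is available as `or_mode="sum"`; it needs no binaries, and the auxiliary's
upper bound is widened to the child count so the encoding remains feasible
when the children's sum exceeds 1. Max is the default.

## The integration MILP: scope rules and parameters

- **Scaled-flux matching (and its ε deviations) applies only to reactions
  that carry a GPR rule and are non-degenerate in the envelope**
  (envelope range > `ω_flux = 0.001`). `ĝ` is undefined without genes;
  a degenerate denominator is undefined arithmetic. Exchange, biomass and
  rule-less reactions therefore contribute no ε terms.
- **Binaries** exist only for split reversible pairs (plus GPR selectors).
  An unpaired reaction's activity indicator is fixed at 1: with `b = 1` the
  feasible box is strictly larger and `b` appears in no objective term, so
  this loses nothing and shrinks the MILP.
- **Measured exchange fluxes** (`exp_mode`): the default `equality` pins each
  measured reaction inside `v_exp · (1 ± 1%)` and closes the opposite
  direction of a split pair — measured uptake rates are observations, not
  ceilings. One-sided literal modes `upper` (`v ≤ v_exp`) and `lower`
  (`v ≥ v_exp`) are provided as alternatives.
- **Biomass weight** `c̃` defaults to `B = (2k + 2n) / v_biomass_max`
  (k genes, n irreversible reactions, `v_biomass_max` the condition's FBA
  optimum): dividing by `v_biomass_max` puts the biomass term on a unit
  scale and multiplying by `2k + 2n` (the maximum possible value of the
  deviation totals, each deviation variable being effectively bounded by 1 at
  optimality) makes the two objective parts commensurate. The schedule
  `{1, B/1000, B/100, B/10, B, 2B}` is supported for sensitivity analysis;
  predicted biomass is bounded by the FBA optimum and non-decreasing along
  it. Unknown upper bounds are set to `U = 1000` flux units.
- All deviation weights are 1; `c̃` is the only balance knob.

## Two-step variants

After the base solve, the optimum `z*` is pinned as a constraint
(`|objective − z*| ≤` a slack of `max(retention_tol, 1e-9)`, escalated once to
`1e-6·max(1, |z*|)` if numerically infeasible) and a second objective is
minimized:

- **L1**: `Σ v_j` — removes futile cycles and selects sparse flux routings
  (the transcriptome-constrained analogue of parsimonious FBA). Solved as a
  MILP.
- **L2**: `Σ v_j²` — spreads flux across equivalent routes (two symmetric
  branches carrying total T split T/2 each). The backend has no
  mixed-integer quadratic solver, so the binaries are fixed at their step-1
  values and the remaining convex QP is solved with a trust-region
  constrained method warm-started at the step-1 point.

## Evaluation

- **Measured-flux mapping**: measured fluxes (e.g. from ¹³C-MFA) map onto
  model reactions through a mini-language — `min(...)` for sequential steps
  (the slowest step limits the measured flux), `+` for parallel routes,
  arbitrarily nested. Mapping evaluates on collapsed net fluxes, absolute
  values by default (signed mode available).
- **Uncentered Pearson** `R = Σ v_p v_m / (‖v_p‖ ‖v_m‖)` — cosine similarity
  of raw flux vectors, undefined (error) on zero vectors.
- **RMSE / NRMSE**: standard RMSE `√(Σ(v_p − v_m)²/t)` by default, with an
  `as_printed` switch returning the raw sum of squares for comparison with
  sources that define it that way. NRMSE min-max normalizes RMSE over an
  explicit, caller-named batch of runs (methods, conditions, or both); a
  constant batch maps to 0 with a warning.
- **Flexibility**: with the stage-1 objective (FBA's `f*` or the MILP's `z*`)
  pinned within relative tolerance 1e-6, each original reaction's net flux is
  independently minimized and maximized; `FR = |v_max − v_min|`. Subsystem
  means and IGM/FBA ratios quantify how much the expression constraints
  shrink the alternate-optima space (ratios ≤ 1 on all bundled fixtures; an
  empirical observation, not a theorem).

## Flux-change analytics

Subsystem tables average |net flux| per subsystem per condition (sign
conventions across reversible reactions make raw means uninterpretable), then
min-max normalize each row; constant rows map to 0.5. Reaction-level change
is `log2(max(v_t, ε) / max(v_c, ε))` with floor `ε = 1e-6`; reactions below
the floor in both conditions carry no signal and are excluded and flagged
rather than reported as an artificial 0. Top-k lists break ties
lexicographically by reaction id for determinism.

## Synthetic fixtures

The generator emulates the structure of the benchmark inputs — a stoichiometric
model with AND/OR GPR rules, per-condition uptake rates, and multi-condition
expression — at toy scale (≤ ~30 reactions, all solves well under 10 s on one
CPU). Motifs: a linear chain, parallel branches, branches plus a futile
two-reaction loop (exercising L1), and a two-branch diamond with nested GPRs.
Every motif contains one reversible step, so the irreversible split always
produces a direction pair.

Conditions get distinct uptake levels (40–100% of the uptake bound, order
shuffled by seed) and distinct designed routings (round-robin branch
preference); designed fluxes satisfy `S v = 0` exactly. Expression is
generated **from relative designed fluxes**, matching the method's own
assumption that relative expression aligns with envelope-relative flux: each
reaction's target activity is its cross-condition relative |flux|, each
gene's activity the max over its reactions (setting all leaves of a rule to
the reaction's target reproduces it under min/max aggregation), scaled to a
nominal level of 100 with multiplicative log-normal noise of caller-chosen
sd. Noise defaults to 0 (the ground-truth-recovery regime); 0.1 is used as a
moderate-noise regime. All randomness flows through mandatory seeds.

What passing tests on these fixtures do **not** show: behavior on
genome-scale models (thousands of reactions, deep nested GPRs, measured-flux
mappings with real ¹³C coverage), robustness to systematic expression biases
(batch effects, platform saturation), or solver performance at genome scale.
The fixtures verify the mathematics — encoding correctness against
brute-force oracles, variant contracts, envelope behavior — not biological
generality.

## Numerical choices

- All LPs/MILPs solve through scipy's HiGHS interface; feasibility/optimality
  tolerances 1e-9, MIP relative gap 1e-9, single-threaded and deterministic.
- FVA bounds are rounded at 1e-9 to suppress sign noise, and min/max are
  clamped to be ordered against LP tolerance crossings.
- Ties among alternate optima are acknowledged: tests assert objective values
  and envelope-level properties rather than raw flux vectors, except after L1.
- Degenerate inputs: all-zero expression rows → 0.5; zero-growth conditions
  make `B` undefined (error); zero-norm vectors make the uncentered
  correlation undefined (error).

## Known limitations

- FVA on the split network admits the usual forward+backward cancellation on
  reversible pairs (the pair exclusivity binaries exist only in the
  integration MILP, not in plain FVA), so envelopes of reversible reactions
  can be wide; rule-less reversible steps are unaffected since they carry no
  matching constraint.
- The L2 variant's binary-fixing fallback returns the exact QP optimum only
  for the step-1 integer assignment; if an alternate assignment admitted a
  smaller flux norm it would be missed.
- NRMSE depends on the normalization batch; callers must name it explicitly.
- No loopless-FVA, thermodynamic constraints, or flux sampling.
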