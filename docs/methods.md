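# Methods

## Model and assumptions

The unit of analysis is a mature, monogynous colony of fixed size `n`
performing tasks `τ_1 … τ_η`.  The model's standing assumptions, in the order
they enter the code:

1. Colonies are founded by a single queen and reach a stable size; queens and
   males disperse and found daughter colonies independently (the simulator
   therefore treats daughter colonies as i.i.d. branches of a lineage).
2. Task ability is a property of an ant's morph (caste); the offspring types a
   queen produces and their fractions are heritable and mutable, which shifts
   selection to the colony level.
3. Subsistence `E = Σ_i E_i` is exactly linear in `n` at fixed caste
   proportions (each morph has a fixed basal rate).
4. Colony fitness `w` (daughter colonies per generation) is strictly
   increasing in per-capita net productivity `p = P/n`, and clamped at 0.
5. Task utilities obey diminishing marginal utility past a threshold, and
   their work-term derivative vanishes as a task saturates (finite resources
   around the nest).

Proximate caste-determination mechanisms, haplodiploid genetics, polygyny and
individual task-switching schedules are out of scope; only colony-level
aggregates are modelled.

## Utility families

The shape constraints above leave the functional form open.  Shipped families
(per task: importance `k ∈ (0,1]`, capacity `R ≥ 0` energy units, rate `a > 0`,
per-performer task energy `c ≥ 0`; all rates per time step):

| family | `U(n, ε)` | notes |
|---|---|---|
| `saturating` (default) | `kR(1 − e^{−anε}) − cnε` | strictly concave everywhere; work marginal → 0 at saturation, total marginal → `−cn` |
| `saturating_satcost` | `(kR − c/a)(1 − e^{−anε})` | task energy saturates with the work, so the *total* marginal utility → 0; concave iff `kRa > c` |
| `logistic` | shifted logistic minus linear cost | concave only past the inflection `threshold_n0`; refused by the solver |
| `power` | `kRε^a − cnε`, `a ∈ (0,1)` | homogeneous of degree `a` when `c = 0`; used for the biomass proxy |
| `linear` | `kRε − cnε` | reference family for derivative tests; not strictly concave |

The saturating-exponential default is the simplest strictly concave family
with closed-form derivatives.  The vanishing-marginal limit is exact for the
work component; with a linear task cost the total derivative tends to `−cn`,
so the `saturating_satcost` variant is provided for users who want the limit
to hold for the total.  Both cost conventions are deliberate: the shape
constraints do not determine which part of the utility the saturation applies
to, and the two variants bracket the possibilities.

Marginal utilities are analytic per family; the *fractional* marginal utility
`ν(ε, Δε) = [U(ε+Δε) − U(ε)]/Δε` converges to the analytic `μ` as `Δε → 0`
and is exposed for finite-increment reasoning.

## The ledger

`colony_ledger` keeps the per-ant accounting: `u_ij = k_τ ω_ij` for
performers, configured per-task energy `e_ij = c_τ`, competences and task
utilities as row/column sums.  `G` is defined as the sum of task utilities in
that fixed order, so `G == Σ_j U_j` holds bitwise and `Σ_i c_i` agrees to
machine precision.  Worker counts per task use largest-remainder rounding of
`n·ε_j` so integer counts sum consistently.  Time is discrete: one ledger per
step, all rates per step.

## Equilibrium solver

`solve_equilibrium` maximizes `P(ε) = Σ_j U_j(n, ε_j) − E` over
`{ε_j ≥ 0, Σ ε_j ≤ 1}`.  Since `E` does not depend on `ε`, this is a
separable concave program.  The solver:

1. refuses any task family that is not strictly concave for its parameters
   (a stationary point would not certify a global optimum);
2. runs a direct SLSQP maximization with the analytic gradient (skipped when a
   family's marginal utility diverges at 0, where gradient steps are
   ill-posed);
3. polishes with block-coordinate water-filling: per caste, invert
   `μ_j(ε) = λ` by bisection on each task (Brent's method, xtol 1e-15) and
   bisect `λ` to exhaust the caste's share.  For a monomorphic colony one pass
   is exact; multi-caste colonies iterate to a 1e-14 sweep tolerance.

The result carries a KKT certificate: active tasks share a common multiplier
`λ` (all pairwise MRS = 1 within 1e-4 relative, in practice ~1e-15), inactive
tasks satisfy `μ_j(0) ≤ λ` (the "task dropped" corner the equal-marginal
condition alone does not cover), and with colony-wide slack all active
`μ_j = 0`.  Tasks with `ε < 1e-9` count as inactive.  An exhaustive,
solver-independent grid oracle (`grid_oracle`: 0.01 lattice over the simplex,
refined at 0.001 then 0.0001 in a window around the incumbent) agrees with the
solver to better than 1e-6 relative on all ≤3-task scenarios; the two-stage
refinement is what makes lattice truncation error (quadratic in the final
step) smaller than that tolerance.

**Multi-caste colonies.**  Utility families take the *total* fraction on a
task; caste work rates `ω` gate capability (`ω > 0` means the caste can
perform the task) and feed the ledger.  Allocation is then a transportation
polytope program (each caste spreads its share over its performable tasks),
solved by the same machinery.  This is the minimal extension of the
monomorphic theory; making `U` depend on the performing castes' `ω` mix is a
known limitation (see below).

## Worker-loss perturbation

`redistribute_after_loss(task, δε)` interprets `δε` as the absolute decrement
of the task's fraction: `n·δε` workers die and are removed (they are gone, not
idle — `n` and `E` shrink; deaths fall proportionally on the castes staffing
the task).  Fractions are treated as continuous here, as appropriate for
`n ≫ 1`.  Before re-solving, the depleted task's marginal utility exceeds the
others' (MRS > 1) by strict concavity; re-solving on the reduced workforce
yields `P_original ≥ P_redistributed ≥ P_unredistributed`, strictly when
`δε > 0`.  The strictness of the first inequality additionally requires the
marginal worker to be worth more than her subsistence (`λ/n > E_basal`), which
the reference parameter ranges guarantee by a wide margin.

## Invasion dynamics

Discrete, non-overlapping colony generations: each colony produces
`Poisson(w)` daughters (`round(w)` in deterministic mode) and dies.  Daughters
inherit the queen's trait position `x` and mutant offspring fraction `f`, each
perturbed by a Gaussian kernel (`mutation_sigma`, `fraction_sigma`; the
fraction is clipped to [0, 1]).  The mutant count is integer,
`m = round(f·n)`; mutant per-capita productivity comes from a landscape
`p_m(x)` — sigmoid (trait beneficial past a threshold) or piecewise-linear.
Lineage populations are capped by uniform, seed-controlled thinning
(default ceiling 10,000 colonies).

Classification per lineage: extinction before the mean `p_m` ever reaches
`p_0` is **Case 1** (fitness still declining); extinction after is **Case 2**
(failure to recover; the asymptotic "number of colonies times mean fitness
powered over the recovery window" criterion is operationalized per-lineage as
exactly this event).  A lineage with mutants alive and mean `w ≥ 1` at the
horizon is **fixed**; anything else is **censored**, never silently dropped.

`phase_analysis` reports `θ⁻` (first step with `p_m ≥ p_0`; horizon and a
censoring flag if never), `θ⁺` (steps from the fitness minimum back to
`w ≥ 1`; 0 if fitness never dips below 1) and `Δw`, the integral of the
fitness rate `φ = dw/dt` over `[0, θ⁻+θ⁺]`.  With unit steps the rate lives
on the intervals between records, so the integral is the telescoping sum of
forward differences and equals `w(θ) − w(0)` to round-off — the discrete
fundamental-theorem identity the tests assert at 1e-8.

Note on symbols: the fitness *rate* and the recovery-window *duration* are
distinct quantities here (`φ` is used in the literature for both); the code
names them `phi` (rate) and `theta_plus` (duration).

The `m*` prediction — the mutant count stops growing where `p_m(m*) = p_0` —
is computed by `hill_climb_mutant_count` with continuous `m` and adaptive step
halving (initial step 1 ant, final 1e-9), because integer steps cannot
generically hit the 1e-3 equalization tolerance.  The stochastic simulator
keeps `m` integer; the hill-climb is the deterministic, analytic mode of that
prediction.

## Proxies and knockouts

The biomass proxy rests on per-capita utility `Ū_i = U_i/(n ε_i)` being equal
across active tasks at equilibrium.  Equal *marginal* utilities imply equal
*per-capita* utilities only when the two are proportional with a common
constant — i.e. for utility families homogeneous of one common degree in `ε`
(Euler's identity: `μ_i = a·U_i/ε_i` for the `power` family with shared
exponent `a` and zero linear cost).  For that family the proxy is exact
in-model (measured proportionality error ~1e-16); for the saturating default
it is an approximation and `ProxyReport.proportionality_error` carries the
measured gap rather than a claim of exactness.  The proxy refuses polymorphic
colonies, where per-ant mass differs across tasks.

`knockout_experiment` removes a caste, re-solves, and flags redistribution iff
a surviving caste's *worker count* (not fraction — `n` changed) on an orphaned
task strictly increased.  "Capable" means `ω > 0` for the task.  No capable
survivor ⇒ no-redistribution is reported as a capability limit, not a
falsification; capable survivors and still no shift would set
`falsified_flag`.  Removing a caste that exclusively staffed one task is
consistent with `redistribute_after_loss` at `δε = ε_task` (cross-module
identity, tested).

## Synthetic scenarios: what they emulate and what they do not

The fixture generator defines the package's reference study conditions:
colonies of `n = 100`, 2–4 tasks, `k ~ U(0.4, 1)`, `R ~ U(10, 30)` energy
units, `a ~ U(0.03, 0.08)` per worker (tasks saturate within the colony's
reach, `an ∈ [3, 8]`), task energy `c ~ U(0.002, 0.01)`, basal subsistence
`E_basal ~ U(5·10⁻⁴, 5·10⁻³)` — an ant's upkeep far below its marginal task
value, as in real colonies.  Under these ranges the allocation constraint
binds (every `μ_j` is still positive when the colony is fully employed) and
worker losses are strictly costly.  The invasion study uses `p_0 = 2`,
a sigmoid landscape from 0.5 to 3.5 with threshold at `x = 1` and rate 1.5,
trait walks of scale 0.25 starting at `x = −1`, and a linear fitness map
`w = max(0, 1.4 + 0.6(p − 2))` — a trait that starts clearly deleterious,
sub-critical lineage growth when half the colony carries it, super-critical
when few do.

What passing tests on these scenarios show: the analytic claims (equal
marginals, redistribution ordering, accounting identities, the `m*` stopping
rule, monotone fixation) hold in-model, at realistic scale separations.  What
they do not show: anything about measured ant energetics (parameters are not
calibrated to real basal metabolic rates or foraging yields), about
finite-`n` integer effects (fractions are continuous in the solver), or about
ecological structure the landscape abstracts away (seasonality, density
dependence between colonies).

## Problem sizes and numerical choices

Default study sizes keep every check cheap: 100 fixture scenarios for the
constraint sweep, ≤3-task grids for the oracle, 50 equilibria × 3 loss levels
for the redistribution ordering, and 2,000 lineages per initial-fraction level
(horizon 60 generations, population ceiling 300 colonies for this study —
fixation classification is insensitive to the cap once a lineage is large) for
the invasion monotonicity, which is the dominant cost at roughly half a
minute.  Key tolerances: active-set threshold 1e-9; MRS certificate 1e-4
relative (achieved ~1e-15); oracle agreement 1e-6 relative; phase integral
1e-8; `m*` equalization 1e-3.  Randomness: one `numpy` generator per
replicate, seeded `[seed, replicate]`, so results are reproducible under
changes of replicate count for shared prefixes; reports serialize floats at 12
significant digits with no timestamps, making identical runs byte-identical.

## Known limitations

- Multi-caste task utility ignores *how well* each caste performs a task
  (capability is binary in the solver); `ω` magnitudes matter only in the
  ledger.
- The continuous-fraction solver is a large-`n` idealization; for very small
  colonies integer allocations would bind.
- The Case-2 extinction criterion is an event definition, not the asymptotic
  statement it operationalizes; borderline lineages near the horizon are
  reported censored rather than forced into a class.
- The biomass proxy's exactness is family-dependent (see above); empirical
  use would require checking the homogeneity assumption.
- `k_τ` (task importance) has no estimation procedure; it is a free
  configuration parameter.
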