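# Methods

## Model

`coevolearn` simulates the coevolution of strategy and *learning ability* in
the spatial weak prisoner's dilemma. Players occupy the nodes of a symmetric
interaction graph — by default the L×L square lattice with periodic
boundaries and the von Neumann 4-neighbourhood — and are cooperators (C) or
defectors (D). Pair payoffs use the weak-dilemma parameterisation

    T = b,  R = 1,  P = S = 0,        1 < b ≤ 2,

so a single temptation parameter b controls the dilemma strength, and a
player's payoff P_x is the sum of pair payoffs against its k_x neighbours.

Strategies evolve by Fermi imitation scaled by the focal player's learning
ability w_x ∈ [w_min, w_max]:

    W(s_y → s_x) = w_x · 1 / (1 + exp((P_x − P_y)/K)),

with adoption noise K = 0.1 by default. High w marks an eager imitator, low
w a conservative one.

The learning ability coevolves by the winner-weaken-loser-strengthen rule:
after each adoption attempt the focal player compares P_x with the average
payoff of its environment,

    P̄_x = (Σ_{i=1..k_x} P_i) / k_x,

and moves w_x by a fixed increment d ∈ [0, 1]:

    w_x ← w_x + d   if P_x < P̄_x      (loser strengthens)
    w_x ← w_x − d   if P_x ≥ P̄_x      (winner weakens; ties weaken)

clamped to [w_min, w_max]. Three gating variants control who coevolves:
rule I (everyone), rule II (cooperators only), rule III (defectors only).
d = 0 recovers the classical homogeneous spatial game exactly.

## Update scheme

One full Monte Carlo (MC) step performs N = L² asynchronous elementary
updates with replacement (random sequential updating), so each player is
selected once on average. Within an elementary update:

1. the focal site x and all its neighbours get payoffs from the *current*
   configuration;
2. a uniformly drawn neighbour y is imitated with the Fermi probability
   above;
3. the w update compares the focal payoff with the environment average on
   the *post-adoption* configuration by default (`w_payoff_basis`): the
   learning ability evolves after the strategy adoption, so a player that
   just imitated a winning strategy is judged as the winner it became.
   The alternative reading — reusing the pre-adoption payoffs of step 1 —
   is available as an option. The choice matters: with pre-adoption
   payoffs a freshly successful imitator is still classified as a loser
   and strengthened, which weakens the winner-weaken feedback enough to
   change the phase diagram (under rule I at d = 0.08 the post-adoption
   basis drives cooperation extinct for every b > 1, the defining collapse
   of that regime, while the pre-adoption basis leaves a sizeable
   coexistence phase);
4. eligibility under rules II/III is judged on the focal player's
   *post-adoption* strategy by default (`gating_basis`); the pre-adoption
   basis is available as an option since the choice is genuinely open;
5. w is a persistent player attribute: a strategy switch carries w over
   unchanged, rules II/III merely freeze its evolution while the player
   holds the non-evolving strategy.

Synchronous updating, payoff accumulation across steps and strategy
mutation are deliberately not implemented.

### Degenerate and edge cases

- Fermi exponent arguments are clipped at ±700 before exponentiation; the
  probability saturates smoothly to 0 or w_x.
- The tie P_x = P̄_x always takes the weaken branch (the comparison is ≥).
- Under the restricted comparison sets (`SAME_STRATEGY` /
  `DIFFERENT_STRATEGY`, an optional variant of the environment average) an
  empty selection leaves w unchanged for that step; the kernel counts these
  occurrences. The restriction is judged relative to the same focal
  strategy used for gating.
- `w_max = 1.0` is a deliberate clamp: the initial endowment w = 1 is the
  maximum learning ability, and the Fermi prefactor must stay a valid
  probability. `w_min = 0.1` avoids frozen states.
- All-C and all-D configurations are absorbing for strategies; scans stop
  early on absorption by default because further strategy dynamics are
  redundant (w dynamics continue only in `advance`, used for snapshot
  series).

## Engines and reproducibility

Two implementations of the same elementary step exist:

- a pure-Python reference engine (`coevolearn.engine`), literal and
  instrumented (`StepOutcome` per update), used for small worlds, the
  enumeration tests and as a cross-check;
- a numba-jitted kernel (`coevolearn._kernel`) for production runs,
  ~10⁷ elementary updates per second on one core.

Both follow the same draw order (focal site → neighbour → acceptance
uniform) but use different RNG streams (numpy `Generator` vs numba's
legacy global state), so they agree exactly on deterministic limits and
statistically on stochastic summaries; the test suite checks both. Within
an engine, a (seed, params, initial world) triple gives bit-identical
trajectories. Replicates derive child seeds from the master seed through
`SeedSequence` spawn keys indexed by grid position, so scan results are
independent of execution order and resumable.

## Observables

- **Stationary density**: f_C averaged over the trailing `average_window`
  MC steps (default 5×10³ of 5×10⁴; the classical protocol), or the
  absorbed value when the run absorbs first.
- **Extinction threshold b_C**: on an increasing b grid, a grid point is
  extinct when stationary f_C < ε in *all* replicates (ε = 10⁻³, i.e.
  below a handful of cooperators at L = 100 — separates near-absorbed runs
  from coexistence without waiting for full absorption). b_C is the
  midpoint of the bracket (largest surviving b, smallest extinct b), and
  the bracket is always reported so other criteria can be applied post
  hoc. A survival pattern that is non-monotone under the all-replicates
  criterion (an isolated survival above an extinct point) is resolved by
  per-b replicate majority and logged. When the whole grid is extinct the
  bracket's lower end is the dilemma's lower limit b = 1 (the model
  requires b > 1); when the whole grid survives there is no estimate.
- **END/EXP decomposition**: the enduring period (cooperation declines
  under defector invasion while clusters form) is separated from the
  expanding period (clusters regrow through network reciprocity) at the
  minimum of the f_C trajectory smoothed with a centred moving average
  (default 50 recorded samples; earliest minimum on ties). An asymmetric
  V with a wide window can shift the smoothed argmin by a sample or two —
  the window should be narrow relative to the slopes of interest.
- **Boundary statistics**: a boundary player has at least one
  opposite-strategy neighbour; `learning_ability_stats` reports per-strategy
  counts and mean w overall and on the boundary, which is the quantity that
  explains the rule II/III asymmetry (boundary cooperators with low w
  endure; boundary defectors with high w defect themselves away).

## Initial conditions

- `random_initial`: each site C or D with probability 1/2, all w = 1 (the
  maximum, "fair" start). This is the default for density curves and
  threshold scans.
- `four_bar_initial`: four vertical bars (default C, D, C, D left→right),
  the two left bars at w = 0.1 and the two right bars at w = 1.0 — the
  controlled start used to watch boundary coevolution between players of
  extreme learning ability. The exact left-to-right strategy order is not
  uniquely determined by the published description; the default places one
  C|D interface inside each w-region, and the order is fully configurable
  (`FourBarSpec`). Bar widths are ⌊L/4⌋ with the remainder absorbed by the
  rightmost bar.

## Problem sizes

Published density curves use L = 100–400, 5×10⁴–10⁵ MC steps and 20
realisations per point. The package defaults keep the classical schedule
(5×10⁴ / 5×10³) available, but the bundled tests and the reproduction
script run desk-scale versions — L = 50–100, (4–20)×10³ steps, 3–10
replicates — chosen so each check finishes in minutes while the phenomena
it probes (coexistence, monotone suppression, threshold collapse) are
already developed at those sizes. The methods the package exposes are
size-agnostic; anyone can rerun the full-scale protocol through the same
API or CLI.

## What the simulations do and do not show

The generator *is* the model under study (there is no external data): runs
emulate exactly the stated study conditions. Scaled-down lattices have
stronger finite-size fluctuations — single replicates near a threshold can
go extinct by drift — which is why threshold estimates aggregate replicates
and report brackets. Conclusions about real social or biological systems
are outside scope: the package demonstrates mechanism (network reciprocity
modulated by heterogeneous learning ability), not calibration to data.

## Known limitations

- Near the collapse point of rule I (d ≈ 0.08, b just above 1) the
  dynamics is knife-edged: most replicates absorb to all-D within
  ~2×10⁴ MC steps at L = 100, but a minority leave a small metastable
  cooperator cluster (f_C ~ 0.01–0.07) that can outlive 10⁵ steps.
  Threshold estimates there are sensitive to the extinction criterion ε
  and to the schedule; the bracket output makes that sensitivity
  explicit.

- The restricted comparison-set variants implement a literal reading of
  "comparison only among players having the same or different strategies";
  the original appendix defining them was not available, so they are
  excluded from any quantitative claim.
- b_C estimates are grid-resolution limited by construction; the bracket
  is the honest statement of uncertainty.
- The jitted kernel seeds numba's global legacy RNG; segmented runs
  (snapshot series) therefore use per-segment child seeds rather than a
  continuous stream. Statistically this is immaterial; bit-level
  continuation across segments is not claimed.
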