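# coevolearn

Monte Carlo simulator for the **coevolution of strategy and heterogeneous
learning ability** in the spatial weak prisoner's dilemma.

## The problem

On a periodic L×L lattice, cooperators (C) and defectors (D) play the weak
prisoner's dilemma with their four nearest neighbours — payoffs T = b,
R = 1, P = S = 0 with temptation 1 < b ≤ 2 — and imitate strategies by the
Fermi rule. Each player additionally carries a *learning ability*
w ∈ [0.1, 1] that scales its probability of imitating at all:

    W(s_y → s_x) = w_x / (1 + exp((P_x − P_y)/K)),      K = 0.1.

After every adoption attempt the focal player's w coevolves by the
**winner-weaken-loser-strengthen rule**: comparing its payoff with the
average payoff P̄_x of its neighbourhood,

    w_x ← w_x + d   if P_x < P̄_x,
    w_x ← w_x − d   if P_x ≥ P̄_x,

clamped to [0.1, 1]. The rule can apply to everyone (**rule I**), only to
cooperators (**rule II**) or only to defectors (**rule III**); d = 0
recovers the classical homogeneous spatial game. The headline phenomena
this package reproduces at desk scale:

- rule I and rule III *suppress* cooperation — under rule I the extinction
  threshold b_C falls roughly linearly with d and collapses to 1 near
  d ≈ 0.08;
- rule II *promotes* cooperation, strongest near d = 0.05, because bulk and
  boundary cooperators become conservative (low w) while defectors stay
  eager imitators (w = 1).

The package is aimed at researchers in evolutionary game dynamics who want
a fast, tested, reproducible implementation: a numba-jitted kernel
(~10⁷ elementary updates/s) behind a plain numpy API, a pure-Python
reference engine for scrutiny, initializers for the standard random 50/50
and "four-bar" starts, observables (stationary density, extinction
thresholds with brackets, enduring/expanding decomposition, boundary
learning-ability statistics, snapshot export) and a thin CLI.

## Worked example

```python
from coevolearn import (GameParams, RuleVariant, Schedule,
                        random_initial, run_to_stationarity)

schedule = Schedule(max_steps=3000, average_window=500, record_every=50)

world = random_initial(L=100, seed=1)
params = GameParams(b=1.02, d=0.0).validate()   # classical homogeneous game
traj, fc = run_to_stationarity(world, params, schedule, seed=1)
print(f"stationary f_C = {fc:.3f}")
```

prints

```
stationary f_C = 0.399
```

— at b = 1.02 the classical game sustains a large cooperator fraction
through network reciprocity (spatial clustering). Running the same start
under rule I with d = 0.05
(`GameParams(b=1.02, d=0.05, rule=RuleVariant.RULE_I)`) yields

```
stationary f_C = 0.000
```

— the winner-weaken-loser-strengthen rule applied to everyone pushes the
extinction threshold below this temptation and cooperation dies out. The scripts in `examples/` walk through one
capability each (single runs, the three-rule comparison, four-bar
snapshot series) and print what each number means; the CLI mirrors them:

```sh
coevolearn run  --b 1.02 --d 0.05 --rule I --L 100 --steps 3000 --avg-window 500 --seed 1 --out out/run
coevolearn scan --b-grid 1.01,1.02,1.05 --d 0.08 --rule I --reps 5 --seed 1 --out out/scan
coevolearn snapshot-series --init four-bar --times 0,10,100,1000 --b 1.01 --d 0.03 --L 100 --out out/snaps
```

Every output directory receives a resolved `config.yaml` that reproduces
the run bit-exactly.

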