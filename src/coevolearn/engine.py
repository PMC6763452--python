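"""Payoffs, Fermi adoption, winner-weaken-loser-strengthen update, MC driver.

This module is the readable reference implementation of the elementary
dynamics; long simulations go through the numerically identical jitted
kernel in :mod:`coevolearn._kernel` (see
:func:`coevolearn.observables.run_to_stationarity`).

The elementary asynchronous step is:

1. draw a focal player x uniformly at random;
2. compute its payoff P_x and the payoffs of all its neighbours from the
   current configuration (each payoff is the sum of weak-PDG pair payoffs
   against that player's own neighbours);
3. draw one neighbour y uniformly;
4. with probability ``w_x / (1 + exp((P_x - P_y)/K))`` copy y's strategy;
5. form the environment average P̄_x = mean of the neighbours' payoffs in
   the *post-adoption* configuration (the default ``w_payoff_basis``; the
   pre-adoption payoffs of step 2 are an option);
6. if the gating rule allows it, increase w_x by d when P_x < P̄_x and
   decrease it by d otherwise (ties weaken), clamped to [w_min, w_max].

One full Monte Carlo step repeats this N = L² times (random sequential
selection with replacement), so every player updates once on average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ComparisonSet, GameParams, GatingBasis, RuleVariant, Strategy, World

__all__ = [
    "NO_COMPARISON",
    "StepOutcome",
    "MCStepStats",
    "pair_payoff",
    "total_payoff",
    "environment_average_payoff",
    "adoption_probability",
    "is_w_evolution_enabled",
    "evolve_learning_ability",
    "elementary_update",
    "full_mc_step",
]

#: Sentinel returned by :func:`environment_average_payoff` when the selected
#: comparison set is empty (possible only under the SAME/DIFFERENT variants).
NO_COMPARISON = float("nan")

_EXP_CLIP = 700.0  # exp argument beyond which the Fermi function saturates


def pair_payoff(s_x: Strategy | int, s_y: Strategy | int, params: GameParams) -> float:
    """Weak-PDG payoff earned by a player with strategy ``s_x`` against ``s_y``.

    (C, C) -> R = 1; (C, D) -> S = 0; (D, C) -> T = b; (D, D) -> P = 0.
    """
    if int(s_x) == int(Strategy.COOPERATE):
        return params.R if int(s_y) == int(Strategy.COOPERATE) else params.S
    return params.T if int(s_y) == int(Strategy.COOPERATE) else params.P


def total_payoff(world: World, site, params: GameParams) -> float:
    """Payoff of ``site``: sum of pair payoffs against each of its neighbours."""
    i = world.flat_index(site)
    s_i = int(world.strategies[i])
    return float(
        sum(pair_payoff(s_i, int(world.strategies[j]), params) for j in world.neighbors_of(i))
    )


def _selected_neighbors(world: World, i: int, reference_strategy: int, comparison_set: ComparisonSet):
    neigh = world.neighbors_of(i)
    if comparison_set is ComparisonSet.ALL_NEIGHBORS:
        return neigh
    same = world.strategies[neigh] == reference_strategy
    if comparison_set is ComparisonSet.SAME_STRATEGY:
        return neigh[same]
    return neigh[~same]


def environment_average_payoff(world: World, site, params: GameParams) -> float:
    """Mean payoff of the neighbours selected by ``params.comparison_set``.

    With ``ALL_NEIGHBORS`` this is P̄_x = (Σ_i P_i) / k_x over all k_x
    neighbours.  Under the SAME/DIFFERENT restrictions an empty selection
    returns :data:`NO_COMPARISON`.
    """
    i = world.flat_index(site)
    sel = _selected_neighbors(world, i, int(world.strategies[i]), params.comparison_set)
    if len(sel) == 0:
        return NO_COMPARISON
    return float(np.mean([total_payoff(world, int(j), params) for j in sel]))


def adoption_probability(P_x: float, P_y: float, w_x: float, K: float) -> float:
    """Fermi adoption probability ``w_x / (1 + exp((P_x - P_y)/K))``.

    Strictly inside (0, w_x) for finite arguments; the exponent is clipped
    so extreme payoff differences saturate smoothly to 0 or w_x.
    """
    arg = (P_x - P_y) / K
    arg = max(-_EXP_CLIP, min(_EXP_CLIP, arg))
    return w_x / (1.0 + math.exp(arg))


def is_w_evolution_enabled(rule: RuleVariant, strategy: Strategy | int) -> bool:
    """Rule I: everyone; rule II: cooperators only; rule III: defectors only."""
    if rule is RuleVariant.RULE_I:
        return True
    if rule is RuleVariant.RULE_II:
        return int(strategy) == int(Strategy.COOPERATE)
    return int(strategy) == int(Strategy.DEFECT)


def evolve_learning_ability(
    w_x: float,
    P_x: float,
    Pbar_x: float,
    d: float,
    w_min: float = 0.1,
    w_max: float = 1.0,
) -> float:
    """Winner-weaken-loser-strengthen update of the learning ability.

    ``w`` grows by ``d`` when the player earns less than its environment
    (P_x < P̄_x) and shrinks by ``d`` otherwise — the tie weakens — clamped
    to [w_min, w_max].  A :data:`NO_COMPARISON` environment leaves ``w``
    unchanged.
    """
    if math.isnan(Pbar_x):
        return w_x
    if P_x < Pbar_x:
        return min(w_x + d, w_max)
    return max(w_x - d, w_min)


@dataclass(frozen=True)
class StepOutcome:
    """Record of one elementary update."""

    site: int
    neighbor: int
    adopted: bool
    strategy_before: Strategy
    strategy_after: Strategy
    payoff_focal: float
    payoff_neighbor: float
    env_avg: float
    w_before: float
    w_after: float


@dataclass(frozen=True)
class MCStepStats:
    """Summary of one full Monte Carlo step."""

    n_adoptions: int
    n_strategy_flips: int
    f_C: float


def elementary_update(
    world: World, rng: np.random.Generator, params: GameParams
) -> StepOutcome:
    """Perform one elementary asynchronous update in place.

    Exactly one site's strategy and one site's ``w`` may change.  The Fermi
    rule always sees pre-adoption payoffs; the learning-ability comparison
    sees the payoffs of the basis selected by ``params.w_payoff_basis``
    (post-adoption by default — a freshly successful imitator is judged as
    the winner it just became).  Rule gating judges the focal strategy on
    the basis selected by ``params.gating_basis``.
    """
    n = world.n_sites
    x = int(rng.integers(n))
    neigh = world.neighbors_of(x)
    k = len(neigh)

    P_x = total_payoff(world, x, params)
    neigh_payoffs = np.array([total_payoff(world, int(j), params) for j in neigh])

    jy = int(rng.integers(k))
    y = int(neigh[jy])
    P_y = float(neigh_payoffs[jy])

    w_x = float(world.w[x])
    prob = adoption_probability(P_x, P_y, w_x, params.K)
    s_x_old = int(world.strategies[x])
    adopted = bool(rng.random() < prob)
    if adopted:
        world.strategies[x] = world.strategies[y]

    gate_strategy = (
        int(world.strategies[x])
        if params.gating_basis is GatingBasis.POST_ADOPTION
        else s_x_old
    )
    env_avg = NO_COMPARISON
    w_after = w_x
    if is_w_evolution_enabled(params.rule, gate_strategy):
        if params.w_payoff_basis is GatingBasis.POST_ADOPTION:
            # a flip by the focal site changes its own and its neighbours'
            # payoffs; recompute on the current configuration
            P_x_cmp = total_payoff(world, x, params)
            cmp_payoffs = np.array(
                [total_payoff(world, int(j), params) for j in neigh]
            )
        else:
            P_x_cmp = P_x
            cmp_payoffs = neigh_payoffs
        if params.comparison_set is ComparisonSet.ALL_NEIGHBORS:
            env_avg = float(cmp_payoffs.mean())
        else:
            same = world.strategies[neigh] == gate_strategy
            mask = same if params.comparison_set is ComparisonSet.SAME_STRATEGY else ~same
            if mask.any():
                env_avg = float(cmp_payoffs[mask].mean())
        w_after = evolve_learning_ability(
            w_x, P_x_cmp, env_avg, params.d, params.w_min, params.w_max
        )
        world.w[x] = w_after

    return StepOutcome(
        site=x,
        neighbor=y,
        adopted=adopted,
        strategy_before=Strategy(s_x_old),
        strategy_after=Strategy(int(world.strategies[x])),
        payoff_focal=P_x,
        payoff_neighbor=P_y,
        env_avg=env_avg,
        w_before=w_x,
        w_after=w_after,
    )


def full_mc_step(
    world: World, rng: np.random.Generator, params: GameParams
) -> MCStepStats:
    """Advance the world one full Monte Carlo step (N elementary updates).

    Random sequential selection with replacement: every player updates once
    on average.
    """
    n = world.n_sites
    n_adopt = 0
    n_flips = 0
    for _ in range(n):
        out = elementary_update(world, rng, params)
        if out.adopted:
            n_adopt += 1
            if out.strategy_after != out.strategy_before:
                n_flips += 1
    return MCStepStats(
        n_adoptions=n_adopt,
        n_strategy_flips=n_flips,
        f_C=float(world.strategies.mean()),
    )
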