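import numpy as np
import pytest

from coevolearn import GameParams, RuleVariant, Strategy, World


@pytest.fixture
def params():
    """Baseline parameters in the classical coexistence region."""
    return GameParams(b=1.05, d=0.03, K=0.1).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_world(tokens, w=1.0):
    """Build a small lattice world from rows of 'C'/'D' tokens."""
    rows = [list(r) for r in tokens]
    L = len(rows)
    strategies = np.array(
        [[int(Strategy.from_token(t)) for t in row] for row in rows], dtype=np.int8
    )
    return World.lattice(L, strategies.ravel(), w=w)


def brute_force_total_payoff(world, site, params):
    """Independent double-loop payoff oracle: iterate over all ordered site
    pairs and accumulate the weak-PDG entries for the focal site's edges."""
    i = world.flat_index(site)
    total = 0.0
    n = world.n_sites
    for a in range(n):
        if a != i:
            continue
        for bsite in range(n):
            if bsite not in set(int(j) for j in world.neighbors_of(a)):
                continue
            sa = int(world.strategies[a])
            sb = int(world.strategies[bsite])
            if sa == 1 and sb == 1:
                total += 1.0
            elif sa == 0 and sb == 1:
                total += params.b
    return total


@pytest.fixture
def all_rules():
    return [RuleVariant.RULE_I, RuleVariant.RULE_II, RuleVariant.RULE_III]
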