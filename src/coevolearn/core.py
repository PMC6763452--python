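"""Domain types: strategies, parameters, and the lattice world.

The :class:`World` stores the population as flat numpy arrays (one strategy
code and one learning ability per site) plus an explicit neighbour table.
Every operation in the package consumes only ``neighbors(x)`` and the degree
``k_x``, never the side length directly, so arbitrary symmetric graphs are
admissible even though the default topology is the periodic von Neumann
lattice.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Strategy",
    "RuleVariant",
    "GatingBasis",
    "ComparisonSet",
    "GameParams",
    "PlayerState",
    "World",
    "ParamError",
    "validate_params",
]


class ParamError(ValueError):
    """A game parameter violates its documented bound."""


class Strategy(enum.IntEnum):
    """Player strategy; cooperators are encoded 1 and defectors 0."""

    DEFECT = 0
    COOPERATE = 1

    @property
    def token(self) -> str:
        return "C" if self is Strategy.COOPERATE else "D"

    @classmethod
    def from_token(cls, token: str) -> "Strategy":
        if token == "C":
            return cls.COOPERATE
        if token == "D":
            return cls.DEFECT
        raise ValueError(f"unknown strategy token {token!r} (expected 'C' or 'D')")


class RuleVariant(enum.Enum):
    """Which strategy class is allowed to evolve its learning ability."""

    RULE_I = "I"  # both cooperators and defectors
    RULE_II = "II"  # cooperators only
    RULE_III = "III"  # defectors only

    @property
    def code(self) -> int:
        return {"I": 0, "II": 1, "III": 2}[self.value]


class GatingBasis(enum.Enum):
    """Whether rule II/III eligibility uses the focal player's strategy
    after or before the adoption attempt of the same elementary step."""

    POST_ADOPTION = "post"
    PRE_ADOPTION = "pre"

    @property
    def code(self) -> int:
        return 0 if self is GatingBasis.POST_ADOPTION else 1


class ComparisonSet(enum.Enum):
    """Which neighbours enter the environment-average payoff."""

    ALL_NEIGHBORS = "all"
    SAME_STRATEGY = "same"
    DIFFERENT_STRATEGY = "different"

    @property
    def code(self) -> int:
        return {"all": 0, "same": 1, "different": 2}[self.value]


@dataclass(frozen=True)
class GameParams:
    """Parameters of the coevolutionary weak prisoner's dilemma.

    Parameters
    ----------
    b:
        Temptation to defect, the single dilemma parameter; must satisfy
        ``1 < b <= 2`` so that the payoff ranking T > R > P >= S holds.
    K:
        Noise of the Fermi adoption rule (uncertainty of strategy adoption).
    d:
        Learning-ability increment of the winner-weaken-loser-strengthen
        update, in ``[0, 1]``; ``d = 0`` recovers the classical homogeneous
        game.
    w_min, w_max:
        Clamps on the learning ability; ``w_min = 0.1`` avoids frozen states
        and ``w_max = 1.0`` keeps the Fermi prefactor a valid probability.
    rule:
        Gating variant: rule I lets everyone coevolve ``w``, rule II only
        cooperators, rule III only defectors.
    gating_basis:
        Strategy (pre- or post-adoption) used to judge rule II/III
        eligibility within an elementary step.
    w_payoff_basis:
        Whether the winner/loser comparison of the learning-ability update
        sees the payoffs of the post-adoption configuration (default) or
        the pre-adoption payoffs that also fed the Fermi rule.
    comparison_set:
        Neighbours entering the environment average; ``SAME_STRATEGY`` and
        ``DIFFERENT_STRATEGY`` restrict the comparison to neighbours holding
        the same / the opposite strategy as the focal player.
    """

    b: float
    d: float = 0.0
    K: float = 0.1
    w_min: float = 0.1
    w_max: float = 1.0
    rule: RuleVariant = RuleVariant.RULE_I
    gating_basis: GatingBasis = GatingBasis.POST_ADOPTION
    w_payoff_basis: GatingBasis = GatingBasis.POST_ADOPTION
    comparison_set: ComparisonSet = ComparisonSet.ALL_NEIGHBORS

    # Derived weak-PDG payoffs.
    @property
    def T(self) -> float:
        return self.b

    @property
    def R(self) -> float:
        return 1.0

    @property
    def P(self) -> float:
        return 0.0

    @property
    def S(self) -> float:
        return 0.0

    def validate(self) -> "GameParams":
        return validate_params(self)

    def with_b(self, b: float) -> "GameParams":
        return replace(self, b=b)


def validate_params(params: GameParams) -> GameParams:
    """Return ``params`` unchanged iff every invariant holds.

    Raises
    ------
    ParamError
        Naming the violated bound.
    """
    if not (1.0 < params.b <= 2.0):
        raise ParamError(f"b={params.b} violates 1 < b <= 2")
    if not (params.K > 0.0):
        raise ParamError(f"K={params.K} violates K > 0")
    if not (0.0 <= params.d <= 1.0):
        raise ParamError(f"d={params.d} violates 0 <= d <= 1")
    if not (0.0 < params.w_min <= params.w_max <= 1.0):
        raise ParamError(
            f"w bounds (w_min={params.w_min}, w_max={params.w_max}) violate "
            "0 < w_min <= w_max <= 1"
        )
    if not isinstance(params.rule, RuleVariant):
        raise ParamError(f"rule={params.rule!r} is not a RuleVariant")
    if not isinstance(params.gating_basis, GatingBasis):
        raise ParamError(f"gating_basis={params.gating_basis!r} is not a GatingBasis")
    if not isinstance(params.w_payoff_basis, GatingBasis):
        raise ParamError(
            f"w_payoff_basis={params.w_payoff_basis!r} is not a GatingBasis"
        )
    if not isinstance(params.comparison_set, ComparisonSet):
        raise ParamError(
            f"comparison_set={params.comparison_set!r} is not a ComparisonSet"
        )
    return params


@dataclass(frozen=True)
class PlayerState:
    """One site's strategy and learning ability."""

    strategy: Strategy
    w: float


def _vonneumann_neighbors(L: int) -> np.ndarray:
    """Neighbour table of the periodic L x L lattice.

    Order is (up, down, left, right) in 0-based (row, col) coordinates; the
    fixed order makes random neighbour draws reproducible under a seed.
    """
    idx = np.arange(L * L).reshape(L, L)
    up = np.roll(idx, 1, axis=0)
    down = np.roll(idx, -1, axis=0)
    left = np.roll(idx, 1, axis=1)
    right = np.roll(idx, -1, axis=1)
    return np.stack(
        [up.ravel(), down.ravel(), left.ravel(), right.ravel()], axis=1
    ).astype(np.int32)


class World:
    """Population state on a symmetric interaction graph.

    Attributes
    ----------
    strategies:
        Flat ``int8`` array of strategy codes (C = 1, D = 0).
    w:
        Flat ``float64`` array of learning abilities.
    neighbors:
        ``(n_sites, max_degree)`` int32 table; row ``i`` lists the neighbours
        of site ``i`` (entries beyond ``degree[i]`` are -1 padding).
    degree:
        Per-site degree ``k_x``.
    L:
        Side length when the graph is the periodic lattice, else ``None``.
    """

    def __init__(
        self,
        strategies: np.ndarray,
        w: np.ndarray,
        neighbors: np.ndarray,
        degree: np.ndarray,
        L: int | None = None,
    ):
        self.strategies = np.asarray(strategies, dtype=np.int8).ravel()
        self.w = np.asarray(w, dtype=np.float64).ravel()
        self.neighbors = np.asarray(neighbors, dtype=np.int32)
        self.degree = np.asarray(degree, dtype=np.int32).ravel()
        self.L = L
        n = self.strategies.size
        if self.w.size != n or self.neighbors.shape[0] != n or self.degree.size != n:
            raise ValueError("strategies, w, neighbors and degree disagree in size")

    # -- constructors ------------------------------------------------------

    @classmethod
    def lattice(
        cls,
        L: int,
        strategies: np.ndarray | None = None,
        w: np.ndarray | float = 1.0,
    ) -> "World":
        """Periodic L x L lattice with the von Neumann 4-neighbourhood."""
        if not (isinstance(L, (int, np.integer)) and L >= 2):
            raise ValueError(f"L={L!r} invalid: lattice side length must be an integer >= 2")
        n = L * L
        if strategies is None:
            strategies = np.ones(n, dtype=np.int8)
        strategies = np.asarray(strategies, dtype=np.int8).ravel()
        if strategies.size != n:
            raise ValueError(f"strategies has {strategies.size} entries, expected {n}")
        if np.isscalar(w):
            w = np.full(n, float(w))
        neigh = _vonneumann_neighbors(L)
        deg = np.full(n, 4, dtype=np.int32)
        return cls(strategies, w, neigh, deg, L=int(L))

    @classmethod
    def from_graph(
        cls,
        adjacency: Sequence[Iterable[int]],
        strategies: np.ndarray,
        w: np.ndarray | float = 1.0,
    ) -> "World":
        """Build a world on an arbitrary symmetric graph from adjacency lists."""
        adj = [list(a) for a in adjacency]
        n = len(adj)
        deg = np.array([len(a) for a in adj], dtype=np.int32)
        kmax = int(deg.max()) if n else 0
        neigh = np.full((n, kmax), -1, dtype=np.int32)
        for i, row in enumerate(adj):
            neigh[i, : len(row)] = row
        for i, row in enumerate(adj):
            for j in row:
                if i not in adj[j]:
                    raise ValueError(f"adjacency is not symmetric at edge ({i}, {j})")
        return cls(
            strategies, w if not np.isscalar(w) else np.full(n, float(w)), neigh, deg
        )

    # -- accessors ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.strategies.size

    def neighbors_of(self, site: int) -> np.ndarray:
        return self.neighbors[site, : self.degree[site]]

    def flat_index(self, site) -> int:
        """Accept either a flat index or a (row, col) coordinate."""
        if isinstance(site, tuple):
            if self.L is None:
                raise ValueError("(row, col) addressing requires a lattice world")
            r, c = site
            if not (0 <= r < self.L and 0 <= c < self.L):
                raise IndexError(f"site {site} outside {self.L}x{self.L} lattice")
            return int(r) * self.L + int(c)
        site = int(site)
        if not (0 <= site < self.n_sites):
            raise IndexError(f"site {site} out of range [0, {self.n_sites})")
        return site

    def player(self, site) -> PlayerState:
        i = self.flat_index(site)
        return PlayerState(Strategy(int(self.strategies[i])), float(self.w[i]))

    def set_player(self, site, state: PlayerState) -> None:
        i = self.flat_index(site)
        self.strategies[i] = int(state.strategy)
        self.w[i] = state.w

    @property
    def strategies_grid(self) -> np.ndarray:
        if self.L is None:
            raise ValueError("not a lattice world")
        return self.strategies.reshape(self.L, self.L)

    @property
    def w_grid(self) -> np.ndarray:
        if self.L is None:
            raise ValueError("not a lattice world")
        return self.w.reshape(self.L, self.L)

    def copy(self) -> "World":
        return World(
            self.strategies.copy(), self.w.copy(), self.neighbors, self.degree, self.L
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, World):
            return NotImplemented
        return (
            self.L == other.L
            and np.array_equal(self.strategies, other.strategies)
            and np.array_equal(self.w, other.w)
            and np.array_equal(self.neighbors, other.neighbors)
            and np.array_equal(self.degree, other.degree)
        )

    # -- grid text format --------------------------------------------------
    # Header "L=<int>", then L lines of L whitespace-separated "C:<w>"/"D:<w>"
    # tokens with w printed to 6 decimals.

    def to_text(self) -> str:
        if self.L is None:
            raise ValueError("grid text format requires a lattice world")
        lines = [f"L={self.L}"]
        grid_s = self.strategies_grid
        grid_w = self.w_grid
        for r in range(self.L):
            tokens = [
                f"{'C' if grid_s[r, c] == 1 else 'D'}:{grid_w[r, c]:.6f}"
                for c in range(self.L)
            ]
            lines.append(" ".join(tokens))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(
        cls, text: str, w_min: float = 0.1, w_max: float = 1.0
    ) -> "World":
        """Parse the grid text format, validating shape and w bounds.

        Raises ``ValueError`` with the offending line (1-based) and column.
        """
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty grid file")
        m = re.fullmatch(r"L=(\d+)", lines[0].strip())
        if not m:
            raise ValueError(f"line 1: malformed header {lines[0]!r}, expected 'L=<int>'")
        L = int(m.group(1))
        if L < 2:
            raise ValueError(f"line 1: L={L} invalid, must be >= 2")
        if len(lines) - 1 != L:
            raise ValueError(f"expected {L} grid rows, found {len(lines) - 1}")
        strategies = np.empty((L, L), dtype=np.int8)
        w = np.empty((L, L), dtype=np.float64)
        for r, line in enumerate(lines[1:], start=2):
            tokens = line.split()
            if len(tokens) != L:
                raise ValueError(f"line {r}: expected {L} tokens, found {len(tokens)}")
            for c, tok in enumerate(tokens):
                m = re.fullmatch(r"([CD]):([0-9.+-eE]+)", tok)
                if not m:
                    raise ValueError(f"line {r}, column {c + 1}: malformed token {tok!r}")
                strategies[r - 2, c] = int(Strategy.from_token(m.group(1)))
                val = float(m.group(2))
                if not (w_min <= val <= w_max + 1e-12):
                    raise ValueError(
                        f"line {r}, column {c + 1}: w={val} outside [{w_min}, {w_max}]"
                    )
                w[r - 2, c] = val
        return cls.lattice(L, strategies.ravel(), w.ravel())
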