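"""Initial configurations: uniform random, four-bar stripes, and grid files."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Strategy, World

__all__ = ["FourBarSpec", "random_initial", "four_bar_initial", "load_grid"]


def random_initial(L: int, seed: int | None = None, rng: np.random.Generator | None = None) -> World:
    """Uniform random start: each site C or D with probability 1/2, all
    learning abilities at the maximum w = 1."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if not (isinstance(L, (int, np.integer)) and L >= 2):
        raise ValueError(f"L={L!r} invalid: must be an integer >= 2")
    strategies = rng.integers(0, 2, size=L * L).astype(np.int8)
    return World.lattice(int(L), strategies, w=1.0)


@dataclass(frozen=True)
class FourBarSpec:
    """Four vertical bars of alternating strategies with extreme learning
    abilities: the two left bars start at ``left_w`` (conservative players)
    and the two right bars at ``right_w`` (eager imitators).

    Bar widths are ``floor(L/4)`` with the remainder absorbed by the
    rightmost bar.
    """

    bar_strategies: tuple[Strategy, Strategy, Strategy, Strategy] = (
        Strategy.COOPERATE,
        Strategy.DEFECT,
        Strategy.COOPERATE,
        Strategy.DEFECT,
    )
    left_w: float = 0.1
    right_w: float = 1.0

    def validate(self) -> "FourBarSpec":
        if len(self.bar_strategies) != 4 or not all(
            isinstance(s, Strategy) for s in self.bar_strategies
        ):
            raise ValueError("bar_strategies must be exactly four Strategy values")
        for name, w in (("left_w", self.left_w), ("right_w", self.right_w)):
            if not (0.0 < w <= 1.0):
                raise ValueError(f"{name}={w} outside (0, 1]")
        return self


def four_bar_initial(L: int, spec: FourBarSpec | None = None) -> World:
    """Deterministic four-bar start used to watch boundary coevolution
    between players of extreme learning ability."""
    if not (isinstance(L, (int, np.integer)) and L >= 8):
        raise ValueError(f"L={L!r} invalid: four-bar layout requires an integer L >= 8")
    spec = (spec or FourBarSpec()).validate()
    width = L // 4
    # column -> bar index; remainder columns join the rightmost bar
    bar_of_col = np.minimum(np.arange(L) // width, 3)
    strategies = np.empty((L, L), dtype=np.int8)
    w = np.empty((L, L), dtype=np.float64)
    for c in range(L):
        bar = int(bar_of_col[c])
        strategies[:, c] = int(spec.bar_strategies[bar])
        w[:, c] = spec.left_w if bar < 2 else spec.right_w
    return World.lattice(int(L), strategies.ravel(), w.ravel())


def load_grid(path, w_min: float = 0.1, w_max: float = 1.0) -> World:
    """Read a world from the grid text format; round-trips with
    :meth:`World.to_text` and the snapshot writer exactly."""
    text = Path(path).read_text()
    try:
        return World.from_text(text, w_min=w_min, w_max=w_max)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
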