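"""Measurement: cooperation density, stationarity, extinction thresholds,
enduring/expanding decomposition, learning-ability statistics, snapshots."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernel, engine
from .core import GameParams, World, validate_params

__all__ = [
    "Schedule",
    "Trajectory",
    "ScanResult",
    "EndExpDecomposition",
    "cooperation_density",
    "run_to_stationarity",
    "advance",
    "replicate_seed",
    "estimate_extinction_threshold",
    "threshold_from_rows",
    "decompose_end_exp",
    "learning_ability_stats",
    "export_snapshot",
]


def replicate_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed for the replicate addressed by ``key``.

    Uses a seed sequence spawned at a fixed key position, so the seed of a
    given replicate does not depend on how many other replicates exist or
    on execution order.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class Schedule:
    """Simulation schedule.

    ``max_steps`` and ``average_window`` default to the standard protocol
    (5e4 steps, stationary density averaged over the trailing 5e3 steps);
    desk-scale runs pass smaller values explicitly.
    """

    max_steps: int = 50_000
    average_window: int = 5_000
    record_every: int = 10
    early_stop_on_absorption: bool = True

    def validate(self) -> "Schedule":
        if self.max_steps < 1:
            raise ValueError(f"max_steps={self.max_steps} must be >= 1")
        if not (0 < self.average_window < self.max_steps):
            raise ValueError(
                f"average_window={self.average_window} must lie in (0, max_steps)"
            )
        if self.record_every < 1:
            raise ValueError(f"record_every={self.record_every} must be >= 1")
        return self


@dataclass
class Trajectory:
    """Time series of cooperation density and per-strategy mean learning
    ability over MC steps; ``mean_w_C``/``mean_w_D`` are nan where the
    strategy is extinct."""

    t: np.ndarray
    f_C: np.ndarray
    mean_w_C: np.ndarray
    mean_w_D: np.ndarray
    seed: int
    absorbed_step: int | None = None

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "f_C": self.f_C,
                "mean_w_C": self.mean_w_C,
                "mean_w_D": self.mean_w_D,
                "seed": self.seed,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def cooperation_density(world: World) -> float:
    """Fraction of cooperators, f_C = (# cooperators) / N."""
    return float(world.strategies.mean())


def _kernel_seed(seed: int) -> int:
    # numba's legacy seeding wants a non-negative 32-bit integer
    return int(seed) % (2**31)


def run_to_stationarity(
    world: World,
    params: GameParams,
    schedule: Schedule | None = None,
    seed: int = 0,
    engine_kind: str = "fast",
) -> tuple[Trajectory, float]:
    """Advance the world to its stationary state, in place.

    The stationary cooperation density is the mean of f_C over the trailing
    ``schedule.average_window`` MC steps, or the absorbed density when the
    strategy dynamics hit an absorbing state (all-C / all-D) first and early
    stopping is enabled.

    ``engine_kind="fast"`` runs the jitted kernel; ``"reference"`` runs the
    pure-Python elementary updates (tiny worlds only).
    """
    schedule = (schedule or Schedule()).validate()
    validate_params(params)
    if engine_kind == "fast":
        (rec_t, rec_fc, rec_wc, rec_wd, n_rec, absorbed, stat_fc, _noc) = _kernel.run_steps(
            world.strategies,
            world.w,
            world.neighbors,
            world.degree,
            float(params.b),
            float(params.K),
            float(params.d),
            float(params.w_min),
            float(params.w_max),
            params.rule.code,
            params.gating_basis.code,
            params.w_payoff_basis.code,
            params.comparison_set.code,
            int(schedule.max_steps),
            int(schedule.record_every),
            int(schedule.average_window),
            schedule.early_stop_on_absorption,
            _kernel_seed(seed),
        )
        traj = Trajectory(
            t=rec_t[:n_rec].copy(),
            f_C=rec_fc[:n_rec].copy(),
            mean_w_C=rec_wc[:n_rec].copy(),
            mean_w_D=rec_wd[:n_rec].copy(),
            seed=int(seed),
            absorbed_step=int(absorbed) if absorbed >= 0 else None,
        )
        return traj, float(stat_fc)

    if engine_kind != "reference":
        raise ValueError(f"unknown engine_kind {engine_kind!r}")

    rng = np.random.default_rng(seed)
    ts = [0]
    fcs = [cooperation_density(world)]
    stats = learning_ability_stats(world)
    wcs = [stats.get("C", {}).get("mean_w", math.nan)]
    wds = [stats.get("D", {}).get("mean_w", math.nan)]
    absorbed_step = None
    tail: list[float] = []
    tail_start = schedule.max_steps - schedule.average_window
    for t in range(1, schedule.max_steps + 1):
        st = engine.full_mc_step(world, rng, params)
        if t > tail_start:
            tail.append(st.f_C)
        if t % schedule.record_every == 0 or (
            schedule.early_stop_on_absorption and st.f_C in (0.0, 1.0)
        ):
            ts.append(t)
            fcs.append(st.f_C)
            s = learning_ability_stats(world)
            wcs.append(s.get("C", {}).get("mean_w", math.nan))
            wds.append(s.get("D", {}).get("mean_w", math.nan))
        if schedule.early_stop_on_absorption and st.f_C in (0.0, 1.0):
            absorbed_step = t
            break
    if absorbed_step is not None:
        stat_fc = cooperation_density(world)
    elif tail:
        stat_fc = float(np.mean(tail))
    else:
        stat_fc = cooperation_density(world)
    traj = Trajectory(
        t=np.array(ts),
        f_C=np.array(fcs),
        mean_w_C=np.array(wcs),
        mean_w_D=np.array(wds),
        seed=int(seed),
        absorbed_step=absorbed_step,
    )
    return traj, float(stat_fc)


def advance(
    world: World,
    params: GameParams,
    n_steps: int,
    seed: int = 0,
    engine_kind: str = "fast",
) -> None:
    """Advance the world ``n_steps`` full MC steps in place, with no
    recording, early stopping or stationary averaging.

    Used for segmented runs (e.g. snapshot series); even after the strategy
    dynamics absorb, the learning abilities keep evolving.
    """
    validate_params(params)
    if n_steps < 1:
        raise ValueError(f"n_steps={n_steps} must be >= 1")
    if engine_kind == "fast":
        _kernel.run_steps(
            world.strategies,
            world.w,
            world.neighbors,
            world.degree,
            float(params.b),
            float(params.K),
            float(params.d),
            float(params.w_min),
            float(params.w_max),
            params.rule.code,
            params.gating_basis.code,
            params.w_payoff_basis.code,
            params.comparison_set.code,
            int(n_steps),
            int(n_steps),  # record only the last step
            0,
            False,
            _kernel_seed(seed),
        )
    elif engine_kind == "reference":
        rng = np.random.default_rng(seed)
        for _ in range(n_steps):
            engine.full_mc_step(world, rng, params)
    else:
        raise ValueError(f"unknown engine_kind {engine_kind!r}")


@dataclass
class ScanResult:
    """Stationary densities over a b grid and the derived extinction
    threshold estimate.

    ``bracket`` is ``(largest surviving b, smallest extinct b)``; when the
    whole grid is extinct the lower end is the dilemma's lower limit b = 1
    (flagged ``open_at="lower"``), and when the whole grid survives there is
    no estimate (``open_at="upper"``, ``b_C`` is None).  ``b_C`` is the
    bracket midpoint.
    """

    rows: pd.DataFrame
    b_C: float | None
    bracket: tuple[float | None, float | None]
    open_at: str | None
    epsilon: float
    cleanup_log: list[str] = field(default_factory=list)


def _default_random_initializer(L: int, seed: int) -> World:
    from .initializers import random_initial

    return random_initial(L, seed=seed)


def estimate_extinction_threshold(
    params: GameParams,
    b_grid: Sequence[float],
    reps: int = 5,
    seed: int = 0,
    schedule: Schedule | None = None,
    L: int = 100,
    initializer: Callable[[int, int], World] | None = None,
    epsilon: float = 1e-3,
    engine_kind: str = "fast",
    b_lower_limit: float = 1.0,
) -> ScanResult:
    """Estimate the extinction threshold b_C on a temptation grid.

    For each b the scan runs ``reps`` replicates (child seeds spawned
    deterministically from ``seed`` by grid position, so results are
    invariant to execution order).  A grid point is *extinct* when the
    stationary f_C falls below ``epsilon`` in every replicate; b_C is the
    midpoint of the bracket between the largest surviving and the smallest
    extinct grid point.  An isolated survival above an extinct b (replicate
    noise) is resolved by majority over replicates and logged.

    ``params.b`` is a placeholder and is replaced by each grid value.
    """
    b_grid = sorted(float(b) for b in b_grid)
    if not b_grid:
        raise ValueError("b_grid is empty")
    if reps < 1:
        raise ValueError(f"reps={reps} must be >= 1")
    schedule = (schedule or Schedule()).validate()
    init = initializer or _default_random_initializer

    records = []
    for bi, b in enumerate(b_grid):
        p = replace(params, b=b)
        for rep in range(reps):
            child = replicate_seed(seed, bi, rep)
            world = init(L, child)
            traj, stat_fc = run_to_stationarity(
                world, p, schedule, seed=child, engine_kind=engine_kind
            )
            records.append(
                {
                    "rule": p.rule.value,
                    "d": p.d,
                    "b": b,
                    "replicate": rep,
                    "seed": child,
                    "stationary_f_C": stat_fc,
                    "absorbed_step": traj.absorbed_step if traj.absorbed_step is not None else -1,
                }
            )
    rows = pd.DataFrame.from_records(records)
    return threshold_from_rows(rows, b_grid, epsilon, b_lower_limit)


def threshold_from_rows(
    rows: pd.DataFrame,
    b_grid: Sequence[float],
    epsilon: float,
    b_lower_limit: float = 1.0,
) -> ScanResult:
    """Derive the b_C estimate from precomputed scan rows (see
    :func:`estimate_extinction_threshold` for the criterion)."""
    log: list[str] = []
    extinct_all = []
    extinct_majority = []
    for b in b_grid:
        vals = rows.loc[rows["b"] == b, "stationary_f_C"].to_numpy()
        extinct_all.append(bool((vals < epsilon).all()))
        extinct_majority.append(bool((vals < epsilon).sum() * 2 > len(vals)))

    flags = list(extinct_all)
    if not _is_monotone(flags):
        log.append(
            "non-monotone survival pattern under the all-replicates criterion; "
            "resolved by per-b replicate majority"
        )
        flags = list(extinct_majority)
    if not _is_monotone(flags):
        # keep the trailing run of extinct grid points as the extinct side
        log.append(
            "majority criterion still non-monotone; using the trailing extinct run"
        )
        last_surv = max(i for i, f in enumerate(flags) if not f)
        flags = [i > last_surv for i in range(len(flags))]

    n = len(b_grid)
    first_extinct = next((i for i, f in enumerate(flags) if f), None)
    if first_extinct is None:
        return ScanResult(rows, None, (b_grid[-1], None), "upper", epsilon, log)
    if first_extinct == 0:
        lo, hi = b_lower_limit, b_grid[0]
        return ScanResult(rows, (lo + hi) / 2.0, (lo, hi), "lower", epsilon, log)
    lo, hi = b_grid[first_extinct - 1], b_grid[first_extinct]
    return ScanResult(rows, (lo + hi) / 2.0, (lo, hi), None, epsilon, log)


def _is_monotone(flags: list[bool]) -> bool:
    # admissible: all False, all True, or False...False True...True
    seen_true = False
    for f in flags:
        if f:
            seen_true = True
        elif seen_true:
            return False
    return True


@dataclass(frozen=True)
class EndExpDecomposition:
    """Split of a trajectory into the enduring period (cooperation declines
    while clusters form) and the expanding period (clusters grow back) at
    the minimum of the smoothed f_C series."""

    t_min: int
    f_C_min: float
    end_slope: float
    exp_slope: float
    recovered: bool
    smoothed: bool


def decompose_end_exp(
    trajectory: Trajectory, smooth_window: int = 50
) -> EndExpDecomposition:
    """Locate the END→EXP turning point of a cooperation-density trajectory.

    The recorded f_C series is smoothed with a centred moving average of
    ``smooth_window`` samples (unsmoothed, with the ``smoothed`` flag False,
    when the trajectory is shorter than the window); the turning point is
    the earliest minimum of the smoothed series.  Slopes are mean one-step
    differences of the raw recorded series before/after the turning point.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    fc = np.asarray(trajectory.f_C, dtype=float)
    n = len(fc)
    use_smoothing = smooth_window > 1 and n >= smooth_window
    if use_smoothing:
        smoothed = (
            pd.Series(fc).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
        )
    else:
        smoothed = fc
    idx = int(np.argmin(smoothed))  # first occurrence = earliest tie
    end_slope = float(np.mean(np.diff(fc[: idx + 1]))) if idx >= 1 else 0.0
    exp_slope = float(np.mean(np.diff(fc[idx:]))) if idx <= n - 2 else 0.0
    f_min = float(fc[idx])
    return EndExpDecomposition(
        t_min=int(trajectory.t[idx]),
        f_C_min=f_min,
        end_slope=end_slope,
        exp_slope=exp_slope,
        recovered=f_min > 0.0,
        smoothed=use_smoothing,
    )


def learning_ability_stats(world: World) -> dict[str, dict]:
    """Per-strategy learning-ability summary.

    For each strategy present: count, mean/min/max w, and the count and
    mean w of *boundary* players (at least one opposite-strategy
    neighbour).  A strategy with no players is absent from the result.
    """
    n = world.n_sites
    strat = world.strategies
    neigh = world.neighbors
    # padded entries (-1) are replaced by the site itself: never "opposite"
    pad = neigh < 0
    safe = neigh.copy()
    if pad.any():
        safe[pad] = np.nonzero(pad)[0].astype(safe.dtype)
    boundary = (strat[safe] != strat[:, None]).any(axis=1)

    out: dict[str, dict] = {}
    for code, token in ((1, "C"), (0, "D")):
        mask = strat == code
        if not mask.any():
            continue
        wsel = world.w[mask]
        bmask = mask & boundary
        out[token] = {
            "count": int(mask.sum()),
            "mean_w": float(wsel.mean()),
            "min_w": float(wsel.min()),
            "max_w": float(wsel.max()),
            "boundary_count": int(bmask.sum()),
            "boundary_mean_w": float(world.w[bmask].mean()) if bmask.any() else math.nan,
        }
    return out


def export_snapshot(world: World, path_prefix) -> dict[str, Path]:
    """Write the grid text format plus aligned numeric matrices.

    ``<prefix>.grid`` is the round-trippable text grid; ``<prefix>.strategy.txt``
    holds the strategy matrix (C = 1, D = 0) and ``<prefix>.w.txt`` the
    learning-ability matrix, index-aligned, ready for heat-map rendering.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "grid": prefix.with_name(prefix.name + ".grid"),
        "strategy": prefix.with_name(prefix.name + ".strategy.txt"),
        "w": prefix.with_name(prefix.name + ".w.txt"),
    }
    paths["grid"].write_text(world.to_text())
    np.savetxt(paths["strategy"], world.strategies_grid, fmt="%d")
    np.savetxt(paths["w"], world.w_grid, fmt="%.6f")
    return paths
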