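"""Summary statistics of SH-game populations and parameter sweeps.

Covers the honest-player rate, the row-scan granularity measure of
cluster structure, punishment-probability / severity sweeps with
transition-interval extraction, critical-probability scans, and the
four-color strategy-transition visualization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import RunConfig, run_simulation
from .init_states import GridState

__all__ = [
    "h_rate",
    "granularity",
    "SweepResult",
    "sweep",
    "TransitionInterval",
    "NoDominationError",
    "transition_interval",
    "refine_interval_bounds",
    "critical_probability",
    "ColorGrid",
    "transition_color_grid",
]


def h_rate(state: GridState) -> float:
    """Fraction of honest players in the population."""
    return state.h_rate()


def granularity(state: GridState) -> float:
    """Row-scan cluster granularity in [0, 1].

    For each lattice row, count the positions where adjacent cells (no
    wrap-around) hold different strategies; granularity is one minus the
    row-averaged count normalized by ``cols - 1``. A random 50/50
    mixture scores about 0.5, a few large clusters score near 1, and a
    perfect checkerboard scores 0.
    """
    if state.cols < 2:
        raise ValueError("granularity needs at least 2 columns")
    changes = state.cells[:, 1:] != state.cells[:, :-1]
    return float(1.0 - changes.sum(axis=1).mean() / (state.cols - 1))


# ---------------------------------------------------------------------------
# Sweeps and transitions
# ---------------------------------------------------------------------------


def _apply_param(config: RunConfig, param: str, value: float) -> RunConfig:
    if param == "p":
        return config.replace(
            params=config.params.replace(p_hd=value, p_dd=value)
        )
    if param == "s":
        return config.replace(params=config.params.replace(s=value))
    raise ValueError(f"swept parameter must be 'p' or 's', got {param!r}")


def _child_seed(master: int, *key: int) -> int:
    seq = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


def _final_rates(
    base_config: RunConfig, param: str, value: float, n_runs: int
) -> np.ndarray:
    """Final honest rates of ``n_runs`` independent seeded runs at one value.

    Child seeds derive from the base config's seed and the (scaled)
    parameter value, so enlarging ``n_runs`` never perturbs the streams
    of earlier runs.
    """
    config = _apply_param(base_config, param, value)
    key_value = int(round(value * 10**6))
    rates = np.empty(n_runs)
    for run_idx in range(n_runs):
        run_cfg = config.replace(
            seed=_child_seed(base_config.seed, key_value, run_idx),
            snapshot_rounds=(),
        )
        rates[run_idx] = run_simulation(run_cfg).h_rate_by_round[-1]
    return rates


@dataclass
class SweepResult:
    """Distribution of final honest rates across a parameter grid."""

    param: str
    grid: np.ndarray
    final_rates: np.ndarray  # shape (len(grid), n_runs)
    config: RunConfig

    @property
    def n_runs(self) -> int:
        return self.final_rates.shape[1]

    @property
    def means(self) -> np.ndarray:
        return self.final_rates.mean(axis=1)

    def to_dict(self) -> dict:
        return {
            "param": self.param,
            "grid": [float(v) for v in self.grid],
            "mean_final_h_rate": [float(v) for v in self.means],
            "n_runs": self.n_runs,
            "rounds": self.config.rounds,
            "rows": self.config.rows,
            "cols": self.config.cols,
            "seed": self.config.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def rates_to_csv(self, path) -> None:
        n_vals, n_runs = self.final_rates.shape
        frame = pd.DataFrame(
            {
                "param_value": np.repeat(self.grid, n_runs),
                "run_index": np.tile(np.arange(n_runs), n_vals),
                "final_h_rate": self.final_rates.ravel(),
            }
        )
        frame.to_csv(path, index=False)


def sweep(
    base_config: RunConfig,
    param: str,
    grid: Sequence[float],
    n_runs: int,
) -> SweepResult:
    """Final honest rates over a strictly increasing parameter grid.

    For each grid value, ``n_runs`` independent seeded simulations run
    for ``base_config.rounds`` rounds and the honest rate at the final
    round is recorded. Fully deterministic given the config seed.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    finals = np.empty((grid.size, n_runs))
    for idx, value in enumerate(grid):
        finals[idx] = _final_rates(base_config, param, value, n_runs)
    return SweepResult(param=param, grid=grid, final_rates=finals, config=base_config)


class NoDominationError(RuntimeError):
    """No grid value satisfies the honest-domination criterion."""


def refine_interval_bounds(
    base_config: RunConfig,
    lower: float,
    upper: float,
    n_runs: int,
    step: float = 0.005,
    eps_low: float = 0.01,
):
    """Tighten coarse transition-interval bounds at ``step`` resolution.

    Probes up to three ``step``-spaced values inside each bound: the
    upper bound moves down to the smallest probed value with full
    honest fixation, the lower bound up to the largest probed value
    whose mean final rate stays at most ``eps_low``. Returns the
    refined ``(lower, upper)``.
    """
    for value in (
        round(upper - 3 * step, 6),
        round(upper - 2 * step, 6),
        round(upper - step, 6),
    ):
        if value <= lower:
            continue
        if np.all(_final_rates(base_config, "p", value, n_runs) == 1.0):
            upper = value
            break
    for value in (
        round(lower + 3 * step, 6),
        round(lower + 2 * step, 6),
        round(lower + step, 6),
    ):
        if value >= upper:
            continue
        if np.mean(_final_rates(base_config, "p", value, n_runs)) <= eps_low:
            lower = value
            break
    return lower, upper


@dataclass
class TransitionInterval:
    """Bounds of the dishonest-to-honest transition on a sweep grid.

    ``lower`` is the last grid value with mean final honest rate at most
    ``eps_low`` (``-inf`` if the sweep never shows dishonest
    domination); ``upper`` is the first value where the domination
    criterion holds.
    """

    lower: float
    upper: float
    eps_low: float
    domination: str

    @property
    def midpoint(self) -> float:
        if np.isneginf(self.lower):
            return self.upper
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return {
            "lower": float(self.lower),
            "upper": float(self.upper),
            "eps_low": self.eps_low,
            "domination": self.domination,
        }


def transition_interval(
    sweep_result: SweepResult,
    eps_low: float = 0.01,
    domination: str = "full_fixation",
    eps_high: float = 0.01,
) -> TransitionInterval:
    """Extract the transition interval from a sweep.

    The upper bound requires honest domination: with the default
    ``full_fixation`` criterion every run's final rate must equal 1.0;
    the ``mean_ge_threshold`` alternative requires the mean final rate
    to reach ``1 - eps_high``.
    """
    if domination not in ("full_fixation", "mean_ge_threshold"):
        raise ValueError(f"unknown domination criterion {domination!r}")
    means = sweep_result.means
    if domination == "full_fixation":
        dominated = np.all(sweep_result.final_rates == 1.0, axis=1)
    else:
        dominated = means >= 1.0 - eps_high
    if not dominated.any():
        raise NoDominationError(
            "honest domination never holds on the sweep grid"
        )
    upper_idx = int(np.argmax(dominated))
    low_mask = means[:upper_idx] <= eps_low
    if low_mask.any():
        lower = float(sweep_result.grid[:upper_idx][low_mask][-1])
    else:
        lower = float("-inf")
    crossing = np.nonzero(means > eps_low)[0]
    if crossing.size:
        tail = means[crossing[0] :]
        if np.any(np.diff(tail) < -0.2):
            warnings.warn(
                "sweep means drop by more than 0.2 after the first crossing; "
                "the transition is not monotone",
                stacklevel=2,
            )
    return TransitionInterval(
        lower=lower,
        upper=float(sweep_result.grid[upper_idx]),
        eps_low=eps_low,
        domination=domination,
    )


def critical_probability(
    base_config: RunConfig,
    p_lo: float,
    p_hi: float,
    step: float,
    n_runs: int,
    final_rates=None,
) -> float:
    """Smallest punishment probability with full honest fixation.

    Scans ``p`` upward from ``p_lo`` to ``p_hi`` in increments of
    ``step`` and returns the smallest value at which *every* one of the
    ``n_runs`` replicate runs fixates to all-honest by the final round,
    refined once at resolution ``step / 5`` below the first hit.

    ``final_rates`` may inject an alternative ``(config, param, value,
    n_runs) -> rates`` callable (used for testing the scan logic).
    """
    if not p_lo < p_hi:
        raise ValueError("p_lo must be < p_hi")
    if step <= 0:
        raise ValueError("step must be > 0")
    rates_fn = _final_rates if final_rates is None else final_rates

    def dominated(value: float) -> bool:
        return bool(np.all(rates_fn(base_config, "p", value, n_runs) == 1.0))

    grid = np.arange(p_lo, p_hi + step / 2, step)
    hit = None
    for value in grid:
        if dominated(value):
            hit = float(value)
            break
    if hit is None:
        raise NoDominationError(
            f"no full honest fixation for p in [{p_lo}, {p_hi}] at step {step}"
        )
    fine = np.arange(max(p_lo, hit - step), hit, step / 5.0)
    for value in fine:
        if value < hit and dominated(value):
            return float(value)
    return hit


# ---------------------------------------------------------------------------
# Transition visualization
# ---------------------------------------------------------------------------

# label codes: (was, is) -> color
BLUE, RED, GREEN, YELLOW = 0, 1, 2, 3
COLOR_NAMES = ("blue", "red", "green", "yellow")
_PALETTE = np.array(
    [
        [40, 70, 220],  # blue: is honest / was honest
        [200, 30, 30],  # red: is dishonest / was dishonest
        [40, 170, 60],  # green: is honest / was dishonest
        [235, 205, 30],  # yellow: is dishonest / was honest
    ],
    dtype=np.uint8,
)


@dataclass
class ColorGrid:
    """Per-cell transition labels (blue/red/green/yellow as codes 0-3)."""

    labels: np.ndarray

    def names(self) -> np.ndarray:
        return np.array(COLOR_NAMES)[self.labels]

    def to_rgb(self) -> np.ndarray:
        return _PALETTE[self.labels]

    def save_png(self, path, scale: int = 4) -> None:
        from PIL import Image

        rgb = self.to_rgb()
        image = Image.fromarray(rgb, mode="RGB")
        if scale > 1:
            image = image.resize(
                (rgb.shape[1] * scale, rgb.shape[0] * scale), Image.NEAREST
            )
        image.save(path)


def transition_color_grid(prev: GridState, curr: GridState) -> ColorGrid:
    """Color-code one round's strategy transitions.

    Blue: honest stayed honest. Red: dishonest stayed dishonest.
    Green: dishonest turned honest. Yellow: honest turned dishonest.
    """
    if prev.shape != curr.shape:
        raise ValueError("states must share a shape")
    labels = np.empty(prev.shape, dtype=np.uint8)
    labels[prev.cells & curr.cells] = BLUE
    labels[~prev.cells & ~curr.cells] = RED
    labels[~prev.cells & curr.cells] = GREEN
    labels[prev.cells & ~curr.cells] = YELLOW
    return ColorGrid(labels)
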