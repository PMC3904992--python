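"""Initial strategy configurations and the plain-text grid format.

States are square or rectangular boolean matrices (True = honest). The
text serialization is one character per cell, ``H``/``D``, one lattice
row per line, no header — trivially diffable and round-trippable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .game_core import Strategy

__all__ = [
    "GridState",
    "TargetNotReachedError",
    "random_state",
    "single_dissident_state",
    "evolved_cluster_state",
]


class TargetNotReachedError(RuntimeError):
    """The evolving population never hit the requested honest rate."""


@dataclass
class GridState:
    """Per-cell strategies on a rows x cols lattice (True = honest)."""

    cells: np.ndarray

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.ndim != 2:
            raise ValueError("state must be a 2-D cell matrix")

    @property
    def shape(self):
        return self.cells.shape

    @property
    def rows(self) -> int:
        return self.cells.shape[0]

    @property
    def cols(self) -> int:
        return self.cells.shape[1]

    @property
    def n(self) -> int:
        return self.cells.size

    def h_count(self) -> int:
        return int(self.cells.sum())

    def h_rate(self) -> float:
        return float(self.cells.mean())

    def copy(self) -> "GridState":
        return GridState(self.cells.copy())

    def to_text(self) -> str:
        lookup = np.array(["D", "H"])
        return "\n".join("".join(row) for row in lookup[self.cells.astype(int)])

    @classmethod
    def from_text(cls, text: str) -> "GridState":
        lines = [line for line in text.strip().splitlines() if line]
        if not lines:
            raise ValueError("empty grid text")
        widths = {len(line) for line in lines}
        if len(widths) != 1:
            raise ValueError("ragged grid rows")
        chars = np.array([list(line) for line in lines])
        bad = ~np.isin(chars, ["H", "D"])
        if bad.any():
            raise ValueError(f"invalid cell characters: {set(chars[bad])}")
        return cls(chars == "H")

    def save(self, path) -> None:
        Path(path).write_text(self.to_text() + "\n")

    @classmethod
    def load(cls, path) -> "GridState":
        return cls.from_text(Path(path).read_text())


def random_state(rows: int, cols: int, h_fraction: float, seed: int) -> GridState:
    """Uniform random mixture with an *exact* honest count.

    Places exactly ``round(h_fraction * rows * cols)`` honest cells
    uniformly at random without replacement, so "50% honest" is literal
    rather than a Bernoulli expectation.
    """
    if not 0.0 <= h_fraction <= 1.0:
        raise ValueError("h_fraction must lie in [0, 1]")
    n = rows * cols
    k = int(round(h_fraction * n))
    rng = np.random.default_rng(seed)
    cells = np.zeros(n, dtype=bool)
    cells[rng.choice(n, size=k, replace=False)] = True
    return GridState(cells.reshape(rows, cols))


def single_dissident_state(rows: int, cols: int, center: Strategy) -> GridState:
    """Uniform field of one strategy with a single dissident in the middle."""
    center = Strategy(center)
    cells = np.full((rows, cols), center == Strategy.D, dtype=bool)
    cells[rows // 2, cols // 2] = center == Strategy.H
    return GridState(cells)


def evolved_cluster_state(
    run_config,
    target_h_rate: float,
    tol: float = 0.02,
    max_rounds: int = 1000,
    seed: int = 0,
    min_rounds: int = 0,
) -> GridState:
    """Generate a naturally clustered state by letting the population evolve.

    Starting from a 50% random mixture, the simulation configured by
    ``run_config`` (its punishment parameters decide where the honest
    rate heads) runs until the honest rate first falls within ``tol`` of
    ``target_h_rate``; that state is returned. Because clusters emerge
    within the first rounds of the dynamics, the captured state is
    spatially clustered rather than well mixed. ``min_rounds`` can delay
    capture past the initial transient.

    Raises
    ------
    TargetNotReachedError
        If no state within tolerance occurs in ``max_rounds`` rounds
        (the caller should adjust the punishment parameters).
    """
    from .engine import Simulation  # deferred: engine imports this module

    if not 0.0 < target_h_rate < 1.0:
        raise ValueError("target_h_rate must lie strictly between 0 and 1")
    from dataclasses import replace as _replace

    config = _replace(
        run_config,
        seed=seed,
        init=type(run_config.init)(kind="random", h_fraction=0.5),
    )
    sim = Simulation(config)
    # the rate is checked after each round, never on the unevolved start
    for round_no in range(1, max_rounds + 1):
        rate = sim.step()
        if round_no >= min_rounds and abs(rate - target_h_rate) <= tol:
            return sim.state.copy()
        if rate in (0.0, 1.0):
            break
    raise TargetNotReachedError(
        f"honest rate never reached {target_h_rate}+-{tol} within "
        f"{max_rounds} rounds (seed {seed})"
    )
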