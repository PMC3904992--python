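"""Round execution and synchronous imitation dynamics.

A round has two phases. First every adjacent pair plays the SH game
exactly once (one shared random realization per unordered pair) and each
player's round payoff is the sum over her interactions. Then all players
revise strategies *synchronously* from the same payoff snapshot, under
one of three imitation rules:

``best``
    Copy the strategy of the highest-payoff player among self and
    neighbors; keep your own strategy when you attain the maximum
    yourself, otherwise break ties uniformly among the maximal
    neighbors.
``best_myopic``
    With probability ``q`` apply the ``best`` decision, otherwise copy a
    uniformly random neighbor's current strategy.
``best_fermi``
    Adopt the best neighbor's strategy with the logistic probability
    ``1 / (1 + exp((pi_self - pi_best) / K))``, else keep your own.

Two equivalent backends implement the dynamics: a roll-based kernel for
periodic lattices (fast, used by :func:`run_simulation` whenever the
topology is a lattice) and an edge-list backend for arbitrary graphs.
They share the payoff rule (:func:`~shgame.game_core.pair_payoffs_from_uniforms`)
but consume random numbers in different orders, so trajectories match in
distribution, not draw for draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .game_core import Params, Strategy, pair_payoffs_from_uniforms, validate_params
from .init_states import GridState, random_state, single_dissident_state
from .topology import (
    NeighborGraph,
    lattice_neighbors,
    lattice_offsets,
    scale_free_neighbors,
    well_mixed_neighbors,
)

__all__ = [
    "TopologySpec",
    "InitSpec",
    "RunConfig",
    "Timeseries",
    "Simulation",
    "build_graph",
    "build_initial_state",
    "play_round",
    "imitate_best",
    "imitate_best_myopic",
    "imitate_best_fermi",
    "run_simulation",
]

UPDATE_RULES = ("best", "best_myopic", "best_fermi")
TOPOLOGY_KINDS = ("moore", "von_neumann", "well_mixed", "scale_free")


@dataclass(frozen=True)
class TopologySpec:
    kind: str = "moore"
    radius: int = 1
    m: int = 4  # scale-free attachment parameter


@dataclass(frozen=True)
class InitSpec:
    kind: str = "random"  # random | single_dissident | grid_file
    h_fraction: float = 0.5
    center: str = "H"
    path: Optional[str] = None


@dataclass(frozen=True)
class RunConfig:
    """Complete, reproducible description of one simulation run."""

    params: Params = field(default_factory=Params)
    rows: int = 100
    cols: int = 100
    topology: TopologySpec = field(default_factory=TopologySpec)
    update_rule: str = "best"
    q: float = 0.9
    K: float = 0.1
    rounds: int = 500
    init: InitSpec = field(default_factory=InitSpec)
    seed: int = 0
    snapshot_rounds: Tuple[int, ...] = ()
    early_stop: bool = True
    include_self: bool = True  # whether own payoff competes in `best`

    @property
    def n(self) -> int:
        return self.rows * self.cols

    def validate(self) -> "RunConfig":
        validate_params(self.params)
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if not self.K > 0:
            raise ValueError("K must be > 0")
        if self.update_rule not in UPDATE_RULES:
            raise ValueError(f"unknown update rule {self.update_rule!r}")
        if self.topology.kind not in TOPOLOGY_KINDS:
            raise ValueError(f"unknown topology kind {self.topology.kind!r}")
        if self.init.kind not in ("random", "single_dissident", "grid_file"):
            raise ValueError(f"unknown init kind {self.init.kind!r}")
        return self

    def replace(self, **changes) -> "RunConfig":
        return replace(self, **changes)


@dataclass
class Timeseries:
    """Honest-rate trajectory of one run (index 0 = initial state)."""

    h_rate_by_round: np.ndarray
    snapshots: Dict[int, GridState]
    config: RunConfig
    seed: int
    final_state: GridState

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.arange(self.h_rate_by_round.size),
                "h_rate": self.h_rate_by_round,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _derive_seed(seed_sequence: np.random.SeedSequence) -> int:
    """Collapse a SeedSequence into a small non-negative int seed."""
    return int(seed_sequence.generate_state(1)[0] & 0x7FFFFFFF)


def build_graph(config: RunConfig) -> NeighborGraph:
    topo = config.topology
    if topo.kind in ("moore", "von_neumann"):
        return lattice_neighbors(config.rows, config.cols, topo.kind, topo.radius)
    if topo.kind == "well_mixed":
        return well_mixed_neighbors(config.n)
    if topo.kind == "scale_free":
        graph = scale_free_neighbors(config.n, topo.m, seed=config.seed)
        graph.shape = (config.rows, config.cols)
        return graph
    raise ValueError(f"unknown topology kind {topo.kind!r}")


def build_initial_state(config: RunConfig, seed: Optional[int] = None) -> GridState:
    init = config.init
    if init.kind == "random":
        state_seed = config.seed if seed is None else seed
        return random_state(config.rows, config.cols, init.h_fraction, state_seed)
    if init.kind == "single_dissident":
        return single_dissident_state(
            config.rows, config.cols, Strategy.from_char(init.center)
        )
    if init.kind == "grid_file":
        state = GridState.load(init.path)
        if state.shape != (config.rows, config.cols):
            raise ValueError(
                f"grid file shape {state.shape} does not match configured "
                f"{(config.rows, config.cols)}"
            )
        return state
    raise ValueError(f"unknown init kind {init.kind!r}")


# ---------------------------------------------------------------------------
# Generic (edge-list) backend: works on any NeighborGraph.
# ---------------------------------------------------------------------------


def play_round(
    state: GridState, graph: NeighborGraph, params: Params, rng: np.random.Generator
) -> np.ndarray:
    """One interaction round; returns the per-player payoff vector.

    Every unordered adjacent pair plays exactly once; both players see
    the same realization. A player's entry is the sum over her incident
    pairs.
    """
    if state.n != graph.n:
        raise ValueError(f"state size {state.n} does not match graph n={graph.n}")
    honest = state.cells.ravel()
    ei, ej = graph.edge_arrays()
    u_i, u_j, u_coin = rng.random((3, ei.size))
    pay_i, pay_j = pair_payoffs_from_uniforms(
        honest[ei], honest[ej], u_i, u_j, u_coin, params
    )
    return np.bincount(ei, pay_i, graph.n) + np.bincount(ej, pay_j, graph.n)


def _neighbor_best_stats(payoffs, honest, graph):
    """Per node: max neighbor payoff, #maximal neighbors, #honest maximal."""
    nbr_pay = payoffs[graph.indices]
    starts = graph.indptr[:-1]
    nbr_max = np.maximum.reduceat(nbr_pay, starts)
    attains = nbr_pay == np.repeat(nbr_max, graph.degrees())
    count_max = np.add.reduceat(attains, starts)
    count_max_h = np.add.reduceat(attains & honest[graph.indices], starts)
    return nbr_max, count_max, count_max_h


def _best_neighbor_strategy(payoffs, honest, graph, rng):
    """Tie-broken strategy of each node's best neighbor (uniform over ties).

    A uniform choice among maximal neighbors adopts H exactly with
    probability (#honest maximal)/(#maximal), so a single Bernoulli draw
    per node realizes it.
    """
    nbr_max, count_max, count_max_h = _neighbor_best_stats(payoffs, honest, graph)
    adopt_h = rng.random(graph.n) < count_max_h / count_max
    return nbr_max, adopt_h


def imitate_best(
    state: GridState,
    payoffs: np.ndarray,
    graph: NeighborGraph,
    rng: np.random.Generator,
    include_self: bool = True,
) -> GridState:
    """Synchronous best-imitation update."""
    honest = state.cells.ravel()
    nbr_max, adopt_h = _best_neighbor_strategy(payoffs, honest, graph, rng)
    if include_self:
        new = np.where(payoffs >= nbr_max, honest, adopt_h)
    else:
        new = adopt_h
    return GridState(new.reshape(state.shape))


def imitate_best_myopic(
    state: GridState,
    payoffs: np.ndarray,
    graph: NeighborGraph,
    q: float,
    rng: np.random.Generator,
    include_self: bool = True,
) -> GridState:
    """Best imitation with probability ``q``, else copy a random neighbor."""
    honest = state.cells.ravel()
    nbr_max, adopt_h = _best_neighbor_strategy(payoffs, honest, graph, rng)
    if include_self:
        best = np.where(payoffs >= nbr_max, honest, adopt_h)
    else:
        best = adopt_h
    frac_h = (
        np.add.reduceat(honest[graph.indices], graph.indptr[:-1]) / graph.degrees()
    )
    copy_random = rng.random(graph.n) < frac_h
    use_best = rng.random(graph.n) < q
    return GridState(np.where(use_best, best, copy_random).reshape(state.shape))


def imitate_best_fermi(
    state: GridState,
    payoffs: np.ndarray,
    graph: NeighborGraph,
    K: float,
    rng: np.random.Generator,
) -> GridState:
    """Adopt the best neighbor's strategy with a Fermi (logistic) probability.

    The switch probability is ``1/(1 + exp((pi_self - pi_best)/K))``
    where ``pi_best`` is the maximum payoff among neighbors (self
    excluded); otherwise the player keeps her strategy.
    """
    honest = state.cells.ravel()
    nbr_max, adopt_h = _best_neighbor_strategy(payoffs, honest, graph, rng)
    z = np.clip((payoffs - nbr_max) / K, -700.0, 700.0)
    p_switch = 1.0 / (1.0 + np.exp(z))
    switch = rng.random(graph.n) < p_switch
    return GridState(np.where(switch, adopt_h, honest).reshape(state.shape))


# ---------------------------------------------------------------------------
# Lattice backend: fused kernels for periodic lattices. The numba-compiled
# kernels consume exactly the same uniform stream as the numpy fallback, so
# both produce bit-identical trajectories for a given seed.
# ---------------------------------------------------------------------------

try:
    from . import _kernels as _nb

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _nb = None
    HAVE_NUMBA = False


class _LatticeKernel:
    """Vectorized SH dynamics on a periodic lattice."""

    def __init__(
        self, rows: int, cols: int, scheme: str, radius: int, use_numba: bool = True
    ):
        if rows < 2 * radius + 1 or cols < 2 * radius + 1:
            raise ValueError(
                f"lattice {rows}x{cols} too small for {scheme} radius {radius}"
            )
        offsets = lattice_offsets(scheme, radius)
        # Half of the offsets enumerate each unordered pair exactly once.
        self.half = [(dr, dc) for dr, dc in offsets if dr > 0 or (dr == 0 and dc > 0)]
        self.full = offsets
        self.degree = len(offsets)
        self._half_arr = np.array(self.half, dtype=np.int64).reshape(-1, 2)
        self._full_arr = np.array(self.full, dtype=np.int64).reshape(-1, 2)
        self.use_numba = use_numba and HAVE_NUMBA

    def payoffs(self, honest: np.ndarray, params: Params, rng) -> np.ndarray:
        uniforms = rng.random((len(self.half), 3) + honest.shape)
        if self.use_numba:
            return _nb.payoffs(
                honest,
                uniforms,
                self._half_arr[:, 0].copy(),
                self._half_arr[:, 1].copy(),
                params.R,
                params.b,
                params.s,
                params.p_hd,
                params.p_dd,
            )
        pay = np.zeros(honest.shape, dtype=float)
        for k, (dr, dc) in enumerate(self.half):
            partner = np.roll(honest, (-dr, -dc), axis=(0, 1))
            pay_i, pay_j = pair_payoffs_from_uniforms(
                honest, partner, uniforms[k, 0], uniforms[k, 1], uniforms[k, 2], params
            )
            pay += pay_i
            pay += np.roll(pay_j, (dr, dc), axis=(0, 1))
        return pay

    def _neighbor_best_stats(self, pay, honest):
        nbr_max = np.full(pay.shape, -np.inf)
        for dr, dc in self.full:
            np.maximum(nbr_max, np.roll(pay, (dr, dc), axis=(0, 1)), out=nbr_max)
        count_max = np.zeros(pay.shape)
        count_max_h = np.zeros(pay.shape)
        for dr, dc in self.full:
            attains = np.roll(pay, (dr, dc), axis=(0, 1)) == nbr_max
            count_max += attains
            count_max_h += attains & np.roll(honest, (dr, dc), axis=(0, 1))
        return nbr_max, count_max, count_max_h

    def _best_neighbor_strategy(self, pay, honest, u_tie):
        nbr_max, count_max, count_max_h = self._neighbor_best_stats(pay, honest)
        adopt_h = u_tie < count_max_h / count_max
        return nbr_max, adopt_h

    def update_best(self, honest, pay, rng, include_self=True):
        u_tie = rng.random(pay.shape)
        if self.use_numba:
            return _nb.update_best(
                honest, pay, u_tie, self._full_arr[:, 0].copy(),
                self._full_arr[:, 1].copy(), include_self,
            )
        nbr_max, adopt_h = self._best_neighbor_strategy(pay, honest, u_tie)
        if include_self:
            return np.where(pay >= nbr_max, honest, adopt_h)
        return adopt_h

    def update_myopic(self, honest, pay, q, rng, include_self=True):
        best = self.update_best(honest, pay, rng, include_self)
        u_copy = rng.random(pay.shape)
        u_gate = rng.random(pay.shape)
        if self.use_numba:
            return _nb.update_myopic(
                honest, best, u_copy, u_gate, q, self._full_arr[:, 0].copy(),
                self._full_arr[:, 1].copy(),
            )
        nbr_h = np.zeros(pay.shape)
        for dr, dc in self.full:
            nbr_h += np.roll(honest, (dr, dc), axis=(0, 1))
        copy_random = u_copy < nbr_h / self.degree
        use_best = u_gate < q
        return np.where(use_best, best, copy_random)

    def update_fermi(self, honest, pay, K, rng):
        u_tie = rng.random(pay.shape)
        u_switch = rng.random(pay.shape)
        if self.use_numba:
            return _nb.update_fermi(
                honest, pay, u_tie, u_switch, K, self._full_arr[:, 0].copy(),
                self._full_arr[:, 1].copy(),
            )
        nbr_max, adopt_h = self._best_neighbor_strategy(pay, honest, u_tie)
        z = np.clip((pay - nbr_max) / K, -700.0, 700.0)
        switch = u_switch < 1.0 / (1.0 + np.exp(z))
        return np.where(switch, adopt_h, honest)


class Simulation:
    """Stateful simulation advancing one synchronous round per :meth:`step`.

    Uses the roll-based lattice kernel for Moore / von Neumann
    topologies and the edge-list backend otherwise.
    """

    def __init__(self, config: RunConfig, state: Optional[GridState] = None):
        config.validate()
        self.config = config
        master = np.random.SeedSequence(config.seed)
        init_seq, dyn_seq = master.spawn(2)
        self.rng = np.random.default_rng(dyn_seq)
        if state is not None:
            if state.shape != (config.rows, config.cols):
                raise ValueError("provided state shape does not match config")
            self.state = state.copy()
        else:
            self.state = build_initial_state(config, seed=_derive_seed(init_seq))
        self._kernel: Optional[_LatticeKernel] = None
        self._graph: Optional[NeighborGraph] = None
        if config.topology.kind in ("moore", "von_neumann"):
            self._kernel = _LatticeKernel(
                config.rows, config.cols, config.topology.kind, config.topology.radius
            )
        else:
            self._graph = build_graph(config)
        self.round = 0

    @property
    def graph(self) -> NeighborGraph:
        if self._graph is None:
            self._graph = build_graph(self.config)
        return self._graph

    def step(self) -> float:
        """Play one round and apply the configured update; returns h rate."""
        cfg = self.config
        if self._kernel is not None:
            kernel = self._kernel
            honest = self.state.cells
            pay = kernel.payoffs(honest, cfg.params, self.rng)
            if cfg.update_rule == "best":
                new = kernel.update_best(honest, pay, self.rng, cfg.include_self)
            elif cfg.update_rule == "best_myopic":
                new = kernel.update_myopic(
                    honest, pay, cfg.q, self.rng, cfg.include_self
                )
            else:
                new = kernel.update_fermi(honest, pay, cfg.K, self.rng)
            self.state = GridState(new)
        else:
            pay = play_round(self.state, self.graph, cfg.params, self.rng)
            if cfg.update_rule == "best":
                self.state = imitate_best(
                    self.state, pay, self.graph, self.rng, cfg.include_self
                )
            elif cfg.update_rule == "best_myopic":
                self.state = imitate_best_myopic(
                    self.state, pay, self.graph, cfg.q, self.rng, cfg.include_self
                )
            else:
                self.state = imitate_best_fermi(
                    self.state, pay, self.graph, cfg.K, self.rng
                )
        self.round += 1
        return self.state.h_rate()


def run_simulation(config: RunConfig) -> Timeseries:
    """Run a full configured simulation and record the honest-rate series.

    The trajectory always has ``rounds + 1`` entries. Homogeneous states
    are absorbing under every rule, so once the population fixates the
    remaining entries are filled with the constant rate without further
    sampling (disable with ``early_stop=False``).
    """
    sim = Simulation(config)
    rounds = config.rounds
    rates = np.empty(rounds + 1)
    rates[0] = sim.state.h_rate()
    snap_rounds = set(config.snapshot_rounds)
    snapshots: Dict[int, GridState] = {}
    if 0 in snap_rounds:
        snapshots[0] = sim.state.copy()
    stopped_at = None
    for t in range(1, rounds + 1):
        rate = sim.step()
        rates[t] = rate
        if t in snap_rounds:
            snapshots[t] = sim.state.copy()
        if config.early_stop and rate in (0.0, 1.0):
            rates[t + 1 :] = rate
            stopped_at = t
            break
    if stopped_at is not None:
        for t in snap_rounds:
            if t > stopped_at:
                snapshots[t] = sim.state.copy()
    return Timeseries(
        h_rate_by_round=rates,
        snapshots=snapshots,
        config=config,
        seed=config.seed,
        final_state=sim.state,
    )
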