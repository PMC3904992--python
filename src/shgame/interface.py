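"""Config-file loading and validation (YAML or JSON).

A config file holds a serialized :class:`~shgame.engine.RunConfig` plus
an optional ``experiment`` block for sweeps. Every field has a default;
unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

from .engine import InitSpec, RunConfig, TopologySpec
from .game_core import Params

__all__ = ["ExperimentSpec", "ConfigError", "load_config", "parse_grid"]


class ConfigError(ValueError):
    """Invalid or unparseable configuration."""


@dataclass(frozen=True)
class ExperimentSpec:
    """Sweep settings attached to a run configuration."""

    param: str = "p"
    grid: Tuple[float, ...] = ()
    n_runs: int = 100
    out_dir: str = "out"


def parse_grid(spec) -> Tuple[float, ...]:
    """Parse a grid given as a list or a ``start:stop:step`` string."""
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ConfigError(f"grid string must be start:stop:step, got {spec!r}")
        start, stop, step = (float(x) for x in parts)
        if step <= 0:
            raise ConfigError("grid step must be > 0")
        values = np.arange(start, stop + step / 2.0, step)
        return tuple(round(float(v), 12) for v in values)
    return tuple(float(v) for v in spec)


def _check_keys(mapping: dict, allowed, context: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")


def _build_params(raw: dict) -> Params:
    _check_keys(raw, ("R", "b", "s", "p", "p_hd", "p_dd"), "params")
    defaults = Params()
    if "p" in raw:
        defaults = Params.with_p(float(raw["p"]))
    kwargs = {k: float(v) for k, v in raw.items() if k != "p"}
    return defaults.replace(**kwargs)


def load_config(path) -> Tuple[RunConfig, ExperimentSpec]:
    """Load and validate a YAML/JSON config, applying defaults.

    An empty file yields the package defaults: a 100x100 Moore radius-1
    torus, best imitation, R=1, b=3, s=2, shared p=0.45, 500 rounds and
    a 50% random initial state.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    _check_keys(
        raw,
        (
            "params", "rows", "cols", "topology", "update_rule", "q", "K",
            "rounds", "init", "seed", "snapshot_rounds", "early_stop",
            "include_self", "experiment",
        ),
        "config",
    )

    params = _build_params(raw.get("params", {}) or {})

    topo_raw = raw.get("topology", {}) or {}
    _check_keys(topo_raw, ("kind", "radius", "m"), "topology")
    topology = TopologySpec(
        kind=topo_raw.get("kind", "moore"),
        radius=int(topo_raw.get("radius", 1)),
        m=int(topo_raw.get("m", 4)),
    )

    init_raw = raw.get("init", {}) or {}
    _check_keys(init_raw, ("kind", "h_fraction", "center", "path"), "init")
    init = InitSpec(
        kind=init_raw.get("kind", "random"),
        h_fraction=float(init_raw.get("h_fraction", 0.5)),
        center=str(init_raw.get("center", "H")),
        path=init_raw.get("path"),
    )

    config = RunConfig(
        params=params,
        rows=int(raw.get("rows", 100)),
        cols=int(raw.get("cols", 100)),
        topology=topology,
        update_rule=str(raw.get("update_rule", "best")),
        q=float(raw.get("q", 0.9)),
        K=float(raw.get("K", 0.1)),
        rounds=int(raw.get("rounds", 500)),
        init=init,
        seed=int(raw.get("seed", 0)),
        snapshot_rounds=tuple(int(t) for t in raw.get("snapshot_rounds", ())),
        early_stop=bool(raw.get("early_stop", True)),
        include_self=bool(raw.get("include_self", True)),
    )
    try:
        config.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    exp_raw = raw.get("experiment", {}) or {}
    _check_keys(exp_raw, ("param", "grid", "n_runs", "out_dir"), "experiment")
    experiment = ExperimentSpec(
        param=exp_raw.get("param", "p"),
        grid=parse_grid(exp_raw.get("grid", ())),
        n_runs=int(exp_raw.get("n_runs", 100)),
        out_dir=str(exp_raw.get("out_dir", "out")),
    )
    if experiment.param not in ("p", "s"):
        raise ConfigError(f"experiment.param must be 'p' or 's', got {experiment.param!r}")
    return config, experiment
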