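"""Core definitions of the Social Honesty (SH) game.

The SH game is a two-strategy social dilemma played between pairs of
players. Each player is either honest (``H``) or dishonest (``D``).
Honest pairs split a constant reward ``R`` each. A dishonest player
facing an honest one leaves the honest player with nothing and either
pockets the dishonest advantage ``b`` or, with probability ``p_hd``, is
caught and punished with payoff ``-s``. When two dishonest players meet,
each may be caught independently with probability ``p_dd``; only if
neither is caught does a fair coin decide who wins ``b`` while the other
gets zero. Payoffs are therefore discrete random variables, which is how
the model encodes the intrinsic uncertainty of social interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import NamedTuple

import numpy as np

__all__ = [
    "Strategy",
    "Params",
    "PairOutcome",
    "InvalidParameterError",
    "validate_params",
    "sample_pair_payoffs",
    "expected_pair_payoffs",
    "pair_payoffs_from_uniforms",
]


class Strategy(IntEnum):
    """Player strategy: honest (``H`` = 1) or dishonest (``D`` = 0)."""

    D = 0
    H = 1

    def __str__(self) -> str:
        return self.name

    @classmethod
    def from_char(cls, char: str) -> "Strategy":
        try:
            return cls[char.upper()]
        except KeyError:
            raise ValueError(f"unknown strategy character {char!r}") from None


class InvalidParameterError(ValueError):
    """A game parameter violates its admissible range."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(message)


@dataclass(frozen=True)
class Params:
    """Payoff and punishment parameters of the SH game.

    Attributes
    ----------
    R : float
        Reward each honest player earns in an H-H interaction (R > 0).
    b : float
        Advantage an unpunished dishonest player earns (b > 0).
    s : float
        Punishment severity; a punished player's payoff is ``-s`` (s >= 0).
    p_hd : float
        Probability that the dishonest player is punished in an H-D
        interaction.
    p_dd : float
        Per-player punishment probability in a D-D interaction.
    """

    R: float = 1.0
    b: float = 3.0
    s: float = 2.0
    p_hd: float = 0.45
    p_dd: float = 0.45

    @classmethod
    def with_p(cls, p: float, **kwargs) -> "Params":
        """Build parameters with a single shared punishment probability."""
        return cls(p_hd=p, p_dd=p, **kwargs)

    def replace(self, **changes) -> "Params":
        return replace(self, **changes)


class PairOutcome(NamedTuple):
    """Realized payoffs of one pairwise interaction."""

    payoff_i: float
    payoff_j: float


def validate_params(params: Params) -> Params:
    """Check all parameter invariants, returning ``params`` unchanged.

    Raises
    ------
    InvalidParameterError
        Naming the offending field.
    """
    if not params.R > 0:
        raise InvalidParameterError("R", f"R must be > 0, got {params.R}")
    if not params.b > 0:
        raise InvalidParameterError("b", f"b must be > 0, got {params.b}")
    if not params.s >= 0:
        raise InvalidParameterError("s", f"s must be >= 0, got {params.s}")
    for field in ("p_hd", "p_dd"):
        value = getattr(params, field)
        if not 0.0 <= value <= 1.0:
            raise InvalidParameterError(field, f"{field} out of [0,1]: {value}")
    return params


def pair_payoffs_from_uniforms(h_i, h_j, u_i, u_j, u_coin, params: Params):
    """Map uniform random draws to pair payoffs; vectorized.

    This is the single source of truth for the SH outcome rule, shared by
    the scalar sampler and the simulation kernels.

    Parameters
    ----------
    h_i, h_j : bool or boolean arrays
        True where the respective player is honest.
    u_i, u_j, u_coin : floats or arrays in [0, 1)
        ``u_i``/``u_j`` are the per-player punishment draws, ``u_coin``
        decides the D-D winner.

    Returns
    -------
    (payoff_i, payoff_j) as arrays broadcast to a common shape.

    Notes
    -----
    D-D resolution follows the game's rule literally: each dishonest
    player is caught independently with probability ``p_dd``; the
    ``(b, 0)`` coin split is awarded only when *neither* player is
    caught. A caught player's payoff is ``-s``; an uncaught player whose
    partner was caught gets 0.
    """
    h_i = np.asarray(h_i, dtype=bool)
    h_j = np.asarray(h_j, dtype=bool)
    u_i = np.asarray(u_i, dtype=float)
    u_j = np.asarray(u_j, dtype=float)
    u_coin = np.asarray(u_coin, dtype=float)
    R, b, s = params.R, params.b, params.s

    # branchless evaluation (cheaper than masked assignment on large grids)
    hd_i = np.where(u_i < params.p_hd, -s, b)  # i dishonest vs honest j
    hd_j = np.where(u_j < params.p_hd, -s, b)
    caught_i = u_i < params.p_dd
    caught_j = u_j < params.p_dd
    neither = ~(caught_i | caught_j)
    i_wins = u_coin < 0.5
    dd_i = np.where(caught_i, -s, np.where(neither & i_wins, b, 0.0))
    dd_j = np.where(caught_j, -s, np.where(neither & ~i_wins, b, 0.0))

    pay_i = np.where(h_i, np.where(h_j, R, 0.0), np.where(h_j, hd_i, dd_i))
    pay_j = np.where(h_j, np.where(h_i, R, 0.0), np.where(h_i, hd_j, dd_j))
    pay_i, pay_j = np.broadcast_arrays(pay_i, pay_j)
    return pay_i, pay_j


def sample_pair_payoffs(
    s_i: Strategy, s_j: Strategy, params: Params, rng: np.random.Generator
) -> PairOutcome:
    """Sample the payoffs of a single interaction between two players.

    Exactly three uniforms are consumed per call regardless of the
    strategy pair, so a fixed seed yields a fixed outcome sequence
    independently of the states encountered.
    """
    u_i, u_j, u_coin = rng.random(3)
    pay_i, pay_j = pair_payoffs_from_uniforms(
        bool(s_i), bool(s_j), u_i, u_j, u_coin, params
    )
    return PairOutcome(float(pay_i), float(pay_j))


def expected_pair_payoffs(s_i: Strategy, s_j: Strategy, params: Params):
    """Exact expected payoffs of a single interaction.

    H-H: ``(R, R)``. H-D: the honest side gets 0 and the dishonest side
    expects ``b(1-p_hd) - s*p_hd``. D-D: each player expects
    ``b(1-p_dd)^2/2 - s*p_dd`` (the win happens only when neither player
    is caught, and then with probability one half).
    """
    R, b, s = params.R, params.b, params.s
    if s_i == Strategy.H and s_j == Strategy.H:
        return (R, R)
    if s_i == Strategy.D and s_j == Strategy.D:
        e = b * (1.0 - params.p_dd) ** 2 / 2.0 - s * params.p_dd
        return (e, e)
    e_d = b * (1.0 - params.p_hd) - s * params.p_hd
    if s_i == Strategy.H:
        return (0.0, e_d)
    return (e_d, 0.0)
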