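"""Numba-compiled lattice kernels.

Each function mirrors the numpy fallback in :mod:`shgame.engine`
operation for operation, consuming pre-drawn uniforms in the identical
layout, so the two backends produce bit-identical trajectories for the
same seed (modulo at most one-ulp libm differences inside the Fermi
exponential). Importing this module requires numba; the engine treats
an ImportError as "numpy fallback only".
"""

import numpy as np
from numba import njit


@njit(cache=True)
def payoffs(honest, uniforms, drs, dcs, R, b, s, p_hd, p_dd):
    """Accumulate per-cell round payoffs over the half-offset pair list.

    ``uniforms`` has shape (n_half_offsets, 3, rows, cols): punishment
    draw of the focal cell, punishment draw of the partner, and the D-D
    winner coin, for the pair (cell, cell + offset).
    """
    rows, cols = honest.shape
    pay = np.zeros((rows, cols), dtype=np.float64)
    for k in range(drs.size):
        dr, dc = drs[k], dcs[k]
        for r in range(rows):
            pr = (r + dr) % rows
            for c in range(cols):
                pc = (c + dc) % cols
                h_i = honest[r, c]
                h_j = honest[pr, pc]
                u_i = uniforms[k, 0, r, c]
                u_j = uniforms[k, 1, r, c]
                u_coin = uniforms[k, 2, r, c]
                if h_i and h_j:
                    p_i = R
                    p_j = R
                elif h_i:
                    p_i = 0.0
                    p_j = -s if u_j < p_hd else b
                elif h_j:
                    p_j = 0.0
                    p_i = -s if u_i < p_hd else b
                else:
                    caught_i = u_i < p_dd
                    caught_j = u_j < p_dd
                    neither = (not caught_i) and (not caught_j)
                    if caught_i:
                        p_i = -s
                    elif neither and u_coin < 0.5:
                        p_i = b
                    else:
                        p_i = 0.0
                    if caught_j:
                        p_j = -s
                    elif neither and not (u_coin < 0.5):
                        p_j = b
                    else:
                        p_j = 0.0
                pay[r, c] += p_i
                pay[pr, pc] += p_j
    return pay


@njit(cache=True)
def _best_neighbor(pay, honest, r, c, drs, dcs, rows, cols):
    """Max neighbor payoff and the counts of (honest) maximal neighbors."""
    best = -np.inf
    count = 0
    count_h = 0
    for k in range(drs.size):
        pr = (r - drs[k]) % rows
        pc = (c - dcs[k]) % cols
        v = pay[pr, pc]
        if v > best:
            best = v
            count = 1
            count_h = 1 if honest[pr, pc] else 0
        elif v == best:
            count += 1
            if honest[pr, pc]:
                count_h += 1
    return best, count, count_h


@njit(cache=True)
def update_best(honest, pay, u_tie, drs, dcs, include_self):
    rows, cols = honest.shape
    new = np.empty((rows, cols), dtype=np.bool_)
    for r in range(rows):
        for c in range(cols):
            best, count, count_h = _best_neighbor(
                pay, honest, r, c, drs, dcs, rows, cols
            )
            adopt_h = u_tie[r, c] < count_h / count
            if include_self and pay[r, c] >= best:
                new[r, c] = honest[r, c]
            else:
                new[r, c] = adopt_h
    return new


@njit(cache=True)
def update_myopic(honest, best_decision, u_copy, u_gate, q, drs, dcs):
    rows, cols = honest.shape
    new = np.empty((rows, cols), dtype=np.bool_)
    degree = drs.size
    for r in range(rows):
        for c in range(cols):
            if u_gate[r, c] < q:
                new[r, c] = best_decision[r, c]
            else:
                n_h = 0
                for k in range(degree):
                    if honest[(r - drs[k]) % rows, (c - dcs[k]) % cols]:
                        n_h += 1
                new[r, c] = u_copy[r, c] < n_h / degree
    return new


@njit(cache=True)
def update_fermi(honest, pay, u_tie, u_switch, K, drs, dcs):
    rows, cols = honest.shape
    new = np.empty((rows, cols), dtype=np.bool_)
    for r in range(rows):
        for c in range(cols):
            best, count, count_h = _best_neighbor(
                pay, honest, r, c, drs, dcs, rows, cols
            )
            adopt_h = u_tie[r, c] < count_h / count
            z = (pay[r, c] - best) / K
            if z > 700.0:
                z = 700.0
            elif z < -700.0:
                z = -700.0
            if u_switch[r, c] < 1.0 / (1.0 + np.exp(z)):
                new[r, c] = adopt_h
            else:
                new[r, c] = honest[r, c]
    return new
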