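"""Interaction structures: periodic lattices, well-mixed and scale-free graphs.

All constructors return a :class:`NeighborGraph`, an undirected,
self-loop-free adjacency stored in CSR form (``indptr``/``indices``)
with the neighbor list of every node sorted. Lattice nodes use 0-based
row-major indexing: cell ``(r, c)`` is node ``r * cols + c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "NeighborGraph",
    "lattice_neighbors",
    "well_mixed_neighbors",
    "scale_free_neighbors",
    "lattice_offsets",
    "write_edge_list",
]

LATTICE_KINDS = ("moore", "von_neumann")


def lattice_offsets(scheme: str, radius: int):
    """All neighbor offsets ``(dr, dc)`` of a lattice scheme, excluding (0,0).

    Moore uses the Chebyshev ball, von Neumann the Manhattan ball.
    """
    if scheme not in LATTICE_KINDS:
        raise ValueError(f"unknown lattice scheme {scheme!r}")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    offsets = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if (dr, dc) == (0, 0):
                continue
            if scheme == "von_neumann" and abs(dr) + abs(dc) > radius:
                continue
            offsets.append((dr, dc))
    return offsets


@dataclass
class NeighborGraph:
    """Undirected interaction structure over ``n`` players (CSR adjacency)."""

    n: int
    indptr: np.ndarray
    indices: np.ndarray
    kind: str
    radius: Optional[int] = None
    shape: Optional[Tuple[int, int]] = None
    _edges: Optional[Tuple[np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def n_edges(self) -> int:
        return int(self.indices.size // 2)

    def edge_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """Unordered edges as two arrays ``(i, j)`` with ``i < j``, cached."""
        if self._edges is None:
            src = np.repeat(np.arange(self.n), self.degrees())
            keep = src < self.indices
            self._edges = (src[keep].copy(), self.indices[keep].copy())
        return self._edges

    def is_lattice(self) -> bool:
        return self.kind in LATTICE_KINDS


def _from_adjacency(pairs_i, pairs_j, n, kind, radius=None, shape=None):
    """Build a CSR NeighborGraph from directed pair arrays (both directions)."""
    order = np.lexsort((pairs_j, pairs_i))
    src = np.asarray(pairs_i)[order]
    dst = np.asarray(pairs_j)[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    np.cumsum(indptr, out=indptr)
    return NeighborGraph(
        n=n, indptr=indptr, indices=dst.astype(np.int64), kind=kind,
        radius=radius, shape=shape,
    )


def lattice_neighbors(
    rows: int, cols: int, scheme: str = "moore", radius: int = 1
) -> NeighborGraph:
    """Periodic (toroidal) lattice neighborhood graph.

    Moore neighborhoods collect cells at Chebyshev distance <= radius
    (degree 8 at radius 1), von Neumann at Manhattan distance <= radius
    (degree 4 at radius 1). Both axes wrap.
    """
    offsets = lattice_offsets(scheme, radius)
    if rows < 2 * radius + 1 or cols < 2 * radius + 1:
        raise ValueError(
            f"lattice {rows}x{cols} too small for {scheme} radius {radius}"
        )
    n = rows * cols
    r_idx, c_idx = np.divmod(np.arange(n), cols)
    src_all, dst_all = [], []
    for dr, dc in offsets:
        dst = ((r_idx + dr) % rows) * cols + (c_idx + dc) % cols
        src_all.append(np.arange(n))
        dst_all.append(dst)
    return _from_adjacency(
        np.concatenate(src_all), np.concatenate(dst_all), n,
        kind=scheme, radius=radius, shape=(rows, cols),
    )


def well_mixed_neighbors(n: int) -> NeighborGraph:
    """Complete graph: everybody interacts with everybody."""
    if n < 2:
        raise ValueError("well-mixed population needs n >= 2")
    src = np.repeat(np.arange(n), n - 1)
    dst = np.concatenate([np.delete(np.arange(n), i) for i in range(n)])
    return _from_adjacency(src, dst, n, kind="well_mixed")


def scale_free_neighbors(n: int, m: int = 4, seed: int = 0) -> NeighborGraph:
    """Barabási–Albert preferential-attachment graph mapped onto the lattice.

    Each of the ``n - m`` newly attached vertices brings ``m`` edges, so
    the construction yields ``m * (n - m)`` edges. Graph vertices are
    identified with lattice cells through a seeded random permutation;
    the mapping only matters for visualization, not for the dynamics.
    """
    if not 1 <= m <= n - 2:
        # m = n - 1 would leave a single attachment step (a degenerate star)
        raise ValueError(f"attachment parameter m={m} must satisfy 1 <= m <= n-2")
    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    perm = rng.permutation(n)
    edges = np.array(graph.edges(), dtype=np.int64)
    ei, ej = perm[edges[:, 0]], perm[edges[:, 1]]
    return _from_adjacency(
        np.concatenate([ei, ej]), np.concatenate([ej, ei]), n, kind="scale_free"
    )


def write_edge_list(graph: NeighborGraph, path) -> None:
    """Export the unordered edge list as two tab-separated integer columns."""
    ei, ej = graph.edge_arrays()
    np.savetxt(path, np.column_stack([ei, ej]), fmt="%d", delimiter="\t")
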