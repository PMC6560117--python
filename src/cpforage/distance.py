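"""Least-cost at-sea distances over the 8-connected sea-cell graph.

Travel cost between adjacent sea cells is the cell size for orthogonal moves
and cell size * sqrt(2) for diagonal moves, so path length never undercuts
the Euclidean distance and detours around land are priced in kilometres.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import LandMask

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def sea_graph(mask: LandMask):
    """Sparse weighted adjacency of sea cells plus the cell->node index raster."""
    sea = mask.is_sea
    nr, nc = sea.shape
    node = np.full(sea.shape, -1, dtype=np.int64)
    node[sea] = np.arange(sea.sum())
    rows_i, cols_i, weights = [], [], []
    cell = mask.grid.cell_size
    for dr, dc in _OFFSETS:
        r0s, r0e = max(0, -dr), min(nr, nr - dr)
        c0s, c0e = max(0, -dc), min(nc, nc - dc)
        src = sea[r0s:r0e, c0s:c0e] & sea[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        a = node[r0s:r0e, c0s:c0e][src]
        b = node[r0s + dr : r0e + dr, c0s + dc : c0e + dc][src]
        w = cell * (np.sqrt(2.0) if dr and dc else 1.0)
        rows_i.append(a)
        cols_i.append(b)
        weights.append(np.full(a.size, w))
    n = int(sea.sum())
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(n, n),
    ).tocsr()
    return graph, node


def least_cost_distance(mask: LandMask, source_cell: tuple[int, int]) -> np.ndarray:
    """Least-cost distance (km) from one sea cell to every cell.

    Land cells and unreachable sea cells are +inf.
    """
    r, c = source_cell
    if mask.is_land[r, c]:
        raise ValueError(f"source cell {source_cell} is on land")
    graph, node = sea_graph(mask)
    d = dijkstra(graph, directed=False, indices=node[r, c])
    out = np.full(mask.grid.shape, np.inf)
    out[mask.is_sea] = d
    return out
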