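"""Least-cost corridors and circuit-theory current density on resistance
rasters.

The landscape graph has one node per valid cell and edges between
8-neighbors; an edge's cost is the mean of its endpoint resistances times
the center-to-center distance (cell size, x sqrt(2) on diagonals) — the
Linkage-Mapper convention.  Cost-weighted distance (CWD) from a core is a
multi-source Dijkstra with every core cell a zero-cost source, which makes
travel within a core free.  A corridor for a core pair is the cell set
where CWD_A + CWD_B exceeds the least-cost-path cost by at most a cutoff
(default 25,000 cost units = resistance x meters).

For pinch points the same graph becomes an electric circuit with per-edge
conductance 1/cost.  In all-to-one mode each core in turn is grounded while
every other core injects one ampere; node voltages solve the graph
Laplacian system and per-cell current is half the sum of absolute currents
on incident edges, accumulated over iterations.  High-current cells inside
narrow corridor sections are the bottlenecks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .occupancy import CoreAreaSet
from .raster import Raster
from .resistance import ResistanceSurface

__all__ = [
    "CostGraph",
    "CorridorResult",
    "build_cost_graph",
    "cost_distance",
    "corridor_pair",
    "current_density",
    "pinch_points",
    "connect_cores",
]

_OFFSETS = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]


@dataclass
class CostGraph:
    """Sparse 8-neighbor cost graph over the valid cells of a surface."""

    matrix: sparse.csr_matrix  # symmetric edge costs
    node_of_cell: np.ndarray  # flat cell index -> node id (-1 invalid)
    cell_of_node: np.ndarray  # node id -> flat cell index
    grid: Raster

    @property
    def n_nodes(self) -> int:
        return self.cell_of_node.size

    def nodes_of(self, cells: np.ndarray) -> np.ndarray:
        """Node ids for an (n, 2) array of (row, col) cells."""
        flat = cells[:, 0] * self.grid.shape[1] + cells[:, 1]
        nodes = self.node_of_cell[flat]
        if (nodes < 0).any():
            raise ValueError("some cells fall on nodata")
        return nodes

    def raster_from_nodes(self, values: np.ndarray, fill=np.nan) -> Raster:
        flat = np.full(self.grid.shape[0] * self.grid.shape[1], fill, dtype=float)
        flat[self.cell_of_node] = values
        return self.grid.like(flat.reshape(self.grid.shape))


def build_cost_graph(surface: ResistanceSurface | Raster) -> CostGraph:
    grid = surface.raster if isinstance(surface, ResistanceSurface) else surface
    vals = grid.data
    nrow, ncol = grid.shape
    valid = ~np.isnan(vals)
    if not valid.any():
        raise ValueError("surface has no valid cells")
    if np.nanmin(vals) <= 0:
        raise ValueError("resistance values must be positive")
    node_of_cell = np.full(nrow * ncol, -1, dtype=np.int64)
    cell_of_node = np.flatnonzero(valid.ravel())
    node_of_cell[cell_of_node] = np.arange(cell_of_node.size)
    rows_i, cols_i, costs = [], [], []
    for dr, dc, mult in _OFFSETS:
        r0 = slice(0, nrow - dr)
        r1 = slice(dr, nrow)
        if dc >= 0:
            c0, c1 = slice(0, ncol - dc), slice(dc, ncol)
        else:
            c0, c1 = slice(-dc, ncol), slice(0, ncol + dc)
        ok = valid[r0, c0] & valid[r1, c1]
        a = (np.arange(nrow * ncol).reshape(nrow, ncol))[r0, c0][ok]
        b = (np.arange(nrow * ncol).reshape(nrow, ncol))[r1, c1][ok]
        w = 0.5 * (vals[r0, c0][ok] + vals[r1, c1][ok]) * grid.cell_size * mult
        rows_i.append(node_of_cell[a])
        cols_i.append(node_of_cell[b])
        costs.append(w)
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_i)
    w = np.concatenate(costs)
    n = cell_of_node.size
    mat = sparse.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    return CostGraph(mat, node_of_cell, cell_of_node, grid)


def cost_distance(surface: ResistanceSurface | Raster, sources: np.ndarray,
                  graph: CostGraph | None = None,
                  return_predecessors: bool = False):
    """Cost-weighted distance from a source cell set (multi-source Dijkstra).

    ``sources`` is an (n, 2) array of (row, col) cells.  Unreachable cells
    carry +inf.  With ``return_predecessors`` also returns the shortest-path
    tree for backtracking.
    """
    graph = graph or build_cost_graph(surface)
    sources = np.atleast_2d(np.asarray(sources))
    if sources.size == 0:
        raise ValueError("empty source set")
    src_nodes = graph.nodes_of(sources)
    if return_predecessors:
        dist, pred, src = dijkstra(graph.matrix, directed=False,
                                   indices=src_nodes, min_only=True,
                                   return_predecessors=True)
        return graph.raster_from_nodes(dist, fill=np.nan), dist, pred, graph
    dist = dijkstra(graph.matrix, directed=False, indices=src_nodes,
                    min_only=True)
    return graph.raster_from_nodes(dist, fill=np.nan), dist, graph


@dataclass
class CorridorResult:
    """Everything computed for one core pair."""

    pair: tuple[int, int]
    lcp_cost: float
    lcp_cells: np.ndarray  # (n, 2) row/col along the least-cost path
    cwd_a: Raster
    cwd_b: Raster
    corridor_mask: Raster  # 1 inside the corridor, 0 outside, NaN on nodata
    cutoff: float
    current: Raster | None = None
    pinch_cells: np.ndarray | None = None

    def lcp_linestring(self):
        from shapely import LineString

        g = self.cwd_a
        return LineString([g.cell_center(int(r), int(c)) for r, c in self.lcp_cells])

    @property
    def corridor_area_km2(self) -> float:
        m = self.corridor_mask
        return float(np.nansum(m.data) * (m.cell_size / 1000.0) ** 2)


def _backtrack(node: int, pred: np.ndarray) -> list[int]:
    path = [node]
    while pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return path


def corridor_pair(surface: ResistanceSurface | Raster, core_a: np.ndarray,
                  core_b: np.ndarray, cutoff: float = 25000.0,
                  graph: CostGraph | None = None,
                  pair: tuple[int, int] = (1, 2)) -> CorridorResult:
    """Least-cost path and cost-cutoff corridor between two cores.

    The LCP cost is min over cells of CWD_A + CWD_B; the corridor is
    {CWD_A + CWD_B − LCP cost <= cutoff}; the path itself is recovered by
    backtracking both shortest-path trees from the argmin cell.
    """
    graph = graph or build_cost_graph(surface)
    cwd_a, dist_a, pred_a, _ = cost_distance(surface, core_a, graph,
                                             return_predecessors=True)
    cwd_b, dist_b, pred_b, _ = cost_distance(surface, core_b, graph,
                                             return_predecessors=True)
    total = dist_a + dist_b
    best = int(np.argmin(total))
    lcp_cost = float(total[best])
    if not np.isfinite(lcp_cost):
        raise ValueError(f"cores {pair} are mutually unreachable")
    to_a = _backtrack(best, pred_a)  # best -> a
    to_b = _backtrack(best, pred_b)  # best -> b
    nodes = list(reversed(to_a)) + to_b[1:]
    cells = np.column_stack(
        np.unravel_index(graph.cell_of_node[nodes], graph.grid.shape)
    )
    in_corridor = total - lcp_cost <= cutoff
    mask = graph.raster_from_nodes(in_corridor.astype(float), fill=np.nan)
    return CorridorResult(pair, lcp_cost, cells, cwd_a, cwd_b, mask, cutoff)


def current_density(surface: ResistanceSurface | Raster,
                    cores: list[np.ndarray],
                    graph: CostGraph | None = None) -> tuple[Raster, list[str]]:
    """All-to-one circuit solve: summed per-cell current over iterations.

    Each iteration grounds one core (all its cells at 0 V) while every other
    core injects a total of 1 A split equally over its cells.  Per-cell
    current is half the sum of absolute incident edge currents, averaged
    over ground iterations (so two single-cell cores joined by one chain
    carry unit current through every chain cell, as Kirchhoff demands).
    Returns the current raster and a list of per-iteration issues (e.g. a
    core disconnected from the ground).
    """
    if len(cores) < 2:
        raise ValueError("need at least two cores")
    graph = graph or build_cost_graph(surface)
    n = graph.n_nodes
    cond = graph.matrix.copy()
    cond.data = 1.0 / cond.data
    lap = sparse.diags(np.asarray(cond.sum(axis=1)).ravel()) - cond
    core_nodes = [graph.nodes_of(np.atleast_2d(c)) for c in cores]
    total_current = np.zeros(n)
    n_solved = 0
    issues: list[str] = []
    coo = cond.tocoo()
    upper = coo.row < coo.col
    e_i, e_j, e_c = coo.row[upper], coo.col[upper], coo.data[upper]
    from scipy.sparse.csgraph import connected_components

    _, comp = connected_components(graph.matrix, directed=False)
    for g_idx, ground in enumerate(core_nodes):
        ground_comps = set(comp[ground])
        inject = np.zeros(n)
        for k_idx, nodes in enumerate(core_nodes):
            if k_idx == g_idx:
                continue
            if not set(comp[nodes]) & ground_comps:
                issues.append(
                    f"iteration grounding core {g_idx}: core {k_idx} is "
                    "disconnected from the ground"
                )
                continue
            inject[nodes] += 1.0 / nodes.size
        free = np.isin(comp, list(ground_comps))
        free[ground] = False
        if not free.any():
            continue
        try:
            v_free = sparse.linalg.spsolve(lap[free][:, free].tocsc(),
                                           inject[free])
        except Exception as exc:
            issues.append(f"iteration grounding core {g_idx}: solve failed ({exc})")
            continue
        v = np.zeros(n)
        v[free] = v_free
        edge_cur = np.abs(v[e_i] - v[e_j]) * e_c
        cur = np.zeros(n)
        np.add.at(cur, e_i, edge_cur)
        np.add.at(cur, e_j, edge_cur)
        total_current += 0.5 * cur
        n_solved += 1
    if n_solved:
        total_current /= n_solved
    return graph.raster_from_nodes(total_current, fill=np.nan), issues


def pinch_points(corridor: CorridorResult, percentile: float = 95.0) -> np.ndarray:
    """Cells inside the corridor whose current >= the given within-corridor
    percentile.  Requires ``corridor.current`` to be populated."""
    if corridor.current is None:
        raise ValueError("current raster not computed for this corridor")
    mask = np.nan_to_num(corridor.corridor_mask.data, nan=0.0) > 0.5
    if not mask.any():
        raise ValueError("empty corridor")
    cur = corridor.current.data
    inside = cur[mask]
    thr = np.percentile(inside[~np.isnan(inside)], percentile)
    hot = mask & (cur >= thr)
    corridor.pinch_cells = np.argwhere(hot)
    return corridor.pinch_cells


def connect_cores(surface: ResistanceSurface | Raster, cores: CoreAreaSet,
                  cutoff: float = 25000.0, pairs: str = "adjacent",
                  percentile: float = 95.0,
                  with_current: bool = True):
    """Corridors (and optionally current/pinch points) for a core-area set.

    ``pairs='all'`` connects every pair; ``pairs='adjacent'`` (default)
    drops pairs whose least-cost path crosses a third core.  Returns the
    kept CorridorResults and a pair summary table.
    """
    graph = build_cost_graph(surface)
    labels = cores.table["label"].tolist()
    core_cells = {int(l): cores.cells(int(l)) for l in labels}
    label_grid = cores.labels.data
    results: list[CorridorResult] = []
    rows = []
    for ai in range(len(labels)):
        for bi in range(ai + 1, len(labels)):
            la, lb = int(labels[ai]), int(labels[bi])
            try:
                res = corridor_pair(surface, core_cells[la], core_cells[lb],
                                    cutoff, graph, pair=(la, lb))
            except ValueError as exc:
                rows.append({"core_a": la, "core_b": lb, "status": str(exc)})
                continue
            crossed = {
                int(label_grid[r, c]) for r, c in res.lcp_cells
            } - {0, la, lb}
            if pairs == "adjacent" and crossed:
                rows.append({"core_a": la, "core_b": lb,
                             "status": f"skipped: LCP crosses cores {sorted(crossed)}"})
                continue
            results.append(res)
            rows.append({"core_a": la, "core_b": lb, "status": "ok",
                         "lcp_cost": res.lcp_cost,
                         "corridor_km2": res.corridor_area_km2})
    if with_current and len(labels) >= 2 and results:
        current, issues = current_density(surface,
                                          [core_cells[int(l)] for l in labels],
                                          graph)
        for res in results:
            res.current = current
            pinch_points(res, percentile)
        for msg in issues:
            rows.append({"core_a": -1, "core_b": -1, "status": msg})
    return results, pd.DataFrame(rows)
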