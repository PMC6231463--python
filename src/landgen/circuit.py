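"""Circuit-theory connectivity: effective resistance and current density.

A resistance surface becomes a resistor network: each valid cell is a node,
each pair of adjacent cells (4- or 8-neighbourhood) is a resistor whose
value is the mean of the two cell resistances, scaled by sqrt(2) for
diagonal neighbours to account for the longer span. Pairwise effective
resistances and per-cell current maps come from sparse solves of the graph
Laplacian, the McRae isolation-by-resistance distance model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .matrix import DistanceMatrix
from .raster import Raster

__all__ = [
    "NodeGraph",
    "build_graph",
    "effective_resistance",
    "resistance_matrix",
    "current_map",
    "LaplacianSolver",
]


@dataclass
class NodeGraph:
    """Weighted undirected graph over valid raster cells.

    ``edges`` is an (m, 2) int array of node-index pairs (i < j),
    ``conductance`` the matching (m,) positive weights. ``cells`` maps
    node index -> (row, col) of the source raster.
    """

    n_nodes: int
    edges: np.ndarray
    conductance: np.ndarray
    cells: np.ndarray  # (n_nodes, 2) int

    def __post_init__(self):
        if np.any(self.conductance <= 0):
            raise ValueError("conductances must be > 0")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops are not allowed")

    def laplacian(self) -> sparse.csc_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.conductance
        n = self.n_nodes
        A = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        ).tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
        return (sparse.diags(deg) - A).tocsc()

    def components(self) -> np.ndarray:
        i, j = self.edges[:, 0], self.edges[:, 1]
        A = sparse.coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(self.n_nodes, self.n_nodes)
        )
        _, labels = connected_components(A, directed=False)
        return labels

    def node_at(self, row: int, col: int) -> int:
        hits = np.flatnonzero((self.cells[:, 0] == row) & (self.cells[:, 1] == col))
        if hits.size == 0:
            raise ValueError(f"cell ({row}, {col}) is not a graph node")
        return int(hits[0])


def build_graph(surface: Raster, neighbourhood: int = 8) -> NodeGraph:
    """Raster -> resistor network (average-resistance edge rule).

    Edge resistance between adjacent cells i, j is (R_i + R_j)/2; diagonal
    edges are scaled by sqrt(2). Conductance is the reciprocal. Nodata
    cells are excluded.
    """
    if neighbourhood not in (4, 8):
        raise ValueError("neighbourhood must be 4 or 8")
    valid = surface.valid()
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid cells")
    nrows, ncols = surface.values.shape
    node_id = -np.ones((nrows, ncols), dtype=int)
    rr, cc = np.nonzero(valid)
    node_id[rr, cc] = np.arange(rr.size)
    R = surface.values

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighbourhood == 8:
        offsets += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]

    ei, ej, ew = [], [], []
    for dr, dc, scale in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        ok = valid[r0, c0] & valid[r1, c1]
        a = node_id[r0, c0][ok]
        b = node_id[r1, c1][ok]
        res = scale * (R[r0, c0][ok] + R[r1, c1][ok]) / 2.0
        ei.append(a)
        ej.append(b)
        ew.append(1.0 / res)
    edges = np.stack([np.concatenate(ei), np.concatenate(ej)], axis=1)
    lo = edges.min(axis=1)
    hi = edges.max(axis=1)
    edges = np.stack([lo, hi], axis=1)
    return NodeGraph(int(rr.size), edges, np.concatenate(ew), np.stack([rr, cc], axis=1))


class LaplacianSolver:
    """Factorized reduced-Laplacian solver, reused across injections.

    One node (``ground``) is removed to make the Laplacian nonsingular;
    the LU factorization is computed once and shared by all pairwise
    solves, so results are independent of solve order.
    """

    def __init__(self, graph: NodeGraph, ground: int):
        self.graph = graph
        self.ground = int(ground)
        n = graph.n_nodes
        keep = np.arange(n) != self.ground
        self.keep_idx = np.flatnonzero(keep)
        self.pos = -np.ones(n, dtype=int)
        self.pos[self.keep_idx] = np.arange(n - 1)
        L = graph.laplacian()
        self.lu = splu(L[keep][:, keep].tocsc())

    def potentials(self, injection: np.ndarray) -> np.ndarray:
        """Node potentials for a net-zero injection vector (ground at 0 V)."""
        if abs(injection.sum()) > 1e-9 * np.abs(injection).max():
            raise ValueError("injection currents must sum to zero")
        b = injection[self.keep_idx]
        v = np.zeros(self.graph.n_nodes)
        v[self.keep_idx] = self.lu.solve(b)
        return v

    def unit_response(self, node: int) -> np.ndarray:
        """Potentials for +1 A at ``node``, -1 A at ground."""
        inj = np.zeros(self.graph.n_nodes)
        inj[node] = 1.0
        inj[self.ground] = -1.0
        return self.potentials(inj)


def _require_connected(graph: NodeGraph, nodes: np.ndarray) -> None:
    labels = graph.components()
    comp = labels[nodes]
    if len(set(comp.tolist())) > 1:
        raise ValueError(
            f"nodes span {len(set(comp.tolist()))} disconnected components: "
            f"{dict(zip(nodes.tolist(), comp.tolist()))}"
        )


def effective_resistance(graph: NodeGraph, a: int, b: int) -> float:
    """Two-terminal effective resistance between nodes ``a`` and ``b``."""
    if a == b:
        raise ValueError("a and b must differ")
    _require_connected(graph, np.array([a, b]))
    solver = LaplacianSolver(graph, ground=b)
    v = solver.unit_response(a)
    return float(v[a] - v[b])


def _nodes_for_points(surface: Raster, graph: NodeGraph, points) -> np.ndarray:
    valid = surface.valid()
    node_id = -np.ones(surface.values.shape, dtype=int)
    node_id[graph.cells[:, 0], graph.cells[:, 1]] = np.arange(graph.n_nodes)
    nodes = []
    for k, (x, y) in enumerate(points):
        try:
            row, col = surface.cell_of(float(x), float(y))
        except ValueError as e:
            raise ValueError(f"point {k} at ({x}, {y}): {e}") from None
        if not valid[row, col]:
            raise ValueError(f"point {k} at ({x}, {y}) falls on a nodata cell")
        nodes.append(node_id[row, col])
    return np.asarray(nodes, dtype=int)


def resistance_matrix(
    surface: Raster, points, labels=None, neighbourhood: int = 8
) -> DistanceMatrix:
    """All-pairs effective resistances among focal points.

    Points are snapped to cell centres; points sharing a cell collapse to
    one node for solving (distance 0 among them). With k distinct focal
    nodes the reduced Laplacian is factorized once and k-1 solves give all
    k(k-1)/2 resistances via the Green's-function identity
    ``R_ab = G_aa + G_bb - G_ab - G_ba`` (ground at the last focal node).
    """
    pts = [(float(x), float(y)) for x, y in points]
    if labels is None:
        labels = [str(i) for i in range(len(pts))]
    graph = build_graph(surface, neighbourhood)
    nodes = _nodes_for_points(surface, graph, pts)
    uniq, inv = np.unique(nodes, return_inverse=True)
    if uniq.size < 2:
        return DistanceMatrix(np.zeros((len(pts), len(pts))), labels)
    _require_connected(graph, uniq)

    ground = int(uniq[-1])
    solver = LaplacianSolver(graph, ground)
    k = uniq.size
    # G[a_idx, b_idx] = potential at uniq[b] when unit current runs uniq[a]->ground
    G = np.zeros((k, k))
    for ai in range(k - 1):
        v = solver.unit_response(int(uniq[ai]))
        G[ai, :] = v[uniq]
    D = np.zeros((k, k))
    for ai in range(k):
        for bi in range(ai + 1, k):
            D[ai, bi] = G[ai, ai] + G[bi, bi] - G[ai, bi] - G[bi, ai]
    D += D.T
    full = D[np.ix_(inv, inv)]
    np.fill_diagonal(full, 0.0)
    return DistanceMatrix(full, labels)


def current_map(
    surface: Raster,
    points,
    pair_subset=None,
    neighbourhood: int = 8,
) -> Raster:
    """Per-cell current density summed over focal pairs at unit injection.

    For each pair, the cell current is half the sum of absolute currents
    on its incident edges; source and sink cells report the injected
    current (1). The map is the sum over all pairs (or ``pair_subset``,
    an iterable of index pairs into ``points``).
    """
    pts = [(float(x), float(y)) for x, y in points]
    graph = build_graph(surface, neighbourhood)
    nodes = _nodes_for_points(surface, graph, pts)
    uniq = np.unique(nodes)
    if uniq.size < 2:
        raise ValueError("need at least two distinct focal cells")
    _require_connected(graph, uniq)

    if pair_subset is None:
        pairs = [(i, j) for i in range(len(pts)) for j in range(i + 1, len(pts))]
    else:
        pairs = [(int(i), int(j)) for i, j in pair_subset]
    node_pairs = {
        (min(nodes[i], nodes[j]), max(nodes[i], nodes[j]))
        for i, j in pairs
        if nodes[i] != nodes[j]
    }

    solver = LaplacianSolver(graph, ground=int(uniq[-1]))
    cache: dict[int, np.ndarray] = {}

    def response(node: int) -> np.ndarray:
        if node == solver.ground:
            return np.zeros(graph.n_nodes)
        if node not in cache:
            cache[node] = solver.unit_response(node)
        return cache[node]

    ei, ej = graph.edges[:, 0], graph.edges[:, 1]
    w = graph.conductance
    total = np.zeros(graph.n_nodes)
    for a, b in sorted(node_pairs):
        v = response(a) - response(b)
        edge_cur = np.abs(w * (v[ei] - v[ej]))
        node_cur = np.zeros(graph.n_nodes)
        np.add.at(node_cur, ei, edge_cur)
        np.add.at(node_cur, ej, edge_cur)
        node_cur *= 0.5
        node_cur[a] = 1.0
        node_cur[b] = 1.0
        total += node_cur

    out = np.full(surface.values.shape, surface.nodata)
    out[graph.cells[:, 0], graph.cells[:, 1]] = total
    return surface.like(out)
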