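"""Corridor identification from current-density and resistance maps.

Turns the circuit outputs into corridor proposals between adjacent habitat
components, under three siting criteria: overlap with low-resistance /
high-current terrain, reconnection of components divided by major roads,
and avoidance of farmland by 1 km and residences by 2 km.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import distance_transform_edt
from scipy.sparse.csgraph import dijkstra

from .raster import Raster, check_aligned

__all__ = [
    "ComponentSet",
    "Corridor",
    "disturbance_mask",
    "distance_to_features",
    "candidate_corridors",
    "select_optimal",
]

log = logging.getLogger(__name__)

FARM_BUFFER_M = 1000.0
RESIDENCE_BUFFER_M = 2000.0


@dataclass
class ComponentSet:
    """Named habitat components (disjoint cell sets) and their adjacency."""

    components: dict           # name -> set of (row, col)
    adjacency: list            # list of (name_a, name_b)

    def __post_init__(self):
        seen: dict[tuple, str] = {}
        for name, cells in self.components.items():
            for c in cells:
                if c in seen:
                    raise ValueError(f"cell {c} in both {seen[c]!r} and {name!r}")
                seen[c] = name
        for a, b in self.adjacency:
            if a not in self.components or b not in self.components:
                raise ValueError(f"adjacency references unknown component ({a}, {b})")

    @classmethod
    def from_raster(cls, labelled: Raster, adjacency: list | None = None) -> "ComponentSet":
        """Components from a raster of integer component ids (0/nodata = none).

        Without an explicit adjacency list, all component pairs are adjacent.
        """
        v = labelled.valid()
        ids = np.unique(labelled.values[v].astype(int))
        ids = ids[ids > 0]
        comps = {
            str(i): set(zip(*np.nonzero(v & (labelled.values.astype(int) == i))))
            for i in ids
        }
        if adjacency is None:
            names = sorted(comps)
            adjacency = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        return cls(comps, adjacency)


@dataclass
class Corridor:
    """One candidate path between two habitat components."""

    pair: tuple
    path: list                      # ordered (row, col) cells, 8-connected
    path_xy: list                   # matching cell-centre map coordinates
    cost: float                     # cumulative resistance-weighted length
    mean_current: float
    mean_resistance: float
    crosses_major_road: bool
    min_dist_farmland: float = np.nan
    min_dist_residence: float = np.nan
    road_warning: bool = False      # selected without a road crossing

    @property
    def length_cells(self) -> int:
        return len(self.path)


# ----------------------------------------------------------------------
def distance_to_features(features: Raster | None, template: Raster) -> np.ndarray:
    """Euclidean cell-centre distance (m) to the nearest feature cell.

    ``features`` marks feature presence with values > 0; ``None`` means no
    features anywhere (infinite distance).
    """
    if features is None:
        return np.full(template.values.shape, np.inf)
    check_aligned(features, template)
    present = features.valid() & (features.values > 0)
    if not present.any():
        return np.full(template.values.shape, np.inf)
    return distance_transform_edt(~present, sampling=features.cellsize)


def disturbance_mask(
    farmland: Raster | None,
    residences: Raster | None,
    template: Raster | None = None,
    farm_buffer: float = FARM_BUFFER_M,
    res_buffer: float = RESIDENCE_BUFFER_M,
) -> Raster:
    """Boolean raster: 1 where a corridor may not pass.

    A cell is masked iff it lies within ``farm_buffer`` of farmland or
    ``res_buffer`` of residences (Euclidean cell-centre distance).
    """
    ref = template or farmland or residences
    if ref is None:
        raise ValueError("need at least one raster to define the grid")
    for r in (farmland, residences):
        if r is not None:
            check_aligned(ref, r)
    d_farm = distance_to_features(farmland, ref)
    d_res = distance_to_features(residences, ref)
    masked = (d_farm <= farm_buffer) | (d_res <= res_buffer)
    return ref.like(masked.astype(float), nodata=-1.0)


# ----------------------------------------------------------------------
def _path_graph(resistance: Raster, allowed: np.ndarray):
    """Sparse 8-neighbour cost graph over allowed cells.

    Edge cost = mean endpoint resistance, x sqrt(2) for diagonal steps
    (cost per cell step; the cumulative cost of a path is its
    resistance-weighted length).
    """
    nrows, ncols = resistance.values.shape
    node_id = -np.ones((nrows, ncols), dtype=int)
    rr, cc = np.nonzero(allowed)
    node_id[rr, cc] = np.arange(rr.size)
    R = resistance.values
    ei, ej, ew = [], [], []
    for dr, dc, scale in [(0, 1, 1.0), (1, 0, 1.0),
                          (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        ok = allowed[r0, c0] & allowed[r1, c1]
        ei.append(node_id[r0, c0][ok])
        ej.append(node_id[r1, c1][ok])
        ew.append(scale * (R[r0, c0][ok] + R[r1, c1][ok]) / 2.0)
    i = np.concatenate(ei)
    j = np.concatenate(ej)
    w = np.concatenate(ew)
    n = rr.size
    G = sparse.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
    cells = np.stack([rr, cc], axis=1)
    return G, node_id, cells


def _best_path(G, sources: np.ndarray, targets: np.ndarray):
    """Lowest-cost path from any source to any target (supersource trick)."""
    n = G.shape[0]
    eps = 1e-12
    super_row = sparse.coo_matrix(
        (np.full(len(sources), eps), (np.zeros(len(sources), dtype=int), sources)),
        shape=(1, n),
    )
    Gx = sparse.bmat([[None, super_row], [super_row.T, G]], format="csr")
    dist, pred = dijkstra(Gx, indices=0, return_predecessors=True)
    tdist = dist[targets + 1]
    if not np.isfinite(tdist).any():
        return None, np.inf
    best = int(targets[int(np.argmin(tdist))]) + 1
    path = []
    node = best
    while node != 0 and node >= 0:
        path.append(node - 1)
        node = pred[node]
    path.reverse()
    return path, float(dist[best])


def candidate_corridors(
    current: Raster,
    resistance: Raster,
    components: ComponentSet,
    roads: Raster | None = None,
    mask: Raster | None = None,
    k: int = 5,
    farmland: Raster | None = None,
    residences: Raster | None = None,
    penalty: float = 10.0,
) -> list[Corridor]:
    """k low-cost candidate paths per adjacent component pair.

    Candidates beyond the first are generated by successive penalization:
    cells of each found path have their resistance multiplied by
    ``penalty`` before the next search, pushing later candidates onto
    alternative routes. All paths avoid masked cells.
    """
    check_aligned(current, resistance)
    valid = resistance.valid()
    masked = np.zeros_like(valid)
    if mask is not None:
        check_aligned(resistance, mask)
        masked = mask.values > 0
    allowed = valid & ~masked

    road_cells = np.zeros_like(valid)
    if roads is not None:
        check_aligned(resistance, roads)
        road_cells = roads.valid() & (roads.values > 0)
    d_farm = distance_to_features(farmland, resistance)
    d_res = distance_to_features(residences, resistance)

    out: list[Corridor] = []
    for name_a, name_b in components.adjacency:
        src_cells = [c for c in components.components[name_a] if allowed[c]]
        tgt_cells = [c for c in components.components[name_b] if allowed[c]]
        if not src_cells or not tgt_cells:
            raise ValueError(
                f"component pair ({name_a}, {name_b}): all cells masked or nodata"
            )
        work = resistance.like(resistance.values.copy())
        found = 0
        seen_paths = set()
        for _ in range(k):
            G, node_id, cells = _path_graph(work, allowed)
            sources = np.array([node_id[c] for c in src_cells])
            targets = np.array([node_id[c] for c in tgt_cells])
            path_nodes, cost = _best_path(G, sources, targets)
            if path_nodes is None:
                if found == 0:
                    raise ValueError(
                        f"no unmasked route between {name_a!r} and {name_b!r}"
                    )
                break
            path = [tuple(cells[i]) for i in path_nodes]
            key = tuple(path)
            if key not in seen_paths:
                seen_paths.add(key)
                idx = tuple(np.array(path).T)
                cur_vals = current.values[idx]
                cur_ok = current.valid()[idx]
                out.append(
                    Corridor(
                        pair=(name_a, name_b),
                        path=path,
                        path_xy=[resistance.center_of(r, c) for r, c in path],
                        cost=cost,
                        mean_current=float(np.mean(cur_vals[cur_ok]))
                        if cur_ok.any() else np.nan,
                        mean_resistance=float(np.mean(resistance.values[idx])),
                        crosses_major_road=bool(road_cells[idx].any()),
                        min_dist_farmland=float(np.min(d_farm[idx])),
                        min_dist_residence=float(np.min(d_res[idx])),
                    )
                )
                found += 1
            # penalize this path's cells for the next round
            w = work.values.copy()
            for r, c in path:
                w[r, c] *= penalty
            work = resistance.like(w)
    return out


def select_optimal(candidates: list[Corridor]) -> dict:
    """One corridor per component pair, by the three siting criteria.

    Among candidates crossing the separating major road, pick the highest
    mean current density; ties go to lower mean resistance, then shorter
    path. If no candidate crosses a road, the highest-current candidate is
    returned with ``road_warning`` set.
    """
    by_pair: dict[tuple, list[Corridor]] = {}
    for c in candidates:
        by_pair.setdefault(c.pair, []).append(c)
    out = {}
    for pair, cands in by_pair.items():
        crossing = [c for c in cands if c.crosses_major_road]
        pool = crossing if crossing else cands
        best = min(
            pool,
            key=lambda c: (-c.mean_current if np.isfinite(c.mean_current) else np.inf,
                           c.mean_resistance, c.length_cells),
        )
        if not crossing:
            best.road_warning = True
            log.warning("pair %s: no candidate crosses a major road", pair)
        out[pair] = best
    return out


def write_corridors(corridors: dict, path) -> None:
    """Corridor paths as delimited text: pair, order, x, y per row."""
    import pandas as pd

    rows = []
    for (a, b), c in corridors.items():
        for order, (x, y) in enumerate(c.path_xy):
            rows.append({"component_a": a, "component_b": b, "order": order,
                         "x": x, "y": y,
                         "mean_current": c.mean_current,
                         "mean_resistance": c.mean_resistance,
                         "crosses_major_road": c.crosses_major_road})
    pd.DataFrame(rows).to_csv(path, index=False)
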