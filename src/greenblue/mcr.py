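"""Green-corridor generation by the minimum cumulative resistance (MCR) model.

Movement cost accumulates along 8-connected paths through a resistance
surface: each step costs ``step_length × (R_here + R_there) / 2`` with step
length equal to the cell size orthogonally and cell size × √2 diagonally —
the accounting used by the standard GIS cost-distance tools. The cumulative
cost from a set of source patches is the MCR value of a cell; tracing the
cost backlinks between two patches yields the least-cost ("green") corridor
and its accumulated resistance L_ab.

The model's monotone response function is taken as the identity: any strictly
increasing function preserves the ranking of paths, so corridor geometry and
relative scores are invariant to that choice.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .hydrology import NEIGHBOURS, _DIAG
from .patches import Patch, PatchSet
from .raster import RasterGrid, ReclassTable, reclassify

__all__ = [
    "build_resistance",
    "cost_distance",
    "least_cost_path",
    "corridor_network",
    "CostResult",
    "Corridor",
    "CorridorSet",
]


@dataclass
class CostResult:
    """Accumulated-cost surface from a source set plus traceback links."""

    cost: np.ndarray  # float, np.inf where unreachable
    backlink: np.ndarray  # int8 neighbour code toward the source, -1 at sources
    length: np.ndarray  # geometric length (m) of the optimal path
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)


@dataclass
class Corridor:
    a: int
    b: int
    chain: list[tuple[int, int]]  # ordered cells from patch a to patch b
    cost: float  # accumulated resistance L_ab
    length: float  # geometric length in metres


@dataclass
class CorridorSet:
    corridors: dict[tuple[int, int], Corridor]
    missing: list[tuple[int, int]]

    @property
    def L_max(self) -> float:
        if not self.corridors:
            raise ValueError("no corridors: L_max undefined")
        return max(c.cost for c in self.corridors.values())

    def __len__(self) -> int:
        return len(self.corridors)

    def __iter__(self):
        return iter(self.corridors.values())

    def __getitem__(self, key: tuple[int, int]) -> Corridor:
        a, b = key
        return self.corridors[(min(a, b), max(a, b))]


def build_resistance(landuse: RasterGrid, table: ReclassTable) -> RasterGrid:
    """Reclassify land-use categories into a strictly positive resistance surface."""
    surface = reclassify(landuse, table)
    vals = surface.values[~surface.nodata_mask()]
    if vals.size and not np.all(vals > 0):
        raise ValueError("resistance surface must be strictly positive everywhere")
    return surface


def _as_source_cells(sources, shape) -> list[tuple[int, int]]:
    if isinstance(sources, PatchSet):
        cells = [tuple(rc) for p in sources for rc in p.cells]
    elif isinstance(sources, Patch):
        cells = [tuple(rc) for rc in sources.cells]
    elif isinstance(sources, np.ndarray) and sources.dtype == bool:
        cells = [tuple(rc) for rc in np.argwhere(sources)]
    else:
        cells = [tuple(map(int, rc)) for rc in sources]
    for r, c in cells:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"source cell ({r}, {c}) outside the grid")
    return sorted(set(cells))


def cost_distance(
    surface: RasterGrid,
    sources,
    targets: np.ndarray | None = None,
) -> CostResult:
    """Multi-source least accumulated resistance to every cell (Dijkstra).

    ``sources`` may be a PatchSet, a Patch, a boolean mask, or an iterable of
    ``(row, col)`` cells; all source cells start at cost 0. Nodata cells are
    impassable. If a boolean ``targets`` mask is given the search stops as
    soon as the cheapest target cell is settled (early exit for single-pair
    corridor queries). Equal-cost ties resolve toward the geometrically
    shorter path, then by cell index — the result is deterministic.
    """
    res = surface.values.astype(float)
    nod = surface.nodata_mask()
    nrows, ncols = res.shape
    cells = _as_source_cells(sources, res.shape)
    if not cells:
        raise ValueError("empty source set")
    for r, c in cells:
        if nod[r, c]:
            raise ValueError(f"source cell ({r}, {c}) lies on nodata")
    cs = surface.cell_size
    sqrt2 = math.sqrt(2.0)
    n = nrows * ncols
    cost = np.full(n, np.inf)
    length = np.full(n, np.inf)
    back = np.full(n, -1, dtype=np.int8)
    resf = res.ravel()
    nodf = nod.ravel()
    heap: list[tuple[float, float, int]] = []
    for r, c in cells:
        i = r * ncols + c
        cost[i] = 0.0
        length[i] = 0.0
        heapq.heappush(heap, (0.0, 0.0, i))
    target_flat = None
    if targets is not None:
        target_flat = targets.ravel()
    offs = [(dr * ncols + dc, dr, dc, cs * (sqrt2 if _DIAG[k] else 1.0), (k + 4) % 8)
            for k, (dr, dc) in enumerate(NEIGHBOURS)]
    while heap:
        cu, lu, u = heapq.heappop(heap)
        if cu > cost[u] or (cu == cost[u] and lu > length[u]):
            continue
        if target_flat is not None and target_flat[u]:
            break
        ru, col_u = divmod(u, ncols)
        half_ru = resf[u]
        for doff, dr, dc, dist, backcode in offs:
            nr, ncol = ru + dr, col_u + dc
            if not (0 <= nr < nrows and 0 <= ncol < ncols):
                continue
            v = u + doff
            if nodf[v]:
                continue
            w = dist * (half_ru + resf[v]) / 2.0
            ncost = cu + w
            nlen = lu + dist
            if ncost < cost[v] or (ncost == cost[v] and nlen < length[v]):
                cost[v] = ncost
                length[v] = nlen
                back[v] = backcode
                heapq.heappush(heap, (ncost, nlen, v))
    return CostResult(
        cost.reshape(nrows, ncols),
        back.reshape(nrows, ncols),
        length.reshape(nrows, ncols),
        cs,
        surface.origin,
    )


def trace_path(result: CostResult, row: int, col: int) -> list[tuple[int, int]]:
    """Follow backlinks from a cell to the nearest source (inclusive)."""
    chain = [(row, col)]
    r, c = row, col
    guard = result.cost.size + 1
    while result.backlink[r, c] >= 0:
        dr, dc = NEIGHBOURS[result.backlink[r, c]]
        r, c = r + dr, c + dc
        chain.append((r, c))
        guard -= 1
        if guard == 0:
            raise RuntimeError("backlink trace did not terminate")
    return chain[::-1]


def least_cost_path(surface: RasterGrid, patch_a: Patch, patch_b: Patch) -> Corridor:
    """The least accumulated-resistance corridor between two patches.

    All cells of each patch act as zero-cost sources/destinations; the
    corridor realizes the minimum cost between any pair of member cells.
    """
    if not patch_a.mask.any() or not patch_b.mask.any():
        raise ValueError("both patches must contain at least one cell")
    result = cost_distance(surface, patch_a, targets=patch_b.mask)
    costs_b = np.where(patch_b.mask, result.cost, np.inf)
    i = int(np.argmin(costs_b.ravel()))
    if not np.isfinite(costs_b.ravel()[i]):
        raise ValueError(f"patches {patch_a.id} and {patch_b.id} are not reachable")
    r, c = divmod(i, surface.ncols)
    chain = trace_path(result, r, c)
    return Corridor(
        a=patch_a.id,
        b=patch_b.id,
        chain=chain,
        cost=float(result.cost[r, c]),
        length=float(result.length[r, c]),
    )


def corridor_network(surface: RasterGrid, patches: PatchSet) -> CorridorSet:
    """Least-cost corridor for every unordered patch pair, plus L_max.

    One Dijkstra per patch serves all pairs involving it. Unreachable pairs
    are reported as missing with a warning and excluded from L_max.
    """
    if len(patches) < 2:
        raise ValueError("need at least two patches for a corridor network")
    plist = sorted(patches.patches, key=lambda p: p.id)
    corridors: dict[tuple[int, int], Corridor] = {}
    missing: list[tuple[int, int]] = []
    for i, pa in enumerate(plist[:-1]):
        result = cost_distance(surface, pa)
        for pb in plist[i + 1 :]:
            costs_b = np.where(pb.mask, result.cost, np.inf)
            j = int(np.argmin(costs_b.ravel()))
            key = (min(pa.id, pb.id), max(pa.id, pb.id))
            if not np.isfinite(costs_b.ravel()[j]):
                warnings.warn(f"patch pair {key} unreachable; corridor skipped")
                missing.append(key)
                continue
            r, c = divmod(j, surface.ncols)
            chain = trace_path(result, r, c)
            corridors[key] = Corridor(
                a=key[0],
                b=key[1],
                chain=chain,
                cost=float(result.cost[r, c]),
                length=float(result.length[r, c]),
            )
    return CorridorSet(corridors, missing)


def corridors_to_geojson(cset: CorridorSet, grid: RasterGrid, scores=None) -> dict:
    """CorridorSet as GeoJSON LineStrings; optional {pair: G_norm} scores."""
    feats = []
    for key in sorted(cset.corridors):
        cor = cset.corridors[key]
        rc = np.array(cor.chain)
        x, y = grid.cell_center(rc[:, 0], rc[:, 1])
        props = {"a": cor.a, "b": cor.b, "L_ab": cor.cost, "length_m": cor.length}
        if scores is not None and key in scores:
            props["G_norm"] = scores[key]
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(a), float(b)] for a, b in zip(x, y)],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}
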