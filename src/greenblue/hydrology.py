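"""Blue-corridor identification from a DEM.

The classical single-flow-direction toolchain: depression filling
(priority-flood with an epsilon gradient), D8 flow direction, flow
accumulation, stream extraction by accumulation threshold, and
mainstream/tributary/runoff classification of the traced channels.

Neighbour convention
--------------------
The 8 neighbours are coded 0..7 **clockwise starting east** in array space
(row 0 at the top): E, SE, S, SW, W, NW, N, NE. Ties in the steepest-descent
choice resolve to the lowest code. ``OUTLET`` (−1) marks cells draining off
the grid (or into nodata); ``UNDEFINED`` (−2) marks nodata cells.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .raster import RasterGrid

__all__ = [
    "FlowField",
    "StreamSegment",
    "StreamNetwork",
    "fill_sinks",
    "flow_direction_d8",
    "flow_accumulation",
    "extract_streams",
    "classify_streams",
    "NEIGHBOURS",
    "OUTLET",
    "UNDEFINED",
]

# clockwise from east: E SE S SW W NW N NE
NEIGHBOURS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_DIAG = (False, True, False, True, False, True, False, True)
OUTLET = -1
UNDEFINED = -2

MAINSTREAM = "mainstream"
TRIBUTARY = "tributary"
RUNOFF = "runoff"


@dataclass
class FlowField:
    """D8 direction codes plus upstream-cell counts on a common grid."""

    direction: np.ndarray  # int8 codes 0..7, OUTLET, UNDEFINED
    accumulation: np.ndarray | None = None  # upstream cell count, excl. self
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.direction.shape

    def downstream(self, row: int, col: int) -> tuple[int, int] | None:
        code = self.direction[row, col]
        if code < 0:
            return None
        dr, dc = NEIGHBOURS[code]
        nr, nc = row + dr, col + dc
        if not (0 <= nr < self.shape[0] and 0 <= nc < self.shape[1]):
            return None
        return nr, nc


@dataclass
class StreamSegment:
    cells: list[tuple[int, int]]  # ordered upstream -> downstream
    order: int = 1  # Strahler
    label: str = TRIBUTARY
    max_accumulation: int = 0


@dataclass
class StreamNetwork:
    segments: list[StreamSegment]
    shape: tuple[int, int]
    threshold: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def mask(self, labels: tuple[str, ...] | None = None) -> np.ndarray:
        """Boolean raster of stream cells, optionally restricted to labels."""
        m = np.zeros(self.shape, dtype=bool)
        for seg in self.segments:
            if labels is None or seg.label in labels:
                for r, c in seg.cells:
                    m[r, c] = True
        return m

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def fill_sinks(dem: RasterGrid, eps_factor: float = 1e-6) -> RasterGrid:
    """Remove closed depressions by priority-flood filling.

    Water must be able to leave every cell: the output is everywhere >= the
    input, cells outside depressions are unchanged, and filled flats receive
    a tiny monotone gradient of ``eps_factor * cell_size`` per step toward
    the spill point so that D8 directions are defined everywhere.
    """
    z = dem.values.astype(float)
    nod = dem.nodata_mask()
    if nod.all():
        raise ValueError("cannot fill an all-nodata DEM")
    nrows, ncols = z.shape
    eps = eps_factor * dem.cell_size
    filled = z.copy()
    visited = nod.copy()
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    # seed: boundary cells and cells adjacent to nodata (they drain off-grid)
    for r in range(nrows):
        for c in range(ncols):
            if nod[r, c]:
                continue
            edge = r in (0, nrows - 1) or c in (0, ncols - 1)
            if not edge:
                for dr, dc in NEIGHBOURS:
                    if nod[r + dr, c + dc]:
                        edge = True
                        break
            if edge:
                heapq.heappush(heap, (filled[r, c], counter, r, c))
                counter += 1
                visited[r, c] = True
    while heap:
        zc, _, r, c = heapq.heappop(heap)
        for dr, dc in NEIGHBOURS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and not visited[nr, nc]:
                visited[nr, nc] = True
                filled[nr, nc] = max(z[nr, nc], zc + eps)
                heapq.heappush(heap, (filled[nr, nc], counter, nr, nc))
                counter += 1
    out = dem.copy(values=filled)
    out.values[nod] = dem.nodata
    return out


def flow_direction_d8(filled: RasterGrid) -> FlowField:
    """Steepest-descent D8 directions on a depression-free DEM.

    Each cell points to the neighbour maximising drop/distance (distance =
    cell size orthogonally, cell size × √2 diagonally). Boundary (or
    nodata-adjacent) cells with no lower neighbour are outlets. A flat
    interior cell means the DEM was not filled — an error instructs to fill.
    """
    z = filled.values.astype(float)
    nod = filled.nodata_mask()
    nrows, ncols = z.shape
    cs = filled.cell_size
    zpad = np.pad(np.where(nod, np.inf, z), 1, constant_values=np.inf)
    grads = np.empty((8, nrows, ncols))
    for k, (dr, dc) in enumerate(NEIGHBOURS):
        zn = zpad[1 + dr : 1 + dr + nrows, 1 + dc : 1 + dc + ncols]
        dist = cs * (np.sqrt(2.0) if _DIAG[k] else 1.0)
        with np.errstate(invalid="ignore"):
            grads[k] = (z - zn) / dist
    grads[:, nod] = -np.inf
    best = np.argmax(grads, axis=0).astype(np.int8)  # first max wins the tie
    bestval = np.take_along_axis(grads, best[None].astype(int), axis=0)[0]
    direction = best.copy()
    no_drop = ~(bestval > 0)
    # off-grid / nodata-adjacent cells with no lower neighbour drain outward
    zpad_nodata = np.pad(nod, 1, constant_values=True)
    touches_edge = np.zeros((nrows, ncols), dtype=bool)
    for dr, dc in NEIGHBOURS:
        touches_edge |= zpad_nodata[1 + dr : 1 + dr + nrows, 1 + dc : 1 + dc + ncols]
    direction[no_drop & touches_edge] = OUTLET
    direction[nod] = UNDEFINED
    stuck = no_drop & ~touches_edge & ~nod
    if stuck.any():
        r, c = np.argwhere(stuck)[0]
        raise ValueError(
            f"flat undrained region at cell ({r}, {c}); run fill_sinks on the DEM first"
        )
    return FlowField(direction, None, cs, filled.origin)


def flow_accumulation(fieldf: FlowField) -> FlowField:
    """Count, per cell, the upstream cells draining through it (self excluded).

    Raises on cycles in the direction grid (the signature of an unfilled DEM).
    """
    direction = fieldf.direction
    nrows, ncols = direction.shape
    n = nrows * ncols
    downstream = np.full(n, -1, dtype=np.int64)
    valid = np.zeros(n, dtype=bool)
    flat = direction.ravel()
    for k, (dr, dc) in enumerate(NEIGHBOURS):
        idx = np.flatnonzero(flat == k)
        rr, cc = idx // ncols, idx % ncols
        downstream[idx] = (rr + dr) * ncols + (cc + dc)
    valid = flat >= 0
    valid |= flat == OUTLET
    acc = np.zeros(n, dtype=np.int64)
    indeg = np.zeros(n, dtype=np.int64)
    has_down = downstream >= 0
    np.add.at(indeg, downstream[has_down], 1)
    stack = list(np.flatnonzero((indeg == 0) & valid))
    processed = 0
    while stack:
        u = stack.pop()
        processed += 1
        d = downstream[u]
        if d >= 0:
            acc[d] += acc[u] + 1
            indeg[d] -= 1
            if indeg[d] == 0:
                stack.append(d)
    if processed < int(valid.sum()):
        raise ValueError("cycle detected in flow directions; fill the DEM first")
    acc_grid = acc.reshape(nrows, ncols)
    acc_grid[direction == UNDEFINED] = 0
    return replace(fieldf, accumulation=acc_grid)


def extract_streams(
    fieldf: FlowField,
    threshold: int,
    runoff_threshold: int | None = None,
) -> StreamNetwork:
    """Trace channels where flow accumulation reaches ``threshold`` cells.

    If ``runoff_threshold`` (< threshold) is given, channels are traced from
    that lower bar as well; segments never reaching the stream threshold are
    later labelled runoff by :func:`classify_streams`. Channel cells are
    chained into polyline segments broken at confluences, and each segment
    carries its Strahler order.
    """
    if threshold < 1:
        raise ValueError("stream threshold must be >= 1")
    if fieldf.accumulation is None:
        raise ValueError("flow accumulation missing; run flow_accumulation first")
    trace_at = threshold if runoff_threshold is None else min(threshold, runoff_threshold)
    acc = fieldf.accumulation
    direction = fieldf.direction
    nrows, ncols = acc.shape
    mask = (acc >= trace_at) & (direction != UNDEFINED)
    if not mask.any():
        warnings.warn("threshold exceeds maximum accumulation; empty stream network")
        return StreamNetwork([], (nrows, ncols), threshold, fieldf.cell_size, fieldf.origin)

    in_deg = np.zeros((nrows, ncols), dtype=np.int64)
    for r, c in np.argwhere(mask):
        d = fieldf.downstream(r, c)
        if d is not None and mask[d]:
            in_deg[d] += 1
    starts = [
        (int(r), int(c))
        for r, c in np.argwhere(mask)
        if in_deg[r, c] == 0 or in_deg[r, c] >= 2
    ]
    starts.sort()
    segments: list[StreamSegment] = []
    seg_at_start: dict[tuple[int, int], int] = {}
    for start in starts:
        cells = [start]
        cur = start
        while True:
            d = fieldf.downstream(*cur)
            if d is None or not mask[d]:
                break
            if in_deg[d] >= 2:  # confluence cell opens the next segment
                break
            cells.append(d)
            cur = d
        seg = StreamSegment(cells=cells, max_accumulation=int(max(acc[r, c] for r, c in cells)))
        seg_at_start[start] = len(segments)
        segments.append(seg)

    # Strahler order: topological pass over the segment graph
    children: dict[int, list[int]] = {i: [] for i in range(len(segments))}
    for i, seg in enumerate(segments):
        d = fieldf.downstream(*seg.cells[-1])
        if d is not None and mask[d] and d in seg_at_start:
            children[seg_at_start[d]].append(i)
    resolved = [False] * len(segments)

    def _order(i: int) -> int:
        if resolved[i]:
            return segments[i].order
        ups = [_order(j) for j in children[i]]
        if not ups:
            o = 1
        else:
            top = max(ups)
            o = top + 1 if ups.count(top) >= 2 else top
        segments[i].order = o
        resolved[i] = True
        return o

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(segments) * 4 + 100))
    try:
        for i in range(len(segments)):
            _order(i)
    finally:
        sys.setrecursionlimit(old)
    net = StreamNetwork(segments, (nrows, ncols), threshold, fieldf.cell_size, fieldf.origin)
    return classify_streams(net, main_threshold=None)


def classify_streams(net: StreamNetwork, main_threshold: int | None) -> StreamNetwork:
    """Label segments mainstream / tributary / runoff by peak accumulation.

    A segment whose maximum accumulation reaches ``main_threshold`` is a
    mainstream; one reaching the network's stream threshold is a tributary;
    traced channels below that (from a runoff trace) are runoff. With
    ``main_threshold=None`` no segment is promoted to mainstream.
    """
    if main_threshold is not None and not net.segments:
        raise ValueError("cannot classify an empty stream network")
    for seg in net.segments:
        if main_threshold is not None and seg.max_accumulation >= main_threshold:
            seg.label = MAINSTREAM
        elif seg.max_accumulation >= net.threshold:
            seg.label = TRIBUTARY
        else:
            seg.label = RUNOFF
    return net


def network_to_geojson(net: StreamNetwork, grid: RasterGrid) -> dict:
    """Stream polylines as GeoJSON LineStrings in world coordinates."""
    feats = []
    for seg in net.segments:
        rc = np.array(seg.cells)
        x, y = grid.cell_center(rc[:, 0], rc[:, 1])
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(a), float(b)] for a, b in zip(x, y)],
                },
                "properties": {
                    "order": seg.order,
                    "label": seg.label,
                    "max_accumulation": seg.max_accumulation,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
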