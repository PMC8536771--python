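"""Ecological-node (saddle) detection.

An ecological node sits where a least-cost corridor squeezes through a pass:
the point is simultaneously on a corridor (a local minimum of cost across
the corridor) and on a ridge of the cost surface (a local maximum along the
divide) — a minimum–maximum saddle. Ridges are found by running the
hydrological toolchain on the **negated** surface: valley lines of −s are
ridge lines of s. Raw corridor–ridge intersections within a merge radius
collapse to a single node at their centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import hydrology
from .hydrology import StreamNetwork
from .network import EcoNetwork
from .raster import RasterGrid

__all__ = ["Node", "NodeSet", "ridge_network", "identify_nodes"]


@dataclass
class Node:
    x: float
    y: float
    corridors: list[tuple[int, int]]  # endpoint pairs of corridors through the node
    resistance: float  # surface value at the node cell
    cluster_size: int  # raw intersections merged into this node


@dataclass
class NodeSet:
    nodes: list[Node]

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def to_geojson(self, path: str | Path | None = None) -> dict:
        obj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [n.x, n.y]},
                    "properties": {
                        "corridors": [list(k) for k in n.corridors],
                        "resistance": n.resistance,
                        "cluster_size": n.cluster_size,
                    },
                }
                for n in self.nodes
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, sort_keys=True))
        return obj


def ridge_network(
    surface: RasterGrid,
    threshold: int | None = None,
    runoff_threshold: int | None = None,
) -> StreamNetwork:
    """Ridge lines of a surface via stream extraction on its negation.

    ``threshold`` defaults to 0.2% of the grid's cell count — deliberately
    lower than the stream-extraction default. A saddle is the watershed
    divide of its own crest line, so crest accumulation is smallest exactly
    at the points the node analysis cares about; a high bar would truncate
    the ridge just there.
    """
    neg = surface.copy(values=np.where(surface.nodata_mask(), surface.nodata, -surface.values.astype(float)))
    if threshold is None:
        threshold = max(5, surface.values.size // 500)
    filled = hydrology.fill_sinks(neg)
    fieldf = hydrology.flow_direction_d8(filled)
    fieldf = hydrology.flow_accumulation(fieldf)
    return hydrology.extract_streams(fieldf, threshold, runoff_threshold)


def identify_nodes(
    ridges: StreamNetwork,
    final: EcoNetwork,
    surface: RasterGrid,
    merge_radius: float | None = None,
) -> NodeSet:
    """Corridor ∩ ridge intersections merged into nodes.

    A corridor cell within one cell (Chebyshev) of a ridge cell is a raw
    intersection; intersections closer than ``merge_radius`` (metres;
    default 10 cells) merge into one node placed at the cluster member
    nearest the cluster centroid — so a node always sits exactly on a
    corridor cell. Each node records the corridors passing through its
    cluster, the surface value at its cell, and the cluster size.
    """
    if not final.links:
        raise ValueError("final network has no corridors")
    if merge_radius is None:
        merge_radius = 10.0 * surface.cell_size
    rmask = ridges.mask()
    near_ridge = ndimage.binary_dilation(rmask, structure=np.ones((3, 3), bool))
    raw: list[tuple[int, int, tuple[int, int]]] = []  # (row, col, corridor key)
    for link in final.links:
        for r, c in link.corridor.chain:
            if near_ridge[r, c]:
                raw.append((r, c, link.key))
    if not raw:
        return NodeSet([])
    pts = np.array([[r, c] for r, c, _ in raw], dtype=float)
    xy = np.column_stack(surface.cell_center(pts[:, 0], pts[:, 1]))
    tree = cKDTree(xy)
    pairs = tree.query_pairs(merge_radius)
    parent = list(range(len(raw)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(raw)):
        clusters.setdefault(find(i), []).append(i)
    nodes = []
    for members in sorted(clusters.values(), key=lambda m: min(m)):
        cx = float(xy[members, 0].mean())
        cy = float(xy[members, 1].mean())
        # snap to the member cell nearest the centroid
        d2 = (xy[members, 0] - cx) ** 2 + (xy[members, 1] - cy) ** 2
        snap = members[int(np.argmin(d2))]
        rr, cc, _ = raw[snap]
        keys = sorted({raw[m][2] for m in members})
        nodes.append(
            Node(
                x=float(xy[snap, 0]),
                y=float(xy[snap, 1]),
                corridors=keys,
                resistance=float(surface.values[rr, cc]),
                cluster_size=len(members),
            )
        )
    nodes.sort(key=lambda n: (n.x, n.y))
    return NodeSet(nodes)
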