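"""Green protection area (GPA) patches.

A :class:`PatchSet` holds the habitat patches that act as the vertices of the
ecological network and as least-cost sources/destinations. Patches are stored
as boolean masks aligned with the reference grid; areas are in m², the study
area total ``A`` is the full grid area by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .raster import RasterGrid

__all__ = ["Patch", "PatchSet"]


@dataclass
class Patch:
    id: int
    mask: np.ndarray  # boolean, aligned with the reference grid
    area: float  # m²
    centroid: tuple[float, float]  # world (x, y)
    resistance: float | None = None  # mean interior resistance P (gravity model)

    @property
    def cells(self) -> np.ndarray:
        return np.argwhere(self.mask)


@dataclass
class PatchSet:
    patches: list[Patch]
    total_area: float  # study-area total A in m²
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patches]
        if len(set(ids)) != len(ids):
            raise ValueError("patch ids must be unique")
        for p in self.patches:
            if not p.area > 0:
                raise ValueError(f"patch {p.id} has non-positive area")
        if self.total_area <= 0:
            raise ValueError("study area A must be positive")

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def __getitem__(self, pid: int) -> Patch:
        for p in self.patches:
            if p.id == pid:
                return p
        raise KeyError(f"no patch with id {pid}")

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self.patches]

    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.patches])

    def subset(self, ids) -> "PatchSet":
        ids = set(ids)
        return PatchSet(
            [p for p in self.patches if p.id in ids],
            self.total_area,
            self.cell_size,
            self.origin,
        )

    # ------------------------------------------------------------------
    def grid_shape(self) -> tuple[int, int]:
        return self.patches[0].mask.shape

    def boundary_cells(self, patch: Patch) -> np.ndarray:
        """(row, col) array of the patch's boundary cells."""
        er = ndimage.binary_erosion(patch.mask, border_value=0)
        b = patch.mask & ~er
        if not b.any():
            b = patch.mask
        return np.argwhere(b)

    def distance_matrix(self) -> np.ndarray:
        """Minimum edge-to-edge Euclidean distance (m) between patch boundaries.

        Distances are between boundary cell centres; the diagonal is 0.
        """
        n = len(self.patches)
        pts = []
        for p in self.patches:
            rc = self.boundary_cells(p)
            x = (rc[:, 1] + 0.5) * self.cell_size
            y = (self.grid_shape()[0] - rc[:, 0] - 0.5) * self.cell_size
            pts.append(np.column_stack([x, y]))
        d = np.zeros((n, n))
        trees = [cKDTree(p) for p in pts]
        for i in range(n):
            for j in range(i + 1, n):
                dd, _ = trees[j].query(pts[i])
                d[i, j] = d[j, i] = float(dd.min())
        return d

    def attach_resistance(self, surface: RasterGrid) -> None:
        """Set each patch's P to the mean resistance of its interior cells."""
        for p in self.patches:
            vals = surface.values[p.mask & ~surface.nodata_mask()]
            if vals.size == 0:
                raise ValueError(f"patch {p.id} has no valid resistance cells")
            p.resistance = float(np.mean(vals))

    # ------------------------------------------------------------------
    def to_geojson(self, path: str | Path) -> None:
        feats = []
        for p in self.patches:
            rc = p.cells
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": list(p.centroid)},
                    "properties": {
                        "id": p.id,
                        "area_m2": p.area,
                        "resistance": p.resistance,
                        "cells": [[int(r), int(c)] for r, c in rc],
                    },
                }
            )
        obj = {
            "type": "FeatureCollection",
            "features": feats,
            "properties": {
                "total_area_m2": self.total_area,
                "cell_size": self.cell_size,
                "origin": list(self.origin),
                "grid_shape": list(self.grid_shape()),
            },
        }
        Path(path).write_text(json.dumps(obj, sort_keys=True))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "PatchSet":
        obj = json.loads(Path(path).read_text())
        meta = obj["properties"]
        shape = tuple(meta["grid_shape"])
        patches = []
        for f in obj["features"]:
            props = f["properties"]
            mask = np.zeros(shape, dtype=bool)
            rc = np.array(props["cells"], dtype=int)
            mask[rc[:, 0], rc[:, 1]] = True
            patches.append(
                Patch(
                    id=int(props["id"]),
                    mask=mask,
                    area=float(props["area_m2"]),
                    centroid=tuple(f["geometry"]["coordinates"]),
                    resistance=props.get("resistance"),
                )
            )
        return cls(patches, meta["total_area_m2"], meta["cell_size"], tuple(meta["origin"]))
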