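"""Synthetic landscapes with known ground truth.

Real provincial inputs for this kind of analysis are a DEM and a land-use
raster; here both are generated with planted structure so every pipeline
stage can be tested against a known answer: a tilted base plane carries
Gaussian-profile ridges and incised valleys, and a cross-valley slope term
(elevation growing with distance from the nearest valley centreline) makes
the planted valleys the landscape's actual drainage system, as in real
dissected terrain. Seeded white noise smoothed by one 3×3 mean pass sits
on top, land-use
categories follow elevation bands with seeded per-cell jitter, water is
forced along valley centrelines, and disc-shaped low-resistance patches
(the green protection areas) are placed on the forest band with a minimum
pairwise separation.

Everything is deterministic under the :class:`LandscapeSpec` integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .patches import Patch, PatchSet
from .raster import RasterGrid

__all__ = [
    "LandscapeSpec",
    "GroundTruth",
    "SyntheticLandscape",
    "make_dem",
    "make_landuse",
    "make_patches",
    "generate",
    "preset",
    "LANDUSE_CODES",
    "DEFAULT_RESISTANCE",
]

# land-use category codes and an example resistance assignment; the
# resistance table is a user input, these defaults just make the synthetic
# pipeline self-contained
LANDUSE_CODES = {"water": 1, "forest": 2, "grassland": 3, "cropland": 4, "urban": 5, "bare": 6}
DEFAULT_RESISTANCE = {1: 30.0, 2: 1.0, 3: 10.0, 4: 50.0, 5: 300.0, 6: 100.0}


@dataclass
class Ridge:
    start: tuple[float, float]  # (row, col)
    end: tuple[float, float]
    height: float  # m
    width: float  # Gaussian sigma in cells


@dataclass
class Valley:
    polyline: list[tuple[float, float]]  # (row, col) vertices
    depth: float  # incision depth, m
    width: float  # Gaussian sigma of the incision, cells


@dataclass
class LandscapeSpec:
    nrows: int = 200
    ncols: int = 200
    cell_size: float = 30.0  # m
    base_elevation: float = 500.0  # m at cell (0, 0)
    tilt: tuple[float, float] = (-0.5, -0.05)  # m per cell along (row, col)
    # dissected-terrain cross slope: metres of extra elevation per cell of
    # distance to the nearest valley centreline (0 with no valleys); makes
    # the planted valleys the landscape's actual drainage system
    cross_slope: float = 3.0
    ridges: list[Ridge] = field(default_factory=list)
    valleys: list[Valley] = field(default_factory=list)
    noise_amplitude: float = 5.0  # m, before the 3x3 smoothing pass
    # land-use bands on min-max normalized elevation: (upper fraction, code)
    bands: list[tuple[float, int]] = field(
        default_factory=lambda: [
            (0.15, LANDUSE_CODES["urban"]),
            (0.30, LANDUSE_CODES["cropland"]),
            (0.80, LANDUSE_CODES["forest"]),
            (0.92, LANDUSE_CODES["grassland"]),
            (1.00, LANDUSE_CODES["bare"]),
        ]
    )
    jitter_rate: float = 0.05  # fraction of cells with a random category
    patch_count: int = 6
    patch_radius: tuple[int, int] = (4, 7)  # cells
    patch_separation: float = 40.0  # min centre distance, cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise ValueError("landscape must be at least 2x2")
        fracs = [f for f, _ in self.bands]
        if fracs != sorted(fracs) or len(set(fracs)) != len(fracs):
            raise ValueError("land-use bands must have strictly increasing thresholds")
        if abs(fracs[-1] - 1.0) > 1e-9:
            raise ValueError("land-use bands must cover the elevation range (last threshold 1.0)")
        if self.patch_separation <= 2 * self.patch_radius[1]:
            raise ValueError("patch separation must exceed twice the maximum radius")


@dataclass
class GroundTruth:
    valley_mask: np.ndarray  # rasterized valley centrelines
    ridge_mask: np.ndarray  # rasterized ridge crests
    saddles: list[tuple[int, int]]  # local crest-elevation minima
    patch_centres: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SyntheticLandscape:
    spec: LandscapeSpec
    dem: RasterGrid
    landuse: RasterGrid
    patches: PatchSet
    truth: GroundTruth


def _rasterize_polyline(points, shape) -> list[tuple[int, int]]:
    """Dense cell chain along a polyline given as fractional (row, col)."""
    cells: list[tuple[int, int]] = []
    pts = [np.asarray(p, dtype=float) for p in points]
    for p0, p1 in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.ceil(np.abs(p1 - p0).max() * 4)))
        for t in np.linspace(0.0, 1.0, n):
            r, c = np.round(p0 + t * (p1 - p0)).astype(int)
            r = int(np.clip(r, 0, shape[0] - 1))
            c = int(np.clip(c, 0, shape[1] - 1))
            if not cells or cells[-1] != (r, c):
                cells.append((r, c))
    # drop revisits while keeping order
    seen = set()
    out = []
    for rc in cells:
        if rc not in seen:
            seen.add(rc)
            out.append(rc)
    return out


def _line_distance_field(cells, shape) -> np.ndarray:
    """Distance (in cells) from every cell to the rasterized line."""
    m = np.zeros(shape, dtype=bool)
    for r, c in cells:
        m[r, c] = True
    return ndimage.distance_transform_edt(~m)


def make_dem(spec: LandscapeSpec) -> tuple[RasterGrid, GroundTruth]:
    """Compose the DEM and record ground-truth masks from the analytic parts.

    DEM = tilted plane + Gaussian-profile ridges − valley incisions
    + cross-valley slope + seeded smoothed noise. Masks come from the
    analytic components *before* noise.
    """
    shape = (spec.nrows, spec.ncols)
    rows, cols = np.meshgrid(np.arange(spec.nrows), np.arange(spec.ncols), indexing="ij")
    z = spec.base_elevation + spec.tilt[0] * rows + spec.tilt[1] * cols
    z = z.astype(float)

    ridge_mask = np.zeros(shape, dtype=bool)
    for ridge in spec.ridges:
        cells = _rasterize_polyline([ridge.start, ridge.end], shape)
        for r, c in cells:
            ridge_mask[r, c] = True
        dist = _line_distance_field(cells, shape)
        z += ridge.height * np.exp(-(dist**2) / (2 * ridge.width**2))

    valley_mask = np.zeros(shape, dtype=bool)
    dist_nearest = None
    for valley in spec.valleys:
        cells = _rasterize_polyline(valley.polyline, shape)
        for r, c in cells:
            valley_mask[r, c] = True
        dist = _line_distance_field(cells, shape)
        z -= valley.depth * np.exp(-(dist**2) / (2 * valley.width**2))
        dist_nearest = dist if dist_nearest is None else np.minimum(dist_nearest, dist)
    if dist_nearest is not None and spec.cross_slope > 0:
        z += spec.cross_slope * dist_nearest

    # saddles: strict local minima of the analytic elevation along each crest
    saddles: list[tuple[int, int]] = []
    for ridge in spec.ridges:
        cells = _rasterize_polyline([ridge.start, ridge.end], shape)
        elev = [z[r, c] for r, c in cells]
        for i in range(1, len(cells) - 1):
            if elev[i] < elev[i - 1] and elev[i] < elev[i + 1]:
                saddles.append(cells[i])

    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed + 1)
        noise = rng.uniform(-spec.noise_amplitude, spec.noise_amplitude, size=shape)
        noise = ndimage.uniform_filter(noise, size=3, mode="nearest")
        z += noise

    dem = RasterGrid(z, spec.cell_size)
    return dem, GroundTruth(valley_mask, ridge_mask, saddles)


def make_landuse(dem: RasterGrid, spec: LandscapeSpec, truth: GroundTruth | None = None) -> RasterGrid:
    """Elevation-banded categories with seeded jitter; water on valley lines."""
    z = dem.values.astype(float)
    zmin, zmax = z.min(), z.max()
    frac = (z - zmin) / (zmax - zmin) if zmax > zmin else np.zeros_like(z)
    codes = np.empty(dem.shape, dtype=np.int32)
    codes.fill(spec.bands[-1][1])
    for upper, code in reversed(spec.bands):
        codes[frac <= upper + 1e-12] = code
    if spec.jitter_rate > 0:
        rng = np.random.default_rng(spec.seed + 2)
        flip = rng.random(dem.shape) < spec.jitter_rate
        options = np.array([code for _, code in spec.bands], dtype=np.int32)
        codes[flip] = rng.choice(options, size=int(flip.sum()))
    if truth is not None:
        codes[truth.valley_mask] = LANDUSE_CODES["water"]
    return RasterGrid(codes, dem.cell_size, dem.origin, nodata=-9999)


def make_patches(
    spec: LandscapeSpec,
    allowed_mask: np.ndarray | None = None,
    max_tries: int = 2000,
) -> PatchSet:
    """Place disc-shaped GPA patches with a minimum pairwise separation.

    Centres come from seeded best-candidate (blue-noise) sampling on the
    allowed mask (e.g. the forest band): each new patch picks, among a pool
    of valid random candidates, the one farthest from the patches already
    placed. This emulates reserves spread evenly across a region rather
    than clumped. A candidate is valid when its disc stays on the grid, its
    centre lies in the allowed area, and it keeps the separation distance
    from every accepted centre. Raises after ``max_tries`` draws, reporting
    how many patches were placed.
    """
    shape = (spec.nrows, spec.ncols)
    rng = np.random.default_rng(spec.seed + 3)
    if allowed_mask is None:
        allowed_mask = np.ones(shape, dtype=bool)
    centres: list[tuple[int, int]] = []
    radii: list[int] = []
    tries = 0
    pool_size = 16
    rmin, rmax = spec.patch_radius
    while len(centres) < spec.patch_count:
        pool: list[tuple[int, int, int]] = []
        while len(pool) < pool_size and tries < max_tries:
            tries += 1
            radius = int(rng.integers(rmin, rmax + 1))
            r = int(rng.integers(radius, spec.nrows - radius))
            c = int(rng.integers(radius, spec.ncols - radius))
            if not allowed_mask[r, c]:
                continue
            if any(np.hypot(r - rr, c - cc) < spec.patch_separation for rr, cc in centres):
                continue
            pool.append((r, c, radius))
        if not pool:
            raise RuntimeError(
                f"could not place {spec.patch_count} patches after {max_tries} tries "
                f"(placed {len(centres)}); relax separation or enlarge the landscape"
            )
        if centres:
            def spread(cand):
                return min(np.hypot(cand[0] - rr, cand[1] - cc) for rr, cc in centres)
            pool.sort(key=lambda cand: (-spread(cand), cand))
        r, c, radius = pool[0]
        centres.append((r, c))
        radii.append(radius)
    rows, cols = np.meshgrid(np.arange(spec.nrows), np.arange(spec.ncols), indexing="ij")
    patches = []
    for i, ((r, c), radius) in enumerate(zip(centres, radii), start=1):
        mask = (rows - r) ** 2 + (cols - c) ** 2 <= radius**2
        x = (c + 0.5) * spec.cell_size
        y = (spec.nrows - r - 0.5) * spec.cell_size
        patches.append(
            Patch(
                id=i,
                mask=mask,
                area=float(mask.sum()) * spec.cell_size**2,
                centroid=(x, y),
            )
        )
    total = spec.nrows * spec.ncols * spec.cell_size**2
    return PatchSet(patches, total, spec.cell_size)


def generate(spec: LandscapeSpec) -> SyntheticLandscape:
    """Full fixture bundle: DEM, land use, patches and ground truth."""
    dem, truth = make_dem(spec)
    landuse = make_landuse(dem, spec, truth)
    forest = landuse.values == LANDUSE_CODES["forest"]
    # keep patch centres clear of planted valleys so GPAs sit on dry land
    clear = ndimage.distance_transform_edt(~truth.valley_mask) > spec.patch_radius[1] + 2
    patches = make_patches(spec, allowed_mask=forest & clear)
    truth.patch_centres = [
        tuple(map(int, np.argwhere(p.mask).mean(axis=0).round())) for p in patches
    ]
    return SyntheticLandscape(spec, dem, landuse, patches, truth)


def preset(name: str, seed: int = 0, **overrides) -> LandscapeSpec:
    """Named study-condition presets.

    ``two-valleys-six-patches`` — the standard 200×200 fixture: two incised
    valleys draining to the southern edge, one dividing ridge, six forest
    patches, noise ≈ 3% of relief.  ``mini`` — an 80×80, one-valley,
    four-patch variant for quick runs.
    """
    if name == "two-valleys-six-patches":
        spec = LandscapeSpec(
            nrows=200,
            ncols=200,
            ridges=[Ridge(start=(0.0, 100.0), end=(199.0, 100.0), height=40.0, width=8.0)],
            valleys=[
                Valley(
                    polyline=[(10.0, 55.0), (100.0, 60.0), (199.0, 65.0)],
                    depth=25.0,
                    width=3.0,
                ),
                Valley(
                    polyline=[(10.0, 145.0), (100.0, 140.0), (199.0, 135.0)],
                    depth=25.0,
                    width=3.0,
                ),
            ],
            noise_amplitude=5.0,
            seed=seed,
        )
    elif name == "mini":
        spec = LandscapeSpec(
            nrows=80,
            ncols=80,
            ridges=[Ridge(start=(0.0, 40.0), end=(79.0, 40.0), height=25.0, width=6.0)],
            valleys=[
                Valley(
                    polyline=[(5.0, 20.0), (79.0, 24.0)],
                    depth=20.0,
                    width=2.5,
                )
            ],
            noise_amplitude=3.0,
            patch_count=4,
            patch_radius=(3, 5),
            patch_separation=22.0,
            seed=seed,
        )
    else:
        raise KeyError(f"unknown preset {name!r}")
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec
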