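"""End-to-end orchestration of the green–blue network workflow.

Stages: synthetic (or loaded) inputs → blue corridors from the DEM →
resistance surface and green corridors → PC/dPC patch classification →
gravity-model corridor filtering → candidate network → scenario generation
and index-based selection → saddle-node detection. Every stage reads its
inputs from, and writes its products to, a workspace directory, so any
stage can be re-run in isolation from the stored artifacts. Identical
config + seed give byte-identical artifacts (timing lives only in the run
report).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, gravity, hydrology, mcr, network, nodes as nodes_mod, synth
from .network import Link, SelectionParams
from .patches import PatchSet
from .raster import RasterGrid, ReclassTable, read_raster, write_raster

__all__ = ["PipelineConfig", "run_pipeline", "Workspace"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline with the defaults the method prescribes.

    The dispersal kernel defaults (2000 m, 0.5) and the selection thresholds
    (normalized dPC > 10, normalized G_ab > 2) are the method's stated
    operating points; everything marked ASSUMPTION in ``describe`` stands in
    for a choice the method leaves open.
    """

    preset: str = "two-valleys-six-patches"
    dem_path: str | None = None  # use real rasters instead of the preset
    landuse_path: str | None = None
    patches_path: str | None = None
    reclass_table: dict[int, float] = field(
        default_factory=lambda: dict(synth.DEFAULT_RESISTANCE)
    )
    seed: int = 0
    # blue corridors
    stream_threshold_frac: float = 0.01  # of total cell count  [ASSUMPTION]
    main_threshold_frac: float = 0.05  # mainstream bar          [ASSUMPTION]
    runoff_threshold_frac: float | None = 0.005  # trace bar     [ASSUMPTION]
    # connectivity
    kernel_d_ref: float = 2000.0
    kernel_p_ref: float = 0.5
    dpc_threshold: float = 10.0
    # gravity
    gab_threshold: float = 2.0
    area_unit: str = "ha"  # ASSUMPTION: unstated in the method
    # selection principles / scenarios
    parallel_dist_cells: float = 5.0  # ASSUMPTION
    detour_eps: float = 0.15  # ASSUMPTION
    blue_weight: float = 0.5  # ASSUMPTION
    blue_buffer_cells: int = 2  # ASSUMPTION
    scenario_count: int = 4
    # nodes
    merge_radius_cells: float = 10.0  # ASSUMPTION
    node_surface: str = "cost"  # "cost" (MCR surface) or "resistance"

    def selection_params(self) -> SelectionParams:
        return SelectionParams(
            self.parallel_dist_cells, self.detour_eps, self.blue_weight, self.blue_buffer_cells
        )

    def to_dict(self) -> dict:
        return asdict(self)


class Workspace:
    """Artifact paths and load/save helpers for one pipeline run."""

    def __init__(self, outdir: str | Path):
        self.dir = Path(outdir)
        self.dir.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        return self.dir / name

    def write_json(self, name: str, obj) -> None:
        self.path(name).write_text(json.dumps(obj, sort_keys=True))

    def read_json(self, name: str):
        return json.loads(self.path(name).read_text())


def _corridorset_to_json(cset: mcr.CorridorSet, grid: RasterGrid, scores=None) -> dict:
    obj = mcr.corridors_to_geojson(cset, grid, scores)
    for feat, key in zip(obj["features"], sorted(cset.corridors)):
        feat["properties"]["cells"] = [[int(r), int(c)] for r, c in cset.corridors[key].chain]
    obj["missing"] = [list(k) for k in cset.missing]
    return obj


def _corridorset_from_json(obj) -> mcr.CorridorSet:
    cors = {}
    for feat in obj["features"]:
        p = feat["properties"]
        chain = [tuple(rc) for rc in p["cells"]]
        coords = np.array(feat["geometry"]["coordinates"])
        seglen = float(np.hypot(*np.diff(coords, axis=0).T).sum()) if len(coords) > 1 else 0.0
        cors[(p["a"], p["b"])] = mcr.Corridor(p["a"], p["b"], chain, p["L_ab"], p.get("length_m", seglen))
    return mcr.CorridorSet(cors, [tuple(k) for k in obj.get("missing", [])])


# ---------------------------------------------------------------------------
# stages


def stage_synth(cfg: PipelineConfig, ws: Workspace) -> None:
    """Generate (or copy in) DEM, land use and patches."""
    if cfg.dem_path:
        dem = read_raster(cfg.dem_path)
        landuse = read_raster(cfg.landuse_path)
        patches = PatchSet.from_geojson(cfg.patches_path)
        truth = None
    else:
        land = synth.generate(synth.preset(cfg.preset, seed=cfg.seed))
        dem, landuse, patches, truth = land.dem, land.landuse, land.patches, land.truth
    write_raster(dem, ws.path("dem.asc"))
    write_raster(landuse, ws.path("landuse.asc"))
    patches.to_geojson(ws.path("patches.geojson"))
    if truth is not None:
        ws.write_json(
            "groundtruth.json",
            {
                "valley_cells": [[int(r), int(c)] for r, c in np.argwhere(truth.valley_mask)],
                "ridge_cells": [[int(r), int(c)] for r, c in np.argwhere(truth.ridge_mask)],
                "saddles": [[int(r), int(c)] for r, c in truth.saddles],
            },
        )


def stage_blue(cfg: PipelineConfig, ws: Workspace) -> None:
    """DEM → filled surface → D8 → accumulation → classified stream network."""
    dem = read_raster(ws.path("dem.asc"))
    ncells = dem.values.size
    filled = hydrology.fill_sinks(dem)
    fieldf = hydrology.flow_direction_d8(filled)
    fieldf = hydrology.flow_accumulation(fieldf)
    thr = max(1, int(cfg.stream_threshold_frac * ncells))
    runoff = (
        max(1, int(cfg.runoff_threshold_frac * ncells))
        if cfg.runoff_threshold_frac is not None
        else None
    )
    net = hydrology.extract_streams(fieldf, thr, runoff)
    net = hydrology.classify_streams(net, max(1, int(cfg.main_threshold_frac * ncells)))
    obj = hydrology.network_to_geojson(net, dem)
    obj["properties"] = {"threshold": net.threshold, "cell_size": net.cell_size}
    for feat, seg in zip(obj["features"], net.segments):
        feat["properties"]["cells"] = [[int(r), int(c)] for r, c in seg.cells]
    ws.write_json("streams.geojson", obj)


def load_streams(ws: Workspace, shape) -> hydrology.StreamNetwork:
    obj = ws.read_json("streams.geojson")
    segs = [
        hydrology.StreamSegment(
            cells=[tuple(rc) for rc in f["properties"]["cells"]],
            order=f["properties"]["order"],
            label=f["properties"]["label"],
            max_accumulation=f["properties"]["max_accumulation"],
        )
        for f in obj["features"]
    ]
    return hydrology.StreamNetwork(
        segs, tuple(shape), obj["properties"]["threshold"], obj["properties"]["cell_size"]
    )


def stage_green(cfg: PipelineConfig, ws: Workspace) -> None:
    """Resistance surface and all-pairs least-cost corridors."""
    landuse = read_raster(ws.path("landuse.asc"))
    table = ReclassTable(cfg.reclass_table)
    surface = mcr.build_resistance(landuse, table)
    write_raster(surface, ws.path("resistance.asc"))
    patches = PatchSet.from_geojson(ws.path("patches.geojson"))
    cset = mcr.corridor_network(surface, patches)
    ws.write_json("corridors.geojson", _corridorset_to_json(cset, surface))


def stage_connect(cfg: PipelineConfig, ws: Workspace) -> None:
    """dPC classification of the patches."""
    patches = PatchSet.from_geojson(ws.path("patches.geojson"))
    kernel = connectivity.make_kernel(cfg.kernel_d_ref, cfg.kernel_p_ref)
    dists = patches.distance_matrix()
    pij = connectivity.pairwise_pij(patches, kernel, dists)
    pc = connectivity.compute_PC(patches, pij)
    dpc = connectivity.compute_dPC_all(patches, pij)
    ids = patches.ids
    norm = connectivity.normalize_scores([dpc[i] for i in ids])
    table = pd.DataFrame(
        {
            "id": ids,
            "area_m2": patches.areas(),
            "dPC": [dpc[i] for i in ids],
            "dPC_norm": norm,
        }
    )
    table["selected"] = table["dPC_norm"] > cfg.dpc_threshold
    table.to_csv(ws.path("patch_scores.csv"), index=False)
    ws.write_json("connectivity.json", {"PC": pc, "selected": [int(i) for i in table[table.selected].id]})


def stage_gravity(cfg: PipelineConfig, ws: Workspace) -> None:
    """Gravity scores and candidate-corridor filtering."""
    patches = PatchSet.from_geojson(ws.path("patches.geojson"))
    surface = read_raster(ws.path("resistance.asc"))
    patches.attach_resistance(surface)
    cset = _corridorset_from_json(ws.read_json("corridors.geojson"))
    scores = gravity.score_corridors(cset, patches, cfg.area_unit)
    selected = ws.read_json("connectivity.json")["selected"]
    kept, scores = gravity.filter_candidate_corridors(scores, cset, selected, cfg.gab_threshold)
    scores.to_csv(ws.path("corridor_scores.csv"), index=False)
    gmap = {(int(r.a), int(r.b)): float(r.G_norm) for r in scores.itertuples()}
    ws.write_json("candidate_corridors.geojson", _corridorset_to_json(kept, surface, gmap))


def stage_network(cfg: PipelineConfig, ws: Workspace) -> None:
    """Candidate network → scenarios → index-ranked final network."""
    surface = read_raster(ws.path("resistance.asc"))
    selected = ws.read_json("connectivity.json")["selected"]
    cset = _corridorset_from_json(ws.read_json("candidate_corridors.geojson"))
    scores = pd.read_csv(ws.path("corridor_scores.csv"))
    gmap = {(int(r.a), int(r.b)): float(r.G_norm) for r in scores.itertuples()}
    links = [
        Link(c.a, c.b, c, gmap[(c.a, c.b)])
        for c in cset
    ]
    candidate = network.build_candidate_network(selected, links)
    if not candidate.links or candidate.v < 3:
        pd.DataFrame(
            columns=["scenario", "v", "l", "alpha", "beta", "gamma", "CR", "d", "selected"]
        ).to_csv(ws.path("scenarios.csv"), index=False)
        obj = _corridorset_to_json(mcr.CorridorSet({}, []), surface)
        obj["properties"] = {"vertices": candidate.vertex_ids, "selected_scenario": None}
        ws.write_json("final_network.geojson", obj)
        return
    blue = load_streams(ws, surface.shape)
    scen = network.generate_scenarios(candidate, blue, cfg.scenario_count, _grid_for(cfg))
    table, best, final = network.rank_scenarios(scen)
    table.to_csv(ws.path("scenarios.csv"), index=False)
    final_set = mcr.CorridorSet({l.key: l.corridor for l in final.links}, [])
    gsel = {l.key: l.G_norm for l in final.links}
    obj = _corridorset_to_json(final_set, surface, gsel)
    obj["properties"] = {"vertices": final.vertex_ids, "selected_scenario": int(best + 1)}
    ws.write_json("final_network.geojson", obj)


def _grid_for(cfg: PipelineConfig):
    base = cfg.selection_params()
    grid = [base] + [p for p in network._SCENARIO_GRID if p != base]
    return tuple(grid)


def stage_nodes(cfg: PipelineConfig, ws: Workspace) -> None:
    """Saddle nodes on the cost (or raw resistance) surface along corridors."""
    surface = read_raster(ws.path("resistance.asc"))
    patches = PatchSet.from_geojson(ws.path("patches.geojson"))
    fobj = ws.read_json("final_network.geojson")
    final_set = _corridorset_from_json(fobj)
    links = [Link(c.a, c.b, c, 0.0) for c in final_set]
    final = network.EcoNetwork(fobj["properties"]["vertices"], links)
    if not final.links:
        ws.write_json("nodes.geojson", {"type": "FeatureCollection", "features": []})
        return
    selected = set(fobj["properties"]["vertices"])
    if cfg.node_surface == "cost":
        src = patches.subset(selected)
        result = mcr.cost_distance(surface, src)
        vals = result.cost
        vals = np.where(np.isfinite(vals), vals, vals[np.isfinite(vals)].max() if np.isfinite(vals).any() else 0.0)
        node_surface = RasterGrid(vals, surface.cell_size, surface.origin, surface.nodata)
    else:
        node_surface = surface
    ridges = nodes_mod.ridge_network(node_surface)
    nset = nodes_mod.identify_nodes(
        ridges, final, node_surface, cfg.merge_radius_cells * surface.cell_size
    )
    ws.write_json("nodes.geojson", nset.to_geojson())


_STAGES = [
    ("synth", stage_synth),
    ("blue", stage_blue),
    ("green", stage_green),
    ("connect", stage_connect),
    ("gravity", stage_gravity),
    ("network", stage_network),
    ("nodes", stage_nodes),
]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; return (and write) the run report.

    On stage failure the exception propagates with the stage name attached;
    artifacts of completed stages remain in the workspace.
    """
    ws = Workspace(outdir)
    timings = {}
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        try:
            fn(cfg, ws)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
    import greenblue

    flags = []
    conn = ws.read_json("connectivity.json")
    if not conn["selected"]:
        flags.append("no GPAs selected")
    report = {
        "config": cfg.to_dict(),
        "artifacts": {name: str(ws.path(p)) for name, p in [
            ("dem", "dem.asc"), ("landuse", "landuse.asc"), ("patches", "patches.geojson"),
            ("streams", "streams.geojson"), ("resistance", "resistance.asc"),
            ("corridors", "corridors.geojson"), ("patch_scores", "patch_scores.csv"),
            ("corridor_scores", "corridor_scores.csv"), ("scenarios", "scenarios.csv"),
            ("final_network", "final_network.geojson"), ("nodes", "nodes.geojson"),
        ]},
        "PC": conn["PC"],
        "selected_gpas": conn["selected"],
        "flags": flags,
        "versions": {"greenblue": greenblue.__version__, "numpy": np.__version__},
        "wall_time_s": timings,
    }
    ws.write_json("report.json", report)
    return report
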