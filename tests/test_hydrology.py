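import numpy as np
import pytest

from greenblue import hydrology
from greenblue.hydrology import (
    MAINSTREAM,
    NEIGHBOURS,
    OUTLET,
    RUNOFF,
    TRIBUTARY,
    FlowField,
    classify_streams,
    extract_streams,
    fill_sinks,
    flow_accumulation,
    flow_direction_d8,
)
from greenblue.raster import RasterGrid

from conftest import random_dem


def plane(nrows, ncols, drow=0.0, dcol=0.0, base=100.0, cell_size=1.0):
    r, c = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    return RasterGrid(base + drow * r + dcol * c, cell_size)


# ---------------------------------------------------------------------------
# oracles


def fill_oracle(dem: RasterGrid, eps: float) -> np.ndarray:
    """Planchon–Darboux fixpoint: start from +inf interior, relax downward."""
    z = dem.values.astype(float)
    nrows, ncols = z.shape
    f = np.full_like(z, np.inf)
    f[0, :] = z[0, :]
    f[-1, :] = z[-1, :]
    f[:, 0] = z[:, 0]
    f[:, -1] = z[:, -1]
    changed = True
    while changed:
        changed = False
        for r in range(1, nrows - 1):
            for c in range(1, ncols - 1):
                lowest = min(f[r + dr, c + dc] for dr, dc in NEIGHBOURS)
                target = max(z[r, c], lowest + eps)
                if target < f[r, c] - 1e-12:
                    f[r, c] = target
                    changed = True
    return f


def d8_oracle(filled: RasterGrid) -> np.ndarray:
    """Per-cell argmax of drop/distance with clockwise-from-east tie-break."""
    z = filled.values
    nrows, ncols = z.shape
    cs = filled.cell_size
    out = np.full((nrows, ncols), OUTLET, dtype=int)
    for r in range(nrows):
        for c in range(ncols):
            best, bestk = 0.0, OUTLET
            for k, (dr, dc) in enumerate(NEIGHBOURS):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < nrows and 0 <= nc < ncols):
                    continue
                dist = cs * (np.sqrt(2.0) if k % 2 else 1.0)
                g = (z[r, c] - z[nr, nc]) / dist
                if g > best:
                    best, bestk = g, k
            out[r, c] = bestk
    return out


def accumulation_oracle(direction: np.ndarray) -> np.ndarray:
    """Walk every cell's flow path and count passages through each cell."""
    nrows, ncols = direction.shape
    acc = np.zeros((nrows, ncols), dtype=int)
    for r in range(nrows):
        for c in range(ncols):
            cr, cc = r, c
            for _ in range(nrows * ncols + 1):
                code = direction[cr, cc]
                if code < 0:
                    break
                dr, dc = NEIGHBOURS[code]
                cr, cc = cr + dr, cc + dc
                acc[cr, cc] += 1
    return acc


# ---------------------------------------------------------------------------


class TestFillSinks:
    def test_monotone_plane_unchanged(self):
        dem = plane(8, 8, drow=-1.0)
        np.testing.assert_array_equal(fill_sinks(dem).values, dem.values)

    def test_single_pit_raised_to_rim_plus_eps(self):
        dem = plane(5, 5, drow=-1.0)  # drains south; row r has elevation 100-r
        dem.values[2, 2] = 96.0  # below all 8 neighbours (lowest is 97)
        filled = fill_sinks(dem)
        assert filled.values[2, 2] == pytest.approx(97.0 + 1e-6, abs=1e-9)

    def test_matches_fixpoint_oracle_on_random_dems(self, rng):
        for _ in range(5):
            dem = random_dem(rng, 15, 15)
            filled = fill_sinks(dem)
            oracle = fill_oracle(dem, 1e-6 * dem.cell_size)
            np.testing.assert_allclose(filled.values, oracle, atol=1e-9)

    def test_idempotent(self, rng):
        dem = random_dem(rng, 12, 12)
        once = fill_sinks(dem)
        twice = fill_sinks(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_output_never_below_input(self, rng):
        dem = random_dem(rng, 15, 15)
        assert np.all(fill_sinks(dem).values >= dem.values - 1e-12)

    def test_all_nodata_rejected(self):
        dem = RasterGrid(np.full((3, 3), -9999.0), 1.0, nodata=-9999.0)
        with pytest.raises(ValueError):
            fill_sinks(dem)


class TestFlowDirection:
    def test_east_tilted_plane_points_east(self):
        f = flow_direction_d8(plane(6, 6, dcol=-1.0))
        assert np.all(f.direction[:, :-1] == 0)  # east code
        assert np.all(f.direction[:, -1] == OUTLET)

    def test_symmetric_ridge_splits_flow(self):
        g = plane(5, 9)
        g.values -= np.abs(np.arange(9) - 4)[None, :] * 5.0  # peak at col 4
        f = flow_direction_d8(fill_sinks(g))
        assert np.all(f.direction[1:-1, 1:4] == 4)  # west of crest -> west
        assert np.all(f.direction[1:-1, 5:-1] == 0)  # east of crest -> east

    def test_matches_per_cell_argmax_oracle(self, rng):
        for _ in range(5):
            filled = fill_sinks(random_dem(rng, 10, 10))
            f = flow_direction_d8(filled)
            np.testing.assert_array_equal(f.direction, d8_oracle(filled))

    def test_flat_region_raises_fill_hint(self):
        dem = plane(5, 5, drow=0.0, dcol=0.0)
        dem.values[1:4, 1:4] = 50.0  # sunken interior flat
        with pytest.raises(ValueError, match="fill"):
            flow_direction_d8(dem)

    def test_direction_field_is_acyclic(self, rng):
        f = flow_direction_d8(fill_sinks(random_dem(rng, 15, 15)))
        n = f.direction.size
        for r in range(15):
            for c in range(15):
                cur, steps = (r, c), 0
                while True:
                    nxt = f.downstream(*cur)
                    if nxt is None:
                        break
                    cur = nxt
                    steps += 1
                    assert steps <= n, "cycle in flow directions"


class TestFlowAccumulation:
    def test_single_chain(self):
        f = flow_direction_d8(plane(1, 6, dcol=-1.0))
        acc = flow_accumulation(f).accumulation
        np.testing.assert_array_equal(acc, [[0, 1, 2, 3, 4, 5]])

    def test_conservation_at_outlets(self, rng):
        dem = fill_sinks(random_dem(rng, 12, 12))
        f = flow_accumulation(flow_direction_d8(dem))
        outlets = f.direction == OUTLET
        assert (f.accumulation[outlets] + 1).sum() == dem.values.size

    def test_matches_path_walking_oracle(self, rng):
        for _ in range(5):
            f = flow_direction_d8(fill_sinks(random_dem(rng, 12, 12)))
            acc = flow_accumulation(f).accumulation
            np.testing.assert_array_equal(acc, accumulation_oracle(f.direction))

    def test_cycle_detected(self):
        direction = np.full((1, 2), OUTLET, dtype=np.int8)
        direction[0, 0] = 0  # east
        direction[0, 1] = 4  # west -> 2-cycle
        with pytest.raises(ValueError, match="cycle"):
            flow_accumulation(FlowField(direction))


class TestStreams:
    def test_vacuous_threshold_gives_empty_network(self, rng):
        f = flow_accumulation(flow_direction_d8(fill_sinks(random_dem(rng, 10, 10))))
        with pytest.warns(UserWarning, match="empty"):
            net = extract_streams(f, int(f.accumulation.max()) + 1)
        assert net.n_segments == 0

    def test_confluence_of_two_order1_streams_is_order2(self):
        # hand-built flow field: two chains meeting at (2, 2), then south
        direction = np.full((5, 5), OUTLET, dtype=np.int8)
        acc = np.zeros((5, 5), dtype=np.int64)
        for c in range(3):  # west arm flows east along row 2
            direction[2, c] = 0
        direction[0, 2] = 2  # north arm flows south along col 2
        direction[1, 2] = 2
        direction[2, 2] = 2
        direction[3, 2] = 2
        acc[2, :3] = [1, 2, 3]
        acc[:2, 2] = [1, 2]
        acc[2, 2] = 7
        acc[3, 2] = 8
        acc[4, 2] = 9
        f = FlowField(direction, acc)
        net = extract_streams(f, 1)
        orders = {tuple(s.cells[0]): s.order for s in net.segments}
        assert orders[(2, 0)] == 1 and orders[(0, 2)] == 1
        assert orders[(2, 2)] == 2  # downstream of the confluence

    def test_every_stream_cell_on_exactly_one_segment(self, mini_landscape):
        dem = mini_landscape.dem
        f = flow_accumulation(flow_direction_d8(fill_sinks(dem)))
        net = extract_streams(f, 64)
        seen = {}
        for i, seg in enumerate(net.segments):
            for rc in seg.cells:
                assert rc not in seen, f"cell {rc} on segments {seen[rc]} and {i}"
                seen[rc] = i

    def test_stream_cells_follow_flow_directions(self, mini_landscape):
        f = flow_accumulation(flow_direction_d8(fill_sinks(mini_landscape.dem)))
        net = extract_streams(f, 64)
        for seg in net.segments:
            for up, down in zip(seg.cells[:-1], seg.cells[1:]):
                assert f.downstream(*up) == down


class TestClassifyStreams:
    def _net(self, mini_landscape, runoff=None):
        f = flow_accumulation(flow_direction_d8(fill_sinks(mini_landscape.dem)))
        return f, extract_streams(f, 64, runoff)

    def test_degenerate_threshold_makes_all_mainstream(self, mini_landscape):
        _, net = self._net(mini_landscape)
        net = classify_streams(net, main_threshold=1)
        assert all(s.label == MAINSTREAM for s in net.segments)

    def test_labels_partition_segments(self, mini_landscape):
        _, net = self._net(mini_landscape, runoff=32)
        net = classify_streams(net, main_threshold=1000)
        labels = {s.label for s in net.segments}
        assert labels <= {MAINSTREAM, TRIBUTARY, RUNOFF}
        assert all(s.label in (MAINSTREAM, TRIBUTARY, RUNOFF) for s in net.segments)

    def test_big_and_small_valley_fixture(self):
        # west arm carries much more accumulation than the north arm
        direction = np.full((5, 5), OUTLET, dtype=np.int8)
        acc = np.zeros((5, 5), dtype=np.int64)
        for c in range(3):
            direction[2, c] = 0
        direction[1, 2] = 2
        direction[2, 2] = 2
        direction[3, 2] = 2
        acc[2, :3] = [40, 41, 42]
        acc[1, 2] = 2
        acc[2, 2] = 45
        acc[3, 2] = 46
        acc[4, 2] = 47
        f = FlowField(direction, acc)
        net = extract_streams(f, 1)
        net = classify_streams(net, main_threshold=40)
        by_start = {tuple(s.cells[0]): s.label for s in net.segments}
        assert by_start[(2, 0)] == MAINSTREAM
        assert by_start[(1, 2)] == TRIBUTARY
        assert by_start[(2, 2)] == MAINSTREAM
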