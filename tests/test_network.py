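import numpy as np
import pytest

from greenblue.hydrology import StreamNetwork, StreamSegment
from greenblue.mcr import Corridor
from greenblue.network import (
    EcoNetwork,
    Link,
    SelectionParams,
    apply_selection_principles,
    build_candidate_network,
    generate_scenarios,
    network_indices,
    rank_scenarios,
)


def link(a, b, cost=10.0, g=50.0, chain=None):
    if chain is None:
        chain = [(a, i) for i in range(5)]
    return Link(a, b, Corridor(a, b, chain, cost, cost), g)


def ring(n=5, cost=10.0):
    links = [link(i + 1, (i % n) + 2 if i + 2 <= n else 1, cost) for i in range(n)]
    # build explicitly: edges (1,2),(2,3),...,(n,1)
    links = [link(i, i + 1, cost) for i in range(1, n)] + [link(1, n, cost)]
    return EcoNetwork(list(range(1, n + 1)), links)


class TestIndices:
    def test_five_ring_is_single_circuit(self):
        m = network_indices(ring(5, cost=10.0))
        assert m.beta == pytest.approx(1.0)
        assert m.alpha == pytest.approx(0.2)
        assert m.gamma == pytest.approx(5.0 / 9.0)
        assert m.cost_ratio == pytest.approx(1.0 - 5.0 / 50.0)

    def test_spanning_tree_is_dendritic(self):
        net = EcoNetwork([1, 2, 3, 4], [link(1, 2), link(2, 3), link(3, 4)])
        m = network_indices(net)
        assert m.beta == pytest.approx(0.75)
        assert m.beta < 1.0

    def test_small_vertex_count_rejected(self):
        with pytest.raises(ValueError, match="v"):
            network_indices(EcoNetwork([1, 2], [link(1, 2)]))

    def test_adding_a_link_raises_alpha_beta_gamma(self):
        base = EcoNetwork([1, 2, 3, 4], [link(1, 2), link(2, 3), link(3, 4)])
        more = EcoNetwork([1, 2, 3, 4], base.links + [link(1, 4)])
        mb, mm = network_indices(base), network_indices(more)
        assert mm.alpha > mb.alpha and mm.beta > mb.beta and mm.gamma > mb.gamma
        # CR recomputation consistency
        assert mm.cost_ratio == pytest.approx(1.0 - mm.l / mm.d)


class TestBuildCandidate:
    def test_isolates_retained_and_reported(self):
        net = build_candidate_network([1, 2, 3], [])
        assert net.v == 3 and net.l == 0
        assert net.isolated() == [1, 2, 3]

    def test_duplicate_links_keep_higher_gravity(self):
        net = build_candidate_network([1, 2], [link(1, 2, g=40.0), link(2, 1, g=90.0)])
        assert net.l == 1
        assert net.links[0].G_norm == 90.0

    def test_adjacency_matches_hand_drawing(self):
        edges = [(1, 2), (1, 3), (2, 3), (2, 4), (3, 5), (4, 5), (1, 5)]
        net = build_candidate_network([1, 2, 3, 4, 5], [link(a, b) for a, b in edges])
        g = net.graph()
        assert sorted(map(tuple, map(sorted, g.edges))) == sorted(edges)

    def test_unselected_endpoint_rejected(self):
        with pytest.raises(ValueError):
            build_candidate_network([1, 2], [link(1, 3)])


def stream_along_row(row, shape=(20, 20)):
    seg = StreamSegment(cells=[(row, c) for c in range(shape[1])], max_accumulation=100)
    return StreamNetwork([seg], shape, threshold=10)


class TestSelectionPrinciples:
    def test_parallel_corridors_keep_higher_rank(self):
        # square: top pair (1,2) and bottom pair (3,4) run close together
        links = [
            link(1, 2, g=90.0, chain=[(5, c) for c in range(20)]),
            link(3, 4, g=40.0, chain=[(7, c) for c in range(20)]),
            link(1, 3, g=80.0, chain=[(r, 0) for r in range(5, 8)]),
            link(2, 4, g=80.0, chain=[(r, 19) for r in range(5, 8)]),
        ]
        cand = build_candidate_network([1, 2, 3, 4], links)
        out = apply_selection_principles(cand, None, SelectionParams(parallel_dist_cells=5.0))
        keys = out.link_keys()
        assert (1, 2) in keys and (3, 4) not in keys

    def test_blue_overlap_wins_among_equal_gravity(self):
        links = [
            link(1, 2, g=50.0, chain=[(5, c) for c in range(20)]),
            link(3, 4, g=50.0, chain=[(7, c) for c in range(20)]),
            link(1, 3, g=80.0, chain=[(r, 0) for r in range(5, 8)]),
            link(2, 4, g=80.0, chain=[(r, 19) for r in range(5, 8)]),
        ]
        cand = build_candidate_network([1, 2, 3, 4], links)
        blue = stream_along_row(7)
        out = apply_selection_principles(
            cand, blue, SelectionParams(parallel_dist_cells=5.0, blue_buffer_cells=1)
        )
        keys = out.link_keys()
        assert (3, 4) in keys and (1, 2) not in keys

    def test_detour_replaces_similar_direct_corridor(self):
        # far-apart chains so the parallel rule stays quiet
        links = [
            link(1, 2, cost=10.0, g=50.0, chain=[(0, c) for c in range(20)]),
            link(1, 3, cost=5.2, g=60.0, chain=[(10, c) for c in range(10)]),
            link(3, 2, cost=5.2, g=60.0, chain=[(19, c) for c in range(10, 20)]),
        ]
        cand = build_candidate_network([1, 2, 3], links)
        out = apply_selection_principles(cand, None, SelectionParams(parallel_dist_cells=2.0, detour_eps=0.15))
        keys = out.link_keys()
        assert (1, 2) not in keys
        assert (1, 3) in keys and (2, 3) in keys

    def test_no_gpa_left_isolated(self):
        links = [
            link(1, 2, g=90.0, chain=[(5, c) for c in range(20)]),
            link(3, 4, g=10.0, chain=[(6, c) for c in range(20)]),
        ]
        cand = build_candidate_network([1, 2, 3, 4], links)
        out = apply_selection_principles(cand, None, SelectionParams(parallel_dist_cells=5.0))
        assert out.isolated() == []

    def test_output_links_are_candidate_links(self):
        links = [
            link(1, 2, g=90.0),
            link(2, 3, g=70.0, chain=[(10, c) for c in range(5)]),
            link(1, 3, g=50.0, chain=[(18, c) for c in range(5)]),
        ]
        cand = build_candidate_network([1, 2, 3], links)
        out = apply_selection_principles(cand, None, SelectionParams())
        assert out.link_keys() <= cand.link_keys()

    def test_deterministic(self):
        links = [
            link(1, 2, g=90.0),
            link(2, 3, g=70.0, chain=[(10, c) for c in range(5)]),
            link(1, 3, g=50.0, chain=[(18, c) for c in range(5)]),
        ]
        cand = build_candidate_network([1, 2, 3], links)
        a = apply_selection_principles(cand, None, SelectionParams())
        b = apply_selection_principles(cand, None, SelectionParams())
        assert a.link_keys() == b.link_keys()


class TestScenarios:
    def _candidate(self):
        chains = {
            (1, 2): [(0, c) for c in range(20)],
            (1, 3): [(r, 0) for r in range(20)],
            (2, 3): [(19, c) for c in range(20)],
            (2, 4): [(r, 19) for r in range(20)],
            (3, 4): [(10, c) for c in range(20)],
            (1, 4): [(r, r) for r in range(20)],
        }
        links = [link(a, b, cost=10.0 + 3 * (a + b), g=30.0 + 10 * a + 5 * b, chain=ch) for (a, b), ch in chains.items()]
        return build_candidate_network([1, 2, 3, 4], links)

    def test_k1_equals_base_principles_output(self):
        cand = self._candidate()
        scen = generate_scenarios(cand, None, k=1)
        base = apply_selection_principles(cand, None, SelectionParams())
        assert scen[0][1].link_keys() == base.link_keys()

    def test_scenarios_are_distinct_and_connected(self):
        cand = self._candidate()
        scen = generate_scenarios(cand, None, k=3)
        sigs = [net.link_keys() for _, net in scen]
        assert len(set(sigs)) == len(sigs)
        for _, net in scen:
            assert net.isolated() == []


class TestRankScenarios:
    def test_single_scenario_selected(self):
        cand = EcoNetwork([1, 2, 3], [link(1, 2), link(2, 3, chain=[(9, c) for c in range(5)])])
        table, best, net = rank_scenarios([(SelectionParams(), cand)])
        assert best == 0 and table.selected.iloc[0]

    def test_cr_breaks_ties(self):
        # same v, l -> same alpha/beta/gamma; cheaper network (higher d) wins on CR? no:
        # lower CR wins, CR = 1 - l/d, so the SMALLER d (bigger l/d) gives lower CR
        cheap = EcoNetwork([1, 2, 3], [link(1, 2, cost=10.0), link(2, 3, cost=10.0, chain=[(9, c) for c in range(5)])])
        dear = EcoNetwork([1, 2, 3], [link(1, 2, cost=50.0), link(2, 3, cost=50.0, chain=[(9, c) for c in range(5)])])
        table, best, net = rank_scenarios([(SelectionParams(), dear), (SelectionParams(), cheap)])
        assert net is cheap

    def test_ordering_matches_hand_sorted_metrics(self):
        tri = EcoNetwork([1, 2, 3], [link(1, 2), link(2, 3, chain=[(9, c) for c in range(5)]), link(1, 3, chain=[(18, c) for c in range(5)])])
        path = EcoNetwork([1, 2, 3], [link(1, 2), link(2, 3, chain=[(9, c) for c in range(5)])])
        table, best, net = rank_scenarios([(SelectionParams(), path), (SelectionParams(), tri)])
        assert net is tri  # higher gamma
        assert list(table.scenario) == [1, 2]
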