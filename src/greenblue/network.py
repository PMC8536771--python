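"""Ecological network assembly, selection principles, scenarios and indices.

The candidate network has selected GPAs as vertices and gravity-filtered
corridors as links. Scenario networks are pruned candidates obeying five
selection principles: (1) keep one corridor per bundle of spatially parallel
corridors, (2) replace a corridor by a two-leg detour through an intermediate
GPA when their costs are similar, (3) rank retention by G_ab, (4) leave no
GPA unconnected, (5) prefer corridors tracking the blue (stream) network.

Scenarios are compared with the classical graph indices

    α = (l − v + 1) / (2v − 5)     loop abundance
    β = l / v                      links per vertex
    γ = l / (3(v − 2))             realized fraction of possible links
    CR = 1 − l / d                 cost ratio, d = Σ corridor resistance
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .hydrology import StreamNetwork
from .mcr import Corridor

__all__ = [
    "EcoNetwork",
    "NetworkMetrics",
    "SelectionParams",
    "build_candidate_network",
    "network_indices",
    "apply_selection_principles",
    "generate_scenarios",
    "rank_scenarios",
]


@dataclass
class Link:
    a: int
    b: int
    corridor: Corridor
    G_norm: float
    blue_frac: float = 0.0

    @property
    def key(self) -> tuple[int, int]:
        return (min(self.a, self.b), max(self.a, self.b))

    def rank(self, blue_weight: float) -> float:
        """Retention rank: G_ab boosted by overlap with the blue network."""
        return self.G_norm * (1.0 + blue_weight * self.blue_frac)


@dataclass
class EcoNetwork:
    vertex_ids: list[int]
    links: list[Link]

    def __post_init__(self) -> None:
        keys = [l.key for l in self.links]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate links between a patch pair")
        for l in self.links:
            if l.a == l.b:
                raise ValueError("self-loop corridors are not allowed")

    @property
    def v(self) -> int:
        return len(self.vertex_ids)

    @property
    def l(self) -> int:
        return len(self.links)

    @property
    def d(self) -> float:
        """Accumulated network resistance: Σ L_ab over links."""
        return float(sum(l.corridor.cost for l in self.links))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertex_ids)
        for l in self.links:
            g.add_edge(*l.key, L_ab=l.corridor.cost, G_norm=l.G_norm)
        return g

    def isolated(self) -> list[int]:
        g = self.graph()
        return sorted(n for n in g.nodes if g.degree(n) == 0)

    def link_keys(self) -> frozenset:
        return frozenset(l.key for l in self.links)


@dataclass
class NetworkMetrics:
    alpha: float
    beta: float
    gamma: float
    cost_ratio: float
    v: int
    l: int
    d: float


def build_candidate_network(selected_ids, links: list[Link]) -> EcoNetwork:
    """Assemble the candidate network, deduplicating parallel same-pair links.

    Duplicate links between one pair keep the higher G_ab. Isolated GPAs are
    retained as vertices (reported via :meth:`EcoNetwork.isolated`).
    """
    selected = sorted(set(selected_ids))
    sset = set(selected)
    best: dict[tuple[int, int], Link] = {}
    for link in links:
        if link.a not in sset or link.b not in sset:
            raise ValueError(f"link {link.key} has an unselected endpoint")
        k = link.key
        if k not in best or link.G_norm > best[k].G_norm:
            best[k] = link
    return EcoNetwork(selected, [best[k] for k in sorted(best)])


def network_indices(net: EcoNetwork) -> NetworkMetrics:
    """α, β, γ and cost ratio of a network; v ≥ 3 and d > 0 required."""
    v, l = net.v, net.l
    if v < 3:
        raise ValueError(f"alpha and gamma are undefined for v={v} (need v >= 3)")
    d = net.d
    if d <= 0:
        raise ValueError("cost ratio undefined: accumulated resistance d must be > 0")
    alpha = (l - v + 1) / (2 * v - 5)
    beta = l / v
    gamma = l / (3 * (v - 2))
    cr = 1.0 - l / d
    return NetworkMetrics(alpha, beta, gamma, cr, v, l, d)


@dataclass(frozen=True)
class SelectionParams:
    """Knobs of the five selection principles.

    parallel_dist_cells: two corridors closer (mean symmetric chain distance)
    than this many cells count as parallel. detour_eps: relative tolerance for
    replacing corridor A by legs B+C through an intermediate GPA.
    blue_weight: strength of the blue-overlap retention bonus.
    blue_buffer_cells: chain cells within this Chebyshev radius of a stream
    cell count as overlapping the blue network.
    """

    parallel_dist_cells: float = 5.0
    detour_eps: float = 0.15
    blue_weight: float = 0.5
    blue_buffer_cells: int = 2


def blue_overlap_fraction(link: Link, stream_mask: np.ndarray, buffer_cells: int) -> float:
    """Fraction of corridor cells lying within the buffered stream mask."""
    if not stream_mask.any():
        return 0.0
    dil = ndimage.binary_dilation(stream_mask, iterations=buffer_cells) if buffer_cells else stream_mask
    rc = np.array(link.corridor.chain)
    hits = dil[rc[:, 0], rc[:, 1]]
    return float(hits.mean())


def _mean_chain_distance(chain_a, chain_b) -> float:
    """Mean symmetric nearest-cell distance between two chains (cell units)."""
    a = np.asarray(chain_a, dtype=float)
    b = np.asarray(chain_b, dtype=float)
    ta, tb = cKDTree(a), cKDTree(b)
    da, _ = tb.query(a)
    db, _ = ta.query(b)
    return float((da.mean() + db.mean()) / 2.0)


def attach_blue_overlap(net: EcoNetwork, blue: StreamNetwork | None, params: SelectionParams) -> EcoNetwork:
    mask = blue.mask() if blue is not None else None
    links = []
    for l in net.links:
        frac = blue_overlap_fraction(l, mask, params.blue_buffer_cells) if mask is not None else 0.0
        links.append(replace(l, blue_frac=frac))
    return EcoNetwork(list(net.vertex_ids), links)


def apply_selection_principles(
    candidate: EcoNetwork,
    blue: StreamNetwork | None = None,
    params: SelectionParams = SelectionParams(),
) -> EcoNetwork:
    """Prune the candidate network into one scenario network.

    Deterministic passes, in order: spatially parallel bundles keep their
    highest-ranked member; cost-similar single corridors give way to two-leg
    detours already present; every GPA left isolated gets its best candidate
    link back; finally components are bridged with the best available
    candidate links so the selected GPAs form one network where possible.
    Ranks are G_ab values boosted by blue-network overlap.
    """
    if not candidate.links:
        warnings.warn("candidate network has no links; nothing to select")
        return EcoNetwork(list(candidate.vertex_ids), [])
    cand = attach_blue_overlap(candidate, blue, params)
    w = params.blue_weight
    links = sorted(cand.links, key=lambda l: (-l.rank(w), l.key))

    # principle 1: bundle spatially parallel corridors, keep the best-ranked
    parent = list(range(len(links)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(links)), 2):
        if _mean_chain_distance(links[i].corridor.chain, links[j].corridor.chain) < params.parallel_dist_cells:
            parent[find(i)] = find(j)
    kept: list[Link] = []
    seen_groups: set[int] = set()
    for i, link in enumerate(links):  # links sorted by rank: first of group wins
        g = find(i)
        if g not in seen_groups:
            seen_groups.add(g)
            kept.append(link)

    # principle 2: drop corridor A when a two-leg detour B+C is cost-similar
    current = {l.key: l for l in kept}
    for link in sorted(kept, key=lambda l: (-l.corridor.cost, l.key)):
        a, b = link.key
        if link.key not in current:
            continue
        others = {k for key in current for k in key if k not in (a, b)}
        for c in sorted(others):
            k1 = (min(a, c), max(a, c))
            k2 = (min(c, b), max(c, b))
            if k1 in current and k2 in current and k1 != link.key and k2 != link.key:
                detour = current[k1].corridor.cost + current[k2].corridor.cost
                if abs(link.corridor.cost - detour) / link.corridor.cost <= params.detour_eps:
                    del current[link.key]
                    break

    # principle 4: no GPA may end up unconnected; re-add its best candidate link
    by_vertex: dict[int, list[Link]] = {vid: [] for vid in cand.vertex_ids}
    for l in cand.links:
        by_vertex[l.a].append(l)
        by_vertex[l.b].append(l)
    net = EcoNetwork(list(cand.vertex_ids), sorted(current.values(), key=lambda l: l.key))
    for vid in net.isolated():
        options = sorted(by_vertex[vid], key=lambda l: (-l.rank(w), l.key))
        if options:
            current[options[0].key] = options[0]
        else:
            warnings.warn(f"GPA {vid} has no candidate corridor; remains isolated")

    # bridge remaining components with the best-ranked cross-component links
    def components(cur):
        g = nx.Graph()
        g.add_nodes_from(cand.vertex_ids)
        g.add_edges_from(cur)
        return list(nx.connected_components(g))

    connectable = True
    while connectable:
        comps = components(current)
        comps = [c for c in comps if len(c) > 1 or by_vertex[next(iter(c))]]
        if len(comps) <= 1:
            break
        comp_of = {}
        for ci, comp in enumerate(comps):
            for vid in comp:
                comp_of[vid] = ci
        bridges = [
            l
            for l in sorted(cand.links, key=lambda l: (-l.rank(w), l.key))
            if l.key not in current
            and l.a in comp_of
            and l.b in comp_of
            and comp_of[l.a] != comp_of[l.b]
        ]
        if not bridges:
            warnings.warn("candidate network cannot be made connected; components remain")
            connectable = False
        else:
            current[bridges[0].key] = bridges[0]
    return EcoNetwork(list(cand.vertex_ids), sorted(current.values(), key=lambda l: l.key))


# parameter grid explored when simulating alternative connection modes
_SCENARIO_GRID: tuple[SelectionParams, ...] = (
    SelectionParams(),
    SelectionParams(parallel_dist_cells=3.0, detour_eps=0.0, blue_weight=0.5),
    SelectionParams(parallel_dist_cells=8.0, detour_eps=0.30, blue_weight=0.5),
    SelectionParams(parallel_dist_cells=5.0, detour_eps=0.15, blue_weight=2.0),
    SelectionParams(parallel_dist_cells=10.0, detour_eps=0.40, blue_weight=0.0),
    SelectionParams(parallel_dist_cells=2.0, detour_eps=0.0, blue_weight=0.0),
    SelectionParams(parallel_dist_cells=12.0, detour_eps=0.50, blue_weight=1.0),
    SelectionParams(parallel_dist_cells=6.0, detour_eps=0.25, blue_weight=0.25),
    SelectionParams(parallel_dist_cells=20.0, detour_eps=0.60, blue_weight=0.5),
    SelectionParams(parallel_dist_cells=16.0, detour_eps=0.20, blue_weight=0.0),
    SelectionParams(parallel_dist_cells=25.0, detour_eps=0.35, blue_weight=1.5),
    SelectionParams(parallel_dist_cells=30.0, detour_eps=0.70, blue_weight=0.25),
)


def generate_scenarios(
    candidate: EcoNetwork,
    blue: StreamNetwork | None = None,
    k: int = 4,
    grid: tuple[SelectionParams, ...] = _SCENARIO_GRID,
) -> list[tuple[SelectionParams, EcoNetwork]]:
    """``k`` distinct scenario networks from a documented parameter grid.

    The grid varies the parallel-distance threshold, detour tolerance and
    blue bonus; duplicates (identical link sets) are discarded. Fewer than
    ``k`` distinct networks triggers a warning and returns the distinct ones.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: list[tuple[SelectionParams, EcoNetwork]] = []
    seen: set[frozenset] = set()
    for params in grid:
        net = apply_selection_principles(candidate, blue, params)
        sig = net.link_keys()
        if sig not in seen:
            seen.add(sig)
            out.append((params, net))
        if len(out) == k:
            break
    if len(out) < k:
        warnings.warn(f"only {len(out)} distinct scenarios available (requested {k})")
    return out


def rank_scenarios(scenarios: list[tuple[SelectionParams, EcoNetwork]]):
    """Order scenarios by (γ desc, β desc, α desc, CR asc) and pick the best.

    Returns ``(table, best_index, best_network)`` where the table lists every
    scenario's v, l, α, β, γ, CR so users can override the default composite.
    """
    if not scenarios:
        raise ValueError("no scenarios to rank")
    rows = []
    for i, (params, net) in enumerate(scenarios):
        m = network_indices(net)
        rows.append(
            {
                "scenario": i + 1,
                "v": m.v,
                "l": m.l,
                "alpha": m.alpha,
                "beta": m.beta,
                "gamma": m.gamma,
                "CR": m.cost_ratio,
                "d": m.d,
            }
        )
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(rows)),
        key=lambda i: (-rows[i]["gamma"], -rows[i]["beta"], -rows[i]["alpha"], rows[i]["CR"]),
    )
    best = order[0]
    table["selected"] = [i == best for i in range(len(rows))]
    return table, best, scenarios[best][1]
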