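"""Directed road graph and nearest-facility network distances.

This module replaces an external routing engine with an explicit contract:
build a directed weighted graph from an edge list, snap point locations to
their nearest graph node, and compute for every postcode the shortest-path
distance (km) to the nearest facility of a category, honouring one-way
restrictions.

Distances are carried internally as integer micro-kilometres.  Edge lengths
are specified to 6 decimal places of a kilometre, so the scaling is lossless,
and integer summation makes path lengths independent of summation order —
the reverse multi-source computation is then *exactly* equal to the forward
per-pair minimum, not merely equal to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError, UnreachableError, ValidationError

__all__ = [
    "Edge",
    "RoadNetwork",
    "ServiceSite",
    "PostcodeRecord",
    "AccessResult",
    "build_graph",
    "snap_to_network",
    "nearest_facility_distances",
]

#: micro-km per km; edge lengths are 6-decimal km so this scaling is exact.
_SCALE = 10**6


def _to_microkm(length_km: float) -> int:
    return int(round(length_km * _SCALE))


@dataclass(frozen=True)
class Edge:
    """A road segment; ``oneway`` means traversable from_node -> to_node only."""

    edge_id: str
    from_node: int
    to_node: int
    length_km: float
    oneway: bool = False


@dataclass(frozen=True)
class ServiceSite:
    """A facility location of one of the 10 accessibility categories."""

    site_id: str
    category: str
    location: tuple[float, float]  # (easting_m, northing_m)


@dataclass(frozen=True)
class PostcodeRecord:
    """A postcode unit: population-weighted centroid plus zone membership."""

    pcd: str
    centroid: tuple[float, float]  # (easting_m, northing_m)
    zone_code: str

    def __post_init__(self):
        if not (np.isfinite(self.centroid[0]) and np.isfinite(self.centroid[1])):
            raise ValidationError(f"postcode {self.pcd}: non-finite centroid")
        if not self.zone_code:
            raise ValidationError(f"postcode {self.pcd}: empty zone_code")


@dataclass(frozen=True)
class AccessResult:
    """Network distance from one postcode to its nearest facility."""

    pcd: str
    category: str
    distance_km: float
    snapped_origin_node: int
    snapped_facility_node: int


class RoadNetwork:
    """Directed weighted graph over planar node coordinates (metres).

    One-way edges are stored in a single direction; two-way edges are
    traversable both ways.  Lengths are km; internal weights integer
    micro-km (attribute ``w`` on the directed graph).
    """

    def __init__(self, nodes: Mapping[int, tuple[float, float]], edges: Sequence[Edge]):
        if not edges:
            raise ValidationError("edge list is empty")
        self.nodes: dict[int, tuple[float, float]] = {
            int(k): (float(v[0]), float(v[1])) for k, v in nodes.items()
        }
        self.edges: list[Edge] = list(edges)
        g = nx.DiGraph()
        for nid, xy in self.nodes.items():
            g.add_node(nid, pos=xy)
        for e in self.edges:
            if not np.isfinite(e.length_km) or e.length_km <= 0:
                raise ValidationError(
                    f"edge {e.edge_id}: nonpositive or non-finite length {e.length_km}"
                )
            for nid in (e.from_node, e.to_node):
                if nid not in self.nodes:
                    raise ValidationError(
                        f"edge {e.edge_id}: dangling node reference {nid}"
                    )
            w = _to_microkm(e.length_km)
            g.add_edge(e.from_node, e.to_node, w=w)
            if not e.oneway:
                g.add_edge(e.to_node, e.from_node, w=w)
        self.graph = g
        # sorted id/coordinate arrays for vectorised snapping
        self._ids = np.array(sorted(self.nodes), dtype=np.int64)
        self._xy = np.array([self.nodes[i] for i in self._ids], dtype=float)

    def __len__(self) -> int:
        return len(self.nodes)

    def reversed_graph(self) -> nx.DiGraph:
        return self.graph.reverse(copy=False)

    def is_strongly_connected(self) -> bool:
        return nx.is_strongly_connected(self.graph)


def build_graph(
    edges: Iterable[Edge | tuple],
    nodes: Mapping[int, tuple[float, float]],
) -> RoadNetwork:
    """Build a :class:`RoadNetwork` from an edge list and node coordinates.

    ``edges`` may contain :class:`Edge` instances or raw
    ``(edge_id, from_node, to_node, length_km, oneway)`` tuples, mirroring
    the ``edges.csv`` columns.
    """
    parsed = [
        e
        if isinstance(e, Edge)
        else Edge(str(e[0]), int(e[1]), int(e[2]), float(e[3]), bool(int(e[4])))
        for e in edges
    ]
    return RoadNetwork(nodes, parsed)


def snap_to_network(
    point: tuple[float, float], network: RoadNetwork
) -> tuple[int, float]:
    """Nearest node by Euclidean distance; ties broken by smallest node id.

    Returns ``(node_id, snap_distance_m)``.
    """
    d2 = ((network._xy - np.asarray(point, dtype=float)) ** 2).sum(axis=1)
    best = d2.min()
    candidates = network._ids[d2 == best]
    return int(candidates.min()), float(np.sqrt(best))


def _facility_node_distances(
    network: RoadNetwork, facility_nodes: Iterable[int]
) -> dict[int, dict[int, int]]:
    """Shortest-path distance (micro-km) from every node TO each facility node.

    One Dijkstra per distinct facility node on the edge-reversed graph;
    exact integer arithmetic makes the result identical to forward per-pair
    Dijkstra."""
    rg = network.reversed_graph()
    return {
        f: nx.single_source_dijkstra_path_length(rg, f, weight="w")
        for f in sorted(set(facility_nodes))
    }


def nearest_facility_distances(
    network: RoadNetwork,
    origins: Sequence[PostcodeRecord],
    facilities: Sequence[ServiceSite],
    allow_unreachable: bool = False,
) -> list[AccessResult]:
    """Distance from each origin to its nearest facility of each category.

    For every origin the reported ``distance_km`` equals the minimum over
    facilities of the directed shortest-path length from the origin's
    snapped node to the facility's snapped node.  Ties between equally near
    facilities report the smallest facility node id.  Origins that cannot
    reach any facility raise :class:`UnreachableError` unless
    ``allow_unreachable`` is set, in which case ``distance_km`` is ``inf``
    and the facility node is ``-1``.
    """
    if not facilities:
        raise ConfigurationError("facility list is empty (no category given)")

    categories = sorted({s.category for s in facilities})
    origin_nodes = {o.pcd: snap_to_network(o.centroid, network)[0] for o in origins}

    results: list[AccessResult] = []
    for cat in categories:
        sites = [s for s in facilities if s.category == cat]
        if not sites:  # pragma: no cover - guarded by the grouping above
            raise ConfigurationError(f"no facilities for category '{cat}'")
        fac_nodes = sorted({snap_to_network(s.location, network)[0] for s in sites})
        dist_to = _facility_node_distances(network, fac_nodes)

        unreachable: list[str] = []
        cat_results: list[AccessResult] = []
        for o in origins:
            onode = origin_nodes[o.pcd]
            best_w: int | None = None
            best_f = -1
            for f in fac_nodes:  # ascending ids => smallest-id tie-break
                w = dist_to[f].get(onode)
                if w is not None and (best_w is None or w < best_w):
                    best_w, best_f = w, f
            if best_w is None:
                unreachable.append(o.pcd)
                cat_results.append(
                    AccessResult(o.pcd, cat, float("inf"), onode, -1)
                )
            else:
                cat_results.append(
                    AccessResult(o.pcd, cat, best_w / _SCALE, onode, best_f)
                )
        if unreachable and not allow_unreachable:
            raise UnreachableError(unreachable, cat)
        results.extend(cat_results)
    return results
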