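"""Shared fixtures and independent oracle helpers.

Oracles are deliberately implemented with different algorithms/directions
than the library code they check (forward per-pair Dijkstra vs reverse
multi-source; Monte-Carlo vs exact geometry; fine rasterisation vs
footprint tests)."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from ahah import (
    PipelineConfig,
    RegionConfig,
    construct_index,
    generate_region,
)
from ahah.pipeline import build_components, compute_access, compute_air, compute_green
from ahah.road_network import Edge, RoadNetwork

MICRO = 10**6


# ---------------------------------------------------------------------------
# region / pipeline fixtures (session-scoped: generation is deterministic)


@pytest.fixture(scope="session")
def default_region():
    return generate_region(RegionConfig(seed=1))


@pytest.fixture(scope="session")
def default_components(default_region):
    region = default_region
    access = compute_access(region)
    green = compute_green(region)
    air = compute_air(region)
    return build_components(region, access, green, air)


@pytest.fixture(scope="session")
def default_result(default_components):
    return construct_index(default_components)


# ---------------------------------------------------------------------------
# random strongly-connected graph generator for routing tests


def random_sc_network(
    rng: np.random.Generator,
    n_nodes: int = 120,
    oneway_fraction: float = 0.12,
) -> RoadNetwork:
    """Random strongly connected directed network: spanning tree + chords,
    then convert edges to one-way while strong connectivity survives."""
    pos = {i: (rng.uniform(0, 10000), rng.uniform(0, 10000)) for i in range(n_nodes)}
    pairs: set[tuple[int, int]] = set()
    order = rng.permutation(n_nodes)
    for k in range(1, n_nodes):
        a, b = int(order[k]), int(order[int(rng.integers(0, k))])
        pairs.add((min(a, b), max(a, b)))
    extra = n_nodes  # chords: enough cycles to support one-way edges
    while extra > 0:
        a, b = (int(x) for x in rng.integers(0, n_nodes, 2))
        if a == b or (min(a, b), max(a, b)) in pairs:
            continue
        pairs.add((min(a, b), max(a, b)))
        extra -= 1
    pairs = sorted(pairs)
    lengths = [round(float(rng.uniform(0.05, 5.0)), 6) for _ in pairs]

    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for a, b in pairs:
        g.add_edge(a, b)
        g.add_edge(b, a)
    oneway = [False] * len(pairs)
    flipped = [False] * len(pairs)
    target = math.ceil(oneway_fraction * len(pairs))
    made = 0
    for k in rng.permutation(len(pairs)):
        if made >= target:
            break
        a, b = pairs[k]
        drop_forward = bool(rng.integers(0, 2))
        u, v = (a, b) if drop_forward else (b, a)
        g.remove_edge(u, v)
        if nx.is_strongly_connected(g):
            oneway[k] = True
            flipped[k] = drop_forward
            made += 1
        else:
            g.add_edge(u, v)
    assert made >= target, "could not reach the one-way fraction"

    edges = []
    for k, (a, b) in enumerate(pairs):
        if oneway[k] and flipped[k]:
            a, b = b, a
        edges.append(Edge(f"E{k}", a, b, lengths[k], oneway[k]))
    return RoadNetwork(pos, edges)


def brute_force_min_distances(
    network: RoadNetwork, origin_nodes: list[int], facility_nodes: list[int]
) -> dict[int, float]:
    """Independent oracle: FORWARD single-source Dijkstra from every origin
    over a separately constructed integer-weight graph, then take the
    minimum over facilities per origin."""
    g = nx.DiGraph()
    for e in network.edges:
        w = int(round(e.length_km * MICRO))
        g.add_edge(e.from_node, e.to_node, w=w)
        if not e.oneway:
            g.add_edge(e.to_node, e.from_node, w=w)
    out = {}
    for o in origin_nodes:
        dist = nx.single_source_dijkstra_path_length(g, o, weight="w")
        best = min((dist[f] for f in facility_nodes if f in dist), default=None)
        out[o] = math.inf if best is None else best / MICRO
    return out


# ---------------------------------------------------------------------------
# geometry oracles


def monte_carlo_intersection_area(
    region_a, region_b, rng: np.random.Generator, n: int = 10**6
) -> float:
    """Monte-Carlo estimate of area(region_a & region_b) by sampling the
    bounding box of region_a."""
    minx, miny, maxx, maxy = region_a.bounds
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    inside = shapely.contains_xy(region_a, xs, ys) & shapely.contains_xy(
        region_b, xs, ys
    )
    return float(inside.mean() * (maxx - minx) * (maxy - miny))


def fine_raster_zone_mean(raster, zone, res_m: float = 10.0) -> float:
    """Independent zonal-mean oracle: rasterise the zone at ``res_m`` and
    collect every parent cell containing an intersected fine cell."""
    poly = zone.shape()
    minx, miny, maxx, maxy = poly.bounds
    x0 = raster.xll + math.floor((minx - raster.xll) / res_m) * res_m
    y0 = raster.yll + math.floor((miny - raster.yll) / res_m) * res_m
    xs = np.arange(x0, maxx + res_m, res_m)
    ys = np.arange(y0, maxy + res_m, res_m)
    xx, yy = np.meshgrid(xs, ys)
    cells = shapely.box(xx.ravel(), yy.ravel(), xx.ravel() + res_m, yy.ravel() + res_m)
    hit = shapely.intersects(poly, cells)
    cx = xx.ravel()[hit] + res_m / 2.0
    cy = yy.ravel()[hit] + res_m / 2.0
    c = raster.cellsize_m
    jj = np.floor((cx - raster.xll) / c).astype(int)
    ii = np.floor((raster.ytop - cy) / c).astype(int)
    keep = (jj >= 0) & (jj < raster.ncols) & (ii >= 0) & (ii < raster.nrows)
    parents = set(zip(ii[keep].tolist(), jj[keep].tolist()))
    vals = [
        raster.values[i, j]
        for i, j in sorted(parents)
        if raster.values[i, j] != raster.nodata
    ]
    return float(np.mean(vals))
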