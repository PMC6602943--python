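"""Seeded synthetic study region for end-to-end testing of the pipeline.

The generator lays out a square planar extent (Cartesian metres, emulating
an Ordnance-Survey-style grid; no geographic CRS anywhere) with the spatial
structure the analysis assumes:

* an **urban core** at the centre of the extent where both service points
  (shops, GPs, pharmacies...) and hazards (pollution) concentrate;
* a **suburban ring** around it;
* a **remote periphery** where services thin out and green space is denser.

Service point densities decay with distance from the core, pollutant
rasters peak at the core plus seeded noise, and green polygons are placed
preferentially towards the periphery.  The road network is a perturbed
lattice with a configurable fraction of one-way edges, strongly connected
by construction and verified.

A single global seed fans out to fixed per-component child streams
(network, zones, postcodes, services, green space, rasters) so adding a
component never reshuffles the others.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Point

from . import io as ahio
from .errors import ConfigurationError, ValidationError
from .indicators import CATEGORIES
from .physical_environment import POLLUTANTS, GreenPolygon, RasterGrid, ZonePolygon
from .road_network import Edge, PostcodeRecord, RoadNetwork, ServiceSite

__all__ = [
    "RegionConfig",
    "SyntheticRegion",
    "generate_region",
    "write_region",
    "read_region",
    "DEFAULT_CATEGORY_COUNTS",
]

#: Default facility counts per category, proportioned like a mid-sized
#: study region: retail hazards are common, A&E hospitals rare.
DEFAULT_CATEGORY_COUNTS: dict[str, int] = {
    "fastfood": 30,
    "gambling": 8,
    "offlicence": 6,
    "tobacconist": 5,
    "pubs": 25,
    "gp": 12,
    "hospital": 3,
    "pharmacy": 12,
    "dentist": 10,
    "leisure": 6,
}

#: (background, amplitude, noise sd) of each pollutant surface; the
#: Gaussian bump is centred on the urban core.
_POLLUTANT_FIELDS: dict[str, tuple[float, float, float]] = {
    "no2": (6.0, 34.0, 1.5),
    "pm10": (9.0, 14.0, 1.0),
    "so2": (0.5, 4.0, 0.3),
}

#: minimum sensible zone area (km^2) used in the feasibility check
_MIN_ZONE_AREA_KM2 = 0.25

#: distance-rank quantile cut-offs for the core / suburban / remote bands
_BAND_CUTS = (0.35, 0.75)

# child-stream keys: adding a component never reshuffles the others
_STREAM_NETWORK, _STREAM_ZONES, _STREAM_POSTCODES = 0, 1, 2
_STREAM_SERVICES, _STREAM_GREEN, _STREAM_RASTERS = 3, 4, 5


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of the synthetic study region.

    ``urban_fraction`` controls clustering intensity: the service/pollution
    clustering scale is ``urban_fraction * extent_km / 2`` kilometres.
    """

    seed: int = 0
    extent_km: float = 20.0
    n_zones: int = 50
    postcodes_per_zone: tuple[int, int] = (5, 20)
    category_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    n_green_polygons: int = 120
    raster_cell_km: float = 1.0
    urban_fraction: float = 0.3
    oneway_fraction: float = 0.10
    background_fraction: float = 0.10  # uniform (non-clustered) service share

    def validate(self) -> None:
        if self.extent_km <= 0:
            raise ConfigurationError("extent_km must be positive")
        if self.n_zones < 1:
            raise ConfigurationError("n_zones must be >= 1")
        if self.extent_km**2 < self.n_zones * _MIN_ZONE_AREA_KM2:
            raise ConfigurationError(
                f"zones cannot tile extent: extent_km^2 = {self.extent_km ** 2:.1f} "
                f"< n_zones x {_MIN_ZONE_AREA_KM2} = "
                f"{self.n_zones * _MIN_ZONE_AREA_KM2:.1f} km^2"
            )
        lo, hi = self.postcodes_per_zone
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"postcodes_per_zone range invalid: ({lo}, {hi})"
            )
        for cat in CATEGORIES:
            if self.category_counts.get(cat, 0) < 1:
                raise ConfigurationError(
                    f"category_counts[{cat}] must be >= 1, got "
                    f"{self.category_counts.get(cat, 0)}"
                )
        unknown = set(self.category_counts) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown service categories: {sorted(unknown)}")
        if not (0 < self.urban_fraction < 1):
            raise ConfigurationError("urban_fraction must lie in (0, 1)")
        if self.raster_cell_km <= 0:
            raise ConfigurationError("raster_cell_km must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["postcodes_per_zone"] = list(self.postcodes_per_zone)
        d["category_counts"] = dict(self.category_counts)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegionConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown region config keys: {sorted(unknown)}")
        if "postcodes_per_zone" in d:
            d["postcodes_per_zone"] = tuple(d["postcodes_per_zone"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SyntheticRegion:
    """A generated study region: network, postcodes, zones, services,
    green space and pollutant rasters."""

    config: RegionConfig
    network: RoadNetwork
    postcodes: list[PostcodeRecord]
    zones: list[ZonePolygon]
    services: dict[str, list[ServiceSite]]
    green: list[GreenPolygon]
    rasters: dict[str, RasterGrid]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticRegion):
            return NotImplemented
        return (
            self.config == other.config
            and self.network.nodes == other.network.nodes
            and sorted(self.network.edges, key=lambda e: e.edge_id)
            == sorted(other.network.edges, key=lambda e: e.edge_id)
            and self.postcodes == other.postcodes
            and self.zones == other.zones
            and self.services == other.services
            and self.green == other.green
            and set(self.rasters) == set(other.rasters)
            and all(
                self.rasters[p].pollutant == other.rasters[p].pollutant
                and self.rasters[p].xll == other.rasters[p].xll
                and self.rasters[p].yll == other.rasters[p].yll
                and self.rasters[p].cellsize_m == other.rasters[p].cellsize_m
                and np.array_equal(self.rasters[p].values, other.rasters[p].values)
                for p in self.rasters
            )
        )

    def zone_by_code(self, code: str) -> ZonePolygon:
        for z in self.zones:
            if z.zone_code == code:
                return z
        raise KeyError(code)

    def validate(self) -> None:
        """Check the structural invariants of a generated region."""
        if not self.network.is_strongly_connected():
            raise ValidationError("road network is not strongly connected")
        extent_m = self.config.extent_km * 1000.0
        shapes = [(z.zone_code, z.shape()) for z in self.zones]
        for pc in self.postcodes:
            pt = Point(pc.centroid)
            owners = [code for code, s in shapes if s.contains(pt)]
            if len(owners) != 1:
                raise ValidationError(
                    f"postcode {pc.pcd} lies in {len(owners)} zones, expected 1"
                )
            if owners[0] != pc.zone_code:
                raise ValidationError(
                    f"postcode {pc.pcd}: zone_code {pc.zone_code} != containing "
                    f"zone {owners[0]}"
                )
        with_pc = {pc.zone_code for pc in self.postcodes}
        empty = [z.zone_code for z in self.zones if z.zone_code not in with_pc]
        if empty:
            raise ValidationError(f"zones without postcodes: {empty}")
        for cat, sites in self.services.items():
            for s in sites:
                x, y = s.location
                if not (0 <= x <= extent_m and 0 <= y <= extent_m):
                    raise ValidationError(
                        f"service {s.site_id} outside extent: {s.location}"
                    )
        for p, r in self.rasters.items():
            if (
                r.xll > 0
                or r.yll > 0
                or r.xll + r.ncols * r.cellsize_m < extent_m
                or r.yll + r.nrows * r.cellsize_m < extent_m
            ):
                raise ValidationError(f"raster {p} does not tile the extent")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _round1(x: float) -> float:
    return round(float(x), 1)


def _ceil6(x: float) -> float:
    return math.ceil(x * 1e6 - 1e-9) / 1e6


def _generate_network(cfg: RegionConfig) -> RoadNetwork:
    rng = _rng(cfg.seed, _STREAM_NETWORK)
    extent_m = cfg.extent_km * 1000.0
    side = max(4, int(round(cfg.extent_km / 1.25)))
    spacing = extent_m / side

    nodes: dict[int, tuple[float, float]] = {}
    for r in range(side):
        for c in range(side):
            jx, jy = rng.uniform(-0.2, 0.2, size=2) * spacing
            x = min(max((c + 0.5) * spacing + jx, 0.0), extent_m)
            y = min(max((r + 0.5) * spacing + jy, 0.0), extent_m)
            nodes[r * side + c] = (_round1(x), _round1(y))

    pairs: list[tuple[int, int]] = []
    for r in range(side):
        for c in range(side):
            nid = r * side + c
            if c + 1 < side:
                pairs.append((nid, nid + 1))
            if r + 1 < side:
                pairs.append((nid, nid + side))

    lengths = []
    for a, b in pairs:
        eu_km = math.dist(nodes[a], nodes[b]) / 1000.0
        lengths.append(_ceil6(eu_km * (1.0 + 0.25 * rng.uniform())))

    # choose one-way edges without breaking strong connectivity
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for (a, b) in pairs:
        g.add_edge(a, b)
        g.add_edge(b, a)
    oneway = [False] * len(pairs)
    flipped = [False] * len(pairs)  # oneway direction b->a instead of a->b
    target = int(round(cfg.oneway_fraction * len(pairs)))
    candidates = rng.permutation(len(pairs))
    made = 0
    for k in candidates:
        if made >= target:
            break
        a, b = pairs[k]
        drop_forward = bool(rng.integers(0, 2))  # keep only one direction
        u, v = (a, b) if drop_forward else (b, a)  # (u, v) is removed
        g.remove_edge(u, v)
        if nx.is_strongly_connected(g):
            oneway[k] = True
            flipped[k] = drop_forward  # kept direction is b->a
            made += 1
        else:
            g.add_edge(u, v)

    edges = []
    for k, (a, b) in enumerate(pairs):
        if oneway[k] and flipped[k]:
            a, b = b, a
        edges.append(Edge(f"E{k:04d}", a, b, lengths[k], oneway[k]))
    return RoadNetwork(nodes, edges)


def _generate_zones(cfg: RegionConfig) -> list[ZonePolygon]:
    rng = _rng(cfg.seed, _STREAM_ZONES)
    extent_m = cfg.extent_km * 1000.0
    n = cfg.n_zones
    rows = max(1, int(round(math.sqrt(n))))
    base, extra = divmod(n, rows)
    cols_per_row = [base + 1 if r < extra else base for r in range(rows)]
    if min(cols_per_row) < 1:
        rows = n
        cols_per_row = [1] * rows
    height = extent_m / rows

    zones: list[ZonePolygon] = []
    k = 0
    for r, ncols in enumerate(cols_per_row):
        width = extent_m / ncols
        y0, y1 = round(r * height, 2), round((r + 1) * height, 2)
        for c in range(ncols):
            x0, x1 = round(c * width, 2), round((c + 1) * width, 2)
            ring = ((x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0))
            zones.append(
                ZonePolygon(
                    zone_code=f"Z{k:03d}",
                    ring=ring,
                    population=int(rng.integers(500, 3001)),
                )
            )
            k += 1

    # classify bands by rank of centroid distance from the core
    centre = (extent_m / 2.0, extent_m / 2.0)
    dist = {
        z.zone_code: math.dist(z.shape().centroid.coords[0], centre) for z in zones
    }
    order = sorted(zones, key=lambda z: (dist[z.zone_code], z.zone_code))
    banded = []
    band_of = {}
    for rank, z in enumerate(order, start=1):
        q = rank / n
        band_of[z.zone_code] = (
            "core" if q <= _BAND_CUTS[0] else "suburban" if q <= _BAND_CUTS[1] else "remote"
        )
    for z in zones:
        banded.append(
            ZonePolygon(z.zone_code, z.ring, z.population, band_of[z.zone_code])
        )
    return banded


def _generate_postcodes(
    cfg: RegionConfig, zones: list[ZonePolygon]
) -> list[PostcodeRecord]:
    rng = _rng(cfg.seed, _STREAM_POSTCODES)
    lo, hi = cfg.postcodes_per_zone
    out: list[PostcodeRecord] = []
    idx = 1
    for z in zones:
        xs = [p[0] for p in z.ring]
        ys = [p[1] for p in z.ring]
        x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
        count = int(rng.integers(lo, hi + 1))
        for _ in range(count):
            x = _round1(rng.uniform(x0 + 1.0, x1 - 1.0))
            y = _round1(rng.uniform(y0 + 1.0, y1 - 1.0))
            out.append(PostcodeRecord(f"PC{idx:05d}", (x, y), z.zone_code))
            idx += 1
    return out


def _sample_clustered(
    rng: np.random.Generator, centre: tuple[float, float], sigma: float, extent_m: float
) -> tuple[float, float]:
    while True:
        r = abs(rng.normal(0.0, sigma))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        x = centre[0] + r * math.cos(theta)
        y = centre[1] + r * math.sin(theta)
        if 0.0 <= x <= extent_m and 0.0 <= y <= extent_m:
            return x, y


def _generate_services(cfg: RegionConfig) -> dict[str, list[ServiceSite]]:
    rng = _rng(cfg.seed, _STREAM_SERVICES)
    extent_m = cfg.extent_km * 1000.0
    centre = (extent_m / 2.0, extent_m / 2.0)
    sigma = cfg.urban_fraction * extent_m / 2.0
    services: dict[str, list[ServiceSite]] = {}
    for cat in CATEGORIES:
        count = int(cfg.category_counts[cat])
        sites = []
        for i in range(count):
            if rng.uniform() < cfg.background_fraction:
                x, y = rng.uniform(0.0, extent_m, size=2)
            else:
                x, y = _sample_clustered(rng, centre, sigma, extent_m)
            sites.append(
                ServiceSite(f"{cat}_{i:03d}", cat, (_round1(x), _round1(y)))
            )
        services[cat] = sites
    return services


def _generate_green(cfg: RegionConfig) -> list[GreenPolygon]:
    rng = _rng(cfg.seed, _STREAM_GREEN)
    extent_m = cfg.extent_km * 1000.0
    centre = (extent_m / 2.0, extent_m / 2.0)
    dmax = math.dist((0.0, 0.0), centre)
    tags = ("park", "wood", "meadow", "recreation_ground", "grass")
    out: list[GreenPolygon] = []
    k = 0
    while len(out) < cfg.n_green_polygons:
        x, y = rng.uniform(0.0, extent_m, size=2)
        d = math.dist((x, y), centre)
        accept = rng.uniform() < (d / dmax) ** 1.5  # denser towards periphery
        w = rng.uniform(100.0, 600.0)
        h = rng.uniform(100.0, 600.0)
        tag = tags[int(rng.integers(0, len(tags)))]
        if not accept:
            continue
        x0 = _round1(max(0.0, x - w / 2))
        x1 = _round1(min(extent_m, x + w / 2))
        y0 = _round1(max(0.0, y - h / 2))
        y1 = _round1(min(extent_m, y + h / 2))
        if x1 - x0 < 10.0 or y1 - y0 < 10.0:
            continue
        ring = ((x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0))
        out.append(GreenPolygon(f"G{k:03d}", ring, tag))
        k += 1
    return out


def _generate_rasters(cfg: RegionConfig) -> dict[str, RasterGrid]:
    rng = _rng(cfg.seed, _STREAM_RASTERS)
    extent_m = cfg.extent_km * 1000.0
    cell = cfg.raster_cell_km * 1000.0
    ncells = int(math.ceil(extent_m / cell))
    centre = (extent_m / 2.0, extent_m / 2.0)
    sigma = cfg.urban_fraction * extent_m / 2.0

    # cell centres; row 0 is the northernmost row (ESRI ASCII layout)
    xs = (np.arange(ncells) + 0.5) * cell
    ys = ncells * cell - (np.arange(ncells) + 0.5) * cell
    xx, yy = np.meshgrid(xs, ys)
    d2 = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2
    bump = np.exp(-d2 / (2.0 * sigma**2))

    rasters: dict[str, RasterGrid] = {}
    for pollutant in POLLUTANTS:
        base, amp, noise = _POLLUTANT_FIELDS[pollutant]
        values = base + amp * bump + noise * rng.standard_normal((ncells, ncells))
        values = np.round(np.clip(values, 0.01, None), 3)
        rasters[pollutant] = RasterGrid(
            pollutant=pollutant,
            xll=0.0,
            yll=0.0,
            cellsize_m=cell,
            values=values,
            nodata=-9999.0,
        )
    return rasters


def generate_region(config: RegionConfig) -> SyntheticRegion:
    """Generate a seeded synthetic study region.

    Deterministic: the same config (including seed) produces an identical
    region, byte-for-byte after serialisation.  Raises
    :class:`ConfigurationError` naming the violated constraint for
    infeasible configs.
    """
    config.validate()
    zones = _generate_zones(config)
    region = SyntheticRegion(
        config=config,
        network=_generate_network(config),
        postcodes=_generate_postcodes(config, zones),
        zones=zones,
        services=_generate_services(config),
        green=_generate_green(config),
        rasters=_generate_rasters(config),
    )
    region.validate()
    return region


# ---------------------------------------------------------------------------
# serialisation


def write_region(region: SyntheticRegion, directory: str | Path) -> dict:
    """Write a region to ``directory``; returns the manifest.

    Emits nodes/edges/postcodes CSVs, zones/services/greenspace GeoJSON,
    one ESRI ASCII grid per pollutant, and ``manifest.json`` recording the
    file list, seed and config.  Round-trips losslessly through
    :func:`read_region`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    nodes_df = pd.DataFrame(
        [
            {"node_id": nid, "easting_m": xy[0], "northing_m": xy[1]}
            for nid, xy in sorted(region.network.nodes.items())
        ]
    )
    ahio.write_csv_table(nodes_df, directory / "nodes.csv", float_format="%.1f")
    files.append("nodes.csv")

    edges_df = pd.DataFrame(
        [
            {
                "edge_id": e.edge_id,
                "from_node": e.from_node,
                "to_node": e.to_node,
                "length_km": e.length_km,
                "oneway": int(e.oneway),
            }
            for e in region.network.edges
        ]
    )
    ahio.write_csv_table(edges_df, directory / "edges.csv", float_format="%.6f")
    files.append("edges.csv")

    pc_df = pd.DataFrame(
        [
            {
                "pcd": p.pcd,
                "easting_m": p.centroid[0],
                "northing_m": p.centroid[1],
                "zone_code": p.zone_code,
            }
            for p in region.postcodes
        ]
    )
    ahio.write_csv_table(pc_df, directory / "postcodes.csv", float_format="%.1f")
    files.append("postcodes.csv")

    from shapely.geometry import Polygon

    ahio.write_geojson(
        [
            (
                Polygon(z.ring),
                {"zone_code": z.zone_code, "population": z.population, "band": z.band},
            )
            for z in region.zones
        ],
        directory / "zones.geojson",
    )
    files.append("zones.geojson")

    for cat in CATEGORIES:
        ahio.write_geojson(
            [
                (Point(s.location), {"site_id": s.site_id, "category": s.category})
                for s in region.services[cat]
            ],
            directory / f"services_{cat}.geojson",
        )
        files.append(f"services_{cat}.geojson")

    ahio.write_geojson(
        [
            (Polygon(g.ring), {"polygon_id": g.polygon_id, "tag": g.tag})
            for g in region.green
        ],
        directory / "greenspace.geojson",
    )
    files.append("greenspace.geojson")

    for pollutant in POLLUTANTS:
        ahio.write_ascii_grid(region.rasters[pollutant], directory / f"{pollutant}.asc")
        files.append(f"{pollutant}.asc")

    manifest = {
        "files": files,
        "seed": region.config.seed,
        "config": region.config.to_dict(),
        "config_hash": region.config.config_hash(),
        "n_postcodes": len(region.postcodes),
        "n_zones": len(region.zones),
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return manifest


def read_region(directory: str | Path) -> SyntheticRegion:
    """Read a region previously written by :func:`write_region`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = RegionConfig.from_dict(manifest["config"])

    nodes_df = ahio.read_csv_table(
        directory / "nodes.csv", ["node_id", "easting_m", "northing_m"]
    )
    nodes = {
        int(r.node_id): (float(r.easting_m), float(r.northing_m))
        for r in nodes_df.itertuples()
    }
    edges_df = ahio.read_csv_table(
        directory / "edges.csv",
        ["edge_id", "from_node", "to_node", "length_km", "oneway"],
    )
    edges = [
        Edge(r.edge_id, int(r.from_node), int(r.to_node), float(r.length_km), bool(r.oneway))
        for r in edges_df.itertuples()
    ]
    network = RoadNetwork(nodes, edges)

    pc_df = ahio.read_csv_table(
        directory / "postcodes.csv", ["pcd", "easting_m", "northing_m", "zone_code"]
    )
    postcodes = [
        PostcodeRecord(r.pcd, (float(r.easting_m), float(r.northing_m)), r.zone_code)
        for r in pc_df.itertuples()
    ]

    zones = [
        ZonePolygon(
            props["zone_code"],
            tuple((x, y) for x, y in geom.exterior.coords),
            int(props["population"]),
            props.get("band", ""),
        )
        for geom, props in ahio.read_geojson(directory / "zones.geojson")
    ]

    services: dict[str, list[ServiceSite]] = {}
    for cat in CATEGORIES:
        services[cat] = [
            ServiceSite(props["site_id"], props["category"], (geom.x, geom.y))
            for geom, props in ahio.read_geojson(directory / f"services_{cat}.geojson")
        ]

    green = [
        GreenPolygon(
            props["polygon_id"],
            tuple((x, y) for x, y in geom.exterior.coords),
            props.get("tag", "park"),
        )
        for geom, props in ahio.read_geojson(directory / "greenspace.geojson")
    ]

    rasters = {
        p: ahio.read_ascii_grid(directory / f"{p}.asc", pollutant=p)
        for p in POLLUTANTS
    }
    return SyntheticRegion(
        config=config,
        network=network,
        postcodes=postcodes,
        zones=zones,
        services=services,
        green=green,
        rasters=rasters,
    )
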