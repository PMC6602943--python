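"""Stage orchestration: chain generation, access, environment, aggregation
and index construction, writing every interchange file along the way.

Each stage is a plain function over in-memory objects; ``run_all`` wires
them together for the CLI and logs the config hash, seed and per-stage row
counts.  Outputs are written in fixed 6-decimal notation, so running the
pipeline twice with one seed yields byte-identical directories.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as ahio
from .config import PipelineConfig
from .errors import ConfigurationError
from .indicators import CATEGORIES, aggregate_postcodes, assemble_table
from .index_construction import AHAHResult, construct_index, diagnostics
from .physical_environment import POLLUTANTS, greenspace_area, raster_zone_mean
from .road_network import nearest_facility_distances
from .synthetic_region import SyntheticRegion, generate_region, write_region

__all__ = [
    "compute_access",
    "compute_green",
    "compute_air",
    "build_components",
    "run_all",
]

log = logging.getLogger("ahah")


def compute_access(
    region: SyntheticRegion,
    categories: Sequence[str] | None = None,
    allow_unreachable: bool = False,
) -> pd.DataFrame:
    """Per-postcode network distance (km) to the nearest facility of each
    category; long frame with columns pcd, category, distance_km."""
    cats = list(categories) if categories else list(CATEGORIES)
    unknown = set(cats) - set(CATEGORIES)
    if unknown:
        raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
    facilities = []
    for cat in cats:
        sites = region.services.get(cat, [])
        if not sites:
            raise ConfigurationError(f"no facilities for category '{cat}'")
        facilities.extend(sites)
    results = nearest_facility_distances(
        region.network, region.postcodes, facilities, allow_unreachable
    )
    df = pd.DataFrame(
        [
            {"pcd": r.pcd, "category": r.category, "distance_km": r.distance_km}
            for r in results
        ]
    )
    order = {c: i for i, c in enumerate(cats)}
    return df.sort_values(
        ["category", "pcd"], key=lambda s: s.map(order) if s.name == "category" else s
    ).reset_index(drop=True)


def compute_green(
    region: SyntheticRegion, buffer_m: float = 900.0, mode: str = "clipped"
) -> pd.DataFrame:
    """Green-space area (m^2) within each postcode's buffer."""
    rows = [
        {
            "pcd": p.pcd,
            "green_area_m2": greenspace_area(p, region.green, buffer_m, mode),
        }
        for p in region.postcodes
    ]
    return pd.DataFrame(rows)


def compute_air(region: SyntheticRegion, rule: str = "footprint") -> pd.DataFrame:
    """Zone-mean pollutant concentrations; frame indexed by zone_code."""
    rows = []
    for z in region.zones:
        row = {"zone_code": z.zone_code}
        for p in POLLUTANTS:
            row[p] = raster_zone_mean(region.rasters[p], z, rule)
        rows.append(row)
    return pd.DataFrame(rows).set_index("zone_code").sort_index()


def build_components(
    region: SyntheticRegion,
    access: pd.DataFrame,
    green: pd.DataFrame,
    air: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate postcode measures to zones and assemble the zone x 14 table."""
    lookup = pd.Series(
        {p.pcd: p.zone_code for p in region.postcodes}, name="zone_code"
    )
    access_zone = {}
    for cat, grp in access.groupby("category"):
        access_zone[cat] = aggregate_postcodes(
            grp.set_index("pcd")["distance_km"], lookup
        )
    access_df = pd.DataFrame(access_zone)
    green_zone = aggregate_postcodes(green.set_index("pcd")["green_area_m2"], lookup)
    return assemble_table(
        access_df,
        green_zone,
        air,
        provenance={
            "seed": region.config.seed,
            "config_hash": region.config.config_hash(),
        },
    )


def run_all(config: PipelineConfig, out_dir: str | Path) -> AHAHResult:
    """Run the whole pipeline and write every artefact under ``out_dir``.

    Layout: ``region/`` (synthetic inputs), ``access_postcode.csv``,
    ``green_postcode.csv``, ``air_zone.csv``, ``ahah_components.csv``,
    ``ahah_index.csv``, ``diagnostics_correlations.csv``,
    ``config_used.yaml``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info(
        "run-all: seed=%d config_hash=%s",
        config.region.seed,
        config.region.config_hash(),
    )

    region = generate_region(config.region)
    write_region(region, out_dir / "region")
    log.info(
        "region: %d zones, %d postcodes, %d nodes",
        len(region.zones),
        len(region.postcodes),
        len(region.network),
    )

    access = compute_access(region)
    ahio.write_csv_table(access, out_dir / "access_postcode.csv")
    log.info("access: %d rows", len(access))

    green = compute_green(region, config.buffer_m, config.green_area_mode)
    ahio.write_csv_table(green, out_dir / "green_postcode.csv")
    air = compute_air(region, config.raster_overlap)
    ahio.write_csv_table(
        air.reset_index(), out_dir / "air_zone.csv"
    )
    log.info("environment: %d green rows, %d air rows", len(green), len(air))

    table = build_components(region, access, green, air)
    result = construct_index(
        table,
        indicator_weights={k: v for k, v in config.weights.items() if k != "domains"},
        domain_weights=config.weights.get("domains"),
    )
    ahio.write_csv_table(
        result.components_frame().reset_index(), out_dir / "ahah_components.csv"
    )
    ahio.write_csv_table(
        result.index_frame().reset_index(), out_dir / "ahah_index.csv"
    )
    corr = diagnostics(table, result, config.correlation)
    ahio.write_csv_table(
        corr.rename_axis("indicator").reset_index(),
        out_dir / "diagnostics_correlations.csv",
    )
    config.to_yaml(out_dir / "config_used.yaml")
    log.info("index: %d zones written", len(table))
    return result
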