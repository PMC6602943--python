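"""Readers and writers for the pipeline's interchange formats.

Formats: CSV tables with declared schemas, GeoJSON feature collections
(planar coordinates in metres — no CRS, by design), and ESRI ASCII grids
for the pollutant rasters.  All tabular numeric output uses fixed 6-decimal
notation so byte-identical reruns are testable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .errors import ParseError
from .physical_environment import RasterGrid

__all__ = [
    "read_csv_table",
    "write_csv_table",
    "read_geojson",
    "write_geojson",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: marker written for undefined (zero-variance) correlations
UNDEFINED_MARKER = "undefined"


def read_csv_table(path: str | Path, schema: Sequence[str]) -> pd.DataFrame:
    """Read a CSV table and validate its header against ``schema``.

    The header must contain every schema column (extra columns are
    rejected); non-numeric cells in numeric columns are reported with their
    row number.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # malformed CSV arity etc.
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing column(s) {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise ParseError(f"{path}: unexpected column(s) {extra}")
    out = df[list(schema)].copy()
    for col in schema:
        if col in _STRING_COLUMNS:
            continue
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[converted.isna() & out[col].notna()]
        if len(bad) > 0:
            raise ParseError(
                f"{path}: non-numeric value in column '{col}' at row "
                f"{int(bad[0]) + 2}"  # +2: header line + 1-based
            )
        out[col] = converted
    return out


#: columns that stay as strings when reading any pipeline CSV
_STRING_COLUMNS = {"pcd", "zone_code", "category", "edge_id", "indicator", "band"}


def write_csv_table(
    df: pd.DataFrame,
    path: str | Path,
    float_format: str = "%.6f",
    index: bool = False,
    na_rep: str = UNDEFINED_MARKER,
) -> None:
    """Write a table in fixed decimal notation (default 6 places)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=float_format, index=index, na_rep=na_rep)


def read_geojson(path: str | Path) -> list[tuple[object, dict]]:
    """Read a GeoJSON FeatureCollection as ``[(shapely geometry, properties)]``."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except FileNotFoundError:
        raise ParseError(f"no such file: {path}")
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    if data.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for k, feat in enumerate(data.get("features", [])):
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise ParseError(f"{path}: feature {k}: bad geometry ({exc})") from exc
        if geom.geom_type in ("Polygon", "MultiPolygon") and not geom.is_valid:
            raise ParseError(f"{path}: feature {k}: invalid ring")
        out.append((geom, dict(feat.get("properties") or {})))
    return out


def write_geojson(
    features: Iterable[tuple[object, dict]], path: str | Path
) -> None:
    """Write ``(geometry, properties)`` pairs as a FeatureCollection.

    Keys are sorted and floats serialised by ``json`` so identical inputs
    produce identical bytes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": props,
            }
            for geom, props in features
        ],
    }
    path.write_text(json.dumps(fc, sort_keys=True, separators=(",", ":")) + "\n")


def read_ascii_grid(path: str | Path, pollutant: str = "") -> RasterGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize/
    NODATA_value header, then row-major values, northernmost row first)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ParseError(f"{path}: missing header field '{req}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    try:
        flat = np.array(" ".join(lines[i:]).split(), dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric grid value ({exc})") from exc
    if flat.size != ncols * nrows:
        raise ParseError(
            f"{path}: expected {ncols * nrows} values for "
            f"{nrows}x{ncols} grid, found {flat.size}"
        )
    return RasterGrid(
        pollutant=pollutant or path.stem,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize_m=header["cellsize"],
        values=flat.reshape(nrows, ncols),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(
    raster: RasterGrid, path: str | Path, value_format: str = "%.3f"
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.1f}\n")
        fh.write(f"yllcorner {raster.yll:.1f}\n")
        fh.write(f"cellsize {raster.cellsize_m:.1f}\n")
        fh.write(f"NODATA_value {raster.nodata:.1f}\n")
        for row in raster.values:
            fh.write(" ".join(value_format % v for v in row) + "\n")
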