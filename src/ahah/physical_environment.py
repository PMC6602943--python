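"""Green-space buffer areas and zonal pollutant means.

Two indicator families are not network distances.  Green space is measured
as the area (m^2) of publicly accessible green polygons intersecting a
900 m circular buffer around each postcode centroid — the radius
corresponding to a roughly 15-minute walk.  Air quality is measured as the
unweighted mean of 1x1 km modelled concentration cells whose footprint
overlaps each zone polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box

from .errors import ValidationError
from .road_network import PostcodeRecord

__all__ = [
    "GreenPolygon",
    "ZonePolygon",
    "RasterGrid",
    "greenspace_area",
    "raster_zone_mean",
    "POLLUTANTS",
]

POLLUTANTS: tuple[str, ...] = ("no2", "pm10", "so2")

#: Segments per quarter circle when approximating buffers as polygons.
DEFAULT_QUAD_SEGS = 64


@dataclass(frozen=True)
class GreenPolygon:
    """A publicly accessible green-space polygon (park, wood, meadow...)."""

    polygon_id: str
    ring: tuple[tuple[float, float], ...]
    tag: str = "park"
    area_m2: float = field(default=0.0)

    def __post_init__(self):
        poly = self.shape()
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError(f"green polygon {self.polygon_id}: invalid ring")
        if self.area_m2 == 0.0:
            object.__setattr__(self, "area_m2", poly.area)
        elif abs(self.area_m2 - poly.area) > 1e-6 * max(1.0, poly.area):
            raise ValidationError(
                f"green polygon {self.polygon_id}: declared area {self.area_m2} "
                f"!= ring area {poly.area}"
            )

    def shape(self) -> Polygon:
        return Polygon(self.ring)


@dataclass(frozen=True)
class ZonePolygon:
    """A small-area statistical zone (LSOA/Data Zone analogue).

    ``band`` records the zone's position in the synthetic urban structure
    ('core', 'suburban' or 'remote'); it is metadata, not used in scoring.
    """

    zone_code: str
    ring: tuple[tuple[float, float], ...]
    population: int = 1500
    band: str = ""

    def __post_init__(self):
        poly = self.shape()
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError(f"zone {self.zone_code}: invalid ring")

    def shape(self) -> Polygon:
        return Polygon(self.ring)


@dataclass
class RasterGrid:
    """A row-major concentration grid in ESRI ASCII layout.

    ``values[0]`` is the NORTHERNMOST row; cell (row i, col j) covers
    x in [xll + j*c, xll + (j+1)*c), y in [ytop - (i+1)*c, ytop - i*c)
    where c is ``cellsize_m`` and ytop = yll + nrows*c.
    """

    pollutant: str
    xll: float
    yll: float
    cellsize_m: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"raster {self.pollutant}: values must be 2-D")
        if self.cellsize_m <= 0:
            raise ValidationError(f"raster {self.pollutant}: cellsize must be > 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def ytop(self) -> float:
        return self.yll + self.nrows * self.cellsize_m

    def cell_box(self, i: int, j: int) -> Polygon:
        c = self.cellsize_m
        x0 = self.xll + j * c
        y1 = self.ytop - i * c
        return box(x0, y1 - c, x0 + c, y1)

    def cell_centre(self, i: int, j: int) -> tuple[float, float]:
        c = self.cellsize_m
        return (self.xll + (j + 0.5) * c, self.ytop - (i + 0.5) * c)


def buffer_polygon(
    centroid: tuple[float, float],
    buffer_m: float,
    quad_segs: int = DEFAULT_QUAD_SEGS,
) -> Polygon:
    """Circular buffer approximated by a regular polygon (fixed segment
    count per quarter circle, so results are platform-deterministic)."""
    return Point(centroid).buffer(buffer_m, quad_segs=quad_segs)


def greenspace_area(
    postcode: PostcodeRecord | tuple[float, float],
    green: Sequence[GreenPolygon],
    buffer_m: float = 900.0,
    mode: str = "clipped",
    quad_segs: int = DEFAULT_QUAD_SEGS,
) -> float:
    """Green-space area (m^2) associated with a postcode's buffer.

    mode='clipped' (default): area of the geometric intersection between the
    buffer and the union of green polygons — overlapping polygons are not
    double-counted and the result is bounded by the buffer area.
    mode='whole_polygon': total area of every green polygon that intersects
    the buffer with positive area, regardless of how much lies inside.
    """
    if buffer_m <= 0:
        raise ValidationError(f"buffer_m must be > 0, got {buffer_m}")
    if mode not in ("clipped", "whole_polygon"):
        raise ValidationError(f"unknown green_area_mode '{mode}'")
    if not green:
        return 0.0
    centroid = postcode.centroid if isinstance(postcode, PostcodeRecord) else postcode
    buf = buffer_polygon(centroid, buffer_m, quad_segs)
    shapes = [g.shape() for g in green]
    if mode == "clipped":
        return float(buf.intersection(shapely.unary_union(shapes)).area)
    total = 0.0
    for g, s in zip(green, shapes):
        if buf.intersection(s).area > 0:
            total += g.area_m2
    return total


def raster_zone_mean(
    raster: RasterGrid,
    zone: ZonePolygon,
    rule: str = "footprint",
) -> float:
    """Unweighted mean of raster cells overlapping a zone polygon.

    rule='footprint' (default): a cell contributes if its square footprint
    intersects the zone with positive area.  rule='centre': a cell
    contributes if its centre point lies within the zone.  Nodata cells are
    excluded.  Raises :class:`ValidationError` if no valid cell overlaps.
    """
    if rule not in ("footprint", "centre"):
        raise ValidationError(f"unknown raster overlap rule '{rule}'")
    poly = zone.shape()
    minx, miny, maxx, maxy = poly.bounds
    c = raster.cellsize_m
    # candidate cell index window from the zone bounding box
    j0 = max(0, int(np.floor((minx - raster.xll) / c)))
    j1 = min(raster.ncols - 1, int(np.floor((maxx - raster.xll) / c)))
    i0 = max(0, int(np.floor((raster.ytop - maxy) / c)))
    i1 = min(raster.nrows - 1, int(np.floor((raster.ytop - miny) / c)))
    if j1 < j0 or i1 < i0:
        raise ValidationError(
            f"zone {zone.zone_code} lies outside raster {raster.pollutant}"
        )

    contributing: list[float] = []
    any_overlap = False
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            if rule == "footprint":
                hit = poly.intersection(raster.cell_box(i, j)).area > 0
            else:
                hit = poly.covers(Point(raster.cell_centre(i, j)))
            if not hit:
                continue
            any_overlap = True
            v = raster.values[i, j]
            if v != raster.nodata and np.isfinite(v):
                contributing.append(float(v))
    if not any_overlap:
        raise ValidationError(
            f"zone {zone.zone_code} does not overlap raster {raster.pollutant}"
        )
    if not contributing:
        raise ValidationError(
            f"zone {zone.zone_code}: all overlapping {raster.pollutant} "
            "cells are nodata"
        )
    return float(np.mean(contributing))
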