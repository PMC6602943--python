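"""Indicator vocabulary and the zone x 14 indicator table.

The index summarises 14 neighbourhood measures in three domains:

* retail environment — network distance (km) to fast food outlets, gambling
  outlets, off-licences, tobacconists, and pubs/bars/nightclubs;
* health services — network distance (km) to GP practices, A&E hospitals,
  pharmacies, dentists, and leisure centres;
* physical environment — green-space area (m^2) within a 900 m buffer of
  each postcode, and zone-mean NO2, PM10 and SO2 concentrations.

Postcode-level measures are aggregated to zones by the unweighted arithmetic
mean; pollutant means are computed directly at zone level.  ``orientation``
records which indicators must be sign-flipped before standardisation so that
a larger value always means *less* healthy: proximity to retail hazards and
abundant green space are health-promoting, so those raw measures are flipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

__all__ = [
    "IndicatorSpec",
    "INDICATORS",
    "INDICATOR_NAMES",
    "CATEGORIES",
    "RETAIL_CATEGORIES",
    "HEALTH_CATEGORIES",
    "DOMAINS",
    "DOMAIN_MEMBERS",
    "aggregate_postcodes",
    "assemble_table",
]


@dataclass(frozen=True)
class IndicatorSpec:
    """One of the 14 indicators feeding the index.

    orientation 'flip' means a larger raw value is *healthier* (distance to a
    hazard, green area) and must be negated before ranking; 'keep' means a
    larger raw value is already less healthy (distance to a service,
    pollutant concentration).
    """

    name: str
    domain: str  # 'retail' | 'health' | 'physical'
    unit: str  # 'km' | 'm2' | 'concentration'
    orientation: str  # 'flip' | 'keep'


#: Canonical indicator order: 5 retail, 5 health services, green space,
#: 3 pollutants.  Leisure centres sit in the health-services domain.
INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("fastfood", "retail", "km", "flip"),
    IndicatorSpec("gambling", "retail", "km", "flip"),
    IndicatorSpec("offlicence", "retail", "km", "flip"),
    IndicatorSpec("tobacconist", "retail", "km", "flip"),
    IndicatorSpec("pubs", "retail", "km", "flip"),
    IndicatorSpec("gp", "health", "km", "keep"),
    IndicatorSpec("hospital", "health", "km", "keep"),
    IndicatorSpec("pharmacy", "health", "km", "keep"),
    IndicatorSpec("dentist", "health", "km", "keep"),
    IndicatorSpec("leisure", "health", "km", "keep"),
    IndicatorSpec("green", "physical", "m2", "flip"),
    IndicatorSpec("no2", "physical", "concentration", "keep"),
    IndicatorSpec("pm10", "physical", "concentration", "keep"),
    IndicatorSpec("so2", "physical", "concentration", "keep"),
)

INDICATOR_NAMES: tuple[str, ...] = tuple(spec.name for spec in INDICATORS)

#: The 10 point-accessibility categories (all km indicators).
CATEGORIES: tuple[str, ...] = tuple(s.name for s in INDICATORS if s.unit == "km")
RETAIL_CATEGORIES: tuple[str, ...] = tuple(
    s.name for s in INDICATORS if s.domain == "retail"
)
HEALTH_CATEGORIES: tuple[str, ...] = tuple(
    s.name for s in INDICATORS if s.domain == "health" and s.unit == "km"
)

DOMAINS: tuple[str, ...] = ("retail", "health", "physical")
DOMAIN_MEMBERS: dict[str, tuple[str, ...]] = {
    d: tuple(s.name for s in INDICATORS if s.domain == d) for d in DOMAINS
}

SPEC_BY_NAME: dict[str, IndicatorSpec] = {s.name: s for s in INDICATORS}


def aggregate_postcodes(
    values: Mapping[str, float] | pd.Series,
    lookup: Mapping[str, str] | pd.Series,
) -> pd.Series:
    """Aggregate per-postcode values to zones by the unweighted mean.

    Parameters
    ----------
    values : postcode -> measure (e.g. distance in km).
    lookup : postcode -> zone_code.

    Returns a Series indexed by zone_code, sorted by zone_code.
    """
    values = pd.Series(values, dtype=float)
    lookup = pd.Series(lookup)
    missing = values.index.difference(lookup.index)
    if len(missing) > 0:
        raise ValidationError(
            f"postcode(s) without a zone: {sorted(missing)[:10]}"
        )
    zones = lookup.reindex(values.index)
    out = values.groupby(zones).mean()
    out.index.name = "zone_code"
    return out.sort_index()


def assemble_table(
    access: pd.DataFrame,
    green: pd.Series,
    air: pd.DataFrame,
    provenance: dict | None = None,
) -> pd.DataFrame:
    """Join the three indicator families into the zone x 14 table.

    Parameters
    ----------
    access : zone x 10 frame of mean network distances (km), columns named
        after the accessibility categories.
    green : zone series of mean green-space area (m^2).
    air : zone x 3 frame of pollutant means, columns no2/pm10/so2.
    provenance : optional metadata (seed, config hash) stored in
        ``DataFrame.attrs['provenance']``.

    Returns the table with columns in the canonical indicator order and rows
    sorted by zone_code.  Raises :class:`ValidationError` with the symmetric
    difference of zone codes if the inputs disagree.
    """
    access = access.copy()
    green = pd.Series(green, dtype=float)
    air = air.copy()

    zone_sets = {
        "access": set(access.index),
        "green": set(green.index),
        "air": set(air.index),
    }
    ref = zone_sets["access"]
    for name, zs in zone_sets.items():
        if zs != ref:
            diff = sorted(ref.symmetric_difference(zs))
            raise ValidationError(
                f"zone_code mismatch between access and {name}: {diff}"
            )

    missing_cols = [c for c in CATEGORIES if c not in access.columns]
    if missing_cols:
        raise ValidationError(f"access table missing categories: {missing_cols}")
    missing_air = [c for c in ("no2", "pm10", "so2") if c not in air.columns]
    if missing_air:
        raise ValidationError(f"air table missing pollutants: {missing_air}")

    table = pd.concat(
        [access[list(CATEGORIES)], green.rename("green"), air[["no2", "pm10", "so2"]]],
        axis=1,
    )
    table = table[list(INDICATOR_NAMES)].sort_index()
    table.index.name = "zone_code"

    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing indicator values for zones: {bad[:10]}")
    if (table[list(CATEGORIES)] < 0).any().any():
        raise ValidationError("negative network distance in indicator table")

    table.attrs["provenance"] = dict(provenance or {})
    return table


def validate_table(table: pd.DataFrame) -> None:
    """Check an indicator table has the 14 canonical columns and no gaps."""
    cols = list(table.columns)
    if cols != list(INDICATOR_NAMES):
        raise ValidationError(
            f"indicator table columns {cols} != canonical order {list(INDICATOR_NAMES)}"
        )
    if table.isna().any().any():
        raise ValidationError("indicator table contains missing cells")
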