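"""Colony census: zone densities and extrapolation to unsurveyed zones.

A chinstrap colony is partitioned into guano-rich zones (GRZ), where nesting
birds cluster at high density, and outer zones (OZ).  Only part of the colony
is photographed at a resolution that supports individual detection; detected
counts in the surveyed zones give per-class densities, which are transferred
to same-class unsurveyed zones to complete the census.  The colony total is
the sum over zones, with uncertainties combined in quadrature (zone counts
treated as independent).

Counts are kept as real numbers internally; rounding to whole individuals
happens only at report time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import shape
from shapely.validation import explain_validity

from .quantities import (
    InvalidInputError,
    UncertainQuantity,
    UndefinedQuotientError,
    propagate_first_order,
)

__all__ = [
    "ZoneCensus",
    "polygon_area",
    "zone_density",
    "extrapolate_count",
    "total_census",
    "load_zone_table",
    "InvalidGeometryError",
    "WrongCRSError",
    "ClassMismatchError",
    "IncompleteCensusError",
]

ZONE_CLASSES = ("GRZ", "OZ")


class InvalidGeometryError(ValueError):
    """Degenerate or self-intersecting zone polygon."""


class WrongCRSError(ValueError):
    """Polygon coordinates look geographic (degrees) instead of projected metres."""


class ClassMismatchError(ValueError):
    """Density transferred between zones of different classes (GRZ vs OZ)."""


class IncompleteCensusError(ValueError):
    """A total was requested while some zone still has no count."""


@dataclass(frozen=True)
class ZoneCensus:
    """One colony zone: class, area, and (if surveyed) a detection count."""

    zone_id: str
    zone_class: str  # "GRZ" | "OZ"
    area: UncertainQuantity  # m2
    count: UncertainQuantity | None = None  # individuals; None = unsurveyed
    density: UncertainQuantity | None = None  # ind/m2, derived

    def __post_init__(self) -> None:
        if self.zone_class not in ZONE_CLASSES:
            raise InvalidInputError(
                f"zone_class must be one of {ZONE_CLASSES}, got {self.zone_class!r}")
        if self.area.value <= 0:
            raise InvalidInputError(f"zone {self.zone_id}: area must be > 0")
        if self.count is not None and self.count.value < 0:
            raise InvalidInputError(f"zone {self.zone_id}: count must be >= 0")

    @property
    def surveyed(self) -> bool:
        return self.count is not None


def polygon_area(polygon) -> UncertainQuantity:
    """Planar (shoelace) area of a zone polygon, in m².

    ``polygon`` may be a shapely geometry, a GeoJSON-like mapping, or a
    sequence of (x, y) vertices.  Coordinates must be projected metric; rings
    whose coordinates all fall within ±360 are heuristically flagged as
    geographic (degree) input.
    """
    if isinstance(polygon, dict):
        geom = shape(polygon)
    elif hasattr(polygon, "geom_type"):
        geom = polygon
    else:
        coords = list(polygon)
        if len(coords) < 3:
            raise InvalidGeometryError(
                f"polygon needs at least 3 vertices, got {len(coords)}")
        geom = shape({"type": "Polygon", "coordinates": [coords]})
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise InvalidGeometryError(f"expected Polygon geometry, got {geom.geom_type}")
    if not geom.is_valid:
        raise InvalidGeometryError(explain_validity(geom))
    if geom.is_empty or geom.area == 0:
        raise InvalidGeometryError("degenerate polygon with zero area")
    minx, miny, maxx, maxy = geom.bounds
    # Degree heuristic: a colony zone spans metres-to-hundreds-of-metres in a
    # projected CRS but well under 0.1 units in lon/lat, so a sub-0.1 footprint
    # inside the lon/lat value range is almost surely geographic input.
    in_degree_range = abs(minx) <= 360 and abs(maxx) <= 360 \
        and abs(miny) <= 360 and abs(maxy) <= 360
    if in_degree_range and max(maxx - minx, maxy - miny) < 0.1:
        raise WrongCRSError(
            "coordinates look like lon/lat degrees; areas require a "
            "projected metric CRS")
    return UncertainQuantity(geom.area, 0.0, "m2")


def zone_density(count: UncertainQuantity,
                 area: UncertainQuantity) -> UncertainQuantity:
    """Penguin density in a surveyed zone: count / area [ind m⁻²]."""
    if area.value == 0:
        raise UndefinedQuotientError("zone area is zero")
    if count.value == 0:
        return UncertainQuantity(0.0, 0.0, "ind/m2")
    return propagate_first_order([count, area], [1, -1], unit="ind/m2")


def extrapolate_count(density: UncertainQuantity, area: UncertainQuantity,
                      *, source_class: str | None = None,
                      target_class: str | None = None) -> UncertainQuantity:
    """Expected count in an unsurveyed zone from a same-class density.

    Density transfer is class-wise only (GRZ densities to GRZ zones, OZ to
    OZ); when both class tags are given a mismatch raises
    :class:`ClassMismatchError`.  The result is not rounded.
    """
    if source_class is not None and target_class is not None \
            and source_class != target_class:
        raise ClassMismatchError(
            f"density from a {source_class} zone cannot be applied to a "
            f"{target_class} zone")
    if density.value == 0:
        return UncertainQuantity(0.0, 0.0, "ind")
    return propagate_first_order([density, area], unit="ind")


def total_census(zones: Sequence[ZoneCensus]) -> UncertainQuantity:
    """Colony total: sum of zone counts, sds combined in quadrature."""
    missing = [z.zone_id for z in zones if not z.surveyed]
    if missing:
        raise IncompleteCensusError(f"zones without counts: {missing}")
    total = UncertainQuantity(0.0, 0.0, "ind")
    for z in zones:
        total = total + z.count.to("ind")
    return total


def complete_census(zones: Iterable[ZoneCensus]) -> list[ZoneCensus]:
    """Fill unsurveyed zones by class-wise density transfer.

    Densities are derived from the surveyed zones (pooled counts over pooled
    area per class) and applied to each unsurveyed zone of the same class.
    """
    zones = list(zones)
    densities: dict[str, UncertainQuantity] = {}
    for cls in ZONE_CLASSES:
        surveyed = [z for z in zones if z.zone_class == cls and z.surveyed]
        if not surveyed:
            continue
        count = surveyed[0].count
        area = surveyed[0].area
        for z in surveyed[1:]:
            count = count + z.count
            area = area + z.area
        densities[cls] = zone_density(count, area)
    out = []
    for z in zones:
        if z.surveyed:
            out.append(replace(z, density=zone_density(z.count, z.area)))
        else:
            if z.zone_class not in densities:
                raise IncompleteCensusError(
                    f"no surveyed {z.zone_class} zone to extrapolate "
                    f"{z.zone_id} from")
            dens = densities[z.zone_class]
            cnt = extrapolate_count(dens, z.area, source_class=z.zone_class,
                                    target_class=z.zone_class)
            out.append(replace(z, count=cnt, density=dens))
    return out


def load_zone_table(path) -> list[ZoneCensus]:
    """Read a zone table CSV.

    Columns: ``zone_id, zone_class, area_m2`` (or ``geojson_path``),
    ``count, count_sd`` — count empty for unsurveyed zones.
    """
    df = pd.read_csv(path)
    zones = []
    for row in df.itertuples(index=False):
        if getattr(row, "geojson_path", None) and isinstance(row.geojson_path, str):
            with open(row.geojson_path) as fh:
                area = polygon_area(json.load(fh))
        else:
            area = UncertainQuantity(float(row.area_m2), 0.0, "m2")
        count = None
        if not pd.isna(getattr(row, "count", float("nan"))):
            sd = float(getattr(row, "count_sd", 0.0) or 0.0)
            count = UncertainQuantity(float(row.count), sd, "ind")
        zones.append(ZoneCensus(str(row.zone_id), str(row.zone_class),
                                area, count))
    return zones
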