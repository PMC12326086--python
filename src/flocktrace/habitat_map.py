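"""Habitat polygon maps and ground-cover classification of track points.

Fine land-cover classes (JNCC Phase 4 definitions as distributed in the
Living England habitat map) are grouped into the three analysis categories —
``open``, ``wooded`` and ``urban`` — and track points are classified by which
category of polygon contains them.  Points covered by no polygon are labelled
``open`` (mirroring the grouping of "Unclassified" ground under open cover);
where categories overlap, the precedence is urban > wooded > open, and points
on a polygon boundary count as inside.

Classification is done directly in WGS84 geographic coordinates: polygon
containment is invariant under the (monotone) plate-carree map at this
extent, so no projection is needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

from .errors import ClassificationError, EmptyMapError

logger = logging.getLogger(__name__)

CATEGORIES = ("open", "wooded", "urban")

#: Precedence when a point lies in polygons of several categories:
#: the most specific (built-up) label wins.
CATEGORY_PRECEDENCE = ("urban", "wooded", "open")

#: Grouping of fine land-cover source classes into the analysis categories.
DEFAULT_CLASS_MAPPING: dict[str, str] = {
    "Water": "open",
    "Acid, Calcareous, and Neutral Grassland": "open",
    "Arable and Horticultural": "open",
    "Bare Ground": "open",
    "Bare Sand": "open",
    "Bracken": "open",
    "Dwarf Shrub Heath": "open",
    "Fen, Marsh, and Swamp": "open",
    "Improved Grassland": "open",
    "Scrub": "open",
    "Unclassified": "open",
    "Broadleaved, Mixed, and Yew Woodland": "wooded",
    "Coniferous Woodland": "wooded",
    "Built-up Areas and Gardens": "urban",
}


def group_source_classes(class_name: str,
                         mapping: dict[str, str] | None = None) -> str:
    """Map a fine land-cover class name to one of open/wooded/urban."""
    if not class_name:
        raise ClassificationError("empty class name")
    mapping = DEFAULT_CLASS_MAPPING if mapping is None else mapping
    try:
        return mapping[class_name]
    except KeyError:
        raise ClassificationError(
            f"unknown land-cover class {class_name!r}") from None


@dataclass
class HabitatMap:
    """Polygons tagged with source class and analysis category.

    ``merged`` caches one (multi)polygon union per category for fast
    containment queries.
    """

    polygons: list[tuple[BaseGeometry, str, str]]  # (geometry, source_class, category)
    merged: dict[str, BaseGeometry] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.merged:
            for cat in CATEGORIES:
                geoms = [g for g, _, c in self.polygons if c == cat]
                if geoms:
                    self.merged[cat] = shapely.union_all(geoms)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return shapely.union_all([g for g, _, _ in self.polygons]).bounds

    def categories(self) -> set[str]:
        return {c for _, _, c in self.polygons}


def load_habitat_geojson(paths, mapping: dict[str, str] | None = None,
                         class_property: str = "class") -> HabitatMap:
    """Load GeoJSON feature collections into a :class:`HabitatMap`.

    Non-polygonal features are skipped with a warning; invalid polygons are
    repaired by zero-width buffering or, failing that, rejected with a logged
    feature id.  Features whose class name has no category mapping raise
    :class:`~flocktrace.errors.ClassificationError`.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    polygons: list[tuple[BaseGeometry, str, str]] = []
    for path in paths:
        with open(path, encoding="utf-8") as fh:
            collection = json.load(fh)
        for i, feature in enumerate(collection.get("features", [])):
            geom = shape(feature["geometry"])
            if geom.geom_type not in ("Polygon", "MultiPolygon"):
                logger.warning("skipping non-polygonal feature %d in %s "
                               "(%s)", i, path, geom.geom_type)
                continue
            source_class = feature.get("properties", {}).get(class_property)
            category = group_source_classes(source_class, mapping)
            if not geom.is_valid:
                repaired = geom.buffer(0)
                if repaired.is_valid and not repaired.is_empty:
                    logger.info("repaired invalid geometry of feature %d in %s",
                                i, path)
                    geom = repaired
                else:
                    logger.warning("rejected unrepairable feature %d in %s",
                                   i, path)
                    continue
            polygons.append((geom, source_class, category))
    if not polygons:
        raise EmptyMapError(f"no polygonal features loaded from {list(paths)}")
    return HabitatMap(polygons)


def classify_point(hmap: HabitatMap, lon: float, lat: float) -> str:
    """Category of the polygon containing (lon, lat); open if none.

    Boundary points count as inside; overlapping categories resolve by
    urban > wooded > open.
    """
    pt = shapely.points(lon, lat)
    for cat in CATEGORY_PRECEDENCE:
        merged = hmap.merged.get(cat)
        if merged is not None and shapely.covers(merged, pt):
            return cat
    return "open"


def classify_track(hmap: HabitatMap, lon, lat) -> np.ndarray:
    """Vectorised :func:`classify_point` over arrays of coordinates.

    Returns one category per input point, in order.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    out = np.full(lon.shape, "open", dtype=object)
    if lon.size == 0:
        return out
    pts = shapely.points(lon, lat)
    unassigned = np.ones(lon.shape, dtype=bool)
    for cat in CATEGORY_PRECEDENCE:
        merged = hmap.merged.get(cat)
        if merged is None or not unassigned.any():
            continue
        hit = shapely.covers(merged, pts) & unassigned
        out[hit] = cat
        unassigned &= ~hit
    return out
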