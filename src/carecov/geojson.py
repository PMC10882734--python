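"""Minimal GeoJSON layer I/O on top of shapely geometries.

A "layer" throughout the package is a list of :class:`Feature` objects —
a shapely geometry plus a flat property dict — matching one GeoJSON
FeatureCollection. Coordinates are planar metres (projected); geographic
longitude/latitude input is rejected by :func:`validate_planar_metres`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


@dataclass
class Feature:
    geometry: BaseGeometry
    properties: dict[str, Any] = field(default_factory=dict)


def read_geojson(path: str | Path) -> list[Feature]:
    """Read a GeoJSON FeatureCollection into a list of features."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection, got {doc.get('type')!r}")
    return [
        Feature(shape(f["geometry"]), dict(f.get("properties") or {}))
        for f in doc["features"]
    ]


def write_geojson(features: Iterable[Feature], path: str | Path) -> None:
    """Write features as a GeoJSON FeatureCollection (stable key order)."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": f.properties,
            }
            for f in features
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def validate_planar_metres(features: Iterable[Feature]) -> None:
    """Reject layers whose coordinates look like geographic degrees.

    Coordinates are declared to be planar metres. A layer whose bounding
    box fits inside [-180, 180] x [-90, 90] *and* spans less than one
    coordinate unit is almost certainly in degrees (a metre-scale study
    region spans hundreds to thousands of units); such input must be
    projected before use.
    """
    xs: list[float] = []
    ys: list[float] = []
    for f in features:
        minx, miny, maxx, maxy = f.geometry.bounds
        xs += [minx, maxx]
        ys += [miny, maxy]
    if not xs:
        return
    if any(not math.isfinite(v) for v in xs + ys):
        raise ValueError("non-finite coordinates in layer")
    span = max(max(xs) - min(xs), max(ys) - min(ys))
    inside_degree_box = (
        min(xs) >= -180 and max(xs) <= 180 and min(ys) >= -90 and max(ys) <= 90
    )
    if inside_degree_box and span < 1.0:
        raise ValueError(
            "layer coordinates look like geographic degrees "
            f"(bounding box span {span:.3g}); project to planar metres first"
        )
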