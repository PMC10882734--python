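"""Synthetic road network, provider and household generators.

The city is a rectangular grid of intersections spaced ``cell_length``
metres apart, with straight road segments along the grid lines and
(optionally) random diagonal shortcuts. Each segment carries a road class
drawn from a configurable mix; per-class speeds turn segment lengths into
travel times downstream. Providers are placed on network nodes (uniformly
or in clusters) and flagged as insurance-partner or not; households are
uniform points in a polygon. All generators are pure functions of their
spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point
from shapely.geometry.base import BaseGeometry

from carecov.geojson import Feature

#: road-class → speed (km/h); motorcycle-era urban values by road class,
#: mirroring per-class speed tables published for city street networks.
DEFAULT_SPEED_TABLE = {
    "primary": 40.0,
    "secondary": 30.0,
    "residential": 20.0,
}

DEFAULT_ROAD_CLASS_MIX = {"primary": 0.15, "secondary": 0.35, "residential": 0.50}


@dataclass
class CitySpec:
    """Parameters of the synthetic city.

    Defaults reproduce the study conditions the pipeline is designed
    around: 106 insurance-partner and 97 non-partner primary-care
    providers on a city-scale street grid.
    """

    grid_rows: int = 40
    grid_cols: int = 40
    cell_length: float = 250.0  # metres between adjacent intersections
    road_class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROAD_CLASS_MIX)
    )
    speed_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPEED_TABLE)
    )
    n_bpjs_providers: int = 106
    n_nonbpjs_providers: int = 97
    n_households: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.road_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("road_class_mix probabilities must sum to 1")
        if any(p < 0 for p in self.road_class_mix.values()):
            raise ValueError("road_class_mix probabilities must be non-negative")
        if any(s <= 0 for s in self.speed_table.values()):
            raise ValueError("all speeds must be > 0")
        if min(self.n_bpjs_providers, self.n_nonbpjs_providers, self.n_households) < 0:
            raise ValueError("counts must be >= 0")
        if self.cell_length <= 0:
            raise ValueError("cell_length must be > 0")
        missing = set(self.road_class_mix) - set(self.speed_table)
        if missing:
            raise ValueError(f"road classes without a speed: {sorted(missing)}")


def gen_road_network(spec: CitySpec, diagonal_prob: float = 0.0) -> list[Feature]:
    """Generate a connected planar grid road network.

    Returns a LineString layer; each segment has properties ``road_class``
    and ``length_m``. ``diagonal_prob`` adds a diagonal shortcut across a
    grid cell with that probability (off by default so segment counts are
    exactly the grid-edge count ``rows*(cols-1) + cols*(rows-1)``).
    """
    if spec.grid_rows < 2 or spec.grid_cols < 2:
        raise ValueError("degenerate grid: need at least 2x2 intersections")
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.road_class_mix)
    probs = np.array([spec.road_class_mix[c] for c in classes])
    h = spec.cell_length

    segments: list[tuple[tuple[float, float], tuple[float, float]]] = []
    for r in range(spec.grid_rows):
        for c in range(spec.grid_cols):
            x, y = c * h, r * h
            if c + 1 < spec.grid_cols:  # horizontal edge
                segments.append(((x, y), (x + h, y)))
            if r + 1 < spec.grid_rows:  # vertical edge
                segments.append(((x, y), (x, y + h)))
    if diagonal_prob > 0:
        for r in range(spec.grid_rows - 1):
            for c in range(spec.grid_cols - 1):
                if rng.random() < diagonal_prob:
                    x, y = c * h, r * h
                    segments.append(((x, y), (x + h, y + h)))

    drawn = rng.choice(len(classes), size=len(segments), p=probs)
    features = []
    for i, ((x0, y0), (x1, y1)) in enumerate(segments):
        geom = LineString([(x0, y0), (x1, y1)])
        features.append(
            Feature(
                geom,
                {
                    "segment_id": i,
                    "road_class": classes[drawn[i]],
                    "length_m": round(geom.length, 6),
                },
            )
        )
    return features


def _network_nodes(network: list[Feature]) -> np.ndarray:
    coords = set()
    for f in network:
        xs, ys = f.geometry.xy
        coords.add((xs[0], ys[0]))
        coords.add((xs[-1], ys[-1]))
    return np.array(sorted(coords))


def gen_providers(
    network: list[Feature],
    spec: CitySpec,
    clustered: bool = False,
    n_clusters: int = 8,
    cluster_sd: float | None = None,
) -> list[Feature]:
    """Place partner and non-partner providers on network nodes.

    Providers snap to distinct intersections. In ``clustered`` mode,
    nodes are drawn with weights decaying from random cluster centres
    (Gaussian kernel, sd ``cluster_sd``, default two cell lengths),
    emulating the central clustering of urban clinics; otherwise placement
    is uniform over nodes. Partner providers split into public health
    centres and private clinics (49:57, the observed partner composition);
    non-partners are private clinics.
    """
    if not network:
        raise ValueError("empty road network")
    n_total = spec.n_bpjs_providers + spec.n_nonbpjs_providers
    nodes = _network_nodes(network)
    if n_total > len(nodes):
        raise ValueError(
            f"{n_total} providers requested but only {len(nodes)} nodes available"
        )
    rng = np.random.default_rng(spec.seed + 1)
    if n_total == 0:
        return []
    if clustered:
        # partners and non-partners cluster around separate centres
        # (public centres spread differently from private clinics), which
        # is what creates zones of low partner but high non-partner access
        if cluster_sd is None:
            cluster_sd = 2.0 * spec.cell_length
        idx_parts = []
        taken = np.zeros(len(nodes), dtype=bool)
        for n_stratum in (spec.n_bpjs_providers, spec.n_nonbpjs_providers):
            centres = nodes[rng.choice(len(nodes), size=min(n_clusters, len(nodes)), replace=False)]
            d2 = ((nodes[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
            w = np.exp(-d2 / (2 * cluster_sd**2)).sum(axis=1)
            w[taken] = 0.0
            w /= w.sum()
            pick = rng.choice(len(nodes), size=n_stratum, replace=False, p=w)
            taken[pick] = True
            idx_parts.append(pick)
        idx = np.concatenate(idx_parts)
    else:
        idx = rng.choice(len(nodes), size=n_total, replace=False)

    n_puskesmas = round(spec.n_bpjs_providers * 49 / 106)
    features = []
    for k, i in enumerate(idx):
        is_bpjs = k < spec.n_bpjs_providers
        if is_bpjs:
            cls = "public_health_centre" if k < n_puskesmas else "private_clinic"
        else:
            cls = "private_clinic"
        features.append(
            Feature(
                Point(nodes[i]),
                {
                    "provider_id": f"P{k:04d}",
                    "bpjs_partner": bool(is_bpjs),
                    "provider_class": cls,
                },
            )
        )
    return features


def gen_households(region: BaseGeometry, n: int, seed: int = 0) -> list[Feature]:
    """Draw ``n`` household points uniformly inside ``region`` (rejection
    sampling over the bounding box)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    if region.area <= 0:
        raise ValueError("region must have positive area")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = region.bounds
    pts: list[tuple[float, float]] = []
    # acceptance rate = area / bbox area; draw in chunks until filled
    while len(pts) < n:
        m = max(1024, int(1.5 * (n - len(pts)) / max(region.area / ((maxx - minx) * (maxy - miny)), 1e-9)))
        xs = rng.uniform(minx, maxx, size=m)
        ys = rng.uniform(miny, maxy, size=m)
        import shapely

        keep = shapely.contains_xy(region, xs, ys)
        pts.extend(zip(xs[keep], ys[keep]))
    return [
        Feature(Point(x, y), {"household_id": f"H{i:06d}"})
        for i, (x, y) in enumerate(pts[:n])
    ]
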