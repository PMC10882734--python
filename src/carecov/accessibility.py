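"""Road-network travel-time catchments and coverage-level mapping.

The spatial model is deliberately simple and fully deterministic:

* roads are undirected segments with one speed per road class, so an edge's
  cost is ``minutes = (length_m / 1000) / speed_kmh * 60``;
* a provider's catchment is the sub-network reachable within a travel-time
  budget (default 15 minutes) from its snapped node, polygonised by
  buffering the reached (possibly partial) segments;
* coverage is counted on a regular grid: a cell's value is the number of
  catchment polygons containing its centroid, each catchment worth one;
* integer coverage values map to ordered levels (no/low/medium/high/very
  high) through stratum-specific interval schemes, and sampling areas are
  the cells with low partner coverage but high non-partner coverage.

Traffic, one-way streets and turn penalties are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import substring, unary_union

from carecov.geojson import Feature

LEVELS = ["no", "low", "medium", "high", "very_high"]

DEFAULT_BUDGET_MIN = 15.0
DEFAULT_CELL_M = 100.0
DEFAULT_BUFFER_M = 100.0


# ---------------------------------------------------------------------------
# travel graph


@dataclass
class TravelGraph:
    """Undirected road graph; nodes are planar coordinates in metres, edges
    carry length (m), road class, speed (km/h) and travel time (minutes)."""

    graph: nx.Graph
    n_components: int

    @property
    def node_coords(self) -> np.ndarray:
        return np.array([self.graph.nodes[n]["xy"] for n in self.graph.nodes])

    @property
    def node_ids(self) -> list:
        return list(self.graph.nodes)


def edge_minutes(length_m: float, speed_kmh: float) -> float:
    """Travel time in minutes over ``length_m`` metres at ``speed_kmh``."""
    return (length_m / 1000.0) / speed_kmh * 60.0


def build_travel_time_graph(
    roads: list[Feature],
    speed_table: dict[str, float],
    snap_tolerance: float = 0.5,
) -> TravelGraph:
    """Build the weighted travel-time graph from a road-segment layer.

    Segment endpoints within ``snap_tolerance`` metres are merged into one
    node. Zero-length segments are dropped with a warning; an unknown road
    class or non-positive speed is an error.
    """
    for cls, v in speed_table.items():
        if v <= 0:
            raise ValueError(f"speed for road class {cls!r} must be > 0, got {v}")

    def key(x: float, y: float) -> tuple[float, float]:
        return (round(x / snap_tolerance) * snap_tolerance,
                round(y / snap_tolerance) * snap_tolerance)

    g = nx.Graph()
    dropped = 0
    for f in roads:
        cls = f.properties.get("road_class")
        if cls not in speed_table:
            raise ValueError(f"unknown road class {cls!r}")
        geom = f.geometry
        length = float(f.properties.get("length_m", geom.length))
        if length <= 0:
            dropped += 1
            continue
        xs, ys = geom.xy
        u, v = key(xs[0], ys[0]), key(xs[-1], ys[-1])
        if not all(np.isfinite([*u, *v])):
            raise ValueError("non-finite node coordinate")
        t = edge_minutes(length, speed_table[cls])
        g.add_node(u, xy=u)
        g.add_node(v, xy=v)
        # keep the fastest edge if parallel segments collapse onto one pair
        if not g.has_edge(u, v) or g.edges[u, v]["time"] > t:
            g.add_edge(u, v, length=length, road_class=cls,
                       speed=speed_table[cls], time=t,
                       geometry=geom)
    if dropped:
        warnings.warn(f"dropped {dropped} zero-length segments", stacklevel=2)
    n_comp = nx.number_connected_components(g) if len(g) else 0
    return TravelGraph(graph=g, n_components=n_comp)


# ---------------------------------------------------------------------------
# catchments


@dataclass
class ReachedEdge:
    u: tuple
    v: tuple
    fraction: float  # fraction of the edge traversed, from `from_node`
    from_node: tuple


@dataclass
class Catchment:
    provider_id: str
    budget: float  # minutes
    snapped_node: tuple
    snap_distance: float  # metres from site to snapped node
    reached_edges: list[ReachedEdge]
    polygon: BaseGeometry
    stratum: str | None = None

    @property
    def reached_length(self) -> float:
        """Total reached road length in metres (partial edges pro rata)."""
        g = self._graph
        return sum(re.fraction * g.edges[re.u, re.v]["length"] for re in self.reached_edges)

    _graph: nx.Graph = field(default=None, repr=False, compare=False)


def compute_catchment(
    tg: TravelGraph,
    site: Point | tuple[float, float],
    budget: float = DEFAULT_BUDGET_MIN,
    buffer_width: float = DEFAULT_BUFFER_M,
    provider_id: str = "",
    stratum: str | None = None,
) -> Catchment:
    """Service area of one provider: everything reachable within ``budget``
    minutes from the site's nearest graph node.

    An edge (u, v) with entry times t(u) ≤ t(v) is fully reached when
    t(u) + time(u,v) ≤ budget; otherwise each reachable endpoint
    contributes a partial piece of fraction (budget − t(end)) / time(u,v).
    The polygon is the union of the reached segment geometries buffered by
    ``buffer_width`` (plus a disk at the snapped node, which is the whole
    polygon when the budget is 0).
    """
    if len(tg.graph) == 0:
        raise ValueError("empty travel graph")
    if budget < 0:
        raise ValueError("budget must be >= 0")
    pt = Point(site) if not isinstance(site, Point) else site
    coords = tg.node_coords
    ids = tg.node_ids
    tree = cKDTree(coords)
    snap_distance, i = tree.query([pt.x, pt.y])
    source = ids[i]

    times = nx.single_source_dijkstra_path_length(tg.graph, source, cutoff=budget, weight="time")
    reached: list[ReachedEdge] = []
    lines: list[BaseGeometry] = []
    g = tg.graph
    seen = set()
    for u, t_u in times.items():
        for v in g.neighbors(u):
            e = tuple(sorted((u, v)))
            if e in seen:
                continue
            seen.add(e)
            t_edge = g.edges[u, v]["time"]
            t_v = times.get(v, np.inf)
            lo, hi = (u, v) if t_u <= t_v else (v, u)
            t_lo = min(t_u, t_v)
            geom = g.edges[u, v].get("geometry") or LineString([u, v])
            # orient geometry from lo to hi for partial cuts
            if (abs(geom.coords[0][0] - lo[0]) > 1e-9) or (abs(geom.coords[0][1] - lo[1]) > 1e-9):
                geom = geom.reverse()
            if t_lo + t_edge <= budget + 1e-12:
                reached.append(ReachedEdge(e[0], e[1], 1.0, lo))
                lines.append(geom)
            else:
                frac_lo = (budget - t_lo) / t_edge
                if frac_lo > 1e-12:
                    reached.append(ReachedEdge(e[0], e[1], float(frac_lo), lo))
                    lines.append(substring(geom, 0, frac_lo, normalized=True))
                t_hi = max(t_u, t_v)
                frac_hi = (budget - t_hi) / t_edge
                if np.isfinite(frac_hi) and frac_hi > 1e-12:
                    reached.append(ReachedEdge(e[0], e[1], float(frac_hi), hi))
                    lines.append(substring(geom, 1 - frac_hi, 1, normalized=True))
    # one buffer over the merged reached lines (plus the snapped-node disk)
    poly = unary_union([shapely.GeometryCollection(lines).buffer(buffer_width),
                        Point(source).buffer(buffer_width)])
    c = Catchment(
        provider_id=provider_id,
        budget=budget,
        snapped_node=source,
        snap_distance=float(snap_distance),
        reached_edges=reached,
        polygon=poly,
        stratum=stratum,
    )
    c._graph = g
    return c


def catchments_for_providers(
    tg: TravelGraph,
    providers: list[Feature],
    budget: float = DEFAULT_BUDGET_MIN,
    buffer_width: float = DEFAULT_BUFFER_M,
    stratum: str | None = None,
) -> list[Catchment]:
    """Catchment per provider point; ``stratum`` filters on the
    ``bpjs_partner`` flag ('bpjs' keeps partners, 'non_bpjs' the rest)."""
    out = []
    for f in providers:
        flag = bool(f.properties.get("bpjs_partner", False))
        if stratum == "bpjs" and not flag:
            continue
        if stratum == "non_bpjs" and flag:
            continue
        out.append(
            compute_catchment(
                tg, f.geometry, budget, buffer_width,
                provider_id=str(f.properties.get("provider_id", "")),
                stratum=stratum,
            )
        )
    return out


# ---------------------------------------------------------------------------
# coverage surfaces


@dataclass
class GridSpec:
    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    @classmethod
    def from_bounds(cls, bounds: tuple[float, float, float, float], cell_size: float) -> "GridSpec":
        minx, miny, maxx, maxy = bounds
        n_cols = max(1, int(np.ceil((maxx - minx) / cell_size)))
        n_rows = max(1, int(np.ceil((maxy - miny) / cell_size)))
        return cls(minx, miny, cell_size, n_rows, n_cols)

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_box(self, row: int, col: int) -> BaseGeometry:
        x0 = self.origin_x + col * self.cell_size
        y0 = self.origin_y + row * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)


@dataclass
class CoverageSurface:
    grid: GridSpec
    values: np.ndarray  # n_rows × n_cols int
    stratum: str


@dataclass
class ClassifiedSurface:
    grid: GridSpec
    values: np.ndarray
    levels: np.ndarray  # n_rows × n_cols object (level labels)
    stratum: str
    scheme: "ClassificationScheme"

    def level_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.levels, return_counts=True)
        return {str(l): int(c) for l, c in zip(labels, counts)}


def coverage_surface(
    catchments: list[Catchment],
    grid: GridSpec,
    stratum: str,
) -> CoverageSurface:
    """Count, per grid cell, how many catchment polygons contain the cell
    centroid — each catchment contributes at most one to each cell."""
    if grid.n_rows < 1 or grid.n_cols < 1:
        raise ValueError("empty grid")
    for c in catchments:
        if c.stratum is not None and c.stratum != stratum:
            raise ValueError(f"catchment {c.provider_id!r} has stratum {c.stratum!r}, expected {stratum!r}")
    gx, gy = grid.centroids()
    values = np.zeros(gx.shape, dtype=int)
    for c in catchments:
        shapely.prepare(c.polygon)
        values += shapely.contains_xy(c.polygon, gx, gy).astype(int)
    return CoverageSurface(grid=grid, values=values, stratum=stratum)


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassificationScheme:
    """Ordered integer intervals (lo, hi, level). Intervals must be
    disjoint and jointly cover 0..top."""

    intervals: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        lo0 = ivs[0][0]
        if lo0 != 0:
            raise ValueError("scheme must start at coverage value 0")
        prev_hi = -1
        for lo, hi, level in ivs:
            if level not in LEVELS:
                raise ValueError(f"unknown level {level!r}")
            if lo != prev_hi + 1:
                raise ValueError("intervals must be contiguous and disjoint")
            if hi < lo:
                raise ValueError("interval upper bound below lower bound")
            prev_hi = hi
        self.intervals = ivs

    @property
    def top(self) -> int:
        return self.intervals[-1][1]

    @property
    def top_level(self) -> str:
        return self.intervals[-1][2]

    def level_of(self, value: int) -> str:
        for lo, hi, level in self.intervals:
            if lo <= value <= hi:
                return level
        return self.top_level  # clamped; caller warns


#: partner-provider scheme: 1–2 low, 3–4 medium, 5–18 high, 19–29 very high
#: (value 0, never listed for this stratum, maps to no coverage)
BPJS_SCHEME = ClassificationScheme(
    [(0, 0, "no"), (1, 2, "low"), (3, 4, "medium"), (5, 18, "high"), (19, 29, "very_high")]
)

#: non-partner scheme: 0 no coverage, 1–2 low, 3 medium, 4–20 high
NONBPJS_SCHEME = ClassificationScheme(
    [(0, 0, "no"), (1, 2, "low"), (3, 3, "medium"), (4, 20, "high")]
)

DEFAULT_SCHEMES = {"bpjs": BPJS_SCHEME, "non_bpjs": NONBPJS_SCHEME}


def classify_coverage(surface: CoverageSurface, scheme: ClassificationScheme) -> ClassifiedSurface:
    """Assign each cell its coverage level; values above the scheme's top
    interval clamp to the top level with a warning."""
    vmax = int(surface.values.max()) if surface.values.size else 0
    if vmax > scheme.top:
        warnings.warn(
            f"coverage value {vmax} above scheme top {scheme.top}; clamping to {scheme.top_level!r}",
            stacklevel=2,
        )
    lut = np.array(
        [scheme.level_of(v) for v in range(max(vmax, scheme.top) + 1)], dtype=object
    )
    levels = lut[surface.values]
    return ClassifiedSurface(
        grid=surface.grid, values=surface.values, levels=levels,
        stratum=surface.stratum, scheme=scheme,
    )


# ---------------------------------------------------------------------------
# sampling-area selection


@dataclass
class SamplingAreaSet:
    grid: GridSpec
    mask: np.ndarray  # boolean n_rows × n_cols
    polygon: BaseGeometry  # dissolved union of selected cells
    rule: tuple[str, str]  # (required partner level, required non-partner level)

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def cell_indices(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.mask)]


def select_sampling_areas(
    bpjs: ClassifiedSurface,
    nonbpjs: ClassifiedSurface,
    rule: tuple[str, str] = ("low", "high"),
) -> SamplingAreaSet:
    """Cells whose partner-provider level equals ``rule[0]`` *and*
    non-partner level equals ``rule[1]`` (defaults: low partner coverage,
    high non-partner coverage)."""
    ga, gb = bpjs.grid, nonbpjs.grid
    if (ga.origin_x, ga.origin_y, ga.cell_size, ga.n_rows, ga.n_cols) != (
        gb.origin_x, gb.origin_y, gb.cell_size, gb.n_rows, gb.n_cols
    ):
        raise ValueError("classified surfaces are on different grids")
    mask = (bpjs.levels == rule[0]) & (nonbpjs.levels == rule[1])
    boxes = [ga.cell_box(r, c) for r, c in np.argwhere(mask)]
    poly = unary_union(boxes) if boxes else shapely.Polygon()
    return SamplingAreaSet(grid=ga, mask=mask, polygon=poly, rule=tuple(rule))


# ---------------------------------------------------------------------------
# tabular export


def surface_table(classified: ClassifiedSurface) -> "pd.DataFrame":
    """Long-format (row, col, x_centroid, y_centroid, value, level) table."""
    import pandas as pd

    gx, gy = classified.grid.centroids()
    rows, cols = np.indices(classified.values.shape)
    return pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "x_centroid": gx.ravel(),
            "y_centroid": gy.ravel(),
            "value": classified.values.ravel(),
            "level": classified.levels.ravel(),
        }
    )
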