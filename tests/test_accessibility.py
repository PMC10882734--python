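"""Spatial engine: travel-time graph arithmetic, catchment reachability
against hand and brute-force oracles, coverage counting, interval
classification, and sampling-area selection."""

import itertools

import networkx as nx
import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point

from carecov.accessibility import (
    BPJS_SCHEME,
    NONBPJS_SCHEME,
    Catchment,
    ClassificationScheme,
    GridSpec,
    build_travel_time_graph,
    classify_coverage,
    compute_catchment,
    coverage_surface,
    edge_minutes,
    select_sampling_areas,
)
from carecov.geojson import Feature

from conftest import random_travel_graph


def line_feature(p0, p1, road_class="residential"):
    geom = LineString([p0, p1])
    return Feature(geom, {"road_class": road_class, "length_m": geom.length})


class TestTravelGraph:
    def test_edge_time_formula(self):
        # 1000 m at 40 km/h -> 1.5 minutes
        tg = build_travel_time_graph([line_feature((0, 0), (1000, 0), "a")], {"a": 40.0})
        (t,) = [d["time"] for _, _, d in tg.graph.edges(data=True)]
        assert t == pytest.approx(1.5, abs=1e-12)
        assert edge_minutes(1000, 40.0) == pytest.approx(1.5)

    def test_small_grid_hand_computation(self):
        # 2x2 grid of 100 m segments at 30 km/h: 4 edges of 0.2 min each
        feats = [
            line_feature((0, 0), (100, 0)), line_feature((0, 100), (100, 100)),
            line_feature((0, 0), (0, 100)), line_feature((100, 0), (100, 100)),
        ]
        tg = build_travel_time_graph(feats, {"residential": 30.0})
        times = [d["time"] for _, _, d in tg.graph.edges(data=True)]
        assert len(times) == 4
        assert np.allclose(times, 0.2)
        assert tg.n_components == 1

    def test_endpoints_merged_within_tolerance(self):
        feats = [line_feature((0, 0), (100, 0)), line_feature((100.0001, 0.0002), (200, 0))]
        tg = build_travel_time_graph(feats, {"residential": 30.0})
        assert len(tg.graph) == 3

    def test_unknown_class_and_bad_speed_rejected(self):
        with pytest.raises(ValueError, match="unknown road class"):
            build_travel_time_graph([line_feature((0, 0), (1, 0), "zz")], {"a": 30.0})
        with pytest.raises(ValueError, match="must be > 0"):
            build_travel_time_graph([line_feature((0, 0), (1, 0), "a")], {"a": -3.0})

    def test_zero_length_dropped_with_warning(self):
        feats = [line_feature((0, 0), (100, 0)), line_feature((50, 50), (50, 50))]
        with pytest.warns(UserWarning, match="zero-length"):
            tg = build_travel_time_graph(feats, {"residential": 30.0})
        assert tg.graph.number_of_edges() == 1

    def test_time_length_speed_consistency(self, small_city):
        _, _, _, tg = small_city
        for _, _, d in tg.graph.edges(data=True):
            assert d["time"] == pytest.approx((d["length"] / 1000) / d["speed"] * 60, rel=1e-9)


class TestCatchment:
    def test_zero_budget_is_disk_at_snapped_node(self, small_city):
        _, _, _, tg = small_city
        c = compute_catchment(tg, (101, 99), budget=0.0, buffer_width=50.0)
        assert c.reached_edges == []
        assert c.snapped_node == (100.0, 100.0)
        assert c.polygon.area == pytest.approx(np.pi * 50**2, rel=1e-2)
        assert c.snap_distance == pytest.approx(np.sqrt(2), rel=1e-6)

    def test_partial_edge_fraction_hand_dijkstra(self):
        # A-B-C, both edges 10 min: from A with budget 15, AB is fully
        # reached and BC half reached
        speed = 6.0  # km/h -> 1000 m = 10 min
        feats = [line_feature((0, 0), (1000, 0), "a"), line_feature((1000, 0), (2000, 0), "a")]
        tg = build_travel_time_graph(feats, {"a": speed})
        c = compute_catchment(tg, (0, 0), budget=15.0, buffer_width=10.0)
        fr = {tuple(sorted((e.u, e.v))): e.fraction for e in c.reached_edges}
        assert fr[((0.0, 0.0), (1000.0, 0.0))] == pytest.approx(1.0)
        assert fr[((1000.0, 0.0), (2000.0, 0.0))] == pytest.approx(0.5)
        assert c.reached_length == pytest.approx(1500.0)

    def test_generous_budget_reaches_every_edge(self, small_city):
        # farthest node in the 10x10 city is ~ 1800 m at 30 km/h = 3.6 min,
        # so the default 15-minute budget must cover the whole network
        _, _, _, tg = small_city
        c = compute_catchment(tg, (0, 0))
        assert c.budget == 15.0
        assert len(c.reached_edges) == tg.graph.number_of_edges()
        assert all(e.fraction == 1.0 for e in c.reached_edges)

    def test_empty_graph_and_negative_budget_rejected(self, small_city):
        _, _, _, tg = small_city
        with pytest.raises(ValueError):
            compute_catchment(tg, (0, 0), budget=-1.0)
        import networkx as nx

        from carecov.accessibility import TravelGraph

        with pytest.raises(ValueError, match="empty"):
            compute_catchment(TravelGraph(nx.Graph(), 0), (0, 0))

    def test_budget_monotonicity(self, small_city):
        _, _, _, tg = small_city
        budgets = [0.5, 1.0, 2.0, 4.0]
        prev_edges: set = set()
        prev_poly = None
        for b in budgets:
            c = compute_catchment(tg, (450, 450), budget=b, buffer_width=30.0)
            edges = {tuple(sorted((e.u, e.v))) for e in c.reached_edges if e.fraction == 1.0}
            assert prev_edges <= edges
            if prev_poly is not None:
                assert prev_poly.difference(c.polygon).area < 1e-6
            prev_edges, prev_poly = edges, c.polygon

    def test_dijkstra_equals_exhaustive_path_enumeration(self):
        # on graphs with <= 12 nodes, compare single-source times against
        # brute-force enumeration of all simple paths
        rng = np.random.default_rng(99)
        for trial in range(15):
            n = int(rng.integers(4, 13))
            tg = random_travel_graph(rng, n)
            g = tg.graph
            nodes = list(g.nodes)
            src = nodes[int(rng.integers(0, n))]
            times = nx.single_source_dijkstra_path_length(g, src, weight="time")
            for dst in nodes:
                if dst == src:
                    assert times[dst] == 0
                    continue
                best = min(
                    (
                        sum(g.edges[p[i], p[i + 1]]["time"] for i in range(len(p) - 1))
                        for p in nx.all_simple_paths(g, src, dst)
                    ),
                    default=np.inf,
                )
                assert times.get(dst, np.inf) == pytest.approx(best, rel=1e-9)


def brute_force_coverage(catchments, grid):
    values = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    for r in range(grid.n_rows):
        for col in range(grid.n_cols):
            cx = grid.origin_x + (col + 0.5) * grid.cell_size
            cy = grid.origin_y + (r + 0.5) * grid.cell_size
            for c in catchments:
                if c.polygon.contains(Point(cx, cy)):
                    values[r, col] += 1
    return values


def disk_catchment(x, y, r, stratum="bpjs", pid="p"):
    return Catchment(provider_id=pid, budget=15.0, snapped_node=(x, y),
                     snap_distance=0.0, reached_edges=[],
                     polygon=Point(x, y).buffer(r), stratum=stratum)


class TestCoverageSurface:
    def test_zero_catchments_all_zero(self):
        grid = GridSpec(0, 0, 10, 5, 5)
        surf = coverage_surface([], grid, "bpjs")
        assert (surf.values == 0).all()

    def test_two_disks_intersection_counts(self):
        grid = GridSpec(0, 0, 10, 20, 20)
        cats = [disk_catchment(60, 100, 50), disk_catchment(120, 100, 50)]
        surf = coverage_surface(cats, grid, "bpjs")
        assert surf.values.max() == 2
        assert set(np.unique(surf.values)) == {0, 1, 2}
        np.testing.assert_array_equal(surf.values, brute_force_coverage(cats, grid))

    def test_random_instances_equal_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            grid = GridSpec(0, 0, 20, int(rng.integers(5, 30)), int(rng.integers(5, 30)))
            cats = [
                disk_catchment(rng.uniform(0, 400), rng.uniform(0, 400), rng.uniform(20, 150), pid=str(k))
                for k in range(int(rng.integers(1, 12)))
            ]
            surf = coverage_surface(cats, grid, "bpjs")
            oracle = brute_force_coverage(cats, grid)
            np.testing.assert_array_equal(surf.values, oracle)
            # conservation: total = sum over catchments of contained cells
            assert surf.values.sum() == oracle.sum()

    def test_value_bounded_by_catchment_count(self):
        grid = GridSpec(0, 0, 10, 10, 10)
        cats = [disk_catchment(50, 50, 40, pid=str(i)) for i in range(7)]
        surf = coverage_surface(cats, grid, "bpjs")
        assert surf.values.max() <= 7

    def test_stratum_mismatch_rejected(self):
        grid = GridSpec(0, 0, 10, 5, 5)
        with pytest.raises(ValueError, match="stratum"):
            coverage_surface([disk_catchment(0, 0, 10, stratum="non_bpjs")], grid, "bpjs")


class TestClassification:
    def test_partner_scheme_interval_examples(self):
        assert BPJS_SCHEME.level_of(3) == "medium"
        assert BPJS_SCHEME.level_of(20) == "very_high"
        assert BPJS_SCHEME.level_of(1) == "low"
        assert BPJS_SCHEME.level_of(0) == "no"

    def test_nonpartner_scheme_interval_examples(self):
        assert NONBPJS_SCHEME.level_of(0) == "no"
        assert NONBPJS_SCHEME.level_of(3) == "medium"
        assert NONBPJS_SCHEME.level_of(4) == "high"

    def test_every_cell_gets_exactly_one_level(self):
        grid = GridSpec(0, 0, 10, 8, 8)
        rng = np.random.default_rng(3)
        surf = coverage_surface([], grid, "bpjs")
        surf.values = rng.integers(0, 29, size=(8, 8))
        cls = classify_coverage(surf, BPJS_SCHEME)
        assert sum(cls.level_counts().values()) == 64
        assert all(l in {"no", "low", "medium", "high", "very_high"} for l in cls.levels.ravel())

    def test_value_above_top_clamps_with_warning(self):
        grid = GridSpec(0, 0, 10, 2, 2)
        surf = coverage_surface([], grid, "non_bpjs")
        surf.values = np.array([[25, 0], [1, 3]])
        with pytest.warns(UserWarning, match="clamping"):
            cls = classify_coverage(surf, NONBPJS_SCHEME)
        assert cls.levels[0, 0] == "high"

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            ClassificationScheme([(1, 2, "low")])  # does not start at 0
        with pytest.raises(ValueError):
            ClassificationScheme([(0, 2, "low"), (2, 4, "medium")])  # overlap


class TestSamplingAreas:
    def _classified(self, levels, stratum, scheme):
        grid = GridSpec(0, 0, 10, levels.shape[0], levels.shape[1])
        surf = coverage_surface([], grid, stratum)
        from carecov.accessibility import ClassifiedSurface

        return ClassifiedSurface(grid=grid, values=np.zeros_like(levels, dtype=int),
                                 levels=levels, stratum=stratum, scheme=scheme)

    def test_rule_on_known_cells(self):
        b = np.array([["low", "high"], ["low", "medium"]], dtype=object)
        nb = np.array([["high", "high"], ["low", "high"]], dtype=object)
        areas = select_sampling_areas(
            self._classified(b, "bpjs", BPJS_SCHEME),
            self._classified(nb, "non_bpjs", NONBPJS_SCHEME),
        )
        assert areas.mask.tolist() == [[True, False], [False, False]]
        assert areas.polygon.area == pytest.approx(100.0)

    def test_random_surfaces_equal_exhaustive_scan_and_idempotent(self):
        rng = np.random.default_rng(8)
        lv = np.array(["no", "low", "medium", "high"], dtype=object)
        b = lv[rng.integers(0, 4, size=(12, 9))]
        nb = lv[rng.integers(0, 4, size=(12, 9))]
        cb = self._classified(b, "bpjs", BPJS_SCHEME)
        cnb = self._classified(nb, "non_bpjs", NONBPJS_SCHEME)
        a1 = select_sampling_areas(cb, cnb)
        a2 = select_sampling_areas(cb, cnb)
        expect = [
            (r, c)
            for r in range(12) for c in range(9)
            if b[r, c] == "low" and nb[r, c] == "high"
        ]
        assert a1.cell_indices() == expect
        assert (a1.mask == a2.mask).all()
        assert a1.polygon.area == pytest.approx(100.0 * len(expect))

    def test_mismatched_grids_rejected(self):
        b = self._classified(np.array([["low"]], dtype=object), "bpjs", BPJS_SCHEME)
        nb = self._classified(np.array([["high", "high"]], dtype=object), "non_bpjs", NONBPJS_SCHEME)
        with pytest.raises(ValueError, match="different grids"):
            select_sampling_areas(b, nb)
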