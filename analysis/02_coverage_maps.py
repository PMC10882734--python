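"""Build the travel-time graph, compute every provider's 15-minute
catchment, overlay the catchments into partner and non-partner coverage
surfaces, classify coverage levels, and select the sampling areas (low
partner coverage AND high non-partner coverage).

Reads the layers written by 01_simulate_city.py; writes per-stratum
coverage tables and the dissolved sampling-area polygon.
"""

import json
import warnings
from pathlib import Path

from shapely.geometry import mapping

from carecov import accessibility as acc
from carecov.geojson import read_geojson
from carecov.pipeline import _layer_bounds

OUT = Path("results/analysis")
BUDGET_MIN = 15.0
CELL_M = 250.0
BUFFER_M = 300.0  # ~half the 500 m block spacing: ribbons dissolve into isochrones


def main() -> None:
    roads = read_geojson(OUT / "roads.geojson")
    providers = read_geojson(OUT / "providers.geojson")
    speed_table = {"primary": 40.0, "secondary": 30.0, "residential": 20.0}

    tg = acc.build_travel_time_graph(roads, speed_table)
    print(f"travel graph: {len(tg.graph)} nodes, {tg.graph.number_of_edges()} edges, "
          f"{tg.n_components} component(s)")

    grid = acc.GridSpec.from_bounds(_layer_bounds(roads), CELL_M)
    classified = {}
    for stratum in ("bpjs", "non_bpjs"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # values above the scheme top clamp
            catchments = acc.catchments_for_providers(tg, providers, BUDGET_MIN, BUFFER_M,
                                                      stratum=stratum)
            surf = acc.coverage_surface(catchments, grid, stratum)
            cls = acc.classify_coverage(surf, acc.DEFAULT_SCHEMES[stratum])
        classified[stratum] = cls
        acc.surface_table(cls).to_csv(OUT / f"coverage_{stratum}.csv", index=False)
        print(f"{stratum}: {len(catchments)} catchments, max coverage value "
              f"{surf.values.max()}, levels {cls.level_counts()}")

    areas = acc.select_sampling_areas(classified["bpjs"], classified["non_bpjs"])
    with open(OUT / "sampling_areas.geojson", "w") as fh:
        json.dump({"type": "Feature", "geometry": mapping(areas.polygon),
                   "properties": {"rule": list(areas.rule), "n_cells": areas.n_cells}}, fh)
    print(f"sampling areas: {areas.n_cells} cells "
          f"({areas.n_cells * CELL_M**2 / 1e6:.1f} km squared) with "
          f"low partner / high non-partner coverage")


if __name__ == "__main__":
    main()
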