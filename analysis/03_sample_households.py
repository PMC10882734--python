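"""Sample-size calculation and seeded household selection.

The Cochran precision formula at the 38.5% anticipated outpatient
insurance-use proportion (6.5-point margin, 95% confidence) gives the
target n; households are then drawn by simple random sampling inside the
sampling areas, with a worked example of the nearest-address replacement
rule for an unreachable household.
"""

import json
from pathlib import Path

import numpy as np
from shapely.geometry import shape

from carecov.accessibility import GridSpec, SamplingAreaSet
from carecov.geojson import read_geojson
from carecov.pipeline import _frame_df
from carecov.sampling import cochran_sample_size, draw_households, replace_unreachable, _inside

OUT = Path("results/analysis")


def main() -> None:
    households = read_geojson(OUT / "households.geojson")
    doc = json.load(open(OUT / "sampling_areas.geojson"))
    areas = SamplingAreaSet(GridSpec(0, 0, 1, 1, 1), np.ones((1, 1), bool),
                            shape(doc["geometry"]), tuple(doc["properties"]["rule"]))

    n_target = cochran_sample_size(p=0.385, alpha=0.05, d=0.065)
    print(f"Cochran n at p=0.385, d=0.065, alpha=0.05: {n_target}")
    print(f"(canonical half-proportion check: {cochran_sample_size(0.5, 0.05, 0.05)})")

    eligible = _inside(households, areas)
    n = min(n_target, len(eligible))
    frame = draw_households(households, areas, n, seed=7)
    print(f"{len(eligible)} households inside the sampling areas; drew {n}")

    # field replacement example: the first selected household is unreachable
    if n >= 2:
        victim = frame.selected[0]
        frame = replace_unreachable(frame, victim)
        print(f"replacement: {victim} -> {frame.replacements[victim]} (nearest eligible)")

    _frame_df(frame).to_csv(OUT / "selected_households.csv", index=False)
    print(f"selection written to {OUT}/selected_households.csv")


if __name__ == "__main__":
    main()
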