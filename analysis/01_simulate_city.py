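"""Simulate the synthetic study city: a 20 km street grid with per-class
speeds, 106 insurance-partner and 97 non-partner primary-care providers
placed in separate cluster patterns, and 20,000 household points.

Writes GeoJSON layers under results/analysis/ and prints the layer sizes.
"""

from pathlib import Path

from shapely.geometry import box

from carecov.geojson import write_geojson
from carecov.synthetic.city import CitySpec, gen_households, gen_providers, gen_road_network

OUT = Path("results/analysis")

SPEC = CitySpec(
    grid_rows=40, grid_cols=40, cell_length=500.0,
    n_bpjs_providers=106, n_nonbpjs_providers=97,
    n_households=20000, seed=0,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    roads = gen_road_network(SPEC)
    providers = gen_providers(roads, SPEC, clustered=True)
    span = (SPEC.grid_cols - 1) * SPEC.cell_length
    households = gen_households(box(0, 0, span, span), SPEC.n_households, seed=SPEC.seed + 2)

    write_geojson(roads, OUT / "roads.geojson")
    write_geojson(providers, OUT / "providers.geojson")
    write_geojson(households, OUT / "households.geojson")

    n_partner = sum(f.properties["bpjs_partner"] for f in providers)
    print(f"city: {len(roads)} road segments over {span/1000:.1f} km squared grid")
    print(f"providers: {n_partner} partner + {len(providers) - n_partner} non-partner")
    print(f"households: {len(households)}")
    print(f"layers written to {OUT}/")


if __name__ == "__main__":
    main()
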