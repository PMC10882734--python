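"""End-to-end pipeline: simulate (or load) the city, build coverage maps,
select sampling areas, sample households, simulate the survey, and run the
descriptive, PCA and choice-model analyses — all from one JSON config,
with every stage's seed recorded in a manifest of output hashes so a run
can be reproduced byte-identically."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import box, mapping

from carecov import accessibility as acc
from carecov import choice_models as cm
from carecov import preference_pca as pca_mod
from carecov import sampling as smp
from carecov import survey_stats as sstats
from carecov.geojson import Feature, write_geojson
from carecov.synthetic import city as syn_city
from carecov.synthetic import survey as syn_survey

log = logging.getLogger("carecov.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run. Defaults mirror the study
    conditions: 15-minute budget, 106 partner / 97 non-partner providers,
    a target sample of 216 from the 38.5% outpatient-insurance-use
    proportion, and low-partner/high-non-partner sampling rule."""

    out_dir: str = "results/pipeline"
    # city generation (used when no road/provider/household paths given)
    city: dict = field(default_factory=dict)
    roads_path: str | None = None
    providers_path: str | None = None
    households_path: str | None = None
    clustered_providers: bool = True
    # accessibility
    budget_min: float = acc.DEFAULT_BUDGET_MIN
    cell_m: float = acc.DEFAULT_CELL_M
    buffer_m: float = acc.DEFAULT_BUFFER_M
    sampling_rule: tuple[str, str] = ("low", "high")
    # sampling
    sample_p: float = 0.385
    sample_alpha: float = 0.05
    sample_d: float = 0.065
    sample_n: int | None = None  # overrides the Cochran computation
    sample_seed: int = 7
    # survey generation + analysis
    survey_seed: int = 11
    run_table1: bool = True
    run_pca: bool = True
    run_choice_models: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        cfg.sampling_rule = tuple(cfg.sampling_rule)
        return cfg

    @classmethod
    def demo(cls, out_dir: str = "results/pipeline", seed: int = 0) -> "PipelineConfig":
        """A compact synthetic city that still exhibits the
        low-partner/high-non-partner contrast the sampling rule targets."""
        return cls(
            out_dir=out_dir,
            city={
                "grid_rows": 40, "grid_cols": 40, "cell_length": 500.0,
                "n_bpjs_providers": 106, "n_nonbpjs_providers": 97,
                "n_households": 20000, "seed": seed,
            },
            cell_m=250.0,
            # buffer ≳ half the 500 m block spacing so the service ribbons
            # dissolve into filled isochrones at this coarse road density
            buffer_m=300.0,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest (also written to
    ``<out_dir>/manifest.json``). Stage failures are re-raised with the
    stage name; artifacts written before the failure are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}, "warnings": []}

    def save_layer(features, name):
        write_geojson(features, out / name)
        manifest["outputs"][name] = _sha256(out / name)

    def save_json(obj, name):
        with open(out / name, "w") as fh:
            json.dump(obj, fh, indent=1, default=_jsonable)
        manifest["outputs"][name] = _sha256(out / name)

    def save_df(df, name):
        df.to_csv(out / name, index=False)
        manifest["outputs"][name] = _sha256(out / name)

    stage = "simulate_city"
    try:
        spec = syn_city.CitySpec(**config.city)
        if config.roads_path:
            from carecov.geojson import read_geojson

            roads = read_geojson(config.roads_path)
        else:
            roads = syn_city.gen_road_network(spec)
            save_layer(roads, "roads.geojson")
        if config.providers_path:
            from carecov.geojson import read_geojson

            providers = read_geojson(config.providers_path)
        else:
            providers = syn_city.gen_providers(roads, spec, clustered=config.clustered_providers)
            save_layer(providers, "providers.geojson")
        region = box(*_layer_bounds(roads))
        if config.households_path:
            from carecov.geojson import read_geojson

            households = read_geojson(config.households_path)
        else:
            households = syn_city.gen_households(region, spec.n_households, seed=spec.seed + 2)
            save_layer(households, "households.geojson")
        manifest["stages"][stage] = {
            "n_roads": len(roads), "n_providers": len(providers),
            "n_households": len(households), "seed": spec.seed,
        }

        stage = "coverage_maps"
        tg = acc.build_travel_time_graph(roads, spec.speed_table)
        grid = acc.GridSpec.from_bounds(region.bounds, config.cell_m)
        classified = {}
        for stratum in ("bpjs", "non_bpjs"):
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                catchments = acc.catchments_for_providers(
                    tg, providers, config.budget_min, config.buffer_m, stratum=stratum
                )
                surf = acc.coverage_surface(catchments, grid, stratum)
                cls = acc.classify_coverage(surf, acc.DEFAULT_SCHEMES[stratum])
            manifest["warnings"] += [str(w.message) for w in wlist]
            classified[stratum] = cls
            save_df(acc.surface_table(cls), f"coverage_{stratum}.csv")
            manifest["stages"].setdefault(stage, {})[stratum] = {
                "n_catchments": len(catchments),
                "max_value": int(surf.values.max()) if surf.values.size else 0,
                "level_counts": cls.level_counts(),
            }
        if len([f for f in providers if f.properties.get("bpjs_partner")]) == 0:
            manifest["warnings"].append("no partner providers: partner coverage all zero")

        stage = "select_sampling_areas"
        areas = acc.select_sampling_areas(
            classified["bpjs"], classified["non_bpjs"], config.sampling_rule
        )
        save_json(
            {"type": "Feature", "geometry": mapping(areas.polygon),
             "properties": {"rule": list(areas.rule), "n_cells": areas.n_cells}},
            "sampling_areas.geojson",
        )
        manifest["stages"][stage] = {"n_cells": areas.n_cells, "rule": list(areas.rule)}

        stage = "sample_households"
        n_target = config.sample_n or smp.cochran_sample_size(
            config.sample_p, config.sample_alpha, config.sample_d
        )
        eligible = smp._inside(households, areas)
        n_drawn = min(n_target, len(eligible))
        if n_drawn < n_target:
            manifest["warnings"].append(
                f"only {len(eligible)} households inside sampling areas; target was {n_target}"
            )
        frame = smp.draw_households(households, areas, n_drawn, seed=config.sample_seed)
        save_df(_frame_df(frame), "selected_households.csv")
        manifest["stages"][stage] = {
            "cochran_n": n_target, "n_selected": n_drawn,
            "n_eligible": len(eligible), "seed": config.sample_seed,
        }

        stage = "simulate_survey"
        respondents = syn_survey.gen_respondents(
            frame.selected_features() if n_drawn else 0, seed=config.survey_seed
        )
        save_df(respondents, "survey.csv")
        manifest["stages"][stage] = {"n_respondents": len(respondents), "seed": config.survey_seed}

        stage = "analyze"
        analysis_summary = {}
        if config.run_table1 and len(respondents):
            report = sstats.descriptive_report(respondents)
            save_json(report, "table1.json")
            (out / "table1.txt").write_text(sstats.render_report(report))
            manifest["outputs"]["table1.txt"] = _sha256(out / "table1.txt")
            analysis_summary["table1_variables"] = len(report["variables"])
        if config.run_pca and len(respondents) > 13:
            pca_results = {}
            for sc in ("mild", "chronic", "serious"):
                items = respondents[[f"pref_{sc}_{it}" for it in syn_survey.PREFERENCE_ITEMS]]
                res = pca_mod.pca_preferences(items, item_labels=list(syn_survey.PREFERENCE_ITEMS))
                pca_results[sc] = res
                save_df(res.loadings_frame().reset_index(names="item"), f"pca_loadings_{sc}.csv")
                save_json(
                    {"eigenvalues": res.eigenvalues.tolist(),
                     "n_retained": res.n_retained,
                     "cumulative_variance_pct": res.cumulative_variance_pct,
                     "n": res.n_used},
                    f"pca_summary_{sc}.json",
                )
            analysis_summary["pca_retained"] = {k: v.n_retained for k, v in pca_results.items()}
        if config.run_choice_models and len(respondents) > 50:
            covs = ["age", "chronic_illness", "income", "education", "pbi", "other_insurance"]
            adjust = ["gender", "mild_illness", "consultations", "ever_used_benefit"]
            tables = 0
            for sc in ("actual", "mild", "chronic", "serious"):
                try:
                    res = cm.fit_multinomial_choice(
                        respondents, f"choice_{sc}", covs, adjust=adjust,
                        reference_levels={"income": "low", "education": "primary"},
                    )
                    save_df(res.table.assign(scenario=sc), f"choice_{sc}.csv")
                    (out / f"choice_{sc}.txt").write_text(cm.render_table(res))
                    manifest["outputs"][f"choice_{sc}.txt"] = _sha256(out / f"choice_{sc}.txt")
                    tables += 1
                except ValueError as exc:
                    manifest["warnings"].append(f"choice model {sc}: {exc}")
            if config.run_pca and len(respondents) > 13:
                for sc in ("mild", "chronic", "serious"):
                    res = pca_results[sc]
                    items = respondents[[f"pref_{sc}_{it}" for it in syn_survey.PREFERENCE_ITEMS]]
                    complete = ~items.isna().any(axis=1)
                    try:
                        pres = cm.preference_choice_models(
                            res.scores, respondents.loc[complete], sc
                        )
                        save_df(pres.table.assign(scenario=sc), f"choice_pref_{sc}.csv")
                        tables += 1
                    except ValueError as exc:
                        manifest["warnings"].append(f"preference choice model {sc}: {exc}")
            analysis_summary["choice_model_tables"] = tables
        manifest["stages"][stage] = analysis_summary
    except Exception as exc:
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    # the manifest itself is not hashed into its own output list
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=_jsonable)


def _layer_bounds(features: list[Feature]) -> tuple[float, float, float, float]:
    bs = np.array([f.geometry.bounds for f in features])
    return float(bs[:, 0].min()), float(bs[:, 1].min()), float(bs[:, 2].max()), float(bs[:, 3].max())


def _frame_df(frame: smp.SampleFrame):
    import pandas as pd

    idx = {str(f.properties["household_id"]): f for f in frame.households}
    back = {v: k for k, v in frame.replacements.items()}
    rows = [
        {"household_id": hid, "x": idx[hid].geometry.x, "y": idx[hid].geometry.y,
         "replaced_from": back.get(hid, "")}
        for hid in frame.selected
    ]
    return pd.DataFrame(rows, columns=["household_id", "x", "y", "replaced_from"])


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
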