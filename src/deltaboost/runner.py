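"""End-to-end run orchestration: fit, predict, diagnose, write outputs.

A run writes, under its output directory: the combined predictions
(`abundance_preds_latlon.csv` with coordinates only, and
`abundance_preds_full.csv` with explanatory variables and both hurdle
components), per-component influence CSVs, the consolidated
`model_report.csv`, the serialized model, representativeness surfaces,
and PNG maps.  The resolved configuration is persisted beside the
outputs as an audit trail.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import brt, diagnostics, geo, rsb
from .core_data import LAT, LON, BrtConfig, GridTable, SampleTable

CSV_FLOAT_FORMAT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_config(config: BrtConfig, path: Path, extra: dict | None = None) -> None:
    payload = dataclasses.asdict(config)
    payload.update(extra or {})
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def run_fit(
    samples: SampleTable,
    grids: GridTable,
    resvar_name: str,
    config: BrtConfig,
    out_dir,
    expvar_names: list[str] | None = None,
    make_maps: bool = True,
    coastline: list | None = None,
) -> brt.DeltaFitResult:
    """The automated pipeline over one response variable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expvars = list(expvar_names or samples.expvars)
    write_config(config, out / "run_config.json", {"resvar": resvar_name, "expvars": expvars})

    result = brt.fit_delta(samples, resvar_name, config, expvars)
    model = result.model
    surface = brt.predict_combined(model, grids)

    _write_csv(surface.df[[LAT, LON, "combined_index"]], out / "abundance_preds_latlon.csv")
    full = grids.df.merge(surface.df, on=[LAT, LON])
    _write_csv(full, out / "abundance_preds_full.csv")

    influence: dict[str, pd.DataFrame] = {}
    interactions: dict[str, pd.DataFrame] = {}
    comps = [("binary", model.binary)]
    if model.gaussian is not None:
        comps.append(("gaussian", model.gaussian))
    for cname, comp in comps:
        table = diagnostics.relative_influence(comp)
        influence[cname] = table
        _write_csv(table, out / f"influence_{cname}.csv")
        X = samples.X(expvars)
        if len(comp.kept_expvars) >= 2:
            interactions[cname] = diagnostics.top_interactions(comp, X, max_pairs=10)

    report = diagnostics.model_report(result, influence, interactions)
    _write_csv(report, out / "model_report.csv")
    brt.persist(model, out / "model.joblib")

    surfaces = rsb.rsb_for_model(
        samples, grids,
        binary_expvars=model.binary.kept_expvars,
        gaussian_expvars=(model.gaussian.kept_expvars if model.gaussian else model.binary.kept_expvars),
    )
    for name, surf in surfaces.items():
        _write_csv(surf.df, out / f"rsb_{name}.csv")

    if make_maps:
        raster = geo.rasterize_surface(
            surface.df[LON], surface.df[LAT], surface.df["combined_index"]
        )
        for grey, tag in ((False, "colour"), (True, "grey")):
            geo.render_map(
                raster, out / f"abundance_map_{tag}.png",
                legend=f"predicted {resvar_name} (combined index)",
                coastline=coastline, greyscale=grey,
            )
        rsb_raster = geo.rasterize_surface(
            surfaces["combined"].df[LON], surfaces["combined"].df[LAT],
            surfaces["combined"].df["total"],
        )
        geo.render_map(
            rsb_raster, out / "rsb_map.png",
            legend="representativeness score (high = poor coverage)",
            coastline=coastline,
        )
        for cname, comp in comps:
            diagnostics.influence_barplot(influence[cname], str(out / f"influence_{cname}"))
            diagnostics.partial_plots(comp, samples.X(expvars), str(out / f"pd_{cname}"))
            diagnostics.dotplots(comp, samples.X(expvars), str(out / f"dot_{cname}"))
    return result
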