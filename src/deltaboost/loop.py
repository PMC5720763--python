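"""Between-run variability of the delta BRT pipeline.

Boosting with a bag fraction below 1 is stochastic, so two runs that
differ only in seed produce (slightly) different abundance surfaces.
Repeating an identical run under seeds base_seed + k and collating the
outputs gives a per-cell coefficient of variation map — a direct,
assumption-free picture of prediction stability — together with
min/mean/max/variance envelopes of variable influence and partial
dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .brt import PredictionSurface, fit_delta, predict_combined
from .core_data import LAT, LON, BrtConfig, GridTable, SampleTable
from .diagnostics import PD_POINTS, partial_dependence, relative_influence


def cv_surface(surfaces: list[PredictionSurface]) -> pd.DataFrame:
    """Per-cell mean, sd (n-1 denominator) and coefficient of variation
    (sd/mean, missing where the mean is 0) of the combined index."""
    if len(surfaces) < 2:
        raise ValueError("need at least two surfaces")
    ref = surfaces[0].df[[LAT, LON]].reset_index(drop=True)
    stack = []
    for s in surfaces:
        cells = s.df[[LAT, LON]].reset_index(drop=True)
        if not cells.equals(ref):
            raise ValueError("surfaces are not on identical cell sets")
        stack.append(s.df["combined_index"].to_numpy())
    M = np.vstack(stack)
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    # byte-identical runs must report exactly zero spread, not float dust
    identical = (M == M[0]).all(axis=0)
    sd = np.where(identical, 0.0, sd)
    mean = np.where(identical, M[0], mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    out = ref.copy()
    out["mean"] = mean
    out["sd"] = sd
    out["cv"] = cv
    return out


@dataclass
class LoopSummary:
    n_runs: int
    cells: pd.DataFrame  # latitude, longitude, mean, sd, cv
    influence: pd.DataFrame  # component, variable, min, mean, max, variance
    pd_envelopes: dict[tuple[str, str], pd.DataFrame]  # (component, var) -> x, min, mean, max
    surfaces: list[PredictionSurface]


def run_loops(
    n_runs: int,
    samples: SampleTable,
    grids: GridTable,
    resvar_name: str,
    config: BrtConfig,
    base_seed: int = 1,
    expvar_names: list[str] | None = None,
    force_identical_seed: bool = False,
) -> LoopSummary:
    """Repeat the identical automated run ``n_runs`` times and summarize.

    Run k uses seed base_seed + k (or base_seed for every run in the
    degenerate forced-identical mode, which must yield CV = 0).
    Simplification is normally toggled off inside loops so the variable
    set stays constant across runs; when it is on, a variable absent
    from a run counts as influence 0 there.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    expvars = list(expvar_names or samples.expvars)
    surfaces: list[PredictionSurface] = []
    infl_runs: list[dict[tuple[str, str], float]] = []
    pd_runs: list[dict[tuple[str, str], np.ndarray]] = []
    pd_grids: dict[tuple[str, str], np.ndarray] = {}

    for k in range(n_runs):
        seed = base_seed if force_identical_seed else base_seed + k
        cfg = replace(config, seed=seed)
        try:
            result = fit_delta(samples, resvar_name, cfg, expvars)
            model = result.model
            surfaces.append(predict_combined(model, grids))
            run_infl: dict[tuple[str, str], float] = {}
            run_pd: dict[tuple[str, str], np.ndarray] = {}
            comps = [("binary", model.binary)]
            if model.gaussian is not None:
                comps.append(("gaussian", model.gaussian))
            for cname, comp in comps:
                table = relative_influence(comp)
                for var in expvars:
                    row = table[table["variable"] == var]
                    run_infl[(cname, var)] = (
                        float(row["influence"].iloc[0]) if len(row) else 0.0
                    )
                X = samples.X(expvars)
                for var in comp.kept_expvars:
                    key = (cname, var)
                    if key not in pd_grids:
                        col = X[var].to_numpy(dtype=float)
                        pd_grids[key] = np.linspace(col.min(), col.max(), PD_POINTS)
                    curve = partial_dependence(comp, X, var)
                    # curves share the common x-grid because the sampled
                    # range is a property of the data, not the run
                    run_pd[key] = curve.effect
            infl_runs.append(run_infl)
            pd_runs.append(run_pd)
        except Exception as exc:
            raise RuntimeError(f"loop run {k} (seed {seed}) failed: {exc}") from exc

    cells = cv_surface(surfaces)

    rows = []
    keys = sorted({k for run in infl_runs for k in run})
    for cname, var in keys:
        vals = np.array([run.get((cname, var), 0.0) for run in infl_runs])
        rows.append(
            {
                "component": cname,
                "variable": var,
                "min": vals.min(),
                "mean": vals.mean(),
                "max": vals.max(),
                "variance": vals.var(ddof=1),
            }
        )
    influence = pd.DataFrame(rows)

    envelopes: dict[tuple[str, str], pd.DataFrame] = {}
    for key, xs in pd_grids.items():
        curves = np.vstack([run[key] for run in pd_runs if key in run])
        envelopes[key] = pd.DataFrame(
            {
                "x": xs,
                "min": curves.min(axis=0),
                "mean": curves.mean(axis=0),
                "max": curves.max(axis=0),
            }
        )

    return LoopSummary(
        n_runs=n_runs,
        cells=cells,
        influence=influence,
        pd_envelopes=envelopes,
        surfaces=surfaces,
    )
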