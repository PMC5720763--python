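"""Model interrogation: variable influence, partial dependence, two-way
interaction strength, dot-plot data, and the consolidated run report.

All quantities are computed on the link scale (log-odds for the
occurrence component, log-abundance for the gaussian component); any
response-scale rendering is a plotting option, not a different
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .brt import ComponentFit, DeltaFitResult
from .core_data import ValidationError

PD_POINTS = 100
INTERACTION_GRID = 20


def relative_influence(fit: ComponentFit) -> pd.DataFrame:
    """Percentage attribution of loss reduction to each kept variable.

    Sums to 100 per component.  A degenerate (constant) fit has no loss
    to attribute; the returned table is all-zero and flagged via
    ``df.attrs['degenerate']``.
    """
    imp = fit.importances
    if imp is None:
        imp = getattr(fit.ensemble, "feature_importances_", np.zeros(len(fit.kept_expvars)))
    imp = np.maximum(np.asarray(imp, dtype=float), 0.0)
    total = imp.sum()
    df = pd.DataFrame({"variable": fit.kept_expvars, "influence": np.zeros(len(imp))})
    if total <= 0:
        df.attrs["degenerate"] = True
        warnings.warn("all-zero influence attribution (degenerate fit)", stacklevel=2)
        return df
    df["influence"] = 100.0 * imp / total
    df.attrs["degenerate"] = False
    return df.sort_values("influence", ascending=False).reset_index(drop=True)


@dataclass
class PartialCurve:
    variable: str
    x: np.ndarray  # strictly increasing, spans the sampled range
    effect: np.ndarray  # link-scale marginal effect, one per x


def partial_dependence(
    fit: ComponentFit, X: pd.DataFrame, variable: str, n_points: int = PD_POINTS
) -> PartialCurve:
    """Marginal effect curve: average link-scale prediction over the
    training rows with ``variable`` clamped to each grid value."""
    if variable not in fit.kept_expvars:
        raise ValidationError(f"{variable!r} is not a kept explanatory variable")
    col = X[variable].to_numpy(dtype=float)
    xs = np.linspace(np.nanmin(col), np.nanmax(col), n_points)
    Xc = X[fit.kept_expvars].copy()
    effects = np.empty(n_points)
    for i, xv in enumerate(xs):
        Xc[variable] = xv
        effects[i] = float(np.mean(fit.raw_predict(Xc)))
    return PartialCurve(variable=variable, x=xs, effect=effects)


def dotplot_data(fit: ComponentFit, X: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-observation fitted contribution against the variable's value.

    contribution(row) = link-scale prediction at the row's observed
    covariates minus the component's mean prediction, so contributions
    are centred on zero.
    """
    if variable not in fit.kept_expvars:
        raise ValidationError(f"{variable!r} is not a kept explanatory variable")
    raw = fit.raw_predict(X)
    return pd.DataFrame(
        {"x": X[variable].to_numpy(dtype=float), "contribution": raw - raw.mean()}
    )


def interaction_strength(
    fit: ComponentFit,
    X: pd.DataFrame,
    var_a: str,
    var_b: str,
    n_grid: int = INTERACTION_GRID,
) -> float:
    """Two-way interaction size: residual variance of the joint
    partial-dependence surface after removing additive row/column
    effects, on an ``n_grid`` x ``n_grid`` lattice over the sampled
    ranges.  Exactly additive pairs score ~0; symmetric in its arguments.
    """
    for v in (var_a, var_b):
        if v not in fit.kept_expvars:
            raise ValidationError(f"{v!r} is not a kept explanatory variable")
    # canonical pair order makes the statistic exactly symmetric
    var_a, var_b = sorted((var_a, var_b))
    a = X[var_a].to_numpy(dtype=float)
    b = X[var_b].to_numpy(dtype=float)
    xa = np.linspace(np.nanmin(a), np.nanmax(a), n_grid)
    xb = np.linspace(np.nanmin(b), np.nanmax(b), n_grid)
    Xc = X[fit.kept_expvars].copy()
    Z = np.empty((n_grid, n_grid))
    for i, va in enumerate(xa):
        Xc[var_a] = va
        for j, vb in enumerate(xb):
            Xc[var_b] = vb
            Z[i, j] = float(np.mean(fit.raw_predict(Xc)))
    resid = Z - Z.mean(axis=1, keepdims=True) - Z.mean(axis=0, keepdims=True) + Z.mean()
    return float(np.var(resid))


def top_interactions(
    fit: ComponentFit, X: pd.DataFrame, max_pairs: int | None = None
) -> pd.DataFrame:
    """Interaction strength for every kept-variable pair, descending."""
    rows = []
    kept = fit.kept_expvars
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            rows.append(
                (kept[i], kept[j], interaction_strength(fit, X, kept[i], kept[j]))
            )
    df = pd.DataFrame(rows, columns=["var_a", "var_b", "strength"])
    df = df.sort_values("strength", ascending=False).reset_index(drop=True)
    return df.head(max_pairs) if max_pairs else df


def model_report(result: DeltaFitResult, influence: dict[str, pd.DataFrame] | None = None,
                 interactions: dict[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """Consolidated run report as a tidy (section, component, key, value)
    table: every grid-search combination's CV metrics and tree count, the
    selected combinations, simplification trail, influence, top
    interactions, train metrics, smearing factor, seed and ZI decision."""
    rows: list[tuple[str, str, str, object]] = []
    model = result.model

    def combo_rows(comp_name: str, fits):
        for f in fits:
            key = f"tc={f.tc} lr={f.lr} bf={f.bf}"
            rows.append(("grid_search", comp_name, key + " cv_deviance_mean", f.cv_deviance_mean))
            rows.append(("grid_search", comp_name, key + " cv_deviance_se", f.cv_deviance_se))
            rows.append(("grid_search", comp_name, key + " n_trees", f.n_trees))

    combo_rows("binary", result.binary_fits)
    combo_rows("gaussian", result.gaussian_fits)

    def selected_rows(comp_name: str, f: ComponentFit):
        rows.append(("selected", comp_name, "tc", f.tc))
        rows.append(("selected", comp_name, "lr", f.lr))
        rows.append(("selected", comp_name, "bf", f.bf))
        rows.append(("selected", comp_name, "n_trees", f.n_trees))
        rows.append(("selected", comp_name, "cv_deviance_mean", f.cv_deviance_mean))
        rows.append(("selected", comp_name, "train_metric", f.train_metric))
        rows.append(("selected", comp_name, "kept_expvars", ";".join(f.kept_expvars)))
        for var, delta in f.simplification_trail:
            rows.append(("simplification", comp_name, var, delta))

    selected_rows("binary", model.binary)
    if model.gaussian is not None:
        selected_rows("gaussian", model.gaussian)

    for comp_name, table in (influence or {}).items():
        for _, r in table.iterrows():
            rows.append(("influence", comp_name, r["variable"], r["influence"]))
    for comp_name, table in (interactions or {}).items():
        for _, r in table.iterrows():
            rows.append(
                ("interaction", comp_name, f"{r['var_a']}:{r['var_b']}", r["strength"])
            )

    rows.append(("run", "", "zi_used", model.zi_used))
    rows.append(("run", "", "resvar", model.resvar_name))
    rows.append(("run", "", "seed", model.seed))
    if model.smearing_factor is not None:
        rows.append(("run", "", "smearing_factor", model.smearing_factor))
    return pd.DataFrame(rows, columns=["section", "component", "key", "value"])


# --- plotting -------------------------------------------------------------

def _save_variants(fig, out_prefix, grey_artists=None):
    fig.savefig(f"{out_prefix}.png", dpi=96)
    plt.close(fig)


def influence_barplot(table: pd.DataFrame, out_prefix: str, greyscale: bool = False) -> None:
    fig, ax = plt.subplots(figsize=(20, 10))
    color = "0.5" if greyscale else "tab:blue"
    ax.barh(table["variable"], table["influence"], color=color)
    ax.set_xlabel("relative influence (%)")
    ax.invert_yaxis()
    _save_variants(fig, out_prefix)


def partial_plots(
    fit: ComponentFit, X: pd.DataFrame, out_prefix: str, greyscale: bool = False
) -> None:
    """One lattice figure of all partial-dependence curves, then one PNG
    per variable, in colour or greyscale."""
    color = "0.2" if greyscale else "tab:blue"
    kept = fit.kept_expvars
    ncol = int(np.ceil(np.sqrt(len(kept))))
    nrow = int(np.ceil(len(kept) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(20, 10), squeeze=False)
    for ax, var in zip(axes.ravel(), kept):
        curve = partial_dependence(fit, X, var)
        ax.plot(curve.x, curve.effect, color=color)
        ax.set_title(var)
    for ax in axes.ravel()[len(kept):]:
        ax.axis("off")
    _save_variants(fig, f"{out_prefix}_matrix")
    for var in kept:
        curve = partial_dependence(fit, X, var)
        fig, ax = plt.subplots(figsize=(20, 10))
        ax.plot(curve.x, curve.effect, color=color)
        ax.set_xlabel(var)
        ax.set_ylabel("marginal effect (link scale)")
        _save_variants(fig, f"{out_prefix}_{var}")


def dotplots(
    fit: ComponentFit, X: pd.DataFrame, out_prefix: str, greyscale: bool = False
) -> None:
    color = "0.3" if greyscale else "tab:orange"
    for var in fit.kept_expvars:
        pts = dotplot_data(fit, X, var)
        fig, ax = plt.subplots(figsize=(20, 10))
        ax.plot(pts["x"], pts["contribution"], ".", ms=2, color=color)
        ax.set_xlabel(var)
        ax.set_ylabel("fitted contribution (link scale)")
        _save_variants(fig, f"{out_prefix}_{var}")
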