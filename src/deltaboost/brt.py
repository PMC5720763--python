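"""Delta log-normal boosted regression trees.

Zero-inflated abundance is modelled as a hurdle: a bernoulli boosted
ensemble predicts the probability of a non-zero catch, and a gaussian
ensemble fitted to ln(catch) on the positive subset predicts its
magnitude.  Back-transformation uses Duan's smearing estimator (the mean
of exponentiated log-scale residuals) rather than a naive exp(), which
would be biased low.  The two predictions are multiplied into a single
abundance index per grid cell.

Ensemble fitting itself delegates to scikit-learn gradient boosting;
what is authored here is the tree-count stopping rule (trees grown in
blocks of 50 under k-fold cross-validation, stopping after two blocks
without improvement of the mean held-out deviance), the nested
hyperparameter grid search over tree complexity / learning rate / bag
fraction, backward simplification under a 1-SE rule, the smearing
retransformation, and the hurdle combination.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .core_data import (
    LAT,
    LON,
    BrtConfig,
    GridTable,
    SampleTable,
    ValidationError,
    check_zero_inflation,
    split_binary_gaussian,
)

log = logging.getLogger(__name__)

BLOCK_SIZE = 50
PATIENCE_BLOCKS = 2
MAX_TREES = 10_000
SCHEMA_VERSION = 1

FAMILIES = ("bernoulli", "gaussian", "poisson")


class FitError(RuntimeError):
    pass


@dataclass
class ComponentFit:
    """One fitted boosted ensemble plus its selection metadata."""

    family: str
    tc: int
    lr: float
    bf: float
    n_trees: int
    cv_deviance_mean: float
    cv_deviance_se: float
    train_metric: float
    kept_expvars: list[str]
    ensemble: object
    cv_curve: list[tuple[int, float, float]] = field(default_factory=list)
    impute_medians: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    simplification_trail: list[tuple[str, float]] = field(default_factory=list)
    importances: np.ndarray | None = None  # unnormalized, aligned to kept_expvars

    def raw_predict(self, X: pd.DataFrame) -> np.ndarray:
        """Link-scale prediction: log-odds (bernoulli), identity (gaussian),
        log-mean (poisson)."""
        Xi = _impute(X[self.kept_expvars], self.impute_medians)
        if self.family == "bernoulli":
            return self.ensemble.decision_function(Xi)
        if self.family == "poisson":
            return np.log(np.maximum(self.ensemble.predict(Xi), 1e-300))
        return self.ensemble.predict(Xi)

    def response_predict(self, X: pd.DataFrame) -> np.ndarray:
        raw = self.raw_predict(X)
        if self.family == "bernoulli":
            return 1.0 / (1.0 + np.exp(-raw))
        if self.family == "poisson":
            return np.exp(raw)
        return raw


@dataclass
class FittedDeltaModel:
    """A fitted hurdle pair (or a single-family fit when not zero-inflated).

    For a delta run, ``binary`` is the occurrence component and
    ``gaussian`` the log-abundance component with its smearing factor.
    A single-family run stores its one component in ``binary`` and leaves
    ``gaussian`` absent; occurrence probability is then reported as 1.
    """

    binary: ComponentFit
    gaussian: ComponentFit | None
    smearing_factor: float | None
    zi_used: bool
    resvar_name: str
    seed: int


@dataclass
class PredictionSurface:
    """Per-cell occurrence probability, positive abundance, combined index."""

    df: pd.DataFrame  # latitude, longitude, p_occurrence, positive_abundance, combined_index

    def __len__(self) -> int:
        return len(self.df)

    @property
    def combined_index(self) -> np.ndarray:
        return self.df["combined_index"].to_numpy()


def _impute(X: pd.DataFrame, medians: dict[str, float]) -> pd.DataFrame:
    # placeholder fill so the estimator accepts the frame; cells with
    # missing expvars get their outputs masked to NaN by predict_combined
    if not X.isna().any().any():
        return X
    return X.fillna(medians if medians else X.median())


def deviance(family: str, y: np.ndarray, raw: np.ndarray) -> float:
    """Mean deviance on the link scale; the CV selection metric.

    bernoulli: -2 * mean Bernoulli log-likelihood; gaussian: MSE;
    poisson: mean unit Poisson deviance.
    """
    y = np.asarray(y, dtype=float)
    if family == "bernoulli":
        p = np.clip(1.0 / (1.0 + np.exp(-raw)), 1e-12, 1 - 1e-12)
        return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    if family == "poisson":
        mu = np.exp(raw)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.mean(term - (y - mu)))
    return float(np.mean((y - raw) ** 2))


def null_deviance(family: str, y: np.ndarray) -> float:
    """Deviance of the intercept-only model, for skill comparisons."""
    y = np.asarray(y, dtype=float)
    if family == "bernoulli":
        p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        raw = np.full_like(y, np.log(p / (1 - p)))
    elif family == "poisson":
        raw = np.full_like(y, np.log(max(y.mean(), 1e-12)))
    else:
        raw = np.full_like(y, y.mean())
    return deviance(family, y, raw)


def _make_estimator(family: str, tc: int, lr: float, bf: float, n_trees: int, seed: int):
    common = dict(
        learning_rate=lr,
        n_estimators=n_trees,
        max_leaf_nodes=tc + 1,  # tc splits per tree (interaction depth)
        max_depth=None,
        subsample=bf,
        random_state=seed,
        warm_start=True,
    )
    if family == "bernoulli":
        return GradientBoostingClassifier(**common)
    if family == "gaussian":
        return GradientBoostingRegressor(loss="squared_error", **common)
    if family == "poisson":
        if bf < 1.0:
            log.warning("poisson family ignores bag fraction (no subsampling support)")
        return HistGradientBoostingRegressor(
            loss="poisson",
            learning_rate=lr,
            max_iter=n_trees,
            max_leaf_nodes=tc + 1,
            early_stopping=False,
            random_state=seed,
            warm_start=True,
        )
    raise ValidationError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _grow_to(est, n: int):
    if isinstance(est, HistGradientBoostingRegressor):
        est.set_params(max_iter=n)
    else:
        est.set_params(n_estimators=n)
    return est


def _raw(est, family: str, X) -> np.ndarray:
    if family == "bernoulli":
        return est.decision_function(X)
    if family == "poisson":
        return np.log(np.maximum(est.predict(X), 1e-300))
    return est.predict(X)


def fit_component(
    X: pd.DataFrame,
    y: np.ndarray,
    family: str,
    tc: int,
    lr: float,
    bf: float,
    cv_folds: int = 10,
    seed: int = 1,
    block_size: int = BLOCK_SIZE,
    patience: int = PATIENCE_BLOCKS,
    max_trees: int = MAX_TREES,
) -> ComponentFit:
    """Fit one boosted ensemble with block-wise CV early stopping.

    Trees are grown in blocks of ``block_size``; after each block the
    mean k-fold held-out deviance is recorded; growth stops once the
    deviance has not improved for ``patience`` consecutive blocks (or at
    ``max_trees``).  The returned tree count is the argmin of the CV
    deviance curve, and the final ensemble is refitted at that size on
    all rows.
    """
    y = np.asarray(y, dtype=float)
    X = X.copy()
    medians: dict[str, float] = {}
    if X.isna().any().any():
        n_missing = int(X.isna().sum().sum())
        medians = X.median().to_dict()
        X = X.fillna(medians)
        log.info("median-imputed %d missing explanatory value(s)", n_missing)

    degenerate = bool(np.all(y == y[0]))
    if family == "bernoulli":
        n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
        if min(n_pos, n_neg) < cv_folds:
            raise FitError(
                f"bernoulli stratification needs >= {cv_folds} cases per class "
                f"(have {n_pos} positive, {n_neg} negative)"
            )
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(X, y))
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(X))

    fold_models = [
        _make_estimator(family, tc, lr, bf, block_size, seed + 1 + k)
        for k in range(cv_folds)
    ]
    curve: list[tuple[int, float, float]] = []
    best = np.inf
    stale = 0
    n = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # warm-start/subsample chatter
        while n < max_trees:
            n += block_size
            devs = []
            for (tr, te), est in zip(folds, fold_models):
                _grow_to(est, n).fit(X.iloc[tr], y[tr])
                devs.append(deviance(family, y[te], _raw(est, family, X.iloc[te])))
            devs = np.asarray(devs)
            mean = float(devs.mean())
            se = float(devs.std(ddof=1) / np.sqrt(cv_folds))
            curve.append((n, mean, se))
            if mean < best - 1e-12:
                best = mean
                stale = 0
            else:
                stale += 1
            if stale >= patience:
                break

    means = [c[1] for c in curve]
    i_best = int(np.argmin(means))
    n_trees, cv_mean, cv_se = curve[i_best]
    if i_best == 0 and len(curve) > 1:
        warnings.warn(
            "CV deviance minimal at the first block: lr may be too high",
            stacklevel=2,
        )

    final = _make_estimator(family, tc, lr, bf, n_trees, seed)
    final.set_params(warm_start=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)

    importances = getattr(final, "feature_importances_", None)
    if importances is None:
        # hist-based ensembles expose no impurity importances; use the
        # variance of each variable's partial-dependence curve instead
        importances = np.empty(X.shape[1])
        for j, col in enumerate(X.columns):
            xs = np.linspace(X[col].min(), X[col].max(), 20)
            Xc = X.copy()
            pd_vals = []
            for xv in xs:
                Xc[col] = xv
                pd_vals.append(float(np.mean(_raw(final, family, Xc))))
            importances[j] = np.var(pd_vals)
    importances = np.asarray(importances, dtype=float)

    raw_train = _raw(final, family, X)
    if family == "bernoulli":
        if degenerate:
            train_metric = float("nan")
        else:
            train_metric = float(roc_auc_score(y, raw_train))
    else:
        var = float(np.var(y))
        train_metric = 1.0 - deviance(family, y, raw_train) / null_deviance(family, y) if var > 0 else 0.0

    return ComponentFit(
        family=family,
        tc=tc,
        lr=lr,
        bf=bf,
        n_trees=n_trees,
        cv_deviance_mean=cv_mean,
        cv_deviance_se=cv_se,
        train_metric=train_metric,
        kept_expvars=list(X.columns),
        ensemble=final,
        cv_curve=curve,
        impute_medians=medians,
        degenerate=degenerate,
        importances=importances,
    )


def _selection_key(fit: ComponentFit) -> tuple:
    # minimal CV deviance; ties -> fewer trees, lower tc, lower lr, lower bf
    return (fit.cv_deviance_mean, fit.n_trees, fit.tc, fit.lr, fit.bf)


def select_best(fits: list[ComponentFit]) -> ComponentFit:
    """Deterministic best-combination choice, invariant to list order."""
    return min(fits, key=_selection_key)


def grid_search_component(
    X: pd.DataFrame,
    y: np.ndarray,
    family: str,
    config: BrtConfig,
) -> tuple[ComponentFit, list[ComponentFit]]:
    """Fit every (tc, lr, bf) combination, bf nested in lr nested in tc.

    Returns the selected fit and all fits (for the model report).  If
    every combination fails, the per-combination reasons are aggregated.
    """
    fits: list[ComponentFit] = []
    failures: list[str] = []
    for tc in config.tc_candidates:
        for lr in config.lr_candidates:
            for bf in config.bf_candidates:
                try:
                    fits.append(
                        fit_component(
                            X, y, family, tc, lr, bf,
                            cv_folds=config.cv_folds, seed=config.seed,
                        )
                    )
                except Exception as exc:  # noqa: BLE001 — aggregated below
                    failures.append(f"tc={tc} lr={lr} bf={bf}: {exc}")
    if not fits:
        raise FitError(
            "every hyperparameter combination failed:\n" + "\n".join(failures)
        )
    return select_best(fits), fits


def simplify(
    fit: ComponentFit,
    X: pd.DataFrame,
    y: np.ndarray,
    config: BrtConfig,
) -> ComponentFit:
    """Backward elimination of explanatory variables under the 1-SE rule.

    Iteratively drops the variable whose removal least increases CV
    deviance, stopping when the best candidate removal would increase it
    by more than one fold-SE of the current model.  Models with a single
    variable are returned unchanged.
    """
    current = fit
    trail: list[tuple[str, float]] = []
    while len(current.kept_expvars) >= 2:
        candidates = []
        for drop in current.kept_expvars:
            keep = [v for v in current.kept_expvars if v != drop]
            refit = fit_component(
                X[keep], y, current.family, current.tc, current.lr, current.bf,
                cv_folds=config.cv_folds, seed=config.seed,
            )
            candidates.append((drop, refit))
        drop, refit = min(
            candidates, key=lambda c: (c[1].cv_deviance_mean, c[0])
        )
        delta = refit.cv_deviance_mean - current.cv_deviance_mean
        if delta > current.cv_deviance_se:
            break
        trail.append((drop, float(delta)))
        current = refit
    if trail:
        current = replace(current, simplification_trail=fit.simplification_trail + trail)
    return current


def smearing_factor(log_residuals) -> float:
    """Duan's smearing estimator: mean of exp(residual) on the log scale."""
    r = np.asarray(log_residuals, dtype=float)
    if r.size == 0:
        raise ValidationError("smearing factor requires at least one residual")
    return float(np.mean(np.exp(r)))


@dataclass
class DeltaFitResult:
    """A fitted model plus the full search record for reporting."""

    model: FittedDeltaModel
    binary_fits: list[ComponentFit]
    gaussian_fits: list[ComponentFit]
    zi_decision: bool


def fit_delta(
    samples: SampleTable,
    resvar_name: str,
    config: BrtConfig,
    expvar_names: list[str] | None = None,
) -> DeltaFitResult:
    """Full automated run: ZI check, hurdle split, grid search per
    component, optional simplification, smearing factor."""
    expvars = list(expvar_names or samples.expvars)
    y = samples.y(resvar_name)
    if config.zi == "auto":
        zi = check_zero_inflation(y, config.zi_threshold)
    else:
        zi = bool(config.zi)
    X = samples.X(expvars)

    if zi:
        binary_y, pos = split_binary_gaussian(samples, resvar_name)
        best_bin, all_bin = grid_search_component(X, binary_y, config.family_binary, config)
        Xg = pos.X(expvars)
        yg = pos.y(resvar_name)  # already ln-transformed
        best_gau, all_gau = grid_search_component(Xg, yg, config.family_gaussian, config)
        if config.simplify:
            if len(best_bin.kept_expvars) >= 2:
                best_bin = simplify(best_bin, X, binary_y, config)
            if len(best_gau.kept_expvars) >= 2:
                best_gau = simplify(best_gau, Xg, yg, config)
        resid = yg - best_gau.raw_predict(Xg)
        smear = smearing_factor(resid)
        model = FittedDeltaModel(
            binary=best_bin, gaussian=best_gau, smearing_factor=smear,
            zi_used=True, resvar_name=resvar_name, seed=config.seed,
        )
        return DeltaFitResult(model, all_bin, all_gau, True)

    family = config.family_gaussian
    best, fits = grid_search_component(X, y, family, config)
    if config.simplify and len(best.kept_expvars) >= 2:
        best = simplify(best, X, y, config)
    model = FittedDeltaModel(
        binary=best, gaussian=None, smearing_factor=None,
        zi_used=False, resvar_name=resvar_name, seed=config.seed,
    )
    return DeltaFitResult(model, fits, [], False)


def predict_combined(model: FittedDeltaModel, grids: GridTable) -> PredictionSurface:
    """Predict the combined abundance index over a grid.

    Delta path: combined = P(occurrence) * smear * exp(log-abundance).
    Single-family path: the component's response-scale prediction
    (clipped at 0, the response being an abundance index), with
    p_occurrence reported as 1.  Cells with missing explanatory values
    get missing predictions, never silent zeros.
    """
    needed = set(model.binary.kept_expvars)
    if model.gaussian is not None:
        needed |= set(model.gaussian.kept_expvars)
    missing_cols = sorted(needed - set(grids.df.columns))
    if missing_cols:
        raise ValidationError(f"grids lack explanatory variable(s) {missing_cols}")
    Xg = grids.df[sorted(needed)]
    nan_mask = Xg.isna().any(axis=1).to_numpy()

    if model.gaussian is not None:
        p = model.binary.response_predict(grids.df)
        pos = model.smearing_factor * np.exp(model.gaussian.raw_predict(grids.df))
    else:
        p = np.ones(len(grids.df))
        pos = np.maximum(model.binary.response_predict(grids.df), 0.0)
    combined = p * pos
    p = np.where(nan_mask, np.nan, p)
    pos = np.where(nan_mask, np.nan, pos)
    combined = np.where(nan_mask, np.nan, combined)
    out = pd.DataFrame(
        {
            LAT: grids.df[LAT].to_numpy(),
            LON: grids.df[LON].to_numpy(),
            "p_occurrence": p,
            "positive_abundance": pos,
            "combined_index": combined,
        }
    )
    return PredictionSurface(df=out)


def persist(model: FittedDeltaModel, path) -> None:
    """Serialize a fitted model (schema-versioned) for later reloading."""
    joblib.dump({"schema_version": SCHEMA_VERSION, "model": model}, path)


def restore(path) -> FittedDeltaModel:
    """Load a model saved by :func:`persist`; predictions are bit-identical."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise FitError(f"cannot restore model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise FitError(f"{path} is not a deltaboost model file")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise FitError(
            f"model schema version {payload['schema_version']} is not supported "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    return payload["model"]
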