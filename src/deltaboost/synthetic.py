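"""Synthetic landscapes, hurdle surveys, and effort surfaces with known truth.

The generator emulates the structure of trawl-survey abundance data: a
smooth multivariate environmental landscape on a regular lattice, a
hurdle sampling process (logistic occurrence times log-normal positive
abundance with known covariate effects, excess zeros, and a long right
tail), and a fishing-effort surface with a controllable rank correlation
to true abundance.  Because the generative constants are recorded, the
true expected abundance of every cell is available in closed form:

    E[catch | cell] = logistic(eta_occ) * exp(eta_abn + sd^2 / 2)

which is what parameter-recovery tests compare fitted surfaces against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from scipy.stats import rankdata

from .core_data import LAT, LON, GridTable, SampleTable

# Default truth: 4 environmental fields, 2 carrying signal in both hurdle
# components and 2 pure noise; occurrence intercept set for ~50-60% zero
# catches; log-scale sd 0.7 gives the long right tail typical of CPUE data.
DEFAULT_EXPVARS = ["depth", "temp", "grainsize", "current"]
DEFAULT_OCC_COEF = {"depth": 1.0, "temp": -0.8, "grainsize": 0.0, "current": 0.0}
DEFAULT_ABN_COEF = {"depth": 0.7, "temp": -0.5, "grainsize": 0.0, "current": 0.0}
DEFAULT_OCC_INTERCEPT = -0.5
DEFAULT_ABN_INTERCEPT = 1.0
DEFAULT_LOG_SD = 0.7


@dataclass
class TruthModel:
    """Generative constants of a synthetic hurdle landscape."""

    expvars: list[str]
    occ_intercept: float
    occ_coef: dict[str, float]
    abn_intercept: float
    abn_coef: dict[str, float]
    log_sd: float
    seed: int
    trend_smoothness: float = 4.0

    @property
    def active_expvars(self) -> list[str]:
        """Variables with a nonzero coefficient in either component."""
        return [
            v
            for v in self.expvars
            if self.occ_coef.get(v, 0.0) != 0.0 or self.abn_coef.get(v, 0.0) != 0.0
        ]

    def eta_occ(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.occ_intercept)
        for v in self.expvars:
            eta += self.occ_coef.get(v, 0.0) * X[v].to_numpy(dtype=float)
        return eta

    def eta_abn(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.abn_intercept)
        for v in self.expvars:
            eta += self.abn_coef.get(v, 0.0) * X[v].to_numpy(dtype=float)
        return eta

    def p_occurrence(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.eta_occ(X))

    def expected_abundance(self, X: pd.DataFrame) -> np.ndarray:
        """Closed-form E[catch]: logistic(eta_occ) * exp(eta_abn + sd^2/2)."""
        return self.p_occurrence(X) * np.exp(self.eta_abn(X) + self.log_sd**2 / 2.0)


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float):
    noise = rng.standard_normal(shape)
    return gaussian_filter(noise, sigma=sigma, mode="nearest")


def gen_landscape(
    n_lon: int = 40,
    n_lat: int = 40,
    expvars: list[str] | None = None,
    seed: int = 1,
    noise_weight: float = 1.0,
    truth_kwargs: dict | None = None,
) -> tuple[GridTable, TruthModel]:
    """Generate a regular lattice of smooth, standardized environmental fields.

    Each field is a linear spatial trend plus Gaussian-smoothed white
    noise, standardized to mean 0 / sd 1 exactly.  ``noise_weight = 0``
    gives purely linear fields.  Deterministic given ``seed``.
    """
    if n_lon < 2 or n_lat < 2:
        raise ValueError("lattice must be at least 2x2")
    expvars = list(expvars or DEFAULT_EXPVARS)
    rng = np.random.default_rng(seed)
    lons = np.linspace(-5.0, -3.0, n_lon)
    lats = np.linspace(53.0, 55.0, n_lat)
    glon, glat = np.meshgrid(lons, lats)
    # normalized spatial coordinates in [-1, 1] for the trend part
    u = (glon - glon.mean()) / (np.ptp(glon) / 2)
    v = (glat - glat.mean()) / (np.ptp(glat) / 2)

    df = pd.DataFrame({LAT: glat.ravel(), LON: glon.ravel()})
    tk = dict(truth_kwargs or {})
    smooth = tk.pop("trend_smoothness", 4.0)
    fields: list[np.ndarray] = []
    for i, name in enumerate(expvars):
        a, b = rng.uniform(-1, 1, size=2)
        trend = a * u + b * v
        fld = trend + noise_weight * _smooth_field((n_lat, n_lon), rng, smooth)
        flat = fld.ravel()
        # decorrelate from earlier fields so "pure noise" covariates are
        # genuinely uninformative proxies, not collinear stand-ins; a
        # linear combination of smooth fields stays smooth
        flat = flat - flat.mean()
        resid = flat.copy()
        for prev in fields:
            resid = resid - (resid @ prev) / (prev @ prev) * prev
        # degenerate case (e.g. noiseless planar fields spanned by two
        # earlier trends): keep the raw field rather than a zero column
        if resid.std() > 1e-9 * max(flat.std(), 1.0):
            flat = resid
        flat = flat / flat.std()
        fields.append(flat)
        df[name] = flat

    defaults = dict(
        occ_intercept=DEFAULT_OCC_INTERCEPT,
        occ_coef={v: DEFAULT_OCC_COEF.get(v, 0.0) for v in expvars},
        abn_intercept=DEFAULT_ABN_INTERCEPT,
        abn_coef={v: DEFAULT_ABN_COEF.get(v, 0.0) for v in expvars},
        log_sd=DEFAULT_LOG_SD,
    )
    defaults.update(tk)
    truth = TruthModel(
        expvars=expvars, seed=seed, trend_smoothness=smooth, **defaults
    )
    return GridTable(df=df, expvars=expvars), truth


def gen_survey(
    grid: GridTable,
    truth: TruthModel,
    n_stations: int = 1000,
    seed: int = 1,
    resvar_name: str = "cpue",
    bias_var: str | None = None,
    bias_strength: float = 2.0,
) -> SampleTable:
    """Draw survey stations from the lattice and simulate hurdle catches.

    catch = Bernoulli(logistic(eta_occ)) * LogNormal(eta_abn, sd), sampled
    without replacement.  By default station placement is uniform; with
    ``bias_var`` set, cells with high values of that covariate are
    preferentially sampled (weights proportional to exp(strength * value)),
    which makes representativeness scores non-trivially positive.
    """
    if n_stations > len(grid):
        raise ValueError("cannot place more stations than grid cells")
    rng = np.random.default_rng(seed)
    if bias_var is None:
        idx = rng.choice(len(grid), size=n_stations, replace=False)
    else:
        w = np.exp(bias_strength * grid.df[bias_var].to_numpy(dtype=float))
        idx = rng.choice(len(grid), size=n_stations, replace=False, p=w / w.sum())
    cells = grid.df.iloc[idx].reset_index(drop=True)
    X = cells[truth.expvars]
    occ = rng.random(n_stations) < expit(truth.eta_occ(X))
    mag = np.exp(truth.eta_abn(X) + truth.log_sd * rng.standard_normal(n_stations))
    cells[resvar_name] = np.where(occ, mag, 0.0)
    return SampleTable(df=cells, expvars=list(truth.expvars), resvars=[resvar_name])


def gen_effort(
    grid: GridTable,
    truth: TruthModel,
    correlation: float = 0.0,
    seed: int = 1,
) -> np.ndarray:
    """Simulate a non-negative fishing-effort surface.

    ``correlation`` targets the Spearman rank correlation between effort
    and the true expected abundance, achieved by mixing the normal scores
    of the abundance field with independent Gaussian noise and
    exponentiating (so effort is >= 0 and right-skewed, like real effort).
    """
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    abn = truth.expected_abundance(grid.X())
    # normal scores of the abundance ranks: a Gaussian copula mix then
    # controls the rank correlation of the exponentiated field
    from scipy.stats import norm

    ns = norm.ppf(rankdata(abn) / (len(abn) + 1))
    eps = rng.standard_normal(len(abn))
    rho = float(correlation)
    latent = rho * ns + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
    return np.exp(latent)
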