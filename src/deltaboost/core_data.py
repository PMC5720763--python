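"""Tabular data model for survey samples and prediction grids.

Survey data arrive as two CSV tables: ``samples`` (stations where the
response, e.g. CPUE, was measured together with explanatory variables)
and ``grids`` (a regular lattice of cell centroids carrying the same
explanatory variables, where abundance is to be predicted).  This module
loads and validates both, detects zero inflation, splits a zero-inflated
response into its binary-occurrence and log-positive-abundance parts,
and computes minimum feasible bag fractions for boosted-tree fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LAT = "latitude"
LON = "longitude"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class SampleTable:
    """Survey stations: coordinates, explanatory variables, response(s).

    ``df`` holds canonical columns ``latitude``/``longitude`` (WGS84
    decimal degrees) plus the named explanatory and response variables.
    All response values must be non-negative (they are abundance indices).
    """

    df: pd.DataFrame
    expvars: list[str]
    resvars: list[str]

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValidationError("samples table must contain at least one row")
        if len(set(self.expvars)) != len(self.expvars):
            raise ValidationError("explanatory variable names must be unique")
        for col in (LAT, LON):
            if self.df[col].isna().any():
                raise ValidationError(f"missing values in required column {col!r}")
        for rv in self.resvars:
            bad = self.df.index[self.df[rv] < 0].tolist()
            if bad:
                raise ValidationError(
                    f"response variable {rv!r} has negative values in rows {bad}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def X(self, expvars: list[str] | None = None) -> pd.DataFrame:
        return self.df[list(expvars or self.expvars)]

    def y(self, resvar: str) -> np.ndarray:
        return self.df[resvar].to_numpy(dtype=float)


@dataclass
class GridTable:
    """Regular prediction lattice: cell centroids + explanatory variables."""

    df: pd.DataFrame
    expvars: list[str]

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValidationError("grids table must contain at least one row")
        dup = self.df.duplicated(subset=[LAT, LON])
        if dup.any():
            raise ValidationError(
                f"duplicate cell centroids at rows {self.df.index[dup].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def X(self, expvars: list[str] | None = None) -> pd.DataFrame:
        return self.df[list(expvars or self.expvars)]


@dataclass
class BrtConfig:
    """Hyperparameter search space and run options for the delta BRT.

    tc = tree complexity (interaction depth, splits per tree),
    lr = learning rate (shrinkage), bf = bag fraction (per-iteration
    training subsample proportion).  ``zi`` selects the hurdle path:
    True forces delta log-normal, False a single-family run, "auto"
    decides from the observed proportion of zeros.
    """

    tc_candidates: list[int] = field(default_factory=lambda: [2])
    lr_candidates: list[float] = field(default_factory=lambda: [0.01, 0.005])
    bf_candidates: list[float] = field(default_factory=lambda: [0.5])
    family_binary: str = "bernoulli"
    family_gaussian: str = "gaussian"
    zi: bool | str = "auto"
    zi_threshold: float = 0.5
    simplify: bool = True
    cv_folds: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.tc_candidates or not self.lr_candidates or not self.bf_candidates:
            raise ValidationError("candidate lists must be non-empty")
        if any(tc < 1 for tc in self.tc_candidates):
            raise ValidationError("all tree complexities must be >= 1")
        if any(lr <= 0 for lr in self.lr_candidates):
            raise ValidationError("all learning rates must be > 0")
        if any(not (0 < bf <= 1) for bf in self.bf_candidates):
            raise ValidationError("all bag fractions must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.zi not in (True, False, "auto"):
            raise ValidationError("zi must be True, False or 'auto'")


def _require_columns(df: pd.DataFrame, names: list[str], path: str) -> None:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_samples(
    path: str,
    resvar_names: list[str],
    expvar_names: list[str],
    lat_name: str = LAT,
    lon_name: str = LON,
) -> SampleTable:
    """Read a samples CSV and validate it.

    Rows with a missing value in any requested response variable are
    dropped (with a logged count); negative responses raise.
    """
    df = pd.read_csv(path)
    _require_columns(df, [lat_name, lon_name, *resvar_names, *expvar_names], str(path))
    df = df.rename(columns={lat_name: LAT, lon_name: LON})
    keep = [LAT, LON, *expvar_names, *resvar_names]
    df = df[keep]
    n0 = len(df)
    df = df.dropna(subset=resvar_names).reset_index(drop=True)
    if len(df) < n0:
        log.info("dropped %d row(s) with missing response values", n0 - len(df))
    return SampleTable(df=df, expvars=list(expvar_names), resvars=list(resvar_names))


def read_grids(
    path: str,
    expvar_names: list[str],
    lat_name: str = LAT,
    lon_name: str = LON,
) -> GridTable:
    """Read a prediction-grid CSV and validate it."""
    df = pd.read_csv(path)
    _require_columns(df, [lat_name, lon_name, *expvar_names], str(path))
    df = df.rename(columns={lat_name: LAT, lon_name: LON})
    return GridTable(df=df[[LAT, LON, *expvar_names]], expvars=list(expvar_names))


@dataclass
class MatchReport:
    """Outcome of comparing samples and grids explanatory variables."""

    ok: bool
    ranges_samples: dict[str, tuple[float, float]]
    ranges_grids: dict[str, tuple[float, float]]
    extrapolated: list[str]


def validate_match(
    samples: SampleTable, grids: GridTable, expvar_names: list[str] | None = None
) -> MatchReport:
    """Check that every explanatory variable exists in both tables.

    Grid ranges that extend beyond the sampled ranges are flagged as a
    non-fatal extrapolation warning in the report; a name missing from
    either table raises.
    """
    names = list(expvar_names or samples.expvars)
    miss_s = [n for n in names if n not in samples.df.columns]
    miss_g = [n for n in names if n not in grids.df.columns]
    if miss_s or miss_g:
        parts = []
        if miss_s:
            parts.append(f"missing from samples: {miss_s}")
        if miss_g:
            parts.append(f"missing from grids: {miss_g}")
        raise ValidationError("explanatory variable mismatch — " + "; ".join(parts))
    rs, rg, extrap = {}, {}, []
    for n in names:
        s = samples.df[n].astype(float)
        g = grids.df[n].astype(float)
        rs[n] = (float(s.min()), float(s.max()))
        rg[n] = (float(g.min()), float(g.max()))
        if rg[n][0] < rs[n][0] or rg[n][1] > rs[n][1]:
            extrap.append(n)
    if extrap:
        log.warning(
            "grid range extends beyond sampled range for %s (extrapolation)", extrap
        )
    return MatchReport(ok=True, ranges_samples=rs, ranges_grids=rg, extrapolated=extrap)


def check_zero_inflation(values, threshold: float = 0.5) -> bool:
    """True iff the proportion of exact zeros is >= ``threshold``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot assess zero inflation of an empty vector")
    if (v < 0).any():
        raise ValidationError("response values must be non-negative")
    return float(np.mean(v == 0)) >= threshold


def split_binary_gaussian(
    samples: SampleTable, resvar_name: str
) -> tuple[np.ndarray, SampleTable]:
    """Split a zero-inflated response into hurdle components.

    Returns the 0/1 occurrence vector over all rows, and a positive-only
    SampleTable in which the response column holds ln(resvar).
    """
    y = samples.y(resvar_name)
    binary = (y > 0).astype(int)
    if binary.sum() == 0:
        raise ValidationError(
            f"response {resvar_name!r} is all zeros: no positive component to model"
        )
    pos = samples.df[y > 0].copy().reset_index(drop=True)
    pos[resvar_name] = np.log(pos[resvar_name].to_numpy(dtype=float))
    pos_table = SampleTable.__new__(SampleTable)  # log response may be < 0 by design
    pos_table.df = pos
    pos_table.expvars = list(samples.expvars)
    pos_table.resvars = [resvar_name]
    return binary, pos_table


def min_bag_fraction(n: int, min_train_rows: int) -> float | None:
    """Smallest bag fraction (2-decimal grid) with floor(bf*n) >= min_train_rows.

    Returns None when even bf = 1 is infeasible.  Integer arithmetic is
    used so floor(k/100 * n) is exact.
    """
    if n < 1:
        return None
    for k in range(1, 101):
        if (k * n) // 100 >= min_train_rows:
            return k / 100.0
    return None


@dataclass
class BfCheckResult:
    bf_min_binary: float | None
    bf_min_gaussian: float | None
    n_binary: int
    n_gaussian: int

    @property
    def binary_feasible(self) -> bool:
        return self.bf_min_binary is not None

    @property
    def gaussian_feasible(self) -> bool:
        return self.bf_min_gaussian is not None


def bfcheck(
    samples: SampleTable, resvar_name: str, min_train_rows: int = 21
) -> BfCheckResult:
    """Minimum feasible bag fractions for the two hurdle components.

    The binary component trains on all rows; the gaussian component only
    on rows with a positive response.  Infeasibility (even bf = 1 leaves
    too few training rows) is reported, not raised — spotting it before
    a long run is the point of this check.
    """
    y = samples.y(resvar_name)
    n_bin = len(y)
    n_gau = int((y > 0).sum())
    return BfCheckResult(
        bf_min_binary=min_bag_fraction(n_bin, min_train_rows),
        bf_min_gaussian=min_bag_fraction(n_gau, min_train_rows),
        n_binary=n_bin,
        n_gaussian=n_gau,
    )
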