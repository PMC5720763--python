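"""Representativeness Surface Builder.

Scores every prediction-grid cell by how poorly the survey samples cover
the explanatory-variable space at that cell: per variable, the absolute
difference between the samples' and the grids' relative frequency in the
equal-width bin containing the cell's value, summed over variables.
High totals mark regions of environmental space where predictions rest
on thin sampling and should be read cautiously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import LAT, LON, GridTable, SampleTable, validate_match

log = logging.getLogger(__name__)

DEFAULT_BINS = 10


@dataclass
class BinComparison:
    edges: np.ndarray
    freq_samples: np.ndarray  # sums to 1
    freq_grids: np.ndarray  # sums to 1


def bin_frequencies(
    values_samples, values_grids, n_bins: int = DEFAULT_BINS
) -> BinComparison | None:
    """Relative frequencies of both vectors over equal-width bins.

    The grids define the universe: bins span the grids range, and sample
    values outside it clamp into the end bins.  A constant grids variable
    has no usable range; None is returned and the caller skips it.
    """
    s = np.asarray(values_samples, dtype=float)
    g = np.asarray(values_grids, dtype=float)
    if s.size == 0 or g.size == 0:
        raise ValueError("both value vectors must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(g.min()), float(g.max())
    if lo == hi:
        log.warning("constant grids variable (degenerate single bin): skipped")
        return None
    edges = np.linspace(lo, hi, n_bins + 1)
    fs = np.histogram(np.clip(s, lo, hi), bins=edges)[0] / s.size
    fg = np.histogram(np.clip(g, lo, hi), bins=edges)[0] / g.size
    return BinComparison(edges=edges, freq_samples=fs, freq_grids=fg)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # right-inclusive last bin, matching np.histogram's convention
    idx = np.searchsorted(edges, np.clip(values, edges[0], edges[-1]), side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


@dataclass
class RsbSurface:
    """Per-cell coverage scores: one column per variable plus the total."""

    df: pd.DataFrame  # latitude, longitude, score_<var>..., total
    variables: list[str]

    @property
    def total(self) -> np.ndarray:
        return self.df["total"].to_numpy()


def rsb_scores(
    samples: SampleTable,
    grids: GridTable,
    expvar_names: list[str] | None = None,
    n_bins: int = DEFAULT_BINS,
    signed: bool = False,
) -> RsbSurface:
    """Per-cell representativeness score for each variable and their sum.

    With ``signed=True`` the per-variable score keeps its sign
    (positive = cell's bin undersampled relative to the grid), useful for
    map interpretation; the default is the unsigned magnitude.
    """
    names = list(expvar_names or samples.expvars)
    validate_match(samples, grids, names)
    out = pd.DataFrame(
        {LAT: grids.df[LAT].to_numpy(), LON: grids.df[LON].to_numpy()}
    )
    used = []
    for var in names:
        comp = bin_frequencies(samples.df[var], grids.df[var], n_bins)
        if comp is None:
            continue
        idx = _bin_index(grids.df[var].to_numpy(dtype=float), comp.edges)
        diff = comp.freq_grids[idx] - comp.freq_samples[idx]
        out[f"score_{var}"] = diff if signed else np.abs(diff)
        used.append(var)
    out["total"] = out[[f"score_{v}" for v in used]].sum(axis=1) if used else 0.0
    return RsbSurface(df=out, variables=used)


def rsb_for_model(
    samples: SampleTable,
    grids: GridTable,
    binary_expvars: list[str],
    gaussian_expvars: list[str],
    n_bins: int = DEFAULT_BINS,
) -> dict[str, RsbSurface]:
    """The three surfaces reported for a delta model: the binary
    component's variable set, the gaussian's, and their union."""
    union = list(dict.fromkeys([*binary_expvars, *gaussian_expvars]))
    return {
        "binary": rsb_scores(samples, grids, binary_expvars, n_bins),
        "gaussian": rsb_scores(samples, grids, gaussian_expvars, n_bins),
        "combined": rsb_scores(samples, grids, union, n_bins),
    }
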