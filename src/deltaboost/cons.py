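"""Multi-subset conservation surfaces.

Simply summing predicted-abundance maps of several species (or life
history subsets) lets the abundant swamp the rare; here each subset is
first scaled to unit maximum so every subset contributes equally at its
own peak, then the scaled surfaces are combined as a weighted sum with
caller-chosen conservation-priority weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brt import PredictionSurface
from .core_data import LAT, LON


def scale_unit_max(values) -> np.ndarray:
    """Divide by the maximum so the surface peaks at exactly 1.

    An all-zero surface stays all-zero (with a warning) rather than
    dividing by zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot scale an empty surface")
    m = np.nanmax(v)
    if m <= 0:
        warnings.warn("all-zero surface: unit-max scaling left it at zero", stacklevel=2)
        return np.zeros_like(v)
    return v / m


def scale_unit_sum(values) -> np.ndarray:
    """Alternative scaling: values divided by their total."""
    v = np.asarray(values, dtype=float)
    s = np.nansum(v)
    if s <= 0:
        warnings.warn("all-zero surface: unit-sum scaling left it at zero", stacklevel=2)
        return np.zeros_like(v)
    return v / s


@dataclass
class ConservationSurface:
    df: pd.DataFrame  # latitude, longitude, <name>_scaled per subset, total
    subset_names: list[str]
    weights: list[float]


def combine_subsets(
    surfaces: list[PredictionSurface],
    weights: list[float] | None = None,
    names: list[str] | None = None,
    scaling: str = "unit_max",
) -> ConservationSurface:
    """Weighted sum of per-subset scaled combined-abundance surfaces.

    All surfaces must share the identical cell set; mismatched cells are
    reported.  Default weights are all 1.
    """
    if not surfaces:
        raise ValueError("need at least one surface")
    weights = list(weights if weights is not None else [1.0] * len(surfaces))
    if len(weights) != len(surfaces):
        raise ValueError("one weight per surface required")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    names = list(names or [f"subset{i + 1}" for i in range(len(surfaces))])
    scaler = {"unit_max": scale_unit_max, "unit_sum": scale_unit_sum}[scaling]

    ref = surfaces[0].df[[LAT, LON]].reset_index(drop=True)
    out = ref.copy()
    total = np.zeros(len(ref))
    for surf, w, name in zip(surfaces, weights, names):
        cells = surf.df[[LAT, LON]].reset_index(drop=True)
        if not cells.equals(ref):
            merged = ref.merge(cells, how="outer", indicator=True)
            bad = merged[merged["_merge"] != "both"][[LAT, LON]]
            raise ValueError(
                f"subset {name!r} is on a different cell set; "
                f"mismatched cells:\n{bad.to_string(index=False)}"
            )
        scaled = scaler(surf.df["combined_index"].to_numpy())
        out[f"{name}_scaled"] = scaled
        total = total + w * scaled
    out["total"] = total
    return ConservationSurface(df=out, subset_names=names, weights=weights)
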