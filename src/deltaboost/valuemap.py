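"""Escapement-biomass Marine Protected Area decision support.

Given per-cell predicted abundance for one or more species (the "good"
columns), a mapped stressor to avoid displacing (the "bad" column,
typically fishing effort), and optionally a conservation-priority
surface, the tool greedily accumulates cells — under one of four sorting
schemes — until each species' precautionary biomass target (Bpa) is
protected.  Closures cascade across species in at-risk order: biomass of
a later species already inside earlier species' closures is credited
before new cells are added, yielding one growing multi-species MPA with
per-cell attribution to the species whose pass added it.

The default Bpa target is (1 - HRMSY) x total predicted biomass, HRMSY
being the harvestable fraction of the stock per year at MSY; any other
target rule can be injected as a callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

SCHEMES = ("combination", "biomass", "effort", "conservation")


@dataclass
class DstInputs:
    """Per-cell inputs for the decision-support tool."""

    latitude: np.ndarray
    longitude: np.ndarray
    good: dict[str, np.ndarray]  # species name -> predicted abundance >= 0
    bad: np.ndarray  # stressor intensity >= 0
    conservation: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.latitude)
        arrays = [self.longitude, self.bad, *self.good.values()]
        if self.conservation is not None:
            arrays.append(self.conservation)
        if any(len(a) != n for a in arrays):
            raise ValueError("all per-cell columns must have the same length")
        for name, v in self.good.items():
            if (np.asarray(v) < 0).any():
                raise ValueError(f"negative abundance for species {name!r}")
        if (np.asarray(self.bad) < 0).any():
            raise ValueError("negative stressor values")
        if self.conservation is not None and (np.asarray(self.conservation) < 0).any():
            raise ValueError("negative conservation values")

    @property
    def n_cells(self) -> int:
        return len(self.latitude)

    @property
    def species(self) -> list[str]:
        return list(self.good)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        good_cols: Sequence[str],
        bad_col: str,
        conserve_col: str | None = None,
        lat_col: str = "latitude",
        lon_col: str = "longitude",
    ) -> "DstInputs":
        return cls(
            latitude=df[lat_col].to_numpy(dtype=float),
            longitude=df[lon_col].to_numpy(dtype=float),
            good={c: df[c].to_numpy(dtype=float) for c in good_cols},
            bad=df[bad_col].to_numpy(dtype=float),
            conservation=(
                df[conserve_col].to_numpy(dtype=float) if conserve_col else None
            ),
        )


def default_bpa(abundance: np.ndarray, hrmsy: float) -> float:
    """Escapement target: the (1 - HRMSY) fraction of total biomass that
    must remain protected."""
    return float((1.0 - hrmsy) * np.asarray(abundance, dtype=float).sum())


@dataclass
class ClosureSpec:
    """Which species, in what at-risk order, under which sorting scheme."""

    species_order: list[str]  # most at-risk first
    hrmsy: dict[str, float]
    scheme: str = "combination"
    importance_ratios: dict[str, float] | None = None
    bpa_rule: Callable[[np.ndarray, float], float] = default_bpa

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        missing = [s for s in self.species_order if s not in self.hrmsy]
        if missing:
            raise ValueError(f"HRMSY missing for species {missing}")
        for s, h in self.hrmsy.items():
            if not 0.0 < h < 1.0:
                raise ValueError(f"HRMSY for {s!r} must be in (0, 1)")
        if self.importance_ratios is not None:
            bad = [s for s, r in self.importance_ratios.items() if r <= 0]
            if bad:
                raise ValueError(f"importance ratios must be positive: {bad}")


def scale_importance(
    good: dict[str, np.ndarray], ratios: dict[str, float] | None = None
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Importance-weighted unit-max scaling.

    Each species' abundance is multiplied by its importance ratio, then
    divided by its own maximum, so every (nonzero) species' scaled vector
    peaks at 1 while the ratio sets its weight in any cross-species sum.
    Returns the scaled vectors and the effective weights.
    """
    ratios = dict(ratios or {s: 1.0 for s in good})
    missing = [s for s in good if s not in ratios]
    if missing:
        raise ValueError(f"importance ratio missing for species {missing}")
    scaled, weights = {}, {}
    import warnings

    for s, v in good.items():
        v = np.asarray(v, dtype=float)
        m = v.max() if v.size else 0.0
        if m <= 0:
            warnings.warn(f"species {s!r} has an all-zero surface", stacklevel=2)
            scaled[s] = np.zeros_like(v)
        else:
            scaled[s] = v / m
        weights[s] = float(ratios[s])
    return scaled, weights


def combined_metric(
    good_scaled: np.ndarray, bad: np.ndarray, aggregator: str = "mean"
) -> np.ndarray:
    """Site desirability for closure, in [0, 1].

    The stressor is unit-max scaled and reversed; the metric is the mean
    (default) or geometric mean of the scaled abundance and the reversed
    stressor.  Endpoints: max stressor with zero abundance scores 0;
    zero stressor with max abundance scores 1.
    """
    g = np.asarray(good_scaled, dtype=float)
    b = np.asarray(bad, dtype=float)
    bm = b.max()
    reversed_bad = 1.0 - (b / bm if bm > 0 else np.zeros_like(b))
    if aggregator == "geometric":
        return np.sqrt(g * reversed_bad)
    return (g + reversed_bad) / 2.0


def order_cells(inputs: DstInputs, species: str, scheme: str,
                scaled: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Greedy closure ordering of cell indices under a sorting scheme.

    combination: descending combined metric; biomass: descending species
    abundance; effort: ascending stressor (ties toward high abundance);
    conservation: descending conservation value.  All residual ties break
    by cell index, so the ordering is fully deterministic.
    """
    abundance = np.asarray(inputs.good[species], dtype=float)
    n = inputs.n_cells
    idx = np.arange(n)
    if scheme == "combination":
        g = scaled[species] if scaled is not None else scale_importance(inputs.good)[0][species]
        key = combined_metric(g, inputs.bad)
        order = np.lexsort((idx, -key))
    elif scheme == "biomass":
        order = np.lexsort((idx, -abundance))
    elif scheme == "effort":
        order = np.lexsort((idx, -abundance, inputs.bad))
    elif scheme == "conservation":
        if inputs.conservation is None:
            raise ValueError("conservation sort requires a conservation column")
        order = np.lexsort((idx, -np.asarray(inputs.conservation, dtype=float)))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return order


def build_closure(
    ordering: np.ndarray, abundance: np.ndarray, bpa_target: float
) -> list[int]:
    """Take cells in order until the cumulative abundance reaches the
    Bpa target; returns that minimal prefix as cell indices."""
    abundance = np.asarray(abundance, dtype=float)
    if bpa_target <= 0:
        return []
    total = abundance.sum()
    if bpa_target > total:
        raise ValueError(
            f"Bpa target {bpa_target:.6g} exceeds the maximum attainable "
            f"protected biomass {total:.6g}"
        )
    cum = 0.0
    members: list[int] = []
    for i in ordering:
        cum += abundance[i]
        members.append(int(i))
        if cum >= bpa_target:
            break
    return members


def effort_overlap(members, bad) -> float | None:
    """Percentage of the stressor total inside the closure; None when
    there is no stressor data to overlap."""
    b = np.asarray(bad, dtype=float)
    total = b.sum()
    if total <= 0:
        return None
    members = list(members)
    return float(100.0 * b[members].sum() / total) if members else 0.0


@dataclass
class SpeciesClosure:
    species: str
    members: list[int]  # cells newly added by this species' pass
    credited: float  # biomass already protected by earlier passes
    protected_biomass: float  # total inside the cumulative MPA
    bpa_target: float


@dataclass
class ClosurePlan:
    """Cascaded multi-species MPA: per-species stats plus per-cell
    attribution to the species whose pass first added the cell."""

    spec: ClosureSpec
    per_species: list[SpeciesClosure]
    attribution: np.ndarray  # per cell: species name or '' (object array)
    effort_overlap_cumulative: list[float | None]  # after each species' pass

    @property
    def member_union(self) -> np.ndarray:
        return np.nonzero(self.attribution != "")[0]

    def report(self) -> pd.DataFrame:
        rows = []
        for sc, ov in zip(self.per_species, self.effort_overlap_cumulative):
            rows.append(
                {
                    "species": sc.species,
                    "bpa_target": sc.bpa_target,
                    "credited_biomass": sc.credited,
                    "protected_biomass": sc.protected_biomass,
                    "cells_added": len(sc.members),
                    "effort_overlap_pct": ov,
                }
            )
        return pd.DataFrame(rows)

    def membership_frame(self, inputs: DstInputs) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "latitude": inputs.latitude,
                "longitude": inputs.longitude,
                "member": (self.attribution != "").astype(int),
                "adder_species": self.attribution,
            }
        )


def cascade_closures(inputs: DstInputs, spec: ClosureSpec) -> ClosurePlan:
    """Build the growing multi-species MPA.

    The most at-risk species' closure is built from scratch; each later
    species is first credited with its biomass inside the union of all
    earlier closures, then cells are added from its own ordering
    (skipping members) until its Bpa target is met.
    """
    scaled, _ = scale_importance(inputs.good, spec.importance_ratios)
    attribution = np.full(inputs.n_cells, "", dtype=object)
    in_mpa = np.zeros(inputs.n_cells, dtype=bool)
    per_species: list[SpeciesClosure] = []
    overlaps: list[float | None] = []

    for sp in spec.species_order:
        abundance = np.asarray(inputs.good[sp], dtype=float)
        target = spec.bpa_rule(abundance, spec.hrmsy[sp])
        credited = float(abundance[in_mpa].sum())
        remaining = target - credited
        added: list[int] = []
        if remaining > 0:
            ordering = order_cells(inputs, sp, spec.scheme, scaled)
            ordering = ordering[~in_mpa[ordering]]
            added = build_closure(ordering, abundance, remaining)
        for i in added:
            in_mpa[i] = True
            attribution[i] = sp
        per_species.append(
            SpeciesClosure(
                species=sp,
                members=added,
                credited=credited,
                protected_biomass=float(abundance[in_mpa].sum()),
                bpa_target=target,
            )
        )
        overlaps.append(effort_overlap(np.nonzero(in_mpa)[0], inputs.bad))
    return ClosurePlan(
        spec=spec,
        per_species=per_species,
        attribution=attribution,
        effort_overlap_cumulative=overlaps,
    )
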