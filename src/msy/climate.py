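"""Breeding-season temperatures and TSD/GSD outlier scoring.

Temperature-dependent sex determination (TSD) species breed where
incubation temperatures can act as a cue; genotypic (GSD) species are
unconstrained.  For each species, the statistic is the median of the
monthly gridded temperatures over its occupied cells, restricted to its
breeding months.  The two sex-determination classes give reference
distributions; a focal species is scored in SD units against a class,
and |z| >= 3 flags it as a thermal outlier for that class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesClimateRecord",
    "OutlierScore",
    "species_breeding_temperature",
    "class_distributions",
    "outlier_score",
    "OUTLIER_SD",
]

logger = logging.getLogger(__name__)

OUTLIER_SD = 3.0

GRID_COLUMNS = ["lat", "lon", "month", "temperature"]


@dataclass
class SpeciesClimateRecord:
    """One species' sex-determination system, phenology and range cells."""

    species: str
    system: str  # "TSD", "GSD", or "unknown" for focal species under test
    breeding_months: frozenset[int]
    cells: frozenset[tuple[float, float]]  # (lat, lon) grid cell centres
    temperature: float | None = None  # filled by species_breeding_temperature

    def __post_init__(self):
        if not self.breeding_months or not self.breeding_months <= set(range(1, 13)):
            raise ValueError(f"{self.species}: breeding months must be a non-empty subset of 1..12")
        if not self.cells:
            raise ValueError(f"{self.species}: species must occupy at least one cell")


@dataclass
class OutlierScore:
    species: str
    reference_class: str
    class_mean: float
    class_sd: float
    z: float
    is_outlier: bool


def species_breeding_temperature(grid: pd.DataFrame, record: SpeciesClimateRecord) -> float:
    """Median temperature over {occupied cell x breeding month}.

    The median of the flat multiset of cell-month values; for an even
    count, the mean of the central pair (numpy convention).  Cell-month
    combinations missing from the grid are excluded with a warning; if
    all are missing this is an error.
    """
    idx = grid.set_index(["lat", "lon", "month"])["temperature"]
    values = []
    n_missing = 0
    for lat, lon in sorted(record.cells):
        for month in sorted(record.breeding_months):
            try:
                v = idx.at[(lat, lon, month)]
            except KeyError:
                n_missing += 1
                continue
            if pd.isna(v):
                n_missing += 1
                continue
            values.append(float(v))
    if not values:
        raise ValueError(f"{record.species}: no grid values for any occupied cell-month")
    if n_missing:
        warnings.warn(f"{record.species}: {n_missing} cell-month values missing from grid")
    temp = float(np.median(values))
    record.temperature = temp
    return temp


def class_distributions(records: pd.DataFrame, statistic: str = "mean") -> pd.DataFrame:
    """Per-class summary of breeding-season temperatures.

    ``records`` needs columns ``system`` and ``temperature``.  Returns one
    row per class present with n, mean, sd (n-1 denominator), median, and
    a 1 degC histogram (bin edges at integers) for plotting parity.
    Classes with fewer than two species are reported without an SD.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    rows = []
    for system, grp in records.groupby("system"):
        temps = grp["temperature"].astype(float).to_numpy()
        lo = int(np.floor(temps.min()))
        hi = int(np.ceil(temps.max())) + 1
        counts, edges = np.histogram(temps, bins=np.arange(lo, hi + 1))
        rows.append(
            {
                "system": system,
                "n": len(temps),
                "mean": float(np.mean(temps)),
                "sd": float(np.std(temps, ddof=1)) if len(temps) > 1 else np.nan,
                "median": float(np.median(temps)),
                "hist_edges": edges.tolist(),
                "hist_counts": counts.tolist(),
            }
        )
    return pd.DataFrame(rows).set_index("system")


def outlier_score(
    species: str,
    temperature: float,
    reference_class: str,
    class_mean: float,
    class_sd: float,
    threshold: float = OUTLIER_SD,
) -> OutlierScore:
    """z-score of one species against a class distribution; |z| >= 3 flags."""
    if not np.isfinite(class_sd) or class_sd <= 0:
        raise ValueError("class SD must be positive")
    z = (temperature - class_mean) / class_sd
    return OutlierScore(
        species=species,
        reference_class=reference_class,
        class_mean=class_mean,
        class_sd=class_sd,
        z=float(z),
        # tolerance so a species sitting exactly on the threshold is not
        # unflagged by one ulp of floating-point round-off
        is_outlier=bool(abs(z) >= threshold - 1e-9),
    )
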