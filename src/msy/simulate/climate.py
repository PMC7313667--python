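"""Synthetic climate grid and species cohort with known thermal truth.

Emulates the study design around breeding-season temperatures: a monthly
gridded temperature surface, a cohort of TSD species breeding warm and
GSD species breeding cooler (two separated normal distributions), and a
focal species planted a fixed number of SDs below the TSD class.

The focal species is planted against the *realized* cohort moments (the
empirical mean and SD of the simulated TSD species' extracted
temperatures), so its true z-score equals the requested offset exactly,
up to the small median-extraction noise.  Truth temperatures are always
recomputed from the final grid, never copied from the targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..climate import SpeciesClimateRecord, species_breeding_temperature

__all__ = ["ClimateSimSpec", "simulate_climate", "records_from_frame"]


@dataclass(frozen=True)
class ClimateSimSpec:
    """Cohort sizes, class temperature distributions and grid geometry."""

    n_rows: int = 50
    n_cols: int = 60
    n_tsd: int = 101
    n_gsd: int = 99
    tsd_mean: float = 27.0
    tsd_sd: float = 4.0
    gsd_mean: float = 19.0
    gsd_sd: float = 5.0
    cell_sd: float = 0.3  # within-range spatial scatter, degC
    background_mean: float = 15.0
    background_sd: float = 8.0
    cells_per_species: tuple[int, int] = (4, 12)
    months_per_species: tuple[int, int] = (2, 5)
    focal_species: str = "focal_outlier"
    focal_offset_sd: float = -3.0
    seed: int = 0

    def __post_init__(self):
        if min(self.tsd_sd, self.gsd_sd, self.cell_sd, self.background_sd) <= 0:
            raise ValueError("all SDs must be positive")
        if self.n_tsd < 2 or self.n_gsd < 2:
            raise ValueError("need at least two species per class")
        n_species = self.n_tsd + self.n_gsd + 1
        if n_species * self.cells_per_species[1] > self.n_rows * self.n_cols:
            raise ValueError("grid too small for the requested cohort")


def _cell_coords(row: int, col: int) -> tuple[float, float]:
    return (-10.0 - 0.5 * row, 110.0 + 0.5 * col)


def simulate_climate(
    spec: ClimateSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Returns (grid, species table, truth table).

    grid: long-form (lat, lon, month, temperature) covering every cell
    and month.  species: name, system, breeding months, occupied cells.
    truth: per-species breeding-season temperature re-extracted from the
    final grid.
    """
    rng = np.random.default_rng(spec.seed)
    all_cells = [
        _cell_coords(r, c) for r in range(spec.n_rows) for c in range(spec.n_cols)
    ]
    order = rng.permutation(len(all_cells))

    systems = ["TSD"] * spec.n_tsd + ["GSD"] * spec.n_gsd
    names = [f"tsd_sp_{i:03d}" for i in range(spec.n_tsd)] + [
        f"gsd_sp_{i:03d}" for i in range(spec.n_gsd)
    ]

    # background surface: every cell-month filled
    temps = {
        (lat, lon, month): float(rng.normal(spec.background_mean, spec.background_sd))
        for lat, lon in all_cells
        for month in range(1, 13)
    }

    lo_c, hi_c = spec.cells_per_species
    lo_m, hi_m = spec.months_per_species
    cursor = 0
    species_rows = []

    def _assign(name: str, system: str, target: float | None) -> dict:
        nonlocal cursor
        n_cells = int(rng.integers(lo_c, hi_c + 1))
        cells = [all_cells[i] for i in order[cursor : cursor + n_cells]]
        cursor += n_cells
        n_months = int(rng.integers(lo_m, hi_m + 1))
        first = int(rng.integers(1, 13 - n_months + 1))
        months = list(range(first, first + n_months))
        if target is not None:
            for lat, lon in cells:
                for month in months:
                    temps[(lat, lon, month)] = float(rng.normal(target, spec.cell_sd))
        return {
            "species": name,
            "system": system,
            "breeding_months": ",".join(map(str, months)),
            "cells": ";".join(f"{lat}:{lon}" for lat, lon in cells),
        }

    for name, system in zip(names, systems):
        mean = spec.tsd_mean if system == "TSD" else spec.gsd_mean
        sd = spec.tsd_sd if system == "TSD" else spec.gsd_sd
        species_rows.append(_assign(name, system, float(rng.normal(mean, sd))))
    # reserve the focal species' cells/months before its target is known
    focal_row = _assign(spec.focal_species, "unknown", None)
    species_rows.append(focal_row)

    grid = pd.DataFrame(
        [(lat, lon, month, t) for (lat, lon, month), t in temps.items()],
        columns=["lat", "lon", "month", "temperature"],
    )
    species = pd.DataFrame(species_rows)

    # realized TSD moments from the grid as built so far
    records = records_from_frame(species)
    tsd_temps = np.array(
        [
            species_breeding_temperature(grid, rec)
            for rec in records
            if rec.system == "TSD"
        ]
    )
    focal_target = float(
        tsd_temps.mean() + spec.focal_offset_sd * tsd_temps.std(ddof=1)
    )
    # the focal species' temperature is the planted truth itself: written
    # without spatial scatter so its z-offset is exact by construction
    focal_rec = next(r for r in records if r.species == spec.focal_species)
    for lat, lon in sorted(focal_rec.cells):
        for month in sorted(focal_rec.breeding_months):
            temps[(lat, lon, month)] = focal_target
    grid = pd.DataFrame(
        [(lat, lon, month, t) for (lat, lon, month), t in temps.items()],
        columns=["lat", "lon", "month", "temperature"],
    )

    truth = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "system": [r.system for r in records],
            "true_temperature": [
                species_breeding_temperature(grid, r) for r in records
            ],
        }
    )
    return grid, species, truth


def records_from_frame(species: pd.DataFrame) -> list[SpeciesClimateRecord]:
    """Parse the species table back into record objects."""
    records = []
    for _, row in species.iterrows():
        months = frozenset(int(m) for m in str(row["breeding_months"]).split(","))
        cells = frozenset(
            (float(c.split(":")[0]), float(c.split(":")[1]))
            for c in str(row["cells"]).split(";")
        )
        records.append(
            SpeciesClimateRecord(
                species=row["species"],
                system=row["system"],
                breeding_months=months,
                cells=cells,
            )
        )
    return records
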