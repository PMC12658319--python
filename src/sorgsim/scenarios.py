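"""Prescriptive scenario analyses on a calibrated genotype.

Two what-if studies: a stand-density sweep (which planting density
maximizes areal shoot biomass under the same weather and soil moisture?)
and a planting/harvest-date grid (how much yield do earlier or later season
boundaries buy?).  Yield is harvest-day shoot (leaf + stem) dry biomass;
areal yield converts per-plant grams to kg/m2 via the stand count.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import CoverageError, prepare_season, simulate_prepared
from .params import GenotypeParameterVector
from .weather import ManagementRecord, WeatherSeries

__all__ = ["ScenarioResult", "density_sweep", "date_grid"]


@dataclass
class ScenarioResult:
    """Scenario outputs: one row per scenario point, plus the argmax row."""

    table: pd.DataFrame
    argmax: pd.Series
    matrix: Optional[pd.DataFrame] = None  # date grids only

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _final_biomass(genotype, inputs, is_ps):
    trace = simulate_prepared(genotype, inputs, is_ps=is_ps, record=True)
    last = trace.data.iloc[-1]
    return float(last["leaf_weight"]), float(last["stem_weight"])


def density_sweep(
    genotype: GenotypeParameterVector,
    weather: WeatherSeries,
    mgmt: ManagementRecord,
    densities: Sequence[float],
    is_ps: bool = True,
) -> ScenarioResult:
    """Simulate the season across stand densities (plants/m2).

    Weather, soil moisture and season dates are held fixed; only the stand
    count changes.  Areal yield is ``density * per-plant shoot / 1000``
    kg/m2 at harvest.
    """
    densities = list(densities)
    if not densities:
        raise ValueError("density list must not be empty")
    if any(d <= 0 for d in densities):
        raise ValueError("densities must be positive")
    base_inputs = prepare_season(weather, mgmt)
    rows = []
    for density in densities:
        inputs = base_inputs.with_management(
            dataclasses.replace(mgmt, stand_count=float(density)))
        leaf, stem = _final_biomass(genotype, inputs, is_ps)
        shoot = leaf + stem
        rows.append({
            "stand_count": float(density),
            "leaf_per_plant": leaf,
            "stem_per_plant": stem,
            "shoot_per_plant": shoot,
            "areal_yield_kg_m2": shoot * density / 1000.0,
        })
    table = pd.DataFrame(rows)
    argmax = table.loc[table["areal_yield_kg_m2"].idxmax()]
    return ScenarioResult(table=table, argmax=argmax)


def date_grid(
    genotype: GenotypeParameterVector,
    weather: WeatherSeries,
    mgmt: ManagementRecord,
    planting_offsets: Sequence[int],
    harvest_offsets: Sequence[int],
    is_ps: bool = True,
) -> ScenarioResult:
    """Simulate a grid of planting-date x harvest-date shifts (days).

    Offsets shift the management dates; the (0, 0) cell reproduces the
    unshifted simulation exactly.  Raises :class:`CoverageError` naming the
    offending cell if a shifted season leaves the weather coverage.
    """
    planting_offsets = [int(o) for o in planting_offsets]
    harvest_offsets = [int(o) for o in harvest_offsets]
    if not planting_offsets or not harvest_offsets:
        raise ValueError("offset lists must not be empty")
    rows = []
    for dp in planting_offsets:
        for dh in harvest_offsets:
            shifted = dataclasses.replace(
                mgmt,
                planting_date=mgmt.planting_date + dt.timedelta(days=dp),
                harvest_date=mgmt.harvest_date + dt.timedelta(days=dh),
            )
            try:
                inputs = prepare_season(weather, shifted)
            except CoverageError as exc:
                raise CoverageError(
                    f"cell (planting {dp:+d}, harvest {dh:+d}): {exc}"
                ) from exc
            leaf, stem = _final_biomass(genotype, inputs, is_ps)
            shoot = leaf + stem
            rows.append({
                "planting_offset": dp,
                "harvest_offset": dh,
                "leaf_per_plant": leaf,
                "stem_per_plant": stem,
                "shoot_per_plant": shoot,
                "areal_yield_kg_m2": shoot * mgmt.stand_count / 1000.0,
            })
    table = pd.DataFrame(rows)
    argmax = table.loc[table["areal_yield_kg_m2"].idxmax()]
    matrix = table.pivot(index="planting_offset", columns="harvest_offset",
                         values="areal_yield_kg_m2")
    return ScenarioResult(table=table, argmax=argmax, matrix=matrix)
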