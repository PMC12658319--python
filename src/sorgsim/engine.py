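"""Season orchestration: hourly phenology, daily physiology, full traces.

One simulated season walks every calendar day from planting to harvest in a
fixed order of operations — phenology (hourly GDU/GPU, daylength, stage),
stress, light interception and photosynthesis, transpiration, water balance,
maintenance and senescence, growth allocation, tillering — and emits a
per-day :class:`SimulationTrace`.  The engine is deterministic: identical
inputs produce bitwise-identical traces.

Hourly weather enters the phenology accumulators directly; all other
processes are driven by daily aggregates (mean/extreme temperature, total
radiation, mean humidity and wind, summed evapotranspiration, root-zone soil
temperature and moisture).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import plant as pm
from .params import GenotypeParameterVector
from .phenology import (PhenologyParams, PhenologyState, Stage,
                        advance_phenology, daylength)
from .weather import ManagementRecord, WeatherSeries

__all__ = [
    "SeasonInputs", "SimulationTrace", "prepare_season",
    "simulate_season", "simulate_prepared", "predict_biomass_at",
]

_W_TO_MJ = 3600.0 / 1e6  # W/m2 over one hour -> MJ/m2


class CoverageError(ValueError):
    """Weather does not span the requested season."""


@dataclass(frozen=True)
class SeasonInputs:
    """Weather pre-aggregated for one season; reusable across genotypes."""

    mgmt: ManagementRecord
    latitude: float
    dates: Tuple[dt.date, ...]
    temp_hourly: np.ndarray      # (n_days, 24) degC
    rad_hourly: np.ndarray       # (n_days, 24) W/m2
    t_mean: np.ndarray
    t_min: np.ndarray
    t_max: np.ndarray
    rad_mj: np.ndarray           # MJ/m2/day
    rh_mean: np.ndarray
    wind_mean: np.ndarray
    et_day: np.ndarray           # mm/day
    root_temp: np.ndarray
    soil_vwc: np.ndarray
    daylength_h: np.ndarray

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def with_management(self, mgmt: ManagementRecord) -> "SeasonInputs":
        """Same weather, different stand density (dates must match)."""
        if (mgmt.planting_date != self.mgmt.planting_date
                or mgmt.harvest_date != self.mgmt.harvest_date):
            raise ValueError("with_management cannot change season dates")
        return dataclasses.replace(self, mgmt=mgmt)


def prepare_season(weather: WeatherSeries,
                   mgmt: ManagementRecord) -> SeasonInputs:
    """Validate coverage/completeness and aggregate weather for one season."""
    if not weather.covers(mgmt):
        raise CoverageError(
            f"weather [{weather.data.index[0]} .. {weather.data.index[-1]}] "
            f"does not cover season [{mgmt.planting_date} .. {mgmt.harvest_date}]"
        )
    season = weather.slice_days(mgmt.planting_date, mgmt.harvest_date)
    df = season.data
    if df.isna().any().any():
        raise ValueError(
            "weather has missing values inside the season; "
            "run impute_missing_knn first"
        )
    n_days = mgmt.season_days + 1
    if len(df) != n_days * 24:
        raise CoverageError(
            f"expected {n_days * 24} hourly rows in season, got {len(df)}"
        )
    temp = df["air_temp"].to_numpy().reshape(n_days, 24)
    rad = df["solar_radiation"].to_numpy().reshape(n_days, 24)
    rh = df["rel_humidity"].to_numpy().reshape(n_days, 24)
    wind = df["wind_speed"].to_numpy().reshape(n_days, 24)
    et = df["evapotranspiration"].to_numpy().reshape(n_days, 24)
    root_t = 0.5 * (df["soil_temp_4in"] + df["soil_temp_12in"]
                    ).to_numpy().reshape(n_days, 24)
    vwc = 0.5 * (df["soil_vwc_12in"] + df["soil_vwc_24in"]
                 ).to_numpy().reshape(n_days, 24)
    dates = tuple(mgmt.planting_date + dt.timedelta(days=int(d))
                  for d in range(n_days))
    dl = np.array([daylength(weather.latitude, d.timetuple().tm_yday)
                   for d in dates])
    return SeasonInputs(
        mgmt=mgmt,
        latitude=weather.latitude,
        dates=dates,
        temp_hourly=temp,
        rad_hourly=rad,
        t_mean=temp.mean(axis=1),
        t_min=temp.min(axis=1),
        t_max=temp.max(axis=1),
        rad_mj=rad.sum(axis=1) * _W_TO_MJ,
        rh_mean=rh.mean(axis=1),
        wind_mean=wind.mean(axis=1),
        et_day=et.sum(axis=1),
        root_temp=root_t.mean(axis=1),
        soil_vwc=np.clip(vwc.mean(axis=1), 0.0, 1.0),
        daylength_h=dl,
    )


@dataclass
class SimulationTrace:
    """Per-day simulated state for one (genotype, season) run.

    Reported leaf/stem/root/grain weights aggregate the main culm and all
    tillers; ``stem_height`` is the main culm's, ``root_length`` the
    whole-plant total.
    """

    data: pd.DataFrame
    mgmt: ManagementRecord

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def final_shoot_biomass(self) -> float:
        """Harvest-day leaf + stem dry biomass, g/plant."""
        last = self.data.iloc[-1]
        return float(last["leaf_weight"] + last["stem_weight"])


def _day_units(g: Dict[str, float], inputs: SeasonInputs,
               is_ps: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized daily GDU and (photoperiod-gated) GPU sums."""
    base, opt, mx = g["base_temp"], g["opt_temp"], g["max_temp"]
    temp = inputs.temp_hourly
    gdu = np.clip(np.minimum(temp, mx) - base, 0.0, None).sum(axis=1) / 24.0
    up = (temp - base) / (opt - base)
    down = (mx - temp) / (mx - opt)
    t_hat = np.clip(np.minimum(up, down), 0.0, 1.0)
    r_hat = np.clip(inputs.rad_hourly / g["rad_norm"], 0.0, 1.0)
    gpu = (t_hat * r_hat).sum(axis=1) / 24.0
    if is_ps:
        gpu = gpu * (inputs.daylength_h < g["critical_daylength"])
    return gdu, gpu


def simulate_prepared(
    genotype: GenotypeParameterVector,
    inputs: SeasonInputs,
    is_ps: bool = True,
    sample_days: Optional[Sequence[int]] = None,
    record: bool = True,
):
    """Run one season on pre-aggregated inputs.

    With ``record=True`` returns a full :class:`SimulationTrace`; otherwise
    returns an ``(len(sample_days), 2)`` array of (leaf, stem) g/plant at the
    requested days after planting — the fast path used in calibration.
    """
    g = genotype.values
    phen_params = PhenologyParams.from_genotype(genotype)
    phys = pm.PhysiologyParams.from_genotype(genotype, is_ps=is_ps)
    mgmt = inputs.mgmt
    stand = mgmt.stand_count
    day_gdu, day_gpu = _day_units(g, inputs, is_ps)

    state = pm.initial_plant_state(phys)
    phen = PhenologyState()
    seed_reserve = phys.seed_reserve
    state.reserve_carbon = seed_reserve
    water_deficit = 0.0

    sample_lookup = None
    out = None
    if sample_days is not None:
        sample_lookup = {int(d): i for i, d in enumerate(sample_days)}
        bad = [d for d in sample_lookup if d < 0 or d >= inputs.n_days]
        if bad:
            raise ValueError(f"sample days outside the season: {bad}")
        out = np.zeros((len(sample_days), 2))
    rows: List[tuple] = []

    for d in range(inputs.n_days):
        date = inputs.dates[d]
        phen = advance_phenology(
            phen, day_gdu[d], day_gpu[d], inputs.daylength_h[d],
            is_ps, date, mgmt, phen_params,
        )
        stage = phen.stage
        growing = stage in (Stage.VEGETATIVE, Stage.BLOOM_GRAINFILL)

        stress = pm.compute_stress(
            inputs.t_min[d], inputs.t_max[d], inputs.root_temp[d],
            water_deficit, phys,
        )

        if growing:
            intercepted = pm.radiation_interception(
                state.leaf_weight, stand, inputs.rad_mj[d], phys)
            uptake_potential = min(
                phys.water_uptake_coeff * state.root_length
                * inputs.soil_vwc[d]
                / (1.0 + phys.competition_coeff * stand),
                phys.xylem_transport_cap,
            )
            water_supply = state.xylem_water + uptake_potential
            assimilate = pm.daily_photosynthesis(
                state, intercepted, stress, water_supply, phys)
            demand = pm.transpiration_demand(
                inputs.t_mean[d], inputs.rh_mean[d], inputs.wind_mean[d],
                inputs.et_day[d], state.leaf_weight, phys)
        else:
            assimilate = 0.0
            demand = 0.0

        state, water_deficit = pm.water_balance_step(
            state, inputs.soil_vwc[d], demand, stand, phys)

        maintenance, senescence = pm.maintenance_cost(state, stress, phys)

        # the labile seed reserve buffers maintenance deficits until spent
        if seed_reserve > 0.0:
            draw = min(seed_reserve, max(0.0, maintenance - assimilate))
            maintenance -= draw
            seed_reserve -= draw

        state = pm.allocate_growth(
            state, assimilate, maintenance, senescence, stage, stress, phys)
        if not growing:
            state.reserve_carbon = seed_reserve

        state = pm.tiller_update(state, stage, phys,
                                 cumulative_gdu=phen.cumulative_gdu, day=d)

        if sample_lookup is not None and d in sample_lookup:
            out[sample_lookup[d]] = (state.leaf_weight, state.stem_weight)
        if record:
            diag = state.diag
            rows.append((
                date, d, stage.name, phen.cumulative_gdu,
                phen.cumulative_gpu, state.leaf_weight, state.stem_weight,
                state.root_weight, state.grain_weight, state.stem_height,
                state.root_length, state.tiller_count, state.xylem_water,
                water_deficit, stress.air_heat, stress.air_cold,
                stress.root, stress.water, assimilate, maintenance,
                diag.get("senesced", 0.0), diag.get("net_carbon", 0.0),
                diag.get("structural_gain", 0.0),
                diag.get("remobilized", 0.0),
                diag.get("remobilization_floored", 0.0),
                state.total_weight(),
            ))

    if not record:
        return out
    df = pd.DataFrame(rows, columns=[
        "date", "day_after_planting", "stage", "cumulative_gdu",
        "cumulative_gpu", "leaf_weight", "stem_weight", "root_weight",
        "grain_weight", "stem_height", "root_length", "tiller_count",
        "xylem_water", "water_deficit", "stress_air_heat",
        "stress_air_cold", "stress_root", "stress_water",
        "daily_assimilate", "daily_maintenance", "daily_senescence",
        "net_carbon", "structural_gain", "remobilized",
        "remobilization_floored", "total_weight",
    ])
    trace = SimulationTrace(df, mgmt)
    if sample_lookup is not None:
        return trace, out
    return trace


def simulate_season(
    genotype: GenotypeParameterVector,
    weather: WeatherSeries,
    mgmt: ManagementRecord,
    is_ps: bool = True,
) -> SimulationTrace:
    """Simulate one growing season from raw (fully imputed) weather."""
    inputs = prepare_season(weather, mgmt)
    return simulate_prepared(genotype, inputs, is_ps=is_ps, record=True)


def predict_biomass_at(
    trace: SimulationTrace,
    days: Sequence[int],
) -> List[Tuple[int, float, float]]:
    """Aggregated (day, leaf, stem) biomass at given days after planting."""
    df = trace.data.set_index("day_after_planting")
    result = []
    for day in days:
        if int(day) not in df.index:
            raise ValueError(f"day {day} outside the simulated season")
        row = df.loc[int(day)]
        result.append((int(day), float(row["leaf_weight"]),
                       float(row["stem_weight"])))
    return result
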