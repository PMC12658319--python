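"""Synthetic weather, genotypes and field trials for the Boone, IA design.

The generator emulates the statistical structure of a two-year biomass
sorghum trial at Boone (42 N): a photoperiod-sensitive panel grown in a
randomized complete block design with two replications, destructively
sampled at eleven scheduled days after planting, at stand counts drawn from
N(14.56, 3.83^2) plants/m2 truncated positive.  Hourly weather is built from
seasonal and diurnal sinusoids with autocorrelated anomalies and a
solar-geometry radiation term; scripted anomalies (a cold October, heavy
rain after planting, an arbitrary cold snap) are opt-in so tests can isolate
mechanisms.  Observation noise is multiplicative lognormal with a
configurable coefficient of variation.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import prepare_season, simulate_prepared
from .params import (PARAMETER_REGISTRY, GenotypeParameterVector,
                     registry_names)
from .weather import (WEATHER_FIELDS, ManagementRecord, TrialObservation,
                      WeatherSeries)

#: Planting / harvest dates of the two trial years (month, day).
SEASON_DATES: Dict[int, Tuple[Tuple[int, int], Tuple[int, int]]] = {
    2021: ((5, 27), (10, 17)),
    2022: ((5, 30), (10, 26)),
}
_DEFAULT_DATES = ((5, 30), (10, 20))

BOONE_LATITUDE = 42.0


def management_for_year(year: int, stand_count: float,
                        row_spacing: float = 70.0) -> ManagementRecord:
    """Planting/harvest dates of the trial year with a given stand count."""
    (pm_, pd_), (hm, hd) = SEASON_DATES.get(year, _DEFAULT_DATES)
    return ManagementRecord(
        planting_date=dt.date(year, pm_, pd_),
        harvest_date=dt.date(year, hm, hd),
        stand_count=stand_count,
        row_spacing=row_spacing,
    )


@dataclass(frozen=True)
class TrialDesign:
    """Shape and noise of a synthetic multi-genotype field trial."""

    n_genotypes: int = 265
    n_blocks: int = 2
    years: Tuple[int, ...] = (2021, 2022)
    sampling_days: Tuple[int, ...] = (22, 36, 43, 50, 57, 64, 71, 78, 85,
                                      110, 145)
    stand_count_mean: float = 14.56
    stand_count_sd: float = 3.83
    obs_noise_cv: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if list(self.sampling_days) != sorted(set(self.sampling_days)):
            raise ValueError("sampling_days must be strictly increasing")
        if self.n_genotypes < 1 or self.n_blocks < 1:
            raise ValueError("design must have at least one genotype/block")


# ---------------------------------------------------------------------------
# weather generation
# ---------------------------------------------------------------------------

#: Seasonal air-temperature sinusoid for Boone, IA: mean, amplitude, peak DOY.
SEASONAL_TEMP = (8.7, 14.9, 201.0)
_AR_PHI = 0.75          # day-to-day anomaly persistence
_AR_SD = 2.0            # stationary anomaly std dev, degC
_DIURNAL_AMP = 5.5      # half-range of the diurnal cycle, degC


def seasonal_mean_temp(day_of_year) -> np.ndarray:
    """The generating seasonal sinusoid (degC) at a day of year."""
    mean, amp, peak = SEASONAL_TEMP
    return mean + amp * np.cos(2 * np.pi * (np.asarray(day_of_year, float)
                                            - peak) / 365.25)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    innov = rng.normal(0.0, sd * math.sqrt(1 - phi * phi), n)
    out = np.empty(n)
    prev = rng.normal(0.0, sd)
    for i in range(n):
        prev = phi * prev + innov[i]
        out[i] = prev
    return out


def generate_weather(
    year: int,
    latitude: float = BOONE_LATITUDE,
    seed: int = 0,
    missing_rate: float = 0.0,
    anomalies: Mapping[str, object] = (),
    start: Optional[dt.date] = None,
    end: Optional[dt.date] = None,
    station_id: Optional[str] = None,
) -> WeatherSeries:
    """Generate one season's hourly weather (default Apr 1 - Dec 15).

    ``anomalies`` may contain:

    * ``"cold_october": True`` — a sustained cold spell through October,
      mimicking the observed 2022 late-season anomaly;
    * ``"heavy_rain_after_planting": True`` — a large early-June rain event;
    * ``"cold_snap": (start_date, end_date, delta_degC)`` — an arbitrary
      scripted temperature offset window (delta is added, so pass negative).
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    anomalies = dict(anomalies)
    rng = np.random.default_rng(seed)
    start = start or dt.date(year, 4, 1)
    end = end or dt.date(year, 12, 15)
    idx = pd.date_range(dt.datetime.combine(start, dt.time(0)),
                        dt.datetime.combine(end, dt.time(23)), freq="h")
    n = len(idx)
    doy = idx.dayofyear.to_numpy().astype(float)
    hour = idx.hour.to_numpy().astype(float)
    n_days = n // 24

    # air temperature: seasonal + diurnal + AR(1) daily anomaly + jitter
    t_season = seasonal_mean_temp(doy)
    t_diurnal = -_DIURNAL_AMP * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    daily_anom = np.repeat(_ar1(rng, n_days + 1, _AR_PHI, _AR_SD), 24)[:n]
    air_temp = t_season + t_diurnal + daily_anom + rng.normal(0, 0.4, n)

    offset = np.zeros(n)
    if anomalies.get("cold_october"):
        in_oct = (doy >= 274) & (doy <= 309)  # Oct 1 - Nov 5
        offset[in_oct] -= 7.0
    snap = anomalies.get("cold_snap")
    if snap:
        s, e, delta = snap
        mask = (idx >= pd.Timestamp(s)) & (idx < pd.Timestamp(e) + pd.Timedelta(days=1))
        offset[np.asarray(mask)] += float(delta)
    air_temp = air_temp + offset

    # solar radiation from clear-sky geometry x autocorrelated cloudiness
    decl = np.radians(-23.44) * np.cos(2 * np.pi * (doy + 10) / 365.25)
    phi_r = math.radians(latitude)
    hour_angle = np.radians((hour + 0.5 - 12.0) * 15.0)
    sin_elev = (math.sin(phi_r) * np.sin(decl)
                + math.cos(phi_r) * np.cos(decl) * np.cos(hour_angle))
    clear = 1000.0 * np.clip(sin_elev, 0.0, None) * 0.78
    cloud_daily = np.clip(0.78 + _ar1(rng, n_days + 1, 0.5, 0.18), 0.25, 1.0)
    cloud = np.repeat(cloud_daily, 24)[:n]
    solar = clear * cloud

    # precipitation: wetter days are cloudier
    rain_day = rng.random(n_days + 1) < 0.25
    rain_amount = rng.exponential(7.0, n_days + 1) * rain_day
    precip = np.zeros(n)
    for d in np.flatnonzero(rain_day[:n_days]):
        hrs = rng.integers(0, 24, size=3)
        for h in hrs:
            precip[d * 24 + int(h)] += rain_amount[d] / 3.0
    if anomalies.get("heavy_rain_after_planting"):
        target = dt.date(year, 6, 2)
        d0 = (target - start).days
        if 0 <= d0 < n_days:
            precip[d0 * 24 + 12: d0 * 24 + 18] += 12.0

    # relative humidity: anti-phase with the diurnal cycle, high on rain days
    rh = (74.0 - 2.2 * t_diurnal + 12.0 * np.repeat(rain_day, 24)[:n]
          + rng.normal(0, 5.0, n))
    rh = np.clip(rh, 15.0, 100.0)

    wind = np.clip(3.2 + _ar1(rng, n, 0.9, 1.6), 0.0, 30.0)
    et = np.clip(0.00085 * solar + 0.002 * np.clip(air_temp - 5, 0, None)
                 * (1 - rh / 100.0), 0.0, None)

    # soil temperature: depth-lagged smoothing of daily air temperature
    daily_temp = air_temp[: n_days * 24].reshape(n_days, 24).mean(axis=1)
    soil = {}
    for name, window, damp in (("soil_temp_4in", 2, 0.95),
                               ("soil_temp_12in", 5, 0.85),
                               ("soil_temp_24in", 10, 0.7),
                               ("soil_temp_50in", 25, 0.5)):
        sm = pd.Series(daily_temp).rolling(window, min_periods=1).mean()
        sm = SEASONAL_TEMP[0] + damp * (sm - SEASONAL_TEMP[0])
        soil[name] = np.repeat(sm.to_numpy(), 24)[:n]

    # soil moisture: slow drawdown with rain recharge, clipped physical
    vwc = np.empty(n_days)
    level = 0.33
    for d in range(n_days):
        level = np.clip(level * 0.995 + rain_amount[d] * 0.0035
                        - 0.0006, 0.08, 0.42)
        vwc[d] = level
    vwc_h = np.repeat(vwc, 24)[:n]

    df = pd.DataFrame({
        "air_temp": air_temp,
        "rel_humidity": rh,
        "solar_radiation": solar,
        "precipitation": precip,
        "wind_speed": wind,
        "evapotranspiration": et,
        "soil_temp_4in": soil["soil_temp_4in"],
        "soil_temp_12in": soil["soil_temp_12in"],
        "soil_temp_24in": soil["soil_temp_24in"],
        "soil_temp_50in": soil["soil_temp_50in"],
        "soil_vwc_12in": vwc_h,
        "soil_vwc_24in": np.clip(vwc_h + 0.01, 0.0, 1.0),
        "soil_vwc_50in": np.clip(vwc_h + 0.02, 0.0, 1.0),
    }, index=idx)

    if missing_rate > 0.0:
        mask = rng.random(df.shape) < missing_rate
        vals = df.to_numpy()
        vals[mask] = np.nan
        df = pd.DataFrame(vals, index=idx, columns=df.columns)

    return WeatherSeries(df, station_id=station_id or f"SYN-BOONE-{year}",
                         latitude=latitude)


# ---------------------------------------------------------------------------
# genotype sampling
# ---------------------------------------------------------------------------

def sample_genotype(seed: int, spread: float = 1.0) -> GenotypeParameterVector:
    """Draw a genotype uniformly within the registry bounds.

    ``spread`` shrinks the sampling box symmetrically about the bound
    midpoints (1.0 = the full expert bounds); useful for generating
    realistic central genotypes in recovery experiments.
    """
    if not (0.0 < spread <= 1.0):
        raise ValueError("spread must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    values = {}
    for s in PARAMETER_REGISTRY:
        half = 0.5 * (s.upper - s.lower) * spread
        mid = 0.5 * (s.upper + s.lower)
        values[s.name] = rng.uniform(mid - half, mid + half)
    return GenotypeParameterVector(values=values, provenance="sampled")


def sample_genotypes(n: int, seed: int = 0,
                     spread: float = 1.0) -> List[GenotypeParameterVector]:
    """Draw ``n`` genotypes from independent substreams of ``seed``."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [sample_genotype(int(c.generate_state(1)[0] % (2 ** 31)),
                            spread=spread) for c in children]


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

@dataclass
class TrialGroundTruth:
    """Generating parameters and noise-free trajectories for recovery tests."""

    genotypes: Dict[str, GenotypeParameterVector]
    design: TrialDesign
    true_biomass: Dict[Tuple[str, int, int], np.ndarray] = field(
        default_factory=dict)  # (genotype, year, block) -> (days, 2)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = 0.5) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    raise RuntimeError("truncated normal sampling failed")  # pragma: no cover


def generate_trial(
    design: TrialDesign,
    genotypes: Sequence[GenotypeParameterVector],
    weather_by_year: Mapping[int, WeatherSeries],
    is_ps: bool = True,
) -> Tuple[List[TrialObservation], TrialGroundTruth]:
    """Simulate a full multi-genotype trial with observation noise.

    For every genotype x year x block, a stand count is drawn from the
    truncated normal N(stand_count_mean, stand_count_sd^2), the season is
    simulated, and leaf/stem biomass at the scheduled sampling days is
    recorded with multiplicative lognormal noise (CV = ``obs_noise_cv``).
    Nominal sampling days beyond the harvest day are clipped to it, matching
    the field practice of sampling at harvest.
    """
    rng = np.random.default_rng(design.rng_seed)
    cv = design.obs_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    gt = TrialGroundTruth(genotypes={}, design=design)
    observations: List[TrialObservation] = []

    base_inputs = {}
    days_by_year = {}
    for year in design.years:
        mgmt0 = management_for_year(year, design.stand_count_mean)
        base_inputs[year] = prepare_season(weather_by_year[year], mgmt0)
        season_len = mgmt0.season_days
        days_by_year[year] = [min(d, season_len) for d in design.sampling_days]

    for gi, genotype in enumerate(genotypes[: design.n_genotypes]):
        gid = f"G{gi + 1:04d}"
        gt.genotypes[gid] = genotype
        for year in design.years:
            days = days_by_year[year]
            for block in range(1, design.n_blocks + 1):
                stand = _truncated_normal(rng, design.stand_count_mean,
                                          design.stand_count_sd)
                mgmt = management_for_year(year, stand)
                inputs = base_inputs[year].with_management(mgmt)
                pred = simulate_prepared(genotype, inputs, is_ps=is_ps,
                                         sample_days=days, record=False)
                gt.true_biomass[(gid, year, block)] = pred.copy()
                noise = (np.exp(rng.normal(-0.5 * sigma * sigma, sigma,
                                           pred.shape))
                         if sigma > 0 else np.ones_like(pred))
                noisy = pred * noise
                for j, day in enumerate(days):
                    observations.append(TrialObservation(
                        genotype_id=gid,
                        year=year,
                        block=block,
                        stand_count=stand,
                        day_after_planting=int(day),
                        leaf_dry_biomass=float(noisy[j, 0]),
                        stem_dry_biomass=float(noisy[j, 1]),
                    ))
    return observations, gt
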