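"""Phenology: thermal/phenology-unit accumulation and growth stages.

Development is tracked with two hourly accumulators:

* **GDU** (growing degree unit) — the hourly analogue of growing degree
  days: ``max(0, min(T, T_max) - T_base) / 24`` per hour, so a day at
  constant temperature reproduces the classical daily GDD value while
  sub-daily fluctuations are captured.
* **GPU** (growing phenology unit) — a stage-transition accumulator
  combining a triangular normalized temperature response with a saturating
  normalized solar-radiation response, ``T_hat * R_hat / 24`` per hour; one
  fully optimal day contributes 1.0 GPU.

The growth-stage machine has four transition points — planting, vegetative,
bloom/grain-filling, harvest — with a photoperiod gate: photoperiod-sensitive
(PS) genotypes flower only when daylength falls below a critical threshold
(default 12 h 20 m), and accumulate GPU only on such inductive days, so in
temperate seasons they remain vegetative until harvest.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace
from enum import Enum


class Stage(Enum):
    """The four-point growth-stage machine (forward-only)."""

    PLANTED = 0
    VEGETATIVE = 1
    BLOOM_GRAINFILL = 2
    HARVESTED = 3


@dataclass(frozen=True)
class PhenologyParams:
    """Cardinal temperatures, normalization scales and stage thresholds."""

    base_temp: float = 11.0
    opt_temp: float = 30.0
    max_temp: float = 42.0
    rad_norm: float = 450.0
    gdu_emergence: float = 60.0
    gpu_maturity: float = 40.0
    critical_daylength: float = 12.0 + 20.0 / 60.0

    def __post_init__(self) -> None:
        if not (self.base_temp < self.opt_temp < self.max_temp):
            raise ValueError("require base_temp < opt_temp < max_temp")
        if self.rad_norm <= 0:
            raise ValueError("rad_norm must be positive")
        if self.gdu_emergence <= 0 or self.gpu_maturity <= 0:
            raise ValueError("stage thresholds must be positive")

    @classmethod
    def from_genotype(cls, g) -> "PhenologyParams":
        return cls(
            base_temp=g["base_temp"],
            opt_temp=g["opt_temp"],
            max_temp=g["max_temp"],
            rad_norm=g["rad_norm"],
            gdu_emergence=g["gdu_emergence"],
            gpu_maturity=g["gpu_maturity"],
            critical_daylength=g["critical_daylength"],
        )


@dataclass(frozen=True)
class PhenologyState:
    """Current stage plus the two development accumulators."""

    stage: Stage = Stage.PLANTED
    cumulative_gdu: float = 0.0
    cumulative_gpu: float = 0.0
    days_after_planting: int = 0


def gdu_increment(air_temp: float, params: PhenologyParams) -> float:
    """Hourly growing-degree-unit increment (GDU/h).

    Truncated-linear: zero at or below the base temperature, linear above,
    capped at the ceiling temperature, divided by 24 so a constant-temperature
    day sums to the classical daily GDD.
    """
    return max(0.0, min(air_temp, params.max_temp) - params.base_temp) / 24.0


def gpu_increment(air_temp: float, solar_radiation: float,
                  params: PhenologyParams) -> float:
    """Hourly growing-phenology-unit increment (GPU/h), in [0, 1/24].

    Product of a triangular temperature response (0 at <= base, 1 at optimum,
    0 at >= maximum) and a saturating radiation response
    ``min(R / rad_norm, 1)``, divided by 24.
    """
    if solar_radiation < 0:
        raise ValueError("solar_radiation must be non-negative")
    t = air_temp
    p = params
    if t <= p.base_temp or t >= p.max_temp:
        t_hat = 0.0
    elif t <= p.opt_temp:
        t_hat = (t - p.base_temp) / (p.opt_temp - p.base_temp)
    else:
        t_hat = (p.max_temp - t) / (p.max_temp - p.opt_temp)
    r_hat = min(solar_radiation / p.rad_norm, 1.0)
    return t_hat * r_hat / 24.0


def daylength(latitude: float, day_of_year: int) -> float:
    """Astronomical daylength in hours from the geometric sunrise equation.

    Solar declination ``delta = -23.44 deg * cos(2*pi*(N+10)/365.25)``; the
    sunrise hour angle is ``omega = arccos(-tan(phi) tan(delta))`` and the
    daylength ``24 * omega / pi``.  No refraction or twilight adjustment.
    """
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitudes are unsupported")
    phi = math.radians(latitude)
    delta = math.radians(-23.44) * math.cos(
        2.0 * math.pi * (day_of_year + 10) / 365.25
    )
    x = -math.tan(phi) * math.tan(delta)
    x = min(1.0, max(-1.0, x))
    return 24.0 * math.acos(x) / math.pi


def advance_phenology(
    state: PhenologyState,
    day_gdu: float,
    day_gpu: float,
    daylength_h: float,
    is_ps: bool,
    date: dt.date,
    mgmt,
    params: PhenologyParams,
) -> PhenologyState:
    """Advance the stage machine by one day.

    Accumulators grow by the day's GDU/GPU; transitions are forward-only:
    PLANTED -> VEGETATIVE once cumulative GDU reaches the emergence
    threshold; VEGETATIVE -> BLOOM_GRAINFILL once cumulative GPU reaches the
    maturity threshold, gated for PS genotypes by daylength below the
    critical photoperiod; any stage -> HARVESTED on the harvest date.
    """
    if date < mgmt.planting_date or date > mgmt.harvest_date:
        raise ValueError(f"{date} is outside the season "
                         f"[{mgmt.planting_date}, {mgmt.harvest_date}]")
    gdu = state.cumulative_gdu + day_gdu
    gpu = state.cumulative_gpu + day_gpu
    stage = state.stage
    if date >= mgmt.harvest_date:
        stage = Stage.HARVESTED
    elif stage is Stage.PLANTED and gdu >= params.gdu_emergence:
        stage = Stage.VEGETATIVE
    elif stage is Stage.VEGETATIVE and gpu >= params.gpu_maturity:
        if (not is_ps) or (daylength_h < params.critical_daylength):
            stage = Stage.BLOOM_GRAINFILL
    if stage.value < state.stage.value:  # pragma: no cover - defensive
        stage = state.stage
    return replace(
        state,
        stage=stage,
        cumulative_gdu=gdu,
        cumulative_gpu=gpu,
        days_after_planting=(date - mgmt.planting_date).days,
    )
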