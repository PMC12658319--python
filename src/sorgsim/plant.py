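"""Daily plant physiology: stress, photosynthesis, water, growth, tillering.

The plant is a main culm plus zero or more tillers, each with its own leaf,
stem, root and grain organ pools.  Organs track a dry weight and, for stem
and root, a structural dimension (height / length) that never decreases —
cell expansion and lignification are irreversible.  Tissue density
(weight per unit dimension) may fall below the reference density only
through remobilization under carbon deficit, and is restored before any new
structural growth when carbon becomes available again.

Daily carbon bookkeeping::

    net = assimilate - maintenance
    net >= 0:  total weight gain = net * growth_efficiency  (then senescence)
    net <  0:  |net| leaves organ pools at 1:1 in the remobilization order
               stem -> root -> leaf, dimensions unchanged

Photosynthesis is the minimum of four capacities (light, water, leaf source,
phloem transport) scaled by the air heat/cold stress product; water uptake
competes with neighbours through stand density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .phenology import Stage

_DENSITY_TOL = 1e-9


@dataclass
class OrganPool:
    """A single organ: dry weight, structural dimension, reference density.

    ``dimension`` is stem height (m) or root length (m); leaf and grain have
    no structural dimension (0).  ``density_ref`` is the weight carried per
    unit dimension at full tissue density (g/m).
    """

    weight: float
    dimension: float = 0.0
    density_ref: float = 0.0

    def check(self) -> None:
        if self.weight < -_DENSITY_TOL:
            raise ValueError(f"negative organ weight {self.weight}")
        if self.density_ref > 0 and self.dimension > 0:
            if self.weight > self.density_ref * self.dimension * (1 + 1e-9) + _DENSITY_TOL:
                raise ValueError("organ density exceeds reference density")


class Culm:
    """One culm (main or tiller) as a lightweight mutable record."""

    __slots__ = ("leaf_w", "stem_w", "stem_h", "root_w", "root_l",
                 "grain_w", "xylem_water", "initiation_day")

    def __init__(self, leaf_w=0.0, stem_w=0.0, stem_h=0.0, root_w=0.0,
                 root_l=0.0, grain_w=0.0, xylem_water=0.0, initiation_day=0):
        self.leaf_w = leaf_w
        self.stem_w = stem_w
        self.stem_h = stem_h
        self.root_w = root_w
        self.root_l = root_l
        self.grain_w = grain_w
        self.xylem_water = xylem_water
        self.initiation_day = initiation_day

    def total_weight(self) -> float:
        return self.leaf_w + self.stem_w + self.root_w + self.grain_w

    def copy(self) -> "Culm":
        c = Culm(self.leaf_w, self.stem_w, self.stem_h, self.root_w,
                 self.root_l, self.grain_w, self.xylem_water,
                 self.initiation_day)
        return c


@dataclass
class PlantState:
    """Whole-plant state: main culm, tillers, shared xylem pool, reserve."""

    main: Culm
    tillers: List[Culm] = field(default_factory=list)
    xylem_water: float = 0.0
    reserve_carbon: float = 0.0
    diag: Dict[str, float] = field(default_factory=dict)

    # -- organ-pool views (main culm) -----------------------------------
    def leaf_pool(self, params=None) -> OrganPool:
        return OrganPool(self.main.leaf_w)

    def stem_pool(self, params) -> OrganPool:
        return OrganPool(self.main.stem_w, self.main.stem_h,
                         params.stem_density_ref)

    def root_pool(self, params) -> OrganPool:
        return OrganPool(self.main.root_w, self.main.root_l,
                         params.root_density_ref)

    # -- aggregates over main culm + tillers ----------------------------
    def culms(self) -> List[Culm]:
        return [self.main, *self.tillers]

    @property
    def leaf_weight(self) -> float:
        return self.main.leaf_w + sum(t.leaf_w for t in self.tillers)

    @property
    def stem_weight(self) -> float:
        return self.main.stem_w + sum(t.stem_w for t in self.tillers)

    @property
    def root_weight(self) -> float:
        return self.main.root_w + sum(t.root_w for t in self.tillers)

    @property
    def grain_weight(self) -> float:
        return self.main.grain_w + sum(t.grain_w for t in self.tillers)

    @property
    def root_length(self) -> float:
        return self.main.root_l + sum(t.root_l for t in self.tillers)

    @property
    def stem_height(self) -> float:
        return self.main.stem_h

    @property
    def tiller_count(self) -> int:
        return len(self.tillers)

    def total_weight(self) -> float:
        return self.main.total_weight() + sum(t.total_weight()
                                              for t in self.tillers)

    def copy(self) -> "PlantState":
        return PlantState(
            main=self.main.copy(),
            tillers=[t.copy() for t in self.tillers],
            xylem_water=self.xylem_water,
            reserve_carbon=self.reserve_carbon,
            diag=dict(self.diag),
        )


@dataclass(frozen=True)
class StressState:
    """Stress factors in [0, 1]; 1 means unstressed."""

    air_heat: float = 1.0
    air_cold: float = 1.0
    root: float = 1.0
    water: float = 1.0

    def __post_init__(self) -> None:
        for name in ("air_heat", "air_cold", "root", "water"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"stress factor {name}={v} outside [0, 1]")

    @property
    def shoot_min(self) -> float:
        """Lowest factor applicable to above-ground organs."""
        return min(self.air_heat, self.air_cold, self.water)

    @property
    def root_min(self) -> float:
        """Lowest factor applicable to the root."""
        return min(self.root, self.water)


@dataclass(frozen=True)
class PhysiologyParams:
    """Physiological coefficients derived from a genotype vector.

    Partition fractions are normalized per stage to sum to one; the grain
    fraction is forced to zero for photoperiod-sensitive genotypes.
    """

    rue: float
    k_light: float
    sla: float
    phloem_cap: float
    leaf_cap_coeff: float
    water_cap_coeff: float
    transp_coeff: float
    wind_coeff: float
    et_scale: float
    water_uptake_coeff: float
    competition_coeff: float
    xylem_capacity: float
    xylem_transport_cap: float
    maint_leaf: float
    maint_stem: float
    maint_root: float
    maint_grain: float
    senescence_leaf: float
    senescence_stem: float
    senescence_root: float
    senescence_grain: float
    growth_efficiency: float
    stem_density_ref: float
    root_density_ref: float
    cold_kill: float
    cold_opt: float
    heat_opt: float
    heat_kill: float
    root_cold_kill: float
    root_cold_opt: float
    root_heat_opt: float
    root_heat_kill: float
    tiller_trigger: float
    tiller_max: int
    tiller_seed_fraction: float
    tiller_discount: float
    tiller_gdu_min: float
    seed_leaf_weight: float
    seed_stem_weight: float
    seed_root_weight: float
    seed_reserve: float
    initial_xylem_fraction: float
    # (leaf, stem, root, grain) fractions per stage, each summing to 1
    partitions: Dict[Stage, Tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        if not (self.cold_kill < self.cold_opt <= self.heat_opt < self.heat_kill):
            raise ValueError("require cold_kill < cold_opt <= heat_opt < heat_kill")
        for stage, frac in self.partitions.items():
            if abs(sum(frac) - 1.0) > 1e-9:
                raise ValueError(f"partition fractions for {stage} must sum to 1")

    @classmethod
    def from_genotype(cls, g, is_ps: bool = True) -> "PhysiologyParams":
        veg = (g["part_leaf_veg"], g["part_stem_veg"], g["part_root_veg"], 0.0)
        rep = [g["part_leaf_rep"], g["part_stem_rep"], g["part_root_rep"],
               g["part_grain_rep"]]
        if is_ps:
            rep[3] = 0.0
        sv = sum(veg)
        sr = sum(rep)
        if sr <= 0:
            rep, sr = [1.0, 1.0, 1.0, 0.0], 3.0
        partitions = {
            Stage.VEGETATIVE: tuple(x / sv for x in veg),
            Stage.BLOOM_GRAINFILL: tuple(x / sr for x in rep),
        }
        return cls(
            rue=g["rue"], k_light=g["k_light"], sla=g["sla"],
            phloem_cap=g["phloem_cap"], leaf_cap_coeff=g["leaf_cap_coeff"],
            water_cap_coeff=g["water_cap_coeff"],
            transp_coeff=g["transp_coeff"], wind_coeff=g["wind_coeff"],
            et_scale=g["et_scale"],
            water_uptake_coeff=g["water_uptake_coeff"],
            competition_coeff=g["competition_coeff"],
            xylem_capacity=g["xylem_capacity"],
            xylem_transport_cap=g["xylem_transport_cap"],
            maint_leaf=g["maint_leaf"], maint_stem=g["maint_stem"],
            maint_root=g["maint_root"], maint_grain=g["maint_grain"],
            senescence_leaf=g["senescence_leaf"],
            senescence_stem=g["senescence_stem"],
            senescence_root=g["senescence_root"],
            senescence_grain=g["senescence_grain"],
            growth_efficiency=g["growth_efficiency"],
            stem_density_ref=g["stem_density_ref"],
            root_density_ref=g["root_density_ref"],
            cold_kill=g["cold_kill"], cold_opt=g["cold_opt"],
            heat_opt=g["heat_opt"], heat_kill=g["heat_kill"],
            root_cold_kill=g["root_cold_kill"],
            root_cold_opt=g["root_cold_opt"],
            root_heat_opt=g["root_heat_opt"],
            root_heat_kill=g["root_heat_kill"],
            tiller_trigger=g["tiller_trigger"],
            tiller_max=int(g["tiller_max"]),
            tiller_seed_fraction=g["tiller_seed_fraction"],
            tiller_discount=g["tiller_discount"],
            tiller_gdu_min=g["tiller_gdu_min"],
            seed_leaf_weight=g["seed_leaf_weight"],
            seed_stem_weight=g["seed_stem_weight"],
            seed_root_weight=g["seed_root_weight"],
            seed_reserve=g["seed_reserve"],
            initial_xylem_fraction=g["initial_xylem_fraction"],
            partitions=partitions,
        )


def initial_plant_state(params: PhysiologyParams) -> PlantState:
    """Seed-derived state at planting: small organ pools at full density."""
    main = Culm(
        leaf_w=params.seed_leaf_weight,
        stem_w=params.seed_stem_weight,
        stem_h=params.seed_stem_weight / params.stem_density_ref,
        root_w=params.seed_root_weight,
        root_l=params.seed_root_weight / params.root_density_ref,
    )
    return PlantState(
        main=main,
        xylem_water=params.initial_xylem_fraction * params.xylem_capacity,
        reserve_carbon=params.seed_reserve,
    )


def _ramp_down(x: float, opt: float, kill: float) -> float:
    """1 at or below opt, linearly to 0 at kill (heat-style ramp)."""
    if x <= opt:
        return 1.0
    if x >= kill:
        return 0.0
    return (kill - x) / (kill - opt)


def _ramp_up(x: float, kill: float, opt: float) -> float:
    """0 at or below kill, linearly to 1 at opt (cold-style ramp)."""
    if x >= opt:
        return 1.0
    if x <= kill:
        return 0.0
    return (x - kill) / (opt - kill)


def compute_stress(
    air_temp_min: float,
    air_temp_max: float,
    root_temp: float,
    water_deficit: float,
    params: PhysiologyParams,
) -> StressState:
    """Piecewise-linear heat/cold/root/water stress factors in [0, 1].

    Heat stress responds to the daily maximum air temperature, cold stress
    to the daily minimum; the root factor combines the root-zone cold and
    heat ramps on soil temperature; water stress is ``1 - water_deficit``.
    """
    air_heat = _ramp_down(air_temp_max, params.heat_opt, params.heat_kill)
    air_cold = _ramp_up(air_temp_min, params.cold_kill, params.cold_opt)
    root = min(
        _ramp_up(root_temp, params.root_cold_kill, params.root_cold_opt),
        _ramp_down(root_temp, params.root_heat_opt, params.root_heat_kill),
    )
    water = min(1.0, max(0.0, 1.0 - water_deficit))
    return StressState(air_heat=air_heat, air_cold=air_cold,
                       root=root, water=water)


def radiation_interception(
    leaf_weight: float,
    stand_count: float,
    daily_radiation: float,
    params: PhysiologyParams,
) -> float:
    """Per-plant intercepted radiation (MJ/plant/day) by Beer's law.

    Canopy interception fraction is ``1 - exp(-k * SLA * leaf_w * stand)``
    (the exponent is leaf area index scaled by the extinction coefficient);
    the per-plant share divides the areal interception by stand count.
    """
    if stand_count <= 0:
        raise ValueError("stand_count must be positive (no crop otherwise)")
    if leaf_weight < 0 or daily_radiation < 0:
        raise ValueError("inputs must be non-negative")
    lai = params.sla * leaf_weight * stand_count
    frac = 1.0 - math.exp(-params.k_light * lai)
    return daily_radiation * frac / stand_count


def daily_photosynthesis(
    state: PlantState,
    intercepted: float,
    stress: StressState,
    water_supply: float,
    params: PhysiologyParams,
) -> float:
    """Daily assimilation (g CH2O/plant): the binding capacity times stress.

    Capacities: light (RUE x intercepted), water (proportional to available
    water), leaf source (per unit leaf mass) and phloem transport; the
    smallest binds.  The air heat/cold stress minimum scales the result.
    """
    leaf_w = state.leaf_weight
    light_cap = params.rue * intercepted
    water_cap = params.water_cap_coeff * water_supply
    leaf_cap = params.leaf_cap_coeff * leaf_w
    cap = min(light_cap, water_cap, leaf_cap, params.phloem_cap)
    return max(0.0, cap) * min(stress.air_heat, stress.air_cold)


def vapor_pressure_deficit(air_temp: float, rel_humidity: float) -> float:
    """VPD in kPa from the Tetens saturation vapour pressure curve."""
    es = 0.6108 * math.exp(17.27 * air_temp / (air_temp + 237.3))
    return es * (1.0 - rel_humidity / 100.0)


def transpiration_demand(
    air_temp: float,
    rel_humidity: float,
    wind_speed: float,
    evapotranspiration: float,
    leaf_weight: float,
    params: PhysiologyParams,
) -> float:
    """Daily transpiration demand (g water/plant).

    Proportional to leaf mass and vapour-pressure deficit, increased by
    wind, and scaled by the day's reference evapotranspiration relative to
    ``et_scale``.  Zero at saturation (RH = 100%).
    """
    vpd = max(0.0, vapor_pressure_deficit(air_temp, rel_humidity))
    et_term = max(0.0, evapotranspiration) / params.et_scale
    return (params.transp_coeff * leaf_weight * vpd
            * (1.0 + params.wind_coeff * wind_speed) * et_term)


def water_balance_step(
    state: PlantState,
    soil_vwc: float,
    demand: float,
    stand_count: float,
    params: PhysiologyParams,
) -> Tuple[PlantState, float]:
    """Advance the xylem water pool one day; return the water deficit.

    Uptake is limited by root length, soil moisture, neighbour competition
    (scaling with stand density) and the xylem transport capacity.  Soil
    moisture is an external input and is never modified.
    """
    if not (0.0 <= soil_vwc <= 1.0):
        raise ValueError("soil_vwc must lie in [0, 1]")
    uptake = min(
        params.water_uptake_coeff * state.root_length * soil_vwc
        / (1.0 + params.competition_coeff * stand_count),
        params.xylem_transport_cap,
    )
    stored = state.xylem_water
    if demand > 0:
        deficit = max(0.0, (demand - uptake - stored) / demand)
    else:
        deficit = 0.0
    state.xylem_water = min(max(stored + uptake - demand, 0.0),
                            params.xylem_capacity)
    state.diag["uptake"] = uptake
    return state, deficit


def maintenance_cost(
    state: PlantState,
    stress: StressState,
    params: PhysiologyParams,
) -> Tuple[float, List[Dict[str, float]]]:
    """Maintenance respiration and stress-driven senescence.

    Cost is linear in organ weight over every culm (main and tillers);
    senescence removes a fraction of each organ proportional to how far the
    lowest applicable stress factor falls below one.  Returns the total cost
    and a per-culm dict of senescence losses (g dry matter, not yet applied).
    """
    shoot_f = 1.0 - stress.shoot_min
    root_f = 1.0 - stress.root_min
    cost = 0.0
    senescence: List[Dict[str, float]] = []
    for culm in state.culms():
        cost += (params.maint_leaf * culm.leaf_w
                 + params.maint_stem * culm.stem_w
                 + params.maint_root * culm.root_w
                 + params.maint_grain * culm.grain_w)
        senescence.append({
            "leaf": params.senescence_leaf * shoot_f * culm.leaf_w,
            "stem": params.senescence_stem * shoot_f * culm.stem_w,
            "root": params.senescence_root * root_f * culm.root_w,
            "grain": params.senescence_grain * shoot_f * culm.grain_w,
        })
    return cost, senescence


def _restore_and_grow(culm: Culm, structure: float, frac, params) -> None:
    """Give one culm ``structure`` g of new dry matter.

    Tissue density of stem and root is restored toward the reference before
    any allocation to new growth; the remainder follows the stage partition
    fractions, extending stem height and root length at reference density.
    """
    stem_gap = max(0.0, params.stem_density_ref * culm.stem_h - culm.stem_w)
    root_gap = max(0.0, params.root_density_ref * culm.root_l - culm.root_w)
    gap = stem_gap + root_gap
    if gap > 0.0:
        restore = min(structure, gap)
        if gap > 1e-300:
            culm.stem_w += restore * stem_gap / gap
            culm.root_w += restore * root_gap / gap
        structure -= restore
    if structure <= 0.0:
        return
    f_leaf, f_stem, f_root, f_grain = frac
    culm.leaf_w += structure * f_leaf
    d_stem = structure * f_stem
    culm.stem_w += d_stem
    culm.stem_h += d_stem / params.stem_density_ref
    d_root = structure * f_root
    culm.root_w += d_root
    culm.root_l += d_root / params.root_density_ref
    culm.grain_w += structure * f_grain


_REMOBILIZE_ORDER = ("stem_w", "root_w", "leaf_w")


def allocate_growth(
    state: PlantState,
    assimilate: float,
    maintenance: float,
    senescence: List[Dict[str, float]],
    stage: Stage,
    stress: StressState,
    params: PhysiologyParams,
) -> PlantState:
    """Apply the daily carbon budget to organ pools (in place).

    Surplus carbon becomes structure at ``growth_efficiency``, restoring
    tissue density first, then splitting by stage partition fractions across
    culms (tiller sinks discounted).  Deficit remobilizes dry matter at 1:1
    in the order stem, root, leaf with structural dimensions untouched.
    Senescence losses are then subtracted, floored at zero.  Diagnostics
    (net, structural gain, remobilized and senesced mass) land in
    ``state.diag`` so callers can audit carbon closure.
    """
    net = assimilate - maintenance
    culms = state.culms()
    diag = state.diag
    diag["net_carbon"] = net
    diag["structural_gain"] = 0.0
    diag["remobilized"] = 0.0
    diag["remobilization_floored"] = 0.0

    if net >= 0.0:
        structure = net * params.growth_efficiency
        diag["structural_gain"] = structure
        if structure > 0.0:
            frac = params.partitions.get(stage,
                                         params.partitions[Stage.VEGETATIVE])
            weights = [1.0] + [params.tiller_discount] * len(state.tillers)
            wsum = sum(weights)
            for culm, w in zip(culms, weights):
                _restore_and_grow(culm, structure * w / wsum, frac, params)
    else:
        need = -net
        removed = 0.0
        for attr in _REMOBILIZE_ORDER:
            if need <= removed:
                break
            avail = sum(getattr(c, attr) for c in culms)
            take = min(need - removed, avail)
            if take <= 0.0 or avail <= 0.0:
                continue
            for c in culms:
                share = getattr(c, attr) / avail
                setattr(c, attr, getattr(c, attr) - take * share)
            removed += take
        diag["remobilized"] = removed
        diag["remobilization_floored"] = float(removed < need - 1e-12)

    senesced = 0.0
    organs = (("leaf", "leaf_w"), ("stem", "stem_w"),
              ("root", "root_w"), ("grain", "grain_w"))
    for culm, sen in zip(culms, senescence):
        for organ, attr in organs:
            loss = min(sen.get(organ, 0.0), getattr(culm, attr))
            if loss > 0.0:
                setattr(culm, attr, getattr(culm, attr) - loss)
                senesced += loss
    diag["senesced"] = senesced
    state.reserve_carbon = max(net, 0.0)
    return state


def tiller_update(
    state: PlantState,
    stage: Stage,
    params: PhysiologyParams,
    cumulative_gdu: float = float("inf"),
    day: int = 0,
) -> PlantState:
    """Initiate a tiller when the carbon surplus crosses the trigger.

    Requires the vegetative stage, sufficient thermal time, a daily surplus
    (``reserve_carbon``) above the trigger and a free tiller slot.  The new
    tiller is seeded by transferring a fraction of the main culm's leaf and
    root mass, so whole-plant dry matter is conserved.
    """
    if (stage is Stage.VEGETATIVE
            and len(state.tillers) < params.tiller_max
            and state.reserve_carbon > params.tiller_trigger
            and cumulative_gdu >= params.tiller_gdu_min
            and state.main.leaf_w > 0.0):
        f = params.tiller_seed_fraction
        leaf_seed = f * state.main.leaf_w
        root_seed = f * state.main.root_w
        state.main.leaf_w -= leaf_seed
        state.main.root_w -= root_seed
        state.tillers.append(Culm(
            leaf_w=leaf_seed,
            root_w=root_seed,
            root_l=root_seed / params.root_density_ref,
            initiation_day=day,
        ))
    return state
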