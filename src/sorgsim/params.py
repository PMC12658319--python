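"""Genotype parameter registry.

The simulator is parameterized by a single bounded vector of 56 genotype
properties ("g*") spanning phenology, stress response, photosynthesis,
transpiration, water relations, maintenance, senescence, growth partitioning,
tillering and seed/initial state.  Defaults are seeded from APSIM sorghum
conventions where an analogue exists (cardinal temperatures, radiation-use
efficiency, extinction coefficient) and from common physiological ranges
otherwise; every entry carries expert-style bounds so a calibrator can search
the full biologically plausible box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np
import yaml

__all__ = [
    "ParameterSpec",
    "GenotypeParameterVector",
    "PARAMETER_REGISTRY",
    "default_genotype",
    "registry_names",
]


@dataclass(frozen=True)
class ParameterSpec:
    """One tunable genotype property: default value, bounds and units."""

    name: str
    default: float
    lower: float
    upper: float
    units: str
    description: str

    def __post_init__(self) -> None:
        if not (self.lower <= self.default <= self.upper):
            raise ValueError(
                f"default for {self.name!r} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )


def _p(name, default, lower, upper, units, description) -> ParameterSpec:
    return ParameterSpec(name, float(default), float(lower), float(upper),
                         units, description)


#: Ordered registry of the 56 tunable genotype parameters.
PARAMETER_REGISTRY: Tuple[ParameterSpec, ...] = (
    # -- phenology -------------------------------------------------------
    _p("base_temp", 11.0, 5.0, 15.0, "degC",
       "base temperature below which no thermal time accrues"),
    _p("opt_temp", 30.0, 24.0, 36.0, "degC",
       "optimum temperature for development"),
    _p("max_temp", 42.0, 38.0, 48.0, "degC",
       "ceiling temperature; development response is zero above"),
    _p("rad_norm", 450.0, 200.0, 900.0, "W/m2",
       "solar-radiation normalization scale for phenology units"),
    _p("gdu_emergence", 60.0, 30.0, 120.0, "GDU",
       "thermal-time threshold for emergence (planted -> vegetative)"),
    _p("gpu_maturity", 40.0, 15.0, 80.0, "GPU",
       "phenology-unit threshold for floral transition"),
    _p("critical_daylength", 12.0 + 20.0 / 60.0, 11.0, 13.5, "h",
       "photoperiod gate: flowering requires daylength below this"),
    # -- air-temperature stress breakpoints ------------------------------
    _p("cold_kill", 0.0, -5.0, 6.0, "degC",
       "air temperature at which cold stress factor reaches 0"),
    _p("cold_opt", 12.0, 8.0, 18.0, "degC",
       "air temperature above which cold stress vanishes"),
    _p("heat_opt", 32.0, 26.0, 38.0, "degC",
       "air temperature below which heat stress vanishes"),
    _p("heat_kill", 45.0, 40.0, 50.0, "degC",
       "air temperature at which heat stress factor reaches 0"),
    # -- root (soil) temperature stress breakpoints ----------------------
    _p("root_cold_kill", 2.0, -2.0, 6.0, "degC", "root-zone cold kill point"),
    _p("root_cold_opt", 12.0, 8.0, 18.0, "degC", "root-zone cold optimum"),
    _p("root_heat_opt", 28.0, 24.0, 35.0, "degC", "root-zone heat optimum"),
    _p("root_heat_kill", 40.0, 36.0, 45.0, "degC", "root-zone heat kill point"),
    # -- photosynthesis --------------------------------------------------
    _p("rue", 3.2, 1.5, 4.5, "g CH2O/MJ",
       "radiation-use efficiency on intercepted shortwave"),
    _p("k_light", 0.55, 0.30, 0.80, "-",
       "canopy light extinction coefficient (Beer's law on LAI)"),
    _p("sla", 0.018, 0.008, 0.030, "m2/g",
       "specific leaf area proxy converting leaf dry mass to area"),
    _p("phloem_cap", 14.0, 5.0, 30.0, "g CH2O/plant/d",
       "maximum daily phloem transport of assimilate"),
    _p("leaf_cap_coeff", 0.42, 0.10, 0.60, "g CH2O/g leaf/d",
       "source-capacity of leaf tissue per unit dry mass"),
    _p("water_cap_coeff", 0.006, 0.002, 0.015, "g CH2O/g H2O",
       "assimilation supported per gram of available water"),
    # -- transpiration ---------------------------------------------------
    _p("transp_coeff", 14.0, 3.0, 25.0, "g H2O/g leaf/kPa/d",
       "transpiration demand per unit leaf mass and VPD"),
    _p("wind_coeff", 0.10, 0.0, 0.30, "s/m",
       "fractional demand increase per m/s wind"),
    _p("et_scale", 5.0, 2.0, 10.0, "mm/d",
       "reference evapotranspiration normalizing the demand term"),
    # -- water relations -------------------------------------------------
    _p("water_uptake_coeff", 35.0, 15.0, 150.0, "g H2O/m root/d",
       "root uptake rate per metre of root at unit soil moisture"),
    _p("competition_coeff", 0.06, 0.0, 0.20, "m2/plant",
       "neighbour competition scaling of per-plant water availability"),
    _p("xylem_capacity", 300.0, 100.0, 1500.0, "g H2O/plant",
       "storage capacity of the xylem water pool"),
    _p("xylem_transport_cap", 2500.0, 500.0, 6000.0, "g H2O/plant/d",
       "maximum daily xylem water transport"),
    # -- maintenance -----------------------------------------------------
    _p("maint_leaf", 0.010, 0.002, 0.030, "g CH2O/g/d",
       "leaf maintenance respiration coefficient"),
    _p("maint_stem", 0.0020, 0.0005, 0.0080, "g CH2O/g/d",
       "stem maintenance respiration coefficient"),
    _p("maint_root", 0.0050, 0.0010, 0.0150, "g CH2O/g/d",
       "root maintenance respiration coefficient"),
    _p("maint_grain", 0.0080, 0.0020, 0.0200, "g CH2O/g/d",
       "grain maintenance respiration coefficient"),
    # -- senescence ------------------------------------------------------
    _p("senescence_leaf", 0.05, 0.01, 0.15, "1/d",
       "leaf dry-mass loss fraction per day at full stress"),
    _p("senescence_stem", 0.005, 0.0, 0.03, "1/d",
       "stem dry-mass loss fraction per day at full stress"),
    _p("senescence_root", 0.010, 0.0, 0.04, "1/d",
       "root dry-mass loss fraction per day at full stress"),
    _p("senescence_grain", 0.005, 0.0, 0.03, "1/d",
       "grain dry-mass loss fraction per day at full stress"),
    # -- growth ----------------------------------------------------------
    _p("growth_efficiency", 0.70, 0.50, 0.85, "g DM/g CH2O",
       "conversion of assimilate to structure net of growth respiration"),
    _p("stem_density_ref", 120.0, 40.0, 300.0, "g/m",
       "stem dry mass per metre of height at full tissue density"),
    _p("root_density_ref", 0.5, 0.1, 2.0, "g/m",
       "root dry mass per metre of length at full tissue density"),
    # -- partitioning (free weights, renormalized per stage) -------------
    _p("part_leaf_veg", 0.30, 0.10, 0.60, "-",
       "vegetative-stage partition weight to leaf"),
    _p("part_stem_veg", 0.45, 0.20, 0.70, "-",
       "vegetative-stage partition weight to stem"),
    _p("part_root_veg", 0.25, 0.05, 0.50, "-",
       "vegetative-stage partition weight to root"),
    _p("part_leaf_rep", 0.10, 0.0, 0.30, "-",
       "reproductive-stage partition weight to leaf"),
    _p("part_stem_rep", 0.35, 0.10, 0.60, "-",
       "reproductive-stage partition weight to stem"),
    _p("part_root_rep", 0.15, 0.05, 0.40, "-",
       "reproductive-stage partition weight to root"),
    _p("part_grain_rep", 0.40, 0.0, 0.70, "-",
       "reproductive-stage partition weight to grain"),
    # -- tillering -------------------------------------------------------
    _p("tiller_trigger", 3.0, 0.5, 10.0, "g CH2O",
       "daily carbon surplus required to initiate a tiller"),
    _p("tiller_max", 2.0, 0.0, 5.0, "count",
       "maximum number of tillers (floored to an integer)"),
    _p("tiller_seed_fraction", 0.05, 0.01, 0.15, "-",
       "fraction of main-culm leaf/root mass seeding a new tiller"),
    _p("tiller_discount", 0.7, 0.3, 1.0, "-",
       "allocation weight of tiller sinks relative to the main culm"),
    _p("tiller_gdu_min", 150.0, 50.0, 400.0, "GDU",
       "thermal time before tillering can begin"),
    # -- seed / initial state --------------------------------------------
    _p("seed_leaf_weight", 0.5, 0.1, 2.0, "g", "leaf dry mass at planting"),
    _p("seed_stem_weight", 0.2, 0.05, 1.0, "g", "stem dry mass at planting"),
    _p("seed_root_weight", 0.3, 0.05, 1.5, "g", "root dry mass at planting"),
    _p("seed_reserve", 1.0, 0.2, 3.0, "g CH2O",
       "labile seed carbon reserve fueling pre-emergence maintenance"),
    _p("initial_xylem_fraction", 0.5, 0.0, 1.0, "-",
       "initial xylem water as a fraction of capacity"),
)

assert len(PARAMETER_REGISTRY) == 56, "registry must expose exactly 56 tunables"

_SPEC_BY_NAME: Dict[str, ParameterSpec] = {s.name: s for s in PARAMETER_REGISTRY}


def registry_names() -> Tuple[str, ...]:
    """Names of the 56 tunable parameters, in registry order."""
    return tuple(s.name for s in PARAMETER_REGISTRY)


@dataclass
class GenotypeParameterVector:
    """A bounded 56-dimensional genotype parameter vector.

    Values are stored in registry order; every value must lie within its
    registry bounds.  ``provenance`` tags where the values came from
    ("default", "sampled", "calibrated", ...).
    """

    values: Dict[str, float] = field(default_factory=dict)
    provenance: str = "default"

    def __post_init__(self) -> None:
        names = registry_names()
        if not self.values:
            self.values = {s.name: s.default for s in PARAMETER_REGISTRY}
        missing = set(names) - set(self.values)
        extra = set(self.values) - set(names)
        if missing or extra:
            raise ValueError(
                f"parameter vector must have exactly the 56 registry entries; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        self.values = {n: float(self.values[n]) for n in names}
        self.validate()

    def validate(self) -> None:
        for name, v in self.values.items():
            s = _SPEC_BY_NAME[name]
            if not (s.lower <= v <= s.upper):
                raise ValueError(
                    f"{name}={v} outside bounds [{s.lower}, {s.upper}]"
                )

    # -- convenience access ---------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in registry_names()])

    @classmethod
    def from_array(cls, arr, provenance: str = "array") -> "GenotypeParameterVector":
        arr = np.asarray(arr, dtype=float)
        names = registry_names()
        if arr.shape != (len(names),):
            raise ValueError(f"expected shape ({len(names)},), got {arr.shape}")
        return cls(values=dict(zip(names, arr.tolist())), provenance=provenance)

    def replace(self, **updates: float) -> "GenotypeParameterVector":
        vals = dict(self.values)
        vals.update(updates)
        return GenotypeParameterVector(values=vals, provenance=self.provenance)

    def clipped(self, values: Mapping[str, float]) -> "GenotypeParameterVector":
        """Copy with ``values`` applied, each clipped to its bounds."""
        vals = dict(self.values)
        for name, v in values.items():
            s = _SPEC_BY_NAME[name]
            vals[name] = min(max(float(v), s.lower), s.upper)
        return GenotypeParameterVector(values=vals, provenance=self.provenance)

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "provenance": self.provenance,
            "parameters": {
                n: {
                    "value": self.values[n],
                    "units": _SPEC_BY_NAME[n].units,
                    "bounds": [_SPEC_BY_NAME[n].lower, _SPEC_BY_NAME[n].upper],
                }
                for n in registry_names()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenotypeParameterVector":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        params = doc.get("parameters", doc)
        values = {
            n: (v["value"] if isinstance(v, dict) else float(v))
            for n, v in params.items()
        }
        return cls(values=values, provenance=doc.get("provenance", "file"))


def default_genotype() -> GenotypeParameterVector:
    """The APSIM-seeded default genotype parameter vector."""
    return GenotypeParameterVector()


def bounds_array() -> Tuple[np.ndarray, np.ndarray]:
    """(lower, upper) bound arrays in registry order."""
    lo = np.array([s.lower for s in PARAMETER_REGISTRY])
    hi = np.array([s.upper for s in PARAMETER_REGISTRY])
    return lo, hi
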