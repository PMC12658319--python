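"""Genotypic parameter calibration by sensitivity-weighted coordinate search.

The objective is the relative root mean square error (RRMSE) of total shoot
dry biomass, pooled over every (series, sampling day) pair of a genotype's
training data::

    RRMSE = sqrt(mean((x - xhat)^2)) / mean(x)

where x is the observed and xhat the predicted leaf + stem dry biomass.

The tuner is a stochastic coordinate search over the bounded 56-dimensional
genotype vector: each iteration samples n parameters (with probability
proportional to their local objective sensitivity, floored so every
parameter stays reachable), proposes one incremented and one decremented
value per selected parameter at the current step size (clipped to bounds),
evaluates the proposals, and accepts the best only if it improves the
incumbent.  Steps decay on stagnation; the search stops on tolerance, a
wall-clock time limit, or an iteration cap.  Runs are fully reproducible
from the configured seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import SeasonInputs, prepare_season, simulate_prepared
from .params import (PARAMETER_REGISTRY, GenotypeParameterVector,
                     bounds_array, registry_names)
from .weather import ManagementRecord, TrialObservation, WeatherSeries, trial_series

__all__ = [
    "rrmse", "estimate_sensitivity", "tune_parameters",
    "train_test_experiment", "CalibrationConfig", "CalibrationResult",
    "StopReason", "SeriesData", "pooled_objective",
]


def rrmse(observed, predicted) -> float:
    """Relative root mean square error: RMSE scaled by the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    mean_obs = obs.mean()
    if mean_obs <= 0:
        raise ValueError("mean of observed values must be positive")
    return float(np.sqrt(np.mean((obs - pred) ** 2)) / mean_obs)


def estimate_sensitivity(
    params: GenotypeParameterVector,
    objective: Callable[[GenotypeParameterVector], float],
    probe_step: float = 0.02,
) -> np.ndarray:
    """Per-parameter sampling probabilities from local objective sensitivity.

    Each parameter is probed at +/- ``probe_step`` of its bound range
    (clipped to bounds); its sensitivity is the larger absolute objective
    change.  Probabilities are the sensitivities plus a small floor,
    normalized to sum to one.  Deterministic given the objective.
    """
    names = registry_names()
    lo, hi = bounds_array()
    f0 = objective(params)
    sens = np.zeros(len(names))
    for j, name in enumerate(names):
        delta = probe_step * (hi[j] - lo[j])
        v = params.values[name]
        for probe in (min(v + delta, hi[j]), max(v - delta, lo[j])):
            if probe == v:
                continue
            fj = objective(params.clipped({name: probe}))
            sens[j] = max(sens[j], abs(fj - f0))
    floor = max(1e-2 * sens.max(), 1e-12)
    probs = sens + floor
    return probs / probs.sum()


class StopReason(Enum):
    TOLERANCE = "tolerance"
    TIME_LIMIT = "time_limit"
    MAX_ITER = "max_iter"


@dataclass(frozen=True)
class CalibrationConfig:
    """Search hyperparameters (schedule defaults chosen for robustness)."""

    n_select: int = 5
    step_sizes: Optional[Mapping[str, float]] = None  # default: 10% of range
    step_decay: float = 0.5
    stagnation_window: int = 50
    step_floor_frac: float = 0.001
    time_limit: Optional[float] = None  # seconds
    tolerance: float = 0.0
    max_iter: int = 2000
    rng_seed: int = 0
    sensitivity_refresh: int = 200
    probe_step: float = 0.02

    def __post_init__(self) -> None:
        if not (1 <= self.n_select <= len(PARAMETER_REGISTRY)):
            raise ValueError("n_select must lie in [1, 56]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class CalibrationResult:
    """Tuned parameters with the objective trace and stopping diagnostics."""

    best_params: GenotypeParameterVector
    best_rrmse: float
    objective_trace: np.ndarray
    iterations: int
    stop_reason: StopReason
    n_evaluations: int = 0


@dataclass
class SeriesData:
    """One observed series prepared for fast repeated simulation."""

    inputs: SeasonInputs
    days: np.ndarray           # days after planting, aligned with observed
    observed_total: np.ndarray  # leaf + stem, g/plant
    observed_leaf: np.ndarray
    observed_stem: np.ndarray

    @classmethod
    def from_observations(
        cls,
        observations: Sequence[TrialObservation],
        weather: WeatherSeries,
        mgmt: ManagementRecord,
    ) -> "SeriesData":
        obs = sorted(observations, key=lambda o: o.day_after_planting)
        days = np.array([o.day_after_planting for o in obs], dtype=int)
        leaf = np.array([o.leaf_dry_biomass for o in obs])
        stem = np.array([o.stem_dry_biomass for o in obs])
        return cls(
            inputs=prepare_season(weather, mgmt),
            days=days,
            observed_total=leaf + stem,
            observed_leaf=leaf,
            observed_stem=stem,
        )


def pooled_objective(series: Sequence[SeriesData],
                     is_ps: bool = True) -> Callable[[GenotypeParameterVector], float]:
    """RRMSE of pooled leaf+stem totals across all series' sampling days."""
    if not series:
        raise ValueError("training set must contain at least one series")
    observed = np.concatenate([s.observed_total for s in series])
    if observed.mean() <= 0:
        raise ValueError("objective undefined: mean observed biomass <= 0")

    def objective(genotype: GenotypeParameterVector) -> float:
        preds = [
            simulate_prepared(genotype, s.inputs, is_ps=is_ps,
                              sample_days=s.days, record=False).sum(axis=1)
            for s in series
        ]
        return rrmse(observed, np.concatenate(preds))

    return objective


def per_organ_rrmse(genotype: GenotypeParameterVector,
                    series: Sequence[SeriesData],
                    is_ps: bool = True) -> Dict[str, float]:
    """Diagnostic per-organ RRMSE (leaf and stem separately)."""
    leaf_o, stem_o, leaf_p, stem_p = [], [], [], []
    for s in series:
        pred = simulate_prepared(genotype, s.inputs, is_ps=is_ps,
                                 sample_days=s.days, record=False)
        leaf_o.append(s.observed_leaf)
        stem_o.append(s.observed_stem)
        leaf_p.append(pred[:, 0])
        stem_p.append(pred[:, 1])
    return {
        "leaf": rrmse(np.concatenate(leaf_o), np.concatenate(leaf_p)),
        "stem": rrmse(np.concatenate(stem_o), np.concatenate(stem_p)),
    }


def tune_parameters(
    training_series: Sequence[Tuple[Sequence[TrialObservation],
                                    WeatherSeries, ManagementRecord]],
    init: GenotypeParameterVector,
    config: CalibrationConfig,
    is_ps: bool = True,
    _prepared: Optional[Sequence[SeriesData]] = None,
) -> CalibrationResult:
    """Tune a genotype vector against observed biomass series.

    ``training_series`` is a list of (observations, weather, management)
    triples for one genotype; all series are pooled into a single RRMSE
    objective.  The search accepts only improving proposals, so the
    objective trace is non-increasing, and every evaluated candidate is
    clipped to the registry bounds.
    """
    if _prepared is not None:
        series = list(_prepared)
    else:
        series = [SeriesData.from_observations(obs, w, m)
                  for obs, w, m in training_series]
    objective = pooled_objective(series, is_ps=is_ps)
    names = registry_names()
    lo, hi = bounds_array()
    ranges = hi - lo

    n_evals = 0

    def evaluate(vec: GenotypeParameterVector) -> float:
        nonlocal n_evals
        n_evals += 1
        return objective(vec)

    best = init
    best_obj = evaluate(best)
    trace = [best_obj]
    if best_obj <= config.tolerance:
        return CalibrationResult(best, best_obj, np.array(trace), 0,
                                 StopReason.TOLERANCE, n_evals)

    rng = np.random.default_rng(config.rng_seed)
    if config.step_sizes is not None:
        steps = np.array([config.step_sizes.get(n, 0.1 * r)
                          for n, r in zip(names, ranges)])
    else:
        steps = 0.1 * ranges
    step_floor = config.step_floor_frac * ranges

    probs = estimate_sensitivity(best, objective, config.probe_step)
    n_evals += 2 * len(names) + 1  # probes billed by estimate_sensitivity

    start = time.monotonic()
    stagnation = 0
    stop = StopReason.MAX_ITER
    iteration = 0
    while iteration < config.max_iter:
        iteration += 1
        chosen = rng.choice(len(names), size=config.n_select,
                            replace=False, p=probs)
        candidates: List[Tuple[str, float]] = []
        for j in chosen:
            name, v = names[j], best.values[names[j]]
            for proposal in (min(v + steps[j], hi[j]),
                             max(v - steps[j], lo[j])):
                if proposal != v:
                    candidates.append((name, proposal))
        improved = False
        for name, proposal in candidates:
            cand = best.clipped({name: proposal})
            obj = evaluate(cand)
            if obj < best_obj:
                best, best_obj = cand, obj
                improved = True
        trace.append(best_obj)
        if improved:
            stagnation = 0
        else:
            stagnation += 1
            if stagnation >= config.stagnation_window:
                steps = np.maximum(steps * config.step_decay, step_floor)
                stagnation = 0
        if best_obj <= config.tolerance:
            stop = StopReason.TOLERANCE
            break
        if (config.time_limit is not None
                and time.monotonic() - start >= config.time_limit):
            stop = StopReason.TIME_LIMIT
            break
        if (config.sensitivity_refresh > 0
                and iteration % config.sensitivity_refresh == 0):
            probs = estimate_sensitivity(best, objective, config.probe_step)
            n_evals += 2 * len(names) + 1
    return CalibrationResult(best, best_obj, np.array(trace), iteration,
                             stop, n_evals)


# ---------------------------------------------------------------------------
# cross-year train/test protocol
# ---------------------------------------------------------------------------

@dataclass
class TrainTestReport:
    """Per-genotype train/test RRMSE with per-direction summaries."""

    per_genotype: pd.DataFrame
    summary: pd.DataFrame
    excluded: List[str] = field(default_factory=list)
    results: Dict[Tuple[str, str], CalibrationResult] = field(
        default_factory=dict)


def _series_for(groups, gid: str, year: int, weather: WeatherSeries,
                dates_for_year) -> List[SeriesData]:
    out = []
    for (g, y, _block), obs in groups.items():
        if g == gid and y == year:
            mgmt = dates_for_year(year, obs[0].stand_count)
            out.append(SeriesData.from_observations(obs, weather, mgmt))
    return out


def train_test_experiment(
    observations: Sequence[TrialObservation],
    weather_by_year: Mapping[int, WeatherSeries],
    config: CalibrationConfig,
    init: Optional[GenotypeParameterVector] = None,
    dates_for_year=None,
    directions: Optional[Sequence[Tuple[int, int]]] = None,
    include_combined: bool = True,
    genotype_ids: Optional[Sequence[str]] = None,
    is_ps: bool = True,
) -> TrainTestReport:
    """Cross-year calibration: train on one year, test on the other.

    For each genotype with data in both years and each (train, test)
    direction, the genotype vector is tuned on all of the training year's
    series and evaluated (pooled RRMSE) on the test year's series with that
    year's weather and management.  A combined-years training run (no held
    out test) is reported alongside.  Genotypes lacking a year are excluded
    and listed in the report.
    """
    from .synth import management_for_year  # default date source

    if dates_for_year is None:
        dates_for_year = management_for_year
    if init is None:
        init = GenotypeParameterVector()
    years = sorted(weather_by_year)
    if len(years) != 2:
        raise ValueError("exactly two years of weather are required")
    if directions is None:
        directions = [(years[0], years[1]), (years[1], years[0])]

    groups = trial_series(observations)
    gids = sorted({g for g, _, _ in groups})
    if genotype_ids is not None:
        gids = [g for g in gids if g in set(genotype_ids)]

    seed_seq = np.random.SeedSequence(config.rng_seed)
    rows = []
    report = TrainTestReport(per_genotype=pd.DataFrame(),
                             summary=pd.DataFrame())

    for gi, gid in enumerate(gids):
        have_years = {y for g, y, _ in groups if g == gid}
        if not set(years) <= have_years:
            report.excluded.append(gid)
            continue
        series_by_year = {
            y: _series_for(groups, gid, y, weather_by_year[y], dates_for_year)
            for y in years
        }
        sub_seeds = np.random.SeedSequence((config.rng_seed, gi)).spawn(
            len(directions) + 1)
        for di, (train_year, test_year) in enumerate(directions):
            cfg = CalibrationConfig(**{
                **config.__dict__,
                "rng_seed": int(sub_seeds[di].generate_state(1)[0] % (2 ** 31)),
            })
            result = tune_parameters([], init, cfg, is_ps=is_ps,
                                     _prepared=series_by_year[train_year])
            test_obj = pooled_objective(series_by_year[test_year], is_ps=is_ps)
            test_rrmse = test_obj(result.best_params)
            label = f"{train_year}->{test_year}"
            report.results[(gid, label)] = result
            rows.append({
                "genotype_id": gid, "direction": label,
                "train_rrmse": result.best_rrmse, "test_rrmse": test_rrmse,
            })
        if include_combined:
            cfg = CalibrationConfig(**{
                **config.__dict__,
                "rng_seed": int(sub_seeds[-1].generate_state(1)[0] % (2 ** 31)),
            })
            both = series_by_year[years[0]] + series_by_year[years[1]]
            result = tune_parameters([], init, cfg, is_ps=is_ps,
                                     _prepared=both)
            report.results[(gid, "combined")] = result
            rows.append({
                "genotype_id": gid, "direction": "combined",
                "train_rrmse": result.best_rrmse, "test_rrmse": np.nan,
            })

    per_genotype = pd.DataFrame(rows)
    report.per_genotype = per_genotype
    if len(per_genotype):
        report.summary = per_genotype.groupby("direction").agg(
            train_mean=("train_rrmse", "mean"),
            train_sd=("train_rrmse", "std"),
            test_mean=("test_rrmse", "mean"),
            test_sd=("test_rrmse", "std"),
            n_genotypes=("genotype_id", "nunique"),
        ).reset_index()
    return report
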