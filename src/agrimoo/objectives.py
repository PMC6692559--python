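"""Optimization objectives and nitrogen accounting.

Six objectives are computed from per-season simulator outputs: mean
yield, mean profit, mean N2O, change in SOC, nitrogen use efficiency and
annualized N surplus. Yield, N2O and profit are nine-season averages;
NUE and surplus are computed from inputs and outputs summed over the
whole simulation; delta-SOC is end minus start. Optimization directions
are fixed here and shared by every other module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import Calibration, DEFAULT_CALIBRATION, load_economics_defaults
from .surrogate import (
    ManagementPlan,
    SeasonResult,
    SoilProfile,
    WeatherSeries,
    simulate,
)

__all__ = [
    "OBJECTIVE_NAMES",
    "DIRECTIONS",
    "MINIMIZED",
    "EconomicParams",
    "ObjectiveVector",
    "mean_annual",
    "profit",
    "nue_and_surplus",
    "delta_soc",
    "eu_panel_compliance",
    "evaluate_plan",
]

#: Canonical objective order used in every array, CSV and frontier.
OBJECTIVE_NAMES = ("yield_mean", "profit_mean", "n2o_mean", "delta_soc", "nue", "n_surplus")

#: +1 = maximize, -1 = minimize. Single source of truth for all modules.
DIRECTIONS = np.array([1, 1, -1, 1, 1, -1], dtype=int)
DIRECTIONS.setflags(write=False)

#: Names of minimized objectives (plots conventionally invert these axes).
MINIMIZED = tuple(n for n, d in zip(OBJECTIVE_NAMES, DIRECTIONS) if d < 0)


@dataclass(frozen=True)
class EconomicParams:
    """Prices and costs entering the profit formula (GBP)."""

    crop_price: float = 150.0
    n_price_mineral: float = 0.79
    n_price_fym: float = 0.40
    p_cost_total: float = 360.0
    application_cost: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "crop_price",
            "n_price_mineral",
            "n_price_fym",
            "p_cost_total",
            "application_cost",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"economic parameter {name} must be >= 0")

    @classmethod
    def from_defaults_file(cls, path=None) -> "EconomicParams":
        return cls(**load_economics_defaults(path))


@dataclass(frozen=True)
class ObjectiveVector:
    yield_mean: float
    profit_mean: float
    n2o_mean: float
    delta_soc: float
    nue: float
    n_surplus: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.yield_mean,
                self.profit_mean,
                self.n2o_mean,
                self.delta_soc,
                self.nue,
                self.n_surplus,
            ]
        )

    @classmethod
    def from_array(cls, arr) -> "ObjectiveVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(OBJECTIVE_NAMES),):
            raise ValueError(f"objective array shape {arr.shape} != ({len(OBJECTIVE_NAMES)},)")
        return cls(*arr)


def mean_annual(values) -> float:
    """Arithmetic mean over seasons."""
    values = list(values)
    if not values:
        raise ValueError("mean_annual: empty list")
    return float(np.mean(values))


def profit(
    yields,
    plan: ManagementPlan,
    econ: EconomicParams,
    n_years: int,
    fym_n_per_t: float = DEFAULT_CALIBRATION.fym_n_per_t,
) -> float:
    """Average annual profit (GBP/ha/yr).

    Revenue from grain sales minus the cost of mineral and FYM nitrogen,
    the (fixed) P fertiliser cost and per-event application costs,
    divided by the number of years. Zero-rate applications incur no cost;
    a non-zero FYM dressing counts as one event per year.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    yields = list(yields)
    revenue = econ.crop_price * float(np.sum(yields))
    mineral_n_per_year = float(np.sum(plan.n_rates))
    fym_n_per_year = plan.fym_amount * fym_n_per_t
    n_cost = n_years * (
        mineral_n_per_year * econ.n_price_mineral + fym_n_per_year * econ.n_price_fym
    )
    events_per_year = sum(1 for r in plan.n_rates if r > 0) + (1 if plan.fym_amount > 0 else 0)
    application_cost = econ.application_cost * events_per_year * n_years
    return (revenue - n_cost - econ.p_cost_total - application_cost) / n_years


def nue_and_surplus(season_results: list[SeasonResult]) -> tuple[float, float]:
    """Whole-simulation NUE and annualized N surplus.

    Inputs and grain+straw outputs are summed over every season; NUE is
    their ratio and the surplus (inputs minus outputs) is divided by the
    number of seasons so its units are kg N/ha/yr.
    """
    if not season_results:
        raise ValueError("nue_and_surplus: no season results")
    inputs_total = sum(r.n_inputs for r in season_results)
    outputs_total = sum(r.n_outputs_grain_straw for r in season_results)
    if inputs_total <= 0:
        raise ValueError("total N inputs must be > 0")
    nue = outputs_total / inputs_total
    surplus = (inputs_total - outputs_total) / len(season_results)
    return nue, surplus


def delta_soc(season_results: list[SeasonResult]) -> float:
    """SOC change (%): final season's end value minus the initial value."""
    if not season_results:
        raise ValueError("delta_soc: no season results")
    return season_results[-1].soc_end - season_results[0].soc_start


def eu_panel_compliance(obj: ObjectiveVector) -> bool:
    """True iff NUE lies in [0.5, 0.9] and N surplus is below 80 kg/ha/yr."""
    return 0.5 <= obj.nue <= 0.9 and obj.n_surplus < 80.0


def evaluate_plan(
    plan: ManagementPlan,
    soil: SoilProfile,
    weather: WeatherSeries,
    econ: EconomicParams,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> ObjectiveVector:
    """Simulate a plan and assemble the six-objective vector."""
    results = simulate(plan, soil, weather, calib)
    yields = [r.yield_t_ha for r in results]
    nue, surplus = nue_and_surplus(results)
    return ObjectiveVector(
        yield_mean=mean_annual(yields),
        profit_mean=profit(yields, plan, econ, len(results), calib.fym_n_per_t),
        n2o_mean=mean_annual([r.n2o_co2eq for r in results]),
        delta_soc=delta_soc(results),
        nue=nue,
        n_surplus=surplus,
    )
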