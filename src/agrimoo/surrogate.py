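"""Surrogate crop-soil simulator.

A deterministic, seed-reproducible stand-in for a daily process-based
crop model. It maps an 11-gene management plan (nine biweekly mineral-N
applications, a farm-yard-manure amount and its pre-sowing timing) plus a
soil profile and a synthetic daily-rain weather stream to per-season
outputs: grain yield, N2O emissions (CO2-equivalent), leached N, the SOC
trajectory and the nitrogen input/output ledger.

The response structure is qualitative by design:

* yield follows a saturating (Mitscherlich) curve in effective N, capped
  at the soil's potential yield;
* N2O grows super-linearly in total N input and increases with clay
  content, so fine-textured soils emit more at equal management;
* FYM raises both SOC and N2O;
* leaching losses increase with sand fraction.

All coefficients live in :mod:`agrimoo.calibration`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .calibration import Calibration, DEFAULT_CALIBRATION

__all__ = [
    "ValidationError",
    "SoilProfile",
    "ManagementPlan",
    "WeatherSeries",
    "SeasonResult",
    "load_soils",
    "schedule_applications",
    "yield_response",
    "n2o_emission",
    "soc_update",
    "simulate",
    "management_bounds",
    "N_APPLICATIONS",
    "GENOME_LENGTH",
    "GENOME_NAMES",
]

N_APPLICATIONS = 9
APPLICATION_INTERVAL_DAYS = 14
MAX_N_RATE = 100.0
MAX_FYM_AMOUNT = 3.0
MAX_FYM_WEEKS = 3
GENOME_LENGTH = N_APPLICATIONS + 2

GENOME_NAMES = tuple(f"n_rate_{i + 1}" for i in range(N_APPLICATIONS)) + (
    "fym_amount",
    "fym_weeks_before_sowing",
)

# Sowing is fixed at 1 October so "weeks before sowing" resolves to a date;
# only the week count affects the simulated FYM availability.
SOWING_DATE = "1 October"


class ValidationError(ValueError):
    """Raised when a domain object violates its declared bounds."""


@dataclass(frozen=True)
class SoilProfile:
    """Topsoil characterisation plus the surrogate's potential-yield knob."""

    name: str
    clay_frac: float
    silt_frac: float
    sand_frac: float
    soc_init: float
    ph: float
    bulk_density: float
    y_pot: float

    def __post_init__(self) -> None:
        total = self.clay_frac + self.silt_frac + self.sand_frac
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"soil {self.name!r}: texture fractions sum to {total}, expected 1"
            )
        if self.soc_init <= 0:
            raise ValidationError(f"soil {self.name!r}: soc_init must be > 0")
        if self.y_pot <= 0:
            raise ValidationError(f"soil {self.name!r}: y_pot must be > 0")


def load_soils(path: str | Path | None = None) -> dict[str, SoilProfile]:
    """Load soil profiles from a CSV fixture (packaged table by default).

    Columns: name, clay_pct, silt_pct, sand_pct, soc_pct, ph,
    bulk_density, y_pot. Texture percentages are converted to fractions.
    """
    if path is None:
        ref = resources.files("agrimoo.data").joinpath("soils.csv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    soils: dict[str, SoilProfile] = {}
    for row in csv.DictReader(text.splitlines()):
        soil = SoilProfile(
            name=row["name"],
            clay_frac=float(row["clay_pct"]) / 100.0,
            silt_frac=float(row["silt_pct"]) / 100.0,
            sand_frac=float(row["sand_pct"]) / 100.0,
            soc_init=float(row["soc_pct"]),
            ph=float(row["ph"]),
            bulk_density=float(row["bulk_density"]),
            y_pot=float(row["y_pot"]),
        )
        soils[soil.name] = soil
    return soils


@dataclass(frozen=True)
class ManagementPlan:
    """The 11-gene management genome.

    ``n_rates`` holds the nine mineral-N application amounts (kg N/ha,
    each in [0, 100]); the first can be applied on 1 March, subsequent
    ones at two-week intervals. ``fym_amount`` is the farm-yard-manure
    dressing (t/ha in [0, 3]) applied ``fym_weeks_before_sowing`` weeks
    (integer 0-3) ahead of sowing.
    """

    n_rates: tuple[float, ...]
    fym_amount: float = 0.0
    fym_weeks_before_sowing: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_rates", tuple(float(r) for r in self.n_rates))
        self.validate()

    def validate(self) -> None:
        if len(self.n_rates) != N_APPLICATIONS:
            raise ValidationError(
                f"n_rates has {len(self.n_rates)} entries, expected {N_APPLICATIONS}"
            )
        for i, r in enumerate(self.n_rates):
            if not (0.0 <= r <= MAX_N_RATE):
                raise ValidationError(
                    f"gene n_rate_{i + 1} = {r} outside [0, {MAX_N_RATE}]"
                )
        if not (0.0 <= self.fym_amount <= MAX_FYM_AMOUNT):
            raise ValidationError(
                f"gene fym_amount = {self.fym_amount} outside [0, {MAX_FYM_AMOUNT}]"
            )
        w = self.fym_weeks_before_sowing
        if w != int(w) or not (0 <= int(w) <= MAX_FYM_WEEKS):
            raise ValidationError(
                f"gene fym_weeks_before_sowing = {w} not an integer in [0, {MAX_FYM_WEEKS}]"
            )

    def to_genome(self) -> np.ndarray:
        """Flatten to an 11-vector (nine N rates, FYM amount, FYM timing)."""
        return np.array(
            list(self.n_rates) + [self.fym_amount, float(self.fym_weeks_before_sowing)]
        )

    @classmethod
    def from_genome(cls, genome: np.ndarray) -> "ManagementPlan":
        genome = np.asarray(genome, dtype=float)
        if genome.shape != (GENOME_LENGTH,):
            raise ValidationError(f"genome shape {genome.shape}, expected ({GENOME_LENGTH},)")
        return cls(
            n_rates=tuple(genome[:N_APPLICATIONS]),
            fym_amount=float(genome[N_APPLICATIONS]),
            fym_weeks_before_sowing=int(round(genome[N_APPLICATIONS + 1])),
        )


def management_bounds() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Box bounds and integer mask for the flattened management genome."""
    lower = np.zeros(GENOME_LENGTH)
    upper = np.array([MAX_N_RATE] * N_APPLICATIONS + [MAX_FYM_AMOUNT, float(MAX_FYM_WEEKS)])
    integer_mask = np.zeros(GENOME_LENGTH, dtype=bool)
    integer_mask[-1] = True
    return lower, upper, integer_mask


class WeatherSeries:
    """Synthetic per-season daily rain grid, reproducible from a seed.

    Day 0 of each season is 1 March. Rain days are i.i.d. Bernoulli draws
    with probability ``rain_prob``; identical seeds give identical grids.
    """

    def __init__(self, rain_days: np.ndarray, rng_seed: int | None = None):
        rain_days = np.asarray(rain_days, dtype=bool)
        if rain_days.ndim != 2:
            raise ValidationError("rain_days must be 2-D (seasons x days)")
        self.rain_days = rain_days
        self.rng_seed = rng_seed
        self.n_seasons = rain_days.shape[0]
        self.n_days = rain_days.shape[1]
        self._next_dry = self._build_next_dry(rain_days)

    @staticmethod
    def _build_next_dry(rain: np.ndarray) -> np.ndarray:
        # next_dry[s, d] = first day >= d with no rain (n_days if none).
        n_seasons, n_days = rain.shape
        nd = np.empty((n_seasons, n_days + 1), dtype=np.int64)
        nd[:, n_days] = n_days
        for d in range(n_days - 1, -1, -1):
            nd[:, d] = np.where(rain[:, d], nd[:, d + 1], d)
        return nd

    @classmethod
    def generate(
        cls,
        seed: int,
        n_seasons: int = 9,
        n_days: int | None = None,
        rain_prob: float | None = None,
        calib: Calibration = DEFAULT_CALIBRATION,
    ) -> "WeatherSeries":
        n_days = calib.n_days if n_days is None else n_days
        rain_prob = calib.rain_prob if rain_prob is None else rain_prob
        rng = np.random.default_rng(seed)
        rain = rng.random((n_seasons, n_days)) < rain_prob
        return cls(rain, rng_seed=seed)

    def next_dry_day(self, season: int, day: int) -> int:
        return int(self._next_dry[season, min(day, self.n_days)])

    def wetness(self, season: int) -> float:
        """Fraction of rain days in a season."""
        return float(self.rain_days[season].mean())


@dataclass(frozen=True)
class SeasonResult:
    """Per-season outputs of the surrogate."""

    season: int
    yield_t_ha: float
    n2o_co2eq: float
    n_leached: float
    n_inputs: float
    n_outputs_grain_straw: float
    soc_start: float
    soc_end: float


def schedule_applications(
    plan: ManagementPlan, weather: WeatherSeries, season: int
) -> list[tuple[int, float]]:
    """Resolve the nine nominal application dates against the rain grid.

    Application ``i`` is nominally due on day ``14 * i`` (day 0 = 1 March)
    and slides forward one day at a time until the first non-rain day.
    Zero-rate applications are omitted. Returns ``(day, rate)`` pairs in
    application order.
    """
    if not (0 <= season < weather.n_seasons):
        raise IndexError(f"season {season} out of range [0, {weather.n_seasons})")
    out = []
    for i, rate in enumerate(plan.n_rates):
        if rate > 0.0:
            nominal = i * APPLICATION_INTERVAL_DAYS
            out.append((weather.next_dry_day(season, nominal), rate))
    return out


def yield_response(
    effective_n: float, soil: SoilProfile, calib: Calibration = DEFAULT_CALIBRATION
) -> float:
    """Saturating Mitscherlich yield response to effective N (t/ha).

    ``y = y_pot * (1 - exp(-(effective_n + n_background) / n_scale))``:
    strictly increasing, concave, asymptoting at the soil's ``y_pot``.
    """
    if effective_n < 0:
        raise ValueError(f"effective_n must be >= 0, got {effective_n}")
    return soil.y_pot * (1.0 - math.exp(-(effective_n + calib.n_background) / calib.n_scale))


def n2o_emission(
    total_n_input: float,
    fym_amount: float,
    soil: SoilProfile,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> float:
    """Convex N2O response (t CO2-eq/ha/yr), increasing with clay content."""
    if total_n_input < 0 or fym_amount < 0:
        raise ValueError("N input and FYM amount must be >= 0")
    texture_factor = calib.n2o_texture_base + calib.n2o_texture_clay * soil.clay_frac
    return texture_factor * (
        calib.n2o_e0
        + calib.n2o_e1 * total_n_input**calib.n2o_alpha
        + calib.n2o_e2 * fym_amount
    )


def soc_update(
    soc_prev: float,
    fym_amount: float,
    residue_c: float,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> float:
    """One-season SOC recurrence: gains from FYM and residues, first-order decay."""
    if soc_prev <= 0:
        raise ValueError("soc_prev must be > 0")
    return (
        soc_prev
        + calib.soc_h_fym * fym_amount
        + calib.soc_h_res * residue_c
        - calib.soc_decay * soc_prev
    )


def simulate(
    plan: ManagementPlan,
    soil: SoilProfile,
    weather: WeatherSeries,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> list[SeasonResult]:
    """Run the surrogate over all seasons of ``weather``.

    Effective N for yield is scheduled mineral N weighted by a mild
    per-slot uptake bonus, plus available FYM N, reduced by the
    texture-dependent leaching fraction and a wetness factor for seasons
    departing from the calibration rain frequency. The N ledger counts
    mineral N, FYM N and a constant atmospheric-deposition term on the
    input side and grain plus straw N removal on the output side.
    """
    plan.validate()
    rates = np.asarray(plan.n_rates)
    slot_eff = 1.0 + calib.timing_bonus * np.arange(N_APPLICATIONS)
    mineral_total = float(rates.sum())
    mineral_effective = float((rates * slot_eff).sum())
    fym_n = plan.fym_amount * calib.fym_n_per_t
    fym_available = fym_n * (
        calib.fym_avail_base + calib.fym_avail_week * plan.fym_weeks_before_sowing
    )
    leach_frac = calib.leach_base + calib.leach_sand * soil.sand_frac
    n_leached = leach_frac * (mineral_total + fym_n)
    base_effective = (mineral_effective + fym_available) * (1.0 - leach_frac)
    n2o = n2o_emission(mineral_total + fym_n, plan.fym_amount, soil, calib)
    n_inputs = mineral_total + fym_n + calib.deposition

    results = []
    soc = soil.soc_init
    for season in range(weather.n_seasons):
        wet = weather.wetness(season)
        wet_factor = max(
            0.0,
            1.0
            - calib.yield_wetness_sens
            * abs(wet - calib.rain_prob)
            / max(calib.rain_prob, 1e-12),
        )
        yield_t = yield_response(base_effective * wet_factor, soil, calib)
        residue_c = calib.residue_c_per_yield * yield_t
        soc_next = soc_update(soc, plan.fym_amount, residue_c, calib)
        n_outputs = yield_t * (
            calib.grain_n_per_t + calib.straw_ratio * calib.straw_n_per_t
        )
        results.append(
            SeasonResult(
                season=season,
                yield_t_ha=yield_t,
                n2o_co2eq=n2o,
                n_leached=n_leached,
                n_inputs=n_inputs,
                n_outputs_grain_straw=n_outputs,
                soc_start=soc,
                soc_end=soc_next,
            )
        )
        soc = soc_next
    return results
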