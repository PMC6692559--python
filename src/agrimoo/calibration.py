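"""Calibration constants for the surrogate simulator.

All surrogate constants are read from a single plain-text TOML file
(``data/calibration.toml`` by default) so that every invented coefficient
is named and documented in one place.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class Calibration:
    """Typed view of the surrogate calibration file."""

    # yield response
    n_background: float
    n_scale: float
    # N2O emission
    n2o_e0: float
    n2o_e1: float
    n2o_alpha: float
    n2o_e2: float
    n2o_texture_base: float
    n2o_texture_clay: float
    # SOC recurrence
    soc_h_fym: float
    soc_h_res: float
    soc_decay: float
    residue_c_per_yield: float
    # nitrogen bookkeeping
    deposition: float
    fym_n_per_t: float
    fym_avail_base: float
    fym_avail_week: float
    leach_base: float
    leach_sand: float
    timing_bonus: float
    # crop N removal
    grain_n_per_t: float
    straw_ratio: float
    straw_n_per_t: float
    # weather
    rain_prob: float
    n_days: int
    yield_wetness_sens: float

    @classmethod
    def from_mapping(cls, raw: dict) -> "Calibration":
        y, n2o, soc = raw["yield"], raw["n2o"], raw["soc"]
        nit, crop, wx = raw["nitrogen"], raw["crop"], raw["weather"]
        return cls(
            n_background=float(y["n_background"]),
            n_scale=float(y["n_scale"]),
            n2o_e0=float(n2o["e0"]),
            n2o_e1=float(n2o["e1"]),
            n2o_alpha=float(n2o["alpha"]),
            n2o_e2=float(n2o["e2"]),
            n2o_texture_base=float(n2o["texture_base"]),
            n2o_texture_clay=float(n2o["texture_clay"]),
            soc_h_fym=float(soc["h_fym"]),
            soc_h_res=float(soc["h_res"]),
            soc_decay=float(soc["decay"]),
            residue_c_per_yield=float(soc["residue_c_per_yield"]),
            deposition=float(nit["deposition"]),
            fym_n_per_t=float(nit["fym_n_per_t"]),
            fym_avail_base=float(nit["fym_avail_base"]),
            fym_avail_week=float(nit["fym_avail_week"]),
            leach_base=float(nit["leach_base"]),
            leach_sand=float(nit["leach_sand"]),
            timing_bonus=float(nit["timing_bonus"]),
            grain_n_per_t=float(crop["grain_n_per_t"]),
            straw_ratio=float(crop["straw_ratio"]),
            straw_n_per_t=float(crop["straw_n_per_t"]),
            rain_prob=float(wx["rain_prob"]),
            n_days=int(wx["n_days"]),
            yield_wetness_sens=float(wx["yield_wetness_sens"]),
        )


def _read_toml(path: Path | None = None) -> dict:
    if path is not None:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    ref = resources.files("agrimoo.data").joinpath("calibration.toml")
    with ref.open("rb") as fh:
        return tomllib.load(fh)


def load_calibration(path: str | Path | None = None) -> Calibration:
    """Load calibration constants from ``path`` or the packaged defaults."""
    return Calibration.from_mapping(_read_toml(Path(path) if path else None))


def load_economics_defaults(path: str | Path | None = None) -> dict:
    """Return the ``[economics]`` block of the calibration file as a dict."""
    return dict(_read_toml(Path(path) if path else None)["economics"])


DEFAULT_CALIBRATION = load_calibration()
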