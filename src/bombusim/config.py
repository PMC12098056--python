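"""General parameter file: parsing and validation.

The configuration mirrors the general-parameter-file convention of the
NetLogo lineage this model descends from: the handling engine is switched
by the Boolean key ``FixedHandlingTime?`` (TRUE/FALSE accepted alongside
true/false), its constant by ``FixedHandlingTime_s``, and the foraging
hazard by ``ForagingMortalityModel`` ∈ {high, intermediate, low}. Unknown
keys are rejected — a silently ignored typo in a parameter file is worse
than an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as _fields
from pathlib import Path as _Path
from typing import Any, Mapping, Optional

import yaml

from .colony import ColonyParams
from .handling import HandlingConfig
from .landscape import LandscapeSpec
from .mortality import MORTALITY_MODELS

__all__ = ["GeneralConfig", "parse_config", "CONFIG_KEYS"]

#: External key -> (attribute, type) map. Types: bool/float/int/str/dict.
CONFIG_KEYS: dict[str, tuple[str, type]] = {
    "FixedHandlingTime?": ("fixed_handling_enabled", bool),
    "FixedHandlingTime_s": ("fixed_handling_time_s", float),
    "ForagingMortalityModel": ("foraging_mortality_model", str),
    "Tmax_s": ("t_max_s", float),
    "FlightSpeed_m_s": ("flight_speed_m_s", float),
    "CropCapacity_ul": ("crop_capacity_ul", float),
    "Years": ("years", int),
    "InitialQueens": ("initial_queens", int),
    "Replicates": ("replicates", int),
    "MasterSeed": ("master_seed", int),
    "LandscapeFile": ("landscape_file", str),
    "FlowerSpeciesFile": ("flower_species_file", str),
    "BeeSpeciesFile": ("bee_species_file", str),
    "Landscape": ("landscape", dict),
    "ColonyParams": ("colony_params", dict),
}


@dataclass(frozen=True)
class GeneralConfig:
    """Validated run configuration with documented defaults."""

    fixed_handling_enabled: bool = False       # FixedHandlingTime?
    fixed_handling_time_s: float = 900.0       # FixedHandlingTime_s
    foraging_mortality_model: str = "high"     # ForagingMortalityModel (default)
    t_max_s: float = 3600.0
    flight_speed_m_s: float = 5.0
    crop_capacity_ul: float = 120.0
    years: int = 5
    initial_queens: int = 100
    replicates: int = 20
    master_seed: int = 0
    landscape_file: Optional[str] = None
    flower_species_file: Optional[str] = None
    bee_species_file: Optional[str] = None
    landscape: LandscapeSpec = field(default_factory=LandscapeSpec)
    colony_params: ColonyParams = field(default_factory=ColonyParams)

    def handling_config(self) -> HandlingConfig:
        return HandlingConfig(
            fixed_handling_enabled=self.fixed_handling_enabled,
            fixed_handling_time_s=self.fixed_handling_time_s,
            t_max_s=self.t_max_s,
            flight_speed_m_s=self.flight_speed_m_s,
            crop_capacity_ul=self.crop_capacity_ul,
        )


def _parse_bool(key: str, value: Any) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.upper() in ("TRUE", "FALSE"):
        return value.upper() == "TRUE"
    raise ValueError(f"{key}: expected TRUE/FALSE or true/false, got {value!r}")


def parse_config(source: str | _Path | Mapping[str, Any]) -> GeneralConfig:
    """Parse a YAML file path or an in-memory mapping into a GeneralConfig.

    Raises ValueError naming the offending key on unknown keys, type
    mismatches and out-of-range values.
    """
    if isinstance(source, (str, _Path)):
        with open(source, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh) or {}
    else:
        mapping = dict(source)
    if not isinstance(mapping, Mapping):
        raise ValueError("config must be a mapping of parameter keys to values")

    kwargs: dict[str, Any] = {}
    for key, value in mapping.items():
        if key not in CONFIG_KEYS:
            valid = ", ".join(sorted(CONFIG_KEYS))
            raise ValueError(f"unknown config key {key!r}; valid keys: {valid}")
        attr, typ = CONFIG_KEYS[key]
        if typ is bool:
            kwargs[attr] = _parse_bool(key, value)
        elif typ is dict:
            if not isinstance(value, Mapping):
                raise ValueError(f"{key}: expected a mapping, got {value!r}")
            kwargs[attr] = dict(value)
        elif typ in (int, float):
            try:
                parsed = typ(value)
            except (TypeError, ValueError):
                raise ValueError(f"{key}: expected {typ.__name__}, got {value!r}") from None
            if isinstance(value, bool):
                raise ValueError(f"{key}: expected {typ.__name__}, got a boolean")
            kwargs[attr] = parsed
        else:
            kwargs[attr] = str(value)

    if "landscape" in kwargs:
        try:
            kwargs["landscape"] = LandscapeSpec(**kwargs["landscape"])
        except TypeError as exc:
            raise ValueError(f"Landscape: {exc}") from exc
    if "colony_params" in kwargs:
        try:
            kwargs["colony_params"] = ColonyParams(**kwargs["colony_params"])
        except TypeError as exc:
            raise ValueError(f"ColonyParams: {exc}") from exc

    cfg = GeneralConfig(**kwargs)

    if cfg.foraging_mortality_model not in MORTALITY_MODELS:
        valid = ", ".join(sorted(MORTALITY_MODELS))
        raise ValueError(
            f"ForagingMortalityModel: {cfg.foraging_mortality_model!r} is not one of "
            f"{{{valid}}}"
        )
    for key, attr in (("FixedHandlingTime_s", "fixed_handling_time_s"),
                      ("Tmax_s", "t_max_s"),
                      ("FlightSpeed_m_s", "flight_speed_m_s"),
                      ("CropCapacity_ul", "crop_capacity_ul")):
        if getattr(cfg, attr) <= 0:
            raise ValueError(f"{key}: must be > 0")
    for key, attr in (("Years", "years"), ("InitialQueens", "initial_queens"),
                      ("Replicates", "replicates")):
        if getattr(cfg, attr) < 1:
            raise ValueError(f"{key}: must be >= 1")
    return cfg
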