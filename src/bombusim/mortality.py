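"""Foraging mortality: three per-second hazard models and per-trip survival.

Foraging is the risky activity of the model; the hazard applies for the full
duration of every foraging trip. Three published rates are built in:

* ``high`` — 1×10⁻⁵ s⁻¹, a honeybee-derived rate (the model default),
* ``intermediate`` — 2.14×10⁻⁶ s⁻¹, measured for *Bombus lucorum*,
* ``low`` — 2.75×10⁻⁷ s⁻¹, a multi-species, multi-site estimate including
  *Bombus terrestris*.

Survival over a trip of duration F uses the exponential hazard
exp(−r·F); at these rates it agrees with (1−r)^F to well under 0.1% and is
additive in exposure time.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["MORTALITY_MODELS", "mortality_rate", "trip_survival", "sample_death"]

#: Per-second foraging mortality hazards (s^-1).
MORTALITY_MODELS: dict[str, float] = {
    "high": 1e-5,
    "intermediate": 2.14e-6,
    "low": 2.75e-7,
}


def mortality_rate(name: str) -> float:
    """Hazard (s⁻¹) for a named mortality model."""
    try:
        return MORTALITY_MODELS[name]
    except KeyError:
        valid = ", ".join(sorted(MORTALITY_MODELS))
        raise ValueError(
            f"unknown ForagingMortalityModel {name!r}; valid names: {valid}"
        ) from None


def trip_survival(rate_per_s: float, trip_s: float) -> float:
    """P(survive a trip of duration ``trip_s``) = exp(−rate·trip)."""
    if rate_per_s < 0 or trip_s < 0:
        raise ValueError("rate and trip duration must be >= 0")
    return math.exp(-rate_per_s * trip_s)


def sample_death(rng: np.random.Generator, survival_p: float) -> bool:
    """One Bernoulli(1 − survival_p) draw: True means the forager died."""
    if not (0.0 <= survival_p <= 1.0):
        raise ValueError("survival_p must lie in [0, 1]")
    return rng.random() >= survival_p
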