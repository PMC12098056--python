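"""Foraging trip durations: the two handling-time engines.

A nectar foraging trip lasts

    F = 2·Δs/v + Th                                    (trip duration)

i.e. the out-and-back flight plus the handling time Th needed to gather one
crop load on the patch. Two engines compute Th:

*Mechanistic (Harder) engine.* Per flower, the access time Ta and the
between-flower travel time Tt scale with the patch filling level γ, and the
ingestion time Ti follows Harder's laboratory regressions on bee weight W,
glossa length G, corolla depth C and per-flower nectar volume V:

    Th = ((Tt + Ta)/γ + Ti) · Nflowers,  capped at Tmax
    Ta = 0.3 + 0.04·C
    Ti = log10(V + 1) / log10(0.3·W^(1/3)·G^1.41·(1 − C/G)^0.4) − 0.3·Ta + 1

Ti has a vertical asymptote where the log10 argument reaches 1 (the
corolla-depth/glossa-length pole); at or past the pole — including C ≥ G,
where the nectar is out of reach — the ingestion time is unbounded and the
engine reports a sentinel that the Tmax cap absorbs.

*Fixed engine.* Th is a configured constant, still depletion-scaled and
capped:

    Th = FixedHandlingTime_s / γ   if below Tmax, else Tmax

The cap exists to keep nearly-emptied patches (γ → 0) from producing
unphysically long trips; a fixed handling time equal to Tmax therefore makes
depletion irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UNBOUNDED",
    "HandlingConfig",
    "ForagerTraits",
    "HandlingResult",
    "access_time",
    "ingestion_time",
    "n_flowers_per_load",
    "harder_handling_time",
    "fixed_handling_time",
    "trip_duration",
    "harder_th_array",
    "fixed_th_array",
]

#: Sentinel for an unbounded ingestion/handling time (at/past the pole, or
#: an empty patch); downstream capping maps it to Tmax.
UNBOUNDED = math.inf


@dataclass(frozen=True)
class HandlingConfig:
    """Engine configuration, populated from the general parameter file.

    ``fixed_handling_enabled`` mirrors the ``FixedHandlingTime?`` switch and
    ``fixed_handling_time_s`` the ``FixedHandlingTime_s`` value. Defaults:
    Tmax = 3600 s, flight speed v = 5 m/s, crop capacity 120 µl.
    """

    fixed_handling_enabled: bool = False
    fixed_handling_time_s: float = 900.0
    t_max_s: float = 3600.0
    flight_speed_m_s: float = 5.0
    crop_capacity_ul: float = 120.0

    def __post_init__(self) -> None:
        for name in ("fixed_handling_time_s", "t_max_s", "flight_speed_m_s",
                     "crop_capacity_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ForagerTraits:
    """Morphology entering the Harder equation: glossa length G and weight W."""

    glossa_mm: float
    weight_g: float = 0.195

    def __post_init__(self) -> None:
        if self.glossa_mm <= 0:
            raise ValueError("glossa_mm must be > 0")
        if self.weight_g <= 0:
            raise ValueError("weight_g must be > 0")


@dataclass(frozen=True)
class HandlingResult:
    per_flower_access_s: float
    per_flower_ingest_s: float
    n_flowers: int
    total_handling_s: float
    capped: bool


def access_time(corolla_depth_mm: float) -> float:
    """Time to access one flower: Ta = 0.3 + 0.04·C (s, C in mm)."""
    if corolla_depth_mm < 0:
        raise ValueError("corolla_depth_mm must be >= 0")
    return 0.3 + 0.04 * corolla_depth_mm


def ingestion_time(
    nectar_volume_ul: float,
    traits: ForagerTraits,
    corolla_depth_mm: float,
    access_s: float,
) -> float:
    """Per-flower ingestion time Ti (s) from Harder's regression.

    Returns :data:`UNBOUNDED` when the corolla is as deep as (or deeper
    than) the glossa, or when the evaluation sits at/past the pole of the
    regression (log10 argument ≤ 1), where the model ceases to describe a
    finite drinking time.
    """
    V, C, G, W = nectar_volume_ul, corolla_depth_mm, traits.glossa_mm, traits.weight_g
    if not all(map(math.isfinite, (V, C, G, W, access_s))):
        raise ValueError("ingestion_time requires finite inputs")
    if V < 0 or C < 0:
        raise ValueError("nectar volume and corolla depth must be >= 0")
    if C >= G:
        return UNBOUNDED
    arg = 0.3 * W ** (1.0 / 3.0) * G ** 1.41 * (1.0 - C / G) ** 0.4
    if arg <= 1.0:  # at/past the pole: denominator log10(arg) <= 0
        return UNBOUNDED
    ti = math.log10(V + 1.0) / math.log10(arg) - 0.3 * access_s + 1.0
    return ti if ti > 0 else UNBOUNDED


def n_flowers_per_load(crop_capacity_ul: float, nectar_volume_ul: float) -> int:
    """Flowers needed for one crop load: ceil(crop/V), at least 1."""
    if crop_capacity_ul <= 0 or nectar_volume_ul <= 0:
        raise ValueError("crop capacity and per-flower volume must be > 0")
    return max(1, math.ceil(crop_capacity_ul / nectar_volume_ul))


def harder_handling_time(
    interflower_travel_s: float,
    access_s: float,
    ingest_s: float,
    gamma: float,
    n_flowers: int,
    t_max_s: float = 3600.0,
) -> HandlingResult:
    """Total handling time Th = ((Tt + Ta)/γ + Ti)·Nflowers, capped at Tmax.

    γ = 0 (empty patch) and an unbounded Ti both yield the cap.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    if n_flowers < 1:
        raise ValueError("n_flowers must be >= 1")
    if gamma == 0.0 or not math.isfinite(ingest_s):
        return HandlingResult(access_s, ingest_s, n_flowers, t_max_s, True)
    th = ((interflower_travel_s + access_s) / gamma + ingest_s) * n_flowers
    if th >= t_max_s:
        return HandlingResult(access_s, ingest_s, n_flowers, t_max_s, True)
    return HandlingResult(access_s, ingest_s, n_flowers, th, False)


def fixed_handling_time(
    fixed_s: float, gamma: float, t_max_s: float = 3600.0
) -> HandlingResult:
    """Fixed-engine handling time Th = fixed_s/γ, capped at Tmax.

    Independent of flower and bee morphology by construction; γ = 0 yields
    the cap.
    """
    if fixed_s <= 0:
        raise ValueError("fixed_s must be > 0")
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    if gamma == 0.0:
        return HandlingResult(0.0, 0.0, 1, t_max_s, True)
    th = fixed_s / gamma
    if th >= t_max_s:
        return HandlingResult(0.0, 0.0, 1, t_max_s, True)
    return HandlingResult(0.0, 0.0, 1, th, False)


def trip_duration(distance_m: float, flight_speed_m_s: float, handling_s: float) -> float:
    """Trip duration F = 2·Δs/v + Th (s)."""
    if distance_m < 0 or handling_s < 0:
        raise ValueError("distance and handling time must be >= 0")
    if flight_speed_m_s <= 0:
        raise ValueError("flight_speed_m_s must be > 0")
    return 2.0 * distance_m / flight_speed_m_s + handling_s


# ---------------------------------------------------------------------------
# Vectorised forms (per-candidate-patch evaluation during patch choice)
# ---------------------------------------------------------------------------

def fixed_th_array(fixed_s: float, gamma: np.ndarray, t_max_s: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        th = np.where(gamma > 0, fixed_s / np.maximum(gamma, 1e-300), np.inf)
    return np.minimum(th, t_max_s)


def harder_th_array(
    interflower_travel_s: np.ndarray,
    corolla_depth_mm: np.ndarray,
    nectar_volume_ul: np.ndarray,
    gamma: np.ndarray,
    traits: ForagerTraits,
    crop_capacity_ul: float,
    t_max_s: float,
) -> np.ndarray:
    """Harder-engine Th for arrays of patches, identical semantics to the
    scalar chain access→ingest→n_flowers→total."""
    G, W = traits.glossa_mm, traits.weight_g
    ta = 0.3 + 0.04 * corolla_depth_mm
    frac = 1.0 - corolla_depth_mm / G
    base = 0.3 * W ** (1.0 / 3.0) * G ** 1.41
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = np.where(frac > 0, base * np.maximum(frac, 0.0) ** 0.4, 0.0)
        den = np.log10(np.maximum(arg, 1e-300))
        ti = np.where(
            arg > 1.0,
            np.log10(nectar_volume_ul + 1.0) / den - 0.3 * ta + 1.0,
            np.inf,
        )
    ti = np.where(ti > 0, ti, np.inf)
    n = np.maximum(1, np.ceil(crop_capacity_ul / nectar_volume_ul))
    with np.errstate(divide="ignore", invalid="ignore"):
        th = np.where(
            gamma > 0,
            ((interflower_travel_s + ta) / np.maximum(gamma, 1e-300) + ti) * n,
            np.inf,
        )
    return np.minimum(th, t_max_s)
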