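"""Floral resources: flower species, food-source patches, depletion and refill.

A landscape is a set of point patches, each monospecific, holding a daily
nectar stock (µl) and pollen stock (g). The *filling level* γ of a patch is
its current nectar stock over its daily capacity — a volume-based proxy for
the fraction of flowers still filled — and feeds straight into the
handling-time engines: emptier patches take longer to work.

Stocks reset to capacity once per day while the species is in flower and are
zero outside the flowering window (daily-turnover model; there is no
sub-daily secretion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path as _Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlowerSpecies",
    "Patch",
    "Landscape",
    "filling_level",
    "deplete",
    "replenish_daily",
    "read_species_table",
    "write_species_table",
    "SPECIES_COLUMNS",
]

SPECIES_COLUMNS = [
    "name",
    "corolla_depth_mm",
    "nectar_volume_ul",
    "interflower_travel_s",
    "pollen_per_flower_g",
    "flowering_start_doy",
    "flowering_end_doy",
    "sugar_energy_kj_per_ul",
]


@dataclass(frozen=True)
class FlowerSpecies:
    """Per-species floral parameters.

    corolla_depth_mm is C in the access/ingestion models, nectar_volume_ul
    the per-flower standing crop V, interflower_travel_s the constant
    between-flower travel time Tt. The flowering window is inclusive on both
    ends, in day-of-year units (no leap days; years are 365 days).
    """

    name: str
    corolla_depth_mm: float
    nectar_volume_ul: float
    interflower_travel_s: float
    pollen_per_flower_g: float = 0.0
    flowering_start_doy: int = 1
    flowering_end_doy: int = 365
    sugar_energy_kj_per_ul: float = 0.01

    def __post_init__(self) -> None:
        if self.corolla_depth_mm < 0:
            raise ValueError(f"{self.name}: corolla_depth_mm must be >= 0")
        if self.nectar_volume_ul <= 0:
            raise ValueError(f"{self.name}: nectar_volume_ul must be > 0")
        if self.interflower_travel_s < 0:
            raise ValueError(f"{self.name}: interflower_travel_s must be >= 0")
        if not (1 <= self.flowering_start_doy <= self.flowering_end_doy <= 365):
            raise ValueError(
                f"{self.name}: flowering window must satisfy "
                "1 <= start <= end <= 365"
            )

    def in_flower(self, day_of_year: int) -> bool:
        return self.flowering_start_doy <= day_of_year <= self.flowering_end_doy


@dataclass
class Patch:
    """A point food source of a single flower species."""

    patch_id: int
    x_m: float
    y_m: float
    species: FlowerSpecies
    n_flowers: int
    nectar_capacity_ul: float
    nectar_stock_ul: float
    pollen_capacity_g: float = 0.0
    pollen_stock_g: float = 0.0
    habitat: str = "unknown"

    def __post_init__(self) -> None:
        if self.n_flowers < 0:
            raise ValueError("n_flowers must be >= 0")
        if not (0 <= self.nectar_stock_ul <= self.nectar_capacity_ul or
                self.nectar_capacity_ul == 0 == self.nectar_stock_ul):
            raise ValueError("nectar stock must lie in [0, capacity]")
        if not (0 <= self.pollen_stock_g <= self.pollen_capacity_g or
                self.pollen_capacity_g == 0 == self.pollen_stock_g):
            raise ValueError("pollen stock must lie in [0, capacity]")


def filling_level(patch: Patch) -> float:
    """Fraction of the patch's daily nectar capacity still standing (γ).

    Returns 0.0 for a zero-capacity patch (e.g. a wind-pollinated crop that
    offers no nectar).
    """
    if patch.nectar_capacity_ul <= 0:
        return 0.0
    return patch.nectar_stock_ul / patch.nectar_capacity_ul


def deplete(patch: Patch, requested_ul: float) -> tuple[float, Patch]:
    """Remove up to ``requested_ul`` of nectar; returns (collected, patch').

    Collection is clamped to the available stock; the stock never goes
    negative. A negative request is a caller bug and raises.
    """
    if requested_ul < 0:
        raise ValueError("requested_ul must be >= 0")
    collected = min(requested_ul, patch.nectar_stock_ul)
    return collected, replace(patch, nectar_stock_ul=patch.nectar_stock_ul - collected)


def replenish_daily(patch: Patch, day_of_year: int) -> Patch:
    """Daily stock reset: full capacity inside the flowering window, else 0."""
    if not (1 <= day_of_year <= 365):
        raise ValueError("day_of_year must be in [1, 365]")
    if patch.species.in_flower(day_of_year):
        return replace(
            patch,
            nectar_stock_ul=patch.nectar_capacity_ul,
            pollen_stock_g=patch.pollen_capacity_g,
        )
    return replace(patch, nectar_stock_ul=0.0, pollen_stock_g=0.0)


# ---------------------------------------------------------------------------
# Vectorised landscape container (hot path of the simulator)
# ---------------------------------------------------------------------------

NESTING_HABITATS = frozenset({"hedgerow", "scrub"})


@dataclass
class Landscape:
    """All patches of a map held as parallel numpy arrays.

    Semantics per patch are exactly those of the record-level operations
    above (``filling_level``/``deplete``/``replenish_daily``); the array form
    exists because patch choice evaluates every candidate patch on every
    foraging trip.
    """

    species: list[FlowerSpecies]
    patch_id: np.ndarray          # int
    x: np.ndarray                 # m
    y: np.ndarray                 # m
    habitat: list[str]
    species_idx: np.ndarray       # int index into ``species``
    n_flowers: np.ndarray         # int
    nectar_capacity: np.ndarray   # µl/day
    pollen_capacity: np.ndarray   # g/day
    nectar_stock: np.ndarray = field(default=None)  # type: ignore[assignment]
    pollen_stock: np.ndarray = field(default=None)  # type: ignore[assignment]
    nest_site_capacity: int = 0

    def __post_init__(self) -> None:
        if self.nectar_stock is None:
            self.nectar_stock = self.nectar_capacity.astype(float).copy()
        if self.pollen_stock is None:
            self.pollen_stock = self.pollen_capacity.astype(float).copy()
        # per-patch species parameter views used by the handling engines
        self.corolla_depth = np.array(
            [self.species[i].corolla_depth_mm for i in self.species_idx]
        )
        self.nectar_volume = np.array(
            [self.species[i].nectar_volume_ul for i in self.species_idx]
        )
        self.interflower_travel = np.array(
            [self.species[i].interflower_travel_s for i in self.species_idx]
        )
        self.flower_start = np.array(
            [self.species[i].flowering_start_doy for i in self.species_idx]
        )
        self.flower_end = np.array(
            [self.species[i].flowering_end_doy for i in self.species_idx]
        )
        self.is_nesting = np.array(
            [h in NESTING_HABITATS for h in self.habitat], dtype=bool
        )

    @property
    def n_patches(self) -> int:
        return len(self.patch_id)

    def gamma(self) -> np.ndarray:
        """Filling level per patch; 0 where the daily capacity is 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(
                self.nectar_capacity > 0,
                self.nectar_stock / np.maximum(self.nectar_capacity, 1e-300),
                0.0,
            )
        return g

    def gamma_pollen(self) -> np.ndarray:
        return np.where(
            self.pollen_capacity > 0,
            self.pollen_stock / np.maximum(self.pollen_capacity, 1e-300),
            0.0,
        )

    def replenish_all(self, day_of_year: int) -> None:
        in_flower = (self.flower_start <= day_of_year) & (day_of_year <= self.flower_end)
        self.nectar_stock[:] = np.where(in_flower, self.nectar_capacity, 0.0)
        self.pollen_stock[:] = np.where(in_flower, self.pollen_capacity, 0.0)

    def deplete_nectar(self, idx: int, requested_ul: float) -> float:
        if requested_ul < 0:
            raise ValueError("requested_ul must be >= 0")
        collected = min(requested_ul, float(self.nectar_stock[idx]))
        self.nectar_stock[idx] -= collected
        return collected

    def deplete_pollen(self, idx: int, requested_g: float) -> float:
        if requested_g < 0:
            raise ValueError("requested_g must be >= 0")
        collected = min(requested_g, float(self.pollen_stock[idx]))
        self.pollen_stock[idx] -= collected
        return collected

    def distances_from(self, x: float, y: float) -> np.ndarray:
        return np.hypot(self.x - x, self.y - y)

    # ---- record-level views -------------------------------------------------
    def patches(self) -> list[Patch]:
        return [
            Patch(
                patch_id=int(self.patch_id[i]),
                x_m=float(self.x[i]),
                y_m=float(self.y[i]),
                species=self.species[self.species_idx[i]],
                n_flowers=int(self.n_flowers[i]),
                nectar_capacity_ul=float(self.nectar_capacity[i]),
                nectar_stock_ul=float(self.nectar_stock[i]),
                pollen_capacity_g=float(self.pollen_capacity[i]),
                pollen_stock_g=float(self.pollen_stock[i]),
                habitat=self.habitat[i],
            )
            for i in range(self.n_patches)
        ]

    @staticmethod
    def from_patches(patches: Sequence[Patch], nest_site_capacity: int = 0) -> "Landscape":
        species: list[FlowerSpecies] = []
        names: dict[str, int] = {}
        idx = []
        for p in patches:
            if p.species.name not in names:
                names[p.species.name] = len(species)
                species.append(p.species)
            idx.append(names[p.species.name])
        return Landscape(
            species=species,
            patch_id=np.array([p.patch_id for p in patches], dtype=int),
            x=np.array([p.x_m for p in patches], dtype=float),
            y=np.array([p.y_m for p in patches], dtype=float),
            habitat=[p.habitat for p in patches],
            species_idx=np.array(idx, dtype=int),
            n_flowers=np.array([p.n_flowers for p in patches], dtype=int),
            nectar_capacity=np.array([p.nectar_capacity_ul for p in patches], dtype=float),
            pollen_capacity=np.array([p.pollen_capacity_g for p in patches], dtype=float),
            nectar_stock=np.array([p.nectar_stock_ul for p in patches], dtype=float),
            pollen_stock=np.array([p.pollen_stock_g for p in patches], dtype=float),
            nest_site_capacity=nest_site_capacity,
        )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_species_table(path: str | _Path) -> list[FlowerSpecies]:
    """Read a flower-species CSV (UTF-8, comma-separated, '.' decimal)."""
    df = pd.read_csv(path)
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species table is missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in SPECIES_COLUMNS]
    if extra:
        warnings.warn(f"species table: ignoring unknown column(s) {extra}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                FlowerSpecies(
                    name=str(row["name"]),
                    corolla_depth_mm=float(row["corolla_depth_mm"]),
                    nectar_volume_ul=float(row["nectar_volume_ul"]),
                    interflower_travel_s=float(row["interflower_travel_s"]),
                    pollen_per_flower_g=float(row["pollen_per_flower_g"]),
                    flowering_start_doy=int(row["flowering_start_doy"]),
                    flowering_end_doy=int(row["flowering_end_doy"]),
                    sugar_energy_kj_per_ul=float(row["sugar_energy_kj_per_ul"]),
                )
            )
        except (TypeError, ValueError) as exc:  # report 1-based data line (+ header)
            raise ValueError(f"species table line {i + 2}: {exc}") from exc
    return out


def write_species_table(species: Sequence[FlowerSpecies], path: str | _Path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "corolla_depth_mm": s.corolla_depth_mm,
                "nectar_volume_ul": s.nectar_volume_ul,
                "interflower_travel_s": s.interflower_travel_s,
                "pollen_per_flower_g": s.pollen_per_flower_g,
                "flowering_start_doy": s.flowering_start_doy,
                "flowering_end_doy": s.flowering_end_doy,
                "sugar_energy_kj_per_ul": s.sugar_energy_kj_per_ul,
            }
            for s in species
        ]
    ).to_csv(path, index=False)
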