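"""Synthetic resource-poor farmland landscape generator.

Emulates the structure of a mixed lowland farm of roughly 4 × 4 km:
semi-improved pasture, maize, hedgerow, scrub, permanent pasture, and a
small flower-rich plot. Patches are points with a daily nectar/pollen
capacity; habitat is drawn per patch from the configured area fractions,
the flower species and flower count from per-habitat tables. Maize is
wind-pollinated: it contributes a brief pollen pulse and no nectar.
Hedgerow and scrub patches double as nest sites, which caps the number of
simultaneously active colonies.

The default calibration is deliberately resource-poor: under the
mechanistic handling engine with high foraging mortality the population
persists with year-end queen counts in the hundreds, not thousands. The
``richness`` multiplier scales every floral capacity linearly to construct
poorer or richer variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path as _Path

import numpy as np
import pandas as pd

from .flora import FlowerSpecies, Landscape, SPECIES_COLUMNS

__all__ = [
    "HABITATS",
    "DEFAULT_FLORA",
    "LandscapeSpec",
    "generate_landscape",
    "write_landscape",
    "read_landscape",
    "LANDSCAPE_COLUMNS",
]

HABITATS = (
    "semi_improved_pasture",
    "maize",
    "hedgerow",
    "scrub",
    "permanent_pasture",
    "flower_rich_plot",
)

#: Default flower species (parameter values are package defaults for a
#: temperate farmland community; corolla depths span shallow forbs to the
#: deep-tubed red clover that short-glossa bees handle poorly).
DEFAULT_FLORA: dict[str, FlowerSpecies] = {
    s.name: s
    for s in [
        FlowerSpecies("pasture_forbs", corolla_depth_mm=1.5, nectar_volume_ul=1.0,
                      interflower_travel_s=1.0, pollen_per_flower_g=0.002,
                      flowering_start_doy=90, flowering_end_doy=280),
        FlowerSpecies("white_clover", corolla_depth_mm=2.0, nectar_volume_ul=1.5,
                      interflower_travel_s=1.2, pollen_per_flower_g=0.002,
                      flowering_start_doy=120, flowering_end_doy=270),
        FlowerSpecies("hawthorn", corolla_depth_mm=2.5, nectar_volume_ul=1.0,
                      interflower_travel_s=1.0, pollen_per_flower_g=0.003,
                      flowering_start_doy=110, flowering_end_doy=160),
        FlowerSpecies("bramble", corolla_depth_mm=3.5, nectar_volume_ul=2.0,
                      interflower_travel_s=1.8, pollen_per_flower_g=0.003,
                      flowering_start_doy=150, flowering_end_doy=240),
        FlowerSpecies("red_clover", corolla_depth_mm=9.0, nectar_volume_ul=2.5,
                      interflower_travel_s=1.5, pollen_per_flower_g=0.002,
                      flowering_start_doy=130, flowering_end_doy=260),
        FlowerSpecies("wildflower_mix", corolla_depth_mm=5.0, nectar_volume_ul=2.0,
                      interflower_travel_s=1.5, pollen_per_flower_g=0.003,
                      flowering_start_doy=100, flowering_end_doy=280),
        # wind-pollinated: pollen pulse only, token nectar volume (unused,
        # patches carry zero nectar capacity)
        FlowerSpecies("maize", corolla_depth_mm=0.0, nectar_volume_ul=0.1,
                      interflower_travel_s=0.5, pollen_per_flower_g=0.0005,
                      flowering_start_doy=190, flowering_end_doy=215),
    ]
}

# habitat -> (species name, flower-count range per patch)
_HABITAT_FLORA: dict[str, tuple[str, tuple[int, int]]] = {
    "semi_improved_pasture": ("pasture_forbs", (200, 400)),
    "permanent_pasture": ("white_clover", (300, 500)),
    "hedgerow": ("hawthorn", (400, 700)),
    "scrub": ("bramble", (300, 500)),
    "flower_rich_plot": ("wildflower_mix", (1500, 2500)),
    "maize": ("maize", (3000, 6000)),
}

_DEFAULT_FRACTIONS: dict[str, float] = {
    "semi_improved_pasture": 0.30,
    "permanent_pasture": 0.25,
    "maize": 0.20,
    "hedgerow": 0.10,
    "scrub": 0.10,
    "flower_rich_plot": 0.05,
}


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the synthetic landscape.

    ``habitat_fractions`` must sum to 1 over the six supported habitats;
    ``richness`` scales all floral capacities linearly.
    """

    extent_m: float = 4000.0
    n_patches: int = 32
    habitat_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    richness: float = 14.0
    nest_sites_per_nesting_patch: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_m <= 0:
            raise ValueError("extent_m must be > 0")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        if not self.habitat_fractions:
            raise ValueError("habitat mix must not be empty")
        unknown = set(self.habitat_fractions) - set(HABITATS)
        if unknown:
            raise ValueError(f"unknown habitat(s): {sorted(unknown)}")
        total = sum(self.habitat_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"habitat fractions must sum to 1 (got {total})")
        if self.richness <= 0:
            raise ValueError("richness must be > 0")


def generate_landscape(
    spec: LandscapeSpec = LandscapeSpec(),
    flora: dict[str, FlowerSpecies] | None = None,
) -> Landscape:
    """Generate a seeded synthetic landscape from ``spec``.

    Patch centroids are uniform over the square extent; habitats follow the
    area-fraction multinomial; flower counts are uniform over the habitat's
    range; daily nectar capacity is flowers × per-flower volume (zero for
    maize) and pollen capacity flowers × per-flower pollen, both scaled by
    ``richness``. Deterministic given ``spec.seed``.
    """
    flora = dict(DEFAULT_FLORA if flora is None else flora)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patches
    habs = list(spec.habitat_fractions)
    probs = np.array([spec.habitat_fractions[h] for h in habs])
    habitat = [habs[i] for i in rng.choice(len(habs), size=n, p=probs)]
    x = rng.uniform(0.0, spec.extent_m, size=n)
    y = rng.uniform(0.0, spec.extent_m, size=n)

    species_list = list(flora.values())
    sp_index = {s.name: i for i, s in enumerate(species_list)}
    species_idx = np.empty(n, dtype=int)
    n_flowers = np.empty(n, dtype=int)
    nectar_cap = np.empty(n, dtype=float)
    pollen_cap = np.empty(n, dtype=float)
    for i, h in enumerate(habitat):
        sp_name, (lo, hi) = _HABITAT_FLORA[h]
        sp = flora[sp_name]
        species_idx[i] = sp_index[sp_name]
        n_flowers[i] = int(rng.integers(lo, hi + 1))
        nectar = 0.0 if h == "maize" else n_flowers[i] * sp.nectar_volume_ul
        nectar_cap[i] = nectar * spec.richness
        pollen_cap[i] = n_flowers[i] * sp.pollen_per_flower_g * spec.richness

    land = Landscape(
        species=species_list,
        patch_id=np.arange(n, dtype=int),
        x=x,
        y=y,
        habitat=habitat,
        species_idx=species_idx,
        n_flowers=n_flowers,
        nectar_capacity=nectar_cap,
        pollen_capacity=pollen_cap,
        nest_site_capacity=0,
    )
    land.nest_site_capacity = int(land.is_nesting.sum()) * spec.nest_sites_per_nesting_patch
    return land


# ---------------------------------------------------------------------------
# Landscape CSV round-trip
# ---------------------------------------------------------------------------

LANDSCAPE_COLUMNS = [
    "patch_id", "x_m", "y_m", "habitat", "species",
    "n_flowers", "nectar_capacity_ul", "pollen_capacity_g",
]


def write_landscape(land: Landscape, path: str | _Path) -> None:
    pd.DataFrame({
        "patch_id": land.patch_id,
        "x_m": land.x,
        "y_m": land.y,
        "habitat": land.habitat,
        "species": [land.species[i].name for i in land.species_idx],
        "n_flowers": land.n_flowers,
        "nectar_capacity_ul": land.nectar_capacity,
        "pollen_capacity_g": land.pollen_capacity,
    }).to_csv(path, index=False)


def read_landscape(
    path: str | _Path,
    flora: dict[str, FlowerSpecies] | None = None,
    nest_sites_per_nesting_patch: int = 4,
) -> Landscape:
    """Read a landscape table; inverse of :func:`write_landscape`.

    Unknown extra columns produce a warning and are ignored; missing
    columns and malformed rows raise with the offending name/line.
    """
    flora = dict(DEFAULT_FLORA if flora is None else flora)
    df = pd.read_csv(path)
    missing = [c for c in LANDSCAPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landscape table is missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in LANDSCAPE_COLUMNS]
    if extra:
        warnings.warn(f"landscape table: ignoring unknown column(s) {extra}")

    species_list = list(flora.values())
    sp_index = {s.name: i for i, s in enumerate(species_list)}
    n = len(df)
    species_idx = np.empty(n, dtype=int)
    for i, row in df.iterrows():
        name = str(row["species"])
        if name not in sp_index:
            raise ValueError(f"landscape table line {i + 2}: unknown species {name!r}")
        try:
            float(row["nectar_capacity_ul"]); float(row["pollen_capacity_g"])
            int(row["n_flowers"]); float(row["x_m"]); float(row["y_m"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"landscape table line {i + 2}: {exc}") from exc
        species_idx[i] = sp_index[name]

    land = Landscape(
        species=species_list,
        patch_id=df["patch_id"].to_numpy(dtype=int),
        x=df["x_m"].to_numpy(dtype=float),
        y=df["y_m"].to_numpy(dtype=float),
        habitat=[str(h) for h in df["habitat"]],
        species_idx=species_idx,
        n_flowers=df["n_flowers"].to_numpy(dtype=int),
        nectar_capacity=df["nectar_capacity_ul"].to_numpy(dtype=float),
        pollen_capacity=df["pollen_capacity_g"].to_numpy(dtype=float),
    )
    land.nest_site_capacity = int(land.is_nesting.sum()) * nest_sites_per_nesting_patch
    return land
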