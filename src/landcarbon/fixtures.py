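"""Seed-controlled synthetic landscapes, climate series and events.

Everything here is a pure function of (spec, seed): identical inputs give
bitwise-identical rasters, so full simulations are testable offline with
no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stsm
from .driver import ClimateSeries
from .pools import N_POOLS
from .stsm import FOREST_BASE, LandscapeState

DEFAULT_SPECIES = (
    "Forest: Douglas-fir Group",
    "Forest: Ponderosa Pine Group",
    "Forest: Oak/Hickory Group",
    "Forest: Maple/Beech/Birch Group",
)


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic test landscape."""

    shape: tuple[int, int] = (100, 100)
    species: tuple[str, ...] = DEFAULT_SPECIES
    pattern: str = "blocks"            # "blocks" | "random"
    age_distribution: str = "uniform"  # "uniform" | "exponential"
    age_mean: float = 80.0
    age_max: int = 300
    fire_initialized_fraction: float = 0.3   # cells with fire as the last
    #                                          stand-replacing disturbance
    t_norm_c: float = 8.0
    p_norm_mm: float = 900.0
    mat_sd: float = 0.8
    map_sd: float = 120.0
    warming_trend_c_per_decade: float = 0.0
    burn_fraction: float = 0.01        # of the landscape, per year
    fire_patch: int = 5                # square patch edge (cells)
    harvest_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for f in ("fire_initialized_fraction", "burn_fraction",
                  "harvest_fraction"):
            if not 0 <= getattr(self, f) <= 1:
                raise ValueError(f"{f} must lie in [0, 1]")
        if self.mat_sd < 0 or self.map_sd < 0:
            raise ValueError("climate SDs must be >= 0")


def _rng(spec: FixtureSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, salt])


def make_landscape(spec: FixtureSpec) -> dict[str, np.ndarray]:
    """State class, age, last-disturbance and stratum rasters."""
    rows, cols = spec.shape
    rng = _rng(spec, 1)
    k = len(spec.species)
    if spec.pattern == "blocks":
        # vertical bands, one per species
        band = np.minimum(np.arange(cols) * k // max(cols, 1), k - 1)
        sp = np.broadcast_to(band, (rows, cols)).copy()
    elif spec.pattern == "random":
        sp = rng.integers(0, k, size=(rows, cols))
    else:
        raise ValueError(f"unknown pattern {spec.pattern!r}")
    state_class = (FOREST_BASE + sp).astype(np.int32)

    if spec.age_distribution == "uniform":
        age = rng.integers(0, int(2 * spec.age_mean) + 1, size=(rows, cols))
    elif spec.age_distribution == "exponential":
        age = rng.exponential(spec.age_mean, size=(rows, cols)).astype(int)
    else:
        raise ValueError(f"unknown age distribution {spec.age_distribution!r}")
    age = np.clip(age, 0, spec.age_max).astype(np.int32)

    fire_init = rng.random((rows, cols)) < spec.fire_initialized_fraction
    last_disturbance = np.where(fire_init, stsm.DIST_FIRE,
                                stsm.DIST_CLEARCUT).astype(np.int8)
    # simple quadrant stratification ("ecoregion" stand-in)
    stratum = ((np.arange(rows)[:, None] >= rows // 2) * 2
               + (np.arange(cols)[None, :] >= cols // 2)).astype(np.int16)
    return {"state_class": state_class, "age": age,
            "last_disturbance": last_disturbance, "stratum": stratum}


def make_climate(spec: FixtureSpec, years: list[int]) -> ClimateSeries:
    """Gaussian anomalies around spatially flat normals, optional trend."""
    rows, cols = spec.shape
    rng = _rng(spec, 2)
    t_norm = np.full((rows, cols), spec.t_norm_c)
    p_norm = np.full((rows, cols), spec.p_norm_mm)
    mat = np.empty((len(years), rows, cols))
    map_mm = np.empty((len(years), rows, cols))
    for t in range(len(years)):
        trend = spec.warming_trend_c_per_decade * t / 10.0
        mat[t] = t_norm + trend + rng.normal(0.0, spec.mat_sd, (rows, cols))
        map_mm[t] = np.clip(
            p_norm + rng.normal(0.0, spec.map_sd, (rows, cols)), 0.0, None)
    return ClimateSeries(list(years), mat, map_mm, t_norm, p_norm)


def _burnable(state_class: np.ndarray) -> np.ndarray:
    return (stsm.is_forest(state_class)
            | (state_class == stsm.SHRUBLAND)
            | (state_class == stsm.GRASSLAND))


def make_fire_events(spec: FixtureSpec, years: list[int],
                     state_class: np.ndarray | None = None
                     ) -> dict[int, np.ndarray]:
    """Annual burn masks built from random square patches.

    Patches accumulate until the burned fraction reaches the target;
    masks only cover burnable (forest/shrub/grass) classes.
    """
    rows, cols = spec.shape
    rng = _rng(spec, 3)
    if state_class is None:
        state_class = make_landscape(spec)["state_class"]
    burnable = _burnable(state_class)
    target = int(round(spec.burn_fraction * rows * cols))
    out = {}
    for year in years:
        mask = np.zeros((rows, cols), dtype=bool)
        guard = 0
        while mask.sum() < target and guard < 10_000:
            guard += 1
            r = int(rng.integers(0, rows))
            c = int(rng.integers(0, cols))
            mask[r:r + spec.fire_patch, c:c + spec.fire_patch] = True
            mask &= burnable
        out[year] = mask
    return out


def make_harvest_events(spec: FixtureSpec, years: list[int],
                        state_class: np.ndarray | None = None
                        ) -> dict[int, np.ndarray]:
    """Annual clearcut masks: random forest cells at the target fraction."""
    rows, cols = spec.shape
    rng = _rng(spec, 4)
    if state_class is None:
        state_class = make_landscape(spec)["state_class"]
    forest = stsm.is_forest(state_class).ravel()
    target = int(round(spec.harvest_fraction * rows * cols))
    out = {}
    for year in years:
        idx = np.nonzero(forest)[0]
        take = min(target, len(idx))
        chosen = rng.choice(idx, size=take, replace=False)
        mask = np.zeros(rows * cols, dtype=bool)
        mask[chosen] = True
        out[year] = mask.reshape(rows, cols)
    return out


def make_initialized_landscape(spec: FixtureSpec, params) -> LandscapeState:
    """Full landscape state with pools from the state attribute tables.

    ``params`` is a :class:`~landcarbon.driver.ParameterSet` whose species
    cover the fixture's species mix and whose tables were built by the
    spin-up.
    """
    from .spinup import initialize_landscape

    maps = make_landscape(spec)
    name_to_idx = {n: i for i, n in enumerate(params.species_names)}
    fix_to_param = np.array([name_to_idx[n] for n in spec.species])
    sp_map = stsm.species_index(maps["state_class"])
    sp_param = np.where(sp_map >= 0, fix_to_param[sp_map], -1)
    state_class = np.where(
        sp_map >= 0, FOREST_BASE + sp_param, maps["state_class"]
    ).astype(np.int32)
    pools = initialize_landscape(
        sp_param, maps["age"], maps["last_disturbance"] == stsm.DIST_FIRE,
        params.species_names, params.tables)
    return LandscapeState(
        state_class=state_class, age=maps["age"],
        time_since_transition=maps["age"].copy(),
        last_disturbance=maps["last_disturbance"],
        pools=pools, strata={"region": maps["stratum"]})
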