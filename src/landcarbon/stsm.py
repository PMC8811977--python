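"""Annual state-and-transition dynamics over the raster landscape.

Cells carry a discrete state class (non-forest land-cover classes plus one
class per forest type-group), an age, a time-since-transition counter and
bookkeeping for the last stand-replacing disturbance.  Transitions are
scheduled stochastically (annual probability or target area), or imposed
from event rasters (e.g. mapped fire perimeters), and return per-cell
assignments that the carbon engine turns into transition-triggered flows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pools import N_POOLS

log = logging.getLogger(__name__)

# state class code space
WATER = 1
DEVELOPED_OPEN = 2
DEVELOPED_LOW = 3
DEVELOPED_MED = 4
DEVELOPED_HIGH = 5
BARREN = 6
GRASSLAND = 7
SHRUBLAND = 8
CROPLAND = 9
PASTURE = 10
WETLAND = 11
POST_FIRE_SHRUBLAND = 12
FOREST_BASE = 100       # forest class = FOREST_BASE + species index

POSTFIRE_RECOVERY_PROBABILITY = 0.064  # annual shrubland-to-forest rate

# last stand-replacing disturbance codes
DIST_NONE = 0
DIST_FIRE = 1
DIST_CLEARCUT = 2

SEVERITY_TRANSITIONS = ("fire_high", "fire_medium", "fire_low")


def is_forest(codes) -> np.ndarray:
    return np.asarray(codes) >= FOREST_BASE


def species_index(codes) -> np.ndarray:
    """Species index for forest cells, -1 elsewhere."""
    codes = np.asarray(codes)
    return np.where(is_forest(codes), codes - FOREST_BASE, -1)


@dataclass
class LandscapeState:
    """Co-registered rasters describing the landscape."""

    state_class: np.ndarray          # (r, c) int
    age: np.ndarray                  # (r, c) int, years
    time_since_transition: np.ndarray
    last_disturbance: np.ndarray     # DIST_* codes
    pools: np.ndarray                # (r, c, 14) tons C/ha
    species_memory: np.ndarray | None = None   # forest class remembered by
    #                                            post-fire shrubland cells
    protected: np.ndarray | None = None        # bool; excluded from change
    frozen: np.ndarray | None = None           # bool; carbon dynamics stopped
    strata: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        shp = self.state_class.shape
        for name in ("age", "time_since_transition", "last_disturbance"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"{name} raster not co-registered")
        if self.pools.shape != shp + (N_POOLS,):
            raise ValueError("pools raster must be (rows, cols, 14)")
        if self.species_memory is None:
            self.species_memory = np.full(shp, -1, dtype=np.int32)
        if self.protected is None:
            self.protected = np.zeros(shp, dtype=bool)
        if self.frozen is None:
            self.frozen = np.zeros(shp, dtype=bool)
        if (self.age < 0).any():
            raise ValueError("ages must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.state_class.shape

    @property
    def n_cells(self) -> int:
        return self.state_class.size

    def forest_mask(self) -> np.ndarray:
        return is_forest(self.state_class)

    def tec(self) -> np.ndarray:
        """Total ecosystem carbon raster (tons C/ha)."""
        return self.pools.sum(axis=-1)

    def copy(self) -> "LandscapeState":
        return LandscapeState(
            self.state_class.copy(), self.age.copy(),
            self.time_since_transition.copy(), self.last_disturbance.copy(),
            self.pools.copy(), self.species_memory.copy(),
            self.protected.copy(), self.frozen.copy(),
            {k: v.copy() for k, v in self.strata.items()})


@dataclass
class TransitionDefinition:
    """Declarative description of one transition pathway."""

    name: str
    transition_type: str | None      # disturbance-matrix key, or None for
    #                                  pure relabeling (no carbon flow)
    source_classes: tuple[int, ...] = ()   # empty = any forest class
    destination: int | str = "same"  # class code, "same", or "forest_memory"
    mode: str = "events"             # "probability" | "target_area" | "events"
    probability: float = 0.0
    severity_split: tuple[float, float, float] | None = None
    age_reset: bool = False
    min_age: int = 0
    sets_last_disturbance: int | None = None
    respect_protected: bool = True

    def __post_init__(self):
        if self.mode not in ("probability", "target_area", "events"):
            raise ValueError(f"unknown scheduling mode {self.mode!r}")
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")
        if self.severity_split is not None:
            if not np.isclose(sum(self.severity_split), 1.0, atol=1e-9):
                raise ValueError("severity proportions must sum to 1")

    def eligible(self, state: LandscapeState) -> np.ndarray:
        """Flat boolean mask of cells this transition may affect."""
        codes = state.state_class.ravel()
        if self.source_classes:
            mask = np.isin(codes, self.source_classes)
        else:
            mask = is_forest(codes)
        if self.min_age > 0:
            mask &= state.age.ravel() >= self.min_age
        if self.respect_protected:
            mask &= ~state.protected.ravel()
        return mask


def _neighbor_weight(state: LandscapeState, mask_flat: np.ndarray
                     ) -> np.ndarray:
    """Weight proportional to the fraction of like cells in a 3x3 window."""
    grid = mask_flat.reshape(state.shape).astype(float)
    acc = np.zeros_like(grid)
    cnt = np.zeros_like(grid)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(grid, dr, axis=0), dc, axis=1)
            acc += shifted
            cnt += 1
    return (acc / cnt).ravel()


def schedule_transitions(state: LandscapeState,
                         defs: list[TransitionDefinition],
                         rates_or_events: dict[str, object] | None,
                         rng: np.random.Generator,
                         use_adjacency: bool = False
                         ) -> dict[str, np.ndarray]:
    """Select cells for each transition this timestep.

    ``rates_or_events`` may supply, per definition name, an event raster
    (2-D boolean/int mask) for ``events`` mode or a target cell count for
    ``target_area`` mode.  Probability mode draws each eligible cell
    independently.  Returns flat cell indices per transition name.
    """
    rates_or_events = rates_or_events or {}
    out: dict[str, np.ndarray] = {}
    for d in defs:
        eligible = d.eligible(state)
        if d.mode == "probability":
            draw = rng.random(state.n_cells) < d.probability
            out[d.name] = np.nonzero(eligible & draw)[0]
        elif d.mode == "events":
            ev = rates_or_events.get(d.name)
            if ev is None:
                out[d.name] = np.array([], dtype=int)
                continue
            mask = np.asarray(ev).ravel().astype(bool)
            out[d.name] = np.nonzero(eligible & mask)[0]
        else:  # target_area
            target = int(rates_or_events.get(d.name, 0))
            idx = np.nonzero(eligible)[0]
            if target > len(idx):
                log.warning("%s: target %d exceeds eligible area %d; "
                            "truncated", d.name, target, len(idx))
                target = len(idx)
            if target == 0:
                out[d.name] = np.array([], dtype=int)
                continue
            if use_adjacency:
                w = _neighbor_weight(state, np.isin(
                    state.state_class.ravel(),
                    d.source_classes or
                    np.unique(state.state_class.ravel()[idx])))[idx]
                w = w + 1e-9
                p = w / w.sum()
                out[d.name] = rng.choice(idx, size=target, replace=False, p=p)
            else:
                out[d.name] = rng.choice(idx, size=target, replace=False)
    return out


def assign_fire_severity(burned: np.ndarray,
                         splits,
                         rng: np.random.Generator,
                         stratum: np.ndarray | None = None
                         ) -> dict[str, np.ndarray]:
    """Partition burned cell indices into high/medium/low severity.

    ``splits`` is either a global (high, med, low) tuple or a mapping of
    stratum code to such a tuple (requires ``stratum`` values per cell).
    Returns ``{"fire_high": idx, "fire_medium": idx, "fire_low": idx}``.
    """
    burned = np.asarray(burned, dtype=int)
    out = {t: [] for t in SEVERITY_TRANSITIONS}
    if len(burned) == 0:
        return {t: np.array(v, dtype=int) for t, v in out.items()}
    if isinstance(splits, dict):
        if stratum is None:
            raise ValueError("per-stratum splits require stratum codes")
        stratum = np.asarray(stratum)
        for code in np.unique(stratum):
            if code not in splits:
                raise KeyError(f"no severity split for stratum {code!r}")
            sub = burned[stratum == code]
            draw = rng.choice(3, size=len(sub), p=np.asarray(splits[code]))
            for k, t in enumerate(SEVERITY_TRANSITIONS):
                out[t].append(sub[draw == k])
        return {t: np.concatenate(v) if v else np.array([], dtype=int)
                for t, v in out.items()}
    p = np.asarray(splits, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("severity proportions must sum to 1")
    draw = rng.choice(3, size=len(burned), p=p)
    return {t: burned[draw == k]
            for k, t in enumerate(SEVERITY_TRANSITIONS)}


def apply_transitions(state: LandscapeState,
                      assignments: dict[str, np.ndarray],
                      defs: list[TransitionDefinition]
                      ) -> tuple[LandscapeState, list[tuple[str, np.ndarray]]]:
    """Apply per-cell assignments; return the new state and carbon work.

    The returned list pairs each disturbance-matrix transition type with
    the flat indices it applies to, in application order.  Cells assigned
    to multiple transitions keep only the first (definition order wins).
    """
    new = state.copy()
    carbon_work: list[tuple[str, np.ndarray]] = []
    taken = np.zeros(state.n_cells, dtype=bool)
    codes = new.state_class.ravel()
    age = new.age.ravel()
    tst = new.time_since_transition.ravel()
    last = new.last_disturbance.ravel()
    memory = new.species_memory.ravel()
    frozen = new.frozen.ravel()

    for d in defs:
        idx = np.asarray(assignments.get(d.name, []), dtype=int)
        idx = idx[~taken[idx]]
        if len(idx) == 0:
            continue
        taken[idx] = True
        if d.transition_type is not None:
            carbon_work.append((d.transition_type, idx))

        if d.destination == "forest_memory":
            lost = memory[idx] < 0
            if lost.any():
                raise ValueError("forest_memory destination with no "
                                 "remembered species")
            codes[idx] = memory[idx]
            memory[idx] = -1
        elif d.destination != "same":
            dest = int(d.destination)
            if dest == POST_FIRE_SHRUBLAND:
                memory[idx] = codes[idx]   # remember the originating forest
            codes[idx] = dest
            if dest < FOREST_BASE and dest != POST_FIRE_SHRUBLAND:
                # leaving the forest system: carbon dynamics stop
                frozen[idx] = True
        if d.age_reset:
            age[idx] = 0
        if d.sets_last_disturbance is not None:
            last[idx] = d.sets_last_disturbance
        tst[idx] = 0
    return new, carbon_work


def postfire_recovery(state: LandscapeState, rng: np.random.Generator,
                      probability: float = POSTFIRE_RECOVERY_PROBABILITY
                      ) -> tuple[LandscapeState, np.ndarray]:
    """Revert post-fire shrubland cells to their remembered forest class.

    Each cell independently recovers with the given annual probability;
    recovered cells restart at age 0.
    """
    shrub = state.state_class.ravel() == POST_FIRE_SHRUBLAND
    draw = rng.random(state.n_cells) < probability
    idx = np.nonzero(shrub & draw)[0]
    if len(idx) == 0:
        return state, idx
    new = state.copy()
    codes = new.state_class.ravel()
    memory = new.species_memory.ravel()
    age = new.age.ravel()
    tst = new.time_since_transition.ravel()
    codes[idx] = memory[idx]
    memory[idx] = -1
    age[idx] = 0
    tst[idx] = 0
    return new, idx


def default_transition_defs() -> list[TransitionDefinition]:
    """The packaged transition pathway set.

    Fire severities are event-driven (perimeter masks split by severity);
    high severity converts forest to post-fire shrubland and resets age,
    medium/low keep class and age.  Clearcut resets age; selection harvest
    does not.  Insect transitions are mortality-only and event-driven.
    Land-use conversions default to probability 0 (enable per scenario).
    """
    return [
        TransitionDefinition(
            "fire_high", "fire_high", destination=POST_FIRE_SHRUBLAND,
            mode="events", age_reset=True, sets_last_disturbance=DIST_FIRE),
        TransitionDefinition("fire_medium", "fire_medium", mode="events"),
        TransitionDefinition("fire_low", "fire_low", mode="events"),
        TransitionDefinition(
            "clearcut", "clearcut", mode="events", age_reset=True,
            sets_last_disturbance=DIST_CLEARCUT),
        TransitionDefinition(
            "selection_harvest", "selection_harvest", mode="events"),
        TransitionDefinition("insect_high", "insect_high", mode="events"),
        TransitionDefinition("insect_medium", "insect_medium", mode="events"),
        TransitionDefinition("insect_low", "insect_low", mode="events"),
        TransitionDefinition(
            "urbanization", "urbanization", destination=DEVELOPED_LOW,
            mode="probability", probability=0.0),
        TransitionDefinition(
            "agricultural_expansion", "agricultural_expansion",
            destination=CROPLAND, mode="probability", probability=0.0),
    ]


def bootstrap_future_rates(history: pd.DataFrame, years: list[int],
                           rng: np.random.Generator) -> pd.DataFrame:
    """Sample future annual rates from the historical record.

    ``history`` is tidy: {year, transition, value} (optionally stratum).
    For each future year and transition, one historical year's value is
    drawn uniformly with replacement, independently across transitions.
    """
    if history.empty:
        raise ValueError("historical rate record is empty")
    group_cols = [c for c in ("transition", "stratum") if c in history]
    rows = []
    for key, grp in history.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        values = grp["value"].to_numpy()
        picks = rng.integers(0, len(values), size=len(years))
        for year, pick in zip(years, picks):
            rows.append(dict(zip(group_cols, key),
                             year=year, value=values[pick]))
    return pd.DataFrame(rows)


def schedule_reforestation(state: LandscapeState,
                           eligibility_mask: np.ndarray,
                           start_year: int, end_year: int,
                           total_cells: int,
                           rng: np.random.Generator
                           ) -> dict[int, np.ndarray]:
    """Spread ``total_cells`` conversions evenly over [start_year, end_year].

    Cells are drawn without replacement from the eligibility mask; a
    shortfall truncates with a warning.  Returns flat indices per year.
    """
    idx = np.nonzero(np.asarray(eligibility_mask).ravel()
                     & ~state.protected.ravel())[0]
    if total_cells > len(idx):
        log.warning("reforestation target %d exceeds eligible area %d; "
                    "truncated", total_cells, len(idx))
        total_cells = len(idx)
    chosen = rng.choice(idx, size=total_cells, replace=False)
    years = list(range(start_year, end_year + 1))
    per_year = np.array_split(chosen, len(years))
    return {y: a for y, a in zip(years, per_year)}
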