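"""Species parameters, growth curves, reference stock tables and NPP schedules.

The growth driver is a merchantable-volume-by-age curve,

    volume(age) = a * (1 - exp(-b * age)) ** 3,

expanded to the five live carbon pools with per-component expansion factors
and a carbon fraction.  Net primary productivity (NPP) by age is derived
from the resulting stock trajectory as net growth plus biomass turnover,
and its allocation proportions (pNPP) distribute annual NPP across the
live pools inside the carbon engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .pools import ALL_POOLS, LIVE_POOLS, N_LIVE, N_POOLS

MAX_AGE = 300  # age grid is 0..MAX_AGE; older ages clamp to the last row

#: order of expansion-factor columns, matched to LIVE_POOLS
_EXPANSION_COLS = ("merchantable", "foliage", "other_wood",
                   "coarse_root", "fine_root")


@dataclass(frozen=True)
class SpeciesParams:
    """One row of the species parameter table."""

    species_name: str
    a: float                 # asymptote of merchantable volume (m3/ha)
    b: float                 # rate of approach to the asymptote (1/yr)
    mean_temp: float         # mean annual temperature across range (degC)
    mri: float               # mean historical fire return interval (yr)
    ecozone: str = ""
    province: str = ""
    cbm_species: str = ""

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError(
                f"{self.species_name}: growth parameters must be positive")
        if self.mri < 1:
            raise ValueError(f"{self.species_name}: mri must be >= 1")

    @classmethod
    def from_row(cls, row: pd.Series) -> "SpeciesParams":
        return cls(
            species_name=row["species_name"], a=float(row["a"]),
            b=float(row["b"]), mean_temp=float(row["mean_temp_c"]),
            mri=float(row["mri_years"]), ecozone=str(row["ecozone"]),
            province=str(row["province"]), cbm_species=str(row["cbm_species"]),
        )


def load_species(path=None) -> list[SpeciesParams]:
    """All species from a parameter CSV (packaged table by default)."""
    df = io.read_species_params(path)
    return [SpeciesParams.from_row(r) for _, r in df.iterrows()]


def get_species(name: str, path=None) -> SpeciesParams:
    for sp in load_species(path):
        if sp.species_name == name or name in sp.species_name:
            return sp
    raise KeyError(f"species {name!r} not found")


@dataclass(frozen=True)
class ExpansionParams:
    """Factors converting merchantable volume to live-component carbon.

    ``factors`` maps each live pool to tons of component biomass per m3 of
    merchantable stem volume; ``carbon_fraction`` converts biomass to
    carbon.
    """

    factors: dict[str, float]
    carbon_fraction: float = 0.5

    def __post_init__(self):
        missing = set(LIVE_POOLS) - set(self.factors)
        if missing:
            raise ValueError(f"missing expansion factors: {sorted(missing)}")
        if any(v < 0 for v in self.factors.values()):
            raise ValueError("expansion factors must be >= 0")
        if not 0 < self.carbon_fraction <= 1:
            raise ValueError("carbon fraction must be in (0, 1]")

    @classmethod
    def for_species(cls, species_name: str, path=None) -> "ExpansionParams":
        df = io.read_expansion_params(path)
        rows = df[df["species_name"] == species_name]
        if rows.empty:
            rows = df[df["species_name"] == "default"]
        if rows.empty:
            raise io.LoadError(
                f"no expansion factors for {species_name!r} and no default row")
        row = rows.iloc[0]
        factors = dict(zip(LIVE_POOLS,
                           (float(row[c]) for c in _EXPANSION_COLS)))
        return cls(factors=factors,
                   carbon_fraction=float(row["carbon_fraction"]))

    def as_array(self) -> np.ndarray:
        """(5,) carbon per m3 of volume, in LIVE_POOLS order."""
        return self.carbon_fraction * np.array(
            [self.factors[p] for p in LIVE_POOLS])


@dataclass
class StockByAgeTable:
    """Pool stocks (tons C/ha) for ages 0..MAX_AGE ("state attribute table")."""

    species_name: str
    last_disturbance: str        # "fire", "clearcut" or "none"
    stocks: np.ndarray           # (MAX_AGE + 1, 14)

    def __post_init__(self):
        self.stocks = np.asarray(self.stocks, dtype=float)
        if self.stocks.shape[1] != N_POOLS:
            raise ValueError("stock table must have 14 pool columns")
        if (self.stocks < -1e-12).any():
            raise ValueError("stock table has negative entries")

    def row(self, age: int | np.ndarray) -> np.ndarray:
        """Stocks at ``age``; ages above the grid clamp to the last row."""
        idx = np.clip(age, 0, self.stocks.shape[0] - 1)
        return self.stocks[idx]

    @property
    def live(self) -> np.ndarray:
        return self.stocks[:, :N_LIVE]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stocks, columns=list(ALL_POOLS))
        df.insert(0, "age", np.arange(self.stocks.shape[0]))
        return df


@dataclass
class NPPSchedule:
    """NPP by age and its allocation proportions over the live pools."""

    species_name: str
    npp: np.ndarray              # (MAX_AGE + 1,), tons C/ha/yr
    pnpp: np.ndarray             # (MAX_AGE + 1, 5); rows sum to 1

    def __post_init__(self):
        self.npp = np.asarray(self.npp, dtype=float)
        self.pnpp = np.asarray(self.pnpp, dtype=float)
        if (self.npp < -1e-12).any():
            raise ValueError("NPP must be >= 0")
        sums = self.pnpp.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("pNPP rows must sum to 1")

    def at(self, age: int | np.ndarray):
        idx = np.clip(age, 0, self.npp.shape[0] - 1)
        return self.npp[idx], self.pnpp[idx]


# ---------------------------------------------------------------------------
# growth curve

def merchantable_volume(params: SpeciesParams, age) -> np.ndarray | float:
    """Merchantable volume (m3/ha) at ``age`` years.

    Monotone increasing in age and bounded above by the asymptote ``a``.
    Raises ``ValueError`` for negative ages.
    """
    age_arr = np.asarray(age, dtype=float)
    if (age_arr < 0).any():
        raise ValueError("age must be >= 0")
    vol = params.a * (1.0 - np.exp(-params.b * age_arr)) ** 3
    return float(vol) if np.isscalar(age) or age_arr.ndim == 0 else vol


def live_stocks_from_volume(params: SpeciesParams,
                            expansion: ExpansionParams,
                            ages: np.ndarray | None = None) -> np.ndarray:
    """(n_ages, 5) live carbon from the volume curve and expansion factors."""
    if ages is None:
        ages = np.arange(MAX_AGE + 1)
    vol = merchantable_volume(params, np.asarray(ages))
    return np.outer(vol, expansion.as_array())


# ---------------------------------------------------------------------------
# NPP derivation

def npp_from_stocks(live: np.ndarray, turnover: np.ndarray) -> np.ndarray:
    """NPP(a) = sum of net live growth at a plus turnover of age a-1 stocks.

    ``live`` is (n_ages, 5); ``turnover`` is the (5,) annual turnover rate.
    NPP(0) is 0 by convention (no age -1 state).
    """
    live = np.asarray(live, dtype=float)
    growth = np.diff(live, axis=0)                     # G at ages 1..N
    turn = live[:-1] * turnover                        # T of age a-1 stocks
    npp = np.zeros(live.shape[0])
    npp[1:] = growth.sum(axis=1) + turn.sum(axis=1)
    return npp


def allocation_proportions(table: StockByAgeTable,
                           turnover: np.ndarray) -> np.ndarray:
    """pNPP(a, pool) = (G + S(a-1) * T) / NPP(a) for the five live pools.

    Ages with NPP = 0 carry forward the proportions of the last age with
    positive NPP; age 0 uses the first positive-NPP age.
    """
    live = table.live
    npp = npp_from_stocks(live, turnover)
    contrib = np.zeros_like(live)
    contrib[1:] = np.diff(live, axis=0) + live[:-1] * turnover
    pnpp = np.full_like(live, np.nan)
    pos = npp > 0
    pnpp[pos] = contrib[pos] / npp[pos, None]
    # fill zero-NPP ages: forward from last positive age, then backward
    filled = pd.DataFrame(pnpp).ffill().bfill().to_numpy()
    if np.isnan(filled).any():   # no positive-NPP age at all
        filled = np.zeros_like(live)
        filled[:, 0] = 1.0
    return filled


def npp_from_reference(table: StockByAgeTable,
                       turnover: np.ndarray) -> NPPSchedule:
    """Build the NPP schedule (total NPP and pNPP by age) from a table."""
    ages = table.stocks.shape[0]
    if ages < 2:
        raise ValueError("stock table must cover consecutive ages (>= 2 rows)")
    npp = npp_from_stocks(table.live, turnover)
    # engine-generated stocks give npp >= 0; clip tiny negatives from rounding
    npp = np.clip(npp, 0.0, None)
    pnpp = allocation_proportions(table, turnover)
    return NPPSchedule(table.species_name, npp, pnpp)


def reference_simulation(params: SpeciesParams,
                         expansion: ExpansionParams,
                         flows) -> StockByAgeTable:
    """Simulate an undisturbed 1-ha stand from age 0 to MAX_AGE.

    Live pools come from the volume curve, expansion factors and carbon
    fraction; DOM pools accumulate from zero through the carbon engine's
    base flows at the species' range mean temperature.  Deterministic: two
    runs with the same inputs are bitwise identical.
    """
    from .engine import base_step

    live = live_stocks_from_volume(params, expansion)
    schedule = NPPSchedule(
        params.species_name,
        npp_from_stocks(live, flows.turnover),
        allocation_proportions(
            StockByAgeTable(params.species_name, "none",
                            np.hstack([live, np.zeros((live.shape[0], 9))])),
            flows.turnover),
    )
    edr = flows.edr(params.mean_temp)
    stocks = np.zeros((MAX_AGE + 1, N_POOLS))
    state = np.zeros((1, N_POOLS))
    for age in range(1, MAX_AGE + 1):
        npp_a, pnpp_a = schedule.at(age)
        state, _ = base_step(state, np.array([npp_a]), pnpp_a[None, :],
                             edr[None, :], flows)
        stocks[age] = state[0]
    return StockByAgeTable(params.species_name, "none", stocks)


# ---------------------------------------------------------------------------
# harvest age rule

def min_harvest_age(params: SpeciesParams,
                    threshold: float = 0.6) -> tuple[int, int]:
    """Minimum (clearcut, selection) harvest ages.

    Clearcut age is the smallest integer age whose volume reaches
    ``threshold`` of the age-grid maximum; selection age is half of that,
    rounded up.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ages = np.arange(MAX_AGE + 1)
    vol = merchantable_volume(params, ages)
    target = threshold * vol.max()
    reached = np.nonzero(vol >= target)[0]
    clearcut_age = int(reached[0]) if len(reached) else MAX_AGE
    return clearcut_age, math.ceil(clearcut_age / 2)
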