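"""The per-cell annual carbon state machine.

State is a ``(n_cells, 14)`` array of pool densities (tons C/ha).  Each
annual step applies eight base flows in a fixed order:

1. snag fall (SnagStem -> AbovegroundMedium, SnagBranch -> AbovegroundFast)
2. emission/decay of snags and down deadwood (AbovegroundMedium)
3. emission from BelowgroundSlow
4. live-to-DOM biomass turnover
5. emission/decay of BelowgroundVeryFast, BelowgroundFast,
   AbovegroundVeryFast, AbovegroundFast
6. emission from AbovegroundSlow
7. AbovegroundSlow -> BelowgroundSlow transfer
8. growth of live pools (NPP allocated by pNPP)

The order is load-bearing: turnover (4) acts on pre-growth stocks, so
feeding an NPP schedule derived from a stock trajectory back through the
engine reproduces that trajectory exactly.  Transition-triggered flows
(fire, harvest, land conversion, ...) are applied after all base flows via
proportional disturbance matrices.

Each decay flow splits into an atmospheric emission (heterotrophic
respiration, proportion ``p_air``) and a humification transfer of the
remainder into the slow pool on the same side of the ground surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .pools import (ABOVEGROUND_DOM, ALL_POOLS, ATMOSPHERE, DOM_INDEX,
                    DOM_POOLS, EXPORT, LIVE_POOLS, N_DOM, N_LIVE, N_POOLS,
                    POOL_INDEX)

log = logging.getLogger(__name__)

T_REF = 10.0  # reference temperature (degC) for base decay rates

_iAGM = POOL_INDEX["AbovegroundMedium"]
_iAGF = POOL_INDEX["AbovegroundFast"]
_iAGS = POOL_INDEX["AbovegroundSlow"]
_iBGS = POOL_INDEX["BelowgroundSlow"]
_iSS = POOL_INDEX["SnagStem"]
_iSB = POOL_INDEX["SnagBranch"]

#: DOM-block column for the slow pool receiving the non-emitted decay
#: fraction of each DOM pool (aboveground -> AbovegroundSlow, else
#: BelowgroundSlow)
_SLOW_DEST = np.array(
    [_iAGS if p in ABOVEGROUND_DOM else _iBGS for p in DOM_POOLS])


def effective_decay_rate(bdr, temp, t_ref: float = T_REF, q10=2.0):
    """EDR = BDR * exp((T - T_ref) * ln(Q10) * 0.1).

    Algebraically equal to ``BDR * Q10 ** ((T - T_ref) / 10)``.
    """
    bdr = np.asarray(bdr, dtype=float)
    if (bdr < 0).any():
        raise ValueError("base decay rate must be >= 0")
    if (np.asarray(q10) <= 0).any():
        raise ValueError("Q10 must be > 0")
    return bdr * np.exp((np.asarray(temp, dtype=float) - t_ref)
                        * np.log(q10) * 0.1)


def carbon_to_co2(mass_c):
    """Convert a carbon mass to CO2 mass (factor 44/12)."""
    mass = np.asarray(mass_c, dtype=float)
    if (mass < 0).any():
        raise ValueError("carbon mass must be >= 0")
    out = mass * (44.0 / 12.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class FlowParams:
    """Base flow rates for one species (or a broadcastable species stack).

    Arrays may carry a leading species/cell axis; scalars and 1-D arrays
    broadcast over cells.
    """

    turnover: np.ndarray      # (..., 5) live-pool turnover rate, 1/yr
    snag_fall: np.ndarray     # (..., 2) SnagStem, SnagBranch fall rate
    base_decay: np.ndarray    # (..., 9) decay rate at T_REF, 1/yr
    p_air: np.ndarray         # (..., 9) emitted proportion of decay
    q10: np.ndarray           # (..., 9) temperature sensitivity
    slow_mixing: float        # AbovegroundSlow -> BelowgroundSlow, 1/yr
    routing: np.ndarray       # (5, 9) turnover destination split

    def __post_init__(self):
        for name in ("turnover", "snag_fall", "base_decay", "p_air", "q10",
                     "routing"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("turnover", "snag_fall", "base_decay", "p_air"):
            arr = getattr(self, name)
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} rates must lie in [0, 1]")
        if not np.allclose(self.routing.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("turnover routing rows must sum to 1")

    @classmethod
    def from_tables(cls, species_name: str = "default",
                    flow_path=None, routing_path=None) -> "FlowParams":
        """Build from the long-format flow CSV with default-row fallback."""
        df = io.read_flow_params(flow_path)
        routing_df = io.read_turnover_routing(routing_path)

        def lookup(parameter: str, pool: str, fallback=None) -> float:
            for name in (species_name, "default"):
                sel = df[(df["species_name"] == name)
                         & (df["parameter"] == parameter)
                         & (df["pool"] == pool)]
                if len(sel):
                    return float(sel["value"].iloc[0])
            if fallback is not None:
                return fallback
            raise io.LoadError(
                f"flow parameter {parameter}/{pool} missing for "
                f"{species_name!r} (no default row)")

        routing = np.zeros((N_LIVE, N_DOM))
        for _, r in routing_df.iterrows():
            routing[LIVE_POOLS.index(r["source_pool"]),
                    DOM_INDEX[r["destination_pool"]]] = r["fraction"]
        return cls(
            turnover=np.array([lookup("turnover", p) for p in LIVE_POOLS]),
            snag_fall=np.array([lookup("snag_fall", "SnagStem"),
                                lookup("snag_fall", "SnagBranch")]),
            base_decay=np.array(
                [lookup("base_decay_rate", p) for p in DOM_POOLS]),
            p_air=np.array([lookup("p_air", p) for p in DOM_POOLS]),
            q10=np.array([lookup("q10", p) for p in DOM_POOLS]),
            slow_mixing=lookup("slow_mixing", "AbovegroundSlow", 0.0),
            routing=routing,
        )

    def edr(self, temp) -> np.ndarray:
        """(..., 9) effective decay rates at temperature ``temp`` (degC)."""
        temp = np.asarray(temp, dtype=float)
        return effective_decay_rate(self.base_decay, temp[..., None]
                                    if temp.ndim else temp,
                                    T_REF, self.q10)


@dataclass
class FluxLedger:
    """Per-cell flux totals (tons C/ha) for one or more timesteps.

    Categories are mutually exclusive; ``turnover`` (base live-to-DOM) and
    ``dom_transfer`` are internal to the ecosystem, so conservation reads
    ``dTEC = npp - rh - combustion - export``.  ``mortality`` is the
    disturbance-triggered live-to-DOM transfer.
    """

    npp: np.ndarray
    rh: np.ndarray
    combustion: np.ndarray
    export: np.ndarray
    mortality: np.ndarray
    turnover: np.ndarray
    dom_transfer: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "FluxLedger":
        return cls(*(np.zeros(n) for _ in range(7)))

    def __iadd__(self, other: "FluxLedger") -> "FluxLedger":
        for name in self.__dataclass_fields__:
            getattr(self, name).__iadd__(getattr(other, name))
        return self

    def net_flux(self) -> np.ndarray:
        """NBP contribution: NPP - Rh - combustion - export."""
        return self.npp - self.rh - self.combustion - self.export

    def totals(self) -> dict[str, float]:
        return {name: float(getattr(self, name).sum())
                for name in self.__dataclass_fields__}


_cap_events = 0


def _capped_rate(rate: np.ndarray) -> np.ndarray:
    global _cap_events
    over = rate > 1.0
    if over.any():
        # log the first few occurrences at warning level, the rest at debug
        level = logging.WARNING if _cap_events < 3 else logging.DEBUG
        log.log(level, "decay outflow proportion > 1 in %d cells; capped "
                "to 1", int(np.count_nonzero(over)))
        _cap_events += 1
        rate = np.minimum(rate, 1.0)
    return rate


def _decay_pool(pools, dom_j, edr, p_air, decay_mult, ledger):
    """Apply emission/decay of DOM pool ``dom_j`` (index into DOM block)."""
    col = N_LIVE + dom_j
    rate = edr[..., dom_j]
    if decay_mult is not None:
        rate = rate * decay_mult[..., dom_j]
    rate = _capped_rate(np.broadcast_to(rate, pools.shape[:1]).copy())
    out = pools[:, col] * rate
    emit = out * np.broadcast_to(p_air[..., dom_j], out.shape)
    rest = out - emit
    pools[:, col] -= out
    pools[:, _SLOW_DEST[dom_j]] += rest
    ledger.rh += emit
    ledger.dom_transfer += rest


def base_step(pools: np.ndarray, npp: np.ndarray, pnpp: np.ndarray,
              edr: np.ndarray, flows: FlowParams,
              growth_mult=1.0, decay_mult: np.ndarray | None = None
              ) -> tuple[np.ndarray, FluxLedger]:
    """Advance one annual timestep of base flows.

    Parameters
    ----------
    pools : (n, 14) pool densities; not modified in place.
    npp : (n,) total NPP for the age being grown into (tons C/ha/yr).
    pnpp : (n, 5) NPP allocation proportions.
    edr : (n, 9) or (9,) effective decay rates (already temperature-scaled).
    flows : base flow rates.
    growth_mult : scalar or (n,) NPP multiplier (climate anomaly).
    decay_mult : optional (n, 9) or (9,) decay multiplier per DOM pool.

    Returns the new state and a :class:`FluxLedger`.  Pools never go
    negative: every outflow is proportional with rate <= 1 (capped), and
    flows apply sequentially.
    """
    p = np.array(pools, dtype=float, copy=True)
    if p.ndim != 2 or p.shape[1] != N_POOLS:
        raise ValueError("pools must be (n_cells, 14)")
    n = p.shape[0]
    ledger = FluxLedger.zeros(n)
    edr = np.asarray(edr, dtype=float)

    # 1. snag fall to down deadwood
    fall_stem = p[:, _iSS] * np.broadcast_to(flows.snag_fall[..., 0], (n,))
    fall_branch = p[:, _iSB] * np.broadcast_to(flows.snag_fall[..., 1], (n,))
    p[:, _iSS] -= fall_stem
    p[:, _iAGM] += fall_stem
    p[:, _iSB] -= fall_branch
    p[:, _iAGF] += fall_branch
    ledger.dom_transfer += fall_stem + fall_branch

    # 2. emission/decay of standing and down deadwood
    for name in ("SnagStem", "SnagBranch", "AbovegroundMedium"):
        _decay_pool(p, DOM_INDEX[name], edr, flows.p_air, decay_mult, ledger)

    # 3. emission from the belowground slow pool
    _decay_pool(p, DOM_INDEX["BelowgroundSlow"], edr, flows.p_air,
                decay_mult, ledger)

    # 4. biomass turnover from live to DOM pools
    turn = p[:, :N_LIVE] * np.broadcast_to(flows.turnover, (n, N_LIVE))
    p[:, :N_LIVE] -= turn
    p[:, N_LIVE:] += turn @ flows.routing
    ledger.turnover += turn.sum(axis=1)

    # 5. emission/decay of the fast and very fast pools
    for name in ("BelowgroundVeryFast", "BelowgroundFast",
                 "AbovegroundVeryFast", "AbovegroundFast"):
        _decay_pool(p, DOM_INDEX[name], edr, flows.p_air, decay_mult, ledger)

    # 6. emission from the aboveground slow pool
    _decay_pool(p, DOM_INDEX["AbovegroundSlow"], edr, flows.p_air,
                decay_mult, ledger)

    # 7. humified transfer from aboveground slow to belowground slow
    mix = p[:, _iAGS] * flows.slow_mixing
    p[:, _iAGS] -= mix
    p[:, _iBGS] += mix
    ledger.dom_transfer += mix

    # 8. growth of live pools
    growth = np.asarray(npp, dtype=float) * np.asarray(growth_mult,
                                                       dtype=float)
    growth = np.broadcast_to(growth, (n,))
    p[:, :N_LIVE] += growth[:, None] * pnpp
    ledger.npp += growth

    return p, ledger


# ---------------------------------------------------------------------------
# transition-triggered flows

@dataclass
class _CompiledMatrix:
    transfer: np.ndarray      # (14, 14) incl. retained diagonal
    to_atm: np.ndarray        # (14,)
    to_export: np.ndarray     # (14,)
    live_to_dom: np.ndarray   # (14,) proportion of each live pool to DOM


class DisturbanceMatrix:
    """Proportional pool moves triggered by an LULC/disturbance transition.

    Built from the long-format CSV ``{transition_type, source_pool,
    destination, proportion}``; destinations are pools, "atmosphere"
    (combustion) or "export" (harvested wood).
    """

    def __init__(self, df: pd.DataFrame):
        self._compiled: dict[str, _CompiledMatrix] = {}
        for ttype, grp in df.groupby("transition_type"):
            transfer = np.eye(N_POOLS)
            to_atm = np.zeros(N_POOLS)
            to_export = np.zeros(N_POOLS)
            live_to_dom = np.zeros(N_POOLS)
            for _, r in grp.iterrows():
                src = POOL_INDEX[r["source_pool"]]
                prop = float(r["proportion"])
                transfer[src, src] -= prop
                if r["destination"] == ATMOSPHERE:
                    to_atm[src] += prop
                elif r["destination"] == EXPORT:
                    to_export[src] += prop
                else:
                    dst = POOL_INDEX[r["destination"]]
                    transfer[src, dst] += prop
                    if src < N_LIVE <= dst:
                        live_to_dom[src] += prop
            diag = np.diag(transfer).copy()
            if (diag < -1e-9).any():
                raise io.LoadError(
                    f"{ttype}: proportions exceed 1 for a source pool")
            # snap float cancellation (proportions summing to exactly 1)
            diag[np.abs(diag) < 1e-12] = 0.0
            np.fill_diagonal(transfer, diag)
            self._compiled[ttype] = _CompiledMatrix(
                transfer, to_atm, to_export, live_to_dom)

    @classmethod
    def load(cls, path=None) -> "DisturbanceMatrix":
        return cls(io.read_disturbance_matrices(path))

    @property
    def types(self) -> list[str]:
        return sorted(self._compiled)

    def apply(self, pools: np.ndarray, transition: str
              ) -> tuple[np.ndarray, FluxLedger]:
        """Apply ``transition`` to every row of ``pools`` simultaneously.

        All proportions act on the pre-transition state.  Conservation:
        TEC_before = TEC_after + combustion + export.
        """
        if transition not in self._compiled:
            raise KeyError(f"unknown transition type {transition!r}; "
                           f"known: {self.types}")
        m = self._compiled[transition]
        p = np.asarray(pools, dtype=float)
        squeeze = p.ndim == 1
        p = np.atleast_2d(p)
        new = p @ m.transfer
        ledger = FluxLedger.zeros(p.shape[0])
        ledger.combustion += p @ m.to_atm
        ledger.export += p @ m.to_export
        ledger.mortality += p @ m.live_to_dom
        # DOM pool re-arrangements (excluding retained mass and live sources)
        dom_moves = m.transfer.copy()
        np.fill_diagonal(dom_moves, 0.0)
        ledger.dom_transfer += p[:, N_LIVE:] @ dom_moves[N_LIVE:].sum(axis=1)
        return (new[0] if squeeze else new), ledger
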