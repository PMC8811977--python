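"""Scenario orchestration: annual landscape timesteps and accounting.

Each simulated year: (i) climate multipliers are computed (or forced to 1
when climate effects are toggled off); (ii) the carbon engine advances all
active cells one base step; (iii) land-use/disturbance transitions are
scheduled and applied together with their triggered carbon flows (or
skipped when toggled off); (iv) ages and counters advance; (v) fluxes are
aggregated into annual accounts.  Accounting identities are enforced every
year: NEP = NPP - Rh, NBP = NEP - combustion - harvest export, and
dTEC = NBP (positive NBP = sink).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stsm
from .climate import MultiplierGrid, build_multipliers
from .engine import DisturbanceMatrix, FlowParams, FluxLedger, base_step
from .params import (ExpansionParams, NPPSchedule, SpeciesParams,
                     load_species, npp_from_reference, reference_simulation)
from .spinup import SpinupConfig, build_state_attribute_tables
from .stsm import LandscapeState, TransitionDefinition

log = logging.getLogger(__name__)

IDENTITY_RTOL = 1e-9


@dataclass
class ScenarioConfig:
    """Run settings, including the sensitivity-analysis toggles."""

    start_year: int = 2001
    end_year: int = 2020
    climate_effects: bool = True
    lulc_disturbance: bool = True
    rng_seed: int = 0
    cell_area_ha: float = 100.0      # 1-km cells
    postfire_recovery_probability: float = stsm.POSTFIRE_RECOVERY_PROBABILITY
    #: (high, medium, low) severity proportions applied inside fire
    #: perimeters supplied under the "fire" event key
    fire_severity_split: tuple[float, float, float] = (0.34, 0.33, 0.33)
    reforestation: dict | None = None   # {start_year, end_year, total_cells,
    #                                      forest_class}

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))


@dataclass
class ParameterSet:
    """Everything the engine needs, keyed by species index."""

    species: list[SpeciesParams]
    schedules: list[NPPSchedule]
    flows: FlowParams
    matrices: DisturbanceMatrix
    tables: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edr_by_species = np.stack(
            [self.flows.edr(sp.mean_temp) for sp in self.species])
        self.npp_stack = np.stack([s.npp for s in self.schedules])
        self.pnpp_stack = np.stack([s.pnpp for s in self.schedules])
        self.max_age = self.npp_stack.shape[1] - 1

    @property
    def species_names(self) -> list[str]:
        return [sp.species_name for sp in self.species]


def build_parameters(species_names: list[str] | None = None,
                     species_path=None, expansion_path=None,
                     flow_path=None, routing_path=None, matrix_path=None,
                     spinup_config: SpinupConfig | None = None,
                     with_tables: bool = True) -> ParameterSet:
    """Load parameter tables, build NPP schedules and (optionally) run the
    spin-up to produce state attribute tables."""
    species = load_species(species_path)
    if species_names is not None:
        by_name = {sp.species_name: sp for sp in species}
        species = [by_name[n] for n in species_names]
    flows = FlowParams.from_tables("default", flow_path, routing_path)
    matrices = DisturbanceMatrix.load(matrix_path)
    schedules = []
    for sp in species:
        expansion = ExpansionParams.for_species(sp.species_name,
                                                expansion_path)
        ref = reference_simulation(sp, expansion, flows)
        schedules.append(npp_from_reference(ref, flows.turnover))
    tables = {}
    if with_tables:
        tables = build_state_attribute_tables(
            species, schedules, flows, matrices, spinup_config)
    return ParameterSet(species, schedules, flows, matrices, tables)


@dataclass
class ClimateSeries:
    """Annual MAT/MAP grids plus 30-year normals."""

    years: list[int]
    mat: np.ndarray       # (n_years, rows, cols) degC
    map_mm: np.ndarray    # (n_years, rows, cols) mm
    t_norm: np.ndarray    # (rows, cols)
    p_norm: np.ndarray    # (rows, cols)

    def multipliers(self, year: int) -> MultiplierGrid:
        t = self.years.index(year)
        return build_multipliers(self.mat[t], self.map_mm[t],
                                 self.t_norm, self.p_norm)


@dataclass
class ScenarioResult:
    accounts: pd.DataFrame              # annual, whole landscape
    stratum_accounts: pd.DataFrame      # annual per stratum system/label
    state: LandscapeState               # final landscape
    nbp_raster: np.ndarray              # cumulative NBP (tons C/ha)


def _account_row(year, ledger: FluxLedger, tec_now, tec_prev, area_ha):
    npp = float(ledger.npp.sum())
    rh = float(ledger.rh.sum())
    comb = float(ledger.combustion.sum())
    exp = float(ledger.export.sum())
    return {
        "year": year, "npp": npp, "rh": rh, "nep": npp - rh,
        "combustion": comb, "harvest": exp,
        "mortality": float(ledger.mortality.sum()),
        "turnover": float(ledger.turnover.sum()),
        "nbp": npp - rh - comb - exp,
        "tec": tec_now, "delta_tec": tec_now - tec_prev,
        "cell_area_ha": area_ha,
    }


def run_scenario(config: ScenarioConfig, landscape: LandscapeState,
                 params: ParameterSet,
                 climate: ClimateSeries | None = None,
                 transition_defs: list[TransitionDefinition] | None = None,
                 events: dict[int, dict[str, np.ndarray]] | None = None,
                 rates: dict[int, dict[str, float]] | None = None
                 ) -> ScenarioResult:
    """Run an annual simulation over the landscape.

    ``events`` maps year -> {transition name -> event raster}; ``rates``
    maps year -> {transition name -> target cell count} for target-area
    scheduling.  Raises ``RuntimeError`` if an accounting identity is
    violated (with the offending year).
    """
    rng = np.random.default_rng(config.rng_seed)
    state = landscape.copy()
    defs = transition_defs if transition_defs is not None else []
    events = events or {}
    rates = rates or {}
    reforest_plan: dict[int, np.ndarray] = {}
    if config.reforestation and config.lulc_disturbance:
        rf = config.reforestation
        reforest_plan = stsm.schedule_reforestation(
            state, rf["eligibility_mask"], rf["start_year"], rf["end_year"],
            rf["total_cells"], rng)

    n = state.n_cells
    sp_idx_max = len(params.species)
    rows = []
    stratum_rows = []
    nbp_cum = np.zeros(n)
    tec_prev = float(state.pools.reshape(n, -1).sum() * config.cell_area_ha)

    for year in config.years:
        ledger = FluxLedger.zeros(n)

        # (i) climate multipliers
        if config.climate_effects and climate is not None:
            mult = climate.multipliers(year)
        else:
            mult = MultiplierGrid.unit(n)

        # (ii) base carbon step on active (forest or recovering) cells
        codes = state.state_class.ravel()
        sp_idx = stsm.species_index(codes)
        shrub = codes == stsm.POST_FIRE_SHRUBLAND
        shrub_species = np.where(
            shrub, stsm.species_index(state.species_memory.ravel()), -1)
        cell_species = np.where(shrub, shrub_species, sp_idx)
        active = (cell_species >= 0) & ~state.frozen.ravel()
        if (cell_species >= sp_idx_max).any():
            bad = np.nonzero(cell_species >= sp_idx_max)[0][:5]
            raise RuntimeError(f"year {year}: unknown species at cells {bad}")
        idx = np.nonzero(active)[0]
        if len(idx):
            spi = cell_species[idx]
            age_next = np.clip(state.age.ravel()[idx] + 1, 0, params.max_age)
            npp = params.npp_stack[spi, age_next]
            pnpp = params.pnpp_stack[spi, age_next]
            npp = np.where(shrub[idx], 0.0, npp)   # no growth until recovery
            edr = params.edr_by_species[spi]
            decay_mult = mult.decay_mult_per_pool(
                params.flows.q10)[idx] if config.climate_effects else None
            growth_mult = mult.npp_anom[idx]
            pools_flat = state.pools.reshape(n, -1)
            new_pools, step_ledger = base_step(
                pools_flat[idx], npp, pnpp, edr, params.flows,
                growth_mult=growth_mult, decay_mult=decay_mult)
            pools_flat[idx] = new_pools
            for name in ledger.__dataclass_fields__:
                getattr(ledger, name)[idx] += getattr(step_ledger, name)

        # (iii) transitions and triggered flows
        disturbed_reset = np.zeros(n, dtype=bool)
        transitioned = np.zeros(n, dtype=bool)
        if config.lulc_disturbance:
            ev_year = dict(events.get(year, {}))
            if "fire" in ev_year:
                # split the perimeter mask into stochastic severity masks
                burn = np.asarray(ev_year.pop("fire")).ravel().astype(bool)
                sev = stsm.assign_fire_severity(
                    np.nonzero(burn)[0], config.fire_severity_split, rng)
                for ttype, cells in sev.items():
                    mask = np.zeros(n, dtype=bool)
                    mask[cells] = True
                    ev_year[ttype] = mask.reshape(state.shape)
            assignments = stsm.schedule_transitions(
                state, defs, {**ev_year, **rates.get(year, {})}, rng)
            state, carbon_work = stsm.apply_transitions(
                state, assignments, defs)
            pools_flat = state.pools.reshape(n, -1)
            for ttype, cells in carbon_work:
                new_p, t_ledger = params.matrices.apply(
                    pools_flat[cells], ttype)
                pools_flat[cells] = new_p
                for name in ledger.__dataclass_fields__:
                    getattr(ledger, name)[cells] += getattr(t_ledger, name)
            for d in defs:
                cells = assignments.get(d.name, [])
                transitioned[cells] = True
                if d.age_reset:
                    disturbed_reset[cells] = True
            state, recovered = stsm.postfire_recovery(
                state, rng, config.postfire_recovery_probability)
            disturbed_reset[recovered] = True
            transitioned[recovered] = True
            if year in reforest_plan:
                cells = reforest_plan[year]
                codes = state.state_class.ravel()
                codes[cells] = config.reforestation["forest_class"]
                state.age.ravel()[cells] = 0
                state.frozen.ravel()[cells] = False
                disturbed_reset[cells] = True
                transitioned[cells] = True

        # (iv) age and counter bookkeeping
        grows = (stsm.is_forest(state.state_class.ravel())
                 & ~disturbed_reset & ~state.frozen.ravel())
        state.age.ravel()[grows] += 1
        state.time_since_transition.ravel()[~transitioned] += 1

        # (v) aggregate and verify identities
        area = config.cell_area_ha
        tec_now = float(state.pools.reshape(n, -1).sum() * area)
        row = {k: (v * area if k in (
            "npp", "rh", "nep", "combustion", "harvest", "mortality",
            "turnover", "nbp") else v)
            for k, v in _account_row(year, ledger, tec_now, tec_prev,
                                     area).items()}
        scale = max(abs(row["tec"]), abs(row["npp"]), 1.0)
        if abs(row["nep"] - (row["npp"] - row["rh"])) > IDENTITY_RTOL * scale:
            raise RuntimeError(f"year {year}: NEP identity violated")
        if abs(row["delta_tec"] - row["nbp"]) > IDENTITY_RTOL * scale:
            raise RuntimeError(
                f"year {year}: dTEC ({row['delta_tec']:.6g}) != NBP "
                f"({row['nbp']:.6g})")
        rows.append(row)
        tec_prev = tec_now
        nbp_cum += ledger.net_flux()

        for system, labels in state.strata.items():
            flat = labels.ravel()
            for lab in np.unique(flat):
                sel = flat == lab
                stratum_rows.append({
                    "year": year, "stratum_system": system,
                    "stratum": lab,
                    "npp": float(ledger.npp[sel].sum()) * area,
                    "rh": float(ledger.rh[sel].sum()) * area,
                    "combustion": float(ledger.combustion[sel].sum()) * area,
                    "harvest": float(ledger.export[sel].sum()) * area,
                    "nbp": float(ledger.net_flux()[sel].sum()) * area,
                })
        log.info("year %d: NBP %.2f tons C", year, row["nbp"])

    return ScenarioResult(
        accounts=pd.DataFrame(rows),
        stratum_accounts=pd.DataFrame(stratum_rows),
        state=state,
        nbp_raster=nbp_cum.reshape(state.shape))


def aggregate_outputs(result: ScenarioResult, cell_area_ha: float = 100.0
                      ) -> dict[str, pd.DataFrame]:
    """Density and mass views of the annual accounts.

    Mass columns are reported both in tons C and Tg C (1 Tg = 1e6 tons).
    """
    acc = result.accounts.copy()
    n_ha = result.nbp_raster.size * cell_area_ha
    dens = acc.copy()
    for col in ("npp", "rh", "nep", "combustion", "harvest", "nbp"):
        dens[col] = acc[col] / n_ha
    mass_tg = acc.copy()
    for col in ("npp", "rh", "nep", "combustion", "harvest", "nbp", "tec",
                "delta_tec"):
        mass_tg[col] = acc[col] / 1e6
    return {"mass_tons": acc, "density_tons_per_ha": dens,
            "mass_tg": mass_tg}
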