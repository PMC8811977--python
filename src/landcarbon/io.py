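"""Table readers/writers, schema validation, and the run manifest.

All parameter tables are plain CSV.  Packaged defaults live in
``landcarbon/data`` and are returned when no path is given.  Every reader
validates its schema and value invariants and raises :class:`LoadError`
with a descriptive message on violation.
"""

from __future__ import annotations

import hashlib
import json
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .pools import ALL_POOLS, DOM_POOLS, LIVE_POOLS

__all__ = [
    "LoadError",
    "data_path",
    "read_species_params",
    "read_expansion_params",
    "read_flow_params",
    "read_turnover_routing",
    "read_disturbance_matrices",
    "write_stock_tables",
    "read_stock_tables",
    "write_manifest",
]

SPECIES_COLUMNS = [
    "species_name", "ecozone", "province", "cbm_species",
    "a", "b", "mean_temp_c", "mri_years",
]


class LoadError(ValueError):
    """A parameter file failed schema or invariant validation."""


def data_path(name: str) -> Path:
    """Path to a packaged default parameter file."""
    return Path(resources.files("landcarbon") / "data" / name)


def _read_csv(path: str | Path | None, default_name: str) -> pd.DataFrame:
    src = Path(path) if path is not None else data_path(default_name)
    if not src.exists():
        raise LoadError(f"parameter file not found: {src}")
    return pd.read_csv(src, comment="#", skip_blank_lines=True)


def read_species_params(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate the species (forest type-group) parameter table.

    Columns: species_name, ecozone, province, cbm_species, a, b,
    mean_temp_c, mri_years.  ``a`` and ``b`` parameterize the merchantable
    volume growth curve; ``mean_temp_c`` is the range mean annual
    temperature used to derive effective decay rates; ``mri_years`` is the
    mean historical fire return interval driving the spin-up.
    """
    df = _read_csv(path, "species_params.csv")
    missing = set(SPECIES_COLUMNS) - set(df.columns)
    if missing:
        raise LoadError(f"species table missing columns: {sorted(missing)}")
    df = df[SPECIES_COLUMNS].copy()
    for col in ("a", "b", "mean_temp_c", "mri_years"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise LoadError(f"species column {col!r} must be numeric")
    if (df["a"] <= 0).any():
        bad = df.loc[df["a"] <= 0, "species_name"].tolist()
        raise LoadError(f"asymptote 'a' must be > 0; offending species: {bad}")
    if (df["b"] <= 0).any():
        bad = df.loc[df["b"] <= 0, "species_name"].tolist()
        raise LoadError(f"rate 'b' must be > 0; offending species: {bad}")
    if (df["mri_years"] < 1).any():
        bad = df.loc[df["mri_years"] < 1, "species_name"].tolist()
        raise LoadError(f"mri_years must be >= 1; offending species: {bad}")
    dups = df["species_name"][df["species_name"].duplicated()].tolist()
    if dups:
        raise LoadError(f"duplicate species names: {dups}")
    return df.reset_index(drop=True)


def read_expansion_params(path: str | Path | None = None) -> pd.DataFrame:
    """Load the volume-to-biomass expansion factor table."""
    df = _read_csv(path, "expansion_params.csv")
    required = {"species_name", "foliage", "merchantable", "other_wood",
                "coarse_root", "fine_root", "carbon_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"expansion table missing columns: {sorted(missing)}")
    factors = df[["foliage", "merchantable", "other_wood",
                  "coarse_root", "fine_root"]].to_numpy(float)
    if (factors < 0).any():
        raise LoadError("expansion factors must be >= 0")
    cf = df["carbon_fraction"].to_numpy(float)
    if ((cf <= 0) | (cf > 1)).any():
        raise LoadError("carbon_fraction must be in (0, 1]")
    return df


def read_flow_params(path: str | Path | None = None) -> pd.DataFrame:
    """Load the long-format base flow-rate table."""
    df = _read_csv(path, "flow_params.csv")
    required = {"species_name", "parameter", "pool", "value"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"flow table missing columns: {sorted(missing)}")
    known = {"turnover", "snag_fall", "base_decay_rate", "p_air", "q10",
             "slow_mixing"}
    bad = set(df["parameter"]) - known
    if bad:
        raise LoadError(f"unknown flow parameters: {sorted(bad)}")
    bad_pools = set(df["pool"]) - set(ALL_POOLS)
    if bad_pools:
        raise LoadError(f"unknown pools in flow table: {sorted(bad_pools)}")
    rates = df.loc[df["parameter"] != "q10", "value"]
    if ((rates < 0) | (rates > 1)).any():
        raise LoadError("flow rates and proportions must lie in [0, 1]")
    if (df.loc[df["parameter"] == "q10", "value"] <= 0).any():
        raise LoadError("q10 must be > 0")
    return df


def read_turnover_routing(path: str | Path | None = None) -> pd.DataFrame:
    """Load the live-to-DOM turnover destination split."""
    df = _read_csv(path, "turnover_routing.csv")
    required = {"source_pool", "destination_pool", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"routing table missing columns: {sorted(missing)}")
    if set(df["source_pool"]) - set(LIVE_POOLS):
        raise LoadError("routing sources must be live pools")
    if set(df["destination_pool"]) - set(DOM_POOLS):
        raise LoadError("routing destinations must be DOM pools")
    sums = df.groupby("source_pool")["fraction"].sum()
    off = sums[~np.isclose(sums, 1.0, atol=1e-9)]
    if len(off):
        raise LoadError(f"routing fractions must sum to 1: {off.to_dict()}")
    return df


def read_disturbance_matrices(path: str | Path | None = None) -> pd.DataFrame:
    """Load the long-format transition-triggered flow table."""
    df = _read_csv(path, "disturbance_matrices.csv")
    required = {"transition_type", "source_pool", "destination", "proportion"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"matrix table missing columns: {sorted(missing)}")
    if set(df["source_pool"]) - set(ALL_POOLS):
        bad = sorted(set(df["source_pool"]) - set(ALL_POOLS))
        raise LoadError(f"unknown source pools: {bad}")
    valid_dest = set(ALL_POOLS) | {"atmosphere", "export"}
    if set(df["destination"]) - valid_dest:
        bad = sorted(set(df["destination"]) - valid_dest)
        raise LoadError(f"unknown destinations: {bad}")
    if (df["proportion"] < 0).any():
        raise LoadError("matrix proportions must be >= 0")
    sums = df.groupby(["transition_type", "source_pool"])["proportion"].sum()
    off = sums[sums > 1 + 1e-9]
    if len(off):
        raise LoadError(
            f"matrix proportions exceed 1 per source pool: {off.to_dict()}")
    return df


# ---------------------------------------------------------------------------
# stock-by-age table serialization (tidy long CSV)

def write_stock_tables(tables, path: str | Path) -> None:
    """Serialize stock-by-age tables as tidy CSV.

    ``tables`` is an iterable of objects with ``species_name``,
    ``last_disturbance`` and ``stocks`` (ages x 14 pools) attributes.
    """
    frames = []
    for t in tables:
        ages = np.arange(t.stocks.shape[0])
        df = pd.DataFrame(t.stocks, columns=list(ALL_POOLS))
        df.insert(0, "age", ages)
        df.insert(0, "last_disturbance", t.last_disturbance)
        df.insert(0, "species", t.species_name)
        frames.append(df.melt(
            id_vars=["species", "last_disturbance", "age"],
            var_name="pool", value_name="tons_c_per_ha"))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_stock_tables(path: str | Path):
    """Inverse of :func:`write_stock_tables`.

    Returns ``{(species, last_disturbance): ndarray (n_ages, 14)}``.
    """
    df = pd.read_csv(path)
    out = {}
    for (sp, dist), grp in df.groupby(["species", "last_disturbance"]):
        wide = grp.pivot(index="age", columns="pool", values="tons_c_per_ha")
        wide = wide.sort_index()[list(ALL_POOLS)]
        out[(sp, dist)] = wide.to_numpy(float)
    return out


# ---------------------------------------------------------------------------
# run manifest

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(outdir: str | Path, config: dict, seeds: dict,
                   param_files: dict[str, str | Path] | None = None,
                   started: float | None = None) -> Path:
    """Write a JSON run manifest atomically (write temp, then rename)."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "config": config,
        "seeds": seeds,
        "parameter_checksums": {
            k: _checksum(Path(v)) for k, v in (param_files or {}).items()
        },
        "wallclock_start": started,
        "wallclock_end": time.time(),
    }
    target = outdir / "manifest.json"
    tmp = target.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    tmp.replace(target)
    return target
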