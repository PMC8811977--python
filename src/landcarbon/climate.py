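"""Climate-driven growth and decay multipliers.

Annual growth is scaled by an NPP anomaly: a climatological NPP estimate
(minimum of a precipitation-limited and a temperature-limited function)
for the current year divided by the same estimate under 30-year normals.
Decay rates are scaled by a Q10 multiplier of the temperature anomaly.
All multipliers equal exactly 1 when the climate equals the normals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pools import DOM_POOLS

log = logging.getLogger(__name__)

Q10_FAST = 2.65
Q10_SLOW = 2.00


def npp_precip(map_mm):
    """Precipitation-limited NPP (g C/m2/yr) from total annual
    precipitation in mm: ``0.551 * MAP**1.055 / exp(0.000306 * MAP)``."""
    map_mm = np.asarray(map_mm, dtype=float)
    if (map_mm < 0).any():
        raise ValueError("precipitation must be >= 0")
    out = 0.551 * map_mm ** 1.055 / np.exp(0.000306 * map_mm)
    return float(out) if out.ndim == 0 else out


def npp_temp(mat_c):
    """Temperature-limited NPP (g C/m2/yr) from mean annual temperature:
    a logistic curve saturating at 2540."""
    mat_c = np.asarray(mat_c, dtype=float)
    out = 2540.0 / (1.0 + np.exp(1.584 - 0.0622 * mat_c))
    return float(out) if out.ndim == 0 else out


def npp_climate(map_mm, mat_c):
    """Climatological NPP: elementwise MIN of the two limitations."""
    out = np.minimum(npp_precip(map_mm), npp_temp(mat_c))
    return float(out) if np.ndim(out) == 0 else out


def npp_anomaly(npp_t, mu_npp):
    """Growth multiplier: current-year NPP over the normal-period NPP.

    Cells with ``mu_npp == 0`` get multiplier 1 (flagged in the log).
    """
    npp_t = np.asarray(npp_t, dtype=float)
    mu = np.asarray(mu_npp, dtype=float)
    zero = mu == 0
    if zero.any():
        log.warning("npp_anomaly: %d cells with zero normal NPP set to 1",
                    int(np.count_nonzero(zero)))
    out = np.divide(npp_t, mu, out=np.ones_like(npp_t * 1.0), where=~zero)
    return float(out) if out.ndim == 0 else out


def decay_multiplier(t_mean, t_norm, q10):
    """DM = Q10 ** ((T_mean - T_norm) / 10)."""
    if (np.asarray(q10) <= 0).any():
        raise ValueError("Q10 must be > 0")
    out = np.asarray(q10, dtype=float) ** (
        (np.asarray(t_mean, dtype=float)
         - np.asarray(t_norm, dtype=float)) / 10.0)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class MultiplierGrid:
    """Per-cell growth and decay multipliers for one year."""

    npp_anom: np.ndarray
    dm_fast: np.ndarray     # Q10 = 2.65 pools
    dm_slow: np.ndarray     # Q10 = 2.00 pools

    def decay_mult_per_pool(self, q10: np.ndarray) -> np.ndarray:
        """(n, 9) decay multiplier matched to each DOM pool's Q10.

        Pools with Q10 equal to ``Q10_FAST`` take ``dm_fast``; all others
        take ``dm_slow``.
        """
        fast = np.isclose(np.broadcast_to(q10, (len(DOM_POOLS),)), Q10_FAST)
        return np.where(fast[None, :], self.dm_fast.reshape(-1, 1),
                        self.dm_slow.reshape(-1, 1))

    @classmethod
    def unit(cls, n: int) -> "MultiplierGrid":
        one = np.ones(n)
        return cls(one, one.copy(), one.copy())


def build_multipliers(mat, map_mm, t_norm, p_norm) -> MultiplierGrid:
    """Compute all multipliers for one year of climate grids.

    The normal-period NPP is derived by running the normals through the
    same precipitation/temperature/min pipeline, so units cancel in the
    anomaly ratio.  NaN climate cells (nodata) get multiplier 1.
    """
    mat = np.asarray(mat, dtype=float).ravel()
    map_mm = np.asarray(map_mm, dtype=float).ravel()
    t_norm = np.asarray(t_norm, dtype=float).ravel()
    p_norm = np.asarray(p_norm, dtype=float).ravel()
    nodata = (np.isnan(mat) | np.isnan(map_mm)
              | np.isnan(t_norm) | np.isnan(p_norm))
    if nodata.any():
        log.warning("build_multipliers: %d nodata cells set to 1",
                    int(np.count_nonzero(nodata)))
        mat = np.where(nodata, 0.0, mat)
        map_mm = np.where(nodata, 0.0, map_mm)
        t_norm = np.where(nodata, 0.0, t_norm)
        p_norm = np.where(nodata, 1.0, p_norm)
    mu = npp_climate(p_norm, t_norm)
    anom = npp_anomaly(npp_climate(map_mm, mat), mu)
    dm_fast = decay_multiplier(mat, t_norm, Q10_FAST)
    dm_slow = decay_multiplier(mat, t_norm, Q10_SLOW)
    if nodata.any():
        anom = np.where(nodata, 1.0, anom)
        dm_fast = np.where(nodata, 1.0, dm_fast)
        dm_slow = np.where(nodata, 1.0, dm_slow)
    return MultiplierGrid(anom, dm_fast, dm_slow)
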