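"""Unit bridges between the iron and carbon pools.

Carbon biomass is carried in µmol C L⁻¹, cellular and dissolved iron in
nmol Fe L⁻¹, and iron quotas (Fe:C) in µmol Fe per mol C.  Every
conversion between those scales goes through the two helpers below so
the factor of 10³ lives in exactly one place.
"""

from __future__ import annotations

import numpy as np

#: grams of carbon per mole, used for Chl:C (µg Chl per µg C) ratios
GRAMS_C_PER_MOL = 12.0

#: nmol Fe per (µmol Fe mol C⁻¹ × µmol C L⁻¹)
_QUOTA_TO_POOL = 1.0e-3


def quota_from_pools(fe_pool: np.ndarray, c_pool: np.ndarray) -> np.ndarray:
    """Cellular Fe:C quota (µmol Fe mol C⁻¹) from an Fe pool (nmol Fe L⁻¹)
    and a carbon pool (µmol C L⁻¹).  Returns 0 where the carbon pool is 0."""
    c = np.asarray(c_pool, dtype=float)
    fe = np.asarray(fe_pool, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(c > 0.0, fe / np.where(c > 0.0, c, 1.0) / _QUOTA_TO_POOL, 0.0)
    return q


def pool_from_quota(quota: np.ndarray, c_pool: np.ndarray) -> np.ndarray:
    """Fe pool (nmol Fe L⁻¹) equivalent to a quota (µmol Fe mol C⁻¹)
    carried by a carbon pool (µmol C L⁻¹)."""
    return np.asarray(quota, dtype=float) * np.asarray(c_pool, dtype=float) * _QUOTA_TO_POOL


def fe_flux_from_specific_uptake(specific_uptake: np.ndarray, c_pool: np.ndarray) -> np.ndarray:
    """Volumetric Fe flux (nmol Fe L⁻¹ d⁻¹) from a carbon-specific uptake
    rate (µmol Fe mol C⁻¹ d⁻¹) and biomass (µmol C L⁻¹)."""
    return np.asarray(specific_uptake, dtype=float) * np.asarray(c_pool, dtype=float) * _QUOTA_TO_POOL


def theta_from_pools(chl_pool: np.ndarray, c_pool: np.ndarray) -> np.ndarray:
    """Chl:C mass ratio (µg Chl per µg C) from chlorophyll (µg Chl L⁻¹)
    and carbon (µmol C L⁻¹) pools.  Returns 0 where carbon is 0."""
    c = np.asarray(c_pool, dtype=float)
    chl = np.asarray(chl_pool, dtype=float)
    denom = GRAMS_C_PER_MOL * np.where(c > 0.0, c, 1.0)
    return np.where(c > 0.0, chl / denom, 0.0)
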