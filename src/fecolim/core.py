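"""Process rate laws and the assembled time derivative of the model state.

The model tracks two biological pools — phytoplankton (carbon,
chlorophyll, cellular Fe) and heterotrophic bacteria (carbon, cellular
Fe) — competing for dissolved iron in a closed 0-D volume, plus the two
dissolved resources (dFe, labile DOC).  Phytoplankton growth is limited
by light (Geider-type photoacclimation) and by the internal Fe quota
(Droop-style); bacterial growth by labile DOC (Monod) and the Fe quota.
Both populations take up Fe in proportion to external availability with
luxury storage up to a shared maximum quota, at which uptake shuts off.
Quadratic mortality recycles carbon to labile DOC and cellular Fe to
dissolved Fe; phytoplankton exude a fixed fraction of fixation as DOC.

All functions broadcast over trailing array dimensions so a whole
experiment grid integrates as one vectorized system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters
from .units import (
    GRAMS_C_PER_MOL,
    fe_flux_from_specific_uptake,
    pool_from_quota,
    quota_from_pools,
    theta_from_pools,
)

# state-vector layout (prognostic pools)
P_C, P_CHL, P_FE, B_C, B_FE, DFE, LDOC = range(7)
NSTATE = 7
# appended cumulative Fe-uptake integrals (pure accumulators, no feedback)
CUM_FE_UP_P, CUM_FE_UP_B = 7, 8
NAUG = 9

STATE_NAMES = ("P_C", "P_Chl", "P_Fe", "B_C", "B_Fe", "dFe", "LDOC")
STATE_UNITS = (
    "umol C/L", "ug Chl/L", "nmol Fe/L", "umol C/L", "nmol Fe/L",
    "nmol Fe/L", "umol C/L",
)


@dataclass(frozen=True)
class ModelState:
    """The seven prognostic pools.  See STATE_UNITS for units."""

    P_C: float = 0.1
    P_Chl: float = 0.032
    P_Fe: float = 0.001
    B_C: float = 0.1
    B_Fe: float = 0.001
    dFe: float = 0.5
    LDOC: float = 5.0

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.P_C, self.P_Chl, self.P_Fe, self.B_C, self.B_Fe,
             self.dFe, self.LDOC], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(float(v) for v in np.asarray(y)[:NSTATE]))

    @classmethod
    def initial(cls, dFe: float, LDOC: float, P_C: float = 0.1,
                B_C: float = 0.1, quota: float = 10.0,
                theta: float | None = None,
                params: ModelParameters | None = None) -> "ModelState":
        """Standard initial condition: small inoculum of each population at
        a quota of 10 µmol Fe mol C⁻¹ and a mid-band Chl:C ratio."""
        if theta is None:
            p = params or ModelParameters()
            theta = 0.5 * (p.theta_min + p.theta_max)
        return cls(
            P_C=P_C,
            P_Chl=theta * GRAMS_C_PER_MOL * P_C,
            P_Fe=float(pool_from_quota(quota, P_C)),
            B_C=B_C,
            B_Fe=float(pool_from_quota(quota, B_C)),
            dFe=dFe,
            LDOC=LDOC,
        )

    def validate(self, params: ModelParameters | None = None) -> None:
        y = self.to_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite value in model state")
        if np.any(y < 0.0):
            bad = STATE_NAMES[int(np.argmin(y))]
            raise ValueError(f"negative pool in model state: {bad}")
        if params is not None:
            for c, fe, name in ((self.P_C, self.P_Fe, "Q_P"),
                                (self.B_C, self.B_Fe, "Q_B")):
                if c > 0:
                    q = float(quota_from_pools(fe, c))
                    if q > params.Q_max * (1.0 + 1e-9):
                        raise ValueError(f"{name} = {q:.3f} exceeds Q_max")

    def total_fe(self) -> float:
        """dFe + cellular Fe of both populations (nmol Fe L⁻¹)."""
        return self.P_Fe + self.B_Fe + self.dFe


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

def temperature_factor(T, params: ModelParameters):
    """Eppley multiplier b**T on the maximum specific growth rates."""
    return np.power(params.temp_coeff_b, T)


def doc_limitation(ldoc, K_DOC: float):
    """Monod limitation of bacterial growth by labile DOC, in [0, 1)."""
    ldoc = np.asarray(ldoc, dtype=float)
    if np.any(ldoc < 0.0):
        raise ValueError("negative labile DOC passed to doc_limitation")
    return ldoc / (ldoc + K_DOC)


def fe_limitation(quota, Q_min: float, Q_opt: float):
    """Quota (Droop-style) Fe limitation: 0 at the subsistence quota,
    rising linearly and saturating at Q_min + Q_opt."""
    return np.clip((np.asarray(quota, dtype=float) - Q_min) / Q_opt, 0.0, 1.0)


def fe_uptake(biomass_c, dfe, quota, V_max: float, K_Fe: float, Q_max: float):
    """Volumetric Fe uptake (nmol Fe L⁻¹ d⁻¹).

    Monod in external Fe, down-regulated linearly as the cellular quota
    approaches Q_max (luxury storage: uptake continues while growth is
    otherwise limited, until the store is full).
    """
    monod = np.asarray(dfe, dtype=float) / (np.asarray(dfe, dtype=float) + K_Fe)
    headroom = np.clip(1.0 - np.asarray(quota, dtype=float) / Q_max, 0.0, None)
    return fe_flux_from_specific_uptake(V_max * monod * headroom, biomass_c)


def light_limitation_and_fixation(par, theta, mu_potential, params: ModelParameters):
    """Light limitation term and the specific carbon-fixation rate (d⁻¹).

    ``mu_potential`` is the light-saturated, Fe-limited maximum growth
    rate µ_max(T)·L_Fe; the realized fixation rate is µ_potential·L_light.
    """
    par = np.asarray(par, dtype=float)
    mu_potential = np.asarray(mu_potential, dtype=float)
    safe_mu = np.where(mu_potential > 0.0, mu_potential, 1.0)
    expo = np.where(mu_potential > 0.0,
                    params.alpha_PI * np.asarray(theta) * par / safe_mu, 0.0)
    l_light = -np.expm1(-expo)
    return l_light, mu_potential * l_light


def chlorophyll_synthesis(c_fix_net, par, theta, mu_net, params: ModelParameters):
    """Chlorophyll synthesis flux (µg Chl L⁻¹ d⁻¹), Geider photoacclimation.

    New chlorophyll is produced in proportion to net carbon growth with a
    Chl:C allocation ρ = θ_max · µ / (α θ E) clipped to the photoadaptive
    band [θ_min, θ_max]: at low light ρ → θ_max (pigment-rich cells), at
    high light ρ falls toward θ_min.  Zero in the dark.
    """
    par = np.asarray(par, dtype=float)
    theta = np.asarray(theta, dtype=float)
    denom = params.alpha_PI * theta * par
    lit = denom > 0.0
    rho = np.where(lit,
                   params.theta_max * np.asarray(mu_net) / np.where(lit, denom, 1.0),
                   params.theta_max)
    rho = np.clip(rho, params.theta_min, params.theta_max)
    return rho * GRAMS_C_PER_MOL * np.asarray(c_fix_net, dtype=float)


def bacterial_growth_and_doc_uptake(b_c, ldoc, q_b, T, params: ModelParameters,
                                    dfe=None):
    """Bacterial specific growth (d⁻¹), DOC uptake and respiration fluxes.

    Growth is Monod in labile DOC and quota-limited in Fe; of the DOC
    consumed, a fraction BGE becomes biomass and the rest is respired.
    In the fixed-quota (no luxury storage) variant Fe limitation is the
    external Monod term at the clamped quota.
    """
    l_doc = doc_limitation(ldoc, params.K_DOC)
    if params.luxury_uptake_B:
        l_fe = fe_limitation(q_b, params.Q_min_B, params.Q_opt_B)
    else:
        if dfe is None:
            raise ValueError("fixed-quota variant needs the dissolved Fe pool")
        # growth capacity of cells pinned at the fixed quota, times an
        # external Monod term so uptake demand cannot outrun supply
        dfe = np.asarray(dfe, dtype=float)
        l_fe = (dfe / (dfe + params.K_Fe_B)) * fe_limitation(
            params.Q_B_fixed, params.Q_min_B, params.Q_opt_B)
    mu_b = params.mu_max_B_ref * temperature_factor(T, params) * l_fe * l_doc
    doc_uptake = mu_b * np.asarray(b_c, dtype=float) / params.BGE
    respiration = (1.0 - params.BGE) * doc_uptake
    return mu_b, doc_uptake, respiration


def quadratic_mortality(biomass_c, m: float):
    """Density-dependent loss m·X² (µmol C L⁻¹ d⁻¹), standing in for
    grazing and viral lysis."""
    x = np.asarray(biomass_c, dtype=float)
    return m * x * x


# ---------------------------------------------------------------------------
# assembled derivative
# ---------------------------------------------------------------------------

def compute_fluxes(y: np.ndarray, par, T, params: ModelParameters) -> dict:
    """Every instantaneous flux and limitation term at state ``y``.

    ``y`` has shape (NSTATE, ...) or (NAUG, ...); PAR and T broadcast
    against the trailing dimensions.
    """
    # intermediate integrator stages may probe slightly negative pools;
    # rate laws are evaluated on the admissible (clipped) state
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    p_c, p_chl, p_fe = y[P_C], y[P_CHL], y[P_FE]
    b_c, b_fe = y[B_C], y[B_FE]
    dfe, ldoc = y[DFE], y[LDOC]

    q_p = quota_from_pools(p_fe, p_c)
    theta = theta_from_pools(p_chl, p_c)

    mu_max_T_P = params.mu_max_P_ref * temperature_factor(T, params)
    l_fe_p = fe_limitation(q_p, params.Q_min_P, params.Q_opt_P)
    mu_potential = mu_max_T_P * l_fe_p
    l_light, mu_gross = light_limitation_and_fixation(par, theta, mu_potential, params)

    c_fix = mu_gross * p_c                         # gross fixation
    exud = params.exud_frac * c_fix
    c_fix_net = c_fix - exud
    mu_p_net = (1.0 - params.exud_frac) * mu_gross

    chl_syn = chlorophyll_synthesis(c_fix_net, par, theta, mu_p_net, params)

    if params.luxury_uptake_B:
        q_b = quota_from_pools(b_fe, b_c)
        mu_b, doc_uptake, respiration = bacterial_growth_and_doc_uptake(
            b_c, ldoc, q_b, T, params)
        l_fe_b = fe_limitation(q_b, params.Q_min_B, params.Q_opt_B)
        # energy gate: active Fe transport runs on DOC catabolism, so
        # carbon-starved cells retain only a maintenance-level capacity
        gate = np.maximum(doc_limitation(ldoc, params.K_DOC_gate),
                          params.fe_uptake_gate_floor)
        fe_up_b = gate * fe_uptake(b_c, dfe, q_b, params.V_max_Fe_B,
                                   params.K_Fe_B, params.Q_max)
    else:
        q_b = np.broadcast_to(params.Q_B_fixed, np.shape(b_c)).astype(float) \
            if np.shape(b_c) else np.asarray(params.Q_B_fixed, dtype=float)
        mu_b, doc_uptake, respiration = bacterial_growth_and_doc_uptake(
            b_c, ldoc, q_b, T, params, dfe=dfe)
        l_fe_b = (dfe / (dfe + params.K_Fe_B)) * fe_limitation(
            params.Q_B_fixed, params.Q_min_B, params.Q_opt_B)
        # Fe uptake exactly covers growth demand at the clamped quota
        fe_up_b = pool_from_quota(params.Q_B_fixed, mu_b * np.asarray(b_c))

    # phytoplankton Fe transport runs on photosynthetic energy: scaled by
    # the light term with a maintenance floor (dark uptake is residual)
    gate_p = np.maximum(l_light, params.fe_uptake_gate_floor_P)
    fe_up_p = gate_p * fe_uptake(p_c, dfe, q_p, params.V_max_Fe_P,
                                 params.K_Fe_P, params.Q_max)

    mort_p = quadratic_mortality(p_c, params.m_P)
    mort_b = quadratic_mortality(b_c, params.m_B)
    # mortality removes Fe and Chl at the cell's current ratios
    fe_mort_p = pool_from_quota(q_p, mort_p)
    fe_mort_b = pool_from_quota(q_b, mort_b)
    chl_mort = theta * GRAMS_C_PER_MOL * mort_p

    return {
        "mu_P": mu_p_net, "mu_B": mu_b, "C_fix": c_fix,
        "exud_flux": exud, "DOC_uptake": doc_uptake,
        "respiration": respiration,
        "Fe_uptake_P": fe_up_p, "Fe_uptake_B": fe_up_b,
        "mort_P": mort_p, "mort_B": mort_b,
        "Fe_mort_P": fe_mort_p, "Fe_mort_B": fe_mort_b,
        "chl_synthesis": chl_syn, "chl_mort": chl_mort,
        "L_light": l_light, "L_Fe_P": l_fe_p, "L_Fe_B": l_fe_b,
        "L_DOC": doc_limitation(ldoc, params.K_DOC),
        "Q_P": q_p, "Q_B": q_b, "theta": theta,
    }


DIAGNOSTIC_NAMES = (
    "mu_P", "mu_B", "C_fix", "exud_flux", "DOC_uptake", "respiration",
    "Fe_uptake_P", "Fe_uptake_B", "mort_P", "mort_B",
    "L_light", "L_Fe_P", "L_Fe_B", "L_DOC", "Q_P", "Q_B", "theta",
)


def derivatives(y: np.ndarray, par, T, params: ModelParameters) -> np.ndarray:
    """Time derivative of the augmented state (7 pools + 2 cumulative
    Fe-uptake integrals).  Accepts (NSTATE, ...) or (NAUG, ...) input and
    always returns (NAUG, ...)."""
    y = np.asarray(y, dtype=float)
    f = compute_fluxes(y, par, T, params)
    dy = np.zeros((NAUG,) + y.shape[1:], dtype=float)
    dy[P_C] = f["C_fix"] - f["exud_flux"] - f["mort_P"]
    dy[P_CHL] = f["chl_synthesis"] - f["chl_mort"]
    dy[P_FE] = f["Fe_uptake_P"] - f["Fe_mort_P"]
    dy[B_C] = f["mu_B"] * y[B_C] - f["mort_B"]
    dy[B_FE] = f["Fe_uptake_B"] - f["Fe_mort_B"]
    dy[DFE] = (-f["Fe_uptake_P"] - f["Fe_uptake_B"]
               + params.mort_Fe_frac * (f["Fe_mort_P"] + f["Fe_mort_B"]))
    dy[LDOC] = (f["exud_flux"]
                + params.mort_DOC_frac_P * f["mort_P"]
                + params.mort_DOC_frac_B * f["mort_B"]
                - f["DOC_uptake"])
    dy[CUM_FE_UP_P] = f["Fe_uptake_P"]
    dy[CUM_FE_UP_B] = f["Fe_uptake_B"]
    return dy


def rate_diagnostics(y: np.ndarray, par, T, params: ModelParameters) -> dict:
    """Named instantaneous diagnostics (the RateDiagnostics record)."""
    f = compute_fluxes(y, par, T, params)
    return {k: f[k] for k in DIAGNOSTIC_NAMES}
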