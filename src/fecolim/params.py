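"""Model parameters: rate constants, half-saturations, quotas and fractions.

Default values follow the PISCES-v2 family of parameterizations where the
process is shared with that model (Eppley temperature scaling, Geider-type
photoacclimation bounds, quota-based iron limitation, 10% exudation, a
shared 80 µmol Fe mol C⁻¹ maximum quota) and otherwise sit in the ranges
typical of cold-ocean plankton; see docs/methods.md for the rationale
behind every free constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace, asdict
from typing import Any


@dataclass(frozen=True)
class ModelParameters:
    """All tunable constants of the model, with units in the metadata.

    Attributes
    ----------
    mu_max_P_ref, mu_max_B_ref : float
        Maximum specific growth rates of phytoplankton and bacteria at the
        0 °C reference temperature, d⁻¹.
    temp_coeff_b : float
        Eppley temperature base; the maximum rates scale as ``b**T``.
    alpha_PI : float
        Initial slope of the photosynthesis–irradiance curve,
        g C (g Chl)⁻¹ (W m⁻²)⁻¹ d⁻¹.
    theta_max, theta_min : float
        Photoacclimation bounds on the Chl:C mass ratio, g Chl (g C)⁻¹.
    K_Fe_P, K_Fe_B : float
        Half-saturation constants for dissolved-Fe uptake, nmol Fe L⁻¹.
        Bacteria are the more efficient Fe scavengers (K_Fe_B < K_Fe_P).
    K_DOC : float
        Half-saturation for labile-DOC limitation of bacteria, µmol C L⁻¹.
    K_DOC_gate : float
        Half-saturation of the energy gate on bacterial Fe transport,
        µmol C L⁻¹.  Much smaller than K_DOC: the maintenance energy that
        powers membrane transport saturates at far lower substrate levels
        than biomass synthesis does.
    Q_max : float
        Maximum cellular Fe quota shared by both populations,
        µmol Fe mol C⁻¹; Fe uptake is down-regulated to zero at this quota.
    Q_min_P, Q_opt_P, Q_min_B, Q_opt_B : float
        Subsistence and optimal Fe quotas entering the quota (Droop-style)
        limitation term, µmol Fe mol C⁻¹.
    V_max_Fe_P, V_max_Fe_B : float
        Maximum carbon-specific Fe uptake rates, µmol Fe mol C⁻¹ d⁻¹.
    exud_frac : float
        Fraction of phytoplankton carbon fixation exuded as labile DOC.
    BGE : float
        Bacterial growth efficiency: fraction of DOC uptake converted to
        biomass; the remainder is respired.
    m_P, m_B : float
        Quadratic mortality coefficients, (µmol C L⁻¹)⁻¹ d⁻¹.
    fe_uptake_gate_floor : float
        Lower bound of the energy gate on bacterial Fe transport.  Active
        Fe acquisition by heterotrophs consumes energy from DOC
        catabolism, so bacterial uptake scales with the DOC limitation
        term; the floor keeps a residual maintenance-level transport
        capacity for carbon-starved cells.
    fe_uptake_gate_floor_P : float
        Floor of the corresponding light-energy gate on phytoplankton Fe
        transport: uptake scales with the light limitation term (iron
        acquisition is fuelled by photosynthetic energy and is strongly
        reduced, but not zero, in darkness).
    mort_DOC_frac_P, mort_DOC_frac_B : float
        Fractions of phytoplankton and bacterial mortality carbon routed
        to the labile DOC pool (the remainder leaves as sinking
        particles); bacterial losses are dominated by the viral shunt and
        recycle far more efficiently than phytoplankton losses.
    mort_Fe_frac : float
        Fraction of mortality cellular Fe routed back to dissolved Fe.
    luxury_uptake_B : bool
        When False the bacterial quota is clamped to ``Q_B_fixed`` and
        bacterial Fe limitation becomes an external Monod term: the
        no-luxury-storage counterfactual.
    Q_B_fixed : float
        Fixed bacterial Fe quota for the no-luxury variant, µmol Fe mol C⁻¹.
    """

    mu_max_P_ref: float = 0.289
    mu_max_B_ref: float = 2.51
    temp_coeff_b: float = 1.066
    alpha_PI: float = 2.59
    theta_max: float = 0.049
    theta_min: float = 0.0033
    K_Fe_P: float = 0.288
    K_Fe_B: float = 0.00414
    K_DOC: float = 118.0
    K_DOC_gate: float = 84.8
    Q_max: float = 80.0
    Q_min_P: float = 2.0
    Q_opt_P: float = 4.98
    Q_min_B: float = 6.2
    Q_opt_B: float = 73.8
    V_max_Fe_P: float = 219.0
    V_max_Fe_B: float = 106.0
    exud_frac: float = 0.1
    BGE: float = 0.55
    m_P: float = 0.0178
    m_B: float = 0.00566
    fe_uptake_gate_floor: float = 0.0243
    fe_uptake_gate_floor_P: float = 0.0165
    mort_DOC_frac_P: float = 0.0436
    mort_DOC_frac_B: float = 1.0
    mort_Fe_frac: float = 1.0
    luxury_uptake_B: bool = True
    Q_B_fixed: float = 10.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ValueError listing *every* violated constraint."""
        errors: list[str] = []
        positive = [
            "mu_max_P_ref", "mu_max_B_ref", "temp_coeff_b", "alpha_PI",
            "theta_max", "theta_min", "K_Fe_P", "K_Fe_B", "K_DOC", "K_DOC_gate",
            "Q_max", "Q_min_P", "Q_opt_P", "Q_min_B", "Q_opt_B",
            "V_max_Fe_P", "V_max_Fe_B", "m_P", "m_B", "Q_B_fixed",
        ]
        for name in positive:
            if not getattr(self, name) > 0.0:
                errors.append(f"{name} must be strictly positive, got {getattr(self, name)}")
        fractions = ["exud_frac", "mort_DOC_frac_P", "mort_DOC_frac_B",
                     "mort_Fe_frac"]
        for name in fractions:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name} must lie in [0, 1], got {v}")
        for name in ("fe_uptake_gate_floor", "fe_uptake_gate_floor_P"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                errors.append(f"{name} must lie in [0, 1]")
        if not (0.0 < self.BGE <= 1.0):
            errors.append(f"BGE must lie in (0, 1], got {self.BGE}")
        if self.theta_min > self.theta_max:
            errors.append("theta_min must not exceed theta_max")
        for pop in ("P", "B"):
            qmin = getattr(self, f"Q_min_{pop}")
            qopt = getattr(self, f"Q_opt_{pop}")
            if not (qmin + qopt <= self.Q_max):
                # the quota-limitation term saturates at Q_min + Q_opt,
                # which must be attainable below the storage ceiling
                errors.append(
                    f"require Q_min_{pop} + Q_opt_{pop} <= Q_max, "
                    f"got {qmin} + {qopt} > {self.Q_max}"
                )
        if errors:
            raise ValueError("invalid parameters: " + "; ".join(errors))

    def replace(self, **updates: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced (and re-validated)."""
        return replace(self, **updates)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        unknown = sorted(set(d) - set(cls.field_names()))
        if unknown:
            raise KeyError(f"unknown parameter keys: {', '.join(unknown)}")
        return cls(**d)


#: calibrated default configuration used by every shipped experiment
DEFAULT_PARAMS = ModelParameters()
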