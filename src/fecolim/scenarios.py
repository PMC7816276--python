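"""Southern Ocean seasonal scenarios.

Eight built-in fixtures — four seasons × two zones (subantarctic, SAZ,
and polar, PZ) — encode the climatological light, dissolved-Fe and
labile-DOC conditions typical of the open Southern Ocean:

========  ====  =============================  ======  =======
season    zone  PAR (W m⁻²)                    dFe₀    LDOC₀
========  ====  =============================  ======  =======
winter    SAZ   4.5 (midpoint of the 2–7 band)  0.9 nM  0 µM
winter    PZ    0 (darkness under deep mixing
                and ice)                        0.9 nM  0 µM
spring    SAZ   30                              0.9 nM  1 µM
spring    PZ    20                              0.9 nM  1 µM
summer    SAZ   40                              0.15 nM 5 µM
summer    PZ    30                              0.15 nM 5 µM
autumn    both  linear ramp 20 → 0 over 35 d    0.1 nM  5 µM
========  ====  =============================  ======  =======

Zone differences are light-only; Fe and DOC initial stocks are shared
across zones within a season.  Winter starts with no labile DOC (deep
water supplies only refractory DOC, which the model does not carry);
spring inherits the ~1 µM that accumulates from exudation over winter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ModelState
from .forcing import Forcing
from .integrate import IntegrationSettings, TimeSeries, integrate
from .params import ModelParameters

SEASONS = ("winter", "spring", "summer", "autumn")
ZONES = ("SAZ", "PZ")


@dataclass(frozen=True)
class Scenario:
    season: str
    zone: str
    forcing: Forcing
    dFe0: float
    LDOC0: float
    P_C0: float = 0.1
    B_C0: float = 0.1
    quota0: float = 10.0
    duration: float = 35.0

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}")
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}")
        for name in ("dFe0", "LDOC0", "P_C0", "B_C0", "duration"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")

    def with_ldoc(self, ldoc: float) -> "Scenario":
        return replace(self, LDOC0=float(ldoc))

    def initial_state(self, params: ModelParameters) -> ModelState:
        return ModelState.initial(dFe=self.dFe0, LDOC=self.LDOC0,
                                  P_C=self.P_C0, B_C=self.B_C0,
                                  quota=self.quota0, params=params)


#: (PAR by zone, initial dFe nM, initial labile DOC µM) per season
_SEASON_TABLE = {
    "winter": ({"SAZ": 4.5, "PZ": 0.0}, 0.9, 0.0),
    "spring": ({"SAZ": 30.0, "PZ": 20.0}, 0.9, 1.0),
    "summer": ({"SAZ": 40.0, "PZ": 30.0}, 0.15, 5.0),
    "autumn": ({"SAZ": None, "PZ": None}, 0.1, 5.0),   # 20 → 0 ramp
}


def get_scenario(season: str, zone: str, duration: float = 35.0) -> Scenario:
    """One built-in fixture; autumn carries the declining-light ramp."""
    if season not in SEASONS or zone not in ZONES:
        raise ValueError(f"unknown scenario {season}/{zone}")
    par_by_zone, dfe0, ldoc0 = _SEASON_TABLE[season]
    if season == "autumn":
        forcing = Forcing.ramp(20.0, 0.0, ramp_end=duration)
    else:
        forcing = Forcing.constant(par_by_zone[zone])
    return Scenario(season=season, zone=zone, forcing=forcing,
                    dFe0=dfe0, LDOC0=ldoc0, duration=duration)


def builtin_scenarios() -> dict[tuple[str, str], Scenario]:
    """All 8 season × zone fixtures."""
    return {(s, z): get_scenario(s, z) for s in SEASONS for z in ZONES}


@dataclass
class ScenarioResult:
    scenario: Scenario
    series: TimeSeries
    summary: dict

    def to_dataframe(self):
        return self.series.to_dataframe()


def run_scenario(scenario: Scenario, params: ModelParameters | None = None,
                 settings: IntegrationSettings | None = None
                 ) -> ScenarioResult:
    """35-day competition run under the scenario's forcing and stocks.

    The summary reports final biomasses and their ratio, final dissolved
    Fe, each population's share of time-integrated Fe uptake, and the
    first day (if any) at which dissolved Fe has drawn down by 98% of its
    initial value.
    """
    params = params or ModelParameters()
    settings = settings or IntegrationSettings()
    if settings.t_end != scenario.duration:
        settings = replace(settings, t_end=scenario.duration)
    series = integrate(scenario.initial_state(params), scenario.forcing,
                       params, settings)
    final = series.final_model_state()
    up_p, up_b = series.cumulative_fe_uptake()
    total_up = float(up_p) + float(up_b)
    share_p = float(up_p) / total_up if total_up > 0.0 else float("nan")
    dfe_traj = series.y[:, 5]
    drawdown_day = None
    if scenario.dFe0 > 0.0:
        below = np.nonzero(dfe_traj <= 0.02 * scenario.dFe0)[0]
        if below.size:
            drawdown_day = float(series.t[below[0]])
    summary = {
        "season": scenario.season,
        "zone": scenario.zone,
        "final_P_C": final.P_C,
        "final_B_C": final.B_C,
        "biomass_ratio_P_to_B": final.P_C / final.B_C if final.B_C > 0 else float("inf"),
        "final_dFe": final.dFe,
        "final_LDOC": final.LDOC,
        "fe_uptake_share_P": share_p,
        "fe_uptake_share_B": 1.0 - share_p if total_up > 0.0 else float("nan"),
        "day_of_98pct_dFe_drawdown": drawdown_day,
        "steady": bool(series.steady),
        "total_fe_initial": float(series.total_fe()[0]),
        "total_fe_final": float(series.total_fe()[-1]),
    }
    return ScenarioResult(scenario=scenario, series=series, summary=summary)
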