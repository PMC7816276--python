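"""Factorial resource-grid experiments.

Five designs are shipped, all run at 1 °C for 35 days per cell:

* ``phyto-only``   — phytoplankton alone over initial Fe × PAR
* ``bact-only``    — bacteria alone over initial Fe × labile DOC
* ``fe-par``       — competition over initial Fe × PAR at 5 µM initial DOC
* ``fe-doc``       — competition over initial Fe × DOC at 20 W m⁻² light
* ``fe-doc-fixed-quota`` — the fe-doc design with bacterial luxury Fe
  storage disabled (quota clamped at 10 µmol Fe mol C⁻¹)

Resource axes set the *initial* stocks of a closed system (no continuous
resupply); each grid cell is an independent 35-day integration, and the
whole grid advances as one vectorized state array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import core
from .core import ModelState, NAUG, NSTATE, STATE_NAMES
from .forcing import Forcing
from .integrate import IntegrationSettings, TimeSeries, integrate
from .params import ModelParameters
from .units import GRAMS_C_PER_MOL, pool_from_quota

EXPERIMENTS = ("phyto-only", "bact-only", "fe-par", "fe-doc",
               "fe-doc-fixed-quota")

#: admissible axis envelopes (min, max) per resource
_ENVELOPES = {"Fe": (0.0, 1.0), "PAR": (1.0, 40.0), "DOC": (0.0, 100.0)}

#: (axis1 resource, axis2 resource, fixed resources) per experiment
_DESIGNS = {
    "phyto-only": ("Fe", "PAR", {"DOC": 0.0}),
    "bact-only": ("Fe", "DOC", {"PAR": 0.0}),
    "fe-par": ("Fe", "PAR", {"DOC": 5.0}),
    "fe-doc": ("Fe", "DOC", {"PAR": 20.0}),
    "fe-doc-fixed-quota": ("Fe", "DOC", {"PAR": 20.0}),
}


@dataclass(frozen=True)
class Axis:
    resource: str
    minimum: float
    maximum: float
    steps: int

    def __post_init__(self) -> None:
        lo, hi = _ENVELOPES[self.resource]
        if not (lo <= self.minimum <= self.maximum <= hi):
            raise ValueError(
                f"{self.resource} axis [{self.minimum}, {self.maximum}] "
                f"outside the admissible envelope [{lo}, {hi}]")
        if self.steps < 2:
            raise ValueError("each axis needs at least 2 steps")

    def values(self) -> np.ndarray:
        return np.linspace(self.minimum, self.maximum, self.steps)


@dataclass(frozen=True)
class GridSpec:
    """A factorial design: two resource axes plus fixed resources and
    initial biomasses."""

    experiment: str
    axis1: Axis
    axis2: Axis
    fixed: dict = field(default_factory=dict)
    P_C0: float = 0.1
    B_C0: float = 0.1
    quota0: float = 10.0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {EXPERIMENTS}")
        a1, a2, _ = _DESIGNS[self.experiment]
        if (self.axis1.resource, self.axis2.resource) != (a1, a2):
            raise ValueError(
                f"experiment {self.experiment} requires axes ({a1}, {a2})")

    @classmethod
    def named(cls, experiment: str, steps: int = 41,
              **overrides) -> "GridSpec":
        """The standard-envelope design for a named experiment."""
        if experiment not in _DESIGNS:
            raise ValueError(f"unknown experiment {experiment!r}; "
                             f"choose from {EXPERIMENTS}")
        a1, a2, fixed = _DESIGNS[experiment]
        lo1, hi1 = _ENVELOPES[a1]
        lo2, hi2 = _ENVELOPES[a2]
        return cls(experiment=experiment,
                   axis1=Axis(a1, lo1, hi1, steps),
                   axis2=Axis(a2, lo2, hi2, steps),
                   fixed=dict(fixed), **overrides)


@dataclass
class GridResult:
    """Day-35 state, diagnostics and steadiness per grid cell.

    Arrays are indexed [i, j] = (axis1 value i, axis2 value j).
    """

    spec: GridSpec
    axis1_values: np.ndarray
    axis2_values: np.ndarray
    final: np.ndarray                  # (NAUG, n1, n2)
    diagnostics: dict                  # name -> (n1, n2)
    steady: np.ndarray                 # (n1, n2) bool
    drift: np.ndarray                  # (NSTATE, n1, n2)
    params: ModelParameters
    settings: IntegrationSettings
    max_quota_P: np.ndarray | None = None   # trajectory max Fe:C per cell
    max_quota_B: np.ndarray | None = None
    failures: list = field(default_factory=list)
    clip_events: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.axis1_values), len(self.axis2_values)

    def pool(self, name: str) -> np.ndarray:
        return self.final[STATE_NAMES.index(name)]

    def cumulative_fe_uptake(self) -> tuple[np.ndarray, np.ndarray]:
        return self.final[core.CUM_FE_UP_P], self.final[core.CUM_FE_UP_B]

    def to_xarray(self) -> xr.Dataset:
        a1 = self.spec.axis1.resource
        a2 = self.spec.axis2.resource
        coords = {a1: self.axis1_values, a2: self.axis2_values}
        data = {}
        for k, name in enumerate(STATE_NAMES):
            data[name] = ((a1, a2), self.final[k],
                          {"units": core.STATE_UNITS[k]})
        data["cum_Fe_uptake_P"] = ((a1, a2), self.final[core.CUM_FE_UP_P],
                                   {"units": "nmol Fe/L"})
        data["cum_Fe_uptake_B"] = ((a1, a2), self.final[core.CUM_FE_UP_B],
                                   {"units": "nmol Fe/L"})
        for name, arr in self.diagnostics.items():
            data[name] = ((a1, a2), np.asarray(arr))
        data["steady"] = ((a1, a2), self.steady.astype(np.int8))
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["experiment"] = self.spec.experiment
        return ds

    def to_dataframe(self) -> pd.DataFrame:
        ds = self.to_xarray()
        return ds.to_dataframe().reset_index()


def _initial_grid_state(spec: GridSpec, params: ModelParameters
                        ) -> tuple[np.ndarray, Forcing]:
    """Flattened (NSTATE, n1*n2) initial state and the per-cell forcing."""
    v1 = spec.axis1.values()
    v2 = spec.axis2.values()
    g1, g2 = np.meshgrid(v1, v2, indexing="ij")
    res = {spec.axis1.resource: g1.ravel(), spec.axis2.resource: g2.ravel()}
    for name, val in spec.fixed.items():
        res[name] = np.full(g1.size, float(val))

    p_c0 = 0.0 if spec.experiment == "bact-only" else spec.P_C0
    b_c0 = 0.0 if spec.experiment == "phyto-only" else spec.B_C0
    theta0 = 0.5 * (params.theta_min + params.theta_max)
    n = g1.size
    y0 = np.zeros((NSTATE, n))
    y0[core.P_C] = p_c0
    y0[core.P_CHL] = theta0 * GRAMS_C_PER_MOL * p_c0
    y0[core.P_FE] = pool_from_quota(spec.quota0, p_c0)
    y0[core.B_C] = b_c0
    y0[core.B_FE] = pool_from_quota(spec.quota0, b_c0)
    y0[core.DFE] = res["Fe"]
    y0[core.LDOC] = res["DOC"]
    forcing = Forcing.constant(res["PAR"])
    return y0, forcing


def run_grid(spec: GridSpec, params: ModelParameters | None = None,
             settings: IntegrationSettings | None = None) -> GridResult:
    """Run every cell of the design for 35 days and collect day-35 output."""
    params = params or ModelParameters()
    settings = settings or IntegrationSettings()
    if spec.experiment == "fe-doc-fixed-quota":
        params = params.replace(luxury_uptake_B=False)

    y0, forcing = _initial_grid_state(spec, params)
    n1, n2 = spec.axis1.steps, spec.axis2.steps
    failures: list[dict] = []
    try:
        series = integrate(y0, forcing, params, settings)
    except FloatingPointError as exc:   # pragma: no cover - defensive
        failures.append({"error": str(exc)})
        raise

    final = series.final_state().reshape(NAUG, n1, n2)
    diag = core.rate_diagnostics(series.final_state(),
                                 forcing.par(settings.t_end),
                                 forcing.temp(settings.t_end), params)
    diagnostics = {k: np.asarray(v).reshape(n1, n2) for k, v in diag.items()}
    steady = np.asarray(series.steady).reshape(n1, n2)
    drift = series.drift.reshape(NSTATE, n1, n2)
    from .units import quota_from_pools
    q_p_traj = quota_from_pools(series.y[:, core.P_FE], series.y[:, core.P_C])
    q_b_traj = quota_from_pools(series.y[:, core.B_FE], series.y[:, core.B_C])
    return GridResult(spec=spec, axis1_values=spec.axis1.values(),
                      axis2_values=spec.axis2.values(), final=final,
                      diagnostics=diagnostics, steady=steady, drift=drift,
                      params=params, settings=settings,
                      max_quota_P=q_p_traj.max(axis=0).reshape(n1, n2),
                      max_quota_B=q_b_traj.max(axis=0).reshape(n1, n2),
                      failures=failures, clip_events=series.clip_events)


def paired_competition_effect(grid_with: GridResult, grid_without: GridResult,
                              population: str = "P") -> np.ndarray:
    """Per-cell relative biomass change (%) due to competition.

    ``100 · (X_competition − X_alone) / X_alone`` for the named population
    ("P" or "B"); negative values mean competitive suppression.  Cells
    where the population is extinct in the solo run are NaN.
    """
    if population not in ("P", "B"):
        raise ValueError("population must be 'P' or 'B'")
    for attr in ("axis1_values", "axis2_values"):
        a = getattr(grid_with, attr)
        b = getattr(grid_without, attr)
        if a.shape != b.shape or not np.allclose(a, b):
            raise ValueError(f"grid axes differ ({attr}); effects are not paired")
    pool = "P_C" if population == "P" else "B_C"
    with_c = grid_with.pool(pool)
    alone = grid_without.pool(pool)
    out = np.full_like(with_c, np.nan)
    ok = alone > 0.0
    out[ok] = 100.0 * (with_c[ok] - alone[ok]) / alone[ok]
    return out
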