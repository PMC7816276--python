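"""Coexistence lines, Fe-uptake shares and DOC-dominance thresholds.

The "line of coexistence" is the contour in a two-resource plane along
which a phytoplankton metric (biomass, specific growth rate, or carbon
production) equals its bacterial counterpart; it separates regions of
phytoplankton and bacterial dominance.  Fe-uptake shares partition the
time-integrated iron consumption of a run between the two populations.
The threshold search finds the minimum initial labile DOC at which
bacteria overtake phytoplankton biomass by day 35 under fixed seasonal
drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure

from .experiments import GridResult
from .integrate import IntegrationSettings
from .params import ModelParameters
from .scenarios import Scenario, run_scenario

COEXISTENCE_VARIABLES = ("biomass", "growth_rate", "carbon_production")

#: relative tolerance below which phytoplankton and bacteria count as tied
TIE_RTOL = 1e-12


def _competition_field(grid: GridResult, variable: str
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(phyto value, bacterial value) per cell for the chosen variable."""
    if variable == "biomass":
        return grid.pool("P_C"), grid.pool("B_C")
    if variable == "growth_rate":
        return grid.diagnostics["mu_P"], grid.diagnostics["mu_B"]
    if variable == "carbon_production":
        prod_p = grid.diagnostics["C_fix"] - grid.diagnostics["exud_flux"] \
            if "exud_flux" in grid.diagnostics else \
            grid.diagnostics["mu_P"] * grid.pool("P_C")
        prod_b = grid.diagnostics["mu_B"] * grid.pool("B_C")
        return prod_p, prod_b
    raise ValueError(
        f"variable must be one of {COEXISTENCE_VARIABLES}, got {variable!r}")


@dataclass
class CoexistenceLine:
    """Zero contours of (phyto − bacteria) plus per-cell dominance labels."""

    variable: str
    segments: list            # list of (n, 2) arrays in (axis1, axis2) coords
    labels: np.ndarray        # (n1, n2) array of "phyto" | "bacteria" | "tie"
    difference: np.ndarray    # (n1, n2) phyto − bacteria field

    @property
    def empty(self) -> bool:
        return len(self.segments) == 0


def coexistence_line(grid: GridResult, variable: str = "biomass"
                     ) -> CoexistenceLine:
    """Extract the 1:1 line for ``variable`` from a competition grid.

    The contour is traced through bilinear interpolation between cell
    centers (marching squares); an empty polyline means one population
    dominates the whole plane.
    """
    phy, bac = _competition_field(grid, variable)
    diff = np.asarray(phy, dtype=float) - np.asarray(bac, dtype=float)
    scale = np.maximum(np.abs(phy), np.abs(bac))
    tie = np.abs(diff) <= TIE_RTOL * np.maximum(scale, 1e-300)
    labels = np.where(tie, "tie", np.where(diff > 0.0, "phyto", "bacteria"))

    segments = []
    if np.any(diff > 0.0) and np.any(diff < 0.0):
        for contour in measure.find_contours(diff, 0.0):
            a1 = np.interp(contour[:, 0], np.arange(len(grid.axis1_values)),
                           grid.axis1_values)
            a2 = np.interp(contour[:, 1], np.arange(len(grid.axis2_values)),
                           grid.axis2_values)
            segments.append(np.column_stack([a1, a2]))
    return CoexistenceLine(variable=variable, segments=segments,
                           labels=labels, difference=diff)


def fe_uptake_share(grid: GridResult) -> np.ndarray:
    """Bacterial fraction of time-integrated Fe uptake per cell, in [0,1].

    Cells where neither population took up any Fe are NaN (the share is
    undefined, not zero).
    """
    up_p, up_b = grid.cumulative_fe_uptake()
    total = up_p + up_b
    share = np.full_like(total, np.nan)
    ok = total > 0.0
    share[ok] = up_b[ok] / total[ok]
    return share


@dataclass
class ThresholdResult:
    """Outcome of the DOC-dominance bisection."""

    threshold: float | None     # µM; None when no crossing in the band
    crossed: bool
    brackets: list = field(default_factory=list)  # all coarse sign-change brackets
    band: tuple = (0.0, 100.0)


def doc_threshold_search(scenario: Scenario,
                         params: ModelParameters | None = None,
                         settings: IntegrationSettings | None = None,
                         band: tuple[float, float] = (0.0, 100.0),
                         resolution: float = 0.5,
                         coarse_points: int = 11) -> ThresholdResult:
    """Minimum initial labile DOC at which bacteria outgrow phytoplankton.

    Runs the scenario at ``coarse_points`` evenly spaced initial-DOC
    levels across ``band``, brackets every sign change of day-35
    (bacterial − phytoplankton) biomass, and bisects the lowest bracket
    to ``resolution`` µM.  All brackets are reported so a non-monotone
    response is visible rather than silently collapsed.
    """
    params = params or ModelParameters()
    lo, hi = band
    if hi <= lo:
        raise ValueError("search band must have positive width")

    def excess(ldoc: float) -> float:
        res = run_scenario(scenario.with_ldoc(ldoc), params, settings)
        return res.summary["final_B_C"] - res.summary["final_P_C"]

    grid = np.linspace(lo, hi, coarse_points)
    values = np.array([excess(x) for x in grid])
    if values[0] > 0.0:
        # bacteria dominate even at the bottom of the band
        return ThresholdResult(threshold=float(lo), crossed=True, band=band)
    brackets = [(float(grid[i]), float(grid[i + 1]))
                for i in range(len(grid) - 1)
                if values[i] <= 0.0 < values[i + 1]]
    if not brackets:
        return ThresholdResult(threshold=None, crossed=False, band=band)

    a, b = brackets[0]
    while b - a > resolution:
        mid = 0.5 * (a + b)
        if excess(mid) > 0.0:
            b = mid
        else:
            a = mid
    return ThresholdResult(threshold=float(b), crossed=True,
                           brackets=brackets, band=band)
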