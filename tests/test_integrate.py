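"""Integrator tests: conservation, convergence, steadiness detection and
the analytic logistic fixed point."""

import numpy as np
import pytest

from fecolim import (Forcing, IntegrationSettings, ModelParameters,
                     ModelState, integrate, quasi_steady_state)
from fecolim.integrate import TimeSeries
from fecolim.units import theta_from_pools


def test_zero_biomass_state_is_constant(params):
    s0 = ModelState(P_C=0, P_Chl=0, P_Fe=0, B_C=0, B_Fe=0, dFe=0.7, LDOC=9.0)
    ts = integrate(s0, Forcing.constant(20.0), params,
                   IntegrationSettings(dt=0.05, t_end=10.0))
    assert np.allclose(ts.y[-1][:7], s0.to_array())


def test_closed_system_iron_conservation_over_35_days(params, fast_settings, state):
    ts = integrate(state, Forcing.constant(20.0), params, fast_settings)
    total = ts.total_fe()
    assert abs(total[-1] - total[0]) <= 1e-8 * total[0]
    assert ts.clip_events == 0


def test_rk4_self_convergence_on_dt_halving(params, state):
    f = Forcing.constant(20.0)
    base = integrate(state, f, params, IntegrationSettings(dt=0.02))
    fine = integrate(state, f, params, IntegrationSettings(dt=0.01))
    scale = np.maximum(np.abs(fine.y[-1][:7]), 1e-10)
    rel = np.abs(base.y[-1][:7] - fine.y[-1][:7]) / scale
    assert rel.max() < 1e-6


def test_rk4_matches_fine_step_euler(params, state):
    f = Forcing.constant(10.0)
    rk4 = integrate(state, f, params, IntegrationSettings(dt=0.02, t_end=5.0))
    euler = integrate(state, f, params,
                      IntegrationSettings(dt=1e-4, t_end=5.0, method="euler"))
    scale = np.maximum(np.abs(euler.y[-1][:7]), 1e-10)
    rel = np.abs(rk4.y[-1][:7] - euler.y[-1][:7]) / scale
    assert rel.max() < 1e-4


def test_quota_ceiling_respected_along_trajectory(params, fast_settings):
    s0 = ModelState.initial(dFe=1.0, LDOC=100.0, params=params)
    ts = integrate(s0, Forcing.constant(40.0), params, fast_settings)
    with np.errstate(invalid="ignore", divide="ignore"):
        q_p = np.where(ts.y[:, 0] > 0, 1000.0 * ts.y[:, 2] / ts.y[:, 0], 0.0)
        q_b = np.where(ts.y[:, 3] > 0, 1000.0 * ts.y[:, 4] / ts.y[:, 3], 0.0)
    tol = params.Q_max * 1e-6
    assert q_p.max() <= params.Q_max + tol
    assert q_b.max() <= params.Q_max + tol


def test_analytic_logistic_fixed_point():
    """With all limitation terms pinned at 1 and exudation off, each
    population settles at the closed-form root mu_max(T)/m of
    mu X = m X^2."""
    p = ModelParameters(exud_frac=0.0, alpha_PI=50.0, K_Fe_P=1e-6, K_Fe_B=1e-6,
                        K_DOC=1e-3, m_P=0.05, m_B=0.05,
                        V_max_Fe_P=500.0, V_max_Fe_B=500.0,
                        Q_min_P=1.0, Q_opt_P=1.0, Q_min_B=1.0, Q_opt_B=1.0,
                        fe_uptake_gate_floor=1.0)
    s0 = ModelState.initial(dFe=50.0, LDOC=2e6, quota=70.0, params=p)
    ts = integrate(s0, Forcing.constant(200.0), p,
                   IntegrationSettings(dt=0.01, t_end=120.0))
    final = ts.final_model_state()
    t_factor = p.temp_coeff_b  # at 1 degree C
    assert final.P_C == pytest.approx(p.mu_max_P_ref * t_factor / p.m_P,
                                      rel=1e-4)
    assert final.B_C == pytest.approx(p.mu_max_B_ref * t_factor / p.m_B,
                                      rel=1e-4)


@pytest.mark.parametrize("par, side", [(40.0, "low"), (1.0, "high")])
def test_photoacclimation_drives_theta_to_band_edges(params, par, side):
    """Long runs at high light pull Chl:C toward the theta_min side of the
    photoadaptive band; dim light pulls it toward theta_max."""
    s0 = ModelState.initial(dFe=1.0, LDOC=0.0, B_C=0.0, params=params)
    ts = integrate(s0, Forcing.constant(par), params,
                   IntegrationSettings(dt=0.05, t_end=100.0))
    final = ts.final_model_state()
    theta = float(theta_from_pools(final.P_Chl, final.P_C))
    if side == "low":
        assert params.theta_min <= theta < 0.5 * params.theta_max
    else:
        assert 0.6 * params.theta_max < theta <= params.theta_max * (1 + 1e-9)


class TestQuasiSteadyState:
    def _series(self, t, y, params):
        return TimeSeries(t=np.asarray(t, dtype=float), y=np.asarray(y),
                          params=params, forcing=Forcing.constant(1.0))

    def test_constant_series_is_steady(self, params):
        y = np.ones((8, 9))
        steady, drift = quasi_steady_state(
            self._series(np.arange(8.0), y, params), 0.01)
        assert steady and np.all(drift == 0.0)

    def test_growing_pool_is_not_steady(self, params):
        y = np.ones((8, 9))
        y[:, 0] = 2.0 ** np.arange(8)
        steady, _ = quasi_steady_state(
            self._series(np.arange(8.0), y, params), 0.01)
        assert not steady

    def test_short_series_rejected(self, params):
        with pytest.raises(ValueError, match="5 days"):
            quasi_steady_state(self._series([0.0, 1.0], np.ones((2, 9)), params), 0.01)

    def test_default_grid_point_is_near_steady_by_day_35(self, params):
        """At a mid-grid resource level the phytoplankton pools are
        within a few percent per day of equilibrium at day 35; the small
        bacterial pool equilibrates on a longer horizon."""
        s0 = ModelState.initial(dFe=0.5, LDOC=5.0, params=params)
        ts = integrate(s0, Forcing.constant(20.0), params,
                       IntegrationSettings(dt=0.02))
        assert np.all(ts.drift[[0, 1, 2]] < 0.05)


def test_nonfinite_state_names_pool_and_time(params, state, monkeypatch):
    """A derivative that turns non-finite mid-run aborts with the pool
    name and the offending time (clipping keeps honest dynamics finite,
    so the fault is injected)."""
    from importlib import import_module
    integrate_mod = import_module("fecolim.integrate")
    real = integrate_mod.derivatives

    def poisoned(y, par, T, p):
        dy = real(y, par, T, p)
        if poisoned.calls > 50:
            dy[0] = np.nan
        poisoned.calls += 1
        return dy

    poisoned.calls = 0
    monkeypatch.setattr(integrate_mod, "derivatives", poisoned)
    with pytest.raises(FloatingPointError, match=r"pool P_C at t = "):
        integrate_mod.integrate(state, Forcing.constant(10.0), params,
                                IntegrationSettings(dt=0.1, t_end=5.0))
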