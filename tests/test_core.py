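"""Unit tests of the elementary rate laws and the assembled derivative."""

import numpy as np
import pytest

from fecolim import ModelParameters, ModelState
from fecolim import core
from fecolim.core import (
    bacterial_growth_and_doc_uptake,
    chlorophyll_synthesis,
    derivatives,
    doc_limitation,
    fe_limitation,
    fe_uptake,
    light_limitation_and_fixation,
    quadratic_mortality,
    rate_diagnostics,
    temperature_factor,
)


class TestTemperatureFactor:
    def test_reference_temperature_is_neutral(self, params):
        assert temperature_factor(0.0, params) == 1.0

    def test_one_degree_gives_the_base(self):
        p = ModelParameters(temp_coeff_b=1.066)
        assert temperature_factor(1.0, p) == pytest.approx(1.066)

    def test_strictly_increasing(self, params):
        assert temperature_factor(2.0, params) > temperature_factor(1.0, params)


class TestDocLimitation:
    @pytest.mark.parametrize("ldoc_over_k, expected",
                             [(0.0, 0.0), (1.0, 0.5), (99.0, 0.99)])
    def test_monod_form(self, params, ldoc_over_k, expected):
        k = params.K_DOC
        assert doc_limitation(ldoc_over_k * k, k) == pytest.approx(expected)

    def test_negative_substrate_signals_corruption(self, params):
        with pytest.raises(ValueError):
            doc_limitation(-0.1, params.K_DOC)


class TestFeLimitation:
    @pytest.mark.parametrize("offset, expected", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)])
    def test_piecewise_linear_quota_form(self, offset, expected):
        q_min, q_opt = 10.0, 30.0
        assert fe_limitation(q_min + offset * q_opt, q_min, q_opt) == expected

    def test_below_subsistence_clamps_to_zero(self):
        assert fe_limitation(1.0, 10.0, 30.0) == 0.0

    def test_saturates_above_optimum(self):
        assert fe_limitation(75.0, 10.0, 30.0) == 1.0


class TestFeUptake:
    def test_full_quota_shuts_off_uptake(self):
        assert fe_uptake(1.0, 100.0, 80.0, V_max=40.0, K_Fe=0.1, Q_max=80.0) == 0.0

    def test_no_external_iron_no_uptake(self):
        assert fe_uptake(1.0, 0.0, 0.0, V_max=40.0, K_Fe=0.1, Q_max=80.0) == 0.0

    def test_half_saturation_closed_form(self):
        # V_max/2 at dFe = K, empty quota, unit biomass; 1e-3 unit bridge
        flux = fe_uptake(1.0, 0.1, 0.0, V_max=40.0, K_Fe=0.1, Q_max=80.0)
        assert flux == pytest.approx(0.02)

    def test_luxury_uptake_continues_when_growth_limited(self, params):
        # quota above the growth optimum but below the ceiling: growth is
        # saturated yet uptake continues (storage)
        q = params.Q_min_P + params.Q_opt_P + 5.0
        assert q < params.Q_max
        assert fe_uptake(1.0, 1.0, q, params.V_max_Fe_P, params.K_Fe_P,
                         params.Q_max) > 0.0


class TestLightLimitation:
    def test_dark_means_no_fixation(self, params):
        l_light, c_fix = light_limitation_and_fixation(0.0, 0.02, 1.0, params)
        assert l_light == 0.0 and c_fix == 0.0

    def test_saturates_at_high_light(self, params):
        l_light, _ = light_limitation_and_fixation(1e6, 0.02, 1.0, params)
        assert l_light == pytest.approx(1.0)

    def test_e_folding_point(self):
        # alpha*theta*PAR equal to mu gives 1 - 1/e
        p = ModelParameters(alpha_PI=2.0)
        mu = 1.0
        par = mu / (p.alpha_PI * 0.02)
        l_light, c_fix = light_limitation_and_fixation(par, 0.02, mu, p)
        assert l_light == pytest.approx(1.0 - np.exp(-1.0))
        assert c_fix == pytest.approx(mu * l_light)


class TestChlorophyllSynthesis:
    def test_dark_synthesis_is_zero(self, params):
        assert chlorophyll_synthesis(0.0, 0.0, 0.02, 0.0, params) == 0.0

    def test_allocation_stays_inside_photoadaptive_band(self, params, rng):
        for _ in range(50):
            c_fix = rng.uniform(0.0, 10.0)
            par = rng.uniform(0.1, 40.0)
            theta = rng.uniform(params.theta_min, params.theta_max)
            mu = rng.uniform(0.01, 2.0)
            syn = chlorophyll_synthesis(c_fix, par, theta, mu, params)
            rho = syn / (12.0 * c_fix) if c_fix > 0 else params.theta_max
            assert params.theta_min - 1e-12 <= rho <= params.theta_max + 1e-12


class TestBacterialGrowth:
    def test_no_substrate_no_growth(self, params):
        mu, uptake, resp = bacterial_growth_and_doc_uptake(
            1.0, 0.0, 40.0, 1.0, params)
        assert mu == 0.0 and uptake == 0.0 and resp == 0.0

    def test_subsistence_quota_stops_growth(self, params):
        mu, _, _ = bacterial_growth_and_doc_uptake(
            1.0, 100.0, params.Q_min_B, 1.0, params)
        assert mu == 0.0

    def test_perfect_efficiency_means_no_respiration(self):
        p = ModelParameters(BGE=1.0)
        q_replete = p.Q_min_B + p.Q_opt_B
        mu, uptake, resp = bacterial_growth_and_doc_uptake(
            2.0, 50.0, q_replete, 1.0, p)
        assert resp == 0.0
        assert uptake == pytest.approx(mu * 2.0)

    def test_growth_carbon_is_bge_times_uptake(self, params):
        q_replete = params.Q_min_B + params.Q_opt_B
        mu, uptake, _ = bacterial_growth_and_doc_uptake(
            2.0, 50.0, q_replete, 1.0, params)
        assert params.BGE * uptake == pytest.approx(mu * 2.0)


class TestQuadraticMortality:
    def test_zero_biomass(self):
        assert quadratic_mortality(0.0, 0.05) == 0.0

    def test_doubling_biomass_quadruples_loss(self):
        assert quadratic_mortality(2.0, 0.05) == pytest.approx(
            4.0 * quadratic_mortality(1.0, 0.05))

    def test_arithmetic(self):
        assert quadratic_mortality(2.0, 0.05) == pytest.approx(0.2)


class TestDerivatives:
    def test_empty_biosphere_is_inert(self, params):
        y = ModelState(P_C=0, P_Chl=0, P_Fe=0, B_C=0, B_Fe=0,
                       dFe=0.5, LDOC=5.0).to_array()
        dy = derivatives(y, 20.0, 1.0, params)
        assert np.all(dy == 0.0)

    def test_total_iron_is_closed_with_full_recycling(self, params, state):
        assert params.mort_Fe_frac == 1.0
        dy = derivatives(state.to_array(), 20.0, 1.0, params)
        d_total_fe = dy[core.P_FE] + dy[core.B_FE] + dy[core.DFE]
        assert d_total_fe == pytest.approx(0.0, abs=1e-15)

    def test_iron_leaks_when_recycling_is_partial(self, state):
        p = ModelParameters(mort_Fe_frac=0.5)
        dy = derivatives(state.to_array(), 20.0, 1.0, p)
        assert dy[core.P_FE] + dy[core.B_FE] + dy[core.DFE] < 0.0

    def test_exudation_is_fixed_fraction_of_fixation(self, params, state):
        diag = rate_diagnostics(state.to_array(), 20.0, 1.0, params)
        assert diag["exud_flux"] == pytest.approx(
            params.exud_frac * diag["C_fix"])
        assert params.exud_frac == 0.1

    def test_carbon_bookkeeping_closes_flux_by_flux(self, params, state):
        y = state.to_array()
        dy = derivatives(y, 20.0, 1.0, params)
        diag = core.compute_fluxes(y, 20.0, 1.0, params)
        lhs = dy[core.P_C] + dy[core.B_C] + dy[core.LDOC]
        rhs = (diag["C_fix"] - diag["respiration"]
               - (1.0 - params.mort_DOC_frac_P) * diag["mort_P"]
               - (1.0 - params.mort_DOC_frac_B) * diag["mort_B"])
        assert lhs == pytest.approx(rhs)

    def test_invalid_state_is_rejected(self, params):
        bad = ModelState(P_C=-0.1)
        with pytest.raises(ValueError, match="negative"):
            bad.validate(params)

    def test_quota_above_ceiling_is_rejected(self, params):
        bad = ModelState(P_C=0.1, P_Fe=1.0)   # quota 10000
        with pytest.raises(ValueError, match="Q_P"):
            bad.validate(params)
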