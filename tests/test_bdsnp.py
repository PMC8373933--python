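"""Unit tests for the BDSNP soil NOx emission model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilnox import (
    BdsnpModel,
    BdsnpParams,
    SoilCellState,
    available_nitrogen,
    fertilizer_fraction,
    fertilizer_pool_step,
    moisture_response,
    pulse_factor,
    run_simulation,
    scale_soil_emissions,
    soil_nox_flux,
    temperature_response,
    update_dry_spell,
)

P = BdsnpParams()


class TestTemperatureResponse:
    @pytest.mark.parametrize("T,expected", [
        (0.0, 1.0),
        (30.0, math.exp(0.103 * 30)),
        (10.0, math.exp(1.03)),
    ])
    def test_exponential_form(self, T, expected):
        assert temperature_response(T, P) == pytest.approx(expected, rel=1e-12)

    def test_clamped_below_and_above(self):
        # the response is defined on 0-30 degC and held constant outside
        assert temperature_response(-5.0, P) == temperature_response(0.0, P)
        assert temperature_response(45.0, P) == temperature_response(30.0, P)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            temperature_response(float("nan"), P)

    @given(st.floats(-50, 80), st.floats(-50, 80))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nondecreasing(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert temperature_response(lo, P) <= temperature_response(hi, P) + 1e-15


class TestMoistureResponse:
    def test_zero_at_dry(self):
        assert moisture_response(0.0, True, P) == 0.0
        assert moisture_response(0.0, False, P) == 0.0

    @pytest.mark.parametrize("arid,theta_opt", [(True, 0.2), (False, 0.3)])
    def test_argmax_at_theta_opt(self, arid, theta_opt):
        theta = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        g = moisture_response(theta, arid, P)
        assert theta[np.argmax(g)] == pytest.approx(theta_opt, abs=1e-4)

    @pytest.mark.parametrize("arid", [True, False])
    def test_normalized_to_one_at_peak(self, arid):
        assert moisture_response(P.theta_opt(arid), arid, P) == pytest.approx(1.0, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            moisture_response(1.5, True, P)
        with pytest.raises(ValueError):
            moisture_response(-0.1, False, P)


class TestDrySpellAndPulse:
    def test_dry_hour_increments_clock(self):
        s = SoilCellState.zeros((1,))
        s.l_dry[:] = 10.0
        s2 = update_dry_spell(s, 0.05, 1.0, P)
        assert s2.l_dry[0] == 11.0

    def test_wetting_resets_clock(self):
        s = SoilCellState.zeros((1,))
        s.l_dry[:] = 10.0
        s2 = update_dry_spell(s, 0.5, 1.0, P)
        assert s2.l_dry[0] == 0.0

    def test_short_dry_spell_no_pulse(self):
        # 13.01 ln(61) - 53.6 < 1: wetting after 61 dry hours starts nothing
        s = SoilCellState.zeros((1,))
        s.l_dry[:] = 61.0
        s2 = update_dry_spell(s, 0.5, 1.0, P)
        assert not s2.pulse_active[0]
        assert pulse_factor(s2, P)[0] == 1.0

    def test_long_dry_spell_starts_pulse_with_bracket_amplitude(self):
        s = SoilCellState.zeros((1,))
        for _ in range(100):
            s = update_dry_spell(s, 0.05, 1.0, P)
        assert s.l_dry[0] == 100.0
        s = update_dry_spell(s, 0.5, 1.0, P)
        assert s.pulse_active[0]
        expected = 13.01 * math.log(100.0) - 53.6
        assert pulse_factor(s, P)[0] == pytest.approx(expected, rel=1e-12)

    def test_pulse_decays_and_expires(self):
        s = SoilCellState.zeros((1,))
        s.l_dry[:] = 200.0
        s = update_dry_spell(s, 0.5, 1.0, P)
        amp = 13.01 * math.log(200.0) - 53.6
        factors = []
        for _ in range(60):
            factors.append(pulse_factor(s, P)[0])
            s = update_dry_spell(s, 0.5, 1.0, P)
        factors = np.array(factors)
        assert factors[0] == pytest.approx(amp, rel=1e-12)
        active = factors > 1.0
        # strictly decreasing while above 1, then pinned at exactly 1
        assert np.all(np.diff(factors[active]) < 0)
        assert np.all(factors[~active] == 1.0)
        assert not s.pulse_active[0]

    def test_factor_never_below_one(self):
        s = SoilCellState.zeros((3,))
        rng = np.random.default_rng(0)
        for _ in range(300):
            s = update_dry_spell(s, rng.uniform(0, 1, 3), 1.0, P)
            assert np.all(pulse_factor(s, P) >= 1.0)


class TestNitrogenPools:
    def test_no_application_no_decay_limit(self):
        params = BdsnpParams(fert_decay_tau=1e12)
        s = SoilCellState.zeros((1,))
        s.n_fert[:] = 5.0
        s2 = fertilizer_pool_step(s, 0.0, 1.0, params)
        assert s2.n_fert[0] == pytest.approx(5.0, rel=1e-9)

    def test_one_tau_decay(self):
        s = SoilCellState.zeros((1,))
        s.n_fert[:] = 5.0
        for _ in range(int(P.fert_decay_tau * 24)):
            s = fertilizer_pool_step(s, 0.0, 1.0, P)
        assert s.n_fert[0] == pytest.approx(5.0 / math.e, rel=1e-9)

    def test_steady_state_approaches_rate_times_tau(self):
        params = BdsnpParams(fert_decay_tau=5.0)  # short tau for a quick limit
        s = SoilCellState.zeros((1,))
        A = 2.0  # kg N ha^-1 day^-1
        for _ in range(24 * 100):
            s = fertilizer_pool_step(s, A, 1.0, params)
        # discrete recursion limit: (A dt/24) / (1 - exp(-dt/tau_h)) ~ A tau_days
        tau_h = params.fert_decay_tau * 24
        exact = (A / 24.0) / -math.expm1(-1.0 / tau_h)
        assert s.n_fert[0] == pytest.approx(exact, rel=1e-6)
        assert s.n_fert[0] == pytest.approx(A * params.fert_decay_tau, rel=0.02)

    def test_available_nitrogen_is_pool_sum(self):
        s = SoilCellState.zeros((1,))
        s.n_natural[:], s.n_fert[:], s.n_dep[:] = 1.0, 2.0, 3.0
        assert available_nitrogen(s)[0] == 6.0
        rng = np.random.default_rng(1)
        s.n_natural[:], s.n_fert[:], s.n_dep[:] = rng.uniform(0, 10, 3)
        assert available_nitrogen(s)[0] == s.n_natural[0] + s.n_fert[0] + s.n_dep[0]


class TestFlux:
    def test_zero_emission_factor_gives_zero_flux(self):
        params = BdsnpParams(emission_base={1: 0.0}, emission_n_slope=0.0)
        s = SoilCellState.zeros((1,))
        flux = soil_nox_flux(s, 25.0, 0.4, True, np.array([1]), params)
        assert np.all(flux == 0.0)

    def test_identity_factors_return_emission_factor(self):
        # T=0 (f=1), theta at the optimum (g=1), no pulse (P=1)
        s = SoilCellState.zeros((1,))
        s.n_natural[:] = 2.0
        params = BdsnpParams(emission_base={2: 0.5}, emission_n_slope=0.1)
        flux = soil_nox_flux(s, 0.0, params.theta_opt_other, False, np.array([2]), params)
        assert flux[0] == pytest.approx(0.5 + 0.1 * 2.0, rel=1e-12)

    def test_flux_equals_product_of_factors(self):
        rng = np.random.default_rng(3)
        s = SoilCellState.zeros((10,))
        s.n_natural[:] = rng.uniform(0, 5, 10)
        s.l_dry[:] = rng.uniform(0, 300, 10)
        s = update_dry_spell(s, 0.5, 1.0, P)
        T = rng.uniform(-5, 40, 10)
        th = rng.uniform(0, 1, 10)
        biome = rng.choice([1, 2], 10)
        arid = biome == 1
        flux = soil_nox_flux(s, T, th, arid, biome, P)
        expected = np.array([
            (P.emission_base[b] + P.emission_n_slope * available_nitrogen(s)[i])
            * temperature_response(T[i], P)
            * moisture_response(th[i], bool(arid[i]), P)
            * pulse_factor(s, P)[i]
            * (1 - P.canopy_reduction[b])
            for i, b in enumerate(biome)
        ])
        np.testing.assert_allclose(flux, expected, rtol=1e-12)

    def test_unknown_biome_rejected(self):
        s = SoilCellState.zeros((1,))
        with pytest.raises(KeyError):
            soil_nox_flux(s, 10.0, 0.3, False, np.array([99]), P)

    def test_homogeneous_in_emission_factor(self):
        s = SoilCellState.zeros((1,))
        s.n_natural[:] = 3.0
        p1 = BdsnpParams(emission_base={1: 0.4}, emission_n_slope=0.05)
        p2 = BdsnpParams(emission_base={1: 0.8}, emission_n_slope=0.10)
        f1 = soil_nox_flux(s, 12.0, 0.25, True, np.array([1]), p1)
        f2 = soil_nox_flux(s, 12.0, 0.25, True, np.array([1]), p2)
        assert f2[0] == pytest.approx(2 * f1[0], rel=1e-12)


class TestSimulation:
    def test_all_zero_inputs_give_zero_field(self, forcing_small):
        params = BdsnpParams(emission_base={1: 0.0, 2: 0.0}, emission_n_slope=0.0)
        field = run_simulation(forcing_small, None, params, n_natural=0.0)
        assert np.all(field.flux == 0.0)

    def test_fertilizer_monotonicity(self, forcing_small, fert_small):
        with_f = run_simulation(forcing_small, fert_small)
        without = run_simulation(forcing_small, fert_small,
                                 include_fertilizer=False)
        assert np.all(with_f.flux >= without.flux - 1e-15)

    def test_component_additivity(self, forcing_small, fert_small):
        """flux(with fert) - flux(without) = gamma * n_fert * f * g * P * (1-CRF)."""
        params = BdsnpParams()
        m = BdsnpModel(forcing_small, fert_small, params, dep_pool=1.0)
        with_f = m.run()
        without = m.run(include_fertilizer=False)
        diff_total = with_f.total_mass_tg() - without.total_mass_tg()
        # re-derive the fertilizer-only contribution from a zero-base run
        p0 = BdsnpParams(emission_base={1: 0.0, 2: 0.0})
        m0 = BdsnpModel(forcing_small, fert_small, p0, dep_pool=0.0, n_natural=0.0)
        fert_only = m0.run()
        assert diff_total == pytest.approx(fert_only.total_mass_tg(), rel=1e-9)

    def test_time_axis_mismatch_rejected(self, forcing_small, fert_small):
        import dataclasses
        short = dataclasses.replace(fert_small, days=fert_small.days[:2],
                                    application=fert_small.application[:2])
        with pytest.raises(ValueError, match="mismatch"):
            BdsnpModel(forcing_small, short)

    def test_determinism(self, cfg_small):
        from soilnox import gen_fertilizer_map, gen_met_forcing
        a = run_simulation(gen_met_forcing(cfg_small), gen_fertilizer_map(cfg_small))
        b = run_simulation(gen_met_forcing(cfg_small), gen_fertilizer_map(cfg_small))
        np.testing.assert_array_equal(a.flux, b.flux)


class TestDerived:
    def test_fertilizer_fraction_limits(self, forcing_small, fert_small):
        with_f = run_simulation(forcing_small, fert_small)
        frac, regional = fertilizer_fraction(with_f, with_f)
        valid = ~np.isnan(frac)
        assert np.all(frac[valid] == 0.0)
        assert regional == 0.0
        zero = scale_soil_emissions(with_f, 1.0)
        zero.flux = np.zeros_like(zero.flux)
        frac, regional = fertilizer_fraction(with_f, zero)
        assert np.all(frac[valid] == 1.0)
        assert regional == pytest.approx(1.0, rel=1e-12)

    def test_fertilizer_fraction_in_unit_interval(self, forcing_small, fert_small):
        with_f = run_simulation(forcing_small, fert_small)
        without = run_simulation(forcing_small, fert_small, include_fertilizer=False)
        frac, regional = fertilizer_fraction(with_f, without)
        v = frac[~np.isnan(frac)]
        assert np.all((v >= 0) & (v <= 1))
        assert 0 <= regional <= 1
        # unfertilized cells contribute exactly zero fraction
        assert np.any(v == 0.0)

    def test_scaling(self, forcing_small, fert_small):
        field = run_simulation(forcing_small, fert_small)
        doubled = scale_soil_emissions(field, 2.0)
        assert doubled.total_mass_tg() == pytest.approx(2 * field.total_mass_tg(), rel=1e-12)
        back = scale_soil_emissions(doubled, 0.5)
        np.testing.assert_allclose(back.flux, field.flux, rtol=1e-15)
        with pytest.raises(ValueError):
            scale_soil_emissions(field, -1.0)
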