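"""Roper energy-balance estimators: round trips, closed forms, degenerate input."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanotherm.photothermal import (
    CoolingFit,
    FitError,
    PhotothermalTrace,
    SampleThermalSpec,
    cycle_stability,
    efficiency_eta,
    fit_cooling_hs,
    fit_point_source,
    heating_efficiency_5min,
    heating_rate,
    osar,
    subtract_control,
)
from nanotherm.synthetic import (
    LumpedModelParams,
    NoiseSpec,
    generate_photothermal_trace,
    generate_point_source_trace,
    water_control_params,
)

PLATEAU = ((1800.0, True), (2400.0, False))


def exponential_cooling_trace(tau=300.0, dt_max=20.0, ambient=20.0, dt=1.0):
    """Heating ramp then exact exponential cooling with time constant tau."""
    t_heat = np.arange(0.0, 100.0, dt)
    heat = ambient + dt_max * t_heat / t_heat[-1]
    t_cool = np.arange(100.0, 1600.0, dt)
    cool = ambient + dt_max * np.exp(-(t_cool - 100.0) / tau)
    return PhotothermalTrace(
        time=np.concatenate([t_heat, t_cool]),
        temperature=np.concatenate([heat, cool]),
        laser_on=np.concatenate(
            [np.ones(t_heat.size, bool), np.zeros(t_cool.size, bool)]
        ),
    )


class TestCoolingFit:
    def test_forced_exponential_recovers_hs_exactly(self):
        """tau = 300 s with C_tot = 12.6 J/K gives hS = 0.042 W/K, r^2 = 1."""
        trace = exponential_cooling_trace(tau=300.0)
        spec = SampleThermalSpec(total_heat_capacity=12.6)
        fit = fit_cooling_hs(trace, spec)
        assert fit.hS == pytest.approx(0.042, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.tau_s == pytest.approx(12.6 / fit.hS, rel=1e-12)

    def test_laser_never_off_raises(self):
        t = np.arange(100.0)
        trace = PhotothermalTrace(
            time=t, temperature=20 + 0.1 * t, laser_on=np.ones(t.size, bool)
        )
        with pytest.raises(FitError, match="never switched off"):
            fit_cooling_hs(trace, SampleThermalSpec(total_heat_capacity=4.186))

    def test_noisy_recovery_within_two_percent(self):
        params = LumpedModelParams(eta=0.4, hS=0.019, q_s=0.0)
        trace = generate_photothermal_trace(
            params, PLATEAU, dt=1.0, noise=NoiseSpec(sd=0.05, seed=7)
        )
        fit = fit_cooling_hs(trace, params.sample_spec())
        assert fit.tau_s == pytest.approx(params.tau_s, rel=0.02)

    def test_window_control(self):
        trace = exponential_cooling_trace()
        spec = SampleThermalSpec(total_heat_capacity=12.6)
        fit = fit_cooling_hs(trace, spec, window=(10.0, 600.0))
        assert fit.hS == pytest.approx(0.042, rel=1e-9)
        with pytest.raises(ValueError):
            fit_cooling_hs(trace, spec, window=(600.0, 10.0))


class TestEfficiency:
    def test_energy_balance_closure_eta_one(self):
        """hS * dT_ss = I with A large and Q_s = 0 closes the balance at 1."""
        params = LumpedModelParams(
            eta=1.0, laser_power=0.5, absorbance_1064=6.0, hS=0.02, q_s=0.0
        )
        trace = generate_photothermal_trace(params, ((3000.0, True), (3000.0, False)))
        spec = params.sample_spec()
        fit = fit_cooling_hs(trace, spec)
        res = efficiency_eta(trace, spec, fit)
        assert res.eta == pytest.approx(1.0, abs=2e-3)

    def test_round_trip_eta_030_to_three_decimals(self):
        params = LumpedModelParams(eta=0.30, hS=0.019, q_s=0.0)
        trace = generate_photothermal_trace(params, ((2500.0, True), (2500.0, False)))
        spec = params.sample_spec()
        res = efficiency_eta(trace, spec, fit_cooling_hs(trace, spec), q_s=0.0)
        assert res.eta == pytest.approx(0.300, abs=5e-4)
        assert not res.out_of_range

    @pytest.mark.parametrize("a1064", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("c_tot", [2.0, 4.186, 12.6])
    def test_eta_invariant_to_consistent_nuisance_parameters(self, a1064, c_tot):
        params = LumpedModelParams(
            eta=0.426, absorbance_1064=a1064, total_heat_capacity=c_tot,
            hS=0.019, q_s=0.0,
        )
        schedule = ((12.0 * params.tau_s, True), (12.0 * params.tau_s, False))
        trace = generate_photothermal_trace(params, schedule, dt=1.0)
        spec = params.sample_spec()
        res = efficiency_eta(trace, spec, fit_cooling_hs(trace, spec), q_s=0.0)
        assert res.eta == pytest.approx(0.426, rel=1e-3)

    def test_qs_from_water_control(self, operating_point, plateau_trace, water_trace):
        spec = operating_point.sample_spec()
        fit = fit_cooling_hs(plateau_trace, spec)
        res = efficiency_eta(plateau_trace, spec, fit, water_control=water_trace)
        assert res.q_s == pytest.approx(operating_point.q_s, rel=1e-3)
        assert res.eta == pytest.approx(operating_point.eta, rel=1e-3)

    def test_out_of_range_is_flagged_not_hidden(self, plateau_trace, operating_point):
        spec = operating_point.sample_spec()
        inflated = CoolingFit(hS=1.0, tau_s=4.186, fit_window=(0, 1), r_squared=1.0)
        res = efficiency_eta(plateau_trace, spec, inflated, q_s=0.0)
        assert res.out_of_range
        assert res.eta == 1.0  # clamped, visibly


class TestRates:
    def _linear_trace(self, slope=0.055, duration=400.0, ambient=20.0):
        t = np.arange(0.0, duration + 1600.0, 1.0)
        on = t <= duration
        temp = np.where(on, ambient + slope * t,
                        ambient + slope * duration)
        return PhotothermalTrace(time=t, temperature=temp, laser_on=on)

    def test_osar_direct_formula(self):
        """slope 0.055 K/s, 1 mL water, 1 mg NP -> 4.186*0.055/1e-3 = 230 W/g."""
        trace = self._linear_trace(0.055)
        spec = SampleThermalSpec(total_heat_capacity=4.186, np_mass=1e-3)
        res = osar(trace, spec, eval_time=120.0)
        assert res.osar == pytest.approx(4.186 * 0.055 / 1e-3, rel=1e-9)
        assert res.osar == pytest.approx(230.0, rel=2e-3)

    def test_osar_zero_slope(self):
        trace = self._linear_trace(0.0)
        res = osar(trace, SampleThermalSpec(total_heat_capacity=4.186))
        assert res.osar == pytest.approx(0.0, abs=1e-12)

    def test_osar_outside_on_block_rejected(self):
        trace = self._linear_trace(duration=100.0)
        with pytest.raises(ValueError, match="outside"):
            osar(trace, SampleThermalSpec(total_heat_capacity=4.186), eval_time=300.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(slope=st.floats(1e-4, 0.5), np_mass=st.floats(1e-4, 1e-1))
    def test_osar_scaling_property(self, slope, np_mass):
        trace = self._linear_trace(slope)
        spec = SampleThermalSpec(total_heat_capacity=4.186, np_mass=np_mass)
        res = osar(trace, spec)
        assert res.osar == pytest.approx(4.186 * slope / np_mass, rel=1e-6)

    def test_heating_rate_exact_ramp(self):
        trace = self._linear_trace(0.055)
        assert heating_rate(trace) == pytest.approx(3.3, rel=1e-9)

    def test_heating_rate_constant_trace_is_zero(self):
        trace = self._linear_trace(0.0)
        assert heating_rate(trace) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(dt_inf=st.floats(5.0, 40.0), tau=st.floats(60.0, 600.0))
    def test_windowed_rate_below_initial_derivative(self, dt_inf, tau):
        """The 2-min OLS slope of an exponential approach underestimates dT_inf/tau."""
        hs = 0.019
        params = LumpedModelParams(
            eta=min(dt_inf * hs / (1.22 * 0.9), 1.0),
            hS=hs, total_heat_capacity=hs * tau, q_s=0.0,
        )
        trace = generate_photothermal_trace(params, ((300.0, True), (300.0, False)))
        rate = heating_rate(trace)
        initial = params.steady_rise() / params.tau_s * 60.0
        assert rate < initial

    def test_heating_efficiency_direct_value(self):
        """C 12.6 J/K, dT 14.5 K at 5 min, 1.22 W -> 12.6*14.5/366 ~ 0.499."""
        trace = self._linear_trace(14.5 / 300.0)
        spec = SampleThermalSpec(total_heat_capacity=12.6)
        eff = heating_efficiency_5min(trace, spec)
        assert eff == pytest.approx(12.6 * 14.5 / (1.22 * 300.0), rel=1e-9)
        assert eff == pytest.approx(0.499, abs=1e-3)

    def test_heating_efficiency_zero_and_short_block(self):
        flat = self._linear_trace(0.0)
        spec = SampleThermalSpec(total_heat_capacity=12.6)
        assert heating_efficiency_5min(flat, spec) == pytest.approx(0.0, abs=1e-12)
        short = self._linear_trace(0.1, duration=100.0)
        with pytest.raises(ValueError, match="shorter"):
            heating_efficiency_5min(short, spec)


class TestPointSourceFit:
    def test_noise_free_inversion(self):
        trace = generate_point_source_trace(26.0, 6.0, 300.0, 0.5)
        fit = fit_point_source(trace)
        assert fit.delta_t_inf == pytest.approx(26.0, rel=1e-6)
        assert fit.beta == pytest.approx(6.0, rel=1e-6)
        assert fit.residual_rms < 1e-9

    def test_wrong_model_converges_with_large_residual(self):
        """An exponential-approach curve still fits, with visible misfit."""
        params = LumpedModelParams(eta=0.426, hS=0.019, q_s=0.0)
        trace = generate_photothermal_trace(params, ((300.0, True), (300.0, False)))
        fit = fit_point_source(trace)
        erfc_rms = fit_point_source(
            generate_point_source_trace(26.0, 6.0, 300.0, 1.0)
        ).residual_rms
        assert fit.residual_rms > 10 * max(erfc_rms, 1e-6)

    def test_too_few_points_rejected(self):
        t = np.arange(15.0)
        trace = PhotothermalTrace(
            time=t, temperature=20 + t, laser_on=np.ones(t.size, bool)
        )
        with pytest.raises(FitError, match=">= 20"):
            fit_point_source(trace)


class TestCycles:
    def test_identical_cycles_have_zero_spread(self):
        """Four exactly repeated on/off patterns: spread is exactly 0."""
        t_on = np.arange(0.0, 300.0, 1.0)
        t_off = np.arange(300.0, 1500.0, 1.0)
        temp_cycle = np.concatenate(
            [20 + 10 * (1 - np.exp(-t_on / 60.0)),
             20 + 10 * np.exp(-(t_off - 300.0) / 60.0)]
        )
        on_cycle = np.concatenate([np.ones(t_on.size, bool), np.zeros(t_off.size, bool)])
        n = temp_cycle.size
        trace = PhotothermalTrace(
            time=np.arange(4 * n, dtype=float),
            temperature=np.tile(temp_cycle, 4),
            laser_on=np.tile(on_cycle, 4),
        )
        rep = cycle_stability(trace)
        assert rep.n_cycles == 4
        assert rep.spread == 0.0

    def test_degradation_recovered_against_closed_form(self, operating_point):
        """5 %/cycle fading: per-cycle maxima match the exact forward recursion."""
        d = 0.05
        params = dataclasses.replace(operating_point, degradation_per_cycle=d)
        schedule = ((300.0, True), (1200.0, False)) * 4
        trace = generate_photothermal_trace(params, schedule, dt=1.0)
        rep = cycle_stability(trace)
        # independent forward recursion of block-edge temperatures
        tau, amb = params.tau_s, params.ambient
        temp, eta = amb, params.eta
        expected = []
        for _ in range(4):
            target = amb + (eta * 1.22 * 0.9 + params.q_s) / params.hS
            start = temp
            peak = target + (start - target) * math.exp(-300.0 / tau)
            expected.append(peak - start)
            temp = amb + (peak - amb) * math.exp(-1200.0 / tau)
            eta *= 1 - d
        assert rep.per_cycle_delta_t_max == pytest.approx(expected, rel=0.02)
        assert rep.spread == pytest.approx(expected[0] - expected[3], rel=0.02)

    def test_single_cycle_rejected(self):
        t = np.arange(100.0)
        trace = PhotothermalTrace(
            time=t, temperature=20 + 0.01 * t, laser_on=t < 50
        )
        with pytest.raises(ValueError, match=">= 2"):
            cycle_stability(trace)


class TestControlSubtraction:
    def test_self_subtraction_is_zero(self, plateau_trace):
        diff = subtract_control(plateau_trace, plateau_trace)
        assert np.max(np.abs(diff.temperature)) == 0.0

    def test_np_minus_water_equals_particle_only_component(self, operating_point):
        np_trace = generate_photothermal_trace(operating_point, PLATEAU, dt=1.0)
        water = generate_photothermal_trace(
            water_control_params(operating_point), PLATEAU, dt=1.0
        )
        only_np = generate_photothermal_trace(
            dataclasses.replace(operating_point, q_s=0.0), PLATEAU, dt=1.0
        )
        diff = subtract_control(np_trace, water)
        np.testing.assert_allclose(
            diff.temperature,
            only_np.temperature - operating_point.ambient,
            atol=1e-9,
        )

    def test_mismatched_schedules_rejected(self, operating_point):
        a = generate_photothermal_trace(operating_point, ((300.0, True), (600.0, False)))
        b = generate_photothermal_trace(operating_point, ((330.0, True), (570.0, False)))
        with pytest.raises(ValueError, match="schedule"):
            subtract_control(a, b)


class TestRoundTripInvariants:
    def test_noise_free_round_trip_to_1e6(self, operating_point):
        trace = generate_photothermal_trace(
            operating_point, ((20 * operating_point.tau_s, True),
                              (20 * operating_point.tau_s, False)), dt=1.0
        )
        spec = operating_point.sample_spec()
        fit = fit_cooling_hs(trace, spec)
        assert fit.hS == pytest.approx(operating_point.hS, rel=1e-6)
        res = efficiency_eta(trace, spec, fit, q_s=operating_point.q_s)
        assert res.eta == pytest.approx(operating_point.eta, rel=1e-5)

    def test_noisy_round_trip_unbiased_within_two_percent(self, operating_point):
        """Mean of 100 seeded noisy replicates stays within 2 % of truth."""
        spec = operating_point.sample_spec()
        etas, hss = [], []
        for seed in range(100):
            trace = generate_photothermal_trace(
                operating_point, PLATEAU, dt=1.0, noise=NoiseSpec(sd=0.1, seed=seed)
            )
            fit = fit_cooling_hs(trace, spec)
            hss.append(fit.hS)
            etas.append(
                efficiency_eta(trace, spec, fit, q_s=operating_point.q_s).eta
            )
        assert np.mean(hss) == pytest.approx(operating_point.hS, rel=0.02)
        assert np.mean(etas) == pytest.approx(operating_point.eta, rel=0.02)


class TestTraceContainer:
    def test_csv_round_trip(self, tmp_path, plateau_trace):
        path = tmp_path / "trace.csv"
        plateau_trace.to_csv(path)
        back = PhotothermalTrace.from_csv(path)
        np.testing.assert_allclose(back.time, plateau_trace.time)
        np.testing.assert_allclose(back.temperature, plateau_trace.temperature)
        assert np.array_equal(back.laser_on, plateau_trace.laser_on)

    def test_validation(self):
        with pytest.raises(ValueError, match=">= 10"):
            PhotothermalTrace(np.arange(5.0), np.zeros(5), np.zeros(5, bool))
        t = np.arange(20.0)
        with pytest.raises(ValueError, match="finite"):
            PhotothermalTrace(t, np.full(20, np.nan), np.zeros(20, bool))
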