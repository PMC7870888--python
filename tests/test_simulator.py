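"""Integrator tests: exponential updates, step control, and the coupled
membrane-potential dynamics, validated against closed forms and the stiff
reference solver."""

import math

import numpy as np
import pytest

import clampsim as cs
from clampsim.errors import ConfigurationError, IntegrationError, InvalidStateError


class TestRushLarsen:
    def test_fixed_point(self):
        assert cs.rush_larsen_update(0.3, 0.3, 1.5, 0.1) == pytest.approx(0.3)

    def test_full_relaxation(self):
        assert cs.rush_larsen_update(0.0, 0.8, 1.0, 1e6) == pytest.approx(0.8)

    def test_one_time_constant(self):
        # y = 0 -> y_inf = 1 over dt = tau gives 1 - 1/e
        assert cs.rush_larsen_update(0.0, 1.0, 2.0, 2.0) == pytest.approx(
            1.0 - math.exp(-1.0), rel=1e-12)

    def test_result_between_start_and_target(self):
        y = cs.rush_larsen_update(0.9, 0.1, 0.5, 0.2)
        assert 0.1 < y < 0.9

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(InvalidStateError):
            cs.rush_larsen_update(0.5, 0.6, 0.0, 0.1)


class TestAdaptTimeStep:
    def test_all_small_doubles_and_accepts(self):
        dt, ok = cs.adapt_time_step([1e-6, 1e-6, 1e-6], 0.2)
        assert dt == pytest.approx(0.4) and ok

    def test_any_large_halves_and_rejects(self):
        dt, ok = cs.adapt_time_step([2e-5, 1e-6, 1e-6], 0.4)
        assert dt == pytest.approx(0.2) and not ok

    def test_between_thresholds_unchanged(self):
        dt, ok = cs.adapt_time_step([8e-6, 1e-6, 1e-6], 0.2)
        assert dt == pytest.approx(0.2) and ok

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            cs.SolverSettings(grow_threshold=1e-5, shrink_threshold=0.5e-5)


class TestPassiveResponse:
    def test_zero_conductance_gives_rc_charging(self):
        """With no channels, Vm relaxes to Vcmd with time constant Rs*Cm."""
        model = cs.build_model("ina_ohara", 1.0).with_g_max(0.0)
        clamp = cs.ClampConfig(rs_mohm=5.0, cm_pf=20.0)  # tau = 0.1 ms
        tr = cs.integrate_step(model, clamp, -100.0, -40.0, 2.0)
        assert np.all(tr.i_nA == 0.0)
        tau = 5.0 * 20.0 * 1e-3
        expected = -40.0 + (-100.0 + 40.0) * np.exp(-tr.t_ms / tau)
        assert np.allclose(tr.vm_mV, expected, atol=0.05)

    def test_reference_matches_closed_form(self):
        model = cs.build_model("ina_ohara", 1.0).with_g_max(0.0)
        clamp = cs.ClampConfig(rs_mohm=10.0, cm_pf=20.0)
        tr = cs.reference_integrate(model, clamp, -80.0, -30.0, 2.0)
        tau = 10.0 * 20.0 * 1e-3
        expected = -30.0 + (-80.0 + 30.0) * np.exp(-tr.t_ms / tau)
        assert np.allclose(tr.vm_mV, expected, atol=1e-4)


class TestIdealClamp:
    def test_vm_equals_vcmd_bitwise(self):
        model = cs.build_model("ina_ohara", 1.0)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0), -100.0, -30.0, 5.0)
        assert np.array_equal(tr.vm_mV, tr.vcmd_mV)
        assert np.all(tr.voltage_error_mV == 0.0)

    def test_shape_invariance_under_gmax_scaling(self):
        """At Rs = 0 the gate trajectory is conductance-independent, so
        currents scale exactly."""
        clamp = cs.ClampConfig(rs_mohm=0.0)
        lo = cs.integrate_step(cs.build_model("ina_ohara", 0.3), clamp,
                               -100.0, -30.0, 10.0)
        hi = cs.integrate_step(cs.build_model("ina_ohara", 3.0), clamp,
                               -100.0, -30.0, 10.0)
        assert np.allclose(hi.i_nA, 10.0 * lo.i_nA, rtol=1e-12, atol=1e-12)

    def test_reference_decouples_at_rs_zero(self):
        model = cs.build_model("ina_ohara", 1.0)
        a = cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0), -100.0, -40.0, 10.0)
        b = cs.reference_integrate(model, cs.ClampConfig(rs_mohm=0.0),
                                   -100.0, -40.0, 10.0)
        assert np.max(np.abs(a.i_nA - b.i_nA)) < 5e-3 * np.max(np.abs(b.i_nA))


class TestCoupledDynamics:
    def test_oracle_equivalence_moderate_condition(self):
        model = cs.build_model("ina_ohara", 0.7)
        clamp = cs.ClampConfig(rs_mohm=2.0)
        a = cs.integrate_step(model, clamp, -100.0, -40.0, 20.0)
        b = cs.reference_integrate(model, clamp, -100.0, -40.0, 20.0)
        assert np.max(np.abs(a.i_nA - b.i_nA)) < 5e-3 * np.max(np.abs(b.i_nA))

    def test_oracle_equivalence_ito(self):
        model = cs.build_model("ito_ohara", 1.0)
        clamp = cs.ClampConfig(rs_mohm=5.0)
        a = cs.integrate_step(model, clamp, -100.0, 20.0, 30.0)
        b = cs.reference_integrate(model, clamp, -100.0, 20.0, 30.0)
        assert np.max(np.abs(a.i_nA - b.i_nA)) < 5e-3 * np.max(np.abs(b.i_nA))

    def test_quasi_steady_state_identity(self):
        """Once dVm/dt ~ 0, the circuit law Vm = Vcmd - Rs*I must hold."""
        model = cs.build_model("ina_ohara", 0.7)
        clamp = cs.ClampConfig(rs_mohm=5.0)
        tr = cs.integrate_step(model, clamp, -100.0, -40.0, 50.0)
        tail = tr.t_ms > 40.0
        assert np.allclose(tr.vm_mV[tail],
                           tr.vcmd_mV[tail] - 5.0 * tr.i_nA[tail], atol=0.02)

    def test_open_fraction_stays_bounded(self):
        """Recovered open probability i / (g (Vm - E)) lies in [0, 1]."""
        model = cs.build_model("ina_ohara", 6.0)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=5.0), -100.0, -20.0, 50.0)
        drive = model.g_max * (tr.vm_mV - model.reversal_mV)
        mask = np.abs(tr.vm_mV - model.reversal_mV) > 1.0
        p = tr.i_nA[mask] / drive[mask]
        assert np.all(p >= -1e-12) and np.all(p <= 1.0 + 1e-12)

    def test_flat_trace_at_holding(self):
        model = cs.build_model("ina_ohara", 1.0)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=5.0),
                               -100.0, -100.0, 10.0)
        assert np.max(np.abs(tr.i_nA)) < 1e-3
        assert np.max(np.abs(tr.voltage_error_mV)) < 1e-2


class TestStepControl:
    def test_coarse_initial_step_recovers_via_rollback(self):
        """Starting 100x too coarse must trigger rejections yet converge to
        the same trace as the default fine start (gate-governed regime)."""
        model = cs.build_model("ina_ohara", 0.7)
        clamp = cs.ClampConfig(rs_mohm=0.0)
        fine = cs.integrate_step(model, clamp, -100.0, -40.0, 10.0)
        coarse = cs.integrate_step(model, clamp, -100.0, -40.0, 10.0,
                                   settings=cs.SolverSettings(dt_init_us=10.0))
        assert coarse.n_rejected > 0
        pf, pc = cs.peak_metrics(fine), cs.peak_metrics(coarse)
        assert pc.peak_nA == pytest.approx(pf.peak_nA, rel=1e-3)
        assert pc.time_to_peak_ms == pytest.approx(pf.time_to_peak_ms, abs=0.04)
        peak = np.max(np.abs(fine.i_nA))
        assert np.max(np.abs(fine.i_nA - coarse.i_nA)) < 1e-2 * peak

    def test_include_vm_controls_charging_accuracy(self):
        """With gates quiescent at step onset the default (gate-only)
        criterion leaves the membrane charging to coarse explicit steps; a
        too-coarse start then distorts the peak, and adding Vm to the step
        control restores agreement with the stiff oracle."""
        model = cs.build_model("ina_ohara", 0.7)
        clamp = cs.ClampConfig(rs_mohm=2.0)
        ref = cs.reference_integrate(model, clamp, -100.0, -40.0, 10.0)
        guarded = cs.integrate_step(
            model, clamp, -100.0, -40.0, 10.0,
            settings=cs.SolverSettings(dt_init_us=10.0, include_vm=True))
        p_ref, p_g = cs.peak_metrics(ref), cs.peak_metrics(guarded)
        assert p_g.peak_nA == pytest.approx(p_ref.peak_nA, rel=1e-2)

    def test_dt_underflow_raises_with_time(self):
        model = cs.build_model("ina_ohara", 1.0)
        settings = cs.SolverSettings(dt_min_us=0.06)  # floor above the demand
        with pytest.raises(IntegrationError) as exc:
            cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0),
                              -100.0, 40.0, 5.0, settings=settings)
        assert exc.value.last_time_ms is not None

    def test_protocol_error_annotated_with_step(self):
        model = cs.build_model("ina_ohara", 1.0)
        protocol = cs.VoltageStepProtocol(steps_mV=(-60.0, 40.0), duration_ms=5.0)
        with pytest.raises(IntegrationError, match="-60"):
            cs.run_protocol(model, cs.ClampConfig(rs_mohm=0.0), protocol,
                            cs.SolverSettings(dt_min_us=0.06))


class TestProtocolAndTraces:
    def test_one_sweep_per_step_from_holding_steady_state(self):
        model = cs.build_model("ina_ohara", 0.5)
        protocol = cs.VoltageStepProtocol(steps_mV=(-60.0, -40.0, -20.0),
                                          duration_ms=5.0)
        traces = cs.run_protocol(model, cs.ClampConfig(rs_mohm=0.0), protocol)
        assert [tr.step_mV for tr in traces] == [-60.0, -40.0, -20.0]
        for tr in traces:
            assert tr.holding_mV == -100.0
            assert tr.t_ms[0] == 0.0 and tr.t_ms[-1] == pytest.approx(5.0)
            assert np.all(np.diff(tr.t_ms) > 0)

    def test_sampling_interval_respected(self):
        model = cs.build_model("ina_ohara", 0.5)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0), -100.0, -40.0,
                               2.0, settings=cs.SolverSettings(sample_ms=0.05))
        assert len(tr.t_ms) == 41
        assert np.allclose(np.diff(tr.t_ms), 0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            cs.ClampConfig(rs_mohm=-1.0)
        with pytest.raises(ConfigurationError):
            cs.ClampConfig(cm_pf=0.0)
        with pytest.raises(ConfigurationError):
            cs.VoltageStepProtocol(steps_mV=())
        with pytest.raises(ConfigurationError):
            cs.VoltageStepProtocol(duration_ms=0.0)
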