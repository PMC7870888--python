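"""Analysis tests: peak extraction, conductance transform, Boltzmann
fitting and amplitude binning.

Ideal-clamp peaks have an independent closed-form oracle: at fixed V each
gate relaxes as an exact exponential, so the peak open probability can be
computed without any ODE solver.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import clampsim as cs
from clampsim import channels as ch
from clampsim.analysis import boltzmann
from clampsim.errors import InvalidInputError


def closed_form_ina_peak(g_max, v, holding=-100.0, duration=50.0):
    """Oracle: exact gate exponentials at fixed V; peak of g*(V-E)*m^3*h*j
    on a dense time grid."""
    t = np.linspace(0.0, duration, 200001)
    gates = []
    for inf, tau in ((ch.m_inf, ch.tau_m), (ch.h_inf, ch.tau_h),
                     (ch.j_inf, ch.tau_j)):
        y0, yinf, tc = inf(holding), inf(v), tau(v)
        gates.append(yinf - (yinf - y0) * np.exp(-t / tc))
    m, h, j = gates
    i = g_max * (v - ch.nernst_potential(ch.NA_PHYSIOLOGICAL)) * m**3 * h * j
    k = int(np.argmin(i))
    return float(i[k]), float(t[k])


class TestPeakMetrics:
    def test_closed_form_oracle_at_minus20(self):
        model = cs.build_model("ina_ohara", 1.0)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0), -100.0, -20.0, 50.0)
        pk = cs.peak_metrics(tr)
        exp_peak, exp_ttp = closed_form_ina_peak(1.0, -20.0)
        assert pk.peak_nA == pytest.approx(exp_peak, rel=1e-3)
        assert pk.time_to_peak_ms == pytest.approx(exp_ttp, abs=0.03)

    def test_closed_form_oracle_at_minus45(self):
        model = cs.build_model("ina_ohara", 1.0)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0), -100.0, -45.0, 50.0)
        pk = cs.peak_metrics(tr)
        exp_peak, exp_ttp = closed_form_ina_peak(1.0, -45.0)
        assert pk.peak_nA == pytest.approx(exp_peak, rel=1e-3)
        assert pk.time_to_peak_ms == pytest.approx(exp_ttp, abs=0.03)

    def test_zero_trace_returns_zero_and_flag(self):
        model = cs.build_model("ina_ohara", 1.0).with_g_max(0.0)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0), -100.0, -20.0, 2.0)
        pk = cs.peak_metrics(tr)
        assert pk.peak_nA == 0.0 and np.isnan(pk.time_to_peak_ms)

    def test_outward_polarity_takes_maximum(self):
        model = cs.build_model("ito_ohara", 1.0)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0), -100.0, 30.0, 20.0)
        pk = cs.peak_metrics(tr, "outward")
        assert pk.peak_nA > 0
        assert pk.peak_nA == pytest.approx(np.max(tr.i_nA))

    def test_unknown_polarity_rejected(self):
        model = cs.build_model("ina_ohara", 1.0)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0), -100.0, -20.0, 2.0)
        with pytest.raises(InvalidInputError):
            cs.peak_metrics(tr, "sideways")


def synthetic_linear_iv(g_uS=0.8, e_rev=71.4):
    v = np.arange(-80.0, 55.0, 5.0)
    return cs.IVCurve(step_mV=v, peak_nA=g_uS * (v - e_rev),
                      time_to_peak_ms=np.ones_like(v))


class TestIVCurve:
    def test_ohmic_fit_recovers_conductance_and_reversal(self):
        iv = synthetic_linear_iv(g_uS=0.8, e_rev=71.4)
        fit = iv.ohmic_fit(v_min_mV=0.0)
        assert fit.slope_uS == pytest.approx(0.8, rel=1e-10)
        assert fit.reversal_mV == pytest.approx(71.4, abs=1e-8)

    def test_ohmic_fit_skipped_with_too_few_points(self):
        iv = synthetic_linear_iv()
        assert iv.ohmic_fit(v_min_mV=60.0) is None

    def test_build_iv_scales_linearly_at_ideal_clamp(self):
        protocol = cs.VoltageStepProtocol(steps_mV=(-45.0, -30.0, -20.0),
                                          duration_ms=10.0)
        clamp = cs.ClampConfig(rs_mohm=0.0)
        iv1 = cs.build_iv(cs.run_protocol(cs.build_model("ina_ohara", 0.4),
                                          clamp, protocol))
        iv2 = cs.build_iv(cs.run_protocol(cs.build_model("ina_ohara", 0.8),
                                          clamp, protocol))
        assert np.allclose(iv2.peak_nA, 2.0 * iv1.peak_nA, rtol=1e-10)

    def test_needs_at_least_two_sweeps(self):
        model = cs.build_model("ina_ohara", 1.0)
        tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=0.0), -100.0, -20.0, 2.0)
        with pytest.raises(InvalidInputError):
            cs.build_iv([tr])


class TestConductanceCurve:
    def test_point_at_reversal_dropped(self):
        v = np.array([-40.0, -20.0, 0.0, 71.4])
        iv = cs.IVCurve(step_mV=v, peak_nA=np.array([-1.0, -3.0, -2.0, 0.0]),
                        time_to_peak_ms=np.ones_like(v))
        cc = cs.conductance_curve(iv, 71.4)
        assert len(cc.v_mV) == 3 and 71.4 not in cc.v_mV

    def test_ideal_clamp_matches_closed_form_profile(self):
        """Normalized G(V) at Rs = 0 equals the analytic peak open
        probability profile (driving force cancels)."""
        steps = np.arange(-50.0, -10.0 + 1e-9, 5.0)
        protocol = cs.VoltageStepProtocol(steps_mV=tuple(steps), duration_ms=50.0)
        model = cs.build_model("ina_ohara", 1.0)
        traces = cs.run_protocol(model, cs.ClampConfig(rs_mohm=0.0), protocol)
        cc = cs.conductance_curve(cs.build_iv(traces), model.reversal_mV)
        oracle = np.array([closed_form_ina_peak(1.0, v)[0] / (v - model.reversal_mV)
                           for v in steps])
        oracle /= oracle.max()
        assert np.allclose(cc.g_norm, oracle, atol=2e-3)


class TestBoltzmannFit:
    def test_exact_round_trip(self):
        v = np.arange(-80.0, 10.0, 2.0)
        g = boltzmann(v, 1.0, -39.0, 7.0)
        fit = cs.fit_boltzmann((v, g))
        assert fit.v_half_mV == pytest.approx(-39.0, abs=1e-6)
        assert fit.k_mV == pytest.approx(7.0, abs=1e-6)
        assert not fit.unreliable

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(v_half=st.floats(-60.0, 0.0), k=st.floats(3.0, 15.0),
           amp=st.floats(0.8, 1.2))
    def test_round_trip_property(self, v_half, k, amp):
        v = np.arange(-90.0, 30.0, 5.0)
        fit = cs.fit_boltzmann((v, boltzmann(v, amp, v_half, k)))
        assert fit.v_half_mV == pytest.approx(v_half, abs=1e-4)
        assert fit.k_mV == pytest.approx(k, abs=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.fit_boltzmann((np.array([-40.0, -20.0, 0.0]),
                              np.array([0.1, 0.5, 0.9])))

    def test_bounded_slope_flagged_unreliable(self):
        # data shallower than any admissible Boltzmann pushes a fit
        # parameter to its bounds
        v = np.arange(-80.0, 50.0, 5.0)
        g = boltzmann(v, 1.0, -15.0, 80.0)
        fit = cs.fit_boltzmann((v, g))
        assert fit.unreliable


class TestAmplitudeBinning:
    @staticmethod
    def records(amps_nA):
        rng = np.random.default_rng(1)
        return pd.DataFrame({
            "amp_nA": amps_nA,
            "v_half_mV": -38.0 + rng.normal(0, 1, len(amps_nA)),
            "k_mV": 7.0 + rng.normal(0, 0.3, len(amps_nA)),
        })

    def test_group_scheme_reproduces_cell_set_partition(self):
        """52 cells, 7 below 1 nA -> groups of (7, 10, 10, 10, 10, 5)."""
        amps = np.concatenate([
            np.linspace(0.35, 0.95, 7),      # reference cells < 1 nA
            np.linspace(1.05, 17.8, 45),     # the rest, up to 17.8 nA
        ])
        out = cs.bin_by_amplitude(self.records(amps), scheme="group",
                                  group_size=10, first_below_nA=1.0)
        assert list(out["n"]) == [7, 10, 10, 10, 10, 5]
        assert out["amp_mean"].is_monotonic_increasing

    def test_single_record_has_undefined_sem(self):
        out = cs.bin_by_amplitude(self.records([2.0]), scheme="group")
        assert len(out) == 1 and out.loc[0, "n"] == 1
        assert np.isnan(out.loc[0, "v05_sem"])

    def test_fixed_width_interval_assignment(self):
        out = cs.bin_by_amplitude(self.records([0.1, 0.6, 0.7]), scheme="width",
                                  width_nA=0.5)
        assert list(out["n"]) == [1, 2]
        assert list(out["bin"]) == ["0-0.5 nA", "0.5-1 nA"]

    def test_signed_amplitudes_binned_by_magnitude(self):
        out = cs.bin_by_amplitude(self.records([-0.3, -0.8, -1.4]), scheme="width",
                                  width_nA=1.0)
        assert list(out["n"]) == [2, 1]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.bin_by_amplitude(self.records([1.0]), scheme="median")

    def test_empty_records_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.bin_by_amplitude(self.records([]))


class TestAmplitudeLimit:
    def test_largest_acceptable_amplitude(self):
        curve = pd.DataFrame({
            "amp_nA": [-1.0, -3.0, -7.0, -12.0],
            "v_half_mV": [-33.0, -35.0, -40.0, -46.0],
            "k_mV": [7.0, 6.5, 5.5, 4.0],
            "fit_ok": [True, True, True, True],
        })
        # reference -32: |dV| < 10 excludes -12 nA; k > 5 also excludes it
        assert cs.amplitude_limit(curve, -32.0, 10.0, 5.0) == pytest.approx(7.0)
        # tighter slope bound excludes the 7-nA point too
        assert cs.amplitude_limit(curve, -32.0, 10.0, 6.0) == pytest.approx(3.0)

    def test_no_qualifying_point_gives_nan(self):
        curve = pd.DataFrame({
            "amp_nA": [-5.0], "v_half_mV": [-50.0], "k_mV": [3.0],
            "fit_ok": [True],
        })
        assert np.isnan(cs.amplitude_limit(curve, -32.0))
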