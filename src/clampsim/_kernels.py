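"""Numba-compiled inner loops of the adaptive-time-step clamp integrator.

The gate-rate formulas here mirror :mod:`clampsim.channels` exactly; the
Python definitions remain the reference surface, these are the hot path.
Each sweep integrates the gate states with exact exponential (Rush-Larsen)
updates and the membrane potential with an explicit update of

    dVm/dt = (Vcmd - Vm) / (Rs * Cm) - i / Cm

over the same adaptive step.  Step control follows the relative-variation
rule: the step doubles when every gate's relative change is below
``grow_thr``, and is halved (with rollback of the trial step) when any
exceeds ``shrink_thr``.
"""

import math

import numpy as np
from numba import njit

MODEL_INA = 0
MODEL_ITO = 1

STATUS_OK = 0
STATUS_DT_UNDERFLOW = 1


@njit(inline="always", cache=False)
def _ina_rates(v, m_vhalf, m_slope, h_scale):
    minf = 1.0 / (1.0 + math.exp(-(v + m_vhalf) / m_slope))
    taum = 1.0 / (
        6.765 * math.exp((v + 11.64) / 34.77)
        + 8.552 * math.exp(-(v + 77.42) / 5.955)
    )
    hinf = 1.0 / (1.0 + math.exp((v + 82.9) / 6.086))
    tauh = h_scale / (
        1.432e-5 * math.exp(-(v + 1.196) / 6.285)
        + 6.149 * math.exp((v + 0.5096) / 20.27)
    )
    tauj = 2.038 + 1.0 / (
        0.02136 * math.exp(-(v + 100.6) / 8.281)
        + 0.3052 * math.exp((v + 0.9941) / 38.45)
    )
    return minf, taum, hinf, tauh, hinf, tauj


@njit(inline="always", cache=False)
def _ito_rates(v):
    ainf = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    taua = 1.0515 / (
        1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.41) / 29.38)))
        + 3.5 / (1.0 + math.exp((v + 100.0) / 29.38))
    )
    iinf = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    tauif = 4.562 + 1.0 / (
        0.3933 * math.exp(-(v + 100.0) / 100.0)
        + 0.08004 * math.exp((v + 50.0) / 16.59)
    )
    tauis = 23.62 + 1.0 / (
        0.001416 * math.exp(-(v + 96.52) / 59.05)
        + 1.78e-8 * math.exp((v + 114.1) / 8.079)
    )
    return ainf, taua, iinf, tauif, iinf, tauis


@njit(inline="always", cache=False)
def _current(model_id, gmax, erev, v, y0, y1, y2):
    if model_id == MODEL_INA:
        # y = (m, h, j)
        return gmax * (v - erev) * y0 * y0 * y0 * y1 * y2
    # y = (a, i_fast, i_slow); fast/slow mixed by the voltage-dependent weight
    afast = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    i_gate = afast * y1 + (1.0 - afast) * y2
    return gmax * (v - erev) * y0 * i_gate


@njit(cache=False)
def integrate_sweep(
    model_id,
    m_vhalf,
    m_slope,
    h_scale,
    gmax,
    erev,
    rs,          # MOhm
    cm,          # pF
    v_hold,      # mV (initial Vm and gate steady-state potential)
    v_cmd,       # mV command during the step
    dur,         # ms
    y_init,      # kinetic state vector, length 3
    dt0,         # ms
    grow_thr,
    shrink_thr,
    dt_max,      # ms
    dt_min,      # ms
    sample,      # ms output sampling interval
    include_vm,  # bool: include Vm variation (scaled by 100 mV) in step control
):
    n = int(round(dur / sample)) + 1
    t_out = np.empty(n)
    vm_out = np.empty(n)
    i_out = np.empty(n)

    y0 = y_init[0]
    y1 = y_init[1]
    y2 = y_init[2]

    clamped = rs == 0.0
    vm = v_cmd if clamped else v_hold
    tau_rc = rs * cm * 1e-3  # MOhm * pF = us -> ms

    i_cur = _current(model_id, gmax, erev, vm, y0, y1, y2)
    t_out[0] = 0.0
    vm_out[0] = vm
    i_out[0] = i_cur
    isamp = 1

    t = 0.0
    dt = dt0
    n_steps = 0
    n_rejected = 0

    while t < dur and isamp <= n:
        if model_id == MODEL_INA:
            inf0, tau0, inf1, tau1, inf2, tau2 = _ina_rates(vm, m_vhalf, m_slope, h_scale)
        else:
            inf0, tau0, inf1, tau1, inf2, tau2 = _ito_rates(vm)

        dt_eff = dt
        if t + dt_eff > dur:
            dt_eff = dur - t

        y0n = inf0 - (inf0 - y0) * math.exp(-dt_eff / tau0)
        y1n = inf1 - (inf1 - y1) * math.exp(-dt_eff / tau1)
        y2n = inf2 - (inf2 - y2) * math.exp(-dt_eff / tau2)

        rel = abs(y0n - y0) / max(abs(y0), 1e-300)
        r1 = abs(y1n - y1) / max(abs(y1), 1e-300)
        if r1 > rel:
            rel = r1
        r2 = abs(y2n - y2) / max(abs(y2), 1e-300)
        if r2 > rel:
            rel = r2

        if clamped:
            vm_new = v_cmd
        else:
            vm_new = vm + dt_eff * ((v_cmd - vm) / tau_rc - 1000.0 * i_cur / cm)
            if include_vm:
                rv = abs(vm_new - vm) / 100.0
                if rv > rel:
                    rel = rv

        if rel > shrink_thr and dt_eff > dt_min:
            # roll the trial step back and retry with a halved step
            dt = dt_eff * 0.5
            n_rejected += 1
            if dt < dt_min:
                return t_out, vm_out, i_out, n_steps, n_rejected, STATUS_DT_UNDERFLOW, t
            continue

        i_new = _current(model_id, gmax, erev, vm_new, y0n, y1n, y2n)
        t_new = t + dt_eff

        while isamp < n and isamp * sample <= t_new + 1e-12:
            ts = isamp * sample
            w = (ts - t) / dt_eff
            t_out[isamp] = ts
            vm_out[isamp] = vm + w * (vm_new - vm)
            i_out[isamp] = i_cur + w * (i_new - i_cur)
            isamp += 1

        t = t_new
        y0 = y0n
        y1 = y1n
        y2 = y2n
        vm = vm_new
        i_cur = i_new
        n_steps += 1

        if rel < grow_thr:
            dt = dt * 2.0
            if dt > dt_max:
                dt = dt_max

    # guard against a final sample missed by float round-off
    while isamp < n:
        t_out[isamp] = isamp * sample
        vm_out[isamp] = vm
        i_out[isamp] = i_cur
        isamp += 1

    return t_out, vm_out, i_out, n_steps, n_rejected, STATUS_OK, t
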