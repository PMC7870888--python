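"""Voltage-clamp sweep integration with series-resistance feedback.

The measured cell is modelled as a single compartment behind an access
(series) resistance R_S: the amplifier clamps V_cmd, but the membrane sees

    dVm/dt = (Vcmd - Vm) / (R_S * C_m) - i / C_m          (R_S > 0)

with the ionic current i(Vm, gates) closing the loop.  R_S = 0 is treated
as the exact algebraic constraint Vm = Vcmd (the ODE is singular there and
the ideal clamp is the reference condition throughout).

Two integration routes are provided:

* :func:`integrate_step` -- the production path: exact exponential
  (Rush-Larsen) gate updates over an adaptive time step controlled by the
  relative gate variations, with an explicit update of Vm over the same
  step.  The inner loop is compiled (numba).
* :func:`reference_integrate` -- an independent stiff-solver oracle
  (scipy LSODA at rtol 1e-8 / atol 1e-10) solving dy/dt = (y_inf - y)/tau_y
  together with the Vm ODE; used to validate the production path.

Reported current is the ionic current i(t); membrane capacitance is taken
as electronically compensated, so the capacitive transient is not part of
the signal.  The pipette-current view (Vcmd - Vm)/R_S is available as a
derived property of :class:`SweepTrace`.

Units: mV / ms / nA / uS / MOhm / pF (MOhm x nA = mV; MOhm x pF = us).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .channels import HHChannelModel
from .errors import ConfigurationError, IntegrationError, InvalidStateError

__all__ = [
    "ClampConfig",
    "VoltageStepProtocol",
    "SolverSettings",
    "SweepTrace",
    "rush_larsen_update",
    "adapt_time_step",
    "integrate_step",
    "reference_integrate",
    "run_protocol",
]


@dataclass(frozen=True)
class ClampConfig:
    """Recording configuration: residual series resistance and cell size."""

    rs_mohm: float = 0.0
    cm_pf: float = 20.0

    def __post_init__(self):
        if self.rs_mohm < 0:
            raise ConfigurationError(f"series resistance must be >= 0, got {self.rs_mohm}")
        if self.cm_pf <= 0:
            raise ConfigurationError(f"membrane capacitance must be > 0, got {self.cm_pf}")


@dataclass(frozen=True)
class VoltageStepProtocol:
    """Family of depolarizing steps from a common holding potential.

    The default grid is the standard activation protocol: HP -100 mV,
    50-ms steps from -80 to +50 mV in 5-mV increments, one sweep every 2 s.
    The inter-sweep interval is metadata only: every sweep starts from gate
    steady state at the holding potential, which the seconds-long intervals
    at -100 mV guarantee.
    """

    holding_mV: float = -100.0
    steps_mV: tuple[float, ...] = tuple(np.arange(-80.0, 50.0 + 1e-9, 5.0))
    duration_ms: float = 50.0
    interval_s: float = 2.0

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ConfigurationError("step duration must be > 0")
        if len(self.steps_mV) == 0:
            raise ConfigurationError("step list must be non-empty")
        object.__setattr__(self, "steps_mV", tuple(float(v) for v in self.steps_mV))


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive-step controls.

    The step starts at 0.1 us, doubles when all relative gate variations
    fall below ``grow_threshold`` (0.5e-5) and is halved -- with the trial
    step rolled back and retried -- when any exceeds ``shrink_threshold``
    (1e-5).  A 10-us ceiling keeps the output resampling well posed.
    ``include_vm`` optionally adds the Vm variation (scaled by 100 mV) to
    the control criterion; default off (gates only).

    ``dt_min_us`` is a runaway-halving guard, not an accuracy control: at
    the onset of strongly depolarized steps the relative criterion
    legitimately demands sub-nanosecond steps (the activation gate starts
    near zero), so the floor sits well below that demand and only trips on
    genuine divergence.
    """

    dt_init_us: float = 0.1
    grow_threshold: float = 0.5e-5
    shrink_threshold: float = 1.0e-5
    dt_max_us: float = 10.0
    dt_min_us: float = 1.0e-9
    sample_ms: float = 0.02
    include_vm: bool = False

    def __post_init__(self):
        if self.dt_init_us <= 0:
            raise ConfigurationError("initial time step must be > 0")
        if not self.grow_threshold < self.shrink_threshold:
            raise ConfigurationError("doubling threshold must be below halving threshold")
        if self.sample_ms <= 0:
            raise ConfigurationError("output sampling interval must be > 0")


DEFAULT_SETTINGS = SolverSettings()


@dataclass
class SweepTrace:
    """Uniformly resampled trajectory of one voltage step.

    ``vm_mV`` is the actual membrane potential; at R_S = 0 it equals
    ``vcmd_mV`` exactly (same floats).  ``i_nA`` is the ionic current,
    inward negative.
    """

    t_ms: np.ndarray
    vcmd_mV: np.ndarray
    vm_mV: np.ndarray
    i_nA: np.ndarray
    step_mV: float
    holding_mV: float
    rs_mohm: float = 0.0
    cm_pf: float = 20.0
    n_steps: int = 0
    n_rejected: int = 0

    def __post_init__(self):
        n = len(self.t_ms)
        if not (len(self.vcmd_mV) == len(self.vm_mV) == len(self.i_nA) == n):
            raise InvalidStateError("trace arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise InvalidStateError("trace time axis must be strictly increasing")

    @property
    def voltage_error_mV(self) -> np.ndarray:
        """Deviation Vcmd - Vm (the series-resistance voltage drop R_S * I)."""
        return self.vcmd_mV - self.vm_mV

    @property
    def pipette_current_nA(self) -> np.ndarray:
        """(Vcmd - Vm)/R_S: the current flowing through the pipette."""
        if self.rs_mohm == 0:
            return self.i_nA.copy()
        return (self.vcmd_mV - self.vm_mV) / self.rs_mohm


# --------------------------------------------------------------------------
# Elementary operations (also used stand-alone and in unit tests)
# --------------------------------------------------------------------------

def rush_larsen_update(y: float, y_inf: float, tau: float, dt: float) -> float:
    """Exact exponential relaxation of a gate over one step:
    y_inf - (y_inf - y) * exp(-dt/tau)."""
    if tau <= 0:
        raise InvalidStateError(f"time constant must be > 0, got {tau}")
    return y_inf - (y_inf - y) * np.exp(-dt / tau)


def adapt_time_step(
    relative_variations,
    current_dt: float,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> tuple[float, bool]:
    """Apply the step-doubling/halving rule.

    Returns ``(new_dt, accept)``.  ``accept`` is False when any variation
    exceeded the halving threshold: the caller must roll the step back and
    retry with the smaller step.
    """
    rel = max(relative_variations)
    if rel > settings.shrink_threshold:
        return current_dt * 0.5, False
    if rel < settings.grow_threshold:
        return current_dt * 2.0, True
    return current_dt, True


# --------------------------------------------------------------------------
# Kernel dispatch
# --------------------------------------------------------------------------

def _kernel_params(model: HHChannelModel) -> tuple[int, float, float, float]:
    if model.label == "ina_ohara":
        return _kernels.MODEL_INA, 39.57, 9.871, 1.0
    if model.label == "ina_nav15_optimized":
        return _kernels.MODEL_INA, 42.57, 12.0, 4.0
    if model.label == "ito_ohara":
        return _kernels.MODEL_ITO, 0.0, 0.0, 0.0
    raise ConfigurationError(
        f"no compiled kernel for model label {model.label!r}; "
        "use reference_integrate for custom models"
    )


def integrate_step(
    model: HHChannelModel,
    clamp: ClampConfig,
    v_start: float,
    v_cmd: float,
    duration_ms: float,
    settings: SolverSettings = DEFAULT_SETTINGS,
    initial_gates: np.ndarray | None = None,
) -> SweepTrace:
    """Integrate one voltage step with the adaptive Rush-Larsen scheme.

    Gates default to steady state at ``v_start``; Vm starts at ``v_start``.
    The returned trace is resampled to ``settings.sample_ms``.
    """
    model_id, p1, p2, p3 = _kernel_params(model)
    y0 = (
        np.asarray(initial_gates, dtype=float)
        if initial_gates is not None
        else model.initial_state(v_start)
    )
    if y0.shape != (3,):
        raise InvalidStateError(f"expected 3 kinetic state variables, got {y0.shape}")

    t, vm, i, n_steps, n_rej, status, t_last = _kernels.integrate_sweep(
        model_id, p1, p2, p3,
        model.g_max, model.reversal_mV,
        clamp.rs_mohm, clamp.cm_pf,
        float(v_start), float(v_cmd), float(duration_ms),
        y0,
        settings.dt_init_us * 1e-3,
        settings.grow_threshold,
        settings.shrink_threshold,
        settings.dt_max_us * 1e-3,
        settings.dt_min_us * 1e-3,
        settings.sample_ms,
        settings.include_vm,
    )
    if status != _kernels.STATUS_OK:
        raise IntegrationError(
            f"time step underflow below {settings.dt_min_us} us at t = {t_last:.6f} ms "
            f"(step to {v_cmd} mV)",
            last_time_ms=t_last,
        )
    vcmd = np.full_like(t, float(v_cmd))
    if clamp.rs_mohm == 0.0:
        vm = vcmd.copy()  # exact algebraic constraint, bitwise equal
    return SweepTrace(
        t_ms=t, vcmd_mV=vcmd, vm_mV=vm, i_nA=i,
        step_mV=float(v_cmd), holding_mV=float(v_start),
        rs_mohm=clamp.rs_mohm, cm_pf=clamp.cm_pf,
        n_steps=int(n_steps), n_rejected=int(n_rej),
    )


def reference_integrate(
    model: HHChannelModel,
    clamp: ClampConfig,
    v_start: float,
    v_cmd: float,
    duration_ms: float,
    settings: SolverSettings = DEFAULT_SETTINGS,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SweepTrace:
    """Independent stiff-solver oracle for :func:`integrate_step`.

    Solves the coupled system dy/dt = (y_inf - y)/tau_y (one equation per
    kinetic state, composite components separate) together with the Vm ODE
    using LSODA at tight tolerances.  Works for any
    :class:`~clampsim.channels.HHChannelModel`, not just the compiled ones.
    """
    y0 = model.initial_state(v_start)
    nstate = len(y0)
    clamped = clamp.rs_mohm == 0.0
    tau_rc_ms = clamp.rs_mohm * clamp.cm_pf * 1e-3

    # flatten (gate, component) rate callables once
    ss_fns, tau_fns = [], []
    for g in model.gates:
        if g.is_composite:
            for c in g.components:
                ss_fns.append(g.steady_state)
                tau_fns.append(c.time_constant)
        else:
            ss_fns.append(g.steady_state)
            tau_fns.append(g.time_constant)

    def ionic_current(v, state):
        gate_vals = model.gate_values_from_state(state, v)
        return model.current(v, np.clip(gate_vals, 0.0, 1.0))

    def rhs(t, z):
        v = v_cmd if clamped else z[nstate]
        dz = np.empty_like(z)
        for k in range(nstate):
            dz[k] = (ss_fns[k](v) - z[k]) / tau_fns[k](v)
        if not clamped:
            i = ionic_current(v, z[:nstate])
            dz[nstate] = (v_cmd - v) / tau_rc_ms - 1000.0 * i / clamp.cm_pf
        return dz

    z0 = y0 if clamped else np.concatenate([y0, [v_start]])
    n = int(round(duration_ms / settings.sample_ms)) + 1
    t_eval = np.linspace(0.0, duration_ms, n)
    sol = solve_ivp(
        rhs, (0.0, duration_ms), z0, method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"reference solver failed: {sol.message}",
                               last_time_ms=float(sol.t[-1]) if len(sol.t) else 0.0)

    vcmd = np.full(n, float(v_cmd))
    if clamped:
        vm = vcmd.copy()
    else:
        vm = sol.y[nstate]
        vm[0] = v_start
    i = np.array([
        ionic_current(vm[k], sol.y[:nstate, k]) for k in range(n)
    ])
    return SweepTrace(
        t_ms=t_eval, vcmd_mV=vcmd, vm_mV=vm, i_nA=i,
        step_mV=float(v_cmd), holding_mV=float(v_start),
        rs_mohm=clamp.rs_mohm, cm_pf=clamp.cm_pf,
    )


def run_protocol(
    model: HHChannelModel,
    clamp: ClampConfig,
    protocol: VoltageStepProtocol = VoltageStepProtocol(),
    settings: SolverSettings = DEFAULT_SETTINGS,
    reference: bool = False,
) -> list[SweepTrace]:
    """One sweep per step potential, each starting from steady state at the
    holding potential.  ``reference=True`` routes through the stiff oracle."""
    integrator = reference_integrate if reference else integrate_step
    traces = []
    for v_step in protocol.steps_mV:
        try:
            traces.append(
                integrator(model, clamp, protocol.holding_mV, v_step,
                           protocol.duration_ms, settings)
            )
        except IntegrationError as exc:
            raise IntegrationError(
                f"integration failed at step potential {v_step} mV: {exc}",
                last_time_ms=exc.last_time_ms,
            ) from exc
    return traces
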