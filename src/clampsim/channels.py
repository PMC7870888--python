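"""Hodgkin-Huxley formulations of cardiac I_Na (Nav1.5) and I_to.

Channel open probability is a product of independent gate variables, each
relaxing exponentially toward a voltage-dependent steady state ``y_inf(V)``
with a voltage-dependent time constant ``tau_y(V)``.  Three models are
provided:

``ina_ohara``
    Fast cardiac Na+ current with activation gate m (cubed) and fast
    inactivation gates h and j.  The slow component of h is omitted (it
    carries ~1% of inactivation).
``ina_nav15_optimized``
    Same as ``ina_ohara`` except the m steady state is shifted/shallower
    (midpoint -42.57 mV, slope 12 mV) and tau_h is scaled by 4, matching
    heterologously over-expressed Nav1.5 recorded under near-ideal clamp.
``ito_ohara``
    Transient outward K+ current with activation gate a and a composite
    inactivation gate i made of fast and slow components mixed by a
    voltage-dependent weight A_fast(V).  The CaMK-dependent component is
    omitted (negligible at low pipette Ca2+).

Unit system: mV / ms / nA / uS throughout, so that uS x mV = nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError, InvalidStateError

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "IonConditions",
    "GateComponent",
    "GateSpec",
    "HHChannelModel",
    "MODEL_LABELS",
    "NA_PHYSIOLOGICAL",
    "K_PHYSIOLOGICAL",
    "nernst_potential",
    "eval_gate",
    "channel_current",
    "build_model",
]

FARADAY = 96485.33212  # C / mol
GAS_CONSTANT = 8.314462618  # J / (mol K)

MODEL_LABELS = ("ina_ohara", "ina_nav15_optimized", "ito_ohara")


# --------------------------------------------------------------------------
# Ionic conditions and reversal potentials
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IonConditions:
    """Extra/intracellular concentrations of a permeant ion.

    Temperature defaults to 310 K, the physiological temperature of the
    ventricular model the gate equations derive from; it is configurable.
    """

    ion: str
    out_mM: float
    in_mM: float
    valence: int = 1
    temperature_K: float = 310.0

    def __post_init__(self):
        if self.out_mM <= 0 or self.in_mM <= 0:
            raise InvalidInputError(
                f"concentrations must be positive, got out={self.out_mM} mM, in={self.in_mM} mM"
            )
        if self.valence == 0:
            raise InvalidInputError("ion valence must be nonzero")
        if self.temperature_K <= 0:
            raise InvalidInputError("temperature must be positive (K)")


NA_PHYSIOLOGICAL = IonConditions("Na", out_mM=145.0, in_mM=10.0, valence=1)
K_PHYSIOLOGICAL = IonConditions("K", out_mM=5.0, in_mM=145.0, valence=1)


def nernst_potential(cond: IonConditions) -> float:
    """Nernst reversal potential in mV: (RT/zF) ln([out]/[in]).

    The natural logarithm is used; for Na+ 145/10 mM at 310 K this gives
    about +71.4 mV, for K+ 5/145 mM about -89.9 mV.
    """
    rt_zf = GAS_CONSTANT * cond.temperature_K / (cond.valence * FARADAY)  # volts
    return 1e3 * rt_zf * math.log(cond.out_mM / cond.in_mM)


# --------------------------------------------------------------------------
# Gate rate formulas
# --------------------------------------------------------------------------
# I_Na gates (m cubed; h, j first order)

def m_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))


def m_inf_optimized(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 42.57) / 12.0))


def tau_m(v: float) -> float:
    return 1.0 / (
        6.765 * math.exp((v + 11.64) / 34.77)
        + 8.552 * math.exp(-(v + 77.42) / 5.955)
    )


def h_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v + 82.9) / 6.086))


def tau_h(v: float) -> float:
    return 1.0 / (
        1.432e-5 * math.exp(-(v + 1.196) / 6.285)
        + 6.149 * math.exp((v + 0.5096) / 20.27)
    )


def tau_h_optimized(v: float) -> float:
    # optimized Nav1.5: inactivation slowed fourfold
    return 4.0 * tau_h(v)


# j shares its steady state with h
j_inf = h_inf


def tau_j(v: float) -> float:
    return 2.038 + 1.0 / (
        0.02136 * math.exp(-(v + 100.6) / 8.281)
        + 0.3052 * math.exp((v + 0.9941) / 38.45)
    )


# I_to gates (a activation; i composite fast/slow inactivation)

def a_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))


def tau_a(v: float) -> float:
    return 1.0515 / (
        1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.41) / 29.38)))
        + 3.5 / (1.0 + math.exp((v + 100.0) / 29.38))
    )


def i_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))


def tau_i_fast(v: float) -> float:
    return 4.562 + 1.0 / (
        0.3933 * math.exp(-(v + 100.0) / 100.0)
        + 0.08004 * math.exp((v + 50.0) / 16.59)
    )


def tau_i_slow(v: float) -> float:
    return 23.62 + 1.0 / (
        0.001416 * math.exp(-(v + 96.52) / 59.05)
        + 1.78e-8 * math.exp((v + 114.1) / 8.079)
    )


def a_i_fast(v: float) -> float:
    """Voltage-dependent weight of the fast inactivation component (in [0,1])."""
    return 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))


def a_i_slow(v: float) -> float:
    return 1.0 - a_i_fast(v)


# --------------------------------------------------------------------------
# Gate and channel containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GateComponent:
    """One kinetic component of a composite gate: its time constant and the
    voltage-dependent weight of its contribution to the gate value."""

    name: str
    time_constant: Callable[[float], float]
    weight: Callable[[float], float]


@dataclass(frozen=True)
class GateSpec:
    """A single Hodgkin-Huxley gate.

    Either ``time_constant`` is set (simple gate) or ``components`` is
    non-empty (composite gate whose value is a weight-mixed sum of
    independently relaxing components, all sharing ``steady_state``).
    """

    name: str
    steady_state: Callable[[float], float]
    time_constant: Callable[[float], float] | None = None
    components: tuple[GateComponent, ...] = ()
    exponent: int = 1
    activating: bool = True

    def __post_init__(self):
        if (self.time_constant is None) == (len(self.components) == 0):
            raise ConfigurationError(
                f"gate {self.name!r}: exactly one of time_constant or components must be given"
            )

    @property
    def is_composite(self) -> bool:
        return bool(self.components)


def eval_gate(gate: GateSpec, v: float) -> tuple[float, float]:
    """Evaluate (steady_state, time_constant) of a gate at potential ``v`` (mV).

    For a composite gate the returned time constant is the weight-averaged
    effective relaxation time ``sum_i A_i(v) * tau_i(v)``; the exact two-
    exponential relaxation is what the integrator uses internally.
    """
    ss = gate.steady_state(v)
    if gate.is_composite:
        tau = sum(c.weight(v) * c.time_constant(v) for c in gate.components)
    else:
        tau = gate.time_constant(v)
    return ss, tau


@dataclass(frozen=True)
class HHChannelModel:
    """A conductance-based channel: I = g_max * (V - E_rev) * prod(gate^exponent).

    ``state_names`` lists the underlying kinetic state variables (composite
    gates contribute one state per component).
    """

    label: str
    gates: tuple[GateSpec, ...]
    g_max: float  # uS
    reversal_mV: float
    conditions: IonConditions
    state_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.g_max < 0:
            raise ConfigurationError(f"g_max must be >= 0, got {self.g_max}")

    def with_g_max(self, g_max: float) -> "HHChannelModel":
        return HHChannelModel(
            self.label, self.gates, g_max, self.reversal_mV, self.conditions,
            self.state_names,
        )

    # ---- state helpers used by the integrators ----

    def initial_state(self, v: float) -> np.ndarray:
        """Kinetic state vector at steady state for potential ``v``."""
        out = []
        for g in self.gates:
            ss = g.steady_state(v)
            if g.is_composite:
                out.extend([ss] * len(g.components))
            else:
                out.append(ss)
        return np.asarray(out, dtype=float)

    def gate_values_from_state(self, state: Sequence[float], v: float) -> np.ndarray:
        """Collapse the kinetic state vector to one value per gate (composite
        gates are weight-mixed at potential ``v``)."""
        vals, k = [], 0
        for g in self.gates:
            if g.is_composite:
                acc = 0.0
                for c in g.components:
                    acc += c.weight(v) * state[k]
                    k += 1
                vals.append(acc)
            else:
                vals.append(state[k])
                k += 1
        return np.asarray(vals, dtype=float)

    def open_fraction(self, gate_values: Sequence[float]) -> float:
        p = 1.0
        for g, y in zip(self.gates, gate_values, strict=True):
            p *= y ** g.exponent
        return p

    def current(self, v: float, gate_values: Sequence[float]) -> float:
        """Ionic current in nA (inward negative) given per-gate values."""
        return channel_current(self, gate_values, v)


def channel_current(model: HHChannelModel, gate_values: Sequence[float], v: float) -> float:
    """I = g_max * (V - E_rev) * product of gate values raised to their exponents.

    Units: uS x mV = nA.  Gate values must lie in [0, 1].
    """
    for g, y in zip(model.gates, gate_values, strict=True):
        if not (0.0 <= y <= 1.0):
            raise InvalidStateError(f"gate {g.name!r} value {y} outside [0, 1]")
    return model.g_max * (v - model.reversal_mV) * model.open_fraction(gate_values)


# --------------------------------------------------------------------------
# Model factory
# --------------------------------------------------------------------------

def build_model(
    label: str,
    g_max: float,
    conditions: IonConditions | None = None,
) -> HHChannelModel:
    """Build one of the three named channel models with maximal conductance
    ``g_max`` (uS).  ``conditions`` overrides the default physiological
    concentrations (Na 145/10 mM, K 5/145 mM, 310 K)."""
    if g_max <= 0:
        raise ConfigurationError(f"g_max must be > 0, got {g_max}")
    if label in ("ina_ohara", "ina_nav15_optimized"):
        cond = conditions or NA_PHYSIOLOGICAL
        minf = m_inf if label == "ina_ohara" else m_inf_optimized
        tauh = tau_h if label == "ina_ohara" else tau_h_optimized
        gates = (
            GateSpec("m", minf, tau_m, exponent=3, activating=True),
            GateSpec("h", h_inf, tauh, exponent=1, activating=False),
            GateSpec("j", j_inf, tau_j, exponent=1, activating=False),
        )
        return HHChannelModel(
            label, gates, g_max, nernst_potential(cond), cond,
            state_names=("m", "h", "j"),
        )
    if label == "ito_ohara":
        cond = conditions or K_PHYSIOLOGICAL
        gates = (
            GateSpec("a", a_inf, tau_a, exponent=1, activating=True),
            GateSpec(
                "i",
                i_inf,
                components=(
                    GateComponent("i_fast", tau_i_fast, a_i_fast),
                    GateComponent("i_slow", tau_i_slow, a_i_slow),
                ),
                exponent=1,
                activating=False,
            ),
        )
        return HHChannelModel(
            label, gates, g_max, nernst_potential(cond), cond,
            state_names=("a", "i_fast", "i_slow"),
        )
    raise ConfigurationError(
        f"unknown model label {label!r}; expected one of {MODEL_LABELS}"
    )
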