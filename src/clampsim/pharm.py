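"""Series-resistance distortion of pharmacological dose-response curves.

A pore blocker is modelled as pure scaling of the maximal conductance by
the Hill remaining fraction 1/(1 + (c/IC50)^nH).  Under imperfect voltage
clamp the *measured* peak current is a sub-linear function of the
theoretical one (the transfer curve), so high-amplitude control currents
make a blocker look weaker than it is: the apparent IC50 fitted from
measured currents exceeds the true IC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .analysis import peak_metrics
from .channels import IonConditions, build_model
from .errors import ExtrapolationError, FitError, InvalidInputError
from .simulate import ClampConfig, SolverSettings, integrate_step

__all__ = [
    "BlockModel",
    "TransferCurve",
    "DoseResponseFit",
    "hill_fraction",
    "hill_concentration",
    "default_concentrations",
    "transfer_curve",
    "apparent_dose_response",
]

# remaining-current fractions spanning 0.75 down to 1e-3, converted to
# concentrations through the Hill inverse to build the default dose grid
DEFAULT_FRACTIONS = (0.75, 0.5, 0.3, 0.2, 0.1, 0.05, 0.02, 0.01, 1e-3)


@dataclass(frozen=True)
class BlockModel:
    """Hill block: remaining fraction = 1 / (1 + (c/IC50)^nH)."""

    ic50_uM: float
    hill: float = 1.0

    def __post_init__(self):
        if self.ic50_uM <= 0:
            raise InvalidInputError(f"IC50 must be > 0, got {self.ic50_uM}")
        if self.hill <= 0:
            raise InvalidInputError(f"Hill coefficient must be > 0, got {self.hill}")


def hill_fraction(block: BlockModel, concentration_uM: float) -> float:
    """Remaining current fraction at a blocker concentration (c = 0 -> 1)."""
    c = np.asarray(concentration_uM, dtype=float)
    if np.any(c < 0):
        raise InvalidInputError("concentration must be >= 0")
    out = 1.0 / (1.0 + (c / block.ic50_uM) ** block.hill)
    return float(out) if np.isscalar(concentration_uM) else out


def hill_concentration(block: BlockModel, fraction: float) -> float:
    """Inverse accessor: concentration (uM) leaving ``fraction`` of the current."""
    f = np.asarray(fraction, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise InvalidInputError("requested fraction must lie strictly in (0, 1)")
    out = block.ic50_uM * ((1.0 - f) / f) ** (1.0 / block.hill)
    return float(out) if np.isscalar(fraction) else out


def default_concentrations(block: BlockModel) -> np.ndarray:
    """Dose grid hitting the standard remaining fractions 0.75 ... 1e-3."""
    return np.array([hill_concentration(block, f) for f in DEFAULT_FRACTIONS])


# --------------------------------------------------------------------------
# Theoretical-vs-measured transfer curve
# --------------------------------------------------------------------------

@dataclass
class TransferCurve:
    """Mapping from theoretical (R_S = 0) to measured peak current at a
    fixed step potential, tabulated over a G_max sweep.

    The curve passes through (0, 0), is the identity at R_S = 0, and is
    monotonic in |theoretical|.  ``measured_for`` interpolates; queries
    outside the tabulated range are refused rather than extrapolated.
    """

    step_mV: float
    rs_mohm: float
    theoretical_nA: np.ndarray
    measured_nA: np.ndarray
    g_max_uS: np.ndarray = field(default=None, repr=False)

    def measured_for(self, theoretical_nA: float) -> float:
        q = abs(theoretical_nA)
        tab = np.abs(self.theoretical_nA)
        if q > tab.max() + 1e-9:
            raise ExtrapolationError(
                f"theoretical amplitude {theoretical_nA} nA outside the tabulated "
                f"range (max {tab.max():.3f} nA); extend the G_max grid")
        sign = np.sign(self.theoretical_nA[np.argmax(tab)]) or 1.0
        m = float(np.interp(q, tab, np.abs(self.measured_nA)))
        return sign * m


def _measured_peak(label, g_max, clamp, step_mV, conditions, settings,
                   holding_mV=-100.0, duration_ms=50.0) -> float:
    model = build_model(label, g_max, conditions)
    polarity = "outward" if label.startswith("ito") else "inward"
    tr = integrate_step(model, clamp, holding_mV, step_mV, duration_ms, settings)
    return peak_metrics(tr, polarity).peak_nA


def transfer_curve(
    label: str,
    clamp: ClampConfig,
    step_mV: float = -20.0,
    gmax_grid_uS=None,
    conditions: IonConditions | None = None,
    settings: SolverSettings | None = None,
    holding_mV: float = -100.0,
    duration_ms: float = 50.0,
) -> TransferCurve:
    """Tabulate measured vs theoretical peak current over a G_max sweep.

    Theoretical values are closed-form by linearity at R_S = 0 (one unit-
    conductance run fixes the peak per uS); measured values are simulated
    at the configured R_S.  The default grid spans 0-2.5 uS, i.e. roughly
    0 to -34 nA theoretical for I_Na at -20 mV.
    """
    settings = settings or SolverSettings()
    grid = np.asarray(
        gmax_grid_uS if gmax_grid_uS is not None else np.linspace(0.05, 2.5, 26)
    )
    if np.any(grid <= 0):
        raise InvalidInputError("G_max grid must be positive")
    unit_peak = _measured_peak(label, 1.0, ClampConfig(0.0, clamp.cm_pf),
                               step_mV, conditions, settings,
                               holding_mV, duration_ms)
    theoretical = grid * unit_peak
    measured = np.array([
        _measured_peak(label, g, clamp, step_mV, conditions, settings,
                       holding_mV, duration_ms)
        for g in grid
    ])
    # anchor at the origin so small-amplitude queries interpolate cleanly
    theoretical = np.concatenate([[0.0], theoretical])
    measured = np.concatenate([[0.0], measured])
    return TransferCurve(step_mV, clamp.rs_mohm, theoretical, measured,
                         g_max_uS=np.concatenate([[0.0], grid]))


# --------------------------------------------------------------------------
# Apparent dose-response
# --------------------------------------------------------------------------

def _hill_response(c, ic50, n):
    return 1.0 / (1.0 + (np.asarray(c) / ic50) ** n)


@dataclass(frozen=True)
class DoseResponseFit:
    """Apparent Hill parameters fitted to measured (artefact-distorted)
    normalized responses."""

    apparent_ic50_uM: float
    apparent_hill: float
    true_ic50_uM: float
    shift_factor: float  # apparent / true IC50
    control_measured_nA: float
    control_theoretical_nA: float
    table: pd.DataFrame = field(repr=False, default=None)


def apparent_dose_response(
    label: str,
    clamp: ClampConfig,
    block: BlockModel,
    control_gmax_uS: float,
    step_mV: float = -20.0,
    concentrations_uM=None,
    conditions: IonConditions | None = None,
    settings: SolverSettings | None = None,
    transfer: TransferCurve | None = None,
    holding_mV: float = -100.0,
    duration_ms: float = 50.0,
) -> DoseResponseFit:
    """Build the dose-response curve an experimenter would measure.

    For each concentration the blocker scales G_max by the Hill remaining
    fraction; the measured peak at ``step_mV`` is then simulated at the
    configured R_S (or read off a precomputed :class:`TransferCurve`),
    normalized by the measured drug-free control, and the normalized
    responses are fitted with a Hill curve leaving both IC50 and the Hill
    coefficient free.
    """
    if control_gmax_uS <= 0:
        raise InvalidInputError("control G_max must be > 0")
    settings = settings or SolverSettings()
    conc = np.asarray(
        concentrations_uM if concentrations_uM is not None
        else default_concentrations(block)
    )
    fractions = hill_fraction(block, conc)

    def measured(g):
        if transfer is not None:
            return transfer.measured_for(g * transfer.theoretical_nA[-1]
                                         / transfer.g_max_uS[-1])
        return _measured_peak(label, g, clamp, step_mV, conditions, settings,
                              holding_mV, duration_ms)

    unit_peak = _measured_peak(label, 1.0, ClampConfig(0.0, clamp.cm_pf),
                               step_mV, conditions, settings,
                               holding_mV, duration_ms)
    control_theoretical = control_gmax_uS * unit_peak
    control_measured = measured(control_gmax_uS)
    if control_measured == 0:
        raise InvalidInputError("control current is zero; nothing to normalize")

    measured_peaks = np.array([measured(control_gmax_uS * f) for f in fractions])
    response = measured_peaks / control_measured

    try:
        popt, _ = curve_fit(
            _hill_response, conc, response,
            p0=(block.ic50_uM, block.hill),
            bounds=([1e-9, 0.05], [1e9, 20.0]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"apparent dose-response fit failed: {exc}") from exc

    table = pd.DataFrame({
        "concentration_uM": conc,
        "theoretical_fraction": fractions,
        "measured_peak_nA": measured_peaks,
        "measured_fraction": response,
    })
    ic50_app = float(popt[0])
    return DoseResponseFit(
        apparent_ic50_uM=ic50_app,
        apparent_hill=float(popt[1]),
        true_ic50_uM=block.ic50_uM,
        shift_factor=ic50_app / block.ic50_uM,
        control_measured_nA=float(control_measured),
        control_theoretical_nA=float(control_theoretical),
        table=table,
    )
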