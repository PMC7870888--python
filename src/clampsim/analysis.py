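"""Biophysical analysis of simulated sweeps.

Extracts peak currents and I/V curves, converts them to apparent
conductance against the *command* potential -- replicating experimenter
practice, which is exactly what produces the series-resistance artefact --
fits Boltzmann activation curves, and builds the amplitude-dependence
(guideline) curves of fitted V0.5 and slope k versus measured peak current.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .channels import HHChannelModel, IonConditions, build_model
from .errors import FitError, InvalidInputError
from .simulate import (
    ClampConfig,
    SolverSettings,
    SweepTrace,
    VoltageStepProtocol,
    integrate_step,
    run_protocol,
)

log = logging.getLogger(__name__)

__all__ = [
    "PeakMetrics",
    "IVCurve",
    "OhmicFit",
    "ActivationFit",
    "ConductanceCurve",
    "peak_metrics",
    "max_voltage_deviation",
    "build_iv",
    "conductance_curve",
    "fit_boltzmann",
    "boltzmann",
    "fit_activation",
    "conductance_fit_window",
    "activation_fit",
    "calibrate_gmax",
    "amplitude_dependence",
    "amplitude_limit",
    "bin_by_amplitude",
]


# --------------------------------------------------------------------------
# Peak extraction and I/V curves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakMetrics:
    peak_nA: float
    time_to_peak_ms: float  # NaN when the trace is identically zero


def peak_metrics(trace: SweepTrace, polarity: str = "inward",
                 onset_ms: float = 0.0) -> PeakMetrics:
    """Signed extremum of the current over the step window and its latency.

    ``polarity='inward'`` takes the minimum (Na+ currents), ``'outward'``
    the maximum (K+ currents).  Time-to-peak is measured from ``onset_ms``
    at the output sampling resolution; the t = onset sample itself is
    excluded so the latency is strictly positive.
    """
    if polarity not in ("inward", "outward"):
        raise InvalidInputError(f"polarity must be 'inward' or 'outward', got {polarity!r}")
    mask = trace.t_ms > onset_ms
    if not mask.any():
        raise InvalidInputError("empty step window")
    i = trace.i_nA[mask]
    t = trace.t_ms[mask]
    if np.all(i == 0.0):
        return PeakMetrics(0.0, float("nan"))
    idx = int(np.argmin(i)) if polarity == "inward" else int(np.argmax(i))
    return PeakMetrics(float(i[idx]), float(t[idx] - onset_ms))


def max_voltage_deviation(trace: SweepTrace, exclude_charging: bool = True) -> float:
    """Largest |Vcmd - Vm| produced by the ionic current (mV).

    At step onset the membrane charges passively toward Vcmd with time
    constant R_S * C_m, a transient every amplifier handles; the deviation
    of interest is the one the flowing current sustains afterwards
    (V_S = R_S * I).  ``exclude_charging`` therefore drops the first
    7 R_S C_m (residual < 0.1% of the step) before taking the maximum.
    """
    d = np.abs(trace.vcmd_mV - trace.vm_mV)
    if exclude_charging and trace.rs_mohm > 0:
        t_settle = 7.0 * trace.rs_mohm * trace.cm_pf * 1e-3  # MOhm*pF = us
        mask = trace.t_ms >= t_settle
        if mask.any():
            return float(np.max(d[mask]))
    return float(np.max(d))


@dataclass(frozen=True)
class OhmicFit:
    """Linear fit of the fully-activated I/V limb: I = slope * (V - reversal)."""
    slope_uS: float
    reversal_mV: float
    n_points: int


@dataclass
class IVCurve:
    """Peak current / voltage relationship over an activation protocol."""

    step_mV: np.ndarray
    peak_nA: np.ndarray
    time_to_peak_ms: np.ndarray
    polarity: str = "inward"

    def __post_init__(self):
        if len(np.unique(self.step_mV)) != len(self.step_mV):
            raise InvalidInputError("one I/V point per step potential required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step_mV": self.step_mV,
            "peak_nA": self.peak_nA,
            "time_to_peak_ms": self.time_to_peak_ms,
        })

    def ohmic_fit(self, v_min_mV: float = 0.0) -> OhmicFit | None:
        """Straight-line fit of the limb where activation is complete
        (step potentials >= ``v_min_mV``).  Slope estimates the maximal
        conductance; the voltage-axis intercept estimates the reversal."""
        mask = self.step_mV >= v_min_mV
        if mask.sum() < 2:
            log.warning("ohmic limb has fewer than 2 points (threshold %s mV); fit skipped",
                        v_min_mV)
            return None
        a, b = np.polyfit(self.step_mV[mask], self.peak_nA[mask], 1)
        return OhmicFit(float(a), float(-b / a), int(mask.sum()))


def build_iv(traces: list[SweepTrace], polarity: str = "inward") -> IVCurve:
    """Collect (step potential, peak current, time-to-peak) over a protocol."""
    if len(traces) < 2:
        raise InvalidInputError("need at least 2 sweeps to build an I/V curve")
    pts = [(tr.step_mV, peak_metrics(tr, polarity)) for tr in traces]
    pts.sort(key=lambda p: p[0])
    return IVCurve(
        step_mV=np.array([p[0] for p in pts]),
        peak_nA=np.array([p[1].peak_nA for p in pts]),
        time_to_peak_ms=np.array([p[1].time_to_peak_ms for p in pts]),
        polarity=polarity,
    )


# --------------------------------------------------------------------------
# Conductance transformation and Boltzmann fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductanceCurve:
    """Apparent conductance G = I_peak / (V_cmd - E_rev), max-normalized.

    The command potential is used deliberately: the experimenter does not
    know Vm, and dividing by (V_cmd - E_rev) is what imprints the
    series-resistance artefact onto the activation curve.
    """

    v_mV: np.ndarray
    g_uS: np.ndarray
    g_norm: np.ndarray


def conductance_curve(iv: IVCurve, reversal_mV: float) -> ConductanceCurve:
    """Convert an I/V curve to a normalized conductance-voltage curve.

    Points whose step potential coincides with the reversal potential are
    dropped (zero driving force) with a log notice.
    """
    keep = np.abs(iv.step_mV - reversal_mV) > 1e-9
    if not keep.all():
        log.info("dropping %d I/V point(s) at the reversal potential (%.3f mV)",
                 (~keep).sum(), reversal_mV)
    v = iv.step_mV[keep]
    g = iv.peak_nA[keep] / (v - reversal_mV)
    gmax = np.max(g)
    if gmax <= 0:
        raise InvalidInputError("conductance curve has no positive values")
    return ConductanceCurve(v, g, g / gmax)


def boltzmann(v, g_max, v_half, k):
    """G(V) = G_max / (1 + exp(-(V - V0.5)/k))."""
    return g_max / (1.0 + np.exp(-(np.asarray(v) - v_half) / k))


@dataclass(frozen=True)
class ActivationFit:
    """Boltzmann activation parameters fitted to apparent conductance."""

    v_half_mV: float
    k_mV: float  # slope factor, > 0
    g_max: float  # fitted normalization (≈1 for max-normalized input)
    residual_norm: float
    v_mV: np.ndarray = field(repr=False, default=None)
    g_norm: np.ndarray = field(repr=False, default=None)
    unreliable: bool = False  # k driven to its bounds

    def predicted(self) -> np.ndarray:
        return boltzmann(self.v_mV, self.g_max, self.v_half_mV, self.k_mV)


_K_BOUNDS = (0.1, 60.0)


def _initial_guess(v: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    gmax0 = float(np.max(g))
    gn = g / gmax0
    # V at half-maximum by linear interpolation on the rising phase
    above = np.nonzero(gn >= 0.5)[0]
    if len(above) and above[0] > 0:
        i1 = above[0]
        i0 = i1 - 1
        w = (0.5 - gn[i0]) / (gn[i1] - gn[i0])
        v50 = v[i0] + w * (v[i1] - v[i0])
    else:
        v50 = float(v[np.argmin(np.abs(gn - 0.5))])
    # slope from the 20-80% rise span: V(0.8) - V(0.2) = 2 ln(4) k
    try:
        v20 = float(np.interp(0.2, gn[: np.argmax(gn) + 1], v[: np.argmax(gn) + 1]))
        v80 = float(np.interp(0.8, gn[: np.argmax(gn) + 1], v[: np.argmax(gn) + 1]))
        k0 = max((v80 - v20) / (2.0 * np.log(4.0)), 0.5)
    except Exception:  # degenerate rise
        k0 = 7.0
    return gmax0, float(v50), float(k0)


def fit_boltzmann(curve: ConductanceCurve | tuple[np.ndarray, np.ndarray],
                  rng: np.random.Generator | None = None) -> ActivationFit:
    """Nonlinear least-squares Boltzmann fit of a normalized conductance curve.

    Initial guesses come from the data (half-max crossing; 20-80% rise
    span); on failure the fit is retried from 3 perturbed starting points
    before raising :class:`FitError`.  A slope factor driven to its bounds
    (0.1-30 mV) flags the result as unreliable.
    """
    if isinstance(curve, ConductanceCurve):
        v, g = curve.v_mV, curve.g_norm
    else:
        v, g = np.asarray(curve[0], float), np.asarray(curve[1], float)
    if len(v) < 4:
        raise InvalidInputError("need at least 4 points spanning the rising phase")

    gmax0, v500, k0 = _initial_guess(v, g)
    rng = rng or np.random.default_rng(0)
    starts = [(gmax0, v500, k0)]
    for _ in range(3):
        starts.append((
            gmax0 * (1 + 0.2 * rng.standard_normal()),
            v500 + 5.0 * rng.standard_normal(),
            max(k0 * (1 + 0.3 * rng.standard_normal()), 0.5),
        ))

    bounds = ([1e-6, -150.0, _K_BOUNDS[0]], [10.0, 100.0, _K_BOUNDS[1]])
    last_err = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(boltzmann, v, g, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        resid = float(np.linalg.norm(g - boltzmann(v, *popt)))
        k_fit = float(popt[2])
        v_fit = float(popt[1])
        unreliable = bool(
            k_fit <= _K_BOUNDS[0] * 1.001 or k_fit >= _K_BOUNDS[1] * 0.999
            or v_fit <= bounds[0][1] + 0.1 or v_fit >= bounds[1][1] - 0.1
        )
        if unreliable:
            log.warning("Boltzmann slope factor %.3f mV at fit bounds; flagged unreliable",
                        k_fit)
        return ActivationFit(float(popt[1]), k_fit, float(popt[0]), resid,
                             v_mV=v, g_norm=g, unreliable=unreliable)
    raise FitError(
        "Boltzmann fit failed from all starting points",
        diagnostics={"starts": starts, "error": repr(last_err)},
    )


@lru_cache(maxsize=32)
def _ideal_window_cached(label, protocol, conditions, settings) -> float:
    model = build_model(label, 1.0, conditions)
    polarity = "outward" if label.startswith("ito") else "inward"
    traces = run_protocol(model, ClampConfig(rs_mohm=0.0), protocol, settings)
    cc = conductance_curve(build_iv(traces, polarity), model.reversal_mV)
    return float(cc.v_mV[int(np.argmax(cc.g_norm))])


def conductance_fit_window(
    label: str,
    protocol: VoltageStepProtocol = VoltageStepProtocol(),
    conditions: IonConditions | None = None,
    settings: SolverSettings | None = None,
) -> float:
    """Upper voltage bound of the Boltzmann fit window for a channel model.

    The window runs up to the potential of maximal apparent conductance
    under ideal clamp (R_S = 0): activation is complete there, and beyond
    it the peak-conductance transform is no longer a pure activation
    readout -- for fast Na+ currents peak-time inactivation bends the
    curve down, and at high R_S the shrinking driving-force denominator
    blows it up near the reversal potential.  The bound is a property of
    the model and protocol (independent of G_max), so it is computed once
    from a unit-conductance run and cached.  For the transient outward K+
    current the ideal-clamp maximum sits at the top of the protocol, so
    the window spans the whole range.
    """
    return _ideal_window_cached(label, protocol, conditions,
                                settings or SolverSettings())


def fit_activation(
    iv: IVCurve,
    reversal_mV: float,
    fit_window_mV: float | None = None,
    rng: np.random.Generator | None = None,
) -> ActivationFit:
    """Conductance transform + Boltzmann fit of an I/V curve, restricted to
    step potentials <= ``fit_window_mV`` (None = full range) and re-
    normalized within the window."""
    cc = conductance_curve(iv, reversal_mV)
    v, g = cc.v_mV, cc.g_uS
    if fit_window_mV is not None:
        mask = v <= fit_window_mV + 1e-9
        v, g = v[mask], g[mask]
    if len(v) < 4:
        raise InvalidInputError("fewer than 4 conductance points in the fit window")
    return fit_boltzmann((v, g / np.max(g)), rng=rng)


def activation_fit(
    model: HHChannelModel,
    clamp: ClampConfig,
    protocol: VoltageStepProtocol = VoltageStepProtocol(),
    settings: SolverSettings | None = None,
    polarity: str | None = None,
    fit_window_mV: float | str | None = "auto",
) -> ActivationFit:
    """Protocol -> I/V -> conductance -> Boltzmann, in one call.

    ``fit_window_mV='auto'`` (default) restricts the fit to the rising
    phase of the ideal-clamp conductance curve, see
    :func:`conductance_fit_window`; pass None to fit the full range or a
    float for an explicit upper bound.
    """
    settings = settings or SolverSettings()
    polarity = polarity or ("outward" if model.label.startswith("ito") else "inward")
    if fit_window_mV == "auto":
        fit_window_mV = conductance_fit_window(
            model.label, protocol, model.conditions, settings)
    traces = run_protocol(model, clamp, protocol, settings)
    iv = build_iv(traces, polarity)
    return fit_activation(iv, model.reversal_mV, fit_window_mV)


# --------------------------------------------------------------------------
# Amplitude calibration and guideline curves
# --------------------------------------------------------------------------

def calibrate_gmax(
    label: str,
    target_peak_nA: float,
    protocol: VoltageStepProtocol = VoltageStepProtocol(),
    conditions: IonConditions | None = None,
    settings: SolverSettings | None = None,
) -> float:
    """G_max (uS) such that the maximal absolute peak current across the
    activation protocol at R_S = 0 equals ``target_peak_nA``.

    Closed-form by linearity: at R_S = 0 the trajectory is independent of
    G_max, so one unit-conductance run fixes the scale.
    """
    settings = settings or SolverSettings()
    ref = build_model(label, 1.0, conditions)
    traces = run_protocol(ref, ClampConfig(rs_mohm=0.0), protocol, settings)
    polarity = "outward" if label.startswith("ito") else "inward"
    peak_per_unit = max(abs(peak_metrics(tr, polarity).peak_nA) for tr in traces)
    if peak_per_unit == 0:
        raise InvalidInputError("protocol elicits no current at unit conductance")
    return abs(target_peak_nA) / peak_per_unit


def amplitude_dependence(
    label: str,
    rs_list_mohm,
    gmax_grid_uS,
    protocol: VoltageStepProtocol = VoltageStepProtocol(),
    reference_mV: float = -20.0,
    cm_pf: float = 20.0,
    conditions: IonConditions | None = None,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Fitted V0.5 and k versus measured peak amplitude, per R_S.

    For each (R_S, G_max) the activation protocol is simulated, the peak
    current at ``reference_mV`` recorded (the amplitude an experimenter
    would report), and a Boltzmann fitted to the apparent activation
    curve.  Failed fits are flagged (``fit_ok=False``) and left out of
    guideline queries.
    """
    settings = settings or SolverSettings()
    rs_list = list(rs_list_mohm)
    grid = list(gmax_grid_uS)
    if not rs_list or not grid:
        raise InvalidInputError("R_S and G_max grids must be non-empty")
    if reference_mV not in protocol.steps_mV:
        raise InvalidInputError(
            f"reference potential {reference_mV} mV not in the protocol steps")
    polarity = "outward" if label.startswith("ito") else "inward"
    window = conductance_fit_window(label, protocol, conditions, settings)
    rows = []
    for rs in rs_list:
        clamp = ClampConfig(rs_mohm=rs, cm_pf=cm_pf)
        for g in grid:
            model = build_model(label, g, conditions)
            traces = run_protocol(model, clamp, protocol, settings)
            ref_trace = next(tr for tr in traces if tr.step_mV == reference_mV)
            amp = peak_metrics(ref_trace, polarity).peak_nA
            row = {"rs_mohm": rs, "g_max_uS": g, "amp_nA": amp,
                   "v_half_mV": np.nan, "k_mV": np.nan, "fit_ok": False}
            try:
                iv = build_iv(traces, polarity)
                fit = fit_activation(iv, model.reversal_mV, window)
                row.update(v_half_mV=fit.v_half_mV, k_mV=fit.k_mV,
                           fit_ok=not fit.unreliable)
            except (FitError, InvalidInputError) as exc:
                log.warning("fit failed at R_S=%s MOhm, G_max=%s uS: %s", rs, g, exc)
            rows.append(row)
    return pd.DataFrame(rows)


def amplitude_limit(
    curve: pd.DataFrame,
    v_half_reference_mV: float,
    dv_max_mV: float = 10.0,
    k_min_mV: float = 5.0,
) -> float:
    """Largest measured |amplitude| on the curve for which the apparent
    activation parameters stay acceptable: |V0.5 - reference| < ``dv_max_mV``
    and k > ``k_min_mV``.  NaN when no point qualifies."""
    ok = curve[curve["fit_ok"]].copy()
    ok = ok[(np.abs(ok["v_half_mV"] - v_half_reference_mV) < dv_max_mV)
            & (ok["k_mV"] > k_min_mV)]
    if ok.empty:
        return float("nan")
    return float(np.max(np.abs(ok["amp_nA"])))


# --------------------------------------------------------------------------
# Amplitude binning (population summaries)
# --------------------------------------------------------------------------

def _summarize(group: pd.DataFrame, label: str) -> dict:
    n = len(group)
    out = {"bin": label, "n": n}
    for col, name in (("amp_nA", "amp"), ("v_half_mV", "v05"), ("k_mV", "k")):
        vals = group[col].to_numpy(float)
        out[f"{name}_mean"] = float(np.mean(vals))
        out[f"{name}_sem"] = (
            float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        )
    return out


def bin_by_amplitude(
    records: pd.DataFrame,
    scheme: str = "group",
    group_size: int = 10,
    first_below_nA: float = 1.0,
    width_nA: float = 0.5,
) -> pd.DataFrame:
    """Pool per-cell (amplitude, V0.5, k) records into amplitude bins.

    Two schemes:

    ``'group'``
        Cells sorted by |amplitude|; the first bin holds every cell below
        ``first_below_nA``, the rest are consecutive groups of
        ``group_size`` (last group smaller if needed).
    ``'width'``
        Fixed |amplitude| intervals of ``width_nA`` (0-0.5, 0.5-1.0, ...
        nA); empty intervals are omitted.

    Returns one row per bin with n, mean and s.e.m. of amplitude, V0.5 and
    k (s.e.m. is NaN for single-record bins).  Amplitudes are summarized
    as absolute values.
    """
    if len(records) == 0:
        raise InvalidInputError("no records to bin")
    df = records.copy()
    df["amp_nA"] = np.abs(df["amp_nA"].to_numpy(float))
    df = df.sort_values("amp_nA", kind="stable").reset_index(drop=True)

    rows = []
    if scheme == "group":
        first = df[df["amp_nA"] < first_below_nA]
        rest = df[df["amp_nA"] >= first_below_nA]
        if len(first):
            rows.append(_summarize(first, f"<{first_below_nA:g} nA"))
        for k in range(0, len(rest), group_size):
            chunk = rest.iloc[k: k + group_size]
            rows.append(_summarize(chunk, f"group {len(rows) + 1}"))
    elif scheme == "width":
        idx = np.floor(df["amp_nA"].to_numpy(float) / width_nA).astype(int)
        for b in np.unique(idx):
            chunk = df[idx == b]
            lo, hi = b * width_nA, (b + 1) * width_nA
            rows.append(_summarize(chunk, f"{lo:g}-{hi:g} nA"))
    else:
        raise InvalidInputError(f"unknown binning scheme {scheme!r}")
    return pd.DataFrame(rows)
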