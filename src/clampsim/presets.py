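"""Reproducible experiment presets.

Each preset is a fully deterministic figure-level workflow: it simulates,
analyzes, and writes tidy CSV tables plus a JSON manifest recording every
parameter and solver setting, so re-running a manifest reproduces the
outputs byte-identically.

Available presets:

``ina_rs_grid``
    I_Na sweep families over an R_S x amplitude-range grid, with the
    per-sweep voltage-deviation maxima.
``ina_activation``
    I_Na activation analysis at R_S = 0/2/5 MOhm, 10-nA calibration:
    traces, I/V points, Boltzmann fits and the V0.5/k shifts.
``ina_pharma``
    Theoretical-vs-measured transfer curves and apparent TTX
    dose-response distortion at two control amplitudes.
``ito_rs_grid``
    I_to activation analysis at R_S = 0/5/15 MOhm, 100-nA calibration.
``guideline_lines``
    Amplitude-dependence (V0.5, k vs measured amplitude) lines for the
    optimized Nav1.5 model at R_S = 0/2/5 MOhm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .analysis import (
    amplitude_dependence,
    build_iv,
    calibrate_gmax,
    conductance_fit_window,
    fit_activation,
    max_voltage_deviation,
    peak_metrics,
)
from .channels import build_model
from .errors import ConfigurationError
from .io import traces_to_frame, write_traces
from .pharm import BlockModel, apparent_dose_response, transfer_curve
from .simulate import ClampConfig, SolverSettings, VoltageStepProtocol, run_protocol

log = logging.getLogger(__name__)

__all__ = ["PRESETS", "run_preset"]

_FLOAT_FMT = "%.10g"
_SETTINGS = SolverSettings()


def _write(df: pd.DataFrame, outdir: Path, name: str) -> str:
    path = outdir / name
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return name


def _manifest(outdir: Path, name: str, params: dict, outputs: list[str]) -> None:
    payload = {
        "preset": name,
        "clampsim_version": __version__,
        "solver": asdict(_SETTINGS),
        "parameters": params,
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _ina_rs_grid(outdir: Path) -> dict:
    label = "ina_ohara"
    rs_list = [0.0, 2.0, 5.0]
    amplitudes = [1.0, 3.0, 10.0]  # nA peak-current ranges, R_S = 0 calibration
    protocol = VoltageStepProtocol()
    outputs = []
    rows = []
    for amp in amplitudes:
        g = calibrate_gmax(label, amp, protocol)
        for rs in rs_list:
            model = build_model(label, g)
            traces = run_protocol(model, ClampConfig(rs_mohm=rs), protocol, _SETTINGS)
            outputs.append(_write(traces_to_frame(traces), outdir,
                                  f"traces_amp{amp:g}nA_rs{rs:g}.csv"))
            for tr in traces:
                pk = peak_metrics(tr, "inward")
                rows.append({
                    "amplitude_range_nA": amp, "rs_mohm": rs,
                    "g_max_uS": g, "step_mV": tr.step_mV,
                    "peak_nA": pk.peak_nA, "time_to_peak_ms": pk.time_to_peak_ms,
                    "max_voltage_deviation_mV": max_voltage_deviation(tr),
                })
    outputs.append(_write(pd.DataFrame(rows), outdir, "summary.csv"))
    return {"params": {"model": label, "rs_mohm": rs_list,
                       "amplitude_ranges_nA": amplitudes},
            "outputs": outputs}


def _activation_preset(label: str, rs_list, amplitude_nA: float,
                       protocol: VoltageStepProtocol, outdir: Path) -> dict:
    g = calibrate_gmax(label, amplitude_nA, protocol)
    model = build_model(label, g)
    polarity = "outward" if label.startswith("ito") else "inward"
    window = conductance_fit_window(label, protocol)
    outputs, fits, iv_rows = [], [], []
    for rs in rs_list:
        traces = run_protocol(model, ClampConfig(rs_mohm=rs), protocol, _SETTINGS)
        outputs.append(_write(traces_to_frame(traces), outdir, f"traces_rs{rs:g}.csv"))
        iv = build_iv(traces, polarity)
        for v, p, ttp in zip(iv.step_mV, iv.peak_nA, iv.time_to_peak_ms):
            iv_rows.append({"rs_mohm": rs, "step_mV": v, "peak_nA": p,
                            "time_to_peak_ms": ttp})
        fit = fit_activation(iv, model.reversal_mV, window)
        fits.append({"rs_mohm": rs, "v_half_mV": fit.v_half_mV, "k_mV": fit.k_mV,
                     "g_max_fit": fit.g_max, "residual_norm": fit.residual_norm})
    fits = pd.DataFrame(fits)
    ref = fits[fits["rs_mohm"] == 0].iloc[0]
    fits["delta_v_half_mV"] = fits["v_half_mV"] - ref["v_half_mV"]
    fits["k_ratio_vs_rs0"] = ref["k_mV"] / fits["k_mV"]
    outputs.append(_write(pd.DataFrame(iv_rows), outdir, "iv_points.csv"))
    outputs.append(_write(fits, outdir, "activation_fits.csv"))
    return {"params": {"model": label, "rs_mohm": list(rs_list),
                       "amplitude_range_nA": amplitude_nA, "g_max_uS": g},
            "outputs": outputs}


def _ina_activation(outdir: Path) -> dict:
    return _activation_preset("ina_ohara", [0.0, 2.0, 5.0], 10.0,
                              VoltageStepProtocol(), outdir)


def _ito_rs_grid(outdir: Path) -> dict:
    protocol = VoltageStepProtocol(duration_ms=100.0)
    return _activation_preset("ito_ohara", [0.0, 5.0, 15.0], 100.0,
                              protocol, outdir)


def _ina_pharma(outdir: Path) -> dict:
    label = "ina_ohara"
    block = BlockModel(ic50_uM=2.3, hill=1.0)
    rs_list = [0.0, 2.0, 5.0]
    controls_uS = [2.0, 0.2]  # theoretical control peaks ~ -27 and -2.7 nA
    outputs, tc_rows, dr_rows, summary = [], [], [], []
    for rs in rs_list:
        clamp = ClampConfig(rs_mohm=rs)
        tc = transfer_curve(label, clamp)
        for th, me in zip(tc.theoretical_nA, tc.measured_nA):
            tc_rows.append({"rs_mohm": rs, "theoretical_nA": th, "measured_nA": me})
        for g in controls_uS:
            fit = apparent_dose_response(label, clamp, block, g)
            for _, row in fit.table.iterrows():
                dr_rows.append({"rs_mohm": rs, "control_g_max_uS": g, **row})
            summary.append({
                "rs_mohm": rs, "control_g_max_uS": g,
                "control_theoretical_nA": fit.control_theoretical_nA,
                "control_measured_nA": fit.control_measured_nA,
                "apparent_ic50_uM": fit.apparent_ic50_uM,
                "apparent_hill": fit.apparent_hill,
                "shift_factor": fit.shift_factor,
            })
    outputs.append(_write(pd.DataFrame(tc_rows), outdir, "transfer_curves.csv"))
    outputs.append(_write(pd.DataFrame(dr_rows), outdir, "dose_response.csv"))
    outputs.append(_write(pd.DataFrame(summary), outdir, "pharma_summary.csv"))
    return {"params": {"model": label, "rs_mohm": rs_list,
                       "ic50_uM": block.ic50_uM, "hill": block.hill,
                       "control_g_max_uS": controls_uS},
            "outputs": outputs}


def _guideline_lines(outdir: Path) -> dict:
    label = "ina_nav15_optimized"
    rs_list = [0.0, 2.0, 5.0]
    grid = list(np.geomspace(0.03, 2.0, 12))
    curve = amplitude_dependence(label, rs_list, grid)
    outputs = [_write(curve, outdir, "guideline_curve.csv")]
    return {"params": {"model": label, "rs_mohm": rs_list, "g_max_grid_uS": grid},
            "outputs": outputs}


PRESETS = {
    "ina_rs_grid": _ina_rs_grid,
    "ina_activation": _ina_activation,
    "ina_pharma": _ina_pharma,
    "ito_rs_grid": _ito_rs_grid,
    "guideline_lines": _guideline_lines,
}


def run_preset(name: str, outdir) -> Path:
    """Run a named preset, writing its CSV outputs and manifest to ``outdir``.

    Returns the output directory.  All presets are deterministic: identical
    inputs produce byte-identical files.
    """
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("running preset %s -> %s", name, outdir)
    result = PRESETS[name](outdir)
    _manifest(outdir, name, result["params"], result["outputs"])
    return outdir
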