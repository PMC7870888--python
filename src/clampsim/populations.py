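"""Synthetic heterogeneous cell populations.

Transiently transfected cells show widely scattered expression levels:
peak currents spanning roughly 0.4-18 nA in a typical 52-cell set.  The
generator emulates that spread with a log-normal G_max distribution and a
truncated-normal residual series resistance, so that the per-cell
simulate-fit-bin pipeline can be exercised end to end without any
experimental data.  It reproduces the amplitude *spread* of real cell
sets, not their biological covariances (G_max and R_S are sampled
independently; real pipettes may do worse on big cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import amplitude_dependence
from .errors import InvalidInputError
from .simulate import SolverSettings, VoltageStepProtocol

__all__ = ["SyntheticPopulation", "generate_population", "population_study"]


@dataclass(frozen=True)
class SyntheticPopulation:
    """Sampling recipe for a synthetic cell set.

    G_max ~ LogNormal(ln(median), sigma); R_S ~ Normal(mean, sd) truncated
    at ``rs_min_mohm``; C_m fixed.  The defaults target a 52-cell set with
    measured peak amplitudes spanning ~0.4-18 nA at R_S near 2 MOhm,
    i.e. G_max roughly 0.03-1.3 uS.
    """

    n_cells: int = 52
    gmax_median_uS: float = 0.2
    gmax_sigma_log: float = 0.9
    rs_mean_mohm: float = 2.3
    rs_sd_mohm: float = 0.6
    rs_min_mohm: float = 0.5
    cm_pf: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise InvalidInputError("population must have at least one cell")
        if self.gmax_median_uS <= 0 or self.gmax_sigma_log < 0:
            raise InvalidInputError("invalid G_max distribution parameters")
        if self.rs_sd_mohm < 0 or self.rs_min_mohm < 0:
            raise InvalidInputError("invalid R_S distribution parameters")
        if self.cm_pf <= 0:
            raise InvalidInputError("C_m must be > 0")


def generate_population(spec: SyntheticPopulation) -> pd.DataFrame:
    """Deterministic sample: one row per cell (g_max_uS, rs_mohm, cm_pf).

    The top-level seed is fanned out into one independent stream per cell,
    so cell k's draw is invariant to the population size.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_cells)
    rows = []
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        g = spec.gmax_median_uS * np.exp(spec.gmax_sigma_log * rng.standard_normal())
        if spec.rs_sd_mohm == 0:
            rs = max(spec.rs_mean_mohm, spec.rs_min_mohm)
        else:
            rs = spec.rs_mean_mohm + spec.rs_sd_mohm * rng.standard_normal()
            while rs < spec.rs_min_mohm:
                rs = spec.rs_mean_mohm + spec.rs_sd_mohm * rng.standard_normal()
        rows.append({"cell": k, "g_max_uS": g, "rs_mohm": rs, "cm_pf": spec.cm_pf})
    return pd.DataFrame(rows)


def population_study(
    population: pd.DataFrame,
    label: str = "ina_nav15_optimized",
    protocol: VoltageStepProtocol = VoltageStepProtocol(),
    reference_mV: float = -20.0,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Simulate + fit every cell: returns per-cell records with the measured
    peak amplitude at ``reference_mV`` and the fitted (V0.5, k), ready for
    :func:`clampsim.analysis.bin_by_amplitude`."""
    frames = []
    for _, cell in population.iterrows():
        rec = amplitude_dependence(
            label, [cell["rs_mohm"]], [cell["g_max_uS"]],
            protocol=protocol, reference_mV=reference_mV,
            cm_pf=cell["cm_pf"], settings=settings,
        )
        rec.insert(0, "cell", int(cell["cell"]))
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)
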