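"""A synthetic transfected-cell population through the full pipeline.

Samples a small heterogeneous cell set (log-normal expression, truncated-
normal residual Rs around 2.3 MOhm), simulates and fits every cell, and
pools the results into amplitude bins -- the workflow used to compare a
real cell set against the deterministic model lines.
"""

import numpy as np

import clampsim as cs

spec = cs.SyntheticPopulation(n_cells=12, gmax_median_uS=0.2,
                              gmax_sigma_log=0.8, rs_mean_mohm=2.3,
                              rs_sd_mohm=0.3, seed=7)
pop = cs.generate_population(spec)
print(f"{len(pop)} synthetic cells; G_max {pop['g_max_uS'].min():.3f}-"
      f"{pop['g_max_uS'].max():.3f} uS, Rs {pop['rs_mohm'].min():.2f}-"
      f"{pop['rs_mohm'].max():.2f} MOhm\n")

protocol = cs.VoltageStepProtocol(
    steps_mV=tuple(np.arange(-80.0, 40.0 + 1e-9, 10.0)))
records = cs.population_study(pop, "ina_nav15_optimized", protocol)

binned = cs.bin_by_amplitude(records[records["fit_ok"]], scheme="width",
                             width_nA=3.0)
print("Amplitude bins (|peak @ -20 mV|):")
print("  bin          n   amp (nA)      V0.5 (mV)        k (mV)")
for _, row in binned.iterrows():
    sem = "" if np.isnan(row["v05_sem"]) else f" +- {row['v05_sem']:.2f}"
    ksem = "" if np.isnan(row["k_sem"]) else f" +- {row['k_sem']:.2f}"
    print(f"  {row['bin']:10s} {row['n']:3d}   {row['amp_mean']:7.2f}   "
          f"{row['v05_mean']:9.2f}{sem:10s} {row['k_mean']:6.2f}{ksem}")

print("\nLow-amplitude bins report the true activation parameters; the")
print("high-amplitude bins drift hyperpolarized with shrinking slope --")
print("pooling them uncritically would bias the population estimate.")
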