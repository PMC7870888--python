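"""Amplitude-cutoff guideline curves for over-expressed Nav1.5.

Sweeps G_max for the optimized Nav1.5 model at residual Rs = 2 MOhm
(C_m = 20 pF), recording for each expression level the measured peak at
-20 mV and the fitted activation parameters, then reports the largest
amplitude at which the apparent V0.5 error stays below 10 mV and the
slope factor above 5 mV -- the quantity on which practical recording
cutoffs are based.
"""

import numpy as np

import clampsim as cs

label = "ina_nav15_optimized"
grid = np.geomspace(0.05, 1.2, 8)

curve = cs.amplitude_dependence(label, [0.0, 2.0], grid)
ref = curve[curve["rs_mohm"] == 0.0]
line = curve[curve["rs_mohm"] == 2.0]
v_ref = float(ref["v_half_mV"].iloc[0])  # flat across the grid at Rs = 0

print("Optimized Nav1.5, Rs = 2 MOhm, C_m = 20 pF\n")
print("  |peak @ -20 mV| (nA)   V0.5 (mV)   dV0.5 (mV)   k (mV)")
for _, row in line.iterrows():
    print(f"  {abs(row['amp_nA']):18.2f}   {row['v_half_mV']:9.2f}   "
          f"{row['v_half_mV'] - v_ref:10.2f}   {row['k_mV']:6.2f}")

limit = cs.amplitude_limit(line, v_ref, dv_max_mV=10.0, k_min_mV=5.0)
print(f"\nLargest amplitude with |dV0.5| < 10 mV and k > 5 mV: {limit:.1f} nA")
print("Recordings beyond this cutoff misreport the activation gate; they")
print("should be prevented (lower expression, partial block) or discarded.")
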