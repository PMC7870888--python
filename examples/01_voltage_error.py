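"""How series resistance corrupts a single voltage step.

Simulates one depolarizing step (-100 -> -40 mV) of a cardiac Na+ current
calibrated to a 10-nA peak range, under ideal clamp and with a 5-MOhm
residual series resistance, and prints what the electrode drop does to the
membrane potential and the current peak.
"""

import numpy as np

import clampsim as cs

protocol = cs.VoltageStepProtocol()
g10 = cs.calibrate_gmax("ina_ohara", 10.0, protocol)
model = cs.build_model("ina_ohara", g10)
print(f"G_max calibrated to a 10-nA range at Rs = 0: {g10:.3f} uS\n")

for rs in (0.0, 5.0):
    tr = cs.integrate_step(model, cs.ClampConfig(rs_mohm=rs), -100.0, -40.0, 50.0)
    pk = cs.peak_metrics(tr)
    dev = cs.max_voltage_deviation(tr)
    print(f"Rs = {rs:g} MOhm:")
    print(f"  peak current        {pk.peak_nA:8.2f} nA at {pk.time_to_peak_ms:.2f} ms")
    if rs:
        # Vm at the peak of the current-driven deviation (charging excluded)
        settled = tr.t_ms >= 7 * rs * 20.0 * 1e-3
        vm_peak = tr.vm_mV[settled][np.argmax(np.abs(tr.voltage_error_mV[settled]))]
        print(f"  max |Vcmd - Vm|     {dev:8.2f} mV (Vm reaches {vm_peak:.1f} mV "
              "while commanding -40 mV)")
    else:
        print(f"  max |Vcmd - Vm|     {dev:8.2f} mV (ideal clamp)")
    print()

print("With Rs = 5 MOhm the inward current drops tens of mV across the")
print("electrode, so the membrane sits far positive of the command: near")
print("threshold this regeneratively inflates and delays the local peak,")
print("while the largest currents of the family are attenuated.")
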