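# clampsim

Whole-cell voltage-clamp simulation of series-resistance artefacts in
voltage-gated ion-channel recordings.

## The problem

In whole-cell patch clamp (manual or automated planar-chip), the pipette
tip adds a series resistance R<sub>S</sub> of a few MΩ between amplifier
and cell. A current *I* in the nA range then drops
V<sub>S</sub> = R<sub>S</sub>·I across the electrode, so the membrane sees

```
Vm = Vcmd − Rs·I
```

rather than the command potential. For fast, large currents this
undetected error systematically distorts the quantities electrophysiologists
report: activation curves shift hyperpolarized and steepen, current peaks
slow down, and blocker dose–response curves shift toward higher
concentrations. `clampsim` reproduces all of these artefacts
quantitatively from Hodgkin–Huxley kinetic models, so that recording
limits ("never accept inward currents above X nA at Y MΩ residual
R<sub>S</sub>") can be derived rather than guessed.

## What it computes

* **Channel models** — cardiac fast Na⁺ current (gates m³·h·j), an
  over-expressed Nav1.5 variant (shifted/shallower m<sub>∞</sub>, 4×
  slower τ<sub>h</sub>), and the transient outward K⁺ current I<sub>to</sub>
  (gates a·i with voltage-weighted fast/slow inactivation). Reversal
  potentials from the Nernst relation (Na⁺ 145/10 mM → +71.4 mV, K⁺
  5/145 mM → −90.0 mV at 310 K).
* **Clamp dynamics** — the coupled system of exact exponential
  (Rush–Larsen) gate updates and the membrane ODE
  `dVm/dt = (Vcmd − Vm)/(Rs·Cm) − i/Cm`, integrated with an adaptive
  time step controlled by the relative gate variations (doubling below
  0.5×10⁻⁵, halving with rollback above 10⁻⁵, initial step 0.1 µs).
  An independent stiff-solver oracle (LSODA at rtol 10⁻⁸) validates the
  integrator; at the harshest setting (G<sub>max</sub> = 6 µS,
  R<sub>S</sub> = 5 MΩ) the two agree to ~10⁻⁵ of the peak current.
* **Analysis** — peak I/V curves, apparent conductance
  G = I<sub>peak</sub>/(V<sub>cmd</sub> − E<sub>rev</sub>), Boltzmann fits
  `G = Gmax / (1 + exp(−(V − V0.5)/k))`, time-to-peak, amplitude-dependence
  (guideline) curves of V0.5 and k versus measured peak current, and
  amplitude binning for cell populations.
* **Pharmacology** — Hill block `f = 1/(1 + (c/IC50)^nH)` applied as
  G<sub>max</sub> scaling; theoretical-vs-measured peak transfer curves;
  the apparent IC50 an experimenter would fit from distorted currents.
* **Workbench** — deterministic experiment presets, synthetic
  heterogeneous cell populations, tidy-CSV and Axon-Text-File trace I/O,
  and a thin `clampsim` command-line wrapper.

## Worked example

```bash
python examples/02_activation_distortion.py
```

```
Na+ model, G_max = 0.712 uS (10-nA range), C_m = 20 pF

  Rs (MOhm)   V0.5 (mV)   k (mV)
         0      -32.36     5.68
         2      -40.11     3.32
         5      -43.87     3.14

Rs = 2 MOhm: V0.5 shifted -7.8 mV, slope factor reduced 1.71-fold vs ideal clamp
Rs = 5 MOhm: V0.5 shifted -11.5 mV, slope factor reduced 1.81-fold vs ideal clamp
```

The same channel, measured through 2 or 5 MΩ of uncompensated series
resistance with a 10-nA current range, appears to activate 8–12 mV more
negative and ~1.7–1.8× more steeply than it really does. The other
examples cover the single-sweep voltage error (`01`), dose–response
distortion (`03`), amplitude-cutoff guideline curves (`04`), and the
synthetic-population pipeline (`05`). From the shell:

```bash
clampsim simulate --model ina_ohara --amplitude-na 10 --rs-mohm 5 --out traces.csv
clampsim analyze traces.csv --reversal-mv 71.4 --out fit.json
clampsim doseresponse --model ina_ohara --rs-mohm 5 --control-gmax-us 2 --out dr.csv
```

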