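# Methods

## Model

A voltage-clamped cell is reduced to one compartment of capacitance
C_m behind an access (series) resistance R_S. The amplifier clamps the
command potential V_cmd; the membrane potential obeys

    dVm/dt = (Vcmd − Vm) / (R_S · C_m) − i / C_m

with the ionic current i(Vm, gates) closing a feedback loop: for an
inward Na⁺ current, depolarization beyond the command begets more
current, which is what makes large Na⁺ currents so much more sensitive
to R_S than outward K⁺ currents (whose voltage error is
self-limiting). R_S = 0 is handled as the exact algebraic constraint
Vm ≡ Vcmd — the ODE is singular there and the ideal clamp is the
reference condition for every artefact quantity. Pipette capacitance,
seal leak, amplifier response time and space-clamp effects are outside
the model's scope; C_m is taken as electronically compensated, so the
reported signal is the ionic current (the pipette-current view
(Vcmd − Vm)/R_S is available as a derived trace).

Channels follow Hodgkin–Huxley kinetics: each gate relaxes as
dy/dt = (y_inf(V) − y)/τ_y(V). Three models are built in:

* `ina_ohara` — fast cardiac Na⁺ current, I = G·(V − E_Na)·m³·h·j.
  The slow inactivation component (~1% of h) is omitted.
* `ina_nav15_optimized` — the same current retuned to over-expressed
  Nav1.5: m_inf midpoint −42.57 mV and slope 12 mV, τ_h scaled ×4.
  All other rates identical (asserted by test).
* `ito_ohara` — transient outward K⁺ current, I = G·(V − E_K)·a·i,
  where i mixes independently relaxing fast and slow components with a
  voltage-dependent weight A_fast(V) (A_slow = 1 − A_fast). The
  CaMK-dependent component (negligible at low pipette Ca²⁺) is omitted.

Reversal potentials use the Nernst relation with the natural logarithm
(E = (RT/zF)·ln([out]/[in])); with Na⁺ 145/10 mM and K⁺ 5/145 mM at the
default 310 K this gives +71.4 and −90.0 mV. 310 K is the source
kinetic model's physiological temperature and reproduces the nA-scale
driving forces the artefact analysis relies on; temperature and
concentrations are configurable (`IonConditions`). No Q10 rescaling of
rate constants is attempted.

## Units

mV / ms / nA / µS / MΩ / pF throughout. The system is closed:
µS·mV = nA, MΩ·nA = mV, MΩ·pF = µs (converted to ms internally).

## Integration

Gates advance by the exact exponential (Rush–Larsen) update
y ← y_inf − (y_inf − y)·exp(−Δt/τ_y) with rates frozen at the
step-start Vm; Vm advances by an explicit Euler update of the membrane
ODE over the same step. The time step adapts on the relative gate
variations |Δy|/y: it starts at 0.1 µs, doubles (ceiling 10 µs) when
all variations fall below 0.5×10⁻⁵, and is halved — with the trial
step rolled back and recomputed — when any exceeds 10⁻⁵.

Two numerical choices deserve note:

* The relative-variation criterion is extremely demanding when a gate
  starts near zero: stepping from −100 mV to +50 mV, the activation
  gate must creep from ~0.002 upward in relative increments of 10⁻⁵,
  which requires sub-nanosecond steps at onset and ~10⁶–10⁷ accepted
  steps per sweep. This is inherent to the criterion, not a defect; the
  underflow guard (default 10⁻⁹ µs, configurable) therefore sits well
  below that legitimate demand and only trips on runaway halving. The
  inner loop is numba-compiled, making a 27-sweep protocol a matter of
  ~10 s on one CPU.
* Because the default criterion watches only the gates, the Vm update
  is unguarded while the gates are quiescent (e.g. during the initial
  RC charging). With the default 0.1-µs initial step this is harmless —
  the production integrator agrees with the stiff reference solver to
  ~10⁻⁵ of peak current even at G_max = 6 µS, R_S = 5 MΩ — but a
  deliberately coarse initial step can distort the charging phase. The
  optional `include_vm` setting adds the Vm variation (scaled by
  100 mV) to the step control; correctness of the default path is
  guaranteed by the mandatory oracle-equivalence test rather than by
  the controller.

The reference oracle (`reference_integrate`) solves the full coupled
system with scipy's LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰ and accepts any
`HHChannelModel`, including custom ones the compiled path does not know.

Every sweep starts from gate steady state at the holding potential with
Vm equal to it: the seconds-long inter-sweep intervals at −100 mV
exceed the gate time constants (the slow I_to inactivation component,
τ ≈ 0.7 s at −100 mV, recovers to ~94% in 2 s; the residual is ignored
— a known simplification). Output traces are resampled to 0.02 ms
(50 kHz-equivalent); the acquisition rate of the computed traces is a
package choice, not a published one.

## Analysis conventions

**Amplitude calibration.** "An X-nA current range" means G_max chosen
so the maximal absolute peak over the activation protocol at R_S = 0
equals X; by linearity at R_S = 0 this is closed-form from one
unit-conductance run. The measured amplitude of a cell is its peak
current at the −20 mV step at its actual R_S.

**Voltage deviation.** `max_voltage_deviation` reports the largest
|Vcmd − Vm| after the passive RC charging (first 7·R_S·C_m) — the
deviation the flowing current sustains, which is the artefact of
interest; the onset transient is an amplifier-handled inevitability.

**Conductance transform and Boltzmann fit window.** Apparent
conductance is G = I_peak/(V_cmd − E_rev) — command potential, not Vm,
because that is what the experimenter can use and what imprints the
artefact. For the Na⁺ models this transform is only a clean activation
readout up to the potential of maximal ideal-clamp conductance (about
−15 mV for `ina_ohara`): beyond it, fast inactivation outpaces
activation and bends the curve down, and at high R_S the shrinking
driving-force denominator inflates it near the reversal potential.
The Boltzmann fit window therefore runs up to that ideal-clamp maximum,
computed once per model/protocol (`conductance_fit_window`) and applied
identically at every R_S; conductances are re-normalized within the
window and the fit leaves amplitude, V0.5 and k free (k bounded to
0.1–60 mV; parameters at bounds flag the fit unreliable). For I_to the
ideal-clamp maximum sits at the top of the protocol, so the window is
the full range. Initial guesses come from the half-max crossing and the
20–80% rise span, with three perturbed restarts before failure.

**Dose–response.** Block is pure G_max scaling by the Hill remaining
fraction — no state dependence, matching how such distortion is
analyzed. The default concentration grid hits remaining fractions
0.75…10⁻³ through the Hill inverse; the reference Hill coefficient
defaults to 1 (the experimental value behind the TTX IC50 of 2.3 µM is
not published alongside it) and the apparent fit leaves both IC50 and
n_H free, so the sensitivity of the shift factor to n_H is itself an
output rather than an assumption.

**Binning.** Two population schemes: threshold-defined first group plus
fixed-size groups (the transfected-cell convention: 7 cells below 1 nA,
then groups of 10), and fixed-width amplitude intervals (the
automated-patch convention, 500 pA). s.e.m. is undefined (NaN) for
single-cell bins.

## Synthetic populations

`SyntheticPopulation` emulates the amplitude spread of transient
transfection: log-normal G_max (default median 0.2 µS, σ_log 0.9,
spanning roughly 0.03–1.3 µS, i.e. sub-nA to ~18 nA measured peaks
around R_S ≈ 2 MΩ) and truncated-normal residual R_S (default
2.3 ± 0.6 MΩ, floor 0.5 MΩ), C_m fixed at 20 pF. The top-level seed is
fanned into one independent stream per cell, so populations are
reproducible and cell k's draw is invariant to population size. The
generator reproduces amplitude heterogeneity only: G_max and R_S are
sampled independently, there is no cell-to-cell kinetic variability, no
leak, and no measurement noise — so passing population tests show the
pipeline's statistical machinery is correct, not that real data will be
as clean.

## Problem sizes

The test suite and acceptance script run everything at published scale:
full 27-sweep activation protocols, three R_S levels per family, and a
12→36-cell synthetic population on a 13-step protocol for the
convergence check. The one deliberate reduction is the population size
(tens of cells rather than hundreds), chosen because bin-mean
convergence is already unambiguous there.

## Known limitations

* The Na⁺ kinetic formulation inactivates faster than it activates at
  strongly depolarized potentials, so its peak-conductance curve is not
  sigmoid over a full activation protocol and its I/V has no true ohmic
  limb; the fit-window convention above is how the package keeps
  Boltzmann parameters meaningful (the `ohmic_fit` helper remains for
  linear-limb analysis of data that has one).
* Explicit Euler on Vm ties accuracy to the gate-driven step size; with
  pathological settings (coarse initial step, gates quiescent) use
  `include_vm` or the reference integrator.
* No leak current, P/n subtraction, space clamp, R_S-compensation
  circuitry dynamics, or state-dependent block.
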