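# Methods

## Scope and model

`memneuro` simulates the two simplest electrical models of the neuron cell
membrane and compares their behavior: the RC circuit (capacitor C for the
phospholipid bilayer in parallel/series with a fixed leak resistor R for the
ion channels) and the MC circuit, in which the leak is a flux-controlled
memristor whose resistance M depends on the history of the applied voltage
through the flux state φ = ∫v dt. The package covers four layers:

1. the memristor element itself (memristance law, flux dynamics, pinched
   hysteresis loop under sinusoidal drive);
2. first-order series transients — charging V_C = E(1−e^{−t/τ}) and
   discharging V_C = V_C0·e^{−t/τ} with τ = RC (or MC), closed form and
   forward-Euler finite difference, with charge and power bookkeeping;
3. the parallel membrane equation dV/dt = I_ext/C − V/(RC) (or V/(M(φ)C))
   under step, single-pulse, pulse-train, and Gaussian random drive, with
   branch-current decomposition and a morphological response classifier;
4. a 2×10³-neuron excitatory/inhibitory spiking network in the classic
   Izhikevich parameterization, run in asynchronous and synchronous regimes
   with either the faithful reference membrane or a memristive-leak variant.

## Units

mV, ms, μA, Ω, F throughout; charge in coulomb, power in watt. These are
mutually consistent: τ[ms] = R[Ω]·C[F]·10³, I[μA] = V[mV]·10³/R[Ω], and the
drive term I[μA]·10⁻⁶/C[F] is numerically mV/ms. The internal flux unit is
mV·s: `flux_scale` (default 10³ per V·s) converts physical volt·seconds into
flux-units. This choice makes the memristance thresholds (−0.75, 0.25
flux-units) reachable on the millisecond time base of the membrane
experiments — at 100 mV the upper threshold is crossed after 2.5 ms — which
is the only reading under which the piecewise law is operative in the
millisecond transients it is used to explain. The scale is configurable.

## The two memristance laws

The three-branch piecewise law (20000 Ω below φ = −0.75, −3.98×10⁸·φ + 10⁸ Ω
in between, 100 Ω at and above φ = 0.25) is internally inconsistent with the
operating range used in the membrane experiments, which has M varying between
20000 and 100 Ω with M(0) = 10⁴ Ω: the middle branch alone spans ~10⁸ Ω.
Both readings are kept testable:

- `verbatim` reproduces the piecewise law exactly, branch boundaries with
  the printed inequality directions (φ < −0.75 strict, φ ≥ 0.25 inclusive);
- `reconciled` is the linearization M(φ) = clamp(10⁴ − 39600·φ, 100, 20000),
  nonincreasing in φ, with the slope fixed by M(0.25) = 100 Ω.

The reconciled law is the default wherever a memristive membrane is actually
integrated; the verbatim law is used when quoting the endpoint resistances
and for frozen-state time constants (its low-resistance branch value, 100 Ω,
gives the τ = M·C = 0.1 ms MC time constant).

## Transients and the finite-difference scheme

Closed forms are evaluated exactly on the requested grid. The explicit
(forward-Euler) recurrence is V(t+Δt) = V(t) + (Δt/τ)(E − V(t)); the
sign-flipped variant of this recurrence, which runs away from the supply
instead of converging to it, is kept behind `verbatim_sign=True` for
documentation and is exercised by one test demonstrating the divergence.
Default step Δt = τ/1000; a warning is raised above τ/10 and a hard error at
Δt ≥ 2τ (the explicit-Euler stability bound). "Fully charged/discharged" is
operationalized as the 5τ criterion, threshold 1 − e⁻⁵ ≈ 99.33%.

MC transients run in two submodes. `frozen` holds M at its current state and
applies the RC closed forms with R → M — this is what the published
exponential formulas describe. `coupled` advances φ each step from the
voltage across the memristor (E − V_C charging, −V_C discharging) and is
integrated numerically; with the reconciled law and M(0) = 10⁴ Ω the coupled
charge reaches 63.2% of E no later than the fixed-R = 10⁴ Ω circuit, since
charging drives φ up and M monotonically down.

## Stimuli and the response classifier

The pulse protocols specify only a pulse count and a total action time; the
on/off split is the `duty` parameter, default 0.5 (period = duration/count,
width = duty·period), matching the regular alternation of the plotted
waveforms. Samples are left-continuous: the value at a grid point holds over
[t, t+Δt).

The driven oscillations are labeled morphologically — there is no
threshold-and-reset mechanism in the membrane circuit, so "action potential"
here means a full charge/discharge excursion, not a Hodgkin–Huxley spike:

- `quiescent`: max|V| < 1% of the I·R drive scale;
- `oscillatory_potentials`: ≥ 2 prominent local maxima and *every* maximum
  preceded by a trough below 50% of that peak;
- `subthreshold_superposition`: everything else.

Requiring every peak to rise from a deep trough is what separates temporal
summation (a 4-pulse/20 ms staircase, whose later troughs stay above
half-peak because the membrane never discharges) from sustained full-depth
cycling (16 or 38 pulses over 1000 ms, troughs near baseline). Both
thresholds are configurable; peak detection uses a prominence floor of 1% of
the drive scale so the labels are invariant under Δt refinement.

## Network

The network follows the published 1000-neuron recipe scaled to
N = 1600 excitatory + 400 inhibitory cells: v' = 0.04v² + 5v + 140 − u + I,
u' = a(bv − u), spike at 30 mV with reset (c, u+d), heterogeneous
(a, b, c, d) spanning the regular-spiking→chattering (excitatory) and
fast-spiking (inhibitory) continua, per-millisecond Gaussian thalamic drive
(σ = 5 exc / 2 inh), all-to-all uniform random weights, voltage advanced in
two 0.5 ms half-steps per 1 ms step. Weight magnitudes (0.5 exc, 1.0 inh)
are calibrated in the recipe for 1000 cells; they are multiplied by 1000/N
(configurable via `synaptic_scale`) so that the summed synaptic input per
cell is independent of population size. Without this scaling the 2000-cell
network saturates near 80 Hz per neuron and the two collective regimes are
indistinguishable; with it the full-inhibition run shows cortical-like
irregular firing (~7 Hz per neuron) and scaling the inhibitory *weights* by
0.01 ("two orders of magnitude") produces the synchronous vertical-stripe
regime. The scaling is applied to weights, not to the inhibitory thalamic
drive.

Membrane potentials are recorded clipped at the 30 mV spike cut, so the
maximum recorded potential of any run containing a spike is exactly 30 mV.
Synchrony is quantified by a variance-of-population-rate index: spike counts
per neuron in 10 ms bins, χ² = Var(population mean rate) / mean(per-neuron
rate variance) — ≈ 1/N for independent firing, O(1) when the population
spikes in coincident bins; invariant to neuron relabeling; defined as 0 for
an empty raster.

The memristive-leak variant adds, after each 1 ms step, an exact exponential
leak sub-step v ← v·e^{−Δt/(M(φ)·C_m)} (C_m = 10⁻⁶ F) with per-neuron φ
integrated from the clipped (≤ 30 mV) voltage. The explicit form
−v·Δt/(M·C_m) is unstable at Δt = 1 ms whenever M reaches its 100 Ω state
(τ = 0.1 ms), and the quadratic model's pre-reset overshoot (hundreds of mV)
would otherwise pour unphysical flux into φ; operator splitting with the
exact sub-step agrees with the explicit form to O(Δt²) when Δt ≪ τ and is
unconditionally stable. With `flux_scale = 0` and M(0) = R the variant
reproduces the reference scheme with a fixed-R leak bit-exactly. Because the
leak relaxes v toward 0 mV (the extracellular reference), it is mildly
depolarizing relative to the −65 mV rest and raises firing rates; the
regime-switch property is asserted for the reference variant.

## Determinism

Every stochastic component takes an explicit seed. The network splits its
seed into independent streams for construction (weights, cell parameters)
and for the run (thalamic drive), so rasters are bit-reproducible for a
fixed (params, seed). Non-random stimuli are idempotent; fixture generation
is byte-stable under a fixed seed.

## What the simulations do and do not show

All inputs are synthetic by construction — the study object is the circuit
model itself, so there is no external data and no generator/analysis split.
Passing tests show that the implemented equations reproduce the printed
transient benchmarks and the qualitative firing/synchrony regimes at the
printed parameter values; they say nothing about physical memristor devices
(no device fitting, temperature, or stochastic switching), about
conductance-based or spatially extended neurons, or about regimes outside
the simulated parameter ranges. The half-current crossing times printed for
the step-response experiment (8.392/8.286 ms) are not reproducible from the
stated parameters (τ·ln 2 ≈ 6.93 ms after a 3 ms onset for τ = 10 ms) and
are not asserted; the branch-current crossing is tested against the closed
form instead.

## Problem sizes

Default runs used by the tests and the acceptance script: transient grids of
10⁴–10⁵ points (Δt = τ/1000), membrane runs of 2×10³–10⁵ steps
(Δt = 0.01 ms), and full 2000 ms, 2000-neuron network runs (1 ms steps;
a few seconds each on one CPU). The synchrony-ordering check uses 5 seeds
per inhibition level at the full protocol length.
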