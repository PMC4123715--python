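# Methods

## Gating model

The core model is a four-state allosteric scheme for a channel with one
effective voltage sensor and one pore gate. States C, C′, O, O′ carry
statistical weights 1, J, L, J·L·D; the open probability is
Po = (L + J·L·D) / (1 + J + L + J·L·D). Each transition is a
`ThermoTransition` with molar enthalpy ΔH (J/mol), entropy ΔS (J/(mol·K))
and gating charge z (e0, multiplied by Faraday's constant per mole):

    K(V, T) = exp(−(ΔH − T·ΔS − z·F·V) / (R·T)),  R = 8.314, F = 96485.

Assumptions and deliberate simplifications:

- **Equilibrium only.** Temperature ramps are slow enough (0.3 °C/s) that
  gating equilibrates at every sample; no rate constants or relaxation
  kinetics are modelled anywhere.
- **One effective sensor.** The four sensors of a real tetramer are lumped
  into a single transition with an effective apparent charge; the measured
  quantities of interest (Boltzmann fits, Q10 bounds, availability curves)
  are all effective-parameter descriptions, so a per-subunit expansion
  would add states without adding testable structure.
- **CSI as multiplicative steady-state availability.** Closed-state
  inactivation is represented by a decreasing Boltzmann availability
  a(V) = 1/(1 + e^(q·F·(V−V1/2)/RT)) multiplying the open probability,
  not by extra Markov states: all CSI observables handled here are
  steady-state curves. The combined curve of availability × activation can
  alternatively be formed with 1 − a (probability of being inactivated)
  behind a flag; the default multiplies availability as plotted in
  standard CSI analyses.
- **Two-state limit.** A bare `ThermoTransition` is accepted wherever a
  model is expected, giving Po = K/(1+K); this is the TRP-like channel.

Numerics: all four weights are accumulated in log space and normalized
with log-sum-exp, so exponents up to |x| ≈ 500 (|ΔH| up to several hundred
kJ/mol at ±200 mV, temperatures down to 0 °C) never overflow. D = 0 is
allowed (log-weight −∞). Q10 profiles report NaN (undefined) wherever
Po(T₁) < 1e−12 instead of returning spurious infinities.

## Reference parameterizations

The six shipped presets are calibrated to the measured effective
parameters of the corresponding channel classes; no recording-level data
exist to fit, so they are fixture definitions, not estimates:

| preset | J (ΔH, ΔS, z) | L (ΔH, ΔS, z) | D | CSI (V1/2, q) |
|---|---|---|---|---|
| trpv1_like | — | 510 kJ/mol, 1.58 kJ/(mol·K), 0.76 | — | — |
| shaker_like | 88 kJ/mol, 373.80 J/(mol·K), 5.1 | 418 kJ/mol, 1.34 kJ/(mol·K), 0 | 1e4 | — |
| ilt_like | 88 kJ/mol, 328.16 J/(mol·K), 5.1 | as shaker | 5 | — |
| v2_like | as ilt | −418 kJ/mol, −1.34 kJ/(mol·K), 0 | 5 | — |
| kv21_like | as shaker | as shaker | 20 | −60 mV, 3.2 e0 |
| kv43_like | as shaker | as shaker | 20 | −65 mV, 4.0 e0 |

Calibration choices, made once:

- `shaker_like` J.ΔS is solved numerically so the fitted G-V midpoint at
  24 °C is −54.2 mV (the measured Kv value); the fitted apparent charge
  then comes out at 5.09–5.11 e0 against the measured 5.1 ± 1.3. J.ΔH is
  set to 88 kJ/mol — sensor movement is mildly endothermic but far less so
  than pore opening; the Q10 bounds are insensitive to this choice (scans
  of 40–250 kJ/mol move none of them across a threshold).
- `ilt_like` shifts the sensor midpoint depolarized (J = 1 at −20 mV,
  25 °C) and weakens coupling to D = 5, reproducing the separation of Q-V
  and G-V curves that unmasks heat-activated opening.
- `v2_like` flips the sign of the pore ΔH and ΔS. One consequence is a
  model artifact worth naming: because L alone then holds the pore open
  (L ≈ 1700 at 25 °C), the channel is substantially open at *every*
  voltage, there is no voltage with Po ≈ 60%, and a −100 mV "closed
  channel" leak reference actually measures channel current. The
  heat-deactivation Q10 is therefore evaluated at the voltage whose 25 °C
  open probability is closest to 60%, and V2-like heating simulations are
  generated leak-free.
- CSI availability parameters place inactivation through the activation
  range with steepness at least comparable to the activation fit — the
  regime in which the product of the two normalized curves peaks between
  the two midpoints.
- TRP-like parameters give ΔG = 0 at 49.6 °C and 0 mV: the channel is
  heat-gated at physiological-to-noxious temperatures and only weakly
  voltage-sensitive (z = 0.76 e0), with a G-V midpoint far depolarized at
  room temperature.

## Synthetic recordings

`synthesize_sweep` emulates an inside-out macropatch at equilibrium:

    I(t) = n·Po(V(t), T(t))·γ(T)·(V − V_rev) + g_leak·V + ε,
    γ(T) = γ_ref·1.5^((T−22)/10),   ε ~ N(0, σ²).

Defaults: n = 1000 channels, γ_ref = 10 pS (10 nS maximal conductance — a
healthy macropatch), σ = 0.5 pA, g_leak = 0.05 nS, 130 mM symmetric
monovalent solutions (V_rev = 0 via Nernst), 10 kHz sampling for step
protocols and coarser sampling for slow heating sweeps (gating is at
equilibrium, so no information is lost). The leak is ohmic and reverses at
0 mV; driving force is ohmic (no open-channel rectification). Channel-count
binomial noise is omitted — all analyses here are macroscopic.

What the generator does **not** emulate: capacitance transients, series
resistance, perfusion-exchange kinetics, gating currents, channel-number
fluctuations, rundown, or any gating kinetics. Tests passing on this
generator therefore validate the *analysis chain* and the *equilibrium
model*, not robustness to instrumentation artifacts in real recordings.

Protocols shipped: voltage-step families from a −100 mV hold (20 ms hold,
50 ms step), ramps (−100→+50 mV in 200 ms or 1 s; −100→+150 mV for
TRP-like), constant-voltage heating at 0.3 °C/s with a 500 ms −100 mV
prefix for leak referencing, and the triple-pulse CSI protocol (P1 and P3
test pulses flanking a 10 s P2 conditioning segment; occupancy entering P3
is scaled by the steady-state availability at the P2 voltage).

## Measurement pipeline: numerical choices

- **Leak subtraction**: g_leak = mean I at the −100 mV holding samples
  divided by −100 mV; subtracted as g_leak·V everywhere. With 0.5 pA noise
  and ~50–100 holding samples the estimate carries ~1e−3 nS uncertainty,
  which matters only for sub-pA foot currents (see Q10 threshold below).
- **G-V extraction**: mean windowed current / (V − V_rev); the window
  (45–65 ms) sits in the equilibrated portion of the step. Steps within
  1 mV of the reversal potential are excluded with a warning.
- **Boltzmann fit**: deterministic initialization (V1/2 by linear
  interpolation of the half-max crossing; q from the maximal normalized
  slope via q = 4·(RT/F)·max dĜ/dV; g_max from the top-quartile mean),
  then a two-pass normalized least-squares fit (scipy `curve_fit`), each
  pass rescaling by the current g_max estimate. Negative conductances are
  clipped to zero for fitting but retained in returned curves. Degenerate
  inputs (span < 0.1% of the maximum) return a non-converged fit carrying
  the initialization and a failure message.
- **Q10 threshold detection**: the leak-subtracted current is binned on a
  0.5 °C temperature grid; the baseline is the first 1.5 °C. The threshold
  T₁ is the first bin from which the departure from the baseline mean —
  taken in the direction of the sweep's final excursion, so inward and
  falling currents work — exceeds 3 baseline SDs *and stays above it*
  (gating is at equilibrium, so a genuine threshold is never re-crossed).
  The SD uses both the bin-level scatter and a raw-sample noise floor.
  When the baseline is statistically indistinguishable from zero
  (activation from closed), I₁ and I₂ are referenced to the baseline mean,
  cancelling residual leak offsets; a deactivating sweep starts on real
  channel current and uses absolute amplitudes. I₂ is read 10 °C above T₁
  by default; a 5 °C interval is available for channels that inactivate on
  further heating. Because I₁ sits ~3 SD above noise *by construction*,
  a single-sweep Q10 carries ~30% uncertainty; replicate averaging (as in
  any real study) is required for tighter comparisons.
- **Conductance correction**: current / 1.5^((T−22)/10), removing the
  single-channel conductance temperature dependence so that remaining
  temperature dependence reflects gating. Model-level Q10 profiles use Po
  ratios directly and never include the γ factor.
- **Voltage-resolved Q10**: the warmer G-V is linearly interpolated onto
  the cooler curve's voltages (no extrapolation); entries with
  non-positive conductance are undefined. In the composed noisy run,
  G-V points whose magnitude is below 3× the windowed conductance noise
  are also marked undefined — foot points below the noise floor carry no
  ratio information.
- **Van't Hoff**: Po = γ-corrected conductance / g_max_ref with the
  generator's true n·γ(22 °C) as reference (the synthetic stand-in for a
  published maximal open probability); Keq = Po/(1−Po); ordinary least
  squares of ln Keq on 1/T; ΔH = −slope·R, ΔS = intercept·R. Bins with
  implied Po outside (1e−3, 0.9) are dropped: below, noise dominates the
  log; above, saturation bends the line. At a transition with z ≠ 0 the
  fitted enthalpy is the apparent value ΔH − z·F·V at the measurement
  voltage. Temperature-binning introduces a small curvature bias (~1% on
  ΔH for the default 50 bins over 20 °C).
- **CSI curve**: availability = mean P3 / mean P1 current over the test
  pulse; triples with |P1| < 1 fA are excluded with a warning; a falling
  Boltzmann is fitted via the rising fit on 1 − availability. If no
  voltage shows ≥ 5% inactivation the result is a non-converged fit with
  an explanatory message rather than a spurious curve.

## Units

SI internally (J, mol, K, V); all public interfaces use mV, °C, pA, nS and
pS. Config files take a `units` block (energy in J/mol, kJ/mol or
kcal/mol; entropy correspondingly) or per-value inline tags such as
`"100 kcal/mol"` (1 kcal = 4184 J); unknown keys and unknown unit tags are
rejected rather than coerced.

## Problem sizes

The shipped experiments are desk-scale by design: G-V recovery uses 12–17
steps × 4–5 patches at 2 kHz sampling; Q10 profiles use 1 mV model grids
and 5 mV measured grids; heating sweeps run 20–24 °C at 10 ms sampling;
the full test suite and the headline recomputation each finish in seconds.

## Known limitations

- The four-state scheme cannot jointly reproduce every effective parameter
  of every channel class (the v2_like artifact above is the clearest
  case); presets target the headline quantities each channel illustrates.
- Q10 at the detection threshold is noise-limited (see above); the
  pipeline reports what a single sweep supports and leaves averaging to
  the caller.
- No inactivation kinetics, recovery protocols, gating-current simulation,
  or GHK open-channel rectification.
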