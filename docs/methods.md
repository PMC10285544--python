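# Methods

This note documents the models and procedures implemented in `cardiopop`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## 1. The electro-mechanical cell surrogate

### Scope and intent

The simulator (`cell_model`) is a *phenomenological surrogate*, not a
reproduction of any published human-ventricular equation set. It is built to
expose the same experimental interface as the full models used in
population-of-models studies — eleven multiplicatively scaled parameters,
pacing at 1 Hz to steady state, isometric and afterloaded protocols, a
pore-block drug hook — and to satisfy, with the all-ones scaling vector,
every calibration range of the packaged experimental biomarker table
(`data/calibration_criteria.csv`). Population *counts* obtained with it are
not comparable to studies based on detailed ionic models; directions,
orderings and the calibration machinery are.

### Electrophysiology

Membrane potential (capacitance normalized to 1) carries eight currents:

* `I_Na = g_Na · m³h (V − 65)` — fast sodium; activation τ 0.12 ms,
  inactivation τ 0.8–7.8 ms (voltage-dependent). Sets the upstroke
  (dV/dt_max ≈ 230 mV/ms at reference).
* `I_CaL = g_CaL · d f f_Ca (V − 60)` — L-type calcium; voltage inactivation
  τ 30–200 ms plus calcium-dependent inactivation
  `f_Ca = 1/(1 + (Cai/0.8)²)`. Sustains the plateau and triggers SR release.
* `I_Kr = g_Kr · x_r (V + 88)` and `I_Ks = g_Ks · x_s (V + 88)` — delayed
  rectifiers (τ 160 / 500 ms); the principal repolarizing currents.
* `I_K1` — inward rectifier, open below ≈ −60 mV; clamps the resting
  potential near −86 mV.
* `I_NaK` (NKX, scale P_NaK), `I_NCX` (inward, proportional to the NCX
  extrusion flux, scale K_NaCa), and a small sodium background current.

The stimulus is a 1 ms rectangular current of 112 mV/ms — twice the
measured diastolic threshold (56 mV/ms for a 1 ms pulse), calibrated once
and frozen.

### Calcium handling

Cytosolic Ca²⁺ (µM) balances: influx through I_CaL (`J_CaL = −k_cal·I_CaL`)
plus a constant background influx; SR release
`J_rel = k_s · O · (Ca_SR − Ca_i)` through a Markov RyR gate; SERCA uptake
`J_up = V_maxup · Ca²/(Ca² + K_up²)`; NCX extrusion; an SR leak; and the
CaTnC buffering term −dB/dt (below). The RyR gate has open (O), inactivated
(I) and available (R = 1 − O − I) fractions: opening is driven by the
L-type gate (calcium-induced calcium release) plus a calcium-overload
term `(Cai/1.0)⁴/(1 + (Cai/1.0)⁴)` that enables spontaneous diastolic
release when the cell is overloaded; closing at rate `k_om`, inactivation
proportional to Cai, recovery at `k_im`. SR content sensitizes opening
through `Ca_SR²/(Ca_SR² + 1500²)`, so release self-limits when the SR
depletes.

### Mechanics and mechano-calcium feedback

* **CaTnC** (B, µM): `dB/dt = a_on·(0.6 + 0.4·ov)·Cai·(B_tot − B) −
  a_off·π(N,B)·B` with `π(N,B) = e^(−α·N) (1 − 0.5 B/B_tot)` — dissociation
  slows when many cross-bridges are attached or much CaTnC has formed
  (cooperativity), and the on-rate falls at shorter sarcomere length
  (length-dependent activation; the factor is 1 at the reference overlap).
  −dB/dt enters the Ca²⁺ ODE, closing the mechano-calcium-electric loop:
  clamping the cell at 0.80 instead of 0.93 L_max raises the free Ca²⁺
  transient by ≈ 8 %.
* **Cross-bridges** (N): attachment `k_p·ov²·hill(B)·(1 − N)` with
  `ov(L) = (L − 0.60)/(0.93 − 0.60)` (clipped) and a Hill function of B
  (half 30 µM, exponent 3); detachment accelerates with shortening velocity
  and when CaTnC support collapses (`k_m·(1 + 2v/v₀ + 3(1 − hill)⁴)`),
  which sharpens the twitch tail so the twitch-duration and decay-time
  biomarkers can sit in their experimental ranges simultaneously.
* **Force**: active `F_a = N·(1 − v/v₀)` (linear force–velocity, capped at
  1.4 for lengthening), exponential parallel elastic element. All reported
  forces are normalized to the reference model's peak isometric force at
  0.93 L_max (frozen constant `reference_peak_force`).
* **Afterloaded twitch**: isometric until total force reaches the load
  (`afterload_fraction · F_max` + passive), then isotonic — the shortening
  velocity is solved algebraically from the force balance — then isometric
  again once the initial length is re-attained. Phase switches use
  event detection with one-integration-step hysteresis. Re-lengthening is
  rate-limited at 8 L_max/s; during that limited phase the cell is below
  the load (the rig restrains the return), so the force-clamp invariant is
  asserted over the shortening phase.

### Numerics

Fixed-step classical Runge–Kutta in a numba-compiled kernel: 0.02 ms steps
during the first 10 ms of each cycle (upstroke), 0.1 ms elsewhere; output
resampled at 0.5 ms. Halving both steps changes the reference APD90 by
< 10⁻⁶ ms. The fixed step gives bit-identical reruns, which the seeded
pipeline tests rely on; numerical failure (NaN state) is reported as an
`integration_failed` trace status, never an exception. Gating fractions and
concentrations are clamped to their physical ranges after each step.
A 200-cycle run takes roughly a second; steady state (< 1 % cycle-to-cycle
change in APD90, peak Ca and peak force) is reached by ≈ cycle 60 at
reference.

### Tuning

The fixed constants in `data/reference_model.json` were tuned once, by
hand, until the all-ones model satisfied all 13 biomarker ranges with
reasonable margins (APD90 312.9 ms against the experimental mean 311 ms;
FTTP 273.9 ms against 275 ms), and then frozen. The 11 scaled parameters
act on exactly the quantities their names promise, so the sensitivity signs
(g_Kr ↑ → APD90 ↓, g_CaL ↓ → APD90 ↓, g_Na ↓ → dV/dt_max ↓) emerge from the
dynamics rather than from fitting.

### Known limitations

The surrogate has 14 state variables, fewer than detailed ionic models; it
omits I_to (no spike notch, so APD20 sits low in its range), intracellular
Na⁺/K⁺ dynamics, stretch-activated channels, rate-dependence beyond 1 Hz
(other pacing rates run but are uncalibrated), and tissue coupling.
Very strong I_K1 scaling (≈ 2×) can raise the excitation threshold enough
that a model fails to fire; such models are rejected as failed excitation
rather than patched.

## 2. Biomarkers

All features are measured on the final paced cycle with linear
interpolation, ties toward the earlier sample. Conventions chosen where the
experimental literature is silent:

* APDxx from the **activation time** (max dV/dt), not the stimulus; RMP is
  the minimum V over the 50 ms before the stimulus.
* Force twitch onset by the **tangent-intercept** method (steepest rise
  projected back to the diastolic level) — exact for a linear rise, robust
  for smooth twitches; FTTP is peak minus onset; FTTr is peak to 90 %
  decay; FTD is the time force exceeds diastolic + 5 % of the amplitude.
* Ca²⁺ onset at 10 % of the amplitude; CaTTP and CTDxx measured from it.
* Missing events (no AP, no transient, no twitch) set flags instead of
  numbers; an AP requires ≥ 30 mV amplitude, a transient ≥ 0.05 µM.

## 3. Abnormality detectors

The abnormality classes follow the population-rejection protocol; the
numeric thresholds are this package's documented defaults
(`AbnormalityThresholds`), frozen for the tests: EAD = sustained (≥ 5 ms)
secondary rise ≥ 2 mV between 10 % and 90 % repolarization; DAD = ≥ 2 mV
rise above the running diastolic baseline after 90 % repolarization;
premature AP = upward −20 mV crossing outside the 25 ms stimulus window;
failed repolarization = 90 % level never reached, or pre-stimulus diastole
above −60 mV (catches cells stuck depolarized, whose within-cycle
"repolarization" fractions are meaningless); alternans = |ΔAPD90| > 5 ms
between the last two cycles; double-peak contraction = ≥ 2 peaks with ≥
10 % prominence; failed contraction = < 1 % isotonic shortening;
spontaneous Ca²⁺ release = a secondary Cai peak ≥ 5 % of the transient
amplitude after the main peak. Detectors are pure functions of the trace
and degrade gracefully to single-cycle traces (afterloaded twitches), where
alternans cannot be assessed.

## 4. History matching

* Implausibility uses the GP predictive variance as Var[f_n(x)]; simulator
  outputs are treated as exact (zero variance). Min-max criteria are applied
  to predictive means only.
* Emulators: one anisotropic-RBF Gaussian process per biomarker
  (constant × RBF + white noise), inputs scaled to the sampling box,
  outputs normalized, marginal-likelihood optimization with one restart
  from a fixed seed; from wave 2 on, optimization warm-starts from the
  previous wave's hyperparameters, which cuts wave cost several-fold
  without changing the toy-run outcome. Leave-one-out RMSE (closed form) is
  recorded per emulator as a diagnostic.
* Training data: the accepted (non-abnormal) simulator runs of up to the
  four most recent waves; fewer than 10 points is an error.
* Wave-1 candidate cloud: Latin hypercube (uniform coverage); simulator
  designs of ≤ 1000 points take the best of five hypercubes by maximin
  distance. Subsequent waves draw simulator points uniformly from the
  surviving cloud and re-evaluate the cloud itself, so the pre-augmentation
  NROY cloud can only shrink.
* Augmentation below the floor: N(x, 0.05·I) jitter around uniformly chosen
  survivors, redrawing out-of-bound draws.
* The *acceptance rate* reported per wave is the fraction of that wave's
  simulator runs meeting the calibration criteria (implausibility at zero
  variance plus min-max); the final population is calibrated by the
  [min, max] columns of every criterion plus the abnormality screen.
* Convergence: < 0.1 % change in surviving-cloud size, or the wave cap
  (default 60).

Defaults mirror the full-scale protocol (300 simulators/wave, 10⁶-point
wave-1 cloud, 10⁵ augmentation floor, 1,000-model population). The test
suite and the acceptance script run a desk-scale toy configuration
(5 waves × 100 simulator points, 2·10⁴-point cloud, 5·10³ floor, 500-model
population) against the analytic toy simulator; these sizes are the
package's reproducibility defaults for that script, chosen so a seeded run
completes in about a minute.

## 5. The toy simulator

`fixtures_and_toy.ToySimulator` maps an 11-D scaling point to the ten
calibrated biomarkers through frozen affine + mild quadratic coefficients:
the all-ones point returns exactly the criteria centers, and the global
amplitude (γ = 1/1.35, coefficient seed 20260925) was set once so the true
plausible region occupies ≈ 14.5 % of the box — large enough that wave 1
finds it, small enough that the acceptance-rate trajectory (≈ 13 % →
≈ 99 % over five waves) is informative. What toy-based tests show: the
calibration machinery (emulation, filtering, augmentation, convergence,
seeding) is correct. What they do not show: anything about the ODE model's
biology — the toy's biomarkers are smooth low-order polynomials with a
connected plausible region, far easier to emulate than a stiff ODE's
response surface; real abnormality-driven rejections have no toy analogue.

## 6. Mechanical calibration and drug testing choices

* L-F strictness: ties (within 10⁻⁶ normalized force) count as failures —
  the Frank–Starling requirement is read as strictly increasing.
* F-V: rejection is operationalized as non-strictly-decreasing maximum
  shortening velocity in afterload; the AP-abnormality and F-V checks are
  applied and flagged separately.
* Preload runs use the full 200-cycle steady-state protocol at every
  length.
* Drug sweeps hold the afterload at 0.5 × the **drug-free** F_max of the
  same model and length: the external load on a cell does not change when
  a drug weakens it, and this is what makes negative inotropes produce
  failed contractions. A twitch that never lifts the load counts as a
  failed contraction.
* Dofetilide's packaged EFTPCmax (0.002 µM) is an editorial reconstruction
  (the source table truncates it to "0.00"); Dofetilide analyses in the
  tests use absolute concentrations around its I_Kr IC50 instead.
* The default concentration grid {0.1, 0.3, 1, 3, 10, 30, 100} × EFTPCmax
  interpolates the published range endpoints logarithmically.

## 7. Population statistics

Parameter summaries are pandas order statistics; Pearson r/p from
scipy; the 1-D Wasserstein distance from scipy (checked in the tests
against the sorted-sample formula). The accept/reject classifier is a
stratified 5-fold cross-validated logistic regression (seeded); the
uniparametric threshold maximizes Youden's J on the raw feature, and the
odds ratio of acceptance below vs above the threshold uses ad/bc with a
Haldane–Anscombe 0.5 correction for zero cells and a Woolf log-normal 95 %
CI. Sensitivity analysis reports plain percent change of each biomarker
under 0.5×/2× parameter scaling. Multi-feature importance is the absolute
standardized logistic coefficient — one defensible reading among several.
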