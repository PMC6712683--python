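# Methods

## Scope and model structure

`oursoft` estimates the oxygen uptake rate (OUR) of a stirred-tank
mammalian cell culture from standard on-line channels, links it to viable
cell volume, and detects the metabolic transition at which the specific
oxygen consumption per cell volume changes. The chain is:

1. solubility: saturation O₂ concentration under prevailing temperature
   and inlet-gas composition;
2. kLa: a dynamic plane model of the volumetric mass transfer coefficient
   in the characterized operating space;
3. OUR: the steady-state identity OUR = OTR = kLa·(c\*_M − c_DO);
4. biomass: two independent PCV soft-sensors (segmented OUR–PCV,
   capacitance);
5. metabolic sensor: agreement logic over the two biomass sensors.

## Oxygen solubility

Water solubility c\*(T) uses Tromans' thermodynamic expression with
R = 8.314 J·mol⁻¹·K⁻¹, T in Kelvin and p_O2 in atm — the combination the
published coefficient set is dimensioned for. Default p_O2 = 0.2095 atm
(air at 1 atm headspace); a pressure-scaling hook exists but defaults to
identity, since no pressure term beyond 1 atm is characterized.

Medium solubility applies the measured relative line
(−0.638·y_CO2 + 95.63)/100, which both scales water solubility to medium
(95.63 % at zero CO₂ — numerically consistent with the independently
measured ≈5 % decrease, treated as the same effect, not stacked) and
accounts for O₂ displacement by CO₂. p_O2 is **not** additionally reduced
by y_CO2; doing both would double-count the displacement. Evaluation
outside the y_CO2 range that keeps the factor positive is a domain error.

Probe conversion: the optical DO probe internally references its reading
to the calibration temperature, so
c_DO = c\*_M·(DO %/100)·c\*(T_proc)/c\*(T_cal). The assignment
(numerator = process temperature, denominator = calibration temperature,
default 310.15 K) is a package convention — the underlying correction is
stated but not fully specified by its source — and both temperatures are
configurable. Salinity/osmolality and viscosity corrections are
deliberately out of scope (negligible in the characterized system).

## kLa estimation and the dynamic plane

Gassing-step estimation regresses ln|DO_∞ − DO(t)| on time restricted to
the 20–80 % band of the response span (bounds configurable, inclusive).
The asymptote DO_∞ is the settled tail of the trace unless given
explicitly, so step experiments should run to ≳9 process time constants.
Probe dynamics are not deconvolved; instead each estimate carries the
validity flag τ_p ≤ 1/kLa (τ_p default 49.6 s). Note that a heavily lagged
probe biases the estimate itself low, which can make the flag read valid
from the estimate even when the true kLa is beyond 1/τ_p — the flag is a
necessary, not sufficient, check.

The dynamic model is a pure plane kLa = β₀ + β_pid·PID + β_T·T (no
T×PID interaction, no volume term — volume showed no effect in the
characterized 10–15 L range). Regressing on PID % directly is correct
here because stirrer speed (91–228 rpm) and air flow (0.3–1.5 L·min⁻¹)
are jointly actuated by the controller; the maps are retained only in the
simulator. Above the characterized PID range (default 60 %) the same
plane is evaluated and an extrapolation flag is set. A prediction of
exactly zero is allowed (it propagates to OUR = 0); negative predictions
raise.

## OUR

Soft-sensor OUR is reported in mmol·L⁻¹·h⁻¹. The accumulation term dC/dt
defaults to zero — at controlled DO it vanishes, and during the brief
uncontrolled start-up it is small against OUR at on-line sampling
intervals. A central-difference estimator with a configurable smoothing
window (default 5 samples) is provided for diagnostics only. Negative OUR
is flagged, never clamped: it diagnoses supersaturation or sensor error.

The off-gas mass balance uses G_out = G_in, ideal-gas molar volumes at
1 atm, inlet gas temperature fixed at 22 °C by convention, outlet
temperature from the measured channel when available. The inlet O₂
fraction is 20.95 % of the process-air share of the total flow (the CO₂
stream carries no O₂). Humidity correction of the off-gas is out of
scope.

## Biomass models

Off-line samples below 80 % viability (inclusive threshold, configurable)
are excluded before any fit: dying cultures contribute volume but not
oxygen demand.

**Segmented OUR–PCV.** Two independent least-squares lines with the
breakpoint defined as their intersection, found iteratively:
initialization at the SSE-minimizing midpoint between consecutive sorted
x values inside the inner 5th–95th percentile band (ties → smaller SSE,
then smaller x), then alternate per-side OLS and breakpoint ←
intersection until the move is below 1e−6 (max 100 iterations).
Continuity is *not* imposed — the breakpoint is the intersection of two
free lines, and non-convergence, parallel lines, or a breakpoint escaping
the data range raise with the last iterate attached. Each side needs ≥ 2
points. The fit is equivariant under affine rescaling of OUR and
translation of PCV.

**Capacitance.** pcv = cell_factor·(permittivity − γ·(conductivity −
conductivity_ref)) + offset. The model is linear in its channels, so the
joint fit is a single OLS with γ recovered from the coefficient ratio
(delta-method standard error). The subtractive conductivity form is a
package design choice: conductivity is used as a temperature-tracking
correction, and the simplest form consistent with that role is a linear
deduction from permittivity. When conductivity does not vary, γ is
unidentifiable; the fit warns and pins γ = 0. In particular, γ can only
be estimated from runs with temperature variation.

Accuracy is summarized with MAPE = 100/n·Σ|(x_i − x̂_i)/x_i|, normalized
by the actual values (zero actuals are an error). A train/test helper
evaluates MAPE under the split semantics used for soft-sensor validation:
designated (replicate, static) runs are held out as the test set.

## Metabolic sensor

At the metabolic shift the culture sits at the intersection of the two
OUR segments, so the PCV obtained by inverting segment 1 and segment 2 at
the current OUR agree there, and both agree with the capacitance PCV. The
shift condition is |PCV_f1 − PCV_f2| ≤ tol AND min_i|PCV_fi − PCV_cap| ≤
tol, required for `debounce` consecutive samples, after which the state
latches 0 → 1 permanently. The transition is treated as one-way; a
non-latching mode exists for exploration. Defaults tol = 0.05 PCV % v/v
and debounce = 3 are package choices (no tolerance or persistence rule is
specified by the method's source); both are configurable and reported
with every detection. Detection time is non-increasing in tol, and with
small tol on noise-free data detection occurs at the first samples after
the breakpoint crossing.

## Synthetic fed-batch generator

The generator emulates a 13-run fed-batch campaign: batch phase at 37 °C,
optional temperature shifts at 72/120/192/240 h with setpoints in
{31, 34, 36.3, 37} °C, DO setpoint 30 %, PID jointly mapped to
91–228 rpm and 0.3–1.5 L·min⁻¹, seeding-scale initial biomass, roughly
two-week duration.

Ground-truth choices, fixed once:

* **Growth**: logistic viable PCV, initial 0.3 % v/v, rate 0.035 h⁻¹,
  capacity 3.2 % v/v — a sigmoidal progression crossing the breakpoint
  mid-run (≈58 h) and plateauing near harvest.
* **Metabolic ground truth**: OUR = 2.52·PCV − 0.66 before the shift and
  0.06·PCV + 2.784 after, breakpoint 1.4 % v/v. The slopes are the
  published-scale segment coefficients expressed per hour (the printed
  per-minute-scale values are ~60× too small to ever pull DO down to a
  30 % setpoint against realistic kLa); the second intercept is chosen so
  the segments meet at the breakpoint — a continuous kink, which is both
  the observed shape of OUR vs PCV and the precondition for the
  intersection-based sensor to be meaningful.
* **kLa truth**: medium plane β₀ = −43.5, β_pid = 0.25 h⁻¹ %⁻¹,
  β_T = 0.15 h⁻¹ K⁻¹ (kLa ≈ 3–28 h⁻¹ over the PID range at 37 °C); the
  water plane used for characterization fixtures is roughly one third of
  it, preserving the >3× medium enhancement.
* **Control loop**: while DO is above the setpoint the PID stays at its
  minimum and the oxygen balance dc/dt = kLa(c\*_M − c) − OUR is advanced
  with its exact exponential solution per step (coefficients are
  piecewise constant). Once the setpoint binds, DO is clamped and the PID
  is solved algebraically from the kLa plane so that transfer equals
  uptake — an idealized tight controller rather than a discrete PI
  update. This makes the soft-sensor and mass-balance round-trips exact
  by construction at steady-state samples (the end-to-end tests verify
  ≤1e−6 relative), so those tests validate algebraic consistency;
  robustness is probed separately by the noise settings. PID demand above
  100 % sets a saturation flag and clears the steady-state flag.
* **Off-gas** is generated from the gas-side transfer OTR (what an
  analyzer actually sees), not from OUR; the two coincide at steady
  state, and the early free-fall discrepancy reproduces the well-known
  misbehavior of the mass-balance route at low uptake.
* **Capacitance truth**: cell factor 0.4 PCV % per pF·cm⁻¹, γ = 0.05,
  conductivity 11 mS·cm⁻¹ at 37 °C with 0.2 mS·cm⁻¹·K⁻¹ temperature
  tracking.
* **Off-line table** every 12 h: total and viable PCV, viability (98 %
  declining linearly after 180 h), VCC derived through a mean cell volume
  drifting from 2.2 pL upward (which is what makes OUR–VCC non-linear
  while OUR–PCV stays piecewise linear), and an Asp/Glu phenomenology
  whose ratio crosses 2 exactly at the breakpoint PCV.
* **Noise** defaults are realistic channel-level magnitudes (DO 0.2 %,
  permittivity 0.03 pF·cm⁻¹, ...); `NoiseConfig.noiseless()` switches all
  off. All randomness flows through one seeded generator (default seed
  20190821); identical configurations are bit-identical.

What the generator does **not** emulate: mechanistic metabolism (the
amino-acid curves are phenomenological), off-gas humidity, probe drift
and fouling, pH dynamics beyond the CO₂-flow decay, feed-pulse
disturbances, and cell lysis/fragment effects on capacitance. Passing
end-to-end tests therefore demonstrates internal consistency of the
estimator chain under the stated model, not field performance on real
cultures.

## Problem sizes and numerics

Default runs use a 0.1 h sampling interval over 240 h (2401 samples);
recovery suites use 200 seeded replicates (gassing steps at 0.5 %
saturation noise; segmented fits at 5–10 % of the response range,
n = 60–100). Gassing fixtures span 9.5 process time constants so the tail
pins the asymptote to ≲0.03 % estimation bias. Breakpoint iteration
tolerance 1e−6 in PCV; tie-breaks as above; all OLS through
statsmodels/numpy least squares.

## Known limitations

* The plane kLa model is only valid inside (plus linear extrapolation
  slightly beyond) the characterized (T, PID) space of one vessel; it
  does not transfer across scales without re-characterization.
* The Eq-10-style probe temperature correction convention (process vs
  calibration temperature) is a documented package decision; a probe with
  a different internal referencing needs the configurable T_cal and, if
  necessary, swapped convention.
* The sensor's tolerance/debounce defaults were chosen for the synthetic
  noise levels; real installations should calibrate them against the
  capacitance channel's observed noise.
* MAPE is undefined at zero actual values and asymmetric by construction;
  it is retained as the field-standard accuracy summary, not as an
  optimal loss.
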