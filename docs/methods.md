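# Methods

`bivent` couples a closed-loop biventricular circulation simulator to the
measurement chain used in large-animal pressure-volume (PV) studies of
cardiogenic shock: conductance-catheter volume calibration, PV-loop
segmentation and fiducial detection, occlusion-based end-systolic
pressure-volume relationship (ESPVR) fitting, and a four-stage support
protocol with cohort statistics.  This note documents the model, the
estimators, the defaults and their rationale, and the known limitations.

## Circulation model

Each ventricle is a time-varying elastance chamber,

    P(t) = [Emin + (Emax - Emin) a(t)] (V - V0) + P_peri,

with a double-Hill activation a(t) (rising Hill of order n1 and time
constant tau1, times a falling Hill of order n2, tau2; both time constants
are *fractions of the beat period*, so systolic timing scales with heart
rate).  The waveform is normalised so its peak is exactly 1; the peak is
located by a bounded scalar minimisation to machine precision so that Emax
is attained exactly once per beat.

The vascular circuit has four windkessel compartments — systemic arterial,
systemic venous, pulmonary arterial, pulmonary venous — connected through
eight resistive paths (four containing soft-diode valves).  Valves use a
softplus flow law Q = softplus(dP; w)/R with width w = 0.25 mmHg: flow is
strictly non-negative, the ODE right-hand side is smooth, and the leak of a
closed valve vanishes exponentially in the back-pressure.  The axial
transvalvular pump is a continuous LV-to-aorta flow source with a linear
head curve, a softplus clamp at zero flow (clamp width proportional to the
maximum flow, so a disabled or near-zero pump contributes no leak) and a
sigmoid suction ramp below a configurable LV volume.

Ventricular interdependence is realised through a shared pericardial
pressure, exponential in total heart volume, P_peri = g exp(k (V_lv + V_rv
- V_ref)): strictly positive and strictly increasing, and the mechanism by
which unloading one ventricle improves filling of the other.  An explicit
septal cross-talk term was considered and omitted; the pericardial coupling
alone reproduces the end-diastolic volume-ratio inversion under support.

States are the six compartment volumes plus two *flow accumulators*
(cumulative pulmonary-valve and systemic outflow).  The right-hand side
moves volume between compartments, so classical Runge-Kutta preserves total
blood volume exactly (net of the maintenance infusion, 1000 mL/h into the
venous compartment).  Integration is fixed-step RK4 at dt = 0.2 ms with
output sampled at 250 Hz.  The system is non-stiff at the chosen valve
smoothing width; step-halving changes the recorded pressure and volume
traces by < 0.05 mmHg / 0.05 mL over a 10-s run (tested), and the fixed
step makes runs bit-reproducible and fast enough for cohort work
(~3 s per full four-stage animal).  The flow accumulators exist because a
naive average of the sampled, spiky ejection pulse under-reads mean flow by
~2%; cardiac output is defined as the accumulator difference over a whole
number of beats (the Swan-Ganz/thermodilution surrogate).

Mixed venous saturation follows the Fick principle,
SvO2 = SaO2 - VO2 / (1.34 * Hb * 10 * CO), clamped to [0, SaO2].

### Nominal animal

The defaults describe a ~70-75 kg anaesthetised pig: heart rate 82 bpm, LV
Emax 0.85 / Emin 0.046 / V0 13 mL, RV Emax 0.26 / Emin 0.034 / V0 10 mL,
systemic arterial resistance 0.612 mmHg s/mL, total blood volume 4.44 L,
and conductance sensors with gain 1.25/1.10, parallel volume 50/60 mL and
2 mL additive Gaussian noise.  At baseline this animal runs CO ≈ 5.6 L/min,
MAP ≈ 66 mmHg, SvO2 ≈ 67%, LV EDV ≈ 180 mL and RV EDV ≈ 170 mL.  The
oxygen-transport defaults (SaO2 0.98, Hb 10 g/dL, VO2 232 mL/min) were
chosen so the Fick relation is simultaneously consistent with the baseline,
shock and support states this preparation exhibits; a single fixed-VO2 Fick
curve cannot match every printed pairing exactly, so the defaults balance
all four stages.

## Interventions

**Microsphere shock** is stepwise: each injection multiplies LV Emax by
(1 - 0.111) and RV Emax by (1 - 0.013), stiffens RV diastole by +5.6%
(ischaemic diastolic dysfunction), raises pulmonary arterial resistance by
+10.2% (hypoxic pulmonary vasoconstriction accompanying the microsphere
load) and adds 27 mL of net fluid (the maintenance drip running over the
real, uncompressed induction interval).  Injections stop when SvO2 has
fallen to half of baseline, or below 30% absolute, or sustained CO (mean
over 10 beats) is <= 2.0 L/min; the stopping rule is re-checked on a
steady re-simulation.  The nominal animal reaches profound shock after
~10 injections at CO ≈ 2.7 L/min.

**Norepinephrine** acts multiplicatively through a saturating Emax-type
dose-response, scale = 1 + eff * d/(d + d50) with d50 = 0.089 ug/kg/min,
on LV/RV Emax (maximal effects +265%/+55%), heart rate (+18.5%), systemic
and pulmonary arterial resistance (+6.4%/+50.6%) and venous unstressed
volume (-15.5%, i.e. venoconstriction recruits stressed volume).  Because
the scaling depends only on the accumulated dose, successive increments
compose exactly and zero dose reproduces baseline bit-for-bit.  Saturation
is essential: the observed pattern — a near-doubling of LV contractility at
the minimum titrated dose but only a further ~50% at +0.10 ug/kg/min — is
far from exponential.

**Pump support** enables the head-curve flow source at the device ceiling
(3.5 L/min at zero head, 0.1 mL/s lost per mmHg of aorto-ventricular
gradient).

## Measurement chain

**Conductance channels.**  G(t) = alpha (g(t) V(t) + Vp) + alpha * noise,
where alpha is the gain, Vp the parallel-conductance volume equivalent and
g(t) the saline-bolus conductivity transient (smoothstep wash-in over a
third of the bolus duration, exponential washout; the true volumes are
unchanged — hypertonic saline alters conductivity only).

**Gain (alpha)** is the ratio of the uncalibrated stroke volume to a
thermodilution-surrogate reference (integrated pulmonary flow over whole
beats divided by heart rate).  The uncalibrated stroke volume is the
excursion of a *phase-resampled ensemble-average beat*: beats are anchored
on sub-sample-refined pressure-peak times, resampled at exact fractional
phases (immune to the beat period being incommensurate with the sampling
rate), averaged, and the extremes refined by local quadratic fits.
Averaging before taking extremes avoids the upward bias that per-beat
peak-to-peak ranges acquire from sensor noise, and the raw (unsmoothed)
channel is used because polynomial smoothing overshoots the sharp
end-diastolic corner.

**Parallel volume (Vp)** uses the hypertonic-saline method: per-beat
(ED, ES) pseudo-volume pairs move along a line whose intersection with the
identity line is the parallel component.  Three refinements keep the
estimator unbiased on this generator: (i) beats are anchored on pressure
peaks, because the conductivity transient distorts the conductance
waveform itself; (ii) the ED paired with each ES is interpolated between
neighbouring end-diastoles at the ES time, compensating conductivity drift
*within* the beat; (iii) the regression window covers the washout side of
the transient, where the between-beat curvature of g(t) is negligible.
The intersection is averaged over five distinct ES sampling phases (each
phase pair defines a different line through the same point), and the
protocol repeats the bolus (default six times) and averages, as is standard
practice; at zero noise the recovery is exact to < 1% / 1 mL, and at the
default 2 mL noise the averaged Vp error has a standard deviation of a few
mL.

**Beats and fiducials.**  Beats are delimited at end-diastole (volume
maximum between successive systolic pressure peaks).  Within a beat, ED is
the maximal-volume low-pressure sample and ES maximises P/(V - Vo) over the
pressurised part of the beat (maximal-elastance criterion); both rules are
invariant under circular shifts.  Conductance-derived volumes are lightly
Savitzky-Golay smoothed before segmentation.

**ESPVR.**  From an IVC-occlusion beat family (venous-return resistance
ramped 25x over 8 s) with monotonically falling EDV: starting at Vo = 0,
ES points are located, P_es is regressed on V_es by OLS, Vo is updated to
the volume intercept, and the loop repeats to convergence (|dVo| < 0.01 mL).
Ees is the converged slope.  On noise-free true volumes the fit recovers
the ground-truth Emax and V0 essentially exactly; through the calibrated
pipeline at default noise, the median errors over a 50-animal cohort are
well inside 10% (Ees) and 8 mL (Vo).

**Per-beat indices.**  SW is the shoelace polygon area of the loop
(orientation-independent; agrees with the trapezoid loop integral to
0.1%); PE = ESP (ESV - Vo)/2 floored at zero, with Vo from the *baseline*
occlusion fit reused at later stages (the baseline occlusion is the
reference manoeuvre); PVA = SW + PE holds exactly; Ea = ESP/SV; the
coupling ratio is reported as Ea/Ees.  Stage values are medians over the
final 10 beats of a steady window.

## Protocol and statistics

Per animal: baseline (settle 22 s + 12 s window), repeated saline boluses
and a baseline occlusion; shock induction; pump attachment with a -150 mL
net fluid balance (restored diuresis) and titration of the minimum
norepinephrine dose on a 0.05-step grid against a 45 mmHg MAP threshold;
escalation by +0.10 ug/kg/min in a deterministic subset (first 8 of 18).
An occlusion is run at every stage for the per-stage Ees; Vo is baseline
only.  Stage windows are compressed to tens of seconds because the model
has no slow dynamics; the net fluid balance of the omitted intervals is
carried as discrete volume adjustments.

Cohorts are drawn lognormally around the nominal animal.  Paired LV/RV
parameters (Emax, Emin) share a common factor plus small independent
components — global myocardial properties co-vary between ventricles —
which keeps the interventricular volume balance physiological across
animals.  Summaries use mean (SD) when a Shapiro-Wilk check at alpha 0.05
passes and median (Q1, Q3) otherwise; paired comparisons use a paired t
test or a Wilcoxon signed-rank test (exact null for n <= 25, normal
approximation with continuity correction above) chosen by the same
normality gate, with Bonferroni adjustment over the comparisons in each
table family.

## Numerical choices

- RK4 step 0.2 ms; sampling 250 Hz; valve softplus width 0.25 mmHg; pump
  clamp width 2% of maximum flow.
- Volume conservation is exact to floating point (linear invariant of RK);
  the tests require < 1e-9 relative drift net of the infusion.
- ESPVR iteration: tol 0.01 mL on Vo, max 50 iterations, >= 5 usable beats;
  degenerate geometries (flat preload, non-positive slope, no identity-line
  intersection) raise typed errors rather than returning numbers.
- Potential energy is floored at zero with a warning when ESV < Vo.
- Warm starts chain the final state between stages; the beat clock restarts
  at each run, so measurement windows exclude the first seconds after a
  warm start.

## What the generator does and does not emulate

It reproduces the structure the analysis assumes: simultaneous biventricular
P-V signals with gain/parallel-volume/noise sensor artefacts, pulsatile
arterial and venous pressures, occlusion and saline manoeuvres, stepwise
shock with backward failure, pump unloading with pericardially mediated RV
refilling, and saturating vasopressor responses.  It does not model atrial
contraction (measured EDP therefore cannot exceed upstream venous pressure,
and the printed RV EDP values, which sit above CVP, are under-read by
~1-3 mmHg), regional ischaemia or loop-shape changes beyond global
elastance scaling (the thin triangular RV loop of profound shock is
rounder here, overestimating shock RV stroke work), reflex control,
ventilation coupling, or ECG timing.  Passing tests therefore demonstrate
correctness of the estimators against this generator's ground truth and
consistency with the printed stage-level physiology, not fidelity to every
moment of a real conductance recording.

## Known limitations

- The stage tables the calibration targets mirror are cross-animal medians
  from two pooled experimental series and are not jointly realisable by a
  single deterministic animal; the packaged nominal animal prioritises the
  flow/pressure/work trajectory (and reproduces the four headline work and
  coupling quantities within ~8%), leaving a minority of derived rows
  outside their bands.  These appear as plain failures in the acceptance
  test module.
- LV potential energy as printed is inconsistent with the same table's
  ESP/Ees/EDV medians under the triangle formula; the package reproduces
  the self-consistent subset.
- Conductance volumes inherit a per-experiment offset from the saline
  estimate of the parallel volume (a few mL after bolus averaging), exactly
  as in real preparations.
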