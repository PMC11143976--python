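# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `cmjkit`. It is the reference for *why* the pipeline is
built the way it is; the README covers *how* to use it.

## 1. Kinematics from vertical GRF

All motion quantities derive from the impulse–momentum theorem. With body
mass *m* and vertical ground-reaction force *F(t)* sampled at rate *f_s*
(nominally 1,000 Hz):

- net acceleration  a(t) = F(t)/m − g, with g = 9.81 m/s² (configurable);
- velocity          v(t) = ∫ a dt from movement onset, v(onset) = 0;
- displacement      s(t) = ∫ v dt;
- power per kg      P(t) = (F/m)·v.

Integration is cumulative trapezoidal with **no filtering by default**: at
1 kHz the trapezoid error in take-off velocity is O(h²) (≈2×10⁻⁴ m/s on the
default waveform) and filtering would bleed impulse across the phase
boundaries. A filter can be applied upstream by the caller if a plate is
unusually noisy.

**Power convention.** P = (F/m)·v is *total* GRF power, whose concentric peak
sits at the familiar 55–65 W/kg scale for strong jumpers. The alternative
net-force convention (a·v) is available via
`integrate_motion(power_convention="net")`; it changes EccMP/ConMP/PP scales
and is off by default.

### Event detection

- **Body weight**: mean force over the first 1.0 s (standard quiet-standing
  weighing). The window SD must be ≤3% of the mean, otherwise the trial is
  rejected as "subject not still". The SD also calibrates onset detection.
- **Onset**: first sample where |F − BW| exceeds 5× the quiet SD, backtracked
  to the first sample after the trace last sat inside the ±1 SD noise band.
  The 5 SD / 1 SD pair is conventional force-plate practice; both are
  configurable (`onset_k`, and a 0.5 N floor on the noise band for noiseless
  synthetic data).
- **Take-off**: first sample whose force and whose following 10 ms mean force
  are both below 10 N. Using the window *mean* (rather than requiring every
  sample below threshold) makes detection robust to single noise samples
  poking above 10 N; on clean data the two rules agree within 2 ms.
- **End of braking**: first upward zero crossing of v after its minimum,
  snapped to the first non-negative sample. This instant is the
  eccentric/concentric boundary, so EccDur + ConDur spans onset → take-off
  exactly.

## 2. Jump variables

Per trial, all normalized to body mass; three trials per session are averaged
arithmetically per athlete (a single trial passes through with a logged
warning).

| variable | definition | note |
|---|---|---|
| JH (cm) | v²ₚₑₐₖ/(2g), peak concentric velocity | take-off-velocity JH and flight-time JH (g·t_f²/8) also computed for cross-checks |
| PF (N/kg) | max F/m, onset → take-off | |
| PP (W/kg) | max P, onset → take-off | |
| EccI (Ns/kg) | net impulse over the braking portion (v_min → end of braking) | equals \|v_min\| by impulse–momentum |
| ConI (Ns/kg) | net impulse over the concentric phase | equals take-off velocity |
| EccMP (W/kg) | mean \|P\| over the eccentric phase | magnitude by default: COM power is negative during descent |
| ConMP (W/kg) | mean P over the concentric phase | |
| EccDur, ConDur (s) | phase durations | |
| ED:CD | ConDur / EccDur | rises under fatigue (relatively longer push-off) |

Two definitions deserve justification:

- **EccI as braking impulse.** The net impulse over the *whole* eccentric
  phase is identically zero (velocity starts and ends the phase at zero), and
  the gross impulse ∫F dt is ~3.4 Ns/kg at typical durations — neither matches
  the 1.1–1.4 Ns/kg scale this variable carries in monitoring practice. The
  braking net impulse, which equals |v_min|, does. Both impulses are computed
  from the velocity trace with the *interpolated* phase boundary (where v = 0
  by definition), so the impulse–momentum identities hold to the integration
  tolerance rather than to one sample's worth of impulse.
- **ED:CD as ConDur/EccDur.** A 0.35 s / 0.25 s jump then gives ≈0.71, the
  scale this strategy ratio is reported at, and the ratio *increases* under
  fatigue together with the relatively longer concentric phase. The output
  metadata documents the ordering since the label "ED:CD" reads the other way.

Percent changes vs baseline are 100·(x − baseline)/baseline, kept at full
precision internally and rounded to one decimal for presentation
("11.5% lower" ⇔ −11.5).

## 3. Time-normalized curves

Force (N/kg) and power (W/kg) are resampled by linear interpolation at equal
*time fractions* within each phase: 0–50% of normalized time spans the
eccentric phase, 50–100% the concentric phase, Q = 100 intervals (101 nodes,
the common convention in 1D-SPM work; only the 50/50 split is essential).
Node 0 is onset, node 50 the end of braking, node 100 take-off. Curves are
normalized **per trial** and averaged hierarchically: trial mean within
athlete first, then mean ± SD across athletes — so athletes with unequal
trial counts carry equal weight.

## 4. Repeated-measures ANOVA

For each variable, the complete athletes × conditions matrix is decomposed as
SS_total = SS_subjects + SS_conditions + SS_error, F = MS_cond/MS_error with
df (k−1, (k−1)(n−1)) — (4, 36) for 10 athletes × 5 sessions. Sphericity is
tested with Mauchly's W (chi-square approximation including the second-order
term, as in ezANOVA/pingouin); when rejected at 0.05 both df are multiplied
by the Greenhouse–Geisser ε (trace formula on the contrast-projected
covariance, clipped to [1/(k−1), 1]). Partial η² = SS_cond/(SS_cond +
SS_error), classified small/moderate/large at 0.04/0.25/0.64 with inclusive
lower bounds. Post hocs are all k(k−1)/2 paired t-tests with Bonferroni
adjustment p·10 (capped at 1), two-sided throughout; zero-variance pairs
report p = 1. No correction is applied *across* the eleven variables.

Consistency note: with the published RPE effect size η² = 0.85, the identity
F = η²/(1−η²) · df_error/df_effect under the within-subject df (4, 36) gives
F = 51.0, matching the published F = 50.03 within the rounding of η² — which
is why the within-subject df is the one implemented (a between-groups df of
(4, 45) is also available via the AnovaResult fields but is not the model).

## 5. 1D SPM with random field theory

For each condition vs baseline, and separately for force and power curves:

1. **Paired t-field** on the n athlete difference curves, node-wise; nodes
   with zero difference variance are masked (t undefined there).
2. **Smoothness**: residuals (differences minus their node-wise mean) are
   unit-variance normalized per node; FWHM = √(4 ln 2) / RMS gradient of the
   normalized field, averaged over nodes (the gradient-based estimator
   standard for 1D Gaussian fields). Resel count R = Q_effective / FWHM,
   masked nodes excluded.
3. **Critical threshold**: t\* solves, by monotone root finding,
   P(max |T| > t\*) ≈ S_ν(t\*) + R·(√(4 ln 2)/2π)·(1 + t\*²/ν)^{−(ν−1)/2} = α
   — the two-term Euler-characteristic expansion for a 1D t-field with
   ν = n−1 df; the two-tailed test splits α between tails. As R → 0 this
   reduces to the uncorrected t quantile.
4. **Clusters**: maximal runs with |t| > t\*, endpoints refined by linear
   interpolation and reported to 0.1% of normalized time; extent measured in
   resels. Cluster p-values use the Poisson clumping heuristic with the 1D
   extent distribution P(ext ≥ k) = exp(−βk²),
   β = (Γ(3/2)·E[clusters]/E[supra-threshold resels])².

Inference is **two-tailed** by default (fatigue usually depresses the curves,
but direction is not pre-declared) and each condition-vs-baseline comparison
is reported separately, without correction across the four comparisons; both
choices are flags.

Validation is by independent Monte-Carlo oracle: on smooth Gaussian null
fields of known FWHM the familywise error of t\* and the full pipeline's
any-cluster rate sit inside the binomial 95% band of α = 0.05 (3,000 and
2,000 replicates in the test suite), and the smoothness estimator recovers a
known FWHM of 12 nodes within ±15% over 500 replicates.

## 6. The synthetic jump generator

The generator is built in **velocity space** so that Newtonian consistency is
guaranteed rather than approximated: drawing force shapes directly would make
"integrate the force" and "the velocity that generated it" two different
things.

COM velocity is a clamped cubic Hermite spline through six knots: onset
(v = 0, slope 0), mid-unweighting, the velocity minimum at 70% of the
eccentric duration (unweighting is longer than braking), the upward zero
crossing exactly at the eccentric duration, the velocity peak at 97% of the
concentric duration, and take-off (v = v_to, slope −g — the plate force
reaches zero exactly at take-off). Knot slopes are scaled so the implied
force is non-negative everywhere; a parameter combination that would require
the COM to out-accelerate free fall raises an explicit infeasibility error,
and `feasible_downward_velocity_limit` exposes the analytic ceiling
(peak interior spline slope = 1.50·v_min/t_min). Phase durations are snapped
to whole sample intervals so take-off falls exactly on the sampling grid.

Force is F = m(g + dv/dt) with the exact spline derivative, wrapped with
quiet standing at body weight (1.5 s), a flight phase of duration 2·v_to/g at
zero force, and a half-sine landing transient (peak 2.5 body weights,
0.15 s). Additive white Gaussian noise (default sd 5 N — small relative to
body weight, as for a commercial plate) is clamped at zero: a plate cannot
pull.

**Defaults** describe a strong sprint athlete's baseline jump and were chosen
once, from the population the pipeline is meant to emulate: body mass
70 kg, eccentric/concentric durations 0.35/0.25 s, peak downward velocity
1.35 m/s, take-off velocity 3.08 m/s (≈49 cm jump height, ED:CD ≈ 0.71).
Peak force and peak power then *emerge* from the waveform at ≈27 N/kg and
≈56 W/kg; they are not calibration targets (see limitations).

**Fatigue effects** per condition combine (i) multiplicative scales on the
durations and velocities and (ii) a fractional force deficit over a window of
normalized time (default 50–75%: the early concentric push), applied with
2.5%-wide cosine tapers so force stays continuous. The realized take-off
velocity is re-measured from the modified force, so the flight phase stays
consistent; the default `takeoff_velocity_scale` values account for the
impulse the windowed deficit spends. The shipped per-condition defaults
emulate a large deficit 3 min after high-intensity sprinting that resolves
over 24 h in the eccentric parameters but persists as an early-concentric
force deficit.

**Cohorts** (default 10 athletes × 5 sessions × 3 trials) draw lognormal
multipliers: between-athlete sd 0.13/0.14/0.055 on the durations and take-off
velocity, within-athlete 0.04/0.04/0.015; the downward-velocity multiplier is
coupled to the eccentric-duration multiplier (exponent 0.6, residual sd 0.12)
because deeper countermovements both last longer and descend faster — and
because the coupling keeps random athletes clear of the free-fall ceiling
(residually infeasible draws are clamped to it). Session RPE is drawn from
condition-level Borg means (10.4, 18.8, 16.6, 11.0, 9.2) with sd 1.2, rounded
and clipped to 6–20. A fixed seed reproduces the cohort bit-identically.

### What the generator does and does not emulate

It reproduces the *geometry* of real CMJ traces (quiet standing, unweighting,
braking, push-off, flight, landing), realistic variable scales, plausible
between/within-athlete variability, and fatigue signatures localized in
normalized time. It does **not** simulate muscle mechanics or EMG, horizontal
forces, systematic waveform idiosyncrasies of individual athletes
(multi-peaked push-offs), drift or colored plate noise. Passing tests
therefore demonstrate that the *analysis chain* is correct and calibrated —
not that any particular physiological interpretation of real recordings is.

## 7. Problem sizes in the validation suite

Monte-Carlo sizes were chosen to make the binomial confidence bands
informative while keeping the suite quick: 2,000 replicates for the
field-level and matrix-level type-I-error checks, 3,000 for the threshold
calibration, 500 for smoothness recovery, 200 full synthetic studies
(n = 10, one trial per condition) for deficit-detection power, 150 waveform
cohorts for the end-to-end null check, 100 noise-free trials for physics
closure, and 50 random matrices for oracle agreement (ANOVA F/ε/W to 1e-8
against pingouin). The acceptance script uses 1,000 / 100 / 50 replicates
for its recomputed rates.

## 8. Known limitations

- The published variable set this pipeline mirrors is internally inconsistent
  on one point: a concentric impulse of 3.08 Ns/kg over 0.25 s implies a mean
  concentric force of ≈22 N/kg, which no waveform can reconcile with a *peak*
  force of ≈17 N/kg. The generator is calibrated to JH/durations/impulses;
  its PF (≈27 N/kg) and PP land where the physics puts them.
- Onset/take-off thresholds in field practice vary; exact index-level
  agreement with any specific lab's event picks is not guaranteed (both
  thresholds are configurable).
- The RFT cluster p-value uses the standard Poisson-clumping approximation;
  it is accurate for the small supra-threshold clusters relevant at α = 0.05
  but is an approximation, and only the *any-cluster* rate is Monte-Carlo
  calibrated here.
- ANOVA requires complete athlete × condition matrices; sessions with missing
  athletes are skipped with a warning rather than imputed.
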