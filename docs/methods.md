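# Methods

## The measurement chain

One session is a frame table: frame counter, timestamp (s), excitation-LED
state, mean ROI pixel intensity. The session statistic is the mean LED-on
intensity minus the mean interleaved LED-off intensity over the interleaved
window (default seconds 60–120 of a 120 s session). The LED-off frames are a
contemporaneous control for ambient light and motion: any additive signal
common to both frame classes cancels in the difference, up to the sampling
error of two interleaved means. The dark lead-in (first minute) is settling
time and enters no computation.

ΔFRET(t) = 100·(F_t − F_0)/F_0 against the same animal's pre-dose session.
The hour-0 entry is exactly 0 by construction. A non-positive baseline F_0
is a hard error, not a warning: the ratio changes sign with the baseline, so
a failed baseline silently corrupts every downstream number.

Day summaries: max and min ΔFRET over all recorded hours (hour 0 included;
its value 0 anchors max ≥ 0 ≥ min), and the trapezoidal AUC over hours 0–3
in %·h. When an hour is missing, max/min use the available hours but the
AUC is reported unavailable (NaN): a trapezoid over a gapped grid is a
different quantity, and interpolating would manufacture data. Frames are
weighted equally within the window; dropped frames are counted by QC but not
imputed — means are robust to them.

## The simulator

Generative model, per animal and treatment day:

* Intact sensor pool: dS/dt = k_syn − (k_deg + k_cl·a(t))·S, starting at the
  pre-dose steady state S₀ = k_syn/(k_deg + k_cl·a₀).
* Calpain activity: a(t) = a₀·(1 ∓ m·B(t)) with B a Bateman onset/washout
  curve (rates k_on, k_off) normalised to unit peak; minus for inhibitors,
  plus for activators; k_off = 0 models a sustained effect (B → 1). An
  inhibitor magnitude m ≥ 1 is rejected — activity would go negative.
* Frames: LED-on intensity = gain(t)·S(t) + ambient (+ artifact + noise);
  LED-off = ambient (+ artifact + noise). gain(t) = gain·exp(−β·τ_on) with
  τ_on the cumulative LED-on seconds of the day; bleaching accrues only
  under excitation and resets between treatment days (washout ≥ 24 h plus
  continuous synthesis replaces bleached protein).
* Cohorts: per-animal lognormal multipliers (unit mean, CoV `jitter_cv`) on
  k_syn and gain model viral-expression variability; treatment order is a
  cyclic Latin square. Because ΔFRET is a within-animal ratio, this
  between-animal scale heterogeneity cancels in expectation — matching the
  design logic of each animal serving as its own control.

Closed-form anchors: with constant activity the pool sits at its fixed
point; with k_deg = 0 and sustained fractional inhibition f the plateau is
S_ss/S₀ = 1/(1−f), i.e. ΔFRET_ss = 100·f/(1−f) %. These anchor both the
test suite and the effect-size calibration helper
(`magnitude_for_delta_fret` inverts the steady-state map for k_deg ≥ 0).

### Default parameters (units, value, why)

| parameter | default | rationale |
|---|---|---|
| k_syn | 100 u/h | sets the fluorescence scale: S₀ ≈ 31 counts at unit gain |
| k_deg | 0.2 /h | slow activity-independent turnover (t½ ≈ 3.5 h) |
| k_cl·a₀ | 3 /h | cleavage dominates turnover; pool response time ≈ 19 min, consistent with drug effects visible well within the first hour |
| a₀ | 1 | basal activity is the unit of the activity scale |
| gain | 1 count/u | free scale; jittered per animal |
| ambient | 5 counts | dark/stray-light floor |
| noise_sd | 2 counts | per-frame noise; with ~1230 frames per state the session FRET SEM is ≈0.08 counts, so ΔFRET resolves ~0.4% |
| bleach_rate | 1e-5 /s | at 30 s of LED-on per session, ~0.1% gain loss by hour 3 — "brief recordings" keep bleaching well under the noise floor |
| fps | 41 | camera rate; 60 s interleaved → 2460 frames, ~1230 per LED state |
| k_on / k_off | 6 / 0.3 /h | onset visible within ~10 min; washout over several hours |
| jitter_cv | 0.3 | viral-expression variability across animals |

The simulator emulates: interleaved acquisition, the dark lead-in, the
0/1/2/3 h session schedule, drug onset/washout, photobleaching, common-mode
artifacts, frame noise, per-animal expression heterogeneity, Latin-square
ordering, and day-resetting washout. It does **not** emulate: camera shot
noise (noise is additive Gaussian), image-level ROI extraction, calcium
dynamics upstream of calpain activity, within-day carry-over between
treatments, or slow month-scale sensor-expression decay. A green simulation test
therefore establishes that the *analysis* is correct under the stated
generative model — not that the model captures every property of real
recordings.

## Numerical choices

* ODE solver: fixed-step classical RK4 with steps ≤ 1 s. The right-hand
  side is affine in S, so each RK4 step collapses to S_{n+1} = αS_n + β with
  coefficients precomputed from the loss rate at step nodes and midpoints —
  bit-identical to textbook RK4, but vectorisable. Verified against a
  tight-tolerance adaptive integrator to <0.1%.
* The pool ODE is linear in k_syn, so cohort simulation solves one
  unit-synthesis trajectory per treatment profile and scales it per animal —
  an exact identity, not an approximation.
* Interleaving starts LED-off after the lead-in, but the LED-state column is
  authoritative downstream; no parity assumption is made when analysing.
* The "flat data" convention: an ANOVA term whose effect sum of squares is
  exactly zero together with a zero error stratum reports F = 0, p = 1
  rather than NaN.
* Determinism: one `numpy` Generator seeded from the cohort seed drives all
  noise in file order; fixed seed ⇒ byte-identical recordings, manifests and
  summary CSVs.
* The steady-state oracle tests run with noise, bleaching and artifacts all
  off: the closed form describes the uncorrupted kinetics, and each
  corruption has its own dedicated test.

## Statistics layer

* Two-way RM ANOVA (time × treatment, both within subject) uses the
  classical stratified decomposition on complete balanced data. Hour-0 cells
  (identically zero) are kept: they contribute no variance and rescale
  effect and error strata identically, leaving F ratios calibrated — the
  type-I error of the treatment term on null cohorts is verified to sit
  near 5%.
* Missing cells: with `allow_missing=True` the fallback is a REML linear
  mixed model with a random intercept per animal, sum-to-zero coding (so
  Wald tests are orthogonal type-III main effects), and
  containment/between-within denominator df (n_obs − rank(X) − (n_subjects
  − 1)). Satterthwaite df are not available in the underlying library; at
  these balanced sizes the difference is small, and the original
  mixed-model df convention this mirrors is itself unspecified. On large
  balanced cohorts the mixed-model F agrees with the classical F to within
  Monte-Carlo error (verified at ~2% with 1500 subjects; finite-sample
  agreement cannot be tighter because the two procedures pool error strata
  differently).
* No sphericity correction by default (`gg_correction=True` opts in).
* Zero-variance t-test inputs are errors: silent degeneracy hides broken
  fixtures.
* All tests are two-sided at α = 0.05. Genotype is carried through the
  tables but not modelled by default (cohorts are analysed combined).

## Known limitations

* No photobleaching correction or isosbestic-style channel: the LED-off
  control carries no fluorescence, so bleaching biases ΔFRET slightly
  negative. The method is reproduced as practised; with the default bleach
  rate the bias (~0.1%) is far below the noise floor.
* The mixed-model fallback's p-values are approximate in small, very
  unbalanced designs (df convention above).
* AUC refuses gapped days rather than interpolating; analyses needing those
  days should use max/min ΔFRET or the mixed model on the long table.
* Densitometry takes pre-summed fragment band densities; image
  quantification is out of scope.
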