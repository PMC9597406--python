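# Methods

This note records the models, conventions and design decisions behind
`gaitcosts`, in the order the pipeline runs.

## Gait events

Initial foot contacts are upward crossings of a relative threshold,
2% of the record's peak vertical GRF: the contact index is the first
sample at or above the threshold following a sample below it (0-based;
no sub-sample interpolation — at 2000 Hz the 0.5 ms resolution is far
below any tolerance used downstream). A 0.2 s refractory period after
each contact suppresses noise chatter around the threshold; it is an
order of magnitude below walking stride times (~1.1 s) and so cannot
merge true contacts. Only the threshold itself is a measurement
convention inherited from the treadmill protocol; the crossing
direction and refractory guard are this package's choices, made
explicit and configurable.

A relative threshold on a smooth force rise implies a deterministic
detection latency: for a half-sine stance of duration `T_s`, the 2%
crossing sits `arcsin(0.02)·T_s/π ≈ 4.1 ms` (for `T_s` = 0.65 s) after
true onset, plus at most one sample of quantization. Stride *durations*
are unaffected (the latency cancels between consecutive contacts);
absolute contact times carry it, which is why the generator's recovery
contract is ±5 ms.

## EMG envelopes and activation rates

Channel mean removal → 20–350 Hz band-pass → full-wave rectification →
6 Hz low-pass, with fourth-order Butterworth filters applied
forward–backward (`sosfiltfilt`). Zero-phase filtering is standard EMG
practice because it preserves burst timing relative to the GRF events;
the nominal order is 4 per stated cutoff with no cutoff correction for
the double pass. Low-pass undershoot below zero is clipped. Every stage
is positively homogeneous, so envelope, activation rates and costs all
scale linearly (or, for C̄a², quadratically) with input gain — a
property the tests exploit.

Per stride, `a_ij` is the trapezoidal time-average of the envelope over
`[contact_j, contact_{j+1}]`; dividing by `T_j` makes it a recruitment
*rate*, insensitive to stride duration for stationary envelopes. Five
strides per trial are analysed: the first five artifact-free complete
strides of the record, where artifact-free means no channel exceeds a
configurable saturation bound (disabled by default for synthetic data).
Which five of a longer recording to use is a genuine free choice; this
rule is deterministic and logged. Normalization (`A_ij`) divides by the
muscle's 5-stride mean from the participant's own 0%-incline trial, so
that trial's per-muscle mean normalized activation is exactly 1. A
muscle excluded for artefact propagates as missing, and any cost over
an incomplete table raises rather than silently renormalizing — the
analysis drops participants, not muscles.

## Metabolic power

Unweighted means of V̇O₂ and V̇CO₂ (L s⁻¹) over the closed final-minute
window feed `C_met,P = 1000(16.89 V̇O₂ + 4.82 V̇CO₂)/M` in W kg⁻¹. No
cost-per-distance conversion is applied (belt speed is constant across
the conditions compared). No RER validity screen rejects data — a
window-mean RER above 1.05 logs a warning only. At least five breaths
must fall in the window.

## Cost functionals

All three activation costs instantiate `C̄_j = Σ w_i A_ij^p / Σ w_i`,
computed per stride first and then averaged over the five strides (for
the max cost this order — max within stride, then average — matters and
is fixed). The infinite exponent is represented symbolically
(`math.inf` selects an exact per-stride max, not a large-p power). The
volume weights are fixed at the printed two-decimal proportions
(Gmax 0.33, BF 0.08, RF 0.10, VM 0.17, MG 0.10, SOL 0.17, TA 0.05,
summing to 1.00) rather than recomputed from an anatomical atlas, so
the arithmetic is exactly reproducible.

A useful validation identity: the p-th root of the *unnormalized*
equal-weight cost pins the per-stride max within ~1% already at p = 64;
the normalized mean form carries an extra `(1/7)^(1/p)` factor (≈0.970
at p = 64) that vanishes only in the limit. The tests assert both.

## CCP rule and percentages

Crouch cost is the arithmetic mean of the initial and final crouch
trials (initial/final alone are selectable for sensitivity checks). A
CCP is accepted when crouch metabolic power is strictly below, and the
activation cost strictly above, the pre-transition incline's value;
exact ties yield no CCP. All percent changes use the pre-transition
incline value as denominator — for both the activation advantages and
the metabolic penalty. That denominator convention was validated
against the packaged worked-example table: it is the only choice of the
two candidates (incline vs crouch denominator) that reproduces all of
the table's published summary endpoints, including the one participant
with a 210% C̄a² reduction. Non-monotone choice sequences (an incline
selected above a crouch selection) are flagged and excluded from CCP
summaries by default, since the construct presumes a single transition.

Group comparisons (crouch vs pre- vs post-transition) screen each
condition with Shapiro–Wilk at 0.05; if all pass, a one-way
repeated-measures ANOVA with paired-t post-hocs, otherwise Friedman
with Wilcoxon signed-rank post-hocs (exact small-sample p-values via
scipy's defaults). Post-hocs run only after a significant omnibus test
(α = 0.05) and are judged at the Bonferroni-adjusted α = 0.017.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth stored alongside every trial:

* **Stride schedule** — lognormal multiplicative jitter on stride times
  (default mean 1.1 s, cv 0.03); stance duration fixed at 0.65 s. The
  fixed stance keeps the GRF threshold latency deterministic and under
  the 5 ms recovery contract; its side effect is that the stance burst
  occupies a varying fraction of jittered strides, adding ~2–3% spread
  to single-trial activation ratios.
* **EMG** — unit-RMS Gaussian carrier band-limited to 20–350 Hz (so the
  analysis band-pass leaves it statistically intact), amplitude-
  modulated by a raised-cosine burst spanning stance and scaled by the
  condition gain: `baseline_i·(1 + slope_i·grade)` on inclines,
  `baseline_i·crouch_gain_i` in crouch. Rectification of a modulated
  Gaussian has mean proportional to its instantaneous amplitude, so the
  expected envelope — hence every downstream activation quantity — is
  proportional to the gain, and between-condition ratios recover gain
  ratios. `carrier="sine"` substitutes a deterministic in-band 150 Hz
  sinusoid for noise-free validation: with stride jitter also disabled,
  recovery is exact to filter edge effects (relative error < 1e-3).
  Swing-phase EMG is exactly zero (no sensor noise floor by default,
  configurable); real recordings have baseline noise, crosstalk and
  motion artefact that the generator does not emulate, so passing
  recovery tests validate the pipeline's arithmetic, not its robustness
  to recording pathology.
* **GRF** — one half-sine per stance, peak 1.2·m·g, exactly zero in
  swing, constant peak across strides. Real treadmill GRFs are
  double-humped with impact transients; the half-sine is deliberately
  minimal since only threshold crossings are consumed.
* **Gas exchange** — breaths at ~15 min⁻¹ with 10% timing jitter; rates
  rise as `target·(1 − e^(−t/τ))` with τ = 30 s and carry independent
  5% multiplicative Gaussian noise per breath; V̇CO₂ = RER·V̇O₂.

Cohort defaults place the simulated population near the study cohort
(mass 69.6 ± 11.1 kg, height 1.70 ± 0.07 m, n = 10) with level-walking
metabolic power ~4.3 W kg⁻¹, crouch ~1.8× level, incline power rising
~7.5% of level per % grade, and crouch knee-extensor gains ~3.5× with
other muscles 1.2–1.5×. Under these values crouch is metabolically
cheaper than the 18% and 24% inclines but carries a higher C̄a² than
any incline up to ~18%, so a composite-objective chooser that weights
activation (default weights w_met = 1, w_act = 2 on costs rescaled to
the 0% trial) selects the incline through 18% and crouches at 24% —
a single steep-grade transition that yields a CCP, mirroring the
behavioural pattern the paradigm is designed to elicit. Ties select
the incline. The activation term of the composite objective is C̄a²,
the least extreme fatigue-like cost; alternatives are configurable.

Reproducibility: one cohort seed; per-trial seeds derive from
(cohort seed, participant id, condition) via a CRC hash, so streams are
independent but everything reproduces bit-identically from one integer.

## Tolerances and problem sizes

Validation contracts against generator ground truth, and why their
scales are what they are:

* Scheduled contacts recovered within ±5 ms per contact: deterministic
  latency bound 4.1 ms + 0.5 ms quantization (see above).
* Final-minute metabolic power within 2% of the steady-state target as
  a cohort-level mean absolute error. A single trial's final-minute
  mean over ~15 breaths with 5% per-breath noise has a ~1.3% standard
  error, so the worst trial of a 70-trial cohort routinely exceeds 2%
  by sampling alone; the per-trial check is asserted at a looser 6%,
  and the 2% contract is on the cohort mean. With τ = 30 s, the rise
  term biases the final minute of a 300 s trial by ~0.1%, negligible.
* Per-muscle activation ratios within 5% of gain ratios at the cohort
  level (per muscle, averaged over participants). Single-trial
  five-stride ratios carry ~3–4% standard error from envelope noise
  (6 Hz-bandwidth fluctuations averaged over ~0.65 s bursts) plus the
  stride-jitter effect, so the 5% contract is placed on the cohort mean
  where the standard error is ~1%; exactness per trial is asserted in
  the noise-free configuration instead.

Test and acceptance runs use the study's own problem sizes — 10
participants × 7 trials of 300 s at 2000 Hz — which the pipeline
analyses streaming one participant at a time (~35 s total); unit tests
use 90–240 s trials and 2–4 participants.

## Known limitations

* The generator's condition structure is linear in grade and
  multiplicative in crouch; real per-muscle responses are neither, and
  published figures report the crouch knee-extensor inflation only
  graphically, so the crouch gain magnitudes are synthetic choices.
* No artefact classifier: channel exclusion is a manual flag, mirroring
  participant-level exclusion rather than automated repair.
* The choice model is a deterministic composite-cost minimizer; it
  reproduces the qualitative single-transition pattern, not the
  between-participant variability of real preference behaviour.
* Statistical routines assume the matched-triples design; no missing-
  data handling beyond explicit errors, and no mixed-effects modeling.
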