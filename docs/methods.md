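# Methods

## The intervention loop being modelled

`addhrvr` implements the computational core of a heart-rate-variability
(HRV) triggered just-in-time intervention system and the microrandomized
trial (MRT) used to evaluate it:

1. **Calibration.** On one 12-hour day (9:00–21:00), per-minute RMSSD (root
   mean square of successive interbeat-interval differences, ms) is
   regressed on bodily movement (metabolic equivalents, MET) by ordinary
   least squares, per person. The fitted line `intercept + slope * MET`
   predicts movement-explained RMSSD; the dispersion `SD` is the sample SD
   of the person's valid calibration-day RMSSD. Persons with a non-negative
   slope are ineligible and excluded: under the model, movement should
   suppress vagally mediated HRV.
2. **Flagging.** On subsequent days, a minute is an *additional*
   (nonmetabolic) HRV reduction when observed RMSSD ≤ predicted − k·SD
   (k = 0.5, boundary inclusive). Missing minutes never flag.
3. **Triggering.** A prompt is emitted at the first minute whose trailing
   28-minute window (inclusive) holds ≥ 13 flagged minutes, subject to a
   60-minute refractory ("silence") period — at most one rule trigger per
   hour. Random prompts are scheduled independently, uniformly with a
   minimum gap.
4. **Outcomes.** Around each prompt: the mean of per-minute ln-HRV over the
   10 minutes before (time code −1), the intervention phase with a
   ±2-minute timing tolerance (code 0), and the 10 minutes after (code +1).
   The log is taken per minute *before* averaging; only artifact-valid
   minutes enter; a window with no valid minutes is missing.
5. **Estimation.** A linear mixed model per outcome: fixed effects are
   centered MET, momentary smoking, the within-person-centered trigger
   indicator, two time contrasts (pre→during, pre→post) and their
   interactions with trigger (plus the intervention factor and the
   three-way interaction in a two-intervention design); random intercepts
   for person and for prompt. The trigger×time(post) coefficient is the
   proximal effect of prompting at a detected vulnerable moment rather than
   at random.
6. **Controls.** An offline scan finds *virtual* triggers: minutes
   satisfying the same 13-of-28 rule that never caused a prompt (usually
   silenced). Their pre/post windows, kept at least 10 minutes clear of any
   real intervention, estimate spontaneous HRV rebound; the
   (rule-vs-virtual)×time contrast separates intervention effect from
   spontaneous recovery.

## Variance structure of the mixed model

Windows are nested in prompts nested in persons. The model therefore
carries a person random intercept (variance τ00) and a prompt-level
variance component (τ_prompt): the three windows of one prompt share the
person's momentary state, and ignoring that component inflates the Wald SE
of the within-prompt trigger×time contrast by roughly a factor two
(empirically, null z-scores with SD ≈ 0.5 instead of 1.0). Reported
`sigma2` is the total within-person variance (prompt component + window
residual), so ICC = τ00 / (τ00 + σ²). Fixed-effect inference is Wald
(large-sample normal), matching the reported CIs' construction. Covariates
with no variation in the data (e.g. an all-non-smoker cohort) are dropped
from the design rather than producing a singular fit.

## Window geometry

With the prompt at time *t* and a 1-minute intervention starting at *t*:
pre = [t−600 s, t), during = [t−60 s, t+180 s) (the intervention minute
widened by the symmetric ±2-minute timing-tolerance reading), post =
[t+60 s, t+660 s). A minute belongs to a window when fully contained in its
span. Windows truncated by the day edge are kept when at least
`min_minutes` (default 3) valid minutes remain, and flagged. Note one
consequence of the tolerance window: an effect confined to the intervention
minute appears in the during-window mean diluted by the 4-minute span
(≈ one quarter of its per-minute size); pre and post estimands are
undiluted because the boost horizon and the window coincide.

## The synthetic-data generator

There is no public deposited dataset for this design, so the generator is a
first-class module: every downstream stage is tested against data whose
generating process is known.

Per person-day, minute RMSSD is

    RMSSD(t) = max(intercept + slope·MET(t) + ε(t) − depth(t), 5 ms)
               · exp(day level + intervention boosts + smoking effect)

* **Movement.** MET follows a Markov bout model (sedentary ≈ 1.3, walking
  ≈ 3, exercise ≈ 6 MET; geometric dwell times, floored at 0.9 MET).
* **Noise.** ε is white with SD `noise_sd` = 5 ms. The 5-ms floor is a
  physiological lower bound; the log-scale day level is available
  (`day_sd`) but defaults to 0 (see *Design notes*).
* **Episodes.** Discrete vulnerability episodes suppress RMSSD by
  `episode_depth` = 2.0 units of the person's movement-plus-noise
  dispersion (lognormal jitter across episodes, CV 0.2). Episodes arrive as
  a Poisson process (2/day), last 95 + Exp(5) minutes, and are placed at
  least 90 minutes apart.
* **Closed loop.** Intervention days are simulated minute by minute: values
  are flagged against the *fitted* calibration from a simulated calibration
  day, streamed through the trigger rule with silence, and each prompt
  (rule-based or random) feeds multiplicative boosts into later minutes —
  a main during/post effect for every intervention (0.17 / 0.03 ln-units),
  plus the rule-triggered extras: `during_boost` (0.08, applied only when
  the intervention lands in a low state) and `post_boost` (0.12, the
  estimand of trigger×time(post)).
* **Beats.** Optionally each minute is expanded into an interbeat series:
  white Gaussian intervals around a movement-modulated mean (RMSSD of iid
  intervals with SD σ is σ√2), exactly rescaled so the realized minute
  RMSSD equals its target, and mean-shifted to fill the minute exactly —
  the per-minute feature extraction recovers the target to numerical
  precision. Respiratory-band structure is *not* modelled here; spectral
  tests synthesize sinusoidal modulations directly.
* **Self-reports.** Latent momentary stress = person baseline +
  0.8 (Likert) inside episodes + noise; four 1–5 items scatter around it,
  three stored reverse-coded as collected; the post rating adds the
  pre→post time effect (−0.12 stress, −0.11 rumination). Items are
  continuous within [1, 5] (slider-style), so noise-free configurations
  shift scores exactly. Dispositions are sampled with probabilities
  (answered .69, dismissed .04, ignored .19, incomplete .08).

### Design notes (why these defaults)

The generator's contract includes an *estimand identity*: the mixed model's
trigger×time(post) coefficient must recover `post_boost`. Three mechanisms
can break that identity in a closed-loop design, and the defaults are
chosen so that each is negligible rather than merely small:

1. **Rebound contamination.** If an episode can end inside a trigger's
   post window, spontaneous recovery masquerades as intervention effect.
   Episode minimum length (95 min) exceeds detection window + silence +
   post horizon for the trigger phases the silence cycle produces, and the
   90-minute episode spacing prevents silence carry-over from one episode
   randomizing the next one's trigger phase. Gradual onset/offset ramps
   were evaluated and rejected: with ramps, triggers fire on the recovery
   slope itself, which is worse than a rare sharp boundary.
2. **Selection (regression to the mean).** Borderline triggers select
   windows with negative noise. Depth 2.0 dispersion units with 5-ms noise
   makes in-episode flags near-certain and out-of-episode flags rare, so
   conditioning on the trigger carries almost no information about the
   noise. A day-level log-normal level was found to re-introduce this
   pathway (miscalibrated days produce bursts of borderline triggers),
   hence `day_sd = 0` by default; set it > 0 to study that failure mode
   deliberately — it is exactly the calibration-generalizability problem
   ambulatory deployments face.
3. **Floor clipping.** A raw-linear movement line that crosses zero at high
   MET produces floor-clipped minutes whose log values distort both the
   calibration fit and the MET adjustment; the default line (60 − 8·MET)
   stays positive over the bout model's range. Calibration-recovery tests
   run in this linear regime and say nothing about recovery under heavy
   clipping.

Verified at the defaults (50 persons × 3 days): null-generator interaction
bias ≈ +0.003 ln-units, boosted-recovery bias ≈ +0.003 with 39/40 CI
coverage, and 3.1% rejection of the null interaction at nominal 5% over
200 scaled-down replicates.

### What the generator does not emulate

Real ambulatory RMSSD has circadian drift, posture and respiration
structure, ectopic beats, and far larger unexplained within-person variance
(published within-person residual variances on comparable window outcomes
are several times ours). Passing recovery tests therefore demonstrates the
*pipeline's* correctness — windows, centering, model, inference — under a
known generating process; it does not certify detector sensitivity or
effect sizes on real recordings.

## MRT sample size

For a constant standardized proximal effect d, randomization probability ρ,
expected availability τ and T decision points, the test of the proximal
effect has noncentrality λ = N d² τ ρ(1−ρ) T, and with the small-sample
correction power is read from a noncentral F with (p, N−q−p) degrees of
freedom, p = q = 1 for constant effect and availability trends:

    power(N) = 1 − F_{p,N−q−p;λ}( F⁻¹_{p,N−q−p}(1−α) ).

The minimal N is the smallest integer reaching target power. The occasion
count per day is an explicit input; **10 per day** is the package's
documented calibration: for the 4-day design (ρ = .40, τ = .75, power .80,
α .05) it is the unique integer count for which the procedure returns
N = 30 at d = 0.2 and N = 51 at d = 0.15 simultaneously (9/day gives
33 and 56; 11/day gives 27 and 47). The run summary records this note.

## Numerical and interface choices

* SDNN and the calibration SD use the sample (n−1) estimator.
* The flag criterion's SD is the *marginal* calibration-day SD by default;
  the residual SD is a constructor switch (`sd_mode="residual"`).
* Spectral band powers: cubic-spline interpolation of the tachogram to a
  4-Hz grid, linear detrend, Welch periodogram, trapezoidal band
  integration; a record must span two cycles of the band's lower edge.
* Artifact rules (a reproducible surrogate for the recorder's proprietary
  validation): successive-interval change > 30%, any interval outside
  [300, 2000] ms, or fewer than 30 beats in the minute → the minute is set
  to missing, never zero.
* The trailing trigger window includes the current minute (real-time
  causality); emission time is the end of the qualifying minute.
* Random prompt times use the spacing construction (uniform order
  statistics on the gap-reduced window), exact and rejection-free.
* Virtual triggers keep a ±10-minute buffer around real prompts and their
  intervention minute, and successive virtual events respect the silence
  spacing; they do **not** respect silence relative to real triggers —
  windows silenced by a real trigger are precisely the controls wanted.
* Disposition percentages are truncated (not rounded) to two decimals,
  which is the convention that reproduces the published tables.
* All randomness flows from one master seed through per-person
  `SeedSequence` spawns, so any person's data is invariant to cohort size
  and every artifact is byte-identical under a fixed seed.

## Known limitations

* Calibration is static; no within-study recalibration or drift handling.
* The mixed model treats overlapping windows of nearby prompts as
  independent residuals; prompts closer than the window span share minutes.
* Wald inference is first-order; no small-sample (Satterthwaite/KR)
  degrees-of-freedom correction is applied.
* The during-window estimand is diluted by the timing-tolerance span, as
  described above.
* Only the constant proximal-effect shape is implemented for MRT sizing.
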