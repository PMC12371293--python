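# addhrvr

Tools for heart-rate-variability (HRV) triggered just-in-time adaptive
interventions and their evaluation in microrandomized trials (MRTs).

Transient reductions of vagally mediated HRV that are *not* explained by
bodily movement — additional HRV reductions, **AddHRVr** — can mark moments
of psychophysiological vulnerability. A wearable system can exploit this:
calibrate each person's RMSSD-on-movement regression for one day, then flag
every minute whose observed RMSSD falls at least 0.5 SD below the
movement-predicted value, and push a one-minute intervention (paced or
mindful breathing) when **13 flagged minutes accumulate within a 28-minute
window**, with a 60-minute silence period between triggers. Comparing such
prompts against randomly timed ones in an MRT estimates the *proximal*
effect of intervening at the right moment.

This package implements that whole loop, plus the synthetic ambulatory data
needed to test it end to end, for researchers designing or analysing
HRV-triggered intervention studies:

* **`hrv`** — per-minute RMSSD, SDNN and LF/HF band power from interbeat
  intervals, with configurable artifact rules;
* **`calibration`** — the per-person movement calibration
  (`MovementCalibration → CalibrationResult`), eligibility (negative slope)
  and the k·SD flag rule;
* **`triggers`** — the streaming 13-of-28 trigger engine with silence,
  random-prompt scheduling, and the offline *virtual trigger* scan
  (qualifying windows that never prompted — no-intervention controls for
  spontaneous rebound);
* **`mrt`** — outcome windows (10 min pre / intervention ±2 min / 10 min
  post, per-minute ln before averaging), stress-scale scoring with reverse
  coding, and the proximal-effect mixed model
  (`ProximalEffectModel → ProximalEffectResults`) with person and prompt
  random effects, reference rescaling for three-way interactions, and the
  virtual-trigger rebound contrast;
* **`simulate`** — a closed-loop generator of person-days: movement-coupled
  minute RMSSD with person-specific negative slopes, episodic nonmetabolic
  suppression, real-time triggering feeding intervention boosts back into
  the stream, beat-level synthesis, and pre/post self-reports;
* **`design`** — MRT sample-size calculation for a constant proximal effect
  and prompt-disposition descriptives;
* **`pipeline` / CLI** — `addhrvr simulate|calibrate|detect|evaluate|design|summarize`
  over YAML configs with fully seeded, byte-reproducible CSV artifacts.

The model in brief: for person *i*, minute *t* of the calibration day,

    RMSSD_it = intercept_i + slope_i · MET_it + ε_it,        slope_i < 0,

and a later minute is flagged iff
`RMSSD_obs ≤ intercept_i + slope_i·MET − 0.5·SD_i`. Proximal effects are
estimated on window means of ln RMSSD (and ln SDNN, ln HF, ln LF) by

    ln HRV ~ MET_c + smoking + trigger_c + time + trigger_c×time
             (+ intervention_c and its interactions)
             + (1 | person) + (1 | prompt),

with trigger and intervention centered within person; `trigger_c × time(post)`
is the proximal effect of a triggered versus random prompt.

## Worked example

```python
from addhrvr import (MrtDesign, ProximalEffectModel, build_windows,
                     mrt_sample_size, simulate_study, summarize_prompts)

study = simulate_study(n_persons=20, n_days=3, seed=7)   # day 0 calibrates
windows = build_windows(study.minutes[study.minutes["day"] > 0], study.prompts)
result = ProximalEffectModel(windows).fit()

effect = result.proximal_effect("post")
print(f"trigger x time(post): b = {effect['estimate']:.3f} "
      f"(95% CI {effect['ci_low']:.3f} to {effect['ci_high']:.3f})")
print(f"ICC = {result.icc:.2f}; {result.nobs} windows from {len(study.prompts)} prompts")
print(summarize_prompts(study.prompts).to_string(index=False))
print("N(effect=0.2) =", mrt_sample_size(MrtDesign(effect=0.2)))
```

prints

```
trigger x time(post): b = 0.103 (95% CI 0.073 to 0.132)
ICC = 0.63; 3306 windows from 1108 prompts
disposition  count   pct
   answered    783 70.66
  dismissed     42  3.79
    ignored    193 17.41
 incomplete     90  8.12
N(effect=0.2) = 30
```

The generator put a 0.12 ln-unit post-intervention boost on rule-triggered
prompts; the fitted interaction `b = 0.103` recovers it within its CI — HRV
stays elevated for the 10 minutes after a triggered intervention relative
to a random one. The disposition table summarizes prompt compliance, and
the last line is the minimal MRT sample size for a 4-day trial powered at
0.80 for a constant standardized proximal effect of 0.2 (randomization
probability 0.40, availability 0.75, 10 occasions/day).

A full artifact set (minutes, triggers, virtual triggers, windows, model
terms, variance components, JSON run summary) comes from the pipeline:

```bash
addhrvr simulate --seed 11 --out runs/demo          # built-in demo config
addhrvr design --effect 0.15                         # -> minimal N = 51
```

See `docs/methods.md` for the model, the generator's assumptions and the
numerical choices.

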