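"""Synthetic ambulatory person-days with the structure the analysis assumes.

The generator emulates, per person: (i) movement-coupled minute RMSSD with a
person-specific negative slope on metabolic equivalents (MET); (ii) episodic
*nonmetabolic* RMSSD suppression — discrete vulnerability episodes during
which RMSSD drops by a configured number of dispersion units, the construct
the trigger rule is meant to detect; (iii) intervention-contingent HRV boosts
(multiplicative on the natural-log scale) during and after prompts; and
(iv) pre-to-post declines in momentary stress and rumination ratings.

Simulation of an intervention day is a *closed loop*: minute values are
produced in time order, flagged against the deployed calibration, streamed
through the trigger rule, and prompts feed boosts back into subsequent
minutes — exactly the causal structure of the deployed system.

Minute RMSSD is the generator's native resolution.  Beat-level interbeat
streams can additionally be synthesized per minute via the Gaussian-increment
relation (white IBI noise of SD sigma yields RMSSD sigma*sqrt(2)) followed by
an exact empirical rescale, so the per-minute feature extraction recovers the
targeted RMSSD to well under 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, MovementCalibration
from .hrv import DEFAULT_DAY_WINDOW, IbiSeries
from .triggers import TriggerConfig, TriggerEvent, detect_triggers, schedule_random

__all__ = [
    "PersonParams",
    "EffectParams",
    "MetModel",
    "generate_met_series",
    "place_episodes",
    "generate_ibis",
    "generate_selfreports",
    "simulate_person_day",
    "simulate_study",
    "SimulatedStudy",
]

_RMSSD_FLOOR = 5.0  # ms physiological floor; targets are clipped here, never zero


@dataclass(frozen=True)
class MetModel:
    """Markov bout model for per-minute MET values.

    Activity alternates between bouts (sedentary / walking / exercise) with
    geometric dwell times; within a bout the minute value is the bout level
    plus small noise, floored at 0.9 MET (resting metabolism is never lower).
    """

    levels: tuple[float, ...] = (1.3, 3.0, 6.0)
    within_sd: tuple[float, ...] = (0.1, 0.3, 0.6)
    dwell_minutes: tuple[float, ...] = (25.0, 8.0, 5.0)
    # switch destination probabilities, row = current state (self excluded)
    switch_to: tuple[tuple[float, ...], ...] = (
        (0.0, 0.85, 0.15),
        (0.9, 0.0, 0.1),
        (0.5, 0.5, 0.0),
    )

    def stationary(self) -> np.ndarray:
        """Stationary state distribution of the embedded minute-level chain."""
        k = len(self.levels)
        P = np.zeros((k, k))
        for i in range(k):
            stay = 1.0 - 1.0 / self.dwell_minutes[i]
            P[i] = [self.switch_to[i][j] * (1 - stay) for j in range(k)]
            P[i, i] = stay
        vals, vecs = np.linalg.eig(P.T)
        pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
        pi = np.abs(pi)
        return pi / pi.sum()

    def mean(self) -> float:
        return float(self.stationary() @ np.asarray(self.levels))

    def var(self) -> float:
        pi = self.stationary()
        lv = np.asarray(self.levels)
        ws = np.asarray(self.within_sd)
        m = pi @ lv
        return float(pi @ ((lv - m) ** 2 + ws**2))


@dataclass(frozen=True)
class PersonParams:
    """Person-level generator parameters.

    ``episode_depth`` is expressed in units of the person's
    movement-plus-noise dispersion (:meth:`base_sd`), so detector-sensitivity
    settings transfer across persons.  ``day_sd`` adds a log-scale day level
    (good and bad days) shared by a whole person-day — it widens the
    calibration dispersion realistically and, being constant within a day,
    cancels out of every pre/post contrast.
    """

    intercept: float = 60.0        # ms at MET = 0
    slope: float = -8.0            # ms per MET, < 0 for eligible persons
    noise_sd: float = 5.0          # ms, white minute-to-minute noise
    episode_rate: float = 2.0      # episodes per day (Poisson)
    episode_len: float = 100.0     # mean episode length, minutes
    episode_min_len: float = 95.0  # minimum length; tail is exponential
    episode_gap: float = 90.0      # minimum spacing between episodes, minutes
    episode_depth: float = 2.0     # suppression depth in base_sd units
    episode_depth_cv: float = 0.2  # lognormal spread of depth across episodes
    episode_ramp_in: float = 0.0   # optional minutes of linear onset
    episode_ramp_out: float = 0.0  # optional minutes of linear recovery
    day_sd: float = 0.0            # SD of an optional log-scale day level
    smoker: bool = False
    stress_baseline: float = 2.2   # Likert units
    rumination_baseline: float = 2.1
    met_model: MetModel = field(default_factory=MetModel)

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.episode_depth < 0:
            raise ValueError("noise_sd and episode_depth must be >= 0")
        if self.episode_min_len > self.episode_len:
            raise ValueError("episode_min_len cannot exceed the mean episode_len")

    @property
    def base_sd(self) -> float:
        """Movement-plus-noise dispersion of minute RMSSD (episode-depth unit)."""
        return float(np.sqrt(self.noise_sd**2 + self.slope**2 * self.met_model.var()))


@dataclass(frozen=True)
class EffectParams:
    """Effect sizes wired into the generator (the quantities recovery tests estimate).

    Boost terms act multiplicatively on minute RMSSD (log-scale shifts).
    ``during_boost`` and ``post_boost`` are the *additional* boosts when the
    intervention follows a rule trigger — ``post_boost`` is the estimand of
    the trigger-by-time(post) interaction; ``during_boost`` applies only when
    the intervention is actually delivered in a low (episode) state.
    ``time_main_*`` are the intervention main effects shared by every prompt.
    """

    time_effect_stress: float = -0.12     # Likert units, pre -> post
    time_effect_rumination: float = -0.11
    during_boost: float = 0.08            # ln ms, rule-triggered, low state only
    post_boost: float = 0.12              # ln ms, rule-triggered prompts
    met_effect: float = -0.35             # ln ms per MET; log-scale analogue of the
    # movement coupling targeted by the analysis model (bookkeeping; the raw
    # generator couples movement through the calibration line itself)
    smoking_effect: float = -0.03         # ln ms while smoking
    time_main_during: float = 0.17        # ln ms, any prompt, intervention minute
    time_main_post: float = 0.03          # ln ms, any prompt, 10 post minutes
    mindful_during_extra: float = 0.0     # ln ms, 3-way: rule trigger x mindful x during
    stress_episode_gain: float = 0.8      # Likert shift of pre-stress inside episodes
    stress_trigger_interaction: float = 0.0   # extra pre->post shift, rule-triggered
    rumination_trigger_interaction: float = 0.0


def generate_met_series(
    day_window: tuple[float, float],
    rng: np.random.Generator,
    model: MetModel | None = None,
) -> np.ndarray:
    """Per-minute MET values over the day window (Markov bout switching)."""
    model = model or MetModel()
    n = int((day_window[1] - day_window[0]) // 60)
    levels = np.asarray(model.levels)
    within = np.asarray(model.within_sd)
    k = levels.size
    state = int(rng.choice(k, p=model.stationary()))
    states = np.empty(n, dtype=int)
    i = 0
    while i < n:
        dwell = rng.geometric(1.0 / model.dwell_minutes[state])
        j = min(n, i + int(dwell))
        states[i:j] = state
        i = j
        state = int(rng.choice(k, p=np.asarray(model.switch_to[state])))
    vals = levels[states] + rng.normal(0.0, 1.0, size=n) * within[states]
    return np.maximum(vals, 0.9)


def place_episodes(
    person: PersonParams,
    day_window: tuple[float, float],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[tuple[int, int]]:
    """Non-overlapping vulnerability episodes as [start, end) minute indices.

    The number of episodes is Poisson(``episode_rate``); lengths are
    ``episode_min_len`` plus an exponential tail with the mean chosen so the
    overall mean equals ``episode_len`` (``episode_min_len = 0`` gives the
    plain exponential).  Episodes are placed uniformly and re-drawn on
    overlap; an episode must start and end inside the day window.
    """
    n_min = int((day_window[1] - day_window[0]) // 60)
    n_ep = rng.poisson(person.episode_rate)
    gap = int(person.episode_gap)
    taken: list[tuple[int, int]] = []
    for _ in range(n_ep):
        tail = person.episode_len - person.episode_min_len
        for _try in range(max_tries):
            length = person.episode_min_len + (rng.exponential(tail) if tail > 0 else 0.0)
            length = max(1, int(round(length)))
            if length >= n_min:
                length = n_min - 1
            start = int(rng.integers(0, n_min - length))
            end = start + length
            if all(end + gap <= s or start >= e + gap for s, e in taken):
                taken.append((start, end))
                break
    return sorted(taken)


# ---------------------------------------------------------------------------
# closed-loop person-day simulation (minute resolution)
# ---------------------------------------------------------------------------

_DISPOSITIONS = ("answered", "dismissed", "ignored", "incomplete")
_DISPOSITION_P = (0.69, 0.04, 0.19, 0.08)


def _episode_depth_profile(
    person: PersonParams,
    episodes: Sequence[tuple[int, int]],
    n: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-minute suppression depth (ms): trapezoidal profile per episode.

    Vulnerable states set in and resolve gradually: depth ramps linearly over
    ``episode_ramp_in`` minutes, holds a plateau, and recovers over
    ``episode_ramp_out`` minutes.  The plateau depth is ``episode_depth``
    dispersion units, jittered across episodes by a lognormal factor.
    """
    depth = np.zeros(n)
    for s, e in episodes:
        length = e - s
        mult = (
            rng.lognormal(0.0, person.episode_depth_cv)
            if rng is not None and person.episode_depth_cv > 0
            else 1.0
        )
        d = person.episode_depth * mult * person.base_sd
        prof = np.ones(length)
        rin = min(int(person.episode_ramp_in), length // 2)
        rout = min(int(person.episode_ramp_out), length - rin)
        if rin > 0:
            prof[:rin] = np.arange(1, rin + 1) / (rin + 1)
        if rout > 0:
            prof[length - rout:] = np.arange(rout, 0, -1) / (rout + 1)
        depth[s:e] = d * prof
    return depth


@dataclass
class _DayResult:
    minutes: pd.DataFrame
    prompts: pd.DataFrame
    triggers: list[TriggerEvent]
    flags: np.ndarray


def simulate_person_day(
    person: PersonParams,
    effects: EffectParams,
    rng: np.random.Generator,
    calibration: CalibrationResult | None,
    config: TriggerConfig | None = None,
    person_id: str = "p0",
    day: int = 1,
    study: int = 1,
) -> _DayResult:
    """Simulate one person-day at minute resolution.

    With ``calibration=None`` the day is a plain observation day (the
    calibration day): no flags, prompts or boosts.  Otherwise the deployed
    calibration drives AddHRVr flags, the trigger rule runs online with
    silence, random prompts are pre-scheduled, and each prompt's intervention
    feeds multiplicative boosts into the following minutes.
    """
    config = config or TriggerConfig()
    window = config.day_window
    start = window[0]
    n = int((window[1] - window[0]) // 60)

    met = generate_met_series(window, rng, person.met_model)
    episodes = place_episodes(person, window, rng)
    in_episode = np.zeros(n, dtype=bool)
    for s, e in episodes:
        in_episode[s:e] = True
    depth = _episode_depth_profile(person, episodes, n, rng)
    eps = rng.normal(0.0, person.noise_sd, size=n) if person.noise_sd > 0 else np.zeros(n)
    day_level = rng.normal(0.0, person.day_sd) if person.day_sd > 0 else 0.0

    # smoking happens in ~10-minute blocks for smokers
    smoking = np.zeros(n, dtype=bool)
    if person.smoker:
        for _ in range(rng.poisson(3.0)):
            s0 = int(rng.integers(0, n - 10))
            smoking[s0 : s0 + 10] = True

    interventional = calibration is not None
    random_events: list[TriggerEvent] = []
    if interventional and config.random_rate > 0:
        random_events = schedule_random(
            window, config.random_rate, config.random_min_gap, rng, person_id, day
        )
    random_minutes = {int((e.time - start) // 60): e for e in random_events}

    boost = np.zeros(n)  # accumulated log-scale intervention effects
    rmssd_obs = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    counts = np.zeros(n, dtype=int)
    triggers: list[TriggerEvent] = []
    prompts: list[dict] = []
    last_fire = -np.inf
    win = config.window_len

    def _deliver(i: int, kind: str, event_time: float, flag_count: int | None) -> None:
        """Prompt at the end of minute i: intervention occupies minute i+1."""
        iv = "none"
        if study == 2:
            iv = "mindful" if rng.random() < 0.5 else "external"
        j = i + 1  # intervention minute
        low = in_episode[j] if j < n else False
        d = effects.time_main_during
        if kind == "addhrvr" and low:
            d += effects.during_boost
        if study == 2 and kind == "addhrvr" and iv == "mindful":
            d += effects.mindful_during_extra
        if j < n:
            boost[j] += d
        p = effects.time_main_post + (effects.post_boost if kind == "addhrvr" else 0.0)
        boost[j + 1 : j + 11] += p
        prompts.append(
            {
                "person_id": person_id,
                "day": day,
                "time_seconds": event_time,
                "kind": kind,
                "intervention": iv,
                "in_episode": bool(in_episode[min(i, n - 1)]),
                "smoking": bool(smoking[min(i, n - 1)]),
                "window_flag_count": float(flag_count) if flag_count is not None else np.nan,
            }
        )

    for i in range(n):
        target = person.intercept + person.slope * met[i] + eps[i] - depth[i]
        target = max(target, _RMSSD_FLOOR)
        ln_adj = day_level + boost[i] + (effects.smoking_effect if smoking[i] else 0.0)
        rmssd_obs[i] = target * np.exp(ln_adj)
        if interventional:
            if calibration.eligible:
                flags[i] = bool(
                    rmssd_obs[i]
                    <= calibration.intercept + calibration.slope * met[i] - config.k * calibration.sd
                )
            lo = max(0, i - win + 1)
            counts[i] = int(flags[lo : i + 1].sum())
            t_end = start + 60.0 * (i + 1)
            if counts[i] >= config.threshold and t_end - last_fire >= config.silence:
                ev = TriggerEvent(person_id, "addhrvr", day, t_end, counts[i])
                triggers.append(ev)
                last_fire = t_end
                _deliver(i, "addhrvr", t_end, counts[i])
            if i in random_minutes:
                _deliver(i, "random", random_minutes[i].time, None)

    minutes = pd.DataFrame(
        {
            "person_id": person_id,
            "day": day,
            "minute_start": start + 60.0 * np.arange(n),
            "rmssd": rmssd_obs,
            "sdnn": np.nan,
            "hf": np.nan,
            "lf": np.nan,
            "met": met,
            "valid": True,
            "n_beats": 0,
            "in_episode": in_episode,
            "smoking": smoking,
            "flag": flags,
        }
    )
    return _DayResult(minutes, pd.DataFrame(prompts), triggers, flags)


# ---------------------------------------------------------------------------
# beat-level synthesis
# ---------------------------------------------------------------------------


def _minute_targets(
    person: PersonParams,
    met_series: np.ndarray,
    episodes: Sequence[tuple[int, int]],
    effects: EffectParams,
    triggers: Sequence[TriggerEvent],
    rng: np.random.Generator,
    day_window: tuple[float, float],
) -> np.ndarray:
    """Open-loop minute RMSSD targets for beat-level synthesis."""
    n = met_series.size
    start = day_window[0]
    depth = _episode_depth_profile(person, episodes, n)
    eps = rng.normal(0.0, person.noise_sd, size=n) if person.noise_sd > 0 else np.zeros(n)
    boost = np.zeros(n)
    for ev in triggers:
        i = int((ev.time - start) // 60) - 1
        j = i + 1
        d = effects.time_main_during + (effects.during_boost if ev.kind == "addhrvr" else 0.0)
        if 0 <= j < n:
            boost[j] += d
        p = effects.time_main_post + (effects.post_boost if ev.kind == "addhrvr" else 0.0)
        boost[max(j + 1, 0) : j + 11] += p
    raw = person.intercept + person.slope * met_series + eps - depth
    return np.maximum(raw, _RMSSD_FLOOR) * np.exp(boost)


def generate_ibis(
    person: PersonParams,
    met_series: Sequence[float],
    episodes: Sequence[tuple[int, int]] | None,
    effects: EffectParams | None,
    triggers: Sequence[TriggerEvent] | None,
    rng: np.random.Generator,
    day_window: tuple[float, float] = DEFAULT_DAY_WINDOW,
    person_id: str = "p0",
    day: int = 0,
    targets: Sequence[float] | None = None,
) -> IbiSeries:
    """Synthesize a beat stream whose per-minute RMSSD matches its target.

    For each minute the target RMSSD is the movement line plus noise, minus
    episode suppression, times the intervention boosts (``targets`` may
    instead supply precomputed values, e.g. from the closed-loop simulator).
    Beats are Gaussian-increment sequences: white IBI noise of SD
    ``target/sqrt(2)`` around a movement-modulated mean interval, then the
    deviations are rescaled so the realized RMSSD equals the target exactly,
    and the minute is stretched to exactly 60 s (a relative change below 1%).
    Targets at or below zero are clipped to a 1 ms floor.
    """
    met_series = np.asarray(met_series, dtype=float)
    if targets is None:
        targets = _minute_targets(
            person, met_series, episodes or [], effects or EffectParams(),
            triggers or [], rng, day_window,
        )
    targets = np.maximum(np.asarray(targets, dtype=float), _RMSSD_FLOOR)
    start = day_window[0]
    all_t: list[np.ndarray] = []
    all_ibi: list[np.ndarray] = []
    for m, (met, target) in enumerate(zip(met_series, targets)):
        hr = 65.0 + 12.0 * (met - 1.0)  # bpm rises with movement
        mean_ibi = 60000.0 / hr
        nb = max(int(round(60000.0 / mean_ibi)), 4)
        x = mean_ibi + rng.normal(0.0, target / np.sqrt(2.0), size=nb)
        r0 = np.sqrt(np.mean(np.diff(x) ** 2))
        if r0 > 0:
            x = x.mean() + (x - x.mean()) * (target / r0)
        # fill the minute exactly with a mean shift: successive differences,
        # hence the realized RMSSD, are untouched
        x += (60000.0 - x.sum()) / x.size
        x = np.clip(x, 250.0, 2100.0)
        t0 = start + 60.0 * m
        all_t.append(t0 + np.concatenate([[0.0], np.cumsum(x[:-1])]) / 1000.0)
        all_ibi.append(x)
    return IbiSeries(
        person_id=person_id,
        day=day,
        t=np.concatenate(all_t) if all_t else np.empty(0),
        ibi=np.concatenate(all_ibi) if all_ibi else np.empty(0),
    )


# ---------------------------------------------------------------------------
# self-reports
# ---------------------------------------------------------------------------

REVERSE_MASK = (True, True, True, False)  # items 1-3 of the stress scale


def generate_selfreports(
    prompts: pd.DataFrame,
    effects: EffectParams,
    rng: np.random.Generator,
    stress_baseline: float = 2.2,
    rumination_baseline: float = 2.1,
    state_sd: float = 0.3,
    item_sd: float = 0.4,
    change_sd: float = 0.2,
    disposition_p: Sequence[float] = _DISPOSITION_P,
) -> pd.DataFrame:
    """Attach pre/post stress items, a rumination item, and a disposition.

    The latent pre-intervention stress is the baseline plus an episode shift
    (``stress_episode_gain``) plus noise; the four 1-5 items scatter around
    it and items 1-3 are *stored reverse-coded* (as collected).  The post
    latent adds the pre-to-post time effect and, for rule-triggered prompts,
    the configured interaction.  Item values are continuous within [1, 5]
    (slider-style), so a noiseless configuration shifts scores exactly.
    Dispositions are sampled with the configured probabilities; dismissed and
    ignored prompts carry no ratings, incomplete ones only the pre ratings.
    """
    out = prompts.copy()
    n = len(out)
    if n == 0:
        for c in ["disposition", "rumination_pre", "rumination_post"]:
            out[c] = pd.Series(dtype=float if "rum" in c else object)
        return out
    trig = (out["kind"] == "addhrvr").to_numpy()
    in_ep = out.get("in_episode", pd.Series(False, index=out.index)).to_numpy(dtype=bool)

    def _noise(sd, size):
        return rng.normal(0.0, sd, size=size) if sd > 0 else np.zeros(size)

    pre_latent = stress_baseline + effects.stress_episode_gain * in_ep + _noise(state_sd, n)
    post_latent = (
        pre_latent
        + effects.time_effect_stress
        + effects.stress_trigger_interaction * trig
        + _noise(change_sd, n)
    )
    for k in range(4):
        pre_item = np.clip(pre_latent + _noise(item_sd, n), 1.0, 5.0)
        post_item = np.clip(post_latent + _noise(item_sd, n), 1.0, 5.0)
        if REVERSE_MASK[k]:  # stored as collected: reverse-worded items
            pre_item, post_item = 6.0 - pre_item, 6.0 - post_item
        out[f"stress_pre_{k + 1}"] = pre_item
        out[f"stress_post_{k + 1}"] = post_item

    rum_pre = np.clip(
        rumination_baseline + effects.stress_episode_gain * in_ep + _noise(state_sd, n),
        1.0, 5.0,
    )
    rum_post = np.clip(
        rum_pre
        + effects.time_effect_rumination
        + effects.rumination_trigger_interaction * trig
        + _noise(change_sd, n),
        1.0, 5.0,
    )
    out["rumination_pre"] = rum_pre
    out["rumination_post"] = rum_post

    p = np.asarray(disposition_p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("disposition probabilities must sum to 1")
    disp = rng.choice(len(_DISPOSITIONS), size=n, p=p)
    out["disposition"] = [_DISPOSITIONS[d] for d in disp]
    rating_cols = [c for c in out.columns if c.startswith(("stress_", "rumination_"))]
    post_cols = [c for c in rating_cols if "post" in c]
    no_rating = np.isin(out["disposition"], ["dismissed", "ignored"])
    out.loc[no_rating, rating_cols] = np.nan
    out.loc[out["disposition"] == "incomplete", post_cols] = np.nan
    return out


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """All artifacts of one simulated study."""

    persons: pd.DataFrame
    calibrations: list[CalibrationResult]
    minutes: pd.DataFrame
    prompts: pd.DataFrame
    triggers: pd.DataFrame
    config: TriggerConfig
    effects: EffectParams


def _draw_person(rng: np.random.Generator, base: PersonParams) -> PersonParams:
    """Population draw around the template person."""
    slope = min(rng.normal(base.slope, 1.5), -4.0)
    return replace(
        base,
        intercept=max(rng.normal(base.intercept, 12.0), 40.0),
        slope=slope,
        smoker=bool(rng.random() < 0.25),
        stress_baseline=float(np.clip(rng.normal(base.stress_baseline, 0.4), 1.2, 4.5)),
        rumination_baseline=float(np.clip(rng.normal(base.rumination_baseline, 0.4), 1.2, 4.5)),
    )


def simulate_study(
    n_persons: int,
    n_days: int = 3,
    effects: EffectParams | None = None,
    base_person: PersonParams | None = None,
    config: TriggerConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    study: int = 1,
    heterogeneous: bool = True,
) -> SimulatedStudy:
    """Simulate a full study: calibration day + ``n_days`` intervention days.

    Day 0 is the calibration day (no prompts); the movement calibration is
    fitted from it with this package's own calibration model and deployed on
    days 1..n_days.  Randomness is split per person from the master seed, so
    any person's stream is independent of how many persons are simulated.
    """
    effects = effects or EffectParams()
    base = base_person or PersonParams()
    config = config or TriggerConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_persons)

    persons_rows = []
    calibrations: list[CalibrationResult] = []
    minutes_parts: list[pd.DataFrame] = []
    prompts_parts: list[pd.DataFrame] = []
    trigger_rows: list[TriggerEvent] = []

    for p_idx in range(n_persons):
        rng = np.random.default_rng(child_seeds[p_idx])
        pid = f"p{p_idx:03d}"
        person = _draw_person(rng, base) if heterogeneous else base

        cal_day = simulate_person_day(
            person, effects, rng, calibration=None, config=config,
            person_id=pid, day=0, study=study,
        )
        model = MovementCalibration.from_minutes(cal_day.minutes, person_id=pid)
        cal = model.fit()
        calibrations.append(cal)
        minutes_parts.append(cal_day.minutes)
        persons_rows.append(
            {
                "person_id": pid,
                "intercept": person.intercept,
                "slope": person.slope,
                "noise_sd": person.noise_sd,
                "episode_depth": person.episode_depth,
                "smoker": person.smoker,
                "eligible": cal.eligible,
            }
        )
        if not cal.eligible:
            continue  # positive-slope persons are excluded from the trial days
        for d in range(1, n_days + 1):
            res = simulate_person_day(
                person, effects, rng, calibration=cal, config=config,
                person_id=pid, day=d, study=study,
            )
            minutes_parts.append(res.minutes)
            trigger_rows.extend(res.triggers)
            if len(res.prompts):
                prompts_parts.append(
                    generate_selfreports(
                        res.prompts, effects, rng,
                        stress_baseline=person.stress_baseline,
                        rumination_baseline=person.rumination_baseline,
                    )
                )

    from .triggers import triggers_to_frame

    prompts = (
        pd.concat(prompts_parts, ignore_index=True)
        if prompts_parts
        else pd.DataFrame(
            columns=["person_id", "day", "time_seconds", "kind", "intervention",
                     "in_episode", "smoking", "window_flag_count", "disposition"]
        )
    )
    if len(prompts):
        prompts.insert(0, "prompt_id", np.arange(len(prompts)))
    else:
        prompts["prompt_id"] = pd.Series(dtype=int)
    return SimulatedStudy(
        persons=pd.DataFrame(persons_rows),
        calibrations=calibrations,
        minutes=pd.concat(minutes_parts, ignore_index=True),
        prompts=prompts,
        triggers=triggers_to_frame(trigger_rows),
        config=config,
        effects=effects,
    )
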