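"""Real-time "13 out of 28" trigger detection, random prompt scheduling, and
offline virtual-trigger scanning.

A prompt is emitted at the first minute whose trailing window (default 28
minutes, inclusive of the current minute) contains at least ``threshold``
(default 13) flagged minutes, subject to a refractory *silence* period
(default 60 minutes) after the previous emitted trigger — at most one
trigger per hour.  Missing minutes count as not-flagged, so a trigger always
reflects 13 observed reductions.

Virtual triggers are found offline: minutes whose trailing window satisfies
the same rule but where no real trigger fired (typically because silence
suppressed it).  They serve as no-intervention controls for spontaneous HRV
rebound, so a configurable buffer around any real prompt keeps their outcome
windows intervention-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hrv import DEFAULT_DAY_WINDOW

__all__ = [
    "TriggerConfig",
    "TriggerEvent",
    "detect_triggers",
    "schedule_random",
    "scan_virtual",
    "triggers_to_frame",
]


@dataclass(frozen=True)
class TriggerConfig:
    """Settings of the trigger rule and prompt scheduler."""

    window_len: int = 28          # minutes in the trailing detection window
    threshold: int = 13           # flagged minutes required in the window
    k: float = 0.5                # SD multiplier of the flag criterion
    silence: float = 3600.0       # refractory period after a trigger (s)
    day_window: tuple[float, float] = DEFAULT_DAY_WINDOW
    random_rate: int = 15         # random prompts per day
    random_min_gap: float = 1200.0  # minimum spacing of random prompts (s)
    virtual_buffer: float = 600.0   # exclusion zone around real prompts (s)

    def __post_init__(self) -> None:
        if not (1 <= self.threshold <= self.window_len):
            raise ValueError("need 1 <= threshold <= window_len")
        if self.silence < 0:
            raise ValueError("silence must be >= 0")
        if self.random_rate < 0 or self.random_min_gap < 0:
            raise ValueError("random_rate and random_min_gap must be >= 0")


@dataclass(frozen=True)
class TriggerEvent:
    """One prompt cause. ``time`` is seconds since midnight of ``day``;
    for rule-based kinds it is the end of the qualifying minute."""

    person_id: str
    kind: str  # "addhrvr" | "random" | "virtual"
    day: int
    time: float
    window_flag_count: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("addhrvr", "random", "virtual"):
            raise ValueError(f"unknown trigger kind {self.kind!r}")


def _window_counts(flags: np.ndarray, window_len: int) -> np.ndarray:
    """Count of flagged minutes in the trailing window ending at each minute."""
    c = np.concatenate([[0], np.cumsum(flags.astype(int))])
    lo = np.maximum(np.arange(flags.size) - window_len + 1, 0)
    return c[1:] - c[lo]


def detect_triggers(
    flags: Sequence[bool],
    config: TriggerConfig | None = None,
    person_id: str = "",
    day: int = 0,
    last_trigger_time: float | None = None,
) -> list[TriggerEvent]:
    """Stream per-minute flags through the rule; emit real-time triggers.

    ``flags`` is indexed by calendar minute within ``config.day_window``
    (missing minutes must be present as False).  The emission timestamp is
    the end of the qualifying minute.  ``last_trigger_time`` lets silence
    carry over from an earlier stream segment (seconds since midnight of the
    same day; may be negative for the previous day).
    """
    config = config or TriggerConfig()
    f = np.asarray(flags, dtype=bool)
    n_win = int((config.day_window[1] - config.day_window[0]) // 60)
    if f.size != n_win:
        raise ValueError(f"expected {n_win} per-minute flags, got {f.size}")
    counts = _window_counts(f, config.window_len)
    start = config.day_window[0]
    last = -np.inf if last_trigger_time is None else float(last_trigger_time)
    events: list[TriggerEvent] = []
    for i in range(f.size):
        t_end = start + 60.0 * (i + 1)
        if counts[i] >= config.threshold and t_end - last >= config.silence:
            events.append(
                TriggerEvent(person_id, "addhrvr", day, t_end, int(counts[i]))
            )
            last = t_end
    return events


def schedule_random(
    day_window: tuple[float, float],
    rate: int,
    min_gap: float,
    rng: np.random.Generator,
    person_id: str = "",
    day: int = 0,
) -> list[TriggerEvent]:
    """Draw ``rate`` prompt times uniformly in the day window, all gaps >= min_gap.

    Uses the spacing construction (uniform order statistics on the window
    shrunk by the total gap length, then re-inflated), so the draw is exact
    and reproducible under a fixed generator — no rejection loop.
    """
    if rate < 0 or min_gap < 0:
        raise ValueError("rate and min_gap must be >= 0")
    if rate == 0:
        return []
    span = day_window[1] - day_window[0]
    if rate * min_gap > span:
        raise ValueError(
            f"infeasible schedule: {rate} prompts x {min_gap} s gap exceeds {span} s window"
        )
    free = span - (rate - 1) * min_gap
    u = np.sort(rng.uniform(0.0, free, size=rate))
    times = day_window[0] + u + min_gap * np.arange(rate)
    return [TriggerEvent(person_id, "random", day, float(t)) for t in times]


def scan_virtual(
    flags: Sequence[bool],
    emitted: Iterable[TriggerEvent],
    config: TriggerConfig | None = None,
    person_id: str = "",
    day: int = 0,
    prompt_times: Sequence[float] | None = None,
) -> list[TriggerEvent]:
    """Offline pass for qualifying windows that never caused a prompt.

    ``emitted`` must hold the person-day's real-time rule triggers;
    ``prompt_times`` all real prompt times (rule-based and random — defaults
    to the emitted times) whose surroundings are excluded within
    ``config.virtual_buffer`` seconds of the prompt and its 1-minute
    intervention.  Successive virtual events respect the silence spacing so
    they mirror real trigger bookkeeping.
    """
    config = config or TriggerConfig()
    f = np.asarray(flags, dtype=bool)
    counts = _window_counts(f, config.window_len)
    start = config.day_window[0]
    real_times = sorted(e.time for e in emitted)
    if prompt_times is None:
        prompt_times = real_times
    prompt_times = np.asarray(sorted(prompt_times), dtype=float)
    buf = config.virtual_buffer
    events: list[TriggerEvent] = []
    last_virtual = -np.inf
    real_set = set(real_times)
    for i in range(f.size):
        t_end = start + 60.0 * (i + 1)
        if counts[i] < config.threshold:
            continue
        if t_end in real_set:
            continue  # fired in real time
        if t_end - last_virtual < config.silence:
            continue
        # keep outcome windows free of interventions: exclude the vicinity of
        # every real prompt (prompt time .. prompt time + 60 s intervention)
        if prompt_times.size and np.any(
            (t_end >= prompt_times - buf) & (t_end <= prompt_times + 60.0 + buf)
        ):
            continue
        events.append(TriggerEvent(person_id, "virtual", day, t_end, int(counts[i])))
        last_virtual = t_end
    return events


def triggers_to_frame(events: Iterable[TriggerEvent]) -> pd.DataFrame:
    """Tabulate trigger events (columns match the trigger-log CSV schema)."""
    events = list(events)
    return pd.DataFrame(
        {
            "person_id": [e.person_id for e in events],
            "day": [e.day for e in events],
            "kind": [e.kind for e in events],
            "time_seconds": [e.time for e in events],
            "window_flag_count": [e.window_flag_count for e in events],
        }
    )
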