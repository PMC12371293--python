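"""Per-minute heart-rate-variability features from interbeat-interval streams.

The raw input is a timestamped sequence of interbeat intervals (IBIs, in
milliseconds) for one person-day.  Everything downstream — the movement
calibration, the trigger rule, the outcome windows — consumes the per-minute
summaries computed here: RMSSD (root mean square of successive differences,
the vagally sensitive time-domain metric), SDNN (overall variability), and
spectral band powers in the conventional low-frequency (0.04–0.15 Hz) and
high-frequency (0.15–0.40 Hz) bands.

Minutes are half-open calendar intervals ``[t, t + 60)`` in local
seconds-since-midnight; a beat belongs to the minute containing its
timestamp.  Minutes that fail the artifact rules are set to missing (NaN),
never to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

__all__ = [
    "IbiSeries",
    "MinuteRecord",
    "ArtifactRules",
    "rmssd",
    "sdnn",
    "band_power",
    "ln_hrv",
    "segment_minutes",
    "validate_minute",
    "minutes_to_frame",
    "LF_BAND",
    "HF_BAND",
    "DEFAULT_DAY_WINDOW",
]

#: Conventional spectral bands (Hz).
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Default monitoring window: 9:00–21:00 local time, in seconds since midnight.
DEFAULT_DAY_WINDOW = (9 * 3600, 21 * 3600)


@dataclass(frozen=True)
class IbiSeries:
    """Timestamped interbeat intervals for one person-day.

    ``t`` holds beat timestamps in seconds since local midnight; ``ibi`` the
    interval (ms) starting at the corresponding beat, so that contiguous
    recordings satisfy ``t[i + 1] == t[i] + ibi[i] / 1000`` up to a
    tolerance.  Larger deviations are recording gaps, which are allowed and
    can be located with :meth:`gaps`.
    """

    person_id: str
    day: int
    t: np.ndarray
    ibi: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        ibi = np.asarray(self.ibi, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ibi", ibi)
        if t.shape != ibi.shape or t.ndim != 1:
            raise ValueError("t and ibi must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("beat timestamps must be strictly increasing")
        if np.any(ibi <= 0):
            raise ValueError("all interbeat intervals must be positive")

    def __len__(self) -> int:
        return self.t.size

    def gaps(self, tol: float = 0.05) -> np.ndarray:
        """Indices i where the stream is discontinuous between beats i and i+1."""
        if len(self) < 2:
            return np.empty(0, dtype=int)
        expected = self.t[:-1] + self.ibi[:-1] / 1000.0
        return np.nonzero(np.abs(self.t[1:] - expected) > tol)[0]


@dataclass(frozen=True)
class ArtifactRules:
    """Surrogate for the recorder's proprietary per-minute validation.

    A minute is set to missing when any rule fires: a successive-interval
    change larger than ``max_rel_jump`` (fraction of the preceding interval),
    an interval outside the physiological band ``[ibi_min, ibi_max]`` ms, or
    fewer than ``min_beats`` beats in the minute.
    """

    min_beats: int = 30
    ibi_min: float = 300.0
    ibi_max: float = 2000.0
    max_rel_jump: float = 0.30


@dataclass(frozen=True)
class MinuteRecord:
    """One calendar minute of HRV features. Invalid minutes carry NaN features."""

    person_id: str
    day: int
    minute_start: float  # seconds since midnight, multiple of 60
    rmssd: float = np.nan
    sdnn: float = np.nan
    hf_power: float = np.nan
    lf_power: float = np.nan
    met: float = np.nan
    valid: bool = False
    n_beats: int = 0
    ibis: np.ndarray | None = field(default=None, repr=False, compare=False)


def rmssd(ibis: Sequence[float]) -> float:
    """Root mean square of successive differences of IBIs (ms).

    Requires at least 3 intervals; otherwise returns NaN (missing).
    """
    x = np.asarray(ibis, dtype=float)
    if x.size < 3:
        return float("nan")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def sdnn(ibis: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) of IBIs (ms); NaN below 3 intervals."""
    x = np.asarray(ibis, dtype=float)
    if x.size < 3:
        return float("nan")
    return float(np.std(x, ddof=1))


def ln_hrv(x: float) -> float:
    """Natural log of an HRV quantity; zero or missing input propagates as NaN."""
    if x is None or not np.isfinite(x) or x <= 0:
        return float("nan")
    return float(np.log(x))


def band_power(
    ibis: Sequence[float],
    band: tuple[float, float],
    fs: float = 4.0,
) -> float:
    """Spectral power (ms^2) of the IBI tachogram integrated over ``band`` Hz.

    The irregularly sampled tachogram is cubic-spline interpolated onto an
    even ``fs``-Hz grid, linearly detrended and estimated with a Welch
    periodogram; the band integral is taken by the trapezoidal rule.  The
    record must span at least two cycles of the band's lower edge, else the
    result is missing (NaN).
    """
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < lo < hi")
    x = np.asarray(ibis, dtype=float)
    if x.size < 4:
        return float("nan")
    # beat times from the cumulative intervals (s); tachogram value = interval
    t = np.concatenate([[0.0], np.cumsum(x[:-1]) / 1000.0])
    duration = t[-1]
    if duration < 2.0 / lo:
        return float("nan")
    grid = np.arange(0.0, duration, 1.0 / fs)
    tach = CubicSpline(t, x)(grid)
    nperseg = min(tach.size, 256)
    freqs, psd = signal.welch(tach, fs=fs, nperseg=nperseg, detrend="linear")
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        # resolution too coarse to resolve the band: integrate the single bin
        return float(psd[mask].sum() * (freqs[1] - freqs[0])) if mask.any() else 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def _apply_rules(ibis: np.ndarray, rules: ArtifactRules) -> bool:
    """True when the minute passes all artifact rules."""
    if ibis.size < rules.min_beats:
        return False
    if np.any(ibis < rules.ibi_min) or np.any(ibis > rules.ibi_max):
        return False
    if ibis.size >= 2:
        rel = np.abs(np.diff(ibis)) / ibis[:-1]
        if np.any(rel > rules.max_rel_jump):
            return False
    return True


def validate_minute(record: MinuteRecord, rules: ArtifactRules | None = None) -> MinuteRecord:
    """Re-apply artifact rules to a populated minute.

    Invalidation clears every HRV field (missing, never zero).  Requires the
    record to carry its raw intervals; a record without them can only be
    invalidated by the beat-count rule.
    """
    rules = rules or ArtifactRules()
    ibis = record.ibis if record.ibis is not None else np.empty(0)
    ok = _apply_rules(np.asarray(ibis, dtype=float), rules)
    if ok:
        return replace(record, valid=True)
    return replace(
        record,
        valid=False,
        rmssd=float("nan"),
        sdnn=float("nan"),
        hf_power=float("nan"),
        lf_power=float("nan"),
    )


def segment_minutes(
    series: IbiSeries,
    day_window: tuple[float, float] = DEFAULT_DAY_WINDOW,
    rules: ArtifactRules | None = None,
    compute_bands: bool = True,
    met: Sequence[float] | None = None,
) -> list[MinuteRecord]:
    """Cut an IBI stream into per-minute HRV records over ``day_window``.

    Produces exactly one record per calendar minute of the window.  A beat
    belongs to the minute ``[t, t + 60)`` containing its timestamp.  Minutes
    failing the artifact rules (including too few beats — in particular every
    minute of an empty stream) are returned invalid with missing features.

    ``met`` optionally attaches one movement value (metabolic equivalents)
    per minute of the window.
    """
    start, end = day_window
    if start % 60 or end % 60 or end <= start:
        raise ValueError("day_window must be whole minutes with start < end")
    rules = rules or ArtifactRules()
    n_min = int((end - start) // 60)
    if met is not None and len(met) != n_min:
        raise ValueError(f"met must have one value per minute ({n_min})")
    edges = start + 60.0 * np.arange(n_min + 1)
    idx = np.searchsorted(series.t, edges)
    records: list[MinuteRecord] = []
    for m in range(n_min):
        ibis = series.ibi[idx[m]: idx[m + 1]]
        rec = MinuteRecord(
            person_id=series.person_id,
            day=series.day,
            minute_start=float(edges[m]),
            n_beats=int(ibis.size),
            met=float(met[m]) if met is not None else float("nan"),
            ibis=ibis,
        )
        if _apply_rules(ibis, rules):
            rec = replace(
                rec,
                valid=True,
                rmssd=rmssd(ibis),
                sdnn=sdnn(ibis),
                hf_power=band_power(ibis, HF_BAND) if compute_bands else float("nan"),
                lf_power=band_power(ibis, LF_BAND) if compute_bands else float("nan"),
            )
        records.append(rec)
    return records


def minutes_to_frame(records: Sequence[MinuteRecord]) -> pd.DataFrame:
    """Tabulate minute records (columns match the minute CSV schema)."""
    records = list(records)
    return pd.DataFrame(
        {
            "person_id": [r.person_id for r in records],
            "day": [r.day for r in records],
            "minute_start": [r.minute_start for r in records],
            "rmssd": [r.rmssd for r in records],
            "sdnn": [r.sdnn for r in records],
            "hf": [r.hf_power for r in records],
            "lf": [r.lf_power for r in records],
            "met": [r.met for r in records],
            "valid": [r.valid for r in records],
            "n_beats": [r.n_beats for r in records],
        }
    )
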