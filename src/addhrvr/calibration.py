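"""Person-specific calibration of RMSSD against bodily movement.

One 12-hour calibration day per person: minute RMSSD is regressed on
movement (metabolic equivalents, MET) by ordinary least squares.  The fitted
intercept, slope and the dispersion of the calibration-day RMSSD define what
counts as an *additional* (nonmetabolic) HRV reduction afterwards: a minute
whose observed RMSSD lies at least ``k`` (default 0.5) dispersion units below
the movement-predicted value is flagged.

Physiologically, movement raises heart rate and suppresses vagal modulation,
so eligible persons have a negative slope; a non-negative fitted slope marks
the person ineligible for flagging (their movement coupling is not
interpretable under the model) and such persons are excluded, matching how
positive-slope individuals are handled in the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hrv import MinuteRecord

__all__ = [
    "MovementCalibration",
    "CalibrationResult",
    "CalibrationError",
    "addhrvr_flag",
    "calibrations_to_frame",
]


class CalibrationError(ValueError):
    """Raised when a person cannot be calibrated (too few minutes, no dispersion)."""


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted per-person calibration line and the dispersion used for flagging.

    ``sd`` is, by default, the sample SD of the person's valid
    calibration-day RMSSD values (the marginal dispersion); the residual SD
    of the regression is available as ``resid_sd`` and can be selected at fit
    time instead.  ``eligible`` is True iff the slope is negative.
    """

    person_id: str
    intercept: float  # ms
    slope: float      # ms per MET
    sd: float         # ms, dispersion entering the k*SD criterion
    n_minutes_used: int
    r: float          # RMSSD–MET correlation (diagnostic)
    resid_sd: float
    slope_se: float
    eligible: bool

    def predict(self, met) -> np.ndarray | float:
        """Movement-predicted RMSSD (ms) at the given MET value(s)."""
        if not self.eligible:
            raise CalibrationError(
                f"person {self.person_id} is ineligible (slope >= 0); no prediction"
            )
        return self.intercept + self.slope * np.asarray(met, dtype=float)

    def flag(self, observed, met, k: float = 0.5) -> np.ndarray | bool:
        """AddHRVr flags: observed at least ``k`` SD below the predicted value."""
        return addhrvr_flag(observed, self.predict(met), self.sd, k=k)

    def summary(self) -> str:
        lines = [
            f"Movement calibration — person {self.person_id}",
            f"  intercept     {self.intercept:10.3f} ms",
            f"  slope         {self.slope:10.3f} ms/MET (SE {self.slope_se:.3f})",
            f"  dispersion SD {self.sd:10.3f} ms (residual SD {self.resid_sd:.3f})",
            f"  minutes used  {self.n_minutes_used:7d}    r = {self.r:.3f}",
            f"  eligible      {self.eligible}",
        ]
        return "\n".join(lines)


class MovementCalibration:
    """OLS model of minute RMSSD on movement for one person's calibration day.

    Parameters
    ----------
    rmssd, met :
        Paired per-minute values; non-finite pairs are dropped.
    min_minutes :
        Minimum number of usable minutes (default 120 of a 720-minute day);
        below this the person is reported uncalibratable rather than fitted.
    sd_mode :
        ``"marginal"`` (default) uses the sample SD of calibration-day RMSSD
        for the flag criterion; ``"residual"`` uses the regression residual SD.
    """

    def __init__(
        self,
        rmssd: Sequence[float],
        met: Sequence[float],
        person_id: str = "",
        min_minutes: int = 120,
        sd_mode: Literal["marginal", "residual"] = "marginal",
    ) -> None:
        if sd_mode not in ("marginal", "residual"):
            raise ValueError(f"unknown sd_mode {sd_mode!r}")
        y = np.asarray(rmssd, dtype=float)
        x = np.asarray(met, dtype=float)
        if y.shape != x.shape:
            raise ValueError("rmssd and met must align")
        keep = np.isfinite(y) & np.isfinite(x)
        self.endog = y[keep]
        self.exog = x[keep]
        self.person_id = person_id
        self.min_minutes = int(min_minutes)
        self.sd_mode = sd_mode

    @classmethod
    def from_minutes(
        cls,
        minutes: Iterable[MinuteRecord] | pd.DataFrame,
        person_id: str | None = None,
        **kwargs,
    ) -> "MovementCalibration":
        """Build from minute records or a minute-level frame (valid minutes only)."""
        if isinstance(minutes, pd.DataFrame):
            df = minutes[minutes["valid"].astype(bool)]
            pid = person_id if person_id is not None else str(df["person_id"].iloc[0])
            return cls(df["rmssd"].to_numpy(), df["met"].to_numpy(), person_id=pid, **kwargs)
        recs = [m for m in minutes if m.valid]
        pid = person_id if person_id is not None else (recs[0].person_id if recs else "")
        return cls(
            [m.rmssd for m in recs], [m.met for m in recs], person_id=pid, **kwargs
        )

    def fit(self) -> CalibrationResult:
        n = self.endog.size
        if n < self.min_minutes:
            raise CalibrationError(
                f"person {self.person_id!r}: {n} usable minutes < required {self.min_minutes}"
            )
        if np.ptp(self.exog) == 0:
            raise CalibrationError(
                f"person {self.person_id!r}: movement has no variation; slope undefined"
            )
        res = stats.linregress(self.exog, self.endog)
        resid = self.endog - (res.intercept + res.slope * self.exog)
        resid_sd = float(np.std(resid, ddof=2))
        marginal_sd = float(np.std(self.endog, ddof=1))
        sd = marginal_sd if self.sd_mode == "marginal" else resid_sd
        if not sd > 0:
            raise CalibrationError(
                f"person {self.person_id!r}: calibration-day RMSSD has zero dispersion"
            )
        return CalibrationResult(
            person_id=self.person_id,
            intercept=float(res.intercept),
            slope=float(res.slope),
            sd=sd,
            n_minutes_used=int(n),
            r=float(res.rvalue),
            resid_sd=resid_sd,
            slope_se=float(res.stderr),
            eligible=bool(res.slope < 0),
        )


def addhrvr_flag(observed, predicted, sd, k: float = 0.5):
    """True where observed RMSSD is at least ``k`` SD lower than predicted.

    The boundary counts as flagged ("at least"): flag iff
    ``observed <= predicted - k * sd``.  Missing observations never flag.
    """
    if not np.all(np.asarray(sd, dtype=float) > 0):
        raise ValueError("sd must be positive")
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    out = np.less_equal(obs, pred - k * np.asarray(sd, dtype=float))
    out = np.where(np.isfinite(obs), out, False)
    return bool(out) if out.ndim == 0 else out


def calibrations_to_frame(results: Iterable[CalibrationResult]) -> pd.DataFrame:
    """Tabulate fitted calibrations (columns match the calibration CSV schema)."""
    results = list(results)
    return pd.DataFrame(
        {
            "person_id": [r.person_id for r in results],
            "intercept": [r.intercept for r in results],
            "slope": [r.slope for r in results],
            "sd": [r.sd for r in results],
            "n_minutes_used": [r.n_minutes_used for r in results],
            "r": [r.r for r in results],
            "eligible": [r.eligible for r in results],
        }
    )
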