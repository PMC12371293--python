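"""Microrandomized-trial design: power, minimal sample size, and descriptives.

The sample-size machinery follows the published MRT methodology for a
*constant* standardized proximal effect: with N persons, T decision points
(days x occasions per day), randomization probability rho, expected
availability tau and standardized effect d, the Wald test of the proximal
effect has noncentrality

    lambda = N * d^2 * tau * rho * (1 - rho) * T,

and, with the small-sample correction, power is evaluated on an F
distribution with (p, N - q - p) degrees of freedom (p = q = 1 for a
constant effect and a constant availability trend):

    power(N) = 1 - F_{p, N-q-p; lambda}( F^{-1}_{p, N-q-p}(1 - alpha) ).

The minimal N is the smallest integer reaching the target power.  For a
4-day trial with rho = 0.40, tau = 0.75, alpha = .05 and 10 occasions per
day, this yields N = 30 at d = 0.2 and N = 51 at d = 0.15.  The occasion
count is an explicit design input: 10 per day is the package's documented
calibration (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, Decimal
from typing import Mapping

import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import ncf

__all__ = [
    "MrtDesign",
    "mrt_power",
    "mrt_sample_size",
    "PowerError",
    "breathing_frequency",
    "summarize_prompts",
    "disposition_percentages",
    "DISPOSITION_CATEGORIES",
]

DISPOSITION_CATEGORIES = ("answered", "dismissed", "ignored", "incomplete")


class PowerError(ValueError):
    """Raised when the target power is unattainable within the search bound."""


@dataclass(frozen=True)
class MrtDesign:
    """Design inputs of an MRT sample-size calculation (constant proximal effect)."""

    days: int = 4
    occasions_per_day: int = 10
    p_rand: float = 0.40
    availability: float = 0.75
    effect: float = 0.2
    effect_shape: str = "constant"
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.days < 1 or self.occasions_per_day < 1:
            raise ValueError("days and occasions_per_day must be >= 1")
        for name in ("p_rand", "availability", "power", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.effect_shape != "constant":
            raise NotImplementedError("only the constant proximal-effect shape is supported")

    @property
    def decision_points(self) -> int:
        return self.days * self.occasions_per_day


# dimension of the proximal-effect trend (p) and of the availability trend (q)
# for the constant-effect case
_P = 1
_Q = 1


def mrt_power(design: MrtDesign, n: int) -> float:
    """Power of the proximal-effect test at sample size ``n``."""
    df2 = n - _Q - _P
    if df2 < 1:
        return 0.0
    lam = (
        n
        * design.effect**2
        * design.availability
        * design.p_rand
        * (1.0 - design.p_rand)
        * design.decision_points
    )
    crit = f_dist.ppf(1.0 - design.alpha, _P, df2)
    return float(1.0 - ncf.cdf(crit, _P, df2, lam))


def mrt_sample_size(design: MrtDesign, n_max: int = 10_000) -> int:
    """Smallest integer N whose power reaches the design target."""
    for n in range(_P + _Q + 2, n_max + 1):
        if mrt_power(design, n) >= design.power:
            return n
    raise PowerError(
        f"target power {design.power} unattainable with effect {design.effect} "
        f"within N <= {n_max}"
    )


def breathing_frequency(inhale_s: float = 4.0, exhale_s: float = 6.0) -> float:
    """Breathing frequency (Hz) of a paced inhale/exhale cycle.

    The guided slow-breathing intervention paces 4-s inhales and 6-s exhales:
    a 10-s cycle, i.e. 0.1 Hz (6 breaths per minute), the resonance frequency
    at which respiratory sinus arrhythmia shifts into the LF band.
    """
    if inhale_s <= 0 or exhale_s <= 0:
        raise ValueError("phase durations must be positive")
    return 1.0 / (inhale_s + exhale_s)


def _truncate_pct(count: int, total: int) -> float:
    """Percentage truncated (not rounded) to 2 decimals."""
    pct = Decimal(count) * Decimal(100) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_DOWN))


def disposition_percentages(counts: Mapping[str, int], total: int | None = None) -> pd.DataFrame:
    """Counts and percentages per prompt disposition.

    ``total`` defaults to the category sum but may exceed it (prompt tables
    sometimes contain entries outside the four standard categories);
    percentages are then of the supplied total.  Percentages are truncated to
    2 decimals.
    """
    unknown = set(counts) - set(DISPOSITION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown disposition categories: {sorted(unknown)}")
    tot = int(total) if total is not None else int(sum(counts.values()))
    if tot <= 0:
        raise ValueError("total must be positive")
    if sum(counts.values()) > tot:
        raise ValueError("category counts exceed the stated total")
    rows = [
        {"disposition": k, "count": int(counts.get(k, 0)), "pct": _truncate_pct(counts.get(k, 0), tot)}
        for k in DISPOSITION_CATEGORIES
        if k in counts
    ]
    return pd.DataFrame(rows)


def summarize_prompts(prompts: pd.DataFrame, column: str = "disposition") -> pd.DataFrame:
    """Disposition counts and percentages of a prompt table."""
    if column not in prompts:
        raise ValueError(f"prompt table has no {column!r} column")
    counts = prompts[column].value_counts().to_dict()
    return disposition_percentages(counts, total=len(prompts))
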