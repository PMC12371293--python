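"""Outcome windows, self-report scoring and proximal-effect estimation.

Each prompt yields three outcome windows on the minute grid — the 10 minutes
before the prompt (time code −1), the intervention phase with a ±2-minute
timing tolerance (code 0), and the 10 minutes after the intervention
(code +1).  Window outcomes are means of per-minute ln-transformed HRV over
the valid minutes of the span (the log is taken per minute *before*
averaging).

Proximal intervention effects are estimated with a linear mixed model with a
random intercept per person: fixed effects are movement (MET, centered),
momentary smoking, the within-person-centered trigger indicator, two time
contrasts (pre→during, pre→post) and the trigger-by-time interactions; a
two-intervention design adds the intervention indicator and its two- and
three-way interactions.  The trigger-by-time(post) coefficient is the
proximal effect of delivering the intervention at a detected vulnerable
moment rather than at a random one.  Estimation delegates to
``statsmodels`` MixedLM; fixed-effect inference is Wald (large-sample
normal), and the intraclass correlation is tau00 / (tau00 + sigma2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "WindowSpec",
    "score_stress",
    "build_windows",
    "ProximalEffectModel",
    "ProximalEffectResults",
    "fit_proximal_model",
    "rescale_reference",
    "compare_virtual",
]


@dataclass(frozen=True)
class WindowSpec:
    """Window offsets in seconds relative to the prompt time (= intervention start).

    Defaults: pre ``[-600, 0)``, during ``[-60, +180)`` (the 1-minute
    intervention widened by the ±2-minute timing tolerance), post
    ``[+60, +660)`` (the 10 minutes following the intervention minute).
    """

    pre: tuple[float, float] = (-600.0, 0.0)
    during: tuple[float, float] = (-60.0, 180.0)
    post: tuple[float, float] = (60.0, 660.0)
    min_minutes: int = 3  # minimum valid minutes for a truncated window to count


def score_stress(items: Sequence[float], reverse_mask: Sequence[bool] = (True, True, True, False)) -> float:
    """Mean momentary stress from four 1–5 items, reversing the marked items.

    Reverse-coded items score as ``6 - raw``.  Any missing item makes the
    score missing (no partial means).
    """
    x = np.asarray(items, dtype=float)
    if x.shape != (len(reverse_mask),):
        raise ValueError("item vector does not match the reverse mask length")
    if not np.all(np.isfinite(x)):
        return float("nan")
    if np.any((x < 1) | (x > 5)):
        raise ValueError("items must lie in [1, 5]")
    rev = np.asarray(reverse_mask, dtype=bool)
    proc = np.where(rev, 6.0 - x, x)
    return float(proc.mean())


def _nanmean(x: np.ndarray) -> float:
    m = np.isfinite(x)
    return float(x[m].mean()) if m.any() else float("nan")


def build_windows(
    minutes: pd.DataFrame,
    prompts: pd.DataFrame,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Long-format outcome table: one row per prompt and time code.

    Virtual triggers (kind ``"virtual"``) have no intervention, so only their
    pre and post rows are built.  Windows truncated by the day edge are kept
    when at least ``spec.min_minutes`` valid minutes remain, flagged in the
    ``truncated`` column; windows with no valid minutes have missing outcomes.
    The minute table must hold one row per calendar minute per person-day.
    """
    spec = spec or WindowSpec()
    codes = {"pre": -1, "during": 0, "post": 1}
    hrv_cols = [("rmssd", "ln_rmssd"), ("sdnn", "ln_sdnn"), ("hf", "ln_hf"), ("lf", "ln_lf")]
    grouped: dict = {}
    for key, g in minutes.groupby(["person_id", "day"]):
        g = g.sort_values("minute_start")
        starts = g["minute_start"].to_numpy(dtype=float)
        if starts.size > 1 and not np.allclose(np.diff(starts), 60.0):
            raise ValueError("minute table must be a contiguous per-minute grid")
        valid = g["valid"].to_numpy(dtype=bool)
        lns = {}
        for col, name in hrv_cols:
            v = g[col].to_numpy(dtype=float) if col in g else np.full(starts.size, np.nan)
            with np.errstate(invalid="ignore", divide="ignore"):
                ln = np.where(valid & np.isfinite(v) & (v > 0), np.log(np.where(v > 0, v, 1.0)), np.nan)
            lns[name] = ln
        met = g["met"].to_numpy(dtype=float) if "met" in g else np.full(starts.size, np.nan)
        met = np.where(valid, met, np.nan)
        smoking = (
            g["smoking"].to_numpy(dtype=bool) if "smoking" in g
            else np.zeros(starts.size, dtype=bool)
        )
        grouped[key] = (starts[0], starts.size, valid, lns, met, smoking & valid)
    rows = []
    for auto_id, pr in enumerate(prompts.to_dict("records")):
        key = (pr["person_id"], pr["day"])
        if key not in grouped:
            continue
        base, n, valid, lns, met, smoking = grouped[key]
        t = float(pr["time_seconds"])
        spans = {"pre": spec.pre, "during": spec.during, "post": spec.post}
        if pr.get("kind") == "virtual":
            spans.pop("during")
        for phase, (off_lo, off_hi) in spans.items():
            # whole minutes [m, m+60) fully inside [t+off_lo, t+off_hi)
            lo_idx = int(np.ceil((t + off_lo - base) / 60.0))
            hi_idx = int(np.floor((t + off_hi - base) / 60.0))
            truncated = lo_idx < 0 or hi_idx > n
            a, b = max(lo_idx, 0), min(hi_idx, n)
            n_valid = int(valid[a:b].sum()) if b > a else 0
            if truncated and n_valid < spec.min_minutes:
                continue
            agg = {name: (_nanmean(ln[a:b]) if b > a else float("nan"))
                   for name, ln in lns.items()}
            rows.append(
                {
                    "prompt_id": pr.get("prompt_id", auto_id),
                    "person_id": pr["person_id"],
                    "day": pr["day"],
                    "time_code": codes[phase],
                    "trigger_kind": pr.get("kind", "random"),
                    "intervention_kind": pr.get("intervention", "none"),
                    "truncated": bool(truncated),
                    "n_span_minutes": int((off_hi - off_lo) // 60),
                    "n_valid": n_valid,
                    **agg,
                    "met_mean": _nanmean(met[a:b]) if b > a else float("nan"),
                    "smoking": bool(smoking[a:b].any()) if b > a else False,
                }
            )
    cols = [
        "prompt_id", "person_id", "day", "time_code", "trigger_kind",
        "intervention_kind", "truncated", "n_span_minutes", "n_valid",
        "ln_rmssd", "ln_sdnn", "ln_hf", "ln_lf", "met_mean", "smoking",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------


def _fit_mixed(formula: str, df: pd.DataFrame, reml: bool = True, prompt_re: bool = True):
    """Fit a MixedLM with a person random intercept and, optionally, a
    prompt-level variance component (windows nested in prompts)."""
    df = df.copy()
    vc = None
    if prompt_re:
        df["_prompt"] = df["prompt_id"].astype(str)
        vc = {"prompt": "0 + C(_prompt)"}
    model = smf.mixedlm(formula, df, groups=df["person_id"], re_formula="1", vc_formula=vc)
    try:
        res = model.fit(reml=reml, method="lbfgs")
        if not res.converged:
            raise RuntimeError
    except Exception:
        try:
            res = model.fit(reml=reml)
        except Exception:
            if not prompt_re:
                raise
            # degenerate prompt component (e.g. no prompt-level variance):
            # refit with the person intercept only
            return _fit_mixed(formula, df, reml=reml, prompt_re=False)
    fe = res.fe_params.index
    tau_prompt = float(res.vcomp[0]) if prompt_re and len(res.vcomp) else 0.0
    return ProximalEffectResults(
        params=res.params[fe],
        bse=res.bse[fe],
        pvalues=res.pvalues[fe],
        conf_int=res.conf_int().loc[fe],
        sigma2_resid=float(res.scale),
        tau_prompt=tau_prompt,
        tau00=float(np.asarray(res.cov_re)[0, 0]),
        nobs=int(res.nobs),
        formula=formula,
        converged=bool(res.converged),
    )


@dataclass
class ProximalEffectResults:
    """Estimates, Wald inference and variance components of a fitted model.

    ``sigma2`` is the total within-person variance: the window-level residual
    (``sigma2_resid``) plus the prompt-level component (``tau_prompt`` —
    windows of one prompt share its momentary state).  ``tau00`` is the
    between-person random-intercept variance, and
    ICC = tau00 / (tau00 + sigma2).
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    sigma2_resid: float
    tau_prompt: float
    tau00: float       # between-person (random intercept) variance
    nobs: int
    formula: str
    converged: bool

    @property
    def sigma2(self) -> float:
        return self.sigma2_resid + self.tau_prompt

    @property
    def icc(self) -> float:
        return self.tau00 / (self.tau00 + self.sigma2)

    def term(self, name: str) -> dict:
        """One coefficient as a dict: estimate, SE, CI bounds, p."""
        if name not in self.params.index:
            raise KeyError(f"term {name!r} not in model; terms: {list(self.params.index)}")
        return {
            "estimate": float(self.params[name]),
            "se": float(self.bse[name]),
            "ci_low": float(self.conf_int.loc[name, 0]),
            "ci_high": float(self.conf_int.loc[name, 1]),
            "p": float(self.pvalues[name]),
        }

    def proximal_effect(self, phase: str = "post") -> dict:
        """The trigger-by-time interaction for ``phase`` ('during' or 'post')."""
        for name in self.params.index:
            low = name.replace(" ", "")
            if ("trig" in low) and (phase in low) and (":" in low) and ("iv" not in low):
                return self.term(name)
        raise KeyError(f"no trigger-by-{phase} interaction in this model")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "ci_low": self.conf_int[0],
                "ci_high": self.conf_int[1],
                "p": self.pvalues,
            }
        )
        df.index.name = "term"
        return df

    def summary(self) -> str:
        lines = [f"Mixed model: {self.formula}", f"n obs = {self.nobs}", ""]
        lines.append(self.to_frame().to_string(float_format=lambda v: f"{v: .4f}"))
        lines += [
            "",
            f"within-person variance sigma2 = {self.sigma2:.4f}"
            f" (residual {self.sigma2_resid:.4f} + prompt {self.tau_prompt:.4f})",
            f"between-person variance tau00 = {self.tau00:.4f}",
            f"ICC = {self.icc:.3f}",
        ]
        return "\n".join(lines)

    def plot_trajectories(self, windows: pd.DataFrame, outcome: str = "ln_rmssd", ax=None):
        """Raw mean trajectories by trigger kind over the three time codes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for kind, g in windows.groupby("trigger_kind"):
            m = g.groupby("time_code")[outcome].mean()
            se = g.groupby("time_code")[outcome].sem()
            ax.errorbar(m.index, m.values, yerr=1.96 * se.values, label=kind, capsize=3)
        ax.set_xticks([-1, 0, 1], ["pre", "during", "post"])
        ax.set_ylabel(outcome)
        ax.legend()
        return ax


class ProximalEffectModel:
    """Linear mixed model for proximal intervention effects.

    Parameters
    ----------
    windows :
        Long-format outcome table from :func:`build_windows`.
    outcome :
        Outcome column (default ``"ln_rmssd"``).
    design :
        ``"study1"`` — trigger-by-time; ``"study2"`` — adds the intervention
        factor and the three-way interaction.
    trigger_coding, intervention_coding :
        ``"centered"`` (within-person, the default) or the name of a
        reference level for plain 0/1 indicator coding.
    """

    def __init__(
        self,
        windows: pd.DataFrame,
        outcome: str = "ln_rmssd",
        design: str = "study1",
        trigger_coding: str = "centered",
        intervention_coding: str = "centered",
        include_during: bool = True,
        prompt_re: bool = True,
    ) -> None:
        self.prompt_re = prompt_re
        if design not in ("study1", "study2"):
            raise ValueError("design must be 'study1' or 'study2'")
        df = windows[windows["trigger_kind"].isin(["addhrvr", "random"])].copy()
        df = df[np.isfinite(df[outcome])]
        if df["person_id"].nunique() < 2:
            raise ValueError("need at least 2 persons to fit a mixed model")
        df["trig"] = (df["trigger_kind"] == "addhrvr").astype(float)
        if trigger_coding == "centered":
            pm = (
                df.drop_duplicates("prompt_id").groupby("person_id")["trig"].mean()
                .rename("trig_pmean")
            )
            df = df.merge(pm, on="person_id")
            df["trig_c"] = df["trig"] - df["trig_pmean"]
        elif trigger_coding in ("random", "addhrvr"):
            df["trig_c"] = (df["trigger_kind"] != trigger_coding).astype(float)
        else:
            raise ValueError(f"unknown trigger coding/reference {trigger_coding!r}")
        if float(np.abs(df["trig_c"]).sum()) == 0:
            raise ValueError("no within-person trigger contrast; effects inestimable")
        df["during"] = (df["time_code"] == 0).astype(float)
        df["post"] = (df["time_code"] == 1).astype(float)
        df["met_c"] = df["met_mean"] - df["met_mean"].mean()
        df["smoking"] = df["smoking"].astype(float)

        time_terms = ["during", "post"] if include_during else ["post"]
        covariates = [c for c in ("met_c", "smoking") if df[c].nunique() > 1]
        terms = covariates + ["trig_c"] + time_terms
        terms += [f"trig_c:{t}" for t in time_terms]
        if design == "study2":
            df["iv"] = (df["intervention_kind"] == "mindful").astype(float)
            if intervention_coding == "centered":
                ivm = (
                    df.drop_duplicates("prompt_id").groupby("person_id")["iv"].mean()
                    .rename("iv_pmean")
                )
                df = df.merge(ivm, on="person_id")
                df["iv_c"] = df["iv"] - df["iv_pmean"]
            elif intervention_coding in ("mindful", "external"):
                df["iv_c"] = (df["intervention_kind"] != intervention_coding).astype(float)
            else:
                raise ValueError(
                    f"unknown intervention coding/reference {intervention_coding!r}"
                )
            terms += ["iv_c", "trig_c:iv_c"]
            terms += [f"iv_c:{t}" for t in time_terms]
            terms += [f"trig_c:iv_c:{t}" for t in time_terms]
        self.data = df
        self.outcome = outcome
        self.design = design
        self.formula = f"{outcome} ~ " + " + ".join(terms)

    @classmethod
    def from_windows(cls, windows: pd.DataFrame, **kwargs) -> "ProximalEffectModel":
        return cls(windows, **kwargs)

    def fit(self, reml: bool = True) -> ProximalEffectResults:
        return _fit_mixed(self.formula, self.data, reml=reml, prompt_re=self.prompt_re)


def fit_proximal_model(windows: pd.DataFrame, design: str = "study1", **kwargs) -> ProximalEffectResults:
    """Convenience wrapper: build the model and fit it."""
    return ProximalEffectModel(windows, design=design, **kwargs).fit()


def rescale_reference(
    windows: pd.DataFrame,
    reference_trigger: str | None = None,
    reference_intervention: str | None = None,
    design: str = "study2",
    **kwargs,
) -> ProximalEffectResults:
    """Refit with indicator coding against the chosen reference level(s).

    Setting a reference makes the lower-order interactions the *simple*
    effects at that level, the standard way to probe a three-way interaction:
    the two simple trigger-by-time effects under the two intervention
    references differ by exactly the original three-way estimate.
    """
    for name, allowed in [
        (reference_trigger, ("random", "addhrvr")),
        (reference_intervention, ("mindful", "external")),
    ]:
        if name is not None and name not in allowed:
            raise ValueError(f"unknown reference level {name!r}; allowed: {allowed}")
    return ProximalEffectModel(
        windows,
        design=design,
        trigger_coding=reference_trigger or "centered",
        intervention_coding=reference_intervention or "centered",
        **kwargs,
    ).fit()


def compare_virtual(windows: pd.DataFrame, outcome: str = "ln_rmssd") -> ProximalEffectResults:
    """Rebound contrast: trigger kind (virtual / random / addhrvr) by time (pre vs post).

    Virtual windows carry no intervention, so only pre and post rows enter.
    The coefficient of interest is the addhrvr-vs-virtual by time
    interaction: how much more HRV rises after an intervened trigger than
    after an equivalent, un-prompted (virtual) one.
    """
    df = windows[windows["time_code"].isin([-1, 1])].copy()
    df = df[np.isfinite(df[outcome])]
    if not (df["trigger_kind"] == "virtual").any():
        raise ValueError("no virtual-trigger windows in the data; run scan_virtual first")
    if df["person_id"].nunique() < 2:
        raise ValueError("need at least 2 persons")
    df["post"] = (df["time_code"] == 1).astype(float)
    df["met_c"] = df["met_mean"] - df["met_mean"].mean()
    df["smoking"] = df["smoking"].astype(float)
    formula = (
        f"{outcome} ~ met_c + smoking"
        " + C(trigger_kind, Treatment('virtual')) * post"
    )
    return _fit_mixed(formula, df, prompt_re=True)
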