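"""Engagement timecourse: binned response proportions and exponential fits.

Within a session the animal's active responding (HIT, FA) declines while
CR and MISS rise.  The session is cut into fixed-width time bins; each
response type is normalised by the presentations of the relevant tone role
in the bin (HIT and MISS by deviants, FA and CR by standards), so HIT+MISS
and FA+CR each sum to 1 wherever defined.  Each timecourse is summarised by
a single-term exponential ``y(t) = a * exp(b * t)``, and the crossing time
of the fitted HIT and MISS curves marks where misses start to outnumber
hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .paradigm import ROLE_DEVIANT
from .task import CR, FA, HIT, MISS, SessionLog


class TimecourseError(ValueError):
    pass


@dataclass(frozen=True)
class ExponentialFit:
    """y(t) = a * exp(b * t); a > 0, b in 1/s (sign free)."""

    a: float
    b: float
    r_squared: float


@dataclass(frozen=True)
class IntersectionResult:
    t_star_s: float | None
    degenerate: bool


def _trial_frame(trials) -> pd.DataFrame:
    if isinstance(trials, SessionLog):
        return pd.DataFrame(
            {
                "actual_onset_s": [t.actual_onset_s for t in trials.trials],
                "role": [t.tone.role for t in trials.trials],
                "outcome": [t.outcome for t in trials.trials],
            }
        )
    return pd.DataFrame(trials)


def response_timecourse(trials, bin_width_s: float = 120.0) -> pd.DataFrame:
    """Binned response proportions per type.

    Accepts a :class:`~oddball.task.SessionLog`, a trial table with
    ``actual_onset_s``/``role``/``outcome`` columns, or an iterable of such
    (pooled).  Returns a tidy frame with columns ``bin_center_s``,
    ``response_type``, ``n_events``, ``n_presentations``, ``value``; bins
    with zero relevant presentations are omitted for that type.
    """
    if bin_width_s <= 0:
        raise TimecourseError("bin_width_s must be positive")
    if isinstance(trials, (SessionLog, pd.DataFrame)):
        frames = [_trial_frame(trials)]
    else:
        frames = [_trial_frame(t) for t in trials]
    df = pd.concat(frames, ignore_index=True)
    if df.empty:
        raise TimecourseError("no trials in input")
    df["bin"] = (df["actual_onset_s"] // bin_width_s).astype(int)
    rows = []
    for (b, role), grp in df.groupby(["bin", "role"]):
        n_pres = len(grp)
        center = (b + 0.5) * bin_width_s
        pair = (HIT, MISS) if role == ROLE_DEVIANT else (FA, CR)
        for outcome in pair:
            n_ev = int((grp["outcome"] == outcome).sum())
            rows.append(
                {
                    "bin_center_s": center,
                    "response_type": outcome,
                    "n_events": n_ev,
                    "n_presentations": n_pres,
                    "value": n_ev / n_pres,
                }
            )
    out = pd.DataFrame(rows).sort_values(["response_type", "bin_center_s"])
    return out.reset_index(drop=True)


def fit_exponential(
    bin_centers_s: Sequence[float], values: Sequence[float]
) -> ExponentialFit:
    """Least-squares fit of y = a*exp(b*t), a > 0.

    Initialised from a log-linear regression on the strictly positive
    values, then refined by nonlinear least squares on all points (zeros
    included).  All-zero input is unfittable.
    """
    t = np.asarray(bin_centers_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise TimecourseError("need at least 3 bins to fit an exponential")
    pos = y > 0
    if not np.any(pos):
        raise TimecourseError("all values are zero; exponential fit undefined")
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), deg=1)
        p0 = (float(np.exp(intercept)), float(slope))
    else:
        p0 = (float(y[pos][0]), 0.0)
    (a, b), _ = curve_fit(
        lambda tt, a, b: a * np.exp(b * tt),
        t,
        y,
        p0=p0,
        bounds=([1e-12, -np.inf], [np.inf, np.inf]),
        maxfev=20000,
    )
    pred = a * np.exp(b * t)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return ExponentialFit(a=float(a), b=float(b), r_squared=r2)


def fit_timecourses(tc: pd.DataFrame) -> dict[str, ExponentialFit]:
    """Exponential fit per response type from a tidy timecourse frame."""
    fits = {}
    for rtype, grp in tc.groupby("response_type"):
        try:
            fits[rtype] = fit_exponential(grp["bin_center_s"].values, grp["value"].values)
        except (TimecourseError, RuntimeError):
            continue
    return fits


def curve_intersection(
    fit1: ExponentialFit, fit2: ExponentialFit, t_max: float
) -> IntersectionResult:
    """Crossing time of two fitted exponentials within [0, t_max].

    ``t* = ln(a1/a2) / (b2 - b1)`` when the rate constants differ; equal
    rates with different amplitudes never intersect (``None``); identical
    curves are degenerate (everywhere equal).
    """
    if fit1.a <= 0 or fit2.a <= 0:
        raise TimecourseError("amplitudes must be positive")
    if fit1.b == fit2.b:
        if fit1.a == fit2.a:
            return IntersectionResult(t_star_s=None, degenerate=True)
        return IntersectionResult(t_star_s=None, degenerate=False)
    t_star = float(np.log(fit1.a / fit2.a) / (fit2.b - fit1.b))
    if 0.0 <= t_star <= t_max:
        return IntersectionResult(t_star_s=t_star, degenerate=False)
    return IntersectionResult(t_star_s=None, degenerate=False)
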