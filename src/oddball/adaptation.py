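"""Adaptation analysis: hit probability vs. the number of preceding standards.

For each deviant, ``k`` is the length of the maximal run of standards
immediately before it (the first deviant's run includes the session's
lead-in).  Pooling deviant trials across sessions gives a hit rate per
observed ``k``; the trend is summarised with an unweighted second-degree
polynomial least-squares fit and its R².  Behaviourally, a rising curve
that plateaus indicates that detection of the rare tone strengthens as the
regularity (run of standards) before it grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .paradigm import ROLE_DEVIANT, StimulusSequence
from .task import HIT, SessionLog


class AdaptationError(ValueError):
    pass


@dataclass(frozen=True)
class QuadraticFit:
    """y = c0 + c1*k + c2*k**2 with coefficient of determination R²."""

    c0: float
    c1: float
    c2: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class AdaptationCurve:
    """Hit rate per preceding-standard count ``k`` (pooled over sessions)."""

    k: np.ndarray
    n_dev: np.ndarray
    n_hit: np.ndarray
    rate: np.ndarray
    fit: QuadraticFit | None = None


def preceding_standard_counts(seq: StimulusSequence) -> np.ndarray:
    """Per-deviant count of standards in the run immediately before it."""
    ks = []
    run = 0
    for tone in seq.tones:
        if tone.role == ROLE_DEVIANT:
            ks.append(run)
            run = 0
        else:
            run += 1
    return np.asarray(ks, dtype=int)


def _roles_outcomes(table) -> tuple[list[str], list[str]]:
    if isinstance(table, SessionLog):
        return [t.tone.role for t in table.trials], [t.outcome for t in table.trials]
    # anything tabular with 'role' and 'outcome' columns in presentation order
    return list(table["role"]), list(table["outcome"])


def hit_rate_by_preceding(trial_tables: Iterable) -> AdaptationCurve:
    """Pool deviant trials across sessions into a rate-vs-k curve.

    Accepts :class:`~oddball.task.SessionLog` objects or tabular trial
    records carrying ``role`` and ``outcome`` in presentation order.
    ``k`` values with zero deviants are omitted.
    """
    dev: dict[int, int] = {}
    hit: dict[int, int] = {}
    n_deviants = 0
    for table in trial_tables:
        roles, outcomes = _roles_outcomes(table)
        run = 0
        for role, outcome in zip(roles, outcomes):
            if role == ROLE_DEVIANT:
                dev[run] = dev.get(run, 0) + 1
                if outcome == HIT:
                    hit[run] = hit.get(run, 0) + 1
                n_deviants += 1
                run = 0
            else:
                run += 1
    if n_deviants == 0:
        raise AdaptationError("no deviant trials in input")
    ks = np.array(sorted(dev), dtype=int)
    n_dev = np.array([dev[k] for k in ks], dtype=int)
    n_hit = np.array([hit.get(k, 0) for k in ks], dtype=int)
    return AdaptationCurve(k=ks, n_dev=n_dev, n_hit=n_hit, rate=n_hit / n_dev)


def fit_quadratic(curve: AdaptationCurve, weighted: bool = False) -> AdaptationCurve:
    """Least-squares quadratic fit of rate on k, attached to the curve.

    Unweighted by default (each observed ``k`` contributes one point, as
    when fitting the normalised mean curve); ``weighted=True`` weights each
    point by its deviant count.  R² is defined as 1 when the rates are
    constant (zero total variance: the fit explains everything there is).
    """
    k = np.asarray(curve.k, dtype=float)
    y = np.asarray(curve.rate, dtype=float)
    if np.unique(k).size < 3:
        raise AdaptationError("need at least 3 distinct k values for a quadratic fit")
    w = np.sqrt(curve.n_dev.astype(float)) if weighted else None
    # polyfit returns highest degree first
    c2, c1, c0 = np.polyfit(k, y, deg=2, w=w)
    pred = c0 + c1 * k + c2 * k**2
    ww = curve.n_dev.astype(float) if weighted else np.ones_like(y)
    ybar = np.average(y, weights=ww)
    ss_res = float(np.sum(ww * (y - pred) ** 2))
    ss_tot = float(np.sum(ww * (y - ybar) ** 2))
    # constant rates: zero total variance up to float rounding -> perfect fit
    tiny = 1e-12 * max(1.0, float(np.max(np.abs(y))) ** 2) * y.size
    r2 = 1.0 if ss_tot <= tiny else 1.0 - ss_res / ss_tot
    fit = QuadraticFit(c0=float(c0), c1=float(c1), c2=float(c2), r_squared=r2, n_points=k.size)
    return replace(curve, fit=fit)
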