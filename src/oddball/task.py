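"""Go/no-go trial scoring: join tone and nose-poke events into HIT/FA/CR/MISS.

A trial's response window is ``[onset, onset + response_window_s)``; the
earliest not-yet-consumed poke inside it is the trial's response.  A
response to a deviant is a HIT (rewarded with one pellet), a response to a
standard a false alarm (FA, punished with a timeout), no response is a
correct rejection (CR, standard) or a miss (MISS, deviant).

Two clock conventions are supported.  In ``scheduled`` mode the scorer
advances the session clock itself: the next tone's onset is the previous
onset plus the ISI, plus the timeout if the previous trial was an FA.  In
``recorded`` mode the caller supplies the logged onsets and the scorer
trusts them, so data from hardware with either timeout convention is
scorable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .paradigm import ROLE_DEVIANT, ROLE_STANDARD, StimulusSequence, ToneEvent

HIT = "HIT"
FA = "FA"
CR = "CR"
MISS = "MISS"
OUTCOMES = (HIT, FA, CR, MISS)


class ScoringError(ValueError):
    """Invalid scoring input or configuration."""


@dataclass(frozen=True)
class PokeEvent:
    """A nose-poke at absolute session time ``time_s``."""

    time_s: float


@dataclass(frozen=True)
class ScoredTrial:
    """One tone joined with its behavioural outcome."""

    tone: ToneEvent
    actual_onset_s: float
    outcome: str
    latency_s: float | None
    rewarded: bool
    timeout_applied: bool


@dataclass(frozen=True)
class SessionLog:
    """Scored session: one trial per tone plus the pokes no window captured."""

    spec: object
    trials: tuple[ScoredTrial, ...]
    unassigned_pokes: tuple[float, ...]
    n_rewards: int


@dataclass(frozen=True)
class SessionCounts:
    """Per-session response counts, percentages and mean latencies."""

    n_hit: int
    n_fa: int
    n_cr: int
    n_miss: int
    n_dev: int
    n_std: int
    pct_hit: float
    pct_cr: float
    pct_fa: float
    pct_miss: float
    mean_hit_latency_s: float | None
    mean_fa_latency_s: float | None


def _poke_times(pokes) -> np.ndarray:
    times = np.asarray(
        [p.time_s if isinstance(p, PokeEvent) else float(p) for p in pokes], dtype=float
    )
    if times.size and np.any(np.diff(times) < 0):
        raise ScoringError("poke times must be sorted ascending")
    if times.size and times[0] < 0:
        raise ScoringError("poke times must be non-negative")
    return times


def score_session(
    seq: StimulusSequence,
    pokes: Sequence,
    mode: str = "scheduled",
    onsets: Sequence[float] | None = None,
) -> SessionLog:
    """Score a session's pokes against its tone train.

    Each poke is consumed by at most one trial (the first window containing
    it); pokes outside every window — including pokes made during an FA
    timeout — are returned unassigned and trigger no further punishment.
    """
    spec = seq.spec
    if mode not in ("scheduled", "recorded"):
        raise ScoringError(f"mode must be 'scheduled' or 'recorded', got {mode!r}")
    if spec.response_window_s >= spec.isi_s:
        raise ScoringError("response window must be shorter than the ISI")
    times = _poke_times(pokes)
    if mode == "recorded":
        if onsets is None:
            actual = [t.nominal_onset_s for t in seq.tones]
        else:
            actual = list(map(float, onsets))
            if len(actual) != len(seq.tones):
                raise ScoringError("recorded mode needs one onset per tone")
    rw = spec.response_window_s
    trials: list[ScoredTrial] = []
    unassigned: list[float] = []
    j = 0
    clock = seq.tones[0].nominal_onset_s if seq.tones else 0.0
    for i, tone in enumerate(seq.tones):
        onset = actual[i] if mode == "recorded" else clock
        while j < times.size and times[j] < onset:
            unassigned.append(times[j])
            j += 1
        latency = None
        if j < times.size and times[j] < onset + rw:
            latency = times[j] - onset
            j += 1
        if tone.role == ROLE_DEVIANT:
            outcome = HIT if latency is not None else MISS
        else:
            outcome = FA if latency is not None else CR
        trials.append(
            ScoredTrial(
                tone=tone,
                actual_onset_s=onset,
                outcome=outcome,
                latency_s=latency,
                rewarded=outcome == HIT,
                timeout_applied=outcome == FA,
            )
        )
        if mode == "scheduled":
            clock = onset + spec.isi_s + (spec.timeout_s if outcome == FA else 0.0)
    unassigned.extend(times[j:])
    n_rewards = sum(1 for t in trials if t.rewarded)
    return SessionLog(
        spec=spec, trials=tuple(trials), unassigned_pokes=tuple(unassigned), n_rewards=n_rewards
    )


def session_summary(log: SessionLog) -> SessionCounts:
    """Counts, percentages and mean latencies for one scored session.

    Identities: n_hit + n_miss = n_dev and n_fa + n_cr = n_std.  Latency
    means are over present latencies only and ``None`` when there are none.
    """
    n_hit = sum(1 for t in log.trials if t.outcome == HIT)
    n_fa = sum(1 for t in log.trials if t.outcome == FA)
    n_cr = sum(1 for t in log.trials if t.outcome == CR)
    n_miss = sum(1 for t in log.trials if t.outcome == MISS)
    n_dev = n_hit + n_miss
    n_std = n_fa + n_cr
    hit_lat = [t.latency_s for t in log.trials if t.outcome == HIT]
    fa_lat = [t.latency_s for t in log.trials if t.outcome == FA]
    return SessionCounts(
        n_hit=n_hit,
        n_fa=n_fa,
        n_cr=n_cr,
        n_miss=n_miss,
        n_dev=n_dev,
        n_std=n_std,
        pct_hit=100.0 * n_hit / n_dev if n_dev else float("nan"),
        pct_cr=100.0 * n_cr / n_std if n_std else float("nan"),
        pct_fa=100.0 * n_fa / n_std if n_std else float("nan"),
        pct_miss=100.0 * n_miss / n_dev if n_dev else float("nan"),
        mean_hit_latency_s=float(np.mean(hit_lat)) if hit_lat else None,
        mean_fa_latency_s=float(np.mean(fa_lat)) if fa_lat else None,
    )


def criterion_reached(
    dprimes: Sequence[float], threshold: float = 1.0, k: int = 3
) -> tuple[bool, int | None]:
    """Training criterion: ``k`` consecutive sessions with d' >= threshold.

    Returns ``(reached, start)`` where ``start`` is the 0-based index of the
    first qualifying run (``None`` if never reached; an empty list is never
    a pass).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    run = 0
    for i, d in enumerate(dprimes):
        run = run + 1 if d >= threshold else 0
        if run >= k:
            return True, i - k + 1
    return False, None
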