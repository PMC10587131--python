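"""Trial scoring: outcomes, window semantics, scheduled clock, criterion."""

import numpy as np
import pytest

from oddball import (
    ParadigmSpec,
    ScoringError,
    criterion_reached,
    make_oddball_sequence,
    score_session,
    session_summary,
)
from oddball.task import CR, FA, HIT, MISS

from conftest import classic_spec


def tiny_spec(**overrides):
    kwargs = dict(
        kind="oddball",
        n_tones=12,
        n_deviant=1,
        standard_khz=8.0,
        deviant_khz=11.3,
        isi_s=1.5,
        lead_in=5,
        min_run=3,
        seed=0,
    )
    kwargs.update(overrides)
    return ParadigmSpec(**kwargs)


def brute_force_onsets(seq, pokes):
    """Independent event-by-event walk of the session timeline.

    Processes tones and pokes in strict time order with an explicit
    open-window state machine, instead of the scorer's per-tone loop.
    """
    rw = seq.spec.response_window_s
    onsets = []
    outcomes = []
    pokes = list(pokes)
    t = seq.tones[0].nominal_onset_s
    for tone in seq.tones:
        onsets.append(t)
        # discard pokes that happened strictly before this window opened
        while pokes and pokes[0] < t:
            pokes.pop(0)
        responded = bool(pokes) and pokes[0] < t + rw
        if responded:
            pokes.pop(0)
        if tone.role == "deviant":
            outcomes.append(HIT if responded else MISS)
        else:
            outcomes.append(FA if responded else CR)
        t = t + seq.spec.isi_s + (seq.spec.timeout_s if outcomes[-1] == FA else 0.0)
    return onsets, outcomes


def test_hit_with_latency():
    seq = make_oddball_sequence(tiny_spec())
    d = seq.deviant_indices[0]
    onset = d * 1.5
    log = score_session(seq, [onset + 0.50])
    trial = log.trials[d]
    assert trial.outcome == HIT
    assert trial.latency_s == pytest.approx(0.50)
    assert trial.rewarded and not trial.timeout_applied
    assert log.n_rewards == 1


def test_late_poke_is_a_miss_and_may_spill_to_next_window():
    seq = make_oddball_sequence(tiny_spec())
    d = seq.deviant_indices[0]
    onset = d * 1.5
    log = score_session(seq, [onset + 1.60])  # outside the 1.49 s window
    assert log.trials[d].outcome == MISS
    # 1.60 s after onset falls 0.10 s into the NEXT tone's window
    assert log.trials[d + 1].outcome in (FA, HIT)
    assert log.trials[d + 1].latency_s == pytest.approx(0.10)


def test_window_end_is_exclusive():
    seq = make_oddball_sequence(tiny_spec())
    d = seq.deviant_indices[0]
    log = score_session(seq, [d * 1.5 + seq.spec.response_window_s])
    assert log.trials[d].outcome == MISS


def test_fa_timeout_shifts_scheduled_clock():
    """After an FA at onset T, the next tone starts at T + ISI + 5 s."""
    seq = make_oddball_sequence(tiny_spec())
    log = score_session(seq, [0.2])  # FA on the very first (standard) tone
    assert log.trials[0].outcome == FA and log.trials[0].timeout_applied
    assert log.trials[1].actual_onset_s == pytest.approx(0.0 + 1.5 + 5.0)
    # a poke during the timeout is unassigned and triggers nothing
    log2 = score_session(seq, [0.2, 3.0])
    assert 3.0 in log2.unassigned_pokes
    assert log2.trials[1].actual_onset_s == pytest.approx(6.5)


def test_scheduled_clock_matches_event_walk_oracle():
    """Scorer onsets/outcomes equal an independent event-by-event simulation."""
    rng = np.random.default_rng(42)
    for trial in range(60):
        n_tones = int(rng.integers(10, 51))
        n_dev = int(rng.integers(1, max(2, n_tones // 6)))
        spec = ParadigmSpec(
            kind="oddball",
            n_tones=n_tones,
            n_deviant=n_dev,
            standard_khz=8.0,
            deviant_khz=11.3,
            isi_s=1.5,
            lead_in=min(5, n_tones - n_dev - 3 * n_dev),
            min_run=3,
            seed=trial,
        )
        if not spec.is_feasible:
            continue
        seq = make_oddball_sequence(spec)
        # random pokes over an ample horizon (timeouts can stretch the session)
        n_pokes = int(rng.integers(0, n_tones))
        pokes = np.sort(rng.uniform(0, n_tones * 1.5 * 2, size=n_pokes))
        log = score_session(seq, pokes)
        onsets, outcomes = brute_force_onsets(seq, pokes)
        assert [t.actual_onset_s for t in log.trials] == pytest.approx(onsets)
        assert [t.outcome for t in log.trials] == outcomes


def test_poke_partition_and_outcome_conservation():
    """Every poke is consumed once or unassigned; outcomes partition tones."""
    rng = np.random.default_rng(7)
    for i in range(10):
        seq = make_oddball_sequence(classic_spec(seed=i))
        pokes = np.sort(rng.uniform(0, 700 * 1.5 * 1.5, size=200))
        log = score_session(seq, pokes)
        n_consumed = sum(1 for t in log.trials if t.latency_s is not None)
        assert n_consumed + len(log.unassigned_pokes) == len(pokes)
        s = session_summary(log)
        assert s.n_hit + s.n_miss == s.n_dev == 70
        assert s.n_fa + s.n_cr == s.n_std == 630
        assert len(log.trials) == 700


def test_summary_percentages_and_degenerate_latency():
    seq = make_oddball_sequence(tiny_spec(n_tones=80, n_deviant=8, seed=1))
    d = seq.deviant_indices
    log = score_session(seq, [])  # no pokes at all
    s = session_summary(log)
    assert s.pct_hit == 0.0 and s.pct_cr == 100.0
    assert s.mean_hit_latency_s is None and s.mean_fa_latency_s is None
    # respond to the first deviant only
    log = score_session(seq, [log.trials[d[0]].actual_onset_s + 0.4])
    s = session_summary(log)
    assert s.n_hit == 1 and s.pct_hit == pytest.approx(100.0 / 8)
    assert s.mean_hit_latency_s == pytest.approx(0.4)


def test_unsorted_pokes_rejected():
    seq = make_oddball_sequence(tiny_spec())
    with pytest.raises(ScoringError):
        score_session(seq, [5.0, 1.0])


@pytest.mark.parametrize(
    "dprimes, threshold, k, expected",
    [
        ([0.4, 1.0, 1.2, 1.1], 1.0, 3, (True, 1)),
        ([1.2, 0.9, 1.5, 1.4], 1.0, 3, (False, None)),
        ([2.0, 2.0, 2.0], 1.0, 1, (True, 0)),
        ([], 1.0, 3, (False, None)),
    ],
)
def test_training_criterion_runs(dprimes, threshold, k, expected):
    assert criterion_reached(dprimes, threshold, k) == expected
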