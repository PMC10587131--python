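"""Synthetic rat agent: limit behaviour, determinism, session statistics."""

import math

import numpy as np
import pytest
from scipy.special import expit

from oddball import (
    AgentState,
    RatAgentParams,
    dprime_from_counts,
    make_oddball_sequence,
    score_session,
    session_summary,
    simulate_session,
)
from oddball.agent import agent_step
from oddball.paradigm import ToneEvent

from conftest import classic_spec, simulated_logs


def tone(index, role, freq, onset):
    return ToneEvent(index=index, role=role, frequency_khz=freq, nominal_onset_s=onset)


def test_fresh_state_responds_at_baseline():
    """Empty expectation field: nu=1, c=0, p = A*(lambda + (1-lambda)*sigmoid(-beta*theta))."""
    params = RatAgentParams(seed=1)
    state = AgentState()
    rng = np.random.default_rng(0)
    out = agent_step(state, params, tone(0, "standard", 8.0, 0.0), rng)
    assert out.novelty == 1.0 and out.confidence == 0.0
    expected = 1.0 * (
        params.lambda_impulse
        + (1 - params.lambda_impulse) * expit(-params.beta * params.theta)
    )
    assert out.p_response == pytest.approx(expected)


def test_adapted_standard_vs_far_deviant_limits():
    """After many standards: standard ~ impulsive baseline, far deviant ~ ceiling."""
    params = RatAgentParams(seed=1, tau_eng_s=1e12)  # freeze engagement at 1
    state = AgentState()
    rng = np.random.default_rng(0)
    for i in range(400):
        agent_step(state, params, tone(i, "standard", 8.0, i * 1.5), rng)
    out_std = agent_step(state, params, tone(400, "standard", 8.0, 600.0), rng)
    p_floor = params.lambda_impulse + (1 - params.lambda_impulse) * expit(
        params.beta * (out_std.novelty * out_std.confidence - params.theta)
    )
    assert out_std.novelty < 0.1
    assert out_std.p_response == pytest.approx(p_floor)
    assert out_std.p_response < 0.2
    # a deviant 3 octaves away has essentially zero kernel overlap
    out_dev = agent_step(state, params, tone(401, "deviant", 64.0, 601.5), rng)
    assert out_dev.novelty > 0.97
    ceiling = params.lambda_impulse + (1 - params.lambda_impulse) * expit(
        params.beta * (out_dev.novelty * out_dev.confidence - params.theta)
    )
    assert out_dev.p_response == pytest.approx(ceiling)
    assert out_dev.p_response > 0.8


def test_seed_determinism_of_sessions():
    seq = make_oddball_sequence(classic_spec(seed=9))
    p1, t1 = simulate_session(seq, RatAgentParams(seed=42))
    p2, t2 = simulate_session(seq, RatAgentParams(seed=42))
    p3, _ = simulate_session(seq, RatAgentParams(seed=43))
    assert np.array_equal(p1, p2)
    assert t1.equals(t2)
    assert not np.array_equal(p1, p3)


def test_deterministic_discriminator_hits_ceiling():
    """lambda=0, beta->inf, full engagement: every deviant hit, zero FAs."""
    seq = make_oddball_sequence(classic_spec(seed=3))
    params = RatAgentParams(seed=3, lambda_impulse=0.0, beta=1e6, theta=0.5, A_min=1.0)
    pokes, _ = simulate_session(seq, params)
    s = session_summary(score_session(seq, pokes))
    assert s.n_hit == 70 and s.n_fa == 0
    res = dprime_from_counts(s.n_hit, s.n_dev, s.n_fa, s.n_std, correction="auto")
    assert res.rate_pair.corrected
    assert res.d_prime == pytest.approx(5.62, abs=0.01)


def test_non_discriminating_agent_has_zero_dprime():
    """beta=0 makes poke probability role-blind; d' averages to zero."""
    ds = []
    for i in range(12):
        seq = make_oddball_sequence(classic_spec(seed=300 + i))
        pokes, _ = simulate_session(seq, RatAgentParams(seed=900 + i, beta=0.0))
        s = session_summary(score_session(seq, pokes))
        ds.append(dprime_from_counts(s.n_hit, s.n_dev, s.n_fa, s.n_std).d_prime)
    assert abs(np.mean(ds)) < 0.15


def test_default_sessions_land_in_empirical_bands(default_logs):
    """Mean %HIT in 55-80, %CR in 80-95, latencies in 0.5-0.8 s."""
    sums = [session_summary(log) for log in default_logs]
    pct_hit = np.mean([s.pct_hit for s in sums])
    pct_cr = np.mean([s.pct_cr for s in sums])
    assert 55.0 <= pct_hit <= 80.0
    assert 80.0 <= pct_cr <= 95.0
    lat_hit = np.mean([s.mean_hit_latency_s for s in sums])
    lat_fa = np.mean([s.mean_fa_latency_s for s in sums])
    assert 0.5 <= lat_hit <= 0.8
    assert 0.5 <= lat_fa <= 0.8


def test_latencies_respect_truncation_and_window():
    seq = make_oddball_sequence(classic_spec(seed=5))
    pokes, truth = simulate_session(seq, RatAgentParams(seed=5))
    lat = truth.loc[truth.responded, "latency_s"]
    assert (lat >= 0).all()
    assert (lat < seq.spec.response_window_s).all()
    # pokes are onset + latency, sorted, one per responded tone
    assert len(pokes) == int(truth.responded.sum())
    assert np.all(np.diff(pokes) > 0)


def test_agent_clock_matches_scorer_clock():
    """Agent-side scheduled onsets equal the scorer's reconstruction."""
    seq = make_oddball_sequence(classic_spec(seed=8))
    pokes, truth = simulate_session(seq, RatAgentParams(seed=8))
    log = score_session(seq, pokes)
    assert [t.actual_onset_s for t in log.trials] == pytest.approx(
        list(truth.actual_onset_s)
    )
    # and every simulated response is scored as such (no spillover)
    scored_resp = [t.latency_s is not None for t in log.trials]
    assert scored_resp == list(truth.responded)


def test_rare_deviants_are_detected_better_than_frequent_ones():
    """d' at 10% deviants exceeds d' at 30% for matched agent seeds."""
    wins = 0
    n = 15
    for i in range(n):
        d = {}
        for nd, mr, key in ((70, 3, "p10"), (207, 2, "p30")):
            spec = classic_spec(seed=i, n_deviant=nd, min_run=mr)
            seq = make_oddball_sequence(spec)
            pokes, _ = simulate_session(seq, RatAgentParams(seed=5000 + i))
            s = session_summary(score_session(seq, pokes))
            d[key] = dprime_from_counts(s.n_hit, s.n_dev, s.n_fa, s.n_std).d_prime
        wins += d["p30"] < d["p10"]
    assert wins >= n - 2
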