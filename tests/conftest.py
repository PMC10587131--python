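"""Shared fixtures: canonical paradigm specs and simulated sessions."""

import pytest

from oddball import (
    ParadigmSpec,
    RatAgentParams,
    make_oddball_sequence,
    score_session,
    simulate_session,
)

MANY_DEVIANT_CANDIDATES = (4.0, 4.8, 5.7, 6.7, 9.5, 11.3, 13.5, 16.0, 19.0)


def classic_spec(seed: int = 0, **overrides) -> ParadigmSpec:
    """700-tone 90/10 oddball session, 8.0 kHz standard, 0.5-oct deviant."""
    kwargs = dict(
        kind="oddball",
        n_tones=700,
        n_deviant=70,
        standard_khz=8.0,
        deviant_khz=11.3,
        isi_s=1.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return ParadigmSpec(**kwargs)


def many_deviant_spec(seed: int = 0, **overrides) -> ParadigmSpec:
    """720-tone 90/10 many-deviant session with 9 candidate frequencies."""
    kwargs = dict(
        kind="many_deviant",
        n_tones=720,
        n_deviant=72,
        standard_khz=8.0,
        deviant_khz=MANY_DEVIANT_CANDIDATES,
        isi_s=1.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return ParadigmSpec(**kwargs)


def simulated_logs(n_sessions: int, seed0: int = 0, agent_overrides=None, **spec_overrides):
    """Score ``n_sessions`` default-agent sessions (distinct seeds)."""
    logs = []
    for i in range(n_sessions):
        seq = make_oddball_sequence(classic_spec(seed=seed0 + i, **spec_overrides))
        params = RatAgentParams(seed=10_000 + seed0 + i, **(agent_overrides or {}))
        pokes, _ = simulate_session(seq, params)
        logs.append(score_session(seq, pokes))
    return logs


@pytest.fixture(scope="session")
def default_logs():
    """Twenty default-parameter 90/10 sessions, shared across tests."""
    return simulated_logs(20, seed0=0)
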