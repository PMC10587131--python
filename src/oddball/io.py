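"""File formats: sequence/poke/trial CSV dialects and JSON configs.

All event data is plain CSV (sessions are ~10^3 rows; human-auditable text
is the right default).  Every file starts with ``#``-prefixed metadata
lines carrying the tool version, the seed and a hash of the generating
configuration, so reruns with identical inputs are byte-identical and
auditable.  The sequence CSV embeds its paradigm spec as one JSON metadata
line, making the round trip lossless.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .agent import RatAgentParams
from .paradigm import ParadigmSpec, StimulusSequence, ToneEvent
from .task import SessionCounts, SessionLog


class FormatError(ValueError):
    """Malformed file or configuration."""


SEQUENCE_COLUMNS = ["index", "role", "frequency_khz", "nominal_onset_s", "duration_ms"]
POKE_COLUMNS = ["time_s"]
TRIAL_COLUMNS = [
    "index",
    "role",
    "frequency_khz",
    "actual_onset_s",
    "outcome",
    "latency_s",
    "rewarded",
    "timeout_applied",
]


# -- JSON configs -----------------------------------------------------------

def _from_dict(cls, data: dict, what: str):
    if not isinstance(data, dict):
        raise FormatError(f"{what} must be a JSON object")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise FormatError(f"unknown {what} keys: {', '.join(unknown)}")
    if "deviant_khz" in data and isinstance(data["deviant_khz"], list):
        data = {**data, "deviant_khz": tuple(data["deviant_khz"])}
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"invalid {what}: {exc}") from exc


def spec_from_dict(data: dict) -> ParadigmSpec:
    """Build a :class:`ParadigmSpec` from a JSON-style dict; unknown keys rejected."""
    return _from_dict(ParadigmSpec, data, "paradigm config")


def spec_to_dict(spec: ParadigmSpec) -> dict:
    d = dataclasses.asdict(spec)
    if isinstance(d["deviant_khz"], tuple):
        d["deviant_khz"] = list(d["deviant_khz"])
    return d


def params_from_dict(data: dict) -> RatAgentParams:
    return _from_dict(RatAgentParams, data, "agent params")


def params_to_dict(params: RatAgentParams) -> dict:
    return dataclasses.asdict(params)


def read_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, separators=(",", ":")).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:12]


# -- metadata-framed CSV ----------------------------------------------------

def _write_csv(df: pd.DataFrame, path, meta: dict) -> None:
    lines = [f"# oddball {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}={v}")
    body = df.to_csv(index=False, lineterminator="\n", float_format="%.6f")
    Path(path).write_text("\n".join(lines) + "\n" + body, encoding="utf-8")


def _read_csv(path, required: list[str]) -> tuple[pd.DataFrame, dict]:
    text = Path(path).read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    data_lines = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v
            continue
        data_lines.append(line)
    try:
        df = pd.read_csv(_io.StringIO("\n".join(data_lines)))
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV body: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df, meta


# -- sequences --------------------------------------------------------------

def write_sequence(seq: StimulusSequence, path) -> None:
    df = pd.DataFrame(
        {
            "index": [t.index for t in seq.tones],
            "role": [t.role for t in seq.tones],
            "frequency_khz": [t.frequency_khz for t in seq.tones],
            "nominal_onset_s": [t.nominal_onset_s for t in seq.tones],
            "duration_ms": [t.duration_ms for t in seq.tones],
        }
    )
    spec_json = json.dumps(spec_to_dict(seq.spec), sort_keys=True, separators=(",", ":"))
    meta = {
        "seed": seq.spec.seed,
        "config_hash": config_hash(spec_to_dict(seq.spec)),
        "spec": spec_json,
    }
    _write_csv(df, path, meta)


def read_sequence(path) -> StimulusSequence:
    df, meta = _read_csv(path, SEQUENCE_COLUMNS)
    if "spec" not in meta:
        raise FormatError(f"{path}: missing '# spec=...' metadata line")
    spec = spec_from_dict(json.loads(meta["spec"]))
    tones = tuple(
        ToneEvent(
            index=int(r["index"]),
            role=str(r["role"]),
            frequency_khz=float(r["frequency_khz"]),
            nominal_onset_s=float(r["nominal_onset_s"]),
            duration_ms=float(r["duration_ms"]),
        )
        for r in df.to_dict("records")
    )
    return StimulusSequence(spec=spec, tones=tones)


# -- pokes ------------------------------------------------------------------

def write_pokes(times, path, meta: dict | None = None) -> None:
    df = pd.DataFrame({"time_s": list(times)})
    _write_csv(df, path, meta or {})


def read_pokes(path):
    df, _ = _read_csv(path, POKE_COLUMNS)
    return df["time_s"].to_numpy(dtype=float)


# -- scored trials ----------------------------------------------------------

def trials_frame(log: SessionLog) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [t.tone.index for t in log.trials],
            "role": [t.tone.role for t in log.trials],
            "frequency_khz": [t.tone.frequency_khz for t in log.trials],
            "actual_onset_s": [t.actual_onset_s for t in log.trials],
            "outcome": [t.outcome for t in log.trials],
            "latency_s": [t.latency_s for t in log.trials],
            "rewarded": [t.rewarded for t in log.trials],
            "timeout_applied": [t.timeout_applied for t in log.trials],
        }
    )


def write_trials(log: SessionLog, path, meta: dict | None = None) -> None:
    _write_csv(trials_frame(log), path, meta or {})


def read_trials(path) -> pd.DataFrame:
    df, _ = _read_csv(path, TRIAL_COLUMNS)
    return df


def summary_to_dict(counts: SessionCounts) -> dict:
    return dataclasses.asdict(counts)
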