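"""Stimulus-sequence construction for auditory oddball go/no-go tasks.

A session is a fixed-length train of pure tones: a high-probability
*standard* frequency interrupted by low-probability *deviant* tones.
Three paradigm variants are supported:

* ``oddball`` — one standard, one deviant frequency (e.g. 630 standards /
  70 deviants in a 700-tone session).
* ``contrast_variant`` — identical structure, but the deviant frequency is
  chosen at a different octave contrast from the standard.
* ``many_deviant`` — each deviant draws its frequency from a candidate set
  (e.g. 9 quarter-octave neighbours of the standard), standard fixed.

Placement constraints: the first ``lead_in`` tones are standards and every
deviant is preceded by at least ``min_run`` standards.  Deviant positions
are sampled uniformly over all placements satisfying those constraints by
drawing a uniform random composition of the "spare" standards, which avoids
rejection sampling entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import stream

ROLE_STANDARD = "standard"
ROLE_DEVIANT = "deviant"

KINDS = ("oddball", "contrast_variant", "many_deviant")


class ParadigmError(ValueError):
    """Invalid paradigm parameter."""


class FeasibilityError(ParadigmError):
    """The requested counts cannot satisfy the spacing constraints.

    Attributes
    ----------
    max_feasible_min_run : int
        Largest ``min_run`` for which the requested counts are feasible.
    """

    def __init__(self, message: str, max_feasible_min_run: int):
        super().__init__(message)
        self.max_feasible_min_run = max_feasible_min_run


@dataclass(frozen=True)
class ToneEvent:
    """One tone presentation: role, frequency and nominal (planned) onset."""

    index: int
    role: str
    frequency_khz: float
    nominal_onset_s: float
    duration_ms: float = 200.0


@dataclass(frozen=True)
class ParadigmSpec:
    """Full description of a session's stimulus protocol.

    Parameters mirror the behavioural protocol: ``isi_s`` is the
    onset-to-onset interstimulus interval, ``response_window_s`` the limited
    hold during which a nose-poke counts as a response (1.49 s), and
    ``timeout_s`` the punishment delay appended after each false alarm.
    ``deviant_khz`` is a single frequency for oddball/contrast sessions or a
    sequence of candidate frequencies for many-deviant sessions.
    """

    kind: str
    n_tones: int
    n_deviant: int
    standard_khz: float
    deviant_khz: float | tuple[float, ...]
    isi_s: float = 1.5
    response_window_s: float = 1.49
    timeout_s: float = 5.0
    lead_in: int = 5
    min_run: int = 3
    duration_ms: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParadigmError(f"unknown paradigm kind {self.kind!r}; expected one of {KINDS}")
        if not (0 < self.n_deviant < self.n_tones):
            raise ParadigmError(
                f"need 0 < n_deviant < n_tones, got n_deviant={self.n_deviant}, n_tones={self.n_tones}"
            )
        if self.standard_khz <= 0:
            raise ParadigmError("standard_khz must be positive")
        if self.response_window_s >= self.isi_s:
            raise ParadigmError(
                f"response window ({self.response_window_s} s) must be shorter than "
                f"the ISI ({self.isi_s} s): windows would overlap"
            )
        if self.lead_in < 0 or self.min_run < 0:
            raise ParadigmError("lead_in and min_run must be non-negative")
        if self.timeout_s < 0:
            raise ParadigmError("timeout_s must be non-negative")
        if self.kind == "many_deviant":
            cands = self.deviant_khz
            if not isinstance(cands, (tuple, list)) or len(cands) == 0:
                raise ParadigmError("many_deviant requires a non-empty deviant frequency list")
            object.__setattr__(self, "deviant_khz", tuple(float(f) for f in cands))
            if any(f <= 0 for f in self.deviant_khz):
                raise ParadigmError("deviant frequencies must be positive")
            if any(f == self.standard_khz for f in self.deviant_khz):
                raise ParadigmError(
                    "standard frequency must be excluded from the deviant candidate list"
                )
        else:
            if isinstance(self.deviant_khz, (tuple, list)):
                raise ParadigmError(f"{self.kind} takes a single deviant frequency")
            if self.deviant_khz <= 0:
                raise ParadigmError("deviant_khz must be positive")
            if self.deviant_khz == self.standard_khz:
                raise ParadigmError("deviant frequency must differ from the standard")

    @property
    def n_standard(self) -> int:
        return self.n_tones - self.n_deviant

    @property
    def max_feasible_min_run(self) -> int:
        """Largest min_run supported by the counts: floor((n_std − lead_in)/n_deviant)."""
        return (self.n_standard - self.lead_in) // self.n_deviant

    @property
    def is_feasible(self) -> bool:
        return self.n_standard >= self.lead_in + self.min_run * self.n_deviant


@dataclass(frozen=True)
class StimulusSequence:
    """An ordered tone train together with the spec that produced it."""

    spec: ParadigmSpec
    tones: tuple[ToneEvent, ...]

    def __len__(self) -> int:
        return len(self.tones)

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(t.role for t in self.tones)

    @property
    def deviant_indices(self) -> tuple[int, ...]:
        return tuple(t.index for t in self.tones if t.role == ROLE_DEVIANT)

    @property
    def n_deviant(self) -> int:
        return sum(1 for t in self.tones if t.role == ROLE_DEVIANT)

    @property
    def n_standard(self) -> int:
        return len(self.tones) - self.n_deviant


@dataclass(frozen=True)
class Violation:
    rule: str
    index: int
    message: str


def build_frequency_ladder(
    base_khz: float, step_oct: float, n: int, round_to: int = 1
) -> list[float]:
    """Geometric ladder of ``n`` frequencies spaced ``step_oct`` octaves apart.

    The k-th rung is ``round(base_khz * 2**(k*step_oct), round_to)``.  The
    quarter-octave ladder anchored at 4.0 kHz gives the canonical ten-tone
    set 4.0, 4.8, 5.7, 6.7, 8.0, 9.5, 11.3, 13.5, 16.0, 19.0 kHz.
    """
    if base_khz <= 0:
        raise ParadigmError("base_khz must be positive")
    if n < 1:
        raise ParadigmError("n must be at least 1")
    if step_oct < 0:
        raise ParadigmError("step_oct must be non-negative")
    return [round(base_khz * 2.0 ** (k * step_oct), round_to) for k in range(n)]


def frequency_for_contrast(
    standard_khz: float,
    contrast_oct: float,
    ladder: Sequence[float],
    step_oct: float = 0.25,
) -> float:
    """Ladder frequency at ``contrast_oct`` octaves from ``standard_khz``.

    Contrasts are realised as whole ladder steps (``contrast_oct`` must be a
    multiple of ``step_oct``); negative contrasts step down the ladder.
    Using ladder arithmetic rather than direct multiplication reproduces the
    rounded training pairs (8.0 → 11.3 kHz and 4.8 → 6.7 kHz at +0.5 oct).
    """
    ladder = list(ladder)
    matches = [i for i, f in enumerate(ladder) if math.isclose(f, standard_khz)]
    if not matches:
        raise ParadigmError(f"standard {standard_khz} kHz is not a ladder member")
    ratio = contrast_oct / step_oct
    n_steps = round(ratio)
    if not math.isclose(ratio, n_steps, abs_tol=1e-9):
        raise ParadigmError(
            f"contrast {contrast_oct} oct is not a multiple of the ladder step {step_oct} oct"
        )
    idx = matches[0] + n_steps
    if not 0 <= idx < len(ladder):
        raise ParadigmError(
            f"contrast {contrast_oct} oct from {standard_khz} kHz falls outside the ladder"
        )
    return ladder[idx]


def _deviant_positions(spec: ParadigmSpec, min_run: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of deviant indices given lead-in and min-run constraints.

    Draws a uniform random composition of the spare standards
    (n_std − lead_in − min_run·n_dev) into n_dev+1 slots and adds the
    per-gap minima back, so every feasible placement is equally likely.
    """
    n_dev = spec.n_deviant
    spare = spec.n_standard - spec.lead_in - min_run * n_dev
    m = n_dev + 1  # gaps: before first deviant, between deviants, after last
    if spare == 0:
        parts = np.zeros(m, dtype=int)
    else:
        # stars-and-bars: an (m-1)-subset of spare+m-1 slots <-> a composition
        bars = np.sort(rng.choice(spare + m - 1, size=m - 1, replace=False))
        edges = np.concatenate(([-1], bars, [spare + m - 1]))
        parts = np.diff(edges) - 1
    gaps = parts.copy()
    gaps[0] += spec.lead_in
    gaps[1:] += min_run  # inter-deviant gaps and the trailing run
    # deviant index k: after gaps[0..k] standards and k previous deviants
    return np.cumsum(gaps[:-1]) + np.arange(n_dev)


def _check_feasible(spec: ParadigmSpec, auto_relax: bool) -> int:
    if spec.is_feasible:
        return spec.min_run
    best = spec.max_feasible_min_run
    if best < 0:
        raise FeasibilityError(
            f"{spec.n_standard} standards cannot even cover the {spec.lead_in}-tone lead-in",
            max_feasible_min_run=0,
        )
    if auto_relax:
        return best
    raise FeasibilityError(
        f"min_run={spec.min_run} is infeasible for {spec.n_standard} standards / "
        f"{spec.n_deviant} deviants with lead_in={spec.lead_in}; "
        f"largest feasible min_run is {best}",
        max_feasible_min_run=best,
    )


def _assemble(
    spec: ParadigmSpec, dev_idx: np.ndarray, dev_freqs: Sequence[float]
) -> StimulusSequence:
    dev_set = set(int(i) for i in dev_idx)
    freqs = iter(dev_freqs)
    tones = []
    for i in range(spec.n_tones):
        if i in dev_set:
            role, f = ROLE_DEVIANT, next(freqs)
        else:
            role, f = ROLE_STANDARD, spec.standard_khz
        tones.append(
            ToneEvent(
                index=i,
                role=role,
                frequency_khz=float(f),
                nominal_onset_s=i * spec.isi_s,
                duration_ms=spec.duration_ms,
            )
        )
    return StimulusSequence(spec=spec, tones=tuple(tones))


def make_oddball_sequence(spec: ParadigmSpec, auto_relax: bool = False) -> StimulusSequence:
    """Generate a classic (or contrast-variant) oddball sequence.

    The deviant count is exact — e.g. exactly 70 deviants among 700 tones at
    the 90/10 probability — not a Bernoulli draw.  Raises
    :class:`FeasibilityError` (naming the largest feasible ``min_run``) when
    the spacing constraints cannot be met, unless ``auto_relax`` permits
    generation at that relaxed value.
    """
    if spec.kind not in ("oddball", "contrast_variant"):
        raise ParadigmError(f"make_oddball_sequence expects kind oddball/contrast_variant, got {spec.kind!r}")
    min_run = _check_feasible(spec, auto_relax)
    rng = stream(spec.seed, "placement")
    dev_idx = _deviant_positions(spec, min_run, rng)
    return _assemble(spec, dev_idx, [spec.deviant_khz] * spec.n_deviant)


def make_many_deviant_sequence(
    spec: ParadigmSpec, auto_relax: bool = False, balanced: bool = True
) -> StimulusSequence:
    """Generate a many-deviant sequence (deviant frequencies from a candidate set).

    With ``balanced=True`` (default) each candidate frequency is used
    floor(n_deviant / n_candidates) or that plus one times — 72 deviants over
    9 candidates gives exactly 8 each — the remainder assigned at random and
    the order shuffled.  ``balanced=False`` draws frequencies i.i.d.
    """
    if spec.kind != "many_deviant":
        raise ParadigmError(f"make_many_deviant_sequence expects kind many_deviant, got {spec.kind!r}")
    min_run = _check_feasible(spec, auto_relax)
    rng = stream(spec.seed, "placement")
    dev_idx = _deviant_positions(spec, min_run, rng)
    cands = np.asarray(spec.deviant_khz, dtype=float)
    freq_rng = stream(spec.seed, "deviant-frequencies")
    if balanced:
        q, r = divmod(spec.n_deviant, len(cands))
        counts = np.full(len(cands), q, dtype=int)
        if r:
            counts[freq_rng.choice(len(cands), size=r, replace=False)] += 1
        freqs = np.repeat(cands, counts)
        freq_rng.shuffle(freqs)
    else:
        freqs = freq_rng.choice(cands, size=spec.n_deviant, replace=True)
    return _assemble(spec, dev_idx, freqs)


def make_sequence(spec: ParadigmSpec, auto_relax: bool = False, balanced: bool = True) -> StimulusSequence:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "many_deviant":
        return make_many_deviant_sequence(spec, auto_relax=auto_relax, balanced=balanced)
    return make_oddball_sequence(spec, auto_relax=auto_relax)


def validate_sequence(seq: StimulusSequence) -> list[Violation]:
    """Report-only check of the sequence invariants (empty list = valid)."""
    spec = seq.spec
    out: list[Violation] = []
    n_dev = seq.n_deviant
    if n_dev != spec.n_deviant:
        out.append(
            Violation("deviant_count", -1, f"expected {spec.n_deviant} deviants, found {n_dev}")
        )
    if len(seq.tones) != spec.n_tones:
        out.append(
            Violation("tone_count", -1, f"expected {spec.n_tones} tones, found {len(seq.tones)}")
        )
    prev_onset = -math.inf
    for t in seq.tones:
        if t.frequency_khz <= 0:
            out.append(Violation("frequency", t.index, "non-positive frequency"))
        if t.nominal_onset_s <= prev_onset:
            out.append(Violation("onset_order", t.index, "onsets must be strictly increasing"))
        prev_onset = t.nominal_onset_s
        if t.role == ROLE_DEVIANT and t.frequency_khz == spec.standard_khz:
            out.append(
                Violation("deviant_frequency", t.index, "deviant at the standard frequency")
            )
    for t in seq.tones[: spec.lead_in]:
        if t.role == ROLE_DEVIANT:
            out.append(
                Violation("lead_in", t.index, f"deviant inside the {spec.lead_in}-tone lead-in")
            )
    prev_dev = None
    for i in seq.deviant_indices:
        if prev_dev is not None:
            run = i - prev_dev - 1
            if run < spec.min_run:
                out.append(
                    Violation(
                        "min_run",
                        i,
                        f"only {run} standards before deviant at index {i} (min_run={spec.min_run})",
                    )
                )
        prev_dev = i
    return out
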