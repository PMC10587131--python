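"""Signal-detection metrics: response rates, log-linear correction, d'.

Sensitivity is the classic Green & Swets index

    d' = Phi^-1(H) - Phi^-1(F)

with ``H`` the hit proportion over deviants, ``F`` the false-alarm
proportion over standards, and ``Phi^-1`` the standard-normal quantile
function.  Extreme counts (0 or all) make a raw proportion hit 0 or 1 and
d' infinite; the log-linear correction (Hautus) adds 0.5 to both response
counts and 1 to both trial counts, pulling both rates strictly inside
(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm


class DegenerateRateError(ValueError):
    """A proportion of exactly 0 or 1 reached the quantile function."""


@dataclass(frozen=True)
class RatePair:
    """Hit/false-alarm proportions with their source counts."""

    H: float
    F: float
    corrected: bool
    n_hit: int
    n_dev: int
    n_fa: int
    n_std: int


@dataclass(frozen=True)
class DPrimeResult:
    d_prime: float
    rate_pair: RatePair


def response_rates(
    n_hit: int, n_dev: int, n_fa: int, n_std: int, correction: str = "auto"
) -> RatePair:
    """Hit and false-alarm proportions, optionally log-linear corrected.

    ``correction``:

    * ``"auto"`` — apply the correction only when some count is extreme
      (n_hit in {0, n_dev} or n_fa in {0, n_std}); both rates are then
      corrected together.
    * ``"always"`` — correct unconditionally.
    * ``"never"`` — raw proportions; extreme counts raise
      :class:`DegenerateRateError`.
    """
    if n_dev <= 0 or n_std <= 0:
        raise ValueError("n_dev and n_std must be positive")
    if not (0 <= n_hit <= n_dev) or not (0 <= n_fa <= n_std):
        raise ValueError("counts out of range")
    if correction not in ("auto", "always", "never"):
        raise ValueError(f"unknown correction mode {correction!r}")
    extreme = n_hit in (0, n_dev) or n_fa in (0, n_std)
    if correction == "always" or (correction == "auto" and extreme):
        H = (n_hit + 0.5) / (n_dev + 1)
        F = (n_fa + 0.5) / (n_std + 1)
        corrected = True
    else:
        if extreme:
            raise DegenerateRateError(
                f"extreme counts (n_hit={n_hit}/{n_dev}, n_fa={n_fa}/{n_std}) "
                "give a degenerate proportion; use correction='auto' or 'always'"
            )
        H = n_hit / n_dev
        F = n_fa / n_std
        corrected = False
    return RatePair(H=H, F=F, corrected=corrected, n_hit=n_hit, n_dev=n_dev, n_fa=n_fa, n_std=n_std)


def dprime(rates: RatePair | tuple[float, float]) -> DPrimeResult:
    """d' = Phi^-1(H) - Phi^-1(F) for a (possibly corrected) rate pair."""
    if isinstance(rates, RatePair):
        H, F = rates.H, rates.F
        pair = rates
    else:
        H, F = rates
        pair = RatePair(H=H, F=F, corrected=False, n_hit=-1, n_dev=-1, n_fa=-1, n_std=-1)
    if not (0.0 < H < 1.0) or not (0.0 < F < 1.0):
        raise DegenerateRateError(
            f"rates must lie strictly inside (0, 1); got H={H}, F={F} — apply the correction first"
        )
    d = float(norm.ppf(H) - norm.ppf(F))
    return DPrimeResult(d_prime=d, rate_pair=pair)


def dprime_from_counts(
    n_hit: int, n_dev: int, n_fa: int, n_std: int, correction: str = "auto"
) -> DPrimeResult:
    """Compose :func:`response_rates` and :func:`dprime`.

    For many-deviant sessions, hits and deviants are pooled over all deviant
    frequencies before calling this.
    """
    return dprime(response_rates(n_hit, n_dev, n_fa, n_std, correction=correction))
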