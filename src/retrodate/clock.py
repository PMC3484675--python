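"""Molecular-clock dating of a retrocopy from fixed differences, with
rate-interval propagation and phylogenetic presence/absence bounds.

The estimator is linear: ``t = k / (L * r)`` with ``k`` fixed differences
over ``L`` compared sites at ``r`` substitutions per site per year. At the
divergences involved here (d ~ 1e-3) a multiple-hit correction is
negligible; a JC69 toggle exists for larger distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "RateModel",
    "AgeEstimate",
    "TaxonStatus",
    "PresenceTable",
    "EnvelopePolicy",
    "estimate_age",
    "age_interval",
    "presence_bounds",
    "combine",
    "round_my",
]


@dataclass(frozen=True)
class RateModel:
    """A substitution rate (per site per year) with its uncertainty range."""

    point: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.point <= self.high):
            raise ValueError(
                f"rates must satisfy 0 < low <= point <= high, got {self}"
            )


@dataclass(frozen=True)
class AgeEstimate:
    k: int
    L: int
    point_age: float  # years
    age_low: float
    age_high: float

    def __post_init__(self) -> None:
        if self.k < 0 or self.L <= 0:
            raise ValueError("k must be >= 0 and L > 0")
        if not (self.age_low <= self.point_age <= self.age_high):
            raise ValueError("ages must satisfy age_low <= point_age <= age_high")

    @property
    def point_my(self) -> float:
        return round_my(self.point_age)

    @property
    def interval_my(self) -> tuple[float, float]:
        return round_my(self.age_low), round_my(self.age_high)


def round_my(years: float, decimals: int = 1) -> float:
    """Years -> millions of years, rounded half-up at ``decimals`` places
    (display convention; raw years are always retained alongside)."""
    my = years / 1e6
    shifted = my * 10**decimals
    return math.floor(shifted + 0.5) / 10**decimals


def estimate_age(k: int, L: int, rate: float, jc69: bool = False) -> float:
    """Point age in years from ``k`` fixed differences over ``L`` sites at
    per-site-per-year rate ``rate``. With ``jc69`` the per-site distance is
    corrected for multiple hits before dividing by the rate."""
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    d = k / L
    if jc69:
        if d >= 0.75:
            raise ValueError("JC69 distance undefined at d >= 0.75")
        d = -0.75 * math.log(1 - 4 * d / 3)
    return d / rate


def age_interval(k: int, L: int, rate: RateModel, jc69: bool = False) -> AgeEstimate:
    """Age estimate whose interval propagates the rate interval: the slow
    rate bounds the age from above, the fast rate from below."""
    return AgeEstimate(
        k=k,
        L=L,
        point_age=estimate_age(k, L, rate.point, jc69),
        age_low=estimate_age(k, L, rate.high, jc69),
        age_high=estimate_age(k, L, rate.low, jc69),
    )


class TaxonStatus(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class EnvelopePolicy(str, Enum):
    OUTER = "outer"  # most permissive: interval min for lower, max for upper
    INNER = "inner"


@dataclass
class PresenceTable:
    """Per-taxon presence of the retrocopy and the divergence-time interval
    of that taxon from the focal lineage, in years."""

    taxa: dict[str, tuple[TaxonStatus, tuple[float, float]]]

    def __post_init__(self) -> None:
        for taxon, (status, (low, high)) in self.taxa.items():
            if not (0 < low <= high):
                raise ValueError(f"bad divergence interval for {taxon}: ({low}, {high})")
            if not isinstance(status, TaxonStatus):
                self.taxa[taxon] = (TaxonStatus(status), (low, high))


@dataclass(frozen=True)
class PresenceBounds:
    lower: float
    upper: float | None  # None = open upper bound
    conflict: bool = False


def presence_bounds(
    table: PresenceTable, policy: EnvelopePolicy = EnvelopePolicy.OUTER
) -> PresenceBounds:
    """Phylogenetic bounds on the insertion age.

    A taxon carrying the element pushes the origin before that taxon's
    divergence (lower bound); a taxon lacking it pulls the origin after
    its divergence (upper bound). Under the default outer envelope the
    least committal endpoints of the quoted divergence intervals are used.
    """
    lowers, uppers = [], []
    for status, (low, high) in table.taxa.values():
        if status is TaxonStatus.PRESENT:
            lowers.append(low if policy is EnvelopePolicy.OUTER else high)
        elif status is TaxonStatus.ABSENT:
            uppers.append(high if policy is EnvelopePolicy.OUTER else low)
    if not lowers and not uppers:
        raise ValueError("no taxon with known status")
    lower = max(lowers) if lowers else 0.0
    upper = min(uppers) if uppers else None
    conflict = upper is not None and lower > upper
    return PresenceBounds(lower, upper, conflict)


@dataclass(frozen=True)
class ConsensusInterval:
    low: float
    high: float | None
    consistent: bool
    clock: tuple[float, float]
    bounds: tuple[float, float | None]


def combine(clock: AgeEstimate, bounds: PresenceBounds) -> ConsensusInterval:
    """Intersect the clock interval with the phylogenetic bounds; an empty
    intersection flags the two lines of evidence as inconsistent (both are
    still reported)."""
    low = max(clock.age_low, bounds.lower)
    high = clock.age_high if bounds.upper is None else min(clock.age_high, bounds.upper)
    consistent = low <= high and not bounds.conflict
    return ConsensusInterval(
        low=low,
        high=high,
        consistent=consistent,
        clock=(clock.age_low, clock.age_high),
        bounds=(bounds.lower, bounds.upper),
    )
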