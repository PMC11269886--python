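"""Cause-of-mortality classification and proportion analyses.

A dead radio-tagged fledgling is assigned one of four primary causes from
field evidence: successfully ingested by a snake (found inside one, or its
transmitter gut-passed), killed in an unsuccessful ingestion attempt
("slimed": characteristic saliva-matted feathers — no other predator on the
landscape leaves this signature), cat predation or scavenging (partially
consumed carcass with feathers/wings/feet remaining), or unknown.  Snake
saliva evidence dominates cat-remains evidence: a saliva-coated carcass later
scavenged by a cat is still classified as a failed snake ingestion, because
the saliva coating identifies the primary cause of death.

From the classified records the module builds the mortality table (counts
and integer percentages over dead birds), estimates the ingestion-failure
rate — the proportion of snake-killed birds that were slimed rather than
swallowed — with a Wilson score interval, and deduplicates snake capture
events into unique individuals via their PIT-tag identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_records import (
    Evidence,
    Fate,
    FledglingRecord,
    SnakeCapture,
    ValidationError,
)

#: Causes that appear in the mortality table (CENSORED birds are excluded).
DEAD_CAUSES = (Fate.INGESTED, Fate.SLIMED, Fate.CAT, Fate.OTHER, Fate.UNKNOWN)

#: Display label: direct kills and scavenging are not distinguishable.
CAUSE_LABELS = {
    Fate.INGESTED: "ingested by snake",
    Fate.SLIMED: "slimed (failed snake ingestion)",
    Fate.CAT: "cat predation or scavenging",
    Fate.OTHER: "other",
    Fate.UNKNOWN: "unknown",
}


def classify_fate(evidence: frozenset[Evidence] | Iterable[Evidence]) -> Fate:
    """Deterministically map an evidence set to a fate.

    Precedence: alive > snake evidence > saliva > cat remains > other cause >
    unknown.  An empty evidence set on a dead bird is UNKNOWN.

    Raises
    ------
    ValidationError
        If the set contains both IN_SNAKE and SALIVA_COATED — a bird cannot
        simultaneously have been swallowed and rejected.
    """
    ev = frozenset(evidence)
    if Evidence.IN_SNAKE in ev and Evidence.SALIVA_COATED in ev:
        raise ValidationError(
            "IN_SNAKE and SALIVA_COATED are mutually exclusive evidence flags"
        )
    if Evidence.ALIVE_AT_LAST_CHECK in ev:
        return Fate.CENSORED
    if Evidence.IN_SNAKE in ev or Evidence.TRANSMITTER_GUT_PASSED in ev:
        return Fate.INGESTED
    if Evidence.SALIVA_COATED in ev:
        # saliva dominates cat remains: a scavenged, saliva-coated carcass
        # is still a failed snake ingestion
        return Fate.SLIMED
    if Evidence.CARCASS_REMAINS_CAT_PATTERN in ev:
        return Fate.CAT
    if Evidence.OTHER_CAUSE_EVIDENCE in ev:
        return Fate.OTHER
    return Fate.UNKNOWN


@dataclass(frozen=True)
class MortalityTable:
    """Counts and integer-rounded percentages of deaths by cause.

    ``percentages`` is ``None`` when there are no deaths (rather than a NaN
    map).  Snake-attributed deaths are INGESTED + SLIMED.
    """

    counts: Mapping[Fate, int]
    total_dead: int
    percentages: Mapping[Fate, int] | None

    @property
    def snake_attributed(self) -> int:
        return self.counts[Fate.INGESTED] + self.counts[Fate.SLIMED]

    @property
    def snake_attributed_percent(self) -> int | None:
        if self.total_dead == 0:
            return None
        return round(100.0 * self.snake_attributed / self.total_dead)


def mortality_table(records: Sequence[FledglingRecord]) -> MortalityTable:
    """Tabulate deaths by cause; CENSORED birds are excluded."""
    counts = {cause: 0 for cause in DEAD_CAUSES}
    for r in records:
        if r.fate is Fate.CENSORED:
            continue
        counts[r.fate] += 1
    total = sum(counts.values())
    if total == 0:
        return MortalityTable(counts=counts, total_dead=0, percentages=None)
    percentages = {c: round(100.0 * n / total) for c, n in counts.items()}
    return MortalityTable(counts=counts, total_dead=total, percentages=percentages)


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with a Wilson score interval."""

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    ci_method: str = "WILSON"
    alpha: float = 0.05

    @property
    def percent(self) -> float:
        """Proportion on the percentage scale, rounded to two decimals."""
        return round(100.0 * self.proportion, 2)


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Closed form: centre (p + z^2/2n)/(1 + z^2/n), half-width
    z*sqrt(p(1-p)/n + z^2/4n^2)/(1 + z^2/n).  Good small-sample coverage
    and never escapes [0, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    from scipy.stats import norm

    z = norm.ppf(1.0 - alpha / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2.0 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    low, high = max(0.0, centre - half), min(1.0, centre + half)
    if k == 0:
        low = 0.0  # exact, not a rounding artefact
    if k == n:
        high = 1.0
    return low, high


def ingestion_failure_rate(
    n_slimed: int, n_ingested: int, alpha: float = 0.05
) -> ProportionEstimate:
    """Proportion of snake ingestion attempts that failed.

    The numerator is the slimed count, the denominator all snake-caused
    deaths (slimed + ingested).

    Raises
    ------
    ValueError
        If both counts are zero — no snake-caused mortalities to compare.
    """
    if n_slimed < 0 or n_ingested < 0:
        raise ValueError("counts must be non-negative")
    n = n_slimed + n_ingested
    if n == 0:
        raise ValueError("no snake-caused mortalities")
    low, high = wilson_interval(n_slimed, n, alpha)
    return ProportionEstimate(
        numerator=n_slimed,
        denominator=n,
        proportion=n_slimed / n,
        ci_low=low,
        ci_high=high,
        alpha=alpha,
    )


@dataclass(frozen=True)
class DedupResult:
    """Unique individuals behind a set of capture events."""

    n_events: int
    n_individuals: int
    recapture_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_recaptures(self) -> int:
        return self.n_events - self.n_individuals


def dedup_individuals(captures: Sequence[SnakeCapture]) -> DedupResult:
    """Collapse capture events to unique snakes via their stable snake_id."""
    by_snake: dict[str, list[str]] = {}
    for c in captures:
        by_snake.setdefault(c.snake_id, []).append(c.event_id)
    return DedupResult(
        n_events=len(captures),
        n_individuals=len(by_snake),
        recapture_map={s: tuple(evs) for s, evs in by_snake.items()},
    )


__all__ = [
    "CAUSE_LABELS",
    "DEAD_CAUSES",
    "DedupResult",
    "MortalityTable",
    "ProportionEstimate",
    "classify_fate",
    "dedup_individuals",
    "ingestion_failure_rate",
    "mortality_table",
    "wilson_interval",
]
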