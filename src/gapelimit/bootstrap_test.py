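"""Resampling comparison of successful-ingestor size to the attracted population.

Snakes that failed to ingest a bird were never located, so successful and
unsuccessful ingestors cannot be compared directly.  Instead, the observed
mean snout-vent length (SVL) of successful ingestors is compared with the
distribution of mean SVLs of random subsamples drawn from the visually
surveyed snakes that are large enough to be attracted to endothermic prey
(SVL strictly greater than 900 mm, the ontogenetic-shift threshold).  If
ingestor size carried no information, the ingestors would look like one more
random subsample: their mean should fall inside the central quantile
interval of the resampled means.

The population holds one SVL per unique individual (the first capture's
measurement), never per capture event — recaptured snakes would otherwise be
overweighted.  Subsamples are drawn with replacement by default; a
without-replacement mode is available.  The interval is a quantile interval
from order statistics with linear interpolation, closed at its bounds (an
observed mean exactly on a bound counts as inside).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_records import CaptureContext, SnakeCapture


class ConfigError(ValueError):
    """The resampling configuration is infeasible for the given population."""


@dataclass(frozen=True)
class BootstrapConfig:
    """Parameters of the resampling comparison.

    threshold_mm
        Attraction threshold: only survey snakes with SVL strictly above it
        enter the resampled population (default 900 mm).
    n_per_sample
        Subsample size, matched to the number of observed ingestor
        individuals (default 52).
    n_reps
        Number of subsamples (default 5000).
    alpha
        1 - alpha is the quantile-interval level (default 0.05).
    replacement
        Draw with replacement (default) or without.
    """

    threshold_mm: float = 900.0
    n_per_sample: int = 52
    n_reps: int = 5000
    alpha: float = 0.05
    replacement: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if self.n_per_sample < 1:
            raise ConfigError("n_per_sample must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class BootstrapResult:
    """The resampled-mean distribution and the observed comparison.

    ``observed_mean`` and the derived fields are ``None`` until
    :func:`compare_observed` completes the result.  ``outside`` is True when
    the observed mean falls strictly outside the closed quantile interval.
    """

    sample_means: np.ndarray
    grand_mean: float
    ci_low: float
    ci_high: float
    config: BootstrapConfig
    population_n: int
    observed_mean: float | None = None
    observed_n: int | None = None
    outside: bool | None = None
    direction: str | None = None  # "above" | "below" | "inside"


def truncate_survey(
    captures: Sequence[SnakeCapture], threshold_mm: float = 900.0
) -> np.ndarray:
    """SVLs of unique surveyed individuals strictly above the threshold.

    Each individual contributes its first capture's SVL (capture order of
    the input sequence).  Raises ``ConfigError`` if nothing survives the
    truncation.
    """
    first_svl: dict[str, float] = {}
    for c in captures:
        if c.context is not CaptureContext.SURVEY:
            continue
        first_svl.setdefault(c.snake_id, c.svl_mm)
    svls = np.array([v for v in first_svl.values() if v > threshold_mm])
    if svls.size == 0:
        raise ConfigError(f"no snakes above threshold {threshold_mm} mm")
    return svls


def bootstrap_mean_distribution(
    svls: Sequence[float], config: BootstrapConfig
) -> BootstrapResult:
    """Distribution of subsample mean SVLs from the truncated survey population.

    Draws ``config.n_reps`` subsamples of ``config.n_per_sample`` SVLs using
    a generator seeded by ``config.seed`` (bit-reproducible), and forms the
    central 1-alpha quantile interval of the subsample means by linear
    interpolation between order statistics.
    """
    pop = np.asarray(svls, dtype=float)
    if pop.size == 0:
        raise ConfigError("empty population")
    if not config.replacement and config.n_per_sample > pop.size:
        raise ConfigError(
            f"cannot draw {config.n_per_sample} without replacement "
            f"from a population of {pop.size}"
        )
    rng = np.random.default_rng(config.seed)
    if config.replacement:
        draws = rng.choice(pop, size=(config.n_reps, config.n_per_sample), replace=True)
        means = draws.mean(axis=1)
    else:
        means = np.array(
            [
                rng.choice(pop, size=config.n_per_sample, replace=False).mean()
                for _ in range(config.n_reps)
            ]
        )
    lo, hi = np.quantile(means, [config.alpha / 2.0, 1.0 - config.alpha / 2.0])
    return BootstrapResult(
        sample_means=means,
        grand_mean=float(means.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        config=config,
        population_n=int(pop.size),
    )


def compare_observed(
    result: BootstrapResult, consumer_svls: Sequence[float]
) -> BootstrapResult:
    """Complete a bootstrap result with the observed ingestor mean.

    ``consumer_svls`` holds one SVL per unique ingestor individual.  The
    interval is closed: a mean exactly on a bound is inside.
    """
    obs = np.asarray(consumer_svls, dtype=float)
    if obs.size == 0:
        raise ValueError("consumer_svls must be non-empty")
    mean = float(obs.mean())
    if mean < result.ci_low:
        outside, direction = True, "below"
    elif mean > result.ci_high:
        outside, direction = True, "above"
    else:
        outside, direction = False, "inside"
    return replace(
        result,
        observed_mean=mean,
        observed_n=int(obs.size),
        outside=outside,
        direction=direction,
    )


__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "ConfigError",
    "bootstrap_mean_distribution",
    "compare_observed",
    "truncate_survey",
]
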