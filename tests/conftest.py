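import io

import pytest
from hypothesis import settings

import gapelimit as g

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


#: Cause counts matching the study's reported marginals: 294 deaths among
#: 461 tracked fledglings (89 ingested, 82 slimed, 89 cat, 14 other,
#: 20 unknown) plus 167 censored.
STUDY_COUNTS = {
    g.Fate.INGESTED: 89,
    g.Fate.SLIMED: 82,
    g.Fate.CAT: 89,
    g.Fate.OTHER: 14,
    g.Fate.UNKNOWN: 20,
    g.Fate.CENSORED: 167,
}

_EVIDENCE_FOR_FATE = {
    g.Fate.INGESTED: g.Evidence.TRANSMITTER_GUT_PASSED,
    g.Fate.SLIMED: g.Evidence.SALIVA_COATED,
    g.Fate.CAT: g.Evidence.CARCASS_REMAINS_CAT_PATTERN,
    g.Fate.OTHER: g.Evidence.OTHER_CAUSE_EVIDENCE,
    g.Fate.UNKNOWN: g.Evidence.NO_PREDATION_SIGNS,
    g.Fate.CENSORED: g.Evidence.ALIVE_AT_LAST_CHECK,
}


def cohort_with_counts(counts=None) -> list[g.FledglingRecord]:
    """Deterministic cohort with exactly the given per-cause counts."""
    counts = counts or STUDY_COUNTS
    records = []
    i = 0
    for fate, n in counts.items():
        for _ in range(n):
            i += 1
            records.append(
                g.FledglingRecord(
                    bird_id=f"B{i:04d}",
                    mass_g=60.5 + (i % 26),  # deterministic spread in [60.5, 85.5]
                    fate=fate,
                    evidence=frozenset({_EVIDENCE_FOR_FATE[fate]}),
                )
            )
    return records


def captures_with_recaptures(n_individuals: int, n_recaptures: int,
                             context=g.CaptureContext.SURVEY) -> list[g.SnakeCapture]:
    """n_individuals unique snakes plus n_recaptures repeat events."""
    caps = [
        g.SnakeCapture(
            snake_id=f"S{i:04d}", event_id=f"E{i:05d}",
            svl_mm=1000.0 + i, context=context,
        )
        for i in range(n_individuals)
    ]
    for j in range(n_recaptures):
        i = j % n_individuals
        caps.append(
            g.SnakeCapture(
                snake_id=f"S{i:04d}", event_id=f"R{j:05d}",
                svl_mm=1000.0 + i, context=context,
            )
        )
    return caps


def as_csv(frame) -> io.StringIO:
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    buf.seek(0)
    return buf


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset under the default study conditions."""
    return g.simulate_dataset(g.SyntheticConfig(seed=20240725))


@pytest.fixture(scope="session")
def study_cohort():
    return cohort_with_counts()
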