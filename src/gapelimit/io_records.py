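"""Reading, validating and writing the flat-table inputs and result tables.

Two input tables drive every analysis: a fledgling telemetry table (one row
per radio-tagged bird, with its mass at banding and the evidence recovered at
its final check) and a snake capture table (one row per capture event, with
snout-vent length, mass, sex and whether the capture came from a visual
survey or from catching a snake that had consumed a tagged bird).

All files are comma-delimited UTF-8 with a mandatory header row.  Missing
values are empty fields and parse to ``None`` — an optional numeric field is
never silently coerced to zero.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class ValidationError(ValueError):
    """A table-level integrity rule is violated (e.g. duplicate identifier)."""


class Fate(str, enum.Enum):
    """Final fate assigned to a telemetered fledgling."""

    INGESTED = "INGESTED"  # swallowed by a snake (found inside, or gut-passed tag)
    SLIMED = "SLIMED"      # killed in a failed ingestion attempt (saliva-coated)
    CAT = "CAT"            # cat predation or scavenging (not distinguishable)
    OTHER = "OTHER"        # starvation, exposure, road, entanglement, ...
    UNKNOWN = "UNKNOWN"    # dead, no conclusive evidence
    CENSORED = "CENSORED"  # alive at last contact / transmitter expired


class Evidence(str, enum.Enum):
    """Field evidence flags recovered at the final check of a fledgling."""

    IN_SNAKE = "IN_SNAKE"
    TRANSMITTER_GUT_PASSED = "TRANSMITTER_GUT_PASSED"
    SALIVA_COATED = "SALIVA_COATED"
    CARCASS_REMAINS_CAT_PATTERN = "CARCASS_REMAINS_CAT_PATTERN"
    NO_PREDATION_SIGNS = "NO_PREDATION_SIGNS"
    OTHER_CAUSE_EVIDENCE = "OTHER_CAUSE_EVIDENCE"
    ALIVE_AT_LAST_CHECK = "ALIVE_AT_LAST_CHECK"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    J = "J"  # juvenile, sex not determined
    U = "U"  # unknown


class CaptureContext(str, enum.Enum):
    SURVEY = "SURVEY"      # found during a visual search of the landscape
    CONSUMER = "CONSUMER"  # captured after consuming a telemetered bird


class Outcome(str, enum.Enum):
    """Outcome of an ingestion attempt."""

    INGESTED = "INGESTED"
    SLIMED = "SLIMED"


@dataclass(frozen=True)
class FledglingRecord:
    """One telemetered fledgling: identity, prey mass, fate evidence, fate.

    ``mass_g`` is the mass at banding (day 22-23 post-hatching) and serves as
    the prey mass throughout the analyses.
    """

    bird_id: str
    mass_g: float
    fate: Fate
    evidence: frozenset[Evidence] = frozenset()
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.bird_id:
            raise ValidationError("bird_id must be non-empty")
        if not self.mass_g > 0:
            raise ValidationError(f"mass_g must be positive, got {self.mass_g}")


@dataclass(frozen=True)
class SnakeCapture:
    """One snake capture event.

    ``snake_id`` is stable across recaptures (PIT tag); ``event_id`` is
    unique per row.  ``mass_g`` may be absent (``None``), never zero.
    """

    snake_id: str
    event_id: str
    svl_mm: float
    context: CaptureContext
    mass_g: float | None = None
    sex: Sex = Sex.U
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.svl_mm > 0:
            raise ValidationError(f"svl_mm must be positive, got {self.svl_mm}")
        if self.mass_g is not None and not self.mass_g > 0:
            raise ValidationError(f"mass_g must be positive, got {self.mass_g}")


@dataclass(frozen=True)
class PredationEvent:
    """One ingestion attempt linking prey mass to predator mass and outcome.

    ``bird_ids`` usually has length 1; length 2 records a double meal whose
    prey mass is the sum of the two birds.  Failed attempts carry no snake
    link: snakes that killed but could not swallow a bird were never located,
    so their morphometrics are structurally censored.
    """

    bird_ids: tuple[str, ...]
    prey_mass_g: float
    outcome: Outcome
    snake_event_id: str | None = None
    predator_mass_g: float | None = None

    def __post_init__(self) -> None:
        if len(self.bird_ids) == 0:
            raise ValidationError("bird_ids must be non-empty")
        if not self.prey_mass_g > 0:
            raise ValidationError("prey_mass_g must be positive")
        if self.outcome is Outcome.SLIMED and self.snake_event_id is not None:
            raise ValidationError(
                "a SLIMED event cannot carry a snake link: failed ingestors "
                "were never captured"
            )
        if self.predator_mass_g is not None and not self.predator_mass_g > 0:
            raise ValidationError("predator_mass_g must be positive")


@dataclass
class ParseReport:
    """Row accounting for a reader: rows_read = rows_accepted + rows_rejected."""

    rows_read: int = 0
    rows_accepted: int = 0
    rows_rejected: int = 0
    reasons: list[str] = field(default_factory=list)

    def reject(self, row_index: int, reason: str) -> None:
        self.rows_rejected += 1
        self.reasons.append(f"row {row_index}: {reason}")


FLEDGLING_COLUMNS = ("bird_id", "mass_g", "fate", "evidence", "notes")
SNAKE_COLUMNS = ("snake_id", "event_id", "svl_mm", "mass_g", "sex", "context", "date")

_EVIDENCE_SEP = ";"


def _load_frame(source, required: Sequence[str], schema: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _parse_float(token: str) -> float | None:
    token = token.strip()
    if not token:
        return None
    return float(token)  # may raise ValueError


def read_fledgling_table(
    source: str | pathlib.Path | IO[str],
    schema: Mapping[str, str] | None = None,
) -> tuple[list[FledglingRecord], ParseReport]:
    """Read a fledgling telemetry table.

    Parameters
    ----------
    source
        Path or open text stream of a CSV file with a header row.
    schema
        Optional map from canonical column names (``bird_id``, ``mass_g``,
        ``fate``, ``evidence``, ``notes``) to the file's actual column names.

    Returns
    -------
    records, report
        Validated records in file order, plus the row-accounting report.

    Raises
    ------
    SchemaError
        If a required column (``bird_id``, ``mass_g``, and at least one of
        ``fate`` / ``evidence``) is absent.
    ValidationError
        If a ``bird_id`` occurs twice.
    """
    df = _load_frame(source, ("bird_id", "mass_g"), schema)
    if "fate" not in df.columns and "evidence" not in df.columns:
        raise SchemaError("missing required column(s): fate or evidence")

    dup = df["bird_id"][df["bird_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate bird_id: {dup.iloc[0]!r}")

    # local import: fate_analysis owns the evidence -> fate rules
    from .fate_analysis import classify_fate

    report = ParseReport(rows_read=len(df))
    records: list[FledglingRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            mass = _parse_float(getattr(row, "mass_g"))
            if mass is None:
                raise ValueError("mass_g is empty")
            flags = frozenset(
                Evidence(tok.strip())
                for tok in str(getattr(row, "evidence", "")).split(_EVIDENCE_SEP)
                if tok.strip()
            )
            fate_token = str(getattr(row, "fate", "")).strip()
            fate = Fate(fate_token) if fate_token else classify_fate(flags)
            records.append(
                FledglingRecord(
                    bird_id=str(getattr(row, "bird_id")),
                    mass_g=mass,
                    fate=fate,
                    evidence=flags,
                    notes=str(getattr(row, "notes", "")),
                )
            )
            report.rows_accepted += 1
        except (ValueError, KeyError) as exc:
            report.reject(i, str(exc))
    return records, report


def read_snake_captures(
    source: str | pathlib.Path | IO[str],
    schema: Mapping[str, str] | None = None,
) -> tuple[list[SnakeCapture], ParseReport]:
    """Read a snake capture-event table.

    Required columns: ``snake_id``, ``event_id``, ``svl_mm``, ``context``.
    Unknown sex tokens map to ``U``; empty ``mass_g`` becomes ``None``.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If an ``event_id`` occurs twice.
    """
    df = _load_frame(source, ("snake_id", "event_id", "svl_mm", "context"), schema)
    dup = df["event_id"][df["event_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate event_id: {dup.iloc[0]!r}")

    report = ParseReport(rows_read=len(df))
    captures: list[SnakeCapture] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            svl = _parse_float(getattr(row, "svl_mm"))
            if svl is None:
                raise ValueError("svl_mm is empty")
            sex_token = str(getattr(row, "sex", "U")).strip().upper() or "U"
            try:
                sex = Sex(sex_token)
            except ValueError:
                sex = Sex.U
            date_token = str(getattr(row, "date", "")).strip()
            captures.append(
                SnakeCapture(
                    snake_id=str(getattr(row, "snake_id")),
                    event_id=str(getattr(row, "event_id")),
                    svl_mm=svl,
                    context=CaptureContext(str(getattr(row, "context")).strip().upper()),
                    mass_g=_parse_float(str(getattr(row, "mass_g", ""))),
                    sex=sex,
                    date=_dt.date.fromisoformat(date_token) if date_token else None,
                )
            )
            report.rows_accepted += 1
        except (ValueError, KeyError, ValidationError) as exc:
            report.reject(i, str(exc))
    return captures, report


def fledglings_to_frame(records: Iterable[FledglingRecord]) -> pd.DataFrame:
    """Render fledgling records back to the canonical table layout."""
    return pd.DataFrame(
        {
            "bird_id": [r.bird_id for r in records],
            "mass_g": [r.mass_g for r in records],
            "fate": [r.fate.value for r in records],
            "evidence": [
                _EVIDENCE_SEP.join(sorted(e.value for e in r.evidence)) for r in records
            ],
            "notes": [r.notes for r in records],
        }
        if records
        else {c: [] for c in FLEDGLING_COLUMNS}
    )


def snakes_to_frame(captures: Iterable[SnakeCapture]) -> pd.DataFrame:
    """Render snake captures back to the canonical table layout."""
    captures = list(captures)
    return pd.DataFrame(
        {
            "snake_id": [c.snake_id for c in captures],
            "event_id": [c.event_id for c in captures],
            "svl_mm": [c.svl_mm for c in captures],
            "mass_g": ["" if c.mass_g is None else c.mass_g for c in captures],
            "sex": [c.sex.value for c in captures],
            "context": [c.context.value for c in captures],
            "date": ["" if c.date is None else c.date.isoformat() for c in captures],
        }
        if captures
        else {c: [] for c in SNAKE_COLUMNS}
    )


EVENT_COLUMNS = ("bird_ids", "prey_mass_g", "outcome", "snake_event_id", "predator_mass_g")

_BIRD_SEP = ";"


def read_predation_events(
    source: str | pathlib.Path | IO[str],
    schema: Mapping[str, str] | None = None,
) -> tuple[list[PredationEvent], ParseReport]:
    """Read an ingestion-attempt table (one row per meal).

    ``bird_ids`` holds one or two identifiers joined by ``;`` (a double
    meal); ``snake_event_id`` and ``predator_mass_g`` are empty for failed
    attempts, whose snakes were never located.
    """
    df = _load_frame(source, ("bird_ids", "prey_mass_g", "outcome"), schema)
    report = ParseReport(rows_read=len(df))
    events: list[PredationEvent] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            prey_mass = _parse_float(getattr(row, "prey_mass_g"))
            if prey_mass is None:
                raise ValueError("prey_mass_g is empty")
            link = str(getattr(row, "snake_event_id", "")).strip() or None
            events.append(
                PredationEvent(
                    bird_ids=tuple(
                        tok.strip()
                        for tok in str(getattr(row, "bird_ids")).split(_BIRD_SEP)
                        if tok.strip()
                    ),
                    prey_mass_g=prey_mass,
                    outcome=Outcome(str(getattr(row, "outcome")).strip().upper()),
                    snake_event_id=link,
                    predator_mass_g=_parse_float(str(getattr(row, "predator_mass_g", ""))),
                )
            )
            report.rows_accepted += 1
        except (ValueError, KeyError, ValidationError) as exc:
            report.reject(i, str(exc))
    return events, report


def events_to_frame(events: Iterable[PredationEvent]) -> pd.DataFrame:
    """Render predation events back to the canonical table layout."""
    events = list(events)
    return pd.DataFrame(
        {
            "bird_ids": [_BIRD_SEP.join(e.bird_ids) for e in events],
            "prey_mass_g": [e.prey_mass_g for e in events],
            "outcome": [e.outcome.value for e in events],
            "snake_event_id": [e.snake_event_id or "" for e in events],
            "predator_mass_g": [
                "" if e.predator_mass_g is None else e.predator_mass_g for e in events
            ],
        }
        if events
        else {c: [] for c in EVENT_COLUMNS}
    )


def write_results(
    tables: Mapping[str, pd.DataFrame],
    dest: str | pathlib.Path,
    *,
    seed: int | None = None,
    config: Mapping | None = None,
) -> dict:
    """Write one CSV per named table plus a JSON run manifest.

    The manifest records the seed, a hash of the configuration, file names
    and a timestamp, and is returned as a dict (also written to
    ``manifest.json`` in ``dest``).
    """
    dest = pathlib.Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, frame in tables.items():
        path = dest / f"{name}.csv"
        frame.to_csv(path, index=False)
        files[name] = path.name
    config_json = json.dumps(config, sort_keys=True, default=str) if config else ""
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "files": files,
        "written_at": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    (dest / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


__all__ = [
    "CaptureContext",
    "Evidence",
    "Fate",
    "FledglingRecord",
    "Outcome",
    "ParseReport",
    "PredationEvent",
    "SchemaError",
    "Sex",
    "SnakeCapture",
    "ValidationError",
    "events_to_frame",
    "fledglings_to_frame",
    "read_fledgling_table",
    "read_predation_events",
    "read_snake_captures",
    "snakes_to_frame",
    "write_results",
]
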