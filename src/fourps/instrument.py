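"""Structure and data model of the 4Ps instrument.

The Patient Preferences for Patient Participation tool (4Ps) asks a patient
to report, for each of 12 attributes of patient participation, (a) how
important that attribute is to them (*preference*) and (b) to what extent
they experienced it (*experience*).  Both sections use a 4-level ordered
response scale; the two scales are positioned in correspondence so that the
same ordinal position expresses matching degrees.

This module defines the instrument (items, elements, constructs, response
options), the respondent-level data model, and validated CSV ingest/egress.
Only the attribute labels are stored here; the verbatim item wording of the
tool is copyright-protected and obtained from the instrument's licensors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ResponseOption",
    "Item",
    "InstrumentDefinition",
    "ItemResponse",
    "RespondentRecord",
    "Cohort",
    "Violation",
    "CohortReadError",
    "build_default_instrument",
    "validate_record",
    "read_cohort",
    "write_cohort",
    "default_schema",
    "instrument_to_json",
]

N_ITEMS = 12
CODES = (1, 2, 3, 4)

PREFERENCE_LABELS = ("unimportant", "somewhat important", "very important", "crucial")
EXPERIENCE_LABELS = ("not at all", "to some extent", "to a large extent", "entirely")

# attribute label, overarching element; items 1-6 form the "sharing of"
# construct (intellectual exchange), items 7-12 "sharing in" (activities)
_ITEM_TABLE = (
    ("being listened to (by the healthcare staff)", "imparting information"),
    ("my experiences being recognised", "imparting information"),
    ("having reciprocal communication", "imparting information"),
    ("telling about my symptoms/issues", "exchanging knowledge"),
    ("having explanations as to my symptoms/issues", "exchanging knowledge"),
    ("having explanations as to what will be/is done for me", "exchanging knowledge"),
    ("learning what is planned for me", "arranging for healthcare"),
    ("taking part in planning", "arranging for healthcare"),
    ("phrasing my own (health) goals", "arranging for healthcare"),
    ("knowing how to manage symptoms/issues", "accomplishing health and healthcare"),
    ("managing (prescribed) treatments", "accomplishing health and healthcare"),
    ("performing self-care", "accomplishing health and healthcare"),
)

ELEMENTS = tuple(sorted({e for _, e in _ITEM_TABLE}))
CONSTRUCTS = ("sharing of", "sharing in")
ARMS = ("control", "intervention", "none")
DESIGNATIONS = ("primary", "secondary", "unassigned")


@dataclass(frozen=True)
class ResponseOption:
    """One ordered response alternative of a 4Ps section."""

    code: int
    label: str
    section: str  # "preference" | "experience"

    def __post_init__(self) -> None:
        if self.code not in CODES:
            raise ValueError(f"response code must be 1-4, got {self.code}")
        if self.section not in ("preference", "experience"):
            raise ValueError(f"unknown section {self.section!r}")


@dataclass(frozen=True)
class Item:
    """One attribute of patient participation measured by the tool."""

    item_id: int
    attribute: str
    element: str
    construct: str
    designation: str = "unassigned"

    def __post_init__(self) -> None:
        if not 1 <= self.item_id <= N_ITEMS:
            raise ValueError(f"item_id must be 1-{N_ITEMS}, got {self.item_id}")
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}")
        if self.construct not in CONSTRUCTS:
            raise ValueError(f"unknown construct {self.construct!r}")
        if self.designation not in DESIGNATIONS:
            raise ValueError(f"unknown designation {self.designation!r}")


@dataclass(frozen=True)
class InstrumentDefinition:
    """The full 12-item instrument with both option sets."""

    items: tuple[Item, ...]
    preference_options: tuple[ResponseOption, ...]
    experience_options: tuple[ResponseOption, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(f"instrument must have exactly {N_ITEMS} items")
        ids = [it.item_id for it in self.items]
        if sorted(ids) != list(range(1, N_ITEMS + 1)):
            raise ValueError("item_ids must be exactly 1..12, each once")
        for opts, section in (
            (self.preference_options, "preference"),
            (self.experience_options, "experience"),
        ):
            if tuple(o.code for o in opts) != CODES:
                raise ValueError(f"{section} options must be coded 1..4 in order")

    def item(self, item_id: int) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def primary_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.designation == "primary")

    @property
    def secondary_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.designation == "secondary")


@dataclass(frozen=True)
class ItemResponse:
    """Paired ordinal report for one item; either side may be missing."""

    item_id: int
    preference: int | None = None
    experience: int | None = None

    @property
    def complete(self) -> bool:
        return self.preference is not None and self.experience is not None


@dataclass(frozen=True)
class RespondentRecord:
    """One respondent's 4Ps report at one timepoint, with context."""

    respondent_id: str
    site_id: str
    arm: str
    timepoint: int
    covariates: Mapping[str, object]
    responses: tuple[ItemResponse, ...]

    def response(self, item_id: int) -> ItemResponse:
        for r in self.responses:
            if r.item_id == item_id:
                return r
        raise KeyError(item_id)


@dataclass(frozen=True)
class Cohort:
    """A collection of respondent records tied to an instrument."""

    records: tuple[RespondentRecord, ...]
    instrument: InstrumentDefinition
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Violation:
    """One validation failure; ``item_id`` is None for record-level issues."""

    item_id: int | None
    field: str
    reason: str


def build_default_instrument() -> InstrumentDefinition:
    """Construct the standard 12-item 4Ps instrument definition.

    Items 1-6 carry the "sharing of" construct (imparting information,
    exchanging knowledge); items 7-12 carry "sharing in" (arranging for
    healthcare, accomplishing health and healthcare).  Deterministic.
    """
    items = tuple(
        Item(
            item_id=i + 1,
            attribute=attr,
            element=elem,
            construct="sharing of" if i < 6 else "sharing in",
        )
        for i, (attr, elem) in enumerate(_ITEM_TABLE)
    )
    pref = tuple(
        ResponseOption(c, lab, "preference") for c, lab in zip(CODES, PREFERENCE_LABELS)
    )
    exp = tuple(
        ResponseOption(c, lab, "experience") for c, lab in zip(CODES, EXPERIENCE_LABELS)
    )
    return InstrumentDefinition(items=items, preference_options=pref, experience_options=exp)


def validate_record(
    record: RespondentRecord, instrument: InstrumentDefinition
) -> list[Violation]:
    """Check a record against the instrument; returns violations, never raises."""
    violations: list[Violation] = []
    seen: dict[int, int] = {}
    for resp in record.responses:
        seen[resp.item_id] = seen.get(resp.item_id, 0) + 1
        if not 1 <= resp.item_id <= N_ITEMS:
            violations.append(
                Violation(resp.item_id, "item_id", f"item_id {resp.item_id} outside 1-{N_ITEMS}")
            )
            continue
        for side in ("preference", "experience"):
            code = getattr(resp, side)
            if code is not None and code not in CODES:
                violations.append(
                    Violation(resp.item_id, side, f"code {code} outside 1-4")
                )
    for item_id in range(1, N_ITEMS + 1):
        n = seen.get(item_id, 0)
        if n == 0:
            violations.append(Violation(item_id, "responses", "missing item response"))
        elif n > 1:
            violations.append(Violation(item_id, "responses", f"{n} responses for one item"))
    if record.arm not in ARMS:
        violations.append(Violation(None, "arm", f"arm {record.arm!r} not in {ARMS}"))
    if record.timepoint < 0:
        violations.append(Violation(None, "timepoint", "timepoint must be >= 0"))
    return violations


def default_schema() -> dict[str, str]:
    """Column-name map for the wide CSV layout (logical name -> column)."""
    schema = {
        "respondent_id": "respondent_id",
        "site_id": "site_id",
        "arm": "arm",
        "timepoint": "timepoint",
        "sex": "sex",
        "age": "age",
    }
    for i in range(1, N_ITEMS + 1):
        schema[f"pref_{i:02d}"] = f"pref_{i:02d}"
        schema[f"exp_{i:02d}"] = f"exp_{i:02d}"
    return schema


_MANDATORY = ("respondent_id", "site_id", "arm", "timepoint")
_COVARIATE_KEYS = ("sex", "age")


class CohortReadError(ValueError):
    """Raised when a cohort CSV cannot be interpreted at all."""


def _parse_code(value: object) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    try:
        return int(float(value))
    except (TypeError, ValueError):
        # non-numeric survives as an out-of-range marker caught by validation
        return -1


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    instrument: InstrumentDefinition | None = None,
) -> tuple[Cohort, dict[int, list[Violation]]]:
    """Read a wide 4Ps CSV into a :class:`Cohort`.

    Returns ``(cohort, problems)`` where ``problems`` maps 0-based row index
    to the violations found on that row.  Invalid rows are retained in the
    cohort (reported, not dropped); blank response cells become missing.

    Raises :class:`CohortReadError` for unreadable files, missing mandatory
    columns, or duplicated (respondent_id, timepoint) keys.
    """
    schema = dict(schema or default_schema())
    instrument = instrument or build_default_instrument()
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortReadError(f"cannot read {path}: {exc}") from exc

    missing_cols = [
        schema[key]
        for key in schema
        if key.startswith(("pref_", "exp_")) or key in _MANDATORY
        if schema[key] not in frame.columns
    ]
    if missing_cols:
        raise CohortReadError(f"missing mandatory columns: {', '.join(sorted(missing_cols))}")

    records: list[RespondentRecord] = []
    problems: dict[int, list[Violation]] = {}
    keys: set[tuple[str, int]] = set()
    for idx, row in frame.iterrows():
        responses = tuple(
            ItemResponse(
                item_id=i,
                preference=_parse_code(row.get(schema[f"pref_{i:02d}"])),
                experience=_parse_code(row.get(schema[f"exp_{i:02d}"])),
            )
            for i in range(1, N_ITEMS + 1)
        )
        covariates = {
            key: row.get(schema[key]) for key in _COVARIATE_KEYS if schema.get(key) in frame.columns
        }
        try:
            timepoint = int(float(row[schema["timepoint"]]))
        except (TypeError, ValueError):
            timepoint = -1
        record = RespondentRecord(
            respondent_id=str(row[schema["respondent_id"]]),
            site_id=str(row[schema["site_id"]]),
            arm=str(row[schema["arm"]]),
            timepoint=timepoint,
            covariates=covariates,
            responses=responses,
        )
        key = (record.respondent_id, record.timepoint)
        if key in keys:
            raise CohortReadError(f"duplicate (respondent_id, timepoint) {key} at row {idx}")
        keys.add(key)
        viol = validate_record(record, instrument)
        if viol:
            problems[int(idx)] = viol
        records.append(record)
    cohort = Cohort(records=tuple(records), instrument=instrument, provenance=str(path))
    return cohort, problems


def write_cohort(
    cohort: Cohort, path: str | Path, schema: Mapping[str, str] | None = None
) -> None:
    """Write a cohort to the wide CSV layout (blank cell = missing code).

    Round-trips exactly through :func:`read_cohort`.
    """
    schema = dict(schema or default_schema())
    rows = []
    for rec in cohort.records:
        row: dict[str, object] = {
            schema["respondent_id"]: rec.respondent_id,
            schema["site_id"]: rec.site_id,
            schema["arm"]: rec.arm,
            schema["timepoint"]: rec.timepoint,
        }
        for key in _COVARIATE_KEYS:
            if key in rec.covariates and key in schema:
                row[schema[key]] = rec.covariates[key]
        for resp in rec.responses:
            if 1 <= resp.item_id <= N_ITEMS:
                row[schema[f"pref_{resp.item_id:02d}"]] = resp.preference
                row[schema[f"exp_{resp.item_id:02d}"]] = resp.experience
        rows.append(row)
    columns = [schema[k] for k in default_schema()]
    frame = pd.DataFrame(rows, columns=columns)
    # integer codes, blank for missing
    for col in columns:
        if col.startswith(("pref_", "exp_")) or col == schema["timepoint"]:
            frame[col] = frame[col].astype("Int64")
    frame.to_csv(path, index=False)


def instrument_to_json(instrument: InstrumentDefinition) -> str:
    """Serialise an instrument definition to JSON for audit."""
    payload = {
        "items": [
            {
                "item_id": it.item_id,
                "attribute": it.attribute,
                "element": it.element,
                "construct": it.construct,
                "designation": it.designation,
            }
            for it in instrument.items
        ],
        "preference_options": [
            {"code": o.code, "label": o.label} for o in instrument.preference_options
        ],
        "experience_options": [
            {"code": o.code, "label": o.label} for o in instrument.experience_options
        ],
    }
    return json.dumps(payload, indent=2)


def cohort_digest(cohort: Cohort) -> str:
    """Stable short digest of a cohort's response data, for provenance."""
    h = hashlib.sha256()
    for rec in cohort.records:
        h.update(repr((rec.respondent_id, rec.timepoint, rec.site_id, rec.arm)).encode())
        for r in rec.responses:
            h.update(bytes([r.item_id, r.preference or 0, r.experience or 0]))
    return h.hexdigest()[:12]
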