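"""Preference-experience concordance scoring for the 4Ps.

Each item's paired ordinal reports are condensed into four mutually
consistent outcomes:

* a **match category** — match, less participation than preferred, or more
  participation than preferred;
* a signed **gap** (experience position minus preference position, -3..+3) —
  the larger the gap, the lesser the degree of preference-based
  participation;
* a **rank** on the six-graded scale (0-5) of preference-based patient
  participation, looked up in a 16-cell scoring map over the 4x4 cross of
  response options; and
* a clinical **level** collapsing the rank: 0-1 insufficient, 2-3 fair,
  4-5 sufficient.

The shipped default map ranks cells purely by gap class, ordered best to
worst as 0, +1, -1, +2, -2, +3, -3 (ranks 5, 4, 3, 2, 1, 0, 0): the closer
the match the better, and at equal distance, more conditions for
participation than preferred is better than less.  Because seven gap
classes must fit six grades, the two extreme classes share rank 0.  The
map is a first-class, JSON-serialisable artifact so an alternative 16-cell
assignment can be dropped in; :func:`validate_scoring_map` guards any
replacement.

No sum or mean across the 12 items is offered anywhere: the 4Ps is a
single-item tool and each attribute is scored and analysed separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .instrument import (
    CODES,
    N_ITEMS,
    Cohort,
    InstrumentDefinition,
    Violation,
)

__all__ = [
    "MATCH",
    "LESS_THAN_PREFERRED",
    "MORE_THAN_PREFERRED",
    "MATCH_CATEGORIES",
    "LEVELS",
    "ItemScore",
    "ScoringMap",
    "compute_gap",
    "classify_match",
    "default_scoring_map",
    "validate_scoring_map",
    "score_item",
    "level_of",
    "score_cohort",
    "designate_items",
    "scoring_map_to_json",
    "scoring_map_from_json",
]

# match categories
MATCH = "match"
LESS_THAN_PREFERRED = "less_than_preferred"
MORE_THAN_PREFERRED = "more_than_preferred"
MATCH_CATEGORIES = (MATCH, LESS_THAN_PREFERRED, MORE_THAN_PREFERRED)

# clinical levels, in scale order
INSUFFICIENT = "insufficient"
FAIR = "fair"
SUFFICIENT = "sufficient"
LEVELS = (INSUFFICIENT, FAIR, SUFFICIENT)

RANKS = (0, 1, 2, 3, 4, 5)
GAPS = (-3, -2, -1, 0, 1, 2, 3)

# gap class -> rank, best-to-worst class order 0, +1, -1, +2, -2, +3, -3
_DEFAULT_GAP_RANKS = {0: 5, 1: 4, -1: 3, 2: 2, -2: 1, 3: 0, -3: 0}


def _check_code(code: int, side: str) -> None:
    if code not in CODES:
        raise ValueError(f"{side} code must be in 1-4, got {code!r}")


def compute_gap(preference: int, experience: int) -> int:
    """Signed ordinal distance: experience code minus preference code."""
    _check_code(preference, "preference")
    _check_code(experience, "experience")
    return experience - preference


def classify_match(preference: int, experience: int) -> str:
    """Classify a pair into match / less- / more-than-preferred."""
    gap = compute_gap(preference, experience)
    if gap == 0:
        return MATCH
    return LESS_THAN_PREFERRED if gap < 0 else MORE_THAN_PREFERRED


def level_of(rank: int) -> str:
    """Collapse a six-graded rank to the three-level clinical scale.

    0-1 insufficient, 2-3 fair, 4-5 sufficient.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be in 0-5, got {rank!r}")
    if rank <= 1:
        return INSUFFICIENT
    if rank <= 3:
        return FAIR
    return SUFFICIENT


@dataclass(frozen=True)
class ScoringMap:
    """16-cell assignment of a rank 0-5 to each preference x experience pair."""

    cells: Mapping[tuple[int, int], int]
    name: str = "default"
    source: str = ""

    def rank(self, preference: int, experience: int) -> int:
        _check_code(preference, "preference")
        _check_code(experience, "experience")
        return self.cells[(preference, experience)]


@dataclass(frozen=True)
class ItemScore:
    """Derived outcomes for one item's complete pair of reports."""

    item_id: int
    preference: int
    experience: int
    category: str
    gap: int
    rank: int
    level: str


def default_scoring_map() -> ScoringMap:
    """The shipped default map: rank is a function of gap class (see module docs)."""
    cells = {
        (p, e): _DEFAULT_GAP_RANKS[e - p] for p in CODES for e in CODES
    }
    return ScoringMap(cells=cells, name="default", source="gap-class ordering 0,+1,-1,+2,-2,+3,-3 -> 5,4,3,2,1,0,0")


def validate_scoring_map(scoring_map: ScoringMap) -> list[Violation]:
    """Check a scoring map against the ordering principles.

    Requires: exactly the 16 cells of the 4x4 cross; ranks in 0-5; every
    diagonal (perfect match) cell at rank 5; rank non-increasing in |gap|;
    at equal |gap| > 0, the positive-gap cell ranked at least as high as
    the mirrored negative-gap cell; and all six grades emitted by at least
    one cell.  Violations are reported, never raised.
    """
    violations: list[Violation] = []
    expected = {(p, e) for p in CODES for e in CODES}
    got = set(scoring_map.cells)
    for missing in sorted(expected - got):
        violations.append(Violation(None, "cells", f"missing cell {missing}"))
    for extra in sorted(got - expected):
        violations.append(Violation(None, "cells", f"unexpected cell {extra}"))
    if violations:
        return violations

    for (p, e), r in sorted(scoring_map.cells.items()):
        if r not in RANKS:
            violations.append(Violation(None, "rank", f"cell {(p, e)} rank {r} outside 0-5"))
    if violations:
        return violations

    for p in CODES:
        if scoring_map.cells[(p, p)] != 5:
            violations.append(
                Violation(None, "diagonal", f"cell {(p, p)}: perfect match must rank 5")
            )

    # worst rank attained at each |gap| must not recover as |gap| grows,
    # and the best rank at |gap|=g+1 must not beat the worst at |gap|=g
    by_abs_gap: dict[int, list[int]] = {}
    for (p, e), r in scoring_map.cells.items():
        by_abs_gap.setdefault(abs(e - p), []).append(r)
    for g in range(0, 3):
        if max(by_abs_gap[g + 1]) > min(by_abs_gap[g]):
            violations.append(
                Violation(
                    None,
                    "monotonicity",
                    f"some |gap|={g + 1} cell outranks a |gap|={g} cell",
                )
            )

    for g in (1, 2, 3):
        pos = [r for (p, e), r in scoring_map.cells.items() if e - p == g]
        neg = [r for (p, e), r in scoring_map.cells.items() if e - p == -g]
        if min(pos) < max(neg):
            violations.append(
                Violation(
                    None,
                    "direction",
                    f"at |gap|={g}, a more-than-preferred cell ranks below a "
                    "less-than-preferred cell (more must not rank below less)",
                )
            )

    emitted = set(scoring_map.cells.values())
    for r in RANKS:
        if r not in emitted:
            violations.append(Violation(None, "coverage", f"rank {r} emitted by no cell"))
    return violations


def score_item(
    preference: int | None,
    experience: int | None,
    scoring_map: ScoringMap | None = None,
    item_id: int = 0,
) -> ItemScore | None:
    """Score one item's pair of reports; ``None`` if either side is missing.

    Missingness is item-wise: an incomplete pair yields no score (signalled
    by ``None``), never a zero-filled one.
    """
    if preference is None or experience is None:
        return None
    scoring_map = scoring_map or default_scoring_map()
    gap = compute_gap(preference, experience)
    rank = scoring_map.rank(preference, experience)
    return ItemScore(
        item_id=item_id,
        preference=preference,
        experience=experience,
        category=classify_match(preference, experience),
        gap=gap,
        rank=rank,
        level=level_of(rank),
    )


def score_cohort(cohort: Cohort, scoring_map: ScoringMap | None = None) -> pd.DataFrame:
    """Score every complete item pair in a cohort.

    Returns a long table with one row per respondent x timepoint x item for
    items where both codes are present and in range; incomplete items are
    simply absent.  Items are scored independently of one another.
    """
    scoring_map = scoring_map or default_scoring_map()
    problems = validate_scoring_map(scoring_map)
    if problems:
        raise ValueError(f"invalid scoring map: {problems[0].reason}")
    rows = []
    for rec in cohort.records:
        for resp in rec.responses:
            if resp.preference not in CODES or resp.experience not in CODES:
                continue
            sc = score_item(resp.preference, resp.experience, scoring_map, resp.item_id)
            row = {
                "respondent_id": rec.respondent_id,
                "site_id": rec.site_id,
                "arm": rec.arm,
                "timepoint": rec.timepoint,
                "item_id": resp.item_id,
                "preference": resp.preference,
                "experience": resp.experience,
                "category": sc.category,
                "gap": sc.gap,
                "rank": sc.rank,
                "level": sc.level,
            }
            for key, value in rec.covariates.items():
                row[key] = value
            rows.append(row)
    columns = [
        "respondent_id",
        "site_id",
        "arm",
        "timepoint",
        "item_id",
        "preference",
        "experience",
        "category",
        "gap",
        "rank",
        "level",
    ]
    if rows:
        extra = [c for c in rows[0] if c not in columns]
    else:
        extra = []
    return pd.DataFrame(rows, columns=columns + extra)


def designate_items(
    instrument: InstrumentDefinition, primary: Iterable[int]
) -> InstrumentDefinition:
    """Mark items as primary (rest secondary) for research-mode reporting.

    Research use of the tool as an outcome measure requires stating up
    front which attributes the intervention targets; downstream reports
    list primary items before secondary ones.  Passing all 12 ids is the
    clinical mode in which every item is considered without discrepancy.
    """
    primary_set = set(primary)
    unknown = primary_set - set(range(1, N_ITEMS + 1))
    if unknown:
        raise ValueError(f"unknown item_id(s): {sorted(unknown)}")
    if not primary_set:
        raise ValueError("primary designation must be non-empty")
    items = tuple(
        replace(it, designation="primary" if it.item_id in primary_set else "secondary")
        for it in instrument.items
    )
    return replace(instrument, items=items)


def scoring_map_to_json(scoring_map: ScoringMap) -> str:
    """Serialise a scoring map to its JSON interchange form."""
    payload = {
        "name": scoring_map.name,
        "source": scoring_map.source,
        "cells": [
            {"preference": p, "experience": e, "rank": r}
            for (p, e), r in sorted(scoring_map.cells.items())
        ],
    }
    return json.dumps(payload, indent=2)


def scoring_map_from_json(text: str | Path) -> ScoringMap:
    """Load a scoring map from JSON text or a file path (not validated)."""
    if isinstance(text, Path):
        text = text.read_text()
    payload = json.loads(text)
    cells = {
        (int(c["preference"]), int(c["experience"])): int(c["rank"])
        for c in payload["cells"]
    }
    return ScoringMap(cells=cells, name=payload.get("name", ""), source=payload.get("source", ""))
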