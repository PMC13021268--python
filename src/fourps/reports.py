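"""Clinician-facing and research-grade reporting.

Two report builders turn scored data and fitted models into the outputs
the instrument's two audiences need:

* the **clinical report** summarises, per item, how respondents fall over
  the three-level scale (insufficient / fair / sufficient conditions for
  preference-based participation), the direction profile of mismatches
  (less vs. more than preferred), and a lay-language flag for everyday
  dialogue;
* the **research report** lists, per designated item and model, odds
  ratios with 95% credible intervals, probability-of-effect values and
  convergence diagnostics, with primary items first and the total model
  count stated so readers can judge multiplicity by design.

No report aggregates ranks across items (no sums or means): the 4Ps is a
single-item tool and every item stands on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import FitResult, PerItemFit
from .instrument import InstrumentDefinition, build_default_instrument
from .scoring import (
    FAIR,
    INSUFFICIENT,
    LESS_THAN_PREFERRED,
    LEVELS,
    MATCH,
    MORE_THAN_PREFERRED,
    SUFFICIENT,
)

__all__ = [
    "ClinicalReport",
    "ResearchReport",
    "build_clinical_report",
    "build_research_report",
    "LAY_FLAGS",
]

# lay-language phrasing of what each (modal) level calls for
LAY_FLAGS = {
    INSUFFICIENT: "calling for improved person-centredness",
    FAIR: "need to address mismatch",
    SUFFICIENT: "calls for sustainment",
}


@dataclass
class ClinicalReport:
    """Per-item three-level distribution with lay-language flags."""

    table: pd.DataFrame  # one row per item
    n_respondents: int
    n_rows_scored: int
    metadata: Mapping[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_respondents": self.n_respondents,
                "n_rows_scored": self.n_rows_scored,
                "metadata": dict(self.metadata),
                "items": self.table.to_dict(orient="records"),
            },
            indent=2,
            default=str,
        )

    def to_markdown(self) -> str:
        lines = [
            "# Clinical 4Ps report",
            "",
            f"Respondents scored: {self.n_respondents}; scored item pairs: {self.n_rows_scored}.",
            "",
        ]
        for _, row in self.table.iterrows():
            lines.append(f"## Item {row['item_id']}: {row['attribute']}")
            lines.append(
                f"- levels: insufficient {row['prop_insufficient']:.1%}, "
                f"fair {row['prop_fair']:.1%}, sufficient {row['prop_sufficient']:.1%} "
                f"(n = {row['n_scored']})"
            )
            lines.append(
                f"- mismatch direction: less than preferred {row['prop_less']:.1%}, "
                f"more than preferred {row['prop_more']:.1%}, match {row['prop_match']:.1%}"
            )
            lines.append(f"- flag: {row['lay_flag']}")
            lines.append("")
        return "\n".join(lines)


@dataclass
class ResearchReport:
    """Ordered per-item model tables with diagnostics and model count."""

    tables: list[dict]  # one entry per fit, ordered primary first
    n_models: int
    n_primary: int
    metadata: Mapping[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_models": self.n_models,
                "n_primary": self.n_primary,
                "metadata": dict(self.metadata),
                "tables": self.tables,
            },
            indent=2,
            default=str,
        )

    def to_markdown(self) -> str:
        lines = [
            "# Research 4Ps report",
            "",
            f"{self.n_models} models fitted ({self.n_primary} on primary items); "
            "interpret secondary-item findings in that light.",
            "",
        ]
        for entry in self.tables:
            title = f"## Item {entry['item_id']} ({entry['designation']})"
            lines.append(title)
            if entry.get("error"):
                lines.append(f"- not fitted: {entry['error']}")
                lines.append("")
                continue
            lines.append(f"- model: {entry['outcome']} | spec {entry['spec_digest']} | n = {entry['n_obs']}")
            if not entry["usable"]:
                lines.append("- **flagged unusable** (convergence diagnostics failed)")
            header = "| parameter | OR | 95% CrI | P(OR>1) | R-hat | ESS |"
            lines.append(header)
            lines.append("|---|---|---|---|---|---|")
            for row in entry["rows"]:
                lines.append(
                    f"| {row['parameter']} | {row['or_median']:.2f} | "
                    f"({row['or_ci_2.5']:.2f}, {row['or_ci_97.5']:.2f}) | "
                    f"{row['p_or_gt_1']:.3f} | {_fmt(row['rhat'])} | {_fmt(row['ess_bulk'], 0)} |"
                )
            lines.append("")
        return "\n".join(lines)


def _fmt(x: float, digits: int = 3) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "-"
    return f"{x:.{digits}f}"


def build_clinical_report(
    scored: pd.DataFrame,
    instrument: InstrumentDefinition | None = None,
    metadata: Mapping[str, object] | None = None,
) -> ClinicalReport:
    """Summarise a scored long table for clinical dialogue.

    All 12 items are reported (clinical use considers every item, with no
    discrepancy); items without scored rows appear with zero counts.  The
    lay flag is derived from the modal level: experiences out of line with
    preferences call for attention whether they fall short of or exceed
    them.
    """
    if scored.empty:
        raise ValueError("scored table is empty")
    instrument = instrument or build_default_instrument()
    rows = []
    for item in instrument.items:
        sub = scored[scored["item_id"] == item.item_id]
        n = len(sub)
        level_counts = {lev: int((sub["level"] == lev).sum()) for lev in LEVELS}
        cat_counts = {
            MATCH: int((sub["category"] == MATCH).sum()),
            LESS_THAN_PREFERRED: int((sub["category"] == LESS_THAN_PREFERRED).sum()),
            MORE_THAN_PREFERRED: int((sub["category"] == MORE_THAN_PREFERRED).sum()),
        }
        if n:
            # modal level; ties resolved toward the lower (more actionable) level
            modal = max(LEVELS, key=lambda lev: (level_counts[lev], -LEVELS.index(lev)))
            flag = LAY_FLAGS[modal]
        else:
            modal, flag = None, "no scored responses"
        rows.append(
            {
                "item_id": item.item_id,
                "attribute": item.attribute,
                "element": item.element,
                "construct": item.construct,
                "n_scored": n,
                **{f"n_{lev}": level_counts[lev] for lev in LEVELS},
                **{f"prop_{lev}": (level_counts[lev] / n if n else 0.0) for lev in LEVELS},
                "prop_match": cat_counts[MATCH] / n if n else 0.0,
                "prop_less": cat_counts[LESS_THAN_PREFERRED] / n if n else 0.0,
                "prop_more": cat_counts[MORE_THAN_PREFERRED] / n if n else 0.0,
                "modal_level": modal,
                "lay_flag": flag,
            }
        )
    table = pd.DataFrame(rows)
    return ClinicalReport(
        table=table,
        n_respondents=int(scored["respondent_id"].nunique()),
        n_rows_scored=int(len(scored)),
        metadata=dict(metadata or {}),
    )


def _fit_entry(item_id: int, designation: str, fit: FitResult | None, error: str | None) -> dict:
    entry: dict = {"item_id": item_id, "designation": designation, "error": error}
    if fit is None:
        return entry
    reportable = fit.summary[fit.summary["kind"].isin(["coefficient", "intercept"])]
    entry.update(
        {
            "outcome": fit.spec.outcome,
            "spec_digest": fit.spec.digest(),
            "method": fit.method,
            "n_obs": fit.n_obs,
            "usable": fit.usable,
            "warnings": list(fit.warnings),
            "rows": reportable.to_dict(orient="records"),
        }
    )
    return entry


def build_research_report(
    fits: Sequence[PerItemFit] | Sequence[FitResult],
    designation: Iterable[int] = (),
    metadata: Mapping[str, object] | None = None,
) -> ResearchReport:
    """Assemble fitted models into the research-mode report.

    Accepts either :class:`PerItemFit` entries (which carry their own
    designation) or bare :class:`FitResult` objects plus a set of primary
    item ids.  Primary-item tables come first; fits whose diagnostics
    failed are flagged unusable but still shown.
    """
    if not fits:
        raise ValueError("at least one fit is required")
    primary_set = set(designation)
    entries: list[dict] = []
    for f in fits:
        if isinstance(f, PerItemFit):
            entries.append(_fit_entry(f.item_id, f.designation, f.fit, f.error))
        else:
            item_id = f.spec.item_id
            desig = "primary" if item_id in primary_set else "secondary"
            entries.append(_fit_entry(item_id, desig, f, None))
    entries.sort(key=lambda e: (e["designation"] != "primary", e["item_id"]))
    n_primary = sum(1 for e in entries if e["designation"] == "primary")
    return ResearchReport(
        tables=entries,
        n_models=len(entries),
        n_primary=n_primary,
        metadata=dict(metadata or {}),
    )
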