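"""Guideline A/B/C classification and adherence reporting.

Each regimen is compared against the guideline table for its registered
sub-indication: category A if its agent set equals a recommended
first-choice regimen, B if it equals a second-choice regimen, C
(discordant) otherwise; regimens for a sub-indication marked
non-assessable (the 'other' codes) are NOT_ASSESSED. Matching is exact
set equality — a recommended agent plus an extra agent is discordant —
which is the stricter, auditable reading of "in accordance with the
guideline"; subset matching is available behind a flag. The adherence
rate defaults to A+B, the share of regimens on either recommended tier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from .model import GuidelineTable, RecommendedRegimen
from .therapy import Regimen


class AdherenceCategory(str, enum.Enum):
    A = "A"  # matches a first-choice recommendation
    B = "B"  # matches a second-choice recommendation
    C = "C"  # discordant with the guideline
    NOT_ASSESSED = "NOT_ASSESSED"


def _matches(
    regimen: Regimen, rec: RecommendedRegimen, route_strict: bool, allow_superset: bool
) -> bool:
    codes = regimen.atc_codes
    if allow_superset:
        if not rec.agents <= codes:
            return False
    elif codes != rec.agents:
        return False
    if route_strict:
        for atc, required in rec.route_constraint.items():
            routes = {route for code, route in regimen.agents if code == atc}
            if routes and routes != {required}:
                return False
    return True


def classify_regimen(
    regimen: Regimen,
    guideline: GuidelineTable,
    route_strict: bool = False,
    allow_superset: bool = False,
) -> AdherenceCategory:
    """Classify one regimen against the guideline table.

    First choice is tested before second choice, so a regimen can never be
    both A and B. Raises ``KeyError`` for a sub-indication absent from the
    table.
    """
    entry = guideline.entry(regimen.sub_indication)
    if not entry.assessable:
        return AdherenceCategory.NOT_ASSESSED
    for rec in entry.first_choice:
        if _matches(regimen, rec, route_strict, allow_superset):
            return AdherenceCategory.A
    for rec in entry.second_choice:
        if _matches(regimen, rec, route_strict, allow_superset):
            return AdherenceCategory.B
    return AdherenceCategory.C


def combination_label(regimen: Regimen) -> str:
    """Canonical display token for an agent combination (sorted ATC codes)."""
    return "+".join(sorted(regimen.atc_codes))


@dataclass
class SubIndicationSummary:
    sub_indication: str
    n_regimens: int
    proportion_a: float
    proportion_b: float
    proportion_c: float
    adherence_rate: float
    #: (combination label, frequency); combinations below the display
    #: threshold pooled as "other", ordered by descending frequency then label
    combination_frequencies: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class AdherenceReport:
    """Per-sub-indication adherence for one hospital/dataset."""

    hospital: str
    summaries: dict[str, SubIndicationSummary]
    n_not_assessed: int
    adherence_tier: Literal["AB", "A"] = "AB"

    def overall_adherence(self) -> float:
        n = sum(s.n_regimens for s in self.summaries.values())
        if n == 0:
            return float("nan")
        return sum(s.adherence_rate * s.n_regimens for s in self.summaries.values()) / n


def adherence_summary(
    regimens: Sequence[Regimen],
    categories: Sequence[AdherenceCategory],
    hospital: str = "",
    display_threshold: float = 0.05,
    adherence_tier: Literal["AB", "A"] = "AB",
) -> AdherenceReport:
    """Summarise categories per sub-indication over assessable regimens.

    Proportions of A/B/C sum to 1 per sub-indication. Agent-combination
    frequencies are computed within each sub-indication; combinations seen
    in fewer than ``display_threshold`` of cases are pooled as "other"
    (the figures grey 'prescribed in <5% of cases' convention).
    """
    if len(regimens) != len(categories):
        raise ValueError("one category per regimen required")
    per_sub: dict[str, list[tuple[Regimen, AdherenceCategory]]] = {}
    n_not_assessed = 0
    for reg, cat in zip(regimens, categories):
        if cat is AdherenceCategory.NOT_ASSESSED:
            n_not_assessed += 1
            continue
        per_sub.setdefault(reg.sub_indication, []).append((reg, cat))
    summaries: dict[str, SubIndicationSummary] = {}
    for sub, pairs in sorted(per_sub.items()):
        n = len(pairs)
        counts = {c: 0 for c in (AdherenceCategory.A, AdherenceCategory.B, AdherenceCategory.C)}
        for _, cat in pairs:
            counts[cat] += 1
        pa, pb, pc = (counts[c] / n for c in counts)
        freq: dict[str, int] = {}
        for reg, _ in pairs:
            label = combination_label(reg)
            freq[label] = freq.get(label, 0) + 1
        shown: dict[str, float] = {}
        other = 0.0
        for label, k in freq.items():
            f = k / n
            if f < display_threshold:
                other += f
            else:
                shown[label] = f
        ordered = sorted(shown.items(), key=lambda kv: (-kv[1], kv[0]))
        if other > 0:
            ordered.append(("other", other))
        summaries[sub] = SubIndicationSummary(
            sub_indication=sub,
            n_regimens=n,
            proportion_a=pa,
            proportion_b=pb,
            proportion_c=pc,
            adherence_rate=pa + pb if adherence_tier == "AB" else pa,
            combination_frequencies=ordered,
        )
    return AdherenceReport(
        hospital=hospital,
        summaries=summaries,
        n_not_assessed=n_not_assessed,
        adherence_tier=adherence_tier,
    )


def benchmark_table(reports: Sequence[AdherenceReport]) -> pd.DataFrame:
    """Cross-hospital long-format adherence table.

    One row per (hospital, sub-indication) with n and A/B/C/adherence
    percentages, plus per-sub-indication ``range`` rows carrying the
    min-max adherence across hospitals. Hospitals lacking a sub-indication
    (e.g. no mild/severe CAP split in their EMR) simply contribute no row
    for it.
    """
    rows = []
    for rep in reports:
        for sub, s in rep.summaries.items():
            rows.append(
                {
                    "hospital": rep.hospital,
                    "sub_indication": sub,
                    "n": s.n_regimens,
                    "pct_a": 100.0 * s.proportion_a,
                    "pct_b": 100.0 * s.proportion_b,
                    "pct_c": 100.0 * s.proportion_c,
                    "adherence_pct": 100.0 * s.adherence_rate,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["hospital", "sub_indication", "n", "pct_a", "pct_b", "pct_c", "adherence_pct"],
    )
    if df.empty:
        return df
    ranges = (
        df.groupby("sub_indication")["adherence_pct"]
        .agg(adherence_min="min", adherence_max="max")
        .reset_index()
    )
    return df.merge(ranges, on="sub_indication").sort_values(
        ["sub_indication", "hospital"], ignore_index=True
    )
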