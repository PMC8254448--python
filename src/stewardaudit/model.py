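"""Core domain types for antimicrobial-use auditing.

The unit of observation is a single systemic-antibiotic prescription
(ATC class J01) carrying a registered indication: an indication class
(empiric / targeted / prophylaxis), a focus tract (respiratory or
urinary tract infection, or anything else), and — for RTI/UTI — a
sub-indication code from a configurable taxonomy (e.g. mild-to-moderate
community-acquired pneumonia, cystitis, complicated UTI).

Everything downstream (cohort selection, regimen assembly, guideline
classification, accuracy validation) consumes only these types.
"""

from __future__ import annotations

import enum
from datetime import datetime
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class Route(str, enum.Enum):
    """Route of administration of a prescription."""

    oral = "oral"
    iv = "iv"
    im = "im"
    other = "other"


class IndicationClass(str, enum.Enum):
    """Registered therapeutic intent of the prescription."""

    empiric = "empiric"
    targeted = "targeted"
    prophylaxis = "prophylaxis"


class Tract(str, enum.Enum):
    """Registered focus of infection at tract level."""

    RTI = "RTI"
    UTI = "UTI"
    other = "other"


class WardType(str, enum.Enum):
    general = "general"
    icu = "icu"
    other = "other"


class PrescriptionRecord(BaseModel):
    """One systemic-antibiotic order from the EMR extract.

    ``atc_code`` (WHO ATC level 5) is the canonical agent key; ``agent_name``
    is display-only. The activity interval is half-open ``[start_ts,
    stop_ts)``; an absent ``stop_ts`` means the order ran through discharge.
    ``stop_ts < start_ts`` is accepted at ingest and flagged downstream so
    audits stay lossless.
    """

    record_id: str
    patient_id: str
    admission_id: str
    atc_code: str = Field(min_length=1)
    agent_name: str = ""
    start_ts: datetime
    stop_ts: Optional[datetime] = None
    route: Route = Route.other
    dose_text: str = ""
    prescriber_specialty: str = ""
    ward: str = ""
    indication_class: IndicationClass
    focus_tract: Tract
    sub_indication: Optional[str] = None

    @model_validator(mode="after")
    def _sub_indication_required_for_rti_uti(self) -> "PrescriptionRecord":
        if self.focus_tract in (Tract.RTI, Tract.UTI) and not self.sub_indication:
            raise ValueError(
                f"record {self.record_id}: sub_indication required when "
                f"focus_tract is {self.focus_tract.value}"
            )
        return self

    def active_at(self, ts: datetime) -> bool:
        """Whether the order is active at ``ts`` under the half-open convention.

        An absent stop timestamp counts as active indefinitely (the
        admission's discharge bounds it in practice).
        """
        if ts < self.start_ts:
            return False
        return self.stop_ts is None or ts < self.stop_ts


class Admission(BaseModel):
    """One hospital stay. ``age_years`` is the patient's age at admission."""

    patient_id: str
    admission_id: str
    admit_ts: datetime
    discharge_ts: datetime
    age_years: int = Field(ge=0)
    ward_type: WardType = WardType.general

    @model_validator(mode="after")
    def _discharge_after_admit(self) -> "Admission":
        if self.discharge_ts < self.admit_ts:
            raise ValueError(
                f"admission {self.admission_id}: discharge_ts precedes admit_ts"
            )
        return self

    @property
    def stay_hours(self) -> float:
        return (self.discharge_ts - self.admit_ts).total_seconds() / 3600.0


class IndicationTaxonomy(BaseModel):
    """Sub-indication codes per tract, with display labels.

    Every code belongs to exactly one tract. Each tract normally carries an
    ``other`` member; sites may omit it (one study hospital lacked an
    'other' option for RTI, which pushed prescribers to the second-best
    code), so its presence is configurable rather than enforced.
    """

    tracts: dict[Tract, dict[str, str]]

    @field_validator("tracts")
    @classmethod
    def _codes_unique_across_tracts(
        cls, v: dict[Tract, dict[str, str]]
    ) -> dict[Tract, dict[str, str]]:
        seen: dict[str, Tract] = {}
        for tract, codes in v.items():
            for code in codes:
                if code in seen:
                    raise ValueError(
                        f"sub-indication code {code!r} appears in both "
                        f"{seen[code].value} and {tract.value}"
                    )
                seen[code] = tract
        return v

    def tract_of(self, code: str) -> Optional[Tract]:
        for tract, codes in self.tracts.items():
            if code in codes:
                return tract
        return None

    def codes(self, tract: Tract | None = None) -> list[str]:
        if tract is not None:
            return list(self.tracts.get(tract, {}))
        return [c for codes in self.tracts.values() for c in codes]

    def label(self, code: str) -> str:
        for codes in self.tracts.values():
            if code in codes:
                return codes[code]
        return code


#: Default taxonomy mirroring a Dutch hospital indication-registration menu.
DEFAULT_TAXONOMY = IndicationTaxonomy(
    tracts={
        Tract.RTI: {
            "CAP": "community-acquired pneumonia (severity unspecified)",
            "CAP-m": "community-acquired pneumonia, mild to moderate-severe",
            "CAP-s": "community-acquired pneumonia, severe",
            "HAP": "hospital-acquired pneumonia",
            "COPD": "exacerbation of COPD",
            "aspiration-pneumonia": "aspiration pneumonia",
            "bronchitis": "acute bronchitis",
            "other-RTI": "other respiratory tract infection",
        },
        Tract.UTI: {
            "cystitis": "cystitis",
            "complicated-UTI": "complicated UTI (urosepsis / pyelonephritis)",
            "chronic-prostatitis": "chronic bacterial prostatitis",
            "other-UTI": "other urinary tract infection",
        },
    }
)


class RecommendedRegimen(BaseModel):
    """A guideline-recommended agent set, matchable against prescriptions.

    ``agents`` is a duplicate-free set of ATC level-5 codes so that
    combination recommendations (e.g. a beta-lactam plus a macrolide for
    severe CAP) are expressible. ``route_constraint`` optionally restricts
    the route per agent; it only participates in matching when route-strict
    classification is requested.
    """

    agents: frozenset[str]
    route_constraint: dict[str, Route] = Field(default_factory=dict)

    @field_validator("agents")
    @classmethod
    def _non_empty(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("a recommended regimen needs at least one agent")
        return v

    @model_validator(mode="after")
    def _constraint_agents_known(self) -> "RecommendedRegimen":
        unknown = set(self.route_constraint) - set(self.agents)
        if unknown:
            raise ValueError(
                f"route_constraint names agents not in the regimen: {sorted(unknown)}"
            )
        return self

    def key(self) -> frozenset[str]:
        return self.agents


class GuidelineEntry(BaseModel):
    """First- and second-choice recommendations for one sub-indication."""

    assessable: bool = True
    first_choice: list[RecommendedRegimen] = Field(default_factory=list)
    second_choice: list[RecommendedRegimen] = Field(default_factory=list)

    @model_validator(mode="after")
    def _choices_consistent(self) -> "GuidelineEntry":
        first = [r.key() for r in self.first_choice]
        second = [r.key() for r in self.second_choice]
        if len(set(first)) != len(first) or len(set(second)) != len(second):
            raise ValueError("duplicate regimen within a choice list")
        overlap = set(first) & set(second)
        if overlap:
            raise ValueError(
                "regimen(s) appear in both first and second choice: "
                + "; ".join(",".join(sorted(k)) for k in overlap)
            )
        if self.assessable and not self.first_choice:
            raise ValueError("an assessable sub-indication needs >=1 first-choice regimen")
        return self


class GuidelineTable(BaseModel):
    """Per sub-indication recommendations used for A/B/C classification."""

    entries: dict[str, GuidelineEntry]
    taxonomy: IndicationTaxonomy = Field(default_factory=lambda: DEFAULT_TAXONOMY)

    @model_validator(mode="after")
    def _codes_in_taxonomy(self) -> "GuidelineTable":
        known = set(self.taxonomy.codes())
        unknown = set(self.entries) - known
        if unknown:
            raise ValueError(
                f"guideline table names unknown sub-indication code(s): {sorted(unknown)}"
            )
        return self

    def entry(self, sub_indication: str) -> GuidelineEntry:
        try:
            return self.entries[sub_indication]
        except KeyError:
            raise KeyError(
                f"sub-indication {sub_indication!r} not present in the guideline table"
            ) from None


class ReviewStratum(str, enum.Enum):
    """Chart-review sampling strata.

    RTI/UTI strata hold records sampled by their *selected* (registered)
    indication; ``random_other`` holds a random draw from everything else,
    used to estimate how many true RTI/UTI prescriptions the registration
    missed.
    """

    RTI = "RTI"
    UTI = "UTI"
    random_other = "random_other"


#: documented_indication value when the chart gave no verdict.
UNASSESSABLE = "unassessable"
#: marker for an indication outside the RTI/UTI taxonomy.
NON_RTI_UTI = "non-RTI/UTI"


class ChartReviewRecord(BaseModel):
    """One manually reviewed record: selected vs documented indication.

    ``selected_indication`` is what the prescriber registered;
    ``documented_indication`` is what the reviewer found in the chart
    (a sub-indication code, :data:`NON_RTI_UTI`, or :data:`UNASSESSABLE`).
    """

    record_id: str
    stratum: ReviewStratum
    selected_indication: str
    documented_indication: str
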