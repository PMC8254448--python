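"""Empiric-therapy cohort selection.

Turns a raw prescription extract plus an admissions table into the set of
empiric RTI/UTI prescriptions eligible for appropriateness assessment,
recording a conservation-checked flowchart count at every stage.

The empiric regimen of an admission is the antibiotic (combination)
therapy active 24 h after admission — early prescriptions are frequently
adjusted once first diagnostics arrive, and after 24 h therapy typically
switches to targeted — or, for stays of 12-24 h, the last therapy
prescribed before discharge. Stays under 12 h do not count as
hospitalized-clinical admissions at all.

Exclusion attribution is deterministic: each excluded unit is counted
once, under the first failing rule in a fixed order (admission rules:
age, ward, stay, readmission; then per-prescription: erroneous start,
dual tract, indication windows). The fixed order makes flowcharts
reproducible across runs and hospitals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .model import Admission, IndicationClass, PrescriptionRecord, Tract, WardType


class SelectionParams(BaseModel):
    """Tunable rules of the cohort selection.

    Defaults encode the audit design: adults (>=18 y) on general wards,
    hospitalized at least 12 h, empiric therapy read at the 24 h snapshot,
    readmissions within 30 days excluded, prophylaxis-registered orders
    dropped before snapshotting. ``indication_exclusion_windows`` removes
    prescriptions of a given tract started inside a date interval — e.g.
    respiratory prescriptions after 2020-03-01, when no guideline covered
    COVID-19 pneumonia (end date open).
    """

    min_age_years: int = 18
    min_stay_hours: float = 12.0
    snapshot_hours: float = 24.0
    readmission_window_days: int = 30
    indication_exclusion_windows: list[tuple[Tract, date, Optional[date]]] = Field(
        default_factory=list
    )
    exclude_indication_classes: set[IndicationClass] = Field(
        default_factory=lambda: {IndicationClass.prophylaxis}
    )

    @model_validator(mode="after")
    def _stay_leq_snapshot(self) -> "SelectionParams":
        if self.min_stay_hours > self.snapshot_hours:
            raise ValueError("min_stay_hours must not exceed snapshot_hours")
        for tract, start, end in self.indication_exclusion_windows:
            if end is not None and end < start:
                raise ValueError(f"malformed exclusion window for {tract.value}")
        return self


@dataclass
class FlowchartStage:
    label: str
    n_input: int
    n_kept: int
    n_excluded: int


@dataclass
class FlowchartCounts:
    """Ordered exclusion-flowchart counts; consecutive stages must chain."""

    stages: list[FlowchartStage] = field(default_factory=list)

    def add(self, label: str, n_input: int, n_kept: int) -> None:
        self.stages.append(FlowchartStage(label, n_input, n_kept, n_input - n_kept))

    def check(self) -> None:
        """Raise if any stage violates input = kept + excluded or chaining."""
        for st in self.stages:
            if st.n_input != st.n_kept + st.n_excluded:
                raise ValueError(
                    f"flowchart stage {st.label!r}: {st.n_input} != "
                    f"{st.n_kept} + {st.n_excluded}"
                )
            if min(st.n_input, st.n_kept, st.n_excluded) < 0:
                raise ValueError(f"flowchart stage {st.label!r}: negative count")
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_kept != nxt.n_input:
                raise ValueError(
                    f"flowchart stages {prev.label!r}->{nxt.label!r} do not chain: "
                    f"{prev.n_kept} != {nxt.n_input}"
                )

    def excluded(self, label: str) -> int:
        for st in self.stages:
            if st.label == label:
                return st.n_excluded
        raise KeyError(label)

    def stage_share_pct(self, label: str) -> float:
        """Kept share of a stage's input, in percent (e.g. the RTI/UTI share)."""
        for st in self.stages:
            if st.label == label:
                return 100.0 * st.n_kept / st.n_input if st.n_input else 0.0
        raise KeyError(label)


@dataclass
class EmpiricSelection:
    """The empiric prescriptions of one admission.

    ``evaluation_ts`` is the instant actually used: admit + snapshot_hours,
    or the discharge time for the 12-24 h branch.
    """

    admission_id: str
    evaluation_ts: datetime
    records: list[PrescriptionRecord]
    tracts_present: set[Tract]


def flag_readmissions(
    admissions: Sequence[Admission], window_days: int = 30
) -> dict[str, bool]:
    """Flag admissions that start within ``window_days`` of a prior discharge.

    Only the later admission is flagged — empiric guideline recommendations
    still apply to the index admission. A patient's first admission is never
    flagged. Overlapping admissions for one patient trigger a warning; the
    flag is then computed on discharge order.
    """
    flags: dict[str, bool] = {}
    by_patient: dict[str, list[Admission]] = {}
    for adm in admissions:
        by_patient.setdefault(adm.patient_id, []).append(adm)
    window = timedelta(days=window_days)
    for patient, adms in by_patient.items():
        adms.sort(key=lambda a: (a.admit_ts, a.discharge_ts))
        for i, adm in enumerate(adms):
            if i > 0 and adm.admit_ts < adms[i - 1].discharge_ts:
                warnings.warn(
                    f"patient {patient}: overlapping admissions "
                    f"{adms[i - 1].admission_id}/{adm.admission_id}",
                    stacklevel=2,
                )
            prior = [a for a in adms[:i]]
            flags[adm.admission_id] = any(
                timedelta(0) <= adm.admit_ts - a.discharge_ts < window for a in prior
            )
    return flags


ADMISSION_RULES = ("age", "ward", "stay", "readmission")


def select_eligible_admissions(
    admissions: Sequence[Admission],
    params: SelectionParams,
    readmission_flags: dict[str, bool] | None = None,
) -> tuple[list[Admission], dict[str, str]]:
    """Apply the admission-level rules; return kept admissions and, per
    excluded admission, the first failing rule (age / ward / stay /
    readmission)."""
    if readmission_flags is None:
        readmission_flags = flag_readmissions(admissions, params.readmission_window_days)
    kept: list[Admission] = []
    excluded: dict[str, str] = {}
    for adm in admissions:
        if adm.age_years < params.min_age_years:
            excluded[adm.admission_id] = "age"
        elif adm.ward_type != WardType.general:
            excluded[adm.admission_id] = "ward"
        elif adm.stay_hours < params.min_stay_hours:
            excluded[adm.admission_id] = "stay"
        elif readmission_flags.get(adm.admission_id, False):
            excluded[adm.admission_id] = "readmission"
        else:
            kept.append(adm)
    return kept, excluded


def snapshot_empiric(
    records: Sequence[PrescriptionRecord],
    admission: Admission,
    params: SelectionParams,
) -> EmpiricSelection:
    """Derive the admission's empiric prescriptions.

    For stays >= ``snapshot_hours``: the records whose half-open activity
    interval contains admit + snapshot_hours (absent stop = active through
    discharge). For stays in [min_stay_hours, snapshot_hours): the
    record(s) with the latest start on or before discharge; equal starts
    all kept — they form a combination. May be empty (no antibiotic active
    at the snapshot).

    Prophylaxis-class records must already have been removed; passing an
    admission shorter than ``min_stay_hours`` is a contract violation.
    """
    own = [r for r in records if r.admission_id == admission.admission_id]
    stay = admission.stay_hours
    if stay < params.min_stay_hours:
        raise ValueError(
            f"admission {admission.admission_id}: stay {stay:.1f} h below the "
            f"{params.min_stay_hours} h inclusion threshold"
        )
    if stay >= params.snapshot_hours:
        t_snap = admission.admit_ts + timedelta(hours=params.snapshot_hours)
        chosen = [r for r in own if r.active_at(t_snap)]
    else:
        t_snap = admission.discharge_ts
        candidates = [r for r in own if r.start_ts <= admission.discharge_ts]
        if candidates:
            latest = max(r.start_ts for r in candidates)
            chosen = [r for r in candidates if r.start_ts == latest]
        else:
            chosen = []
    return EmpiricSelection(
        admission_id=admission.admission_id,
        evaluation_ts=t_snap,
        records=chosen,
        tracts_present={r.focus_tract for r in chosen},
    )


PRESCRIPTION_RULES = ("erroneous", "dual_tract", "indication_window")


def apply_prescription_exclusions(
    selection: EmpiricSelection,
    admission: Admission,
    params: SelectionParams,
) -> tuple[list[PrescriptionRecord], dict[str, str]]:
    """Per-prescription exclusions on an empiric selection, in fixed order.

    1. erroneous — start before the admission (data-entry artefacts);
    2. dual tract — if the admission's empiric set spans both RTI and UTI,
       all its RTI/UTI records go (the indication is ambiguous, so the
       therapy can be attributed to neither);
    3. indication windows — tract-level date exclusions on the start date.

    Returns kept records and, per excluded record id, the rule that removed
    it (each record counted once, under the first failing rule).
    """
    excluded: dict[str, str] = {}
    kept: list[PrescriptionRecord] = []
    dual = Tract.RTI in selection.tracts_present and Tract.UTI in selection.tracts_present
    for r in selection.records:
        if r.start_ts < admission.admit_ts:
            excluded[r.record_id] = "erroneous"
        elif dual and r.focus_tract in (Tract.RTI, Tract.UTI):
            excluded[r.record_id] = "dual_tract"
        elif _in_exclusion_window(r, params):
            excluded[r.record_id] = "indication_window"
        else:
            kept.append(r)
    return kept, excluded


def _in_exclusion_window(r: PrescriptionRecord, params: SelectionParams) -> bool:
    d = r.start_ts.date()
    for tract, start, end in params.indication_exclusion_windows:
        if r.focus_tract == tract and d >= start and (end is None or d <= end):
            return True
    return False


@dataclass
class SelectionResult:
    records: list[PrescriptionRecord]
    flowchart: FlowchartCounts
    selections: dict[str, EmpiricSelection]  # admission_id -> empiric snapshot
    admission_exclusions: dict[str, str]
    record_exclusions: dict[str, str]


STAGE_ORDER = (
    "total",
    "linked",
    "tract",
    "indication_class",
    "age",
    "ward",
    "stay",
    "readmission",
    "empiric_snapshot",
    "erroneous",
    "dual_tract",
    "indication_window",
)


def run_selection(
    records: Sequence[PrescriptionRecord],
    admissions: Sequence[Admission],
    params: SelectionParams | None = None,
) -> SelectionResult:
    """Full deterministic selection pipeline, counted in prescriptions.

    Stage order: link to admissions; restrict to RTI/UTI focus; drop
    excluded indication classes (prophylaxis by default); admission
    eligibility (age, ward, stay, readmission — each prescription counted
    under its admission's first failing rule); the empiric snapshot; then
    the per-prescription exclusions. The flowchart satisfies
    input = kept + excluded at every stage and chains stage to stage.
    """
    params = params or SelectionParams()
    fc = FlowchartCounts()
    by_id = {a.admission_id: a for a in admissions}
    record_excl: dict[str, str] = {}

    pool = list(records)
    fc.add("total", len(pool), len(pool))

    linked = [r for r in pool if r.admission_id in by_id]
    for r in pool:
        if r.admission_id not in by_id:
            record_excl[r.record_id] = "unlinked"
    fc.add("linked", len(pool), len(linked))

    tract_pool = [r for r in linked if r.focus_tract in (Tract.RTI, Tract.UTI)]
    for r in linked:
        if r.focus_tract not in (Tract.RTI, Tract.UTI):
            record_excl[r.record_id] = "non_rti_uti"
    fc.add("tract", len(linked), len(tract_pool))

    class_pool = [
        r for r in tract_pool if r.indication_class not in params.exclude_indication_classes
    ]
    for r in tract_pool:
        if r.indication_class in params.exclude_indication_classes:
            record_excl[r.record_id] = "indication_class"
    fc.add("indication_class", len(tract_pool), len(class_pool))

    flags = flag_readmissions(admissions, params.readmission_window_days)
    _, adm_excl = select_eligible_admissions(admissions, params, flags)
    pool = class_pool
    for rule in ADMISSION_RULES:
        kept = [r for r in pool if adm_excl.get(r.admission_id) != rule]
        for r in pool:
            if adm_excl.get(r.admission_id) == rule:
                record_excl[r.record_id] = rule
        fc.add(rule, len(pool), len(kept))
        pool = kept

    selections: dict[str, EmpiricSelection] = {}
    snapshot_records: list[PrescriptionRecord] = []
    by_admission: dict[str, list[PrescriptionRecord]] = {}
    for r in pool:
        by_admission.setdefault(r.admission_id, []).append(r)
    for admission_id, recs in by_admission.items():
        sel = snapshot_empiric(recs, by_id[admission_id], params)
        selections[admission_id] = sel
        snapshot_records.extend(sel.records)
    chosen_ids = {r.record_id for r in snapshot_records}
    for r in pool:
        if r.record_id not in chosen_ids:
            record_excl[r.record_id] = "not_empiric"
    fc.add("empiric_snapshot", len(pool), len(snapshot_records))

    pool = snapshot_records
    stage_excl: dict[str, str] = {}
    for admission_id, sel in selections.items():
        _, excl = apply_prescription_exclusions(sel, by_id[admission_id], params)
        stage_excl.update(excl)
    for rule in PRESCRIPTION_RULES:
        kept = [r for r in pool if stage_excl.get(r.record_id) != rule]
        for r in pool:
            if stage_excl.get(r.record_id) == rule:
                record_excl[r.record_id] = rule
        fc.add(rule, len(pool), len(kept))
        pool = kept

    fc.check()
    return SelectionResult(
        records=pool,
        flowchart=fc,
        selections=selections,
        admission_exclusions=adm_excl,
        record_exclusions=record_excl,
    )
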