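"""Cohort selection: readmission flags, eligibility, snapshot, exclusions."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from stewardaudit.cohort import (
    FlowchartCounts,
    SelectionParams,
    apply_prescription_exclusions,
    flag_readmissions,
    run_selection,
    select_eligible_admissions,
    snapshot_empiric,
)
from stewardaudit.model import IndicationClass, Tract, WardType
from tests.conftest import T0


def test_readmission_within_window_flags_only_later_admission(make_admission):
    first = make_admission(admission_id="A1", admit=datetime(2019, 1, 1), stay_hours=48)
    # discharged Jan 3, readmitted Jan 20: 17 days later
    second = make_admission(admission_id="A2", admit=datetime(2019, 1, 20), stay_hours=48)
    flags = flag_readmissions([second, first], window_days=30)
    assert flags == {"A1": False, "A2": True}


def test_readmission_outside_window_not_flagged(make_admission):
    first = make_admission(admission_id="A1", admit=datetime(2019, 1, 1), stay_hours=24)
    second = make_admission(admission_id="A2", admit=datetime(2019, 3, 15), stay_hours=24)
    flags = flag_readmissions([first, second], window_days=30)
    assert flags == {"A1": False, "A2": False}


def test_single_admission_never_flagged(make_admission):
    assert flag_readmissions([make_admission()], 30) == {"A1": False}


def test_overlapping_admissions_warn(make_admission):
    a = make_admission(admission_id="A1", admit=datetime(2019, 1, 1), stay_hours=96)
    b = make_admission(admission_id="A2", admit=datetime(2019, 1, 2), stay_hours=96)
    with pytest.warns(UserWarning, match="overlapping"):
        flag_readmissions([a, b], 30)


def test_eligibility_attributes_first_failing_rule(make_admission):
    params = SelectionParams()
    underage_icu = make_admission(admission_id="A1", patient_id="P1", age=17, ward=WardType.icu)
    icu = make_admission(admission_id="A2", patient_id="P2", age=40, ward=WardType.icu)
    short = make_admission(admission_id="A3", patient_id="P3", age=40, stay_hours=10)
    ok = make_admission(admission_id="A4", patient_id="P4", age=40, stay_hours=48)
    kept, excluded = select_eligible_admissions([underage_icu, icu, short, ok], params)
    assert excluded == {"A1": "age", "A2": "ward", "A3": "stay"}
    assert [a.admission_id for a in kept] == ["A4"]


def test_snapshot_keeps_records_covering_hour_24(make_record, make_admission):
    adm = make_admission(stay_hours=72)
    a = make_record(start=T0 + timedelta(hours=2), stop_hours=46)  # [2h, 48h)
    b = make_record(start=T0 + timedelta(hours=30), stop_hours=30)  # [30h, 60h)
    sel = snapshot_empiric([a, b], adm, SelectionParams())
    assert [r.record_id for r in sel.records] == [a.record_id]
    assert sel.evaluation_ts == T0 + timedelta(hours=24)


def test_snapshot_half_open_boundary_semantics(make_record, make_admission):
    adm = make_admission(stay_hours=72)
    stops_at_24 = make_record(start=T0, stop_hours=24)  # [0, 24): not active at 24
    starts_at_24 = make_record(start=T0 + timedelta(hours=24), stop_hours=24)
    sel = snapshot_empiric([stops_at_24, starts_at_24], adm, SelectionParams())
    assert [r.record_id for r in sel.records] == [starts_at_24.record_id]


def test_short_stay_branch_takes_last_prescribed_therapy(make_record, make_admission):
    adm = make_admission(stay_hours=18)
    early = make_record(start=T0 + timedelta(hours=1))
    late = make_record(start=T0 + timedelta(hours=10))
    sel = snapshot_empiric([early, late], adm, SelectionParams())
    assert [r.record_id for r in sel.records] == [late.record_id]
    assert sel.evaluation_ts == adm.discharge_ts


def test_short_stay_ties_form_a_combination(make_record, make_admission):
    adm = make_admission(stay_hours=18)
    a = make_record(start=T0 + timedelta(hours=10), atc="J01DD04")
    b = make_record(start=T0 + timedelta(hours=10), atc="J01FA01")
    sel = snapshot_empiric([a, b], adm, SelectionParams())
    assert {r.record_id for r in sel.records} == {a.record_id, b.record_id}


def test_snapshot_may_be_empty(make_record, make_admission):
    adm = make_admission(stay_hours=72)
    late = make_record(start=T0 + timedelta(hours=30), stop_hours=10)
    assert snapshot_empiric([late], adm, SelectionParams()).records == []


def test_snapshot_rejects_sub_threshold_stay(make_record, make_admission):
    with pytest.raises(ValueError, match="12"):
        snapshot_empiric([make_record()], make_admission(stay_hours=8), SelectionParams())


def test_prescription_exclusions_fixed_order(make_record, make_admission):
    adm = make_admission(stay_hours=72)
    params = SelectionParams(
        indication_exclusion_windows=[(Tract.RTI, date(2020, 3, 1), None)]
    )
    erroneous = make_record(start=T0 - timedelta(hours=6), record_id="err")
    rti = make_record(record_id="rti")
    uti = make_record(tract=Tract.UTI, sub="cystitis", record_id="uti")
    sel = snapshot_empiric([erroneous, rti, uti], adm, params)
    kept, excluded = apply_prescription_exclusions(sel, adm, params)
    assert excluded == {"err": "erroneous", "rti": "dual_tract", "uti": "dual_tract"}
    assert kept == []


def test_covid_style_window_excludes_by_start_date(make_record, make_admission):
    admit = datetime(2020, 4, 15, 9, 0)
    adm = make_admission(admit=admit, stay_hours=72)
    params = SelectionParams(
        indication_exclusion_windows=[(Tract.RTI, date(2020, 3, 1), None)]
    )
    rti = make_record(start=admit + timedelta(hours=2), record_id="covid-era")
    uti = make_record(
        tract=Tract.UTI, sub="cystitis", start=admit + timedelta(hours=2), record_id="uti"
    )
    sel_rti = snapshot_empiric([rti], adm, params)
    _, excl = apply_prescription_exclusions(sel_rti, adm, params)
    assert excl == {"covid-era": "indication_window"}
    sel_uti = snapshot_empiric([uti], adm, params)
    kept, excl = apply_prescription_exclusions(sel_uti, adm, params)
    assert excl == {} and len(kept) == 1


def test_run_selection_empty_inputs_all_zero():
    result = run_selection([], [], SelectionParams())
    assert result.records == []
    assert all(s.n_input == 0 for s in result.flowchart.stages)


def test_run_selection_determinism(make_record, make_admission):
    adms = [make_admission(), make_admission(admission_id="A2", patient_id="P2")]
    recs = [make_record(), make_record(admission_id="A2", patient_id="P2")]
    r1 = run_selection(recs, adms)
    r2 = run_selection(recs, adms)
    assert [r.record_id for r in r1.records] == [r.record_id for r in r2.records]
    assert r1.flowchart == r2.flowchart


def test_widening_readmission_window_never_keeps_more(make_admission, make_record):
    adms = [
        make_admission(admission_id="A1", admit=datetime(2019, 1, 1), stay_hours=48),
        make_admission(admission_id="A2", admit=datetime(2019, 2, 10), stay_hours=48),
    ]
    recs = [
        make_record(admission_id="A1", start=datetime(2019, 1, 1, 2)),
        make_record(admission_id="A2", start=datetime(2019, 2, 10, 2)),
    ]
    kept = [
        len(run_selection(recs, adms, SelectionParams(readmission_window_days=w)).records)
        for w in (10, 30, 60, 365)
    ]
    assert kept == sorted(kept, reverse=True)


def test_flowchart_conservation_and_chaining_enforced():
    fc = FlowchartCounts()
    fc.add("a", 10, 7)
    fc.add("b", 7, 7)
    fc.check()
    fc.stages[0].n_excluded = 5  # tamper
    with pytest.raises(ValueError, match="10"):
        fc.check()
    fc2 = FlowchartCounts()
    fc2.add("a", 10, 7)
    fc2.add("b", 6, 6)  # does not chain
    with pytest.raises(ValueError, match="chain"):
        fc2.check()


def test_min_stay_above_snapshot_rejected():
    with pytest.raises(ValueError):
        SelectionParams(min_stay_hours=30, snapshot_hours=24)
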