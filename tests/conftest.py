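from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from stewardaudit.io import packaged_guideline_path, read_guideline_table
from stewardaudit.model import (
    Admission,
    IndicationClass,
    PrescriptionRecord,
    Route,
    Tract,
    WardType,
)

T0 = datetime(2019, 3, 10, 8, 0)


@pytest.fixture(scope="session")
def guideline():
    return read_guideline_table(packaged_guideline_path())


@pytest.fixture
def make_admission():
    def _make(
        admission_id="A1",
        patient_id="P1",
        admit=T0,
        stay_hours=72.0,
        age=60,
        ward=WardType.general,
    ):
        return Admission(
            patient_id=patient_id,
            admission_id=admission_id,
            admit_ts=admit,
            discharge_ts=admit + timedelta(hours=stay_hours),
            age_years=age,
            ward_type=ward,
        )

    return _make


@pytest.fixture
def make_record():
    counter = {"n": 0}

    def _make(
        admission_id="A1",
        patient_id="P1",
        atc="J01CA04",
        start=T0 + timedelta(hours=2),
        stop_hours=70.0,
        route=Route.iv,
        indication_class=IndicationClass.empiric,
        tract=Tract.RTI,
        sub="CAP-m",
        record_id=None,
    ):
        counter["n"] += 1
        return PrescriptionRecord(
            record_id=record_id or f"R{counter['n']:04d}",
            patient_id=patient_id,
            admission_id=admission_id,
            atc_code=atc,
            agent_name="",
            start_ts=start,
            stop_ts=None if stop_hours is None else start + timedelta(hours=stop_hours),
            route=route,
            indication_class=indication_class,
            focus_tract=tract,
            sub_indication=sub if tract in (Tract.RTI, Tract.UTI) else None,
        )

    return _make
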