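"""Synthetic cohort generator: determinism, planted anomalies, truth labels."""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pytest

from stewardaudit.io import write_prescription_extract
from stewardaudit.model import IndicationClass, Tract, WardType
from stewardaudit.simulate import (
    DEFAULT_CONFUSION,
    SimConfig,
    SimulationError,
    generate_cohort,
    inject_misselection,
    reviews_from_truth,
)


def test_zero_patients_empty_outputs(guideline):
    adm, recs, truth = generate_cohort(SimConfig(n_patients=0, seed=1), guideline)
    assert adm == [] and recs == [] and truth.records == {}


def test_same_seed_byte_identical_extract(tmp_path, guideline):
    cfg = SimConfig(n_patients=150, seed=9)
    out = []
    for name in ("a.csv", "b.csv"):
        _, recs, _ = generate_cohort(cfg, guideline)
        path = tmp_path / name
        write_prescription_extract(recs, path)
        out.append(path.read_bytes())
    assert out[0] == out[1]


def test_different_seeds_differ(guideline):
    r1 = generate_cohort(SimConfig(n_patients=100, seed=1), guideline)[1]
    r2 = generate_cohort(SimConfig(n_patients=100, seed=2), guideline)[1]
    assert [r.start_ts for r in r1] != [r.start_ts for r in r2]


def _isolated_erroneous_config(n, seed, fraction):
    """Every admission is a clean adult RTI/UTI empiric episode, so the
    erroneous-start draw happens exactly once per patient."""
    return SimConfig(
        n_patients=n,
        seed=seed,
        p_rti=0.5,
        p_uti=0.5,
        p_targeted=0.0,
        p_prophylaxis=0.0,
        underage_fraction=0.0,
        icu_fraction=0.0,
        short_stay_fraction=0.0,
        readmission_fraction=0.0,
        boundary_stay_fraction=0.0,
        extra_admission_fraction=0.0,
        missed_registration_fraction=0.0,
        dual_tract_fraction=0.0,
        extra_order_fraction=0.0,
        erroneous_start_fraction=fraction,
    )


def test_planted_erroneous_count_binomial(guideline):
    """With a 10% erroneous-start fraction over 1000 episodes the planted
    count stays inside the 99% binomial interval around 100."""
    cfg = _isolated_erroneous_config(1000, seed=3, fraction=0.1)
    adm, recs, truth = generate_cohort(cfg, guideline)
    erroneous_admissions = {
        t.admission_id for t in truth.records.values() if t.exclusion_reason == "erroneous"
    }
    n, p = 1000, 0.1
    half_width = 2.576 * np.sqrt(n * p * (1 - p))
    assert abs(len(erroneous_admissions) - n * p) <= half_width


def test_truth_labels_verifiable_from_generated_files(guideline):
    """Every planted exclusion corresponds to an observable anomaly."""
    cfg = SimConfig(n_patients=400, seed=21)
    admissions, records, truth = generate_cohort(cfg, guideline)
    by_adm = {a.admission_id: a for a in admissions}
    by_rec = {r.record_id: r for r in records}
    for rid, t in truth.records.items():
        r = by_rec[rid]
        a = by_adm[t.admission_id]
        reason = t.exclusion_reason
        if reason == "age":
            assert a.age_years < 18
        elif reason == "ward":
            assert a.ward_type is WardType.icu
        elif reason == "stay":
            assert a.stay_hours < 12
        elif reason == "erroneous":
            assert r.start_ts < a.admit_ts
        elif reason == "non_rti_uti":
            assert r.focus_tract is Tract.other
        elif reason == "indication_class":
            assert r.indication_class is IndicationClass.prophylaxis
        elif reason == "not_empiric":
            assert not r.active_at(a.admit_ts + timedelta(hours=24))
        assert t.misselected == (t.registered_sub_indication != t.true_sub_indication)


def test_inject_misselection_rate_zero_is_identity(guideline):
    _, recs, truth = generate_cohort(SimConfig(n_patients=100, seed=4, misselection_rate=0.0), guideline)
    out, truth2 = inject_misselection(recs, truth, rate=0.0, confusion=DEFAULT_CONFUSION, seed=1)
    assert out == recs
    assert all(not t.misselected for t in truth2.records.values())


def test_inject_misselection_degenerate_rate_one(guideline):
    cfg = SimConfig(n_patients=200, seed=5, misselection_rate=0.0)
    _, recs, truth = generate_cohort(cfg, guideline)
    confusion = {"complicated-UTI": {"cystitis": 1.0}}
    out, truth2 = inject_misselection(recs, truth, rate=1.0, confusion=confusion, seed=2)
    originals = [r for r in recs if r.sub_indication == "complicated-UTI"]
    assert originals  # the mix plants some complicated UTIs
    for r in out:
        assert r.sub_indication != "complicated-UTI"
    flipped = [t for t in truth2.records.values() if t.true_sub_indication == "complicated-UTI"]
    assert flipped and all(
        t.misselected and t.registered_sub_indication == "cystitis" for t in flipped
    )


def test_inject_misselection_mean_count(guideline):
    """Rate 0.218 over the planted RTI/UTI records: the mean mis-selected
    count over repeated injections approaches rate * n."""
    cfg = SimConfig(n_patients=220, seed=6, misselection_rate=0.0)
    _, recs, truth = generate_cohort(cfg, guideline)
    n_rti_uti = sum(1 for r in recs if r.focus_tract in (Tract.RTI, Tract.UTI))
    rate, n_rounds = 0.218, 120
    total = 0
    for seed in range(n_rounds):
        _, t2 = inject_misselection(recs, truth, rate, DEFAULT_CONFUSION, seed=seed)
        total += sum(1 for t in t2.records.values() if t.misselected)
    mean = total / n_rounds
    expected = rate * n_rti_uti
    se = np.sqrt(n_rti_uti * rate * (1 - rate) / n_rounds)
    assert abs(mean - expected) < 4 * se


def test_invalid_confusion_row_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(n_patients=1, confusion={"cystitis": {"complicated-UTI": 0.4}})


def test_infeasible_discordant_pool_rejected(guideline, tmp_path):
    from stewardaudit.io import read_guideline_table
    from stewardaudit.simulate import ATC_NAMES

    # a guideline recommending *every* agent leaves no discordant pool
    agents = "\n".join(f"    - [{a}]" for a in sorted(ATC_NAMES))
    path = tmp_path / "g.yaml"
    path.write_text(f"cystitis:\n  first_choice:\n{agents}\n")
    table = read_guideline_table(path)
    with pytest.raises(SimulationError):
        generate_cohort(SimConfig(n_patients=1, seed=0), table)


def test_reviews_from_truth_reflect_registration(guideline):
    cfg = SimConfig(n_patients=300, seed=8)
    _, recs, truth = generate_cohort(cfg, guideline)
    reviews = {rv.record_id: rv for rv in reviews_from_truth(recs, truth)}
    assert len(reviews) == len(recs)
    for r in recs:
        rv = reviews[r.record_id]
        t = truth.records[r.record_id]
        if r.focus_tract in (Tract.RTI, Tract.UTI):
            assert rv.selected_indication == r.sub_indication
            assert (rv.selected_indication != rv.documented_indication) == t.misselected
        else:
            assert rv.stratum.value == "random_other"
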