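"""Synthetic EMR extract generator with planted ground truth.

Hospital prescription-indication data cannot be shared, so every
pipeline stage is exercised on synthetic extracts instead. The generator
emulates the audit's input: an admissions table and a prescription
extract with registered indications, plus a ground-truth table recording,
per prescription, the true sub-indication, the (possibly mis-selected)
registered one, the planted adherence category and the exclusion the
pipeline is expected to apply.

Anomalies are planted disjointly so every flowchart count has a single
ground-truth attribution:

* admission-level — underage, ICU stay, <12 h stay, 30-day readmission;
* record-level (on otherwise clean RTI/UTI admissions) — start date
  before admission ("erroneous"), simultaneous RTI+UTI registration,
  orders not active at the 24 h snapshot;
* registration-level — sub-indication mis-selection driven by a
  confusion matrix (dominant mass on registering cystitis when a
  complicated UTI is documented, the error pattern chart reviews find
  most often), and whole-tract misses (a true RTI/UTI registered under
  another focus).

A single seeded generator with a fixed draw order makes runs
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .model import (
    DEFAULT_TAXONOMY,
    Admission,
    ChartReviewRecord,
    GuidelineTable,
    IndicationClass,
    IndicationTaxonomy,
    NON_RTI_UTI,
    PrescriptionRecord,
    ReviewStratum,
    Route,
    Tract,
    WardType,
)

ATC_NAMES = {
    "J01CA04": "amoxicillin",
    "J01CR02": "amoxicillin-clavulanic acid",
    "J01DD04": "ceftriaxone",
    "J01DC02": "cefuroxime",
    "J01MA02": "ciprofloxacin",
    "J01MA14": "moxifloxacin",
    "J01XE01": "nitrofurantoin",
    "J01XX01": "fosfomycin",
    "J01EA01": "trimethoprim",
    "J01AA02": "doxycycline",
    "J01CE01": "benzylpenicillin",
    "J01FA01": "erythromycin",
    "J01GB03": "gentamicin",
    "J01XD01": "metronidazole",
}

#: Default sub-indication confusion: row code -> {registered code: prob}.
#: Rows sum to 1 and stay within tract; the dominant mass mirrors the
#: classic chart-review finding of cystitis selected for a documented
#: complicated UTI.
DEFAULT_CONFUSION: dict[str, dict[str, float]] = {
    "CAP": {"bronchitis": 0.5, "COPD": 0.5},
    "CAP-m": {"COPD": 0.6, "HAP": 0.4},
    "CAP-s": {"CAP-m": 1.0},
    "HAP": {"other-RTI": 0.6, "CAP-m": 0.4},
    "COPD": {"CAP-m": 1.0},
    "aspiration-pneumonia": {"CAP-s": 1.0},
    "bronchitis": {"COPD": 1.0},
    "other-RTI": {"bronchitis": 1.0},
    "complicated-UTI": {"cystitis": 1.0},
    "cystitis": {"complicated-UTI": 1.0},
    "chronic-prostatitis": {"complicated-UTI": 0.5, "other-UTI": 0.5},
    "other-UTI": {"cystitis": 1.0},
}


class SimConfig(BaseModel):
    """Study conditions for one synthetic hospital.

    Fractions are probabilities per admission unless noted. Defaults give a
    mid-sized general hospital: ~30% of prescriptions registered under
    RTI/UTI, half of regimens guideline-adherent, a 10% sub-indication
    mis-selection rate, and a few percent of each data anomaly.
    """

    n_patients: int = Field(ge=0)
    seed: int = 0
    hospital: str = "SIM"
    study_start: date = date(2019, 1, 1)
    study_days: int = 365

    # admission mix
    extra_admission_fraction: float = 0.03  # benign 2nd admission >30 d later
    underage_fraction: float = 0.02
    icu_fraction: float = 0.05
    short_stay_fraction: float = 0.04  # stay < 12 h
    readmission_fraction: float = 0.05  # planted 2nd admission within 30 d
    boundary_stay_fraction: float = 0.08  # 12-24 h stays (discharge branch)

    # episode mix
    p_rti: float = 0.18
    p_uti: float = 0.12
    p_targeted: float = 0.05  # among RTI/UTI episodes
    p_prophylaxis: float = 0.05  # among RTI/UTI episodes
    rti_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "CAP": 0.05,
            "CAP-m": 0.28,
            "CAP-s": 0.14,
            "HAP": 0.12,
            "COPD": 0.18,
            "aspiration-pneumonia": 0.05,
            "bronchitis": 0.12,
            "other-RTI": 0.06,
        }
    )
    uti_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "cystitis": 0.30,
            "complicated-UTI": 0.50,
            "chronic-prostatitis": 0.05,
            "other-UTI": 0.15,
        }
    )

    # therapy
    adherent_fraction: float = 0.5
    p_first_choice_given_adherent: float = 0.6
    discordant_combination_fraction: float = 0.15
    extra_order_fraction: float = 0.10  # order not active at the snapshot

    # registration errors
    misselection_rate: float = 0.10
    confusion: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONFUSION.items()}
    )
    missed_registration_fraction: float = 0.01  # true RTI/UTI filed under another focus

    # record-level anomalies (on clean RTI/UTI admissions)
    erroneous_start_fraction: float = 0.04
    dual_tract_fraction: float = 0.03

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for name in (
            "extra_admission_fraction",
            "underage_fraction",
            "icu_fraction",
            "short_stay_fraction",
            "readmission_fraction",
            "boundary_stay_fraction",
            "p_rti",
            "p_uti",
            "p_targeted",
            "p_prophylaxis",
            "adherent_fraction",
            "p_first_choice_given_adherent",
            "discordant_combination_fraction",
            "extra_order_fraction",
            "misselection_rate",
            "missed_registration_fraction",
            "erroneous_start_fraction",
            "dual_tract_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for label, mix in (("rti_mix", self.rti_mix), ("uti_mix", self.uti_mix)):
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} must sum to 1")
        for code, row in self.confusion.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"confusion row {code!r} must sum to 1")
        if (
            self.underage_fraction
            + self.icu_fraction
            + self.short_stay_fraction
            + self.readmission_fraction
        ) > 1.0:
            raise ValueError("admission anomaly fractions exceed 1")
        if self.p_rti + self.p_uti > 1.0:
            raise ValueError("p_rti + p_uti exceeds 1")
        if self.erroneous_start_fraction + self.dual_tract_fraction > 1.0:
            raise ValueError("record anomaly fractions exceed 1")
        return self


@dataclass
class TruthRecord:
    """Ground truth for one generated prescription."""

    record_id: str
    admission_id: str
    true_sub_indication: Optional[str]
    registered_sub_indication: Optional[str]
    misselected: bool
    planted_category: Optional[str]  # A / B / C / NOT_ASSESSED / None
    exclusion_reason: Optional[str]  # pipeline stage expected to drop it


@dataclass
class GroundTruth:
    config: SimConfig
    records: dict[str, TruthRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "record_id": t.record_id,
                    "admission_id": t.admission_id,
                    "true_sub_indication": t.true_sub_indication or "",
                    "registered_sub_indication": t.registered_sub_indication or "",
                    "misselected": t.misselected,
                    "planted_category": t.planted_category or "",
                    "exclusion_reason": t.exclusion_reason or "",
                }
                for t in self.records.values()
            ]
        )

    def planted_exclusion_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.records.values():
            if t.exclusion_reason:
                out[t.exclusion_reason] = out.get(t.exclusion_reason, 0) + 1
        return out


class SimulationError(ValueError):
    """Raised for infeasible configurations."""


def _categorical(rng: np.random.Generator, table: dict[str, float]) -> str:
    keys = sorted(table)
    p = np.array([table[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _draw_confused(rng: np.random.Generator, code: str, confusion: dict[str, dict[str, float]]) -> str:
    row = confusion.get(code)
    if not row:
        return code
    return _categorical(rng, row)


def generate_cohort(
    config: SimConfig,
    guideline: GuidelineTable,
    taxonomy: IndicationTaxonomy = DEFAULT_TAXONOMY,
) -> tuple[list[Admission], list[PrescriptionRecord], GroundTruth]:
    """Generate one hospital's admissions, extract and ground truth.

    Each admission carries one infection episode. For RTI/UTI episodes the
    true sub-indication is drawn from the tract mix, the registered one may
    be mis-selected via the confusion matrix, and the prescribed agents are
    drawn from the guideline entry of the *registered* sub-indication:
    adherent with probability ``adherent_fraction`` (first vs second choice
    per ``p_first_choice_given_adherent``), otherwise from the discordant
    pool (agents the entry does not recommend).
    """
    rng = np.random.default_rng(config.seed)
    pool_all = sorted(ATC_NAMES)
    discordant_pools: dict[str, list[str]] = {}
    for code, entry in guideline.entries.items():
        recommended: set[str] = set()
        for reg in entry.first_choice + entry.second_choice:
            recommended |= set(reg.agents)
        pool = [a for a in pool_all if a not in recommended]
        if entry.assessable and not pool:
            raise SimulationError(f"no discordant agents available for {code!r}")
        discordant_pools[code] = pool

    admissions: list[Admission] = []
    records: list[PrescriptionRecord] = []
    truth: dict[str, TruthRecord] = {}
    counters = {"admission": 0, "record": 0}

    def new_admission_id() -> str:
        counters["admission"] += 1
        return f"A{counters['admission']:06d}"

    def new_record_id() -> str:
        counters["record"] += 1
        return f"R{counters['record']:06d}"

    for p in range(config.n_patients):
        patient_id = f"P{p + 1:06d}"
        anomaly = _categorical(
            rng,
            {
                "none": 1.0
                - config.underage_fraction
                - config.icu_fraction
                - config.short_stay_fraction
                - config.readmission_fraction,
                "underage": config.underage_fraction,
                "icu": config.icu_fraction,
                "short_stay": config.short_stay_fraction,
                "readmission": config.readmission_fraction,
            },
        )
        admit = datetime.combine(config.study_start, datetime.min.time()) + timedelta(
            days=float(rng.uniform(0, config.study_days)), hours=float(rng.uniform(0, 24))
        )
        age = int(rng.integers(1, 18)) if anomaly == "underage" else int(rng.integers(18, 96))
        ward = WardType.icu if anomaly == "icu" else WardType.general
        if anomaly == "short_stay":
            los_h = float(rng.uniform(2.0, 11.5))
        elif anomaly == "none" and rng.random() < config.boundary_stay_fraction:
            los_h = float(rng.uniform(13.0, 23.0))
        else:
            los_h = max(26.0, float(np.exp(rng.normal(np.log(96.0), 0.5))))
        adm = Admission(
            patient_id=patient_id,
            admission_id=new_admission_id(),
            admit_ts=admit,
            discharge_ts=admit + timedelta(hours=los_h),
            age_years=age,
            ward_type=ward,
        )
        admissions.append(adm)
        adm_reason = {"underage": "age", "icu": "ward", "short_stay": "stay"}.get(anomaly)
        _plant_episode(
            rng, config, guideline, taxonomy, discordant_pools, adm, adm_reason,
            allow_record_anomalies=(anomaly == "none"),
            records=records, truth=truth, new_record_id=new_record_id,
        )

        follow_up = None
        if anomaly == "readmission":
            follow_up = ("readmission", float(rng.uniform(1.0, 29.0)))
        elif anomaly == "none" and rng.random() < config.extra_admission_fraction:
            follow_up = (None, float(rng.uniform(45.0, 90.0)))
        if follow_up is not None:
            reason, gap_days = follow_up
            admit2 = adm.discharge_ts + timedelta(days=gap_days)
            los2 = max(26.0, float(np.exp(rng.normal(np.log(96.0), 0.5))))
            adm2 = Admission(
                patient_id=patient_id,
                admission_id=new_admission_id(),
                admit_ts=admit2,
                discharge_ts=admit2 + timedelta(hours=los2),
                age_years=age,
                ward_type=WardType.general,
            )
            admissions.append(adm2)
            _plant_episode(
                rng, config, guideline, taxonomy, discordant_pools, adm2, reason,
                allow_record_anomalies=(reason is None),
                records=records, truth=truth, new_record_id=new_record_id,
            )

    return admissions, records, GroundTruth(config=config, records=truth)


def _plant_episode(
    rng: np.random.Generator,
    config: SimConfig,
    guideline: GuidelineTable,
    taxonomy: IndicationTaxonomy,
    discordant_pools: dict[str, list[str]],
    adm: Admission,
    adm_reason: Optional[str],
    allow_record_anomalies: bool,
    records: list[PrescriptionRecord],
    truth: dict[str, TruthRecord],
    new_record_id,
) -> None:
    boundary = adm.stay_hours < 24.0
    tract = _categorical(
        rng,
        {
            "RTI": config.p_rti,
            "UTI": config.p_uti,
            "other": 1.0 - config.p_rti - config.p_uti,
        },
    )

    def emit(
        *,
        atc: str,
        route: Route,
        start: datetime,
        stop: Optional[datetime],
        klass: IndicationClass,
        focus: Tract,
        registered_sub: Optional[str],
        true_sub: Optional[str],
        category: Optional[str],
        reason: Optional[str],
    ) -> None:
        rid = new_record_id()
        records.append(
            PrescriptionRecord(
                record_id=rid,
                patient_id=adm.patient_id,
                admission_id=adm.admission_id,
                atc_code=atc,
                agent_name=ATC_NAMES.get(atc, atc),
                start_ts=start,
                stop_ts=stop,
                route=route,
                dose_text="",
                prescriber_specialty="internal medicine",
                ward=adm.ward_type.value,
                indication_class=klass,
                focus_tract=focus,
                sub_indication=registered_sub,
            )
        )
        truth[rid] = TruthRecord(
            record_id=rid,
            admission_id=adm.admission_id,
            true_sub_indication=true_sub,
            registered_sub_indication=registered_sub,
            misselected=bool(true_sub != registered_sub),
            planted_category=category,
            exclusion_reason=reason,
        )

    def episode_start() -> datetime:
        if boundary:
            return adm.admit_ts + timedelta(hours=float(rng.uniform(1.0, max(1.5, adm.stay_hours - 2.0))))
        return adm.admit_ts + timedelta(hours=float(rng.uniform(1.0, 6.0)))

    if tract == "other":
        atc = str(rng.choice(sorted(ATC_NAMES)))
        start = episode_start()
        emit(
            atc=atc,
            route=Route.iv if rng.random() < 0.6 else Route.oral,
            start=start,
            stop=start + timedelta(hours=float(rng.uniform(48.0, 120.0))),
            klass=IndicationClass(
                _categorical(rng, {"empiric": 0.5, "targeted": 0.3, "prophylaxis": 0.2})
            ),
            focus=Tract.other,
            registered_sub=None,
            true_sub=None,
            category=None,
            reason="non_rti_uti",
        )
        return

    tract_enum = Tract(tract)
    mix = config.rti_mix if tract_enum is Tract.RTI else config.uti_mix
    true_sub = _categorical(rng, mix)

    # whole-tract miss: a true RTI/UTI episode registered under another focus
    if rng.random() < config.missed_registration_fraction:
        atc = str(rng.choice(sorted(ATC_NAMES)))
        start = episode_start()
        emit(
            atc=atc,
            route=Route.iv,
            start=start,
            stop=start + timedelta(hours=float(rng.uniform(48.0, 120.0))),
            klass=IndicationClass.empiric,
            focus=Tract.other,
            registered_sub=None,
            true_sub=true_sub,
            category=None,
            reason="non_rti_uti",
        )
        return

    registered_sub = true_sub
    if rng.random() < config.misselection_rate:
        registered_sub = _draw_confused(rng, true_sub, config.confusion)
    # the registered focus tract follows the registered sub-indication
    registered_tract = taxonomy.tract_of(registered_sub) or tract_enum

    klass = IndicationClass(
        _categorical(
            rng,
            {
                "empiric": 1.0 - config.p_targeted - config.p_prophylaxis,
                "targeted": config.p_targeted,
                "prophylaxis": config.p_prophylaxis,
            },
        )
    )

    record_anomaly = "none"
    if allow_record_anomalies and klass is not IndicationClass.prophylaxis and not boundary:
        record_anomaly = _categorical(
            rng,
            {
                "none": 1.0 - config.erroneous_start_fraction - config.dual_tract_fraction,
                "erroneous": config.erroneous_start_fraction,
                "dual_tract": config.dual_tract_fraction,
            },
        )

    # precedence mirrors the selection pipeline's fixed attribution order
    if klass is IndicationClass.prophylaxis:
        reason = "indication_class"
    elif adm_reason is not None:
        reason = adm_reason
    elif record_anomaly == "erroneous":
        reason = "erroneous"
    elif record_anomaly == "dual_tract":
        reason = "dual_tract"
    else:
        reason = None

    entry = guideline.entry(registered_sub)
    agents: list[tuple[str, Route]]
    if not entry.assessable:
        category = "NOT_ASSESSED"
        agents = [(str(rng.choice(sorted(ATC_NAMES))), Route.iv)]
    elif rng.random() < config.adherent_fraction:
        use_first = rng.random() < config.p_first_choice_given_adherent
        choices = entry.first_choice if (use_first or not entry.second_choice) else entry.second_choice
        if choices is entry.first_choice and not choices:
            choices = entry.second_choice
        category = "A" if choices is entry.first_choice else "B"
        rec = choices[int(rng.integers(0, len(choices)))]
        agents = []
        for atc in sorted(rec.agents):
            route = rec.route_constraint.get(atc)
            if route is None:
                route = Route.iv if rng.random() < 0.7 else Route.oral
            agents.append((atc, route))
    else:
        category = "C"
        pool = discordant_pools[registered_sub]
        k = 2 if (len(pool) > 1 and rng.random() < config.discordant_combination_fraction) else 1
        picked = rng.choice(len(pool), size=k, replace=False)
        agents = [(pool[int(i)], Route.iv if rng.random() < 0.7 else Route.oral) for i in picked]

    if record_anomaly == "erroneous":
        start = adm.admit_ts - timedelta(hours=float(rng.uniform(1.0, 12.0)))
    else:
        start = episode_start()
    stop = start + timedelta(hours=float(rng.uniform(48.0, 120.0)))
    for atc, route in agents:
        emit(
            atc=atc,
            route=route,
            start=start,
            stop=stop,
            klass=klass,
            focus=registered_tract,
            registered_sub=registered_sub,
            true_sub=true_sub,
            category=category,
            reason=reason,
        )

    if record_anomaly == "dual_tract":
        other_tract = Tract.UTI if registered_tract is Tract.RTI else Tract.RTI
        other_mix = config.uti_mix if other_tract is Tract.UTI else config.rti_mix
        other_true = _categorical(rng, other_mix)
        other_registered = other_true
        if rng.random() < config.misselection_rate:
            other_registered = _draw_confused(rng, other_true, config.confusion)
        emit(
            atc=str(rng.choice(sorted(ATC_NAMES))),
            route=Route.iv,
            start=start,
            stop=stop,
            klass=IndicationClass.empiric,
            focus=taxonomy.tract_of(other_registered) or other_tract,
            registered_sub=other_registered,
            true_sub=other_true,
            category=None,
            reason="dual_tract",
        )

    # an order not active at the snapshot (starts after hour 24)
    if (
        not boundary
        and reason is None
        and record_anomaly == "none"
        and rng.random() < config.extra_order_fraction
    ):
        xstart = adm.admit_ts + timedelta(hours=float(rng.uniform(26.0, 48.0)))
        emit(
            atc=str(rng.choice(sorted(ATC_NAMES))),
            route=Route.iv,
            start=xstart,
            stop=xstart + timedelta(hours=48.0),
            klass=IndicationClass.empiric,
            focus=registered_tract,
            registered_sub=registered_sub,
            true_sub=true_sub,
            category=None,
            reason="not_empiric",
        )


def inject_misselection(
    records: Sequence[PrescriptionRecord],
    truth: GroundTruth,
    rate: float,
    confusion: dict[str, dict[str, float]],
    seed: int,
) -> tuple[list[PrescriptionRecord], GroundTruth]:
    """Independently mis-select each RTI/UTI prescription with probability ``rate``.

    The replacement is drawn from the record's confusion row; truth is
    updated consistently (``misselected`` compares against the *true*
    sub-indication, so re-labelling back to the truth clears the flag).
    Returns new record objects; inputs are not mutated.
    """
    for code, row in confusion.items():
        if abs(sum(row.values()) - 1.0) > 1e-9:
            raise SimulationError(f"confusion row {code!r} must sum to 1")
    rng = np.random.default_rng(seed)
    out: list[PrescriptionRecord] = []
    new_truth = {rid: TruthRecord(**vars(t)) for rid, t in truth.records.items()}
    for r in records:
        if r.focus_tract in (Tract.RTI, Tract.UTI) and rng.random() < rate:
            new_sub = _draw_confused(rng, r.sub_indication, confusion)
            r = r.model_copy(update={"sub_indication": new_sub})
            t = new_truth.get(r.record_id)
            if t is not None:
                t.registered_sub_indication = new_sub
                t.misselected = bool(new_sub != t.true_sub_indication)
        out.append(r)
    return out, GroundTruth(config=truth.config, records=new_truth)


def reviews_from_truth(
    records: Sequence[PrescriptionRecord],
    truth: GroundTruth,
    record_ids: Optional[Sequence[str]] = None,
) -> list[ChartReviewRecord]:
    """Build the chart-review table a perfect reviewer would produce.

    The selected indication is what the extract registered; the documented
    indication is the planted truth. Restrict to ``record_ids`` to score a
    drawn validation sample.
    """
    wanted = set(record_ids) if record_ids is not None else None
    reviews: list[ChartReviewRecord] = []
    for r in records:
        if wanted is not None and r.record_id not in wanted:
            continue
        t = truth.records[r.record_id]
        if r.focus_tract is Tract.RTI:
            stratum = ReviewStratum.RTI
        elif r.focus_tract is Tract.UTI:
            stratum = ReviewStratum.UTI
        else:
            stratum = ReviewStratum.random_other
        reviews.append(
            ChartReviewRecord(
                record_id=r.record_id,
                stratum=stratum,
                selected_indication=r.sub_indication or NON_RTI_UTI,
                documented_indication=t.true_sub_indication or NON_RTI_UTI,
            )
        )
    return reviews


def demo_hospital_configs(seed: int = 0, scale: float = 1.0) -> dict[str, SimConfig]:
    """Three hospital configurations with the qualitative shape of a
    multi-centre audit: a large mature site with accurate registration
    (A), a small site with heavy cystitis/complicated-UTI confusion (B)
    and a mid-sized site in between (C). Sizes are scaled-down by default;
    pass ``scale`` to grow them."""
    heavy_uti = {k: dict(v) for k, v in DEFAULT_CONFUSION.items()}
    return {
        "A": SimConfig(
            n_patients=int(1200 * scale),
            seed=seed,
            hospital="A",
            misselection_rate=0.033,
            adherent_fraction=0.55,
        ),
        "B": SimConfig(
            n_patients=int(250 * scale),
            seed=seed + 1,
            hospital="B",
            misselection_rate=0.218,
            confusion=heavy_uti,
            adherent_fraction=0.35,
            uti_mix={"cystitis": 0.25, "complicated-UTI": 0.55, "chronic-prostatitis": 0.05, "other-UTI": 0.15},
        ),
        "C": SimConfig(
            n_patients=int(900 * scale),
            seed=seed + 2,
            hospital="C",
            misselection_rate=0.131,
            adherent_fraction=0.45,
        ),
    }
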