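"""Reading, validating and writing the audit tables.

Four flat inputs drive an audit: the prescription extract (one row per
J01 order), the admissions table, the guideline table (YAML/JSON) and the
chart-review table. Extracts differ between EMR vendors, so reading goes
through a :class:`ColumnMap` that renames columns and translates local
enum spellings; rows that still fail to parse are returned as rejects
with reasons, never dropped.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from pydantic import ValidationError

from .model import (
    Admission,
    ChartReviewRecord,
    GuidelineEntry,
    GuidelineTable,
    IndicationTaxonomy,
    PrescriptionRecord,
    RecommendedRegimen,
    Route,
    Tract,
)

PRESCRIPTION_COLUMNS = [
    "record_id",
    "patient_id",
    "admission_id",
    "atc_code",
    "agent_name",
    "start_ts",
    "stop_ts",
    "route",
    "dose_text",
    "prescriber_specialty",
    "ward",
    "indication_class",
    "focus_tract",
    "sub_indication",
]
MANDATORY_PRESCRIPTION_COLUMNS = [
    "record_id",
    "patient_id",
    "admission_id",
    "atc_code",
    "start_ts",
    "indication_class",
    "focus_tract",
]
ADMISSION_COLUMNS = [
    "patient_id",
    "admission_id",
    "admit_ts",
    "discharge_ts",
    "age_years",
    "ward_type",
]


class SchemaError(ValueError):
    """A structural problem with an input file (missing column, bad config)."""


@dataclass
class ColumnMap:
    """Per-hospital mapping from source columns to the canonical schema.

    ``columns`` maps source column name -> canonical field name; omitted
    when the file already uses canonical headers. ``values`` maps a
    canonical field to a translation table for local spellings (e.g.
    Dutch ``profylaxe`` -> ``prophylaxis``).
    """

    columns: dict[str, str] = field(default_factory=dict)
    values: dict[str, dict[str, str]] = field(default_factory=dict)

    def rename(self, df: pd.DataFrame) -> pd.DataFrame:
        return df.rename(columns=self.columns) if self.columns else df

    def translate(self, fieldname: str, value: str) -> str:
        table = self.values.get(fieldname)
        if table and value in table:
            return table[value]
        return value


@dataclass
class RejectedRow:
    """An input row that failed parsing, kept for the audit trail."""

    row_number: int  # 1-based data-row index
    reason: str
    raw: dict[str, str]


def _sniff_delimiter(path: Path) -> str:
    header = Path(path).open("r", encoding="utf-8").readline()
    return ";" if header.count(";") > header.count(",") else ","


def _parse_ts(value: str) -> datetime:
    ts = pd.Timestamp(value)
    if ts.tzinfo is not None:
        ts = ts.tz_localize(None)
    return ts.to_pydatetime()


def read_prescription_extract(
    path: str | Path,
    column_map: ColumnMap | None = None,
) -> tuple[list[PrescriptionRecord], list[RejectedRow]]:
    """Read a prescription extract into records plus a reject list.

    Timestamps are parsed to a timezone-naive timeline. Every data row ends
    up in exactly one of the two return lists:
    ``len(records) + len(rejects) == n_rows``.

    Raises :class:`SchemaError` if a mandatory column is absent after
    applying ``column_map``.
    """
    path = Path(path)
    cmap = column_map or ColumnMap()
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, keep_default_na=False)
    df = cmap.rename(df)
    missing = [c for c in MANDATORY_PRESCRIPTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"extract {path} is missing mandatory column(s): {missing}")

    records: list[PrescriptionRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        raw = {k: v for k, v in row.items() if k in PRESCRIPTION_COLUMNS}
        try:
            records.append(_parse_prescription_row(raw, cmap))
        except _RowError as exc:
            rejects.append(RejectedRow(row_number=i, reason=exc.reason, raw=raw))
    return records, rejects


class _RowError(Exception):
    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def _parse_prescription_row(raw: dict[str, str], cmap: ColumnMap) -> PrescriptionRecord:
    get = lambda k: cmap.translate(k, str(raw.get(k, "") or "").strip())
    try:
        start_ts = _parse_ts(get("start_ts"))
    except (ValueError, TypeError):
        raise _RowError("timestamp")
    stop_raw = get("stop_ts")
    stop_ts: Optional[datetime] = None
    if stop_raw:
        try:
            stop_ts = _parse_ts(stop_raw)
        except (ValueError, TypeError):
            raise _RowError("timestamp")
    try:
        return PrescriptionRecord(
            record_id=get("record_id"),
            patient_id=get("patient_id"),
            admission_id=get("admission_id"),
            atc_code=get("atc_code"),
            agent_name=get("agent_name"),
            start_ts=start_ts,
            stop_ts=stop_ts,
            route=get("route") or "other",
            dose_text=get("dose_text"),
            prescriber_specialty=get("prescriber_specialty"),
            ward=get("ward"),
            indication_class=get("indication_class"),
            focus_tract=get("focus_tract"),
            sub_indication=get("sub_indication") or None,
        )
    except ValidationError as exc:
        fields = sorted({str(e["loc"][0]) if e["loc"] else "record" for e in exc.errors()})
        raise _RowError(",".join(fields))


def write_prescription_extract(
    records: Iterable[PrescriptionRecord], path: str | Path, sep: str = ","
) -> None:
    """Write records in the canonical extract layout (round-trips with the reader)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=PRESCRIPTION_COLUMNS, delimiter=sep)
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "record_id": r.record_id,
                    "patient_id": r.patient_id,
                    "admission_id": r.admission_id,
                    "atc_code": r.atc_code,
                    "agent_name": r.agent_name,
                    "start_ts": r.start_ts.isoformat(),
                    "stop_ts": r.stop_ts.isoformat() if r.stop_ts else "",
                    "route": r.route.value,
                    "dose_text": r.dose_text,
                    "prescriber_specialty": r.prescriber_specialty,
                    "ward": r.ward,
                    "indication_class": r.indication_class.value,
                    "focus_tract": r.focus_tract.value,
                    "sub_indication": r.sub_indication or "",
                }
            )


def write_rejects(rejects: Iterable[RejectedRow], path: str | Path) -> None:
    """Emit rejected rows to a side file so the audit stays lossless."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_number", "reason", "raw_json"])
        for rej in rejects:
            writer.writerow([rej.row_number, rej.reason, json.dumps(rej.raw)])


def read_admissions(
    path: str | Path, column_map: ColumnMap | None = None
) -> tuple[list[Admission], list[RejectedRow]]:
    """Read the admissions table; same reject semantics as the extract reader."""
    path = Path(path)
    cmap = column_map or ColumnMap()
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, keep_default_na=False)
    df = cmap.rename(df)
    missing = [c for c in ADMISSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"admissions table {path} is missing column(s): {missing}")
    admissions: list[Admission] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        raw = {k: str(row.get(k, "")) for k in ADMISSION_COLUMNS}
        try:
            admissions.append(
                Admission(
                    patient_id=cmap.translate("patient_id", raw["patient_id"]),
                    admission_id=raw["admission_id"],
                    admit_ts=_parse_ts(raw["admit_ts"]),
                    discharge_ts=_parse_ts(raw["discharge_ts"]),
                    age_years=int(raw["age_years"]),
                    ward_type=cmap.translate("ward_type", raw["ward_type"]) or "other",
                )
            )
        except ValidationError as exc:
            fields = sorted({str(e["loc"][0]) if e["loc"] else "row" for e in exc.errors()})
            rejects.append(RejectedRow(row_number=i, reason=",".join(fields), raw=raw))
        except (ValueError, TypeError):
            rejects.append(RejectedRow(row_number=i, reason="timestamp", raw=raw))
    return admissions, rejects


def write_admissions(admissions: Iterable[Admission], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ADMISSION_COLUMNS)
        for a in admissions:
            writer.writerow(
                [
                    a.patient_id,
                    a.admission_id,
                    a.admit_ts.isoformat(),
                    a.discharge_ts.isoformat(),
                    a.age_years,
                    a.ward_type.value,
                ]
            )


# ---------------------------------------------------------------------------
# guideline table


def read_guideline_table(
    path: str | Path, taxonomy: IndicationTaxonomy | None = None
) -> GuidelineTable:
    """Load a guideline table from YAML or JSON.

    Layout: top-level mapping ``sub_indication -> {assessable, first_choice,
    second_choice, route_constraint}`` where each choice list holds regimens
    as lists of ATC codes. ``route_constraint`` maps ATC code -> route and
    applies to every regimen of that sub-indication containing the agent.

    Raises :class:`SchemaError` on an empty file, a regimen present in both
    choice lists, or a sub-indication code outside the taxonomy.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or not data:
        raise SchemaError(f"guideline table {path} is empty or not a mapping")
    kwargs = {"taxonomy": taxonomy} if taxonomy is not None else {}
    entries: dict[str, GuidelineEntry] = {}
    for code, spec in data.items():
        spec = spec or {}
        constraint = {
            atc: Route(route) for atc, route in (spec.get("route_constraint") or {}).items()
        }
        def _regimens(key: str) -> list[RecommendedRegimen]:
            out = []
            for agents in spec.get(key) or []:
                agents = frozenset(agents)
                out.append(
                    RecommendedRegimen(
                        agents=agents,
                        route_constraint={a: r for a, r in constraint.items() if a in agents},
                    )
                )
            return out

        try:
            entries[code] = GuidelineEntry(
                assessable=bool(spec.get("assessable", True)),
                first_choice=_regimens("first_choice"),
                second_choice=_regimens("second_choice"),
            )
        except ValidationError as exc:
            raise SchemaError(f"guideline entry {code!r}: {exc}") from exc
    try:
        return GuidelineTable(entries=entries, **kwargs)
    except ValidationError as exc:
        raise SchemaError(str(exc)) from exc


def write_guideline_table(table: GuidelineTable, path: str | Path) -> None:
    """Write a guideline table as YAML (round-trips with the reader)."""
    data: dict[str, dict] = {}
    for code, entry in table.entries.items():
        constraint: dict[str, str] = {}
        for reg in entry.first_choice + entry.second_choice:
            for atc, route in reg.route_constraint.items():
                constraint[atc] = route.value
        spec: dict = {
            "assessable": entry.assessable,
            "first_choice": [sorted(r.agents) for r in entry.first_choice],
            "second_choice": [sorted(r.agents) for r in entry.second_choice],
        }
        if constraint:
            spec["route_constraint"] = constraint
        data[code] = spec
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def packaged_guideline_path() -> Path:
    """Path of the packaged illustrative guideline fixture.

    The fixture is a synthetic stand-in sketching first/second-choice
    regimens per sub-indication; production audits must supply the current
    national (SWAB) table.
    """
    return Path(__file__).parent / "data" / "guideline_demo.yaml"


# ---------------------------------------------------------------------------
# chart reviews


def read_chart_reviews(path: str | Path) -> list[ChartReviewRecord]:
    df = pd.read_csv(Path(path), sep=_sniff_delimiter(Path(path)), dtype=str, keep_default_na=False)
    needed = ["record_id", "stratum", "selected_indication", "documented_indication"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"chart-review table {path} is missing column(s): {missing}")
    return [ChartReviewRecord(**{k: row[k] for k in needed}) for row in df.to_dict("records")]


def write_chart_reviews(reviews: Iterable[ChartReviewRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "stratum", "selected_indication", "documented_indication"])
        for r in reviews:
            writer.writerow(
                [r.record_id, r.stratum.value, r.selected_indication, r.documented_indication]
            )


# ---------------------------------------------------------------------------
# extract-level consistency report


@dataclass
class ExtractIssue:
    kind: str  # orphan_admission | stop_before_start | start_before_admission | non_J01
    record_id: str
    detail: str = ""


def validate_extract(
    records: list[PrescriptionRecord], admissions: list[Admission]
) -> list[ExtractIssue]:
    """General-inspection checks on an ingested extract.

    Flags orphan prescriptions (admission id absent from the admissions
    table), stop-before-start intervals, prescriptions starting before
    their admission (these feed the erroneous-prescription exclusion
    downstream; they are *not* removed here), and non-J01 ATC codes.
    """
    by_id = {a.admission_id: a for a in admissions}
    issues: list[ExtractIssue] = []
    for r in records:
        adm = by_id.get(r.admission_id)
        if adm is None:
            issues.append(ExtractIssue("orphan_admission", r.record_id, r.admission_id))
        if r.stop_ts is not None and r.stop_ts < r.start_ts:
            issues.append(ExtractIssue("stop_before_start", r.record_id))
        if adm is not None and r.start_ts < adm.admit_ts:
            issues.append(ExtractIssue("start_before_admission", r.record_id))
        if not r.atc_code.startswith("J01"):
            issues.append(ExtractIssue("non_J01", r.record_id, r.atc_code))
    return issues
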