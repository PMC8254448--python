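"""Merge simultaneous prescriptions into combination regimens.

Antibiotics prescribed simultaneously for the same registered
sub-indication constitute one combination therapy; the regimen — not the
individual order — is the unit of appropriateness assessment.
Simultaneity is already guaranteed upstream (all records in an empiric
selection are active at the same evaluation instant), so merging keys
only on (admission, sub-indication).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import PrescriptionRecord, Route


@dataclass(frozen=True)
class Regimen:
    """One admission's combination therapy for one sub-indication."""

    admission_id: str
    sub_indication: str
    agents: frozenset[tuple[str, Route]]  # (ATC code, route) pairs
    source_record_ids: tuple[str, ...]

    @property
    def atc_codes(self) -> frozenset[str]:
        return frozenset(atc for atc, _ in self.agents)


def assemble_regimens(records: Sequence[PrescriptionRecord]) -> list[Regimen]:
    """Group empiric records into one regimen per (admission, sub-indication).

    ``agents`` is the union of the records' (ATC, route) pairs; the same
    agent ordered twice by the same route collapses to one. Records lacking
    a sub-indication (non-RTI/UTI focus) are rejected — they should have
    been excluded upstream.
    """
    groups: dict[tuple[str, str], list[PrescriptionRecord]] = {}
    for r in records:
        if r.sub_indication is None:
            raise ValueError(
                f"record {r.record_id} has no sub-indication; regimens are "
                "assembled on RTI/UTI records only"
            )
        groups.setdefault((r.admission_id, r.sub_indication), []).append(r)
    regimens = []
    for (admission_id, sub), recs in groups.items():
        regimens.append(
            Regimen(
                admission_id=admission_id,
                sub_indication=sub,
                agents=frozenset((r.atc_code, r.route) for r in recs),
                source_record_ids=tuple(r.record_id for r in recs),
            )
        )
    return regimens
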