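"""Audit-ready outputs: flowchart tables, adherence figure data, bundles.

Rendering is pure presentation — every number is a pass-through from the
upstream computation, checked against the conservation invariants before
anything is written. Percentages are displayed at one decimal place;
emitted files keep full precision. A bundle directory carries a manifest
with content digests so re-runs are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .accuracy import AccuracyReport
from .classify import AdherenceReport
from .cohort import FlowchartCounts, SelectionParams


def render_flowchart(counts: FlowchartCounts) -> pd.DataFrame:
    """Flowchart counts as a table (stage, input, kept, excluded).

    Raises ``ValueError`` if any stage violates input = kept + excluded or
    consecutive stages fail to chain — an inconsistent flowchart is never
    rendered.
    """
    counts.check()
    return pd.DataFrame(
        [
            {
                "stage": st.label,
                "n_input": st.n_input,
                "n_kept": st.n_kept,
                "n_excluded": st.n_excluded,
            }
            for st in counts.stages
        ]
    )


def flowchart_json(counts: FlowchartCounts) -> str:
    counts.check()
    return json.dumps(
        [
            {"stage": s.label, "input": s.n_input, "kept": s.n_kept, "excluded": s.n_excluded}
            for s in counts.stages
        ],
        indent=2,
    )


#: colour roles of the stacked adherence figures
CATEGORY_ROLES = {"A": "green", "B": "yellow", "C": "red", "other": "grey"}


def render_adherence_figure_data(report: AdherenceReport) -> pd.DataFrame:
    """Data behind a stacked-proportion adherence figure.

    One block of rows per sub-indication: the A/B/C shares (green, yellow,
    red roles) followed by the agent-combination frequencies with
    below-threshold combinations pooled under the grey "other" role.
    Shares are pass-through from the classifier; nothing is re-computed.
    """
    rows = []
    for sub, s in report.summaries.items():
        for cat, share in (
            ("A", s.proportion_a),
            ("B", s.proportion_b),
            ("C", s.proportion_c),
        ):
            rows.append(
                {
                    "sub_indication": sub,
                    "kind": "category",
                    "label": cat,
                    "role": CATEGORY_ROLES[cat],
                    "share": share,
                    "n_regimens": s.n_regimens,
                }
            )
        for label, freq in s.combination_frequencies:
            rows.append(
                {
                    "sub_indication": sub,
                    "kind": "combination",
                    "label": label,
                    "role": CATEGORY_ROLES["other"] if label == "other" else "",
                    "share": freq,
                    "n_regimens": s.n_regimens,
                }
            )
    return pd.DataFrame(
        rows, columns=["sub_indication", "kind", "label", "role", "share", "n_regimens"]
    )


def accuracy_table(report: AccuracyReport) -> pd.DataFrame:
    """Per-stratum and pooled agreement table (percentages at full precision)."""
    rows = []
    for stratum, s in report.strata.items():
        rows.append(
            {
                "stratum": stratum.value,
                "n_screened": s.n_screened,
                "n_unassessable": s.n_unassessable,
                "n_errors": s.n_errors,
                "error_rate_pct": s.error_rate_pct,
                "agreement_pct": s.agreement_pct,
            }
        )
    rows.append(
        {
            "stratum": "overall",
            "n_screened": sum(s.n_screened for s in report.strata.values()),
            "n_unassessable": sum(s.n_unassessable for s in report.strata.values()),
            "n_errors": report.n_errors,
            "error_rate_pct": report.error_rate_pct,
            "agreement_pct": report.agreement_pct,
        }
    )
    return pd.DataFrame(rows)


def fmt_pct(x: float) -> str:
    """Display convention: one decimal place (96.7%, 49.5%)."""
    return f"{x:.1f}"


@dataclass
class AuditBundle:
    """A directory of audit outputs plus a digest manifest."""

    out_dir: Path
    seed: Optional[int] = None
    params: Optional[SelectionParams] = None
    manifest: dict[str, str] = field(default_factory=dict)

    def add_table(self, name: str, df: pd.DataFrame) -> Path:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        path = self.out_dir / name
        df.to_csv(path, index=False)
        self.manifest[name] = _digest(path)
        return path

    def add_text(self, name: str, text: str) -> Path:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        path = self.out_dir / name
        path.write_text(text, encoding="utf-8")
        self.manifest[name] = _digest(path)
        return path

    def write_manifest(self) -> Path:
        meta = {
            "tool": "stewardaudit",
            "version": __version__,
            "seed": self.seed,
            "params_digest": _params_digest(self.params),
            "files": self.manifest,
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8")
        return path

    def verify(self) -> None:
        """Raise if any emitted file no longer matches its manifest digest."""
        for name, digest in self.manifest.items():
            actual = _digest(self.out_dir / name)
            if actual != digest:
                raise ValueError(f"digest mismatch for {name}: {actual} != {digest}")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _params_digest(params: Optional[SelectionParams]) -> Optional[str]:
    if params is None:
        return None
    payload = params.model_dump_json()
    return hashlib.sha256(payload.encode()).hexdigest()
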