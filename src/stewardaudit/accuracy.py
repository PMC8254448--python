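"""Chart-review validation of the registered indications.

Registered indications are only useful for stewardship surveillance if
they agree with what the chart documents. The workflow: draw a
stratified random sample of prescriptions (strata by *selected*
indication — RTI, UTI, and a random draw of everything else to catch
missed RTI/UTI), review each against the chart, then score agreement.

An error is any mismatch at sub-indication level: selecting cystitis
when the chart documents a complicated UTI counts as an error even
though both are urinary. Records whose chart gave no verdict
(unassessable) are removed from the denominator, not counted as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import (
    DEFAULT_TAXONOMY,
    ChartReviewRecord,
    IndicationTaxonomy,
    PrescriptionRecord,
    ReviewStratum,
    Tract,
    UNASSESSABLE,
)


@dataclass
class ValidationSample:
    """record ids drawn per stratum; ``census`` marks strata where the
    request met or exceeded the population, so the whole stratum was taken."""

    strata: dict[ReviewStratum, list[str]]
    census: set[ReviewStratum]


def stratum_of(record: PrescriptionRecord) -> ReviewStratum:
    if record.focus_tract == Tract.RTI:
        return ReviewStratum.RTI
    if record.focus_tract == Tract.UTI:
        return ReviewStratum.UTI
    return ReviewStratum.random_other


def draw_validation_sample(
    records: Sequence[PrescriptionRecord],
    strata_sizes: Mapping[ReviewStratum | str, int],
    seed: int,
) -> ValidationSample:
    """Sample record ids without replacement, uniformly within each stratum.

    Strata are determined by the *selected* indication tract. If a
    requested size meets or exceeds the stratum population, the entire
    stratum is returned and flagged as a census (the design used when one
    hospital had only 143 RTI/UTI records). Reproducible given ``seed``.
    """
    sizes: dict[ReviewStratum, int] = {}
    for key, n in strata_sizes.items():
        try:
            sizes[ReviewStratum(key)] = int(n)
        except ValueError:
            raise ValueError(f"unknown stratum label: {key!r}") from None
    frames: dict[ReviewStratum, list[str]] = {s: [] for s in sizes}
    for r in records:
        s = stratum_of(r)
        if s in frames:
            frames[s].append(r.record_id)
    rng = np.random.default_rng(seed)
    out: dict[ReviewStratum, list[str]] = {}
    census: set[ReviewStratum] = set()
    for stratum in sorted(sizes, key=lambda s: s.value):  # fixed draw order
        ids = sorted(frames[stratum])
        n = sizes[stratum]
        if n >= len(ids):
            out[stratum] = ids
            census.add(stratum)
        else:
            out[stratum] = [ids[i] for i in rng.choice(len(ids), size=n, replace=False)]
    return ValidationSample(strata=out, census=census)


@dataclass
class StratumAccuracy:
    stratum: ReviewStratum
    n_screened: int
    n_unassessable: int
    n_errors: int

    @property
    def n_assessed(self) -> int:
        return self.n_screened - self.n_unassessable

    @property
    def error_rate_pct(self) -> float:
        return 100.0 * self.n_errors / self.n_assessed if self.n_assessed else float("nan")

    @property
    def agreement_pct(self) -> float:
        return 100.0 - self.error_rate_pct


@dataclass
class AccuracyReport:
    """Agreement between selected and documented indications.

    ``confusion`` lists mismatches as (selected, documented, count) sorted
    by descending count; ``missed_target_count`` is the number of
    random-stratum records whose documented diagnosis was actually RTI/UTI
    — prescriptions the registration missed.
    """

    strata: dict[ReviewStratum, StratumAccuracy]
    confusion: list[tuple[str, str, int]]
    missed_target_count: int
    sampling_unit: str = "prescription record"

    @property
    def n_assessed(self) -> int:
        return sum(s.n_assessed for s in self.strata.values())

    @property
    def n_errors(self) -> int:
        return sum(s.n_errors for s in self.strata.values())

    @property
    def error_rate_pct(self) -> float:
        return 100.0 * self.n_errors / self.n_assessed if self.n_assessed else float("nan")

    @property
    def agreement_pct(self) -> float:
        return 100.0 - self.error_rate_pct


def compute_accuracy(
    reviews: Sequence[ChartReviewRecord],
    taxonomy: IndicationTaxonomy = DEFAULT_TAXONOMY,
) -> AccuracyReport:
    """Score a completed chart review.

    An error is ``selected_indication != documented_indication`` compared as
    exact sub-indication codes; agreement at tract level with a
    sub-indication mismatch still counts as an error. Unassessable records
    shrink the denominator. The overall rate pools error counts and
    assessable denominators across strata.
    """
    if not reviews:
        raise ValueError("empty chart review")
    per: dict[ReviewStratum, StratumAccuracy] = {}
    confusion: dict[tuple[str, str], int] = {}
    missed = 0
    for rec in reviews:
        acc = per.setdefault(
            rec.stratum, StratumAccuracy(rec.stratum, 0, 0, 0)
        )
        acc.n_screened += 1
        if rec.documented_indication == UNASSESSABLE:
            acc.n_unassessable += 1
            continue
        if rec.selected_indication != rec.documented_indication:
            acc.n_errors += 1
            key = (rec.selected_indication, rec.documented_indication)
            confusion[key] = confusion.get(key, 0) + 1
            if rec.stratum is ReviewStratum.random_other and taxonomy.tract_of(
                rec.documented_indication
            ) in (Tract.RTI, Tract.UTI):
                missed += 1
    ordered = sorted(confusion.items(), key=lambda kv: (-kv[1], kv[0]))
    return AccuracyReport(
        strata=per,
        confusion=[(sel, doc, n) for (sel, doc), n in ordered],
        missed_target_count=missed,
    )


@dataclass
class StratumTally:
    """Published summary of one review stratum: screened count, mismatch
    cross-tabulation and unassessable count — enough to reconstruct an
    equivalent record-level review for re-analysis."""

    n_screened: int
    mismatches: list[tuple[str, str, int]] = field(default_factory=list)
    n_unassessable: int = 0
    agree_code: str = "agree"


def reviews_from_tallies(
    tallies: Mapping[ReviewStratum | str, StratumTally],
) -> list[ChartReviewRecord]:
    """Expand stratum tallies into record-level chart reviews.

    Useful to re-score published validation tables: each mismatch pair
    becomes ``count`` discordant records, unassessable records get the
    unassessable marker, and the remainder agree. ``compute_accuracy`` on
    the result reproduces the tally's error rates.
    """
    reviews: list[ChartReviewRecord] = []
    i = 0
    for key, tally in tallies.items():
        stratum = ReviewStratum(key)
        n_err = sum(n for _, _, n in tally.mismatches)
        if n_err + tally.n_unassessable > tally.n_screened:
            raise ValueError(f"stratum {stratum.value}: tallies exceed screened count")
        for selected, documented, n in tally.mismatches:
            for _ in range(n):
                i += 1
                reviews.append(
                    ChartReviewRecord(
                        record_id=f"T{i:05d}",
                        stratum=stratum,
                        selected_indication=selected,
                        documented_indication=documented,
                    )
                )
        for _ in range(tally.n_unassessable):
            i += 1
            reviews.append(
                ChartReviewRecord(
                    record_id=f"T{i:05d}",
                    stratum=stratum,
                    selected_indication=tally.agree_code,
                    documented_indication=UNASSESSABLE,
                )
            )
        for _ in range(tally.n_screened - n_err - tally.n_unassessable):
            i += 1
            reviews.append(
                ChartReviewRecord(
                    record_id=f"T{i:05d}",
                    stratum=stratum,
                    selected_indication=tally.agree_code,
                    documented_indication=tally.agree_code,
                )
            )
    return reviews


def estimate_error_ci(
    n_errors: int, n_screened: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for an error proportion.

    Supports periodic re-validation: the interval tells how precisely a
    yearly sample of size ``n_screened`` pins down the registration error
    rate. Returns (lower, upper) on the proportion scale.
    """
    if n_screened <= 0 or not 0 <= n_errors <= n_screened:
        raise ValueError("need 0 <= n_errors <= n_screened and n_screened > 0")
    alpha = 1.0 - level
    lo = 0.0 if n_errors == 0 else stats.beta.ppf(alpha / 2, n_errors, n_screened - n_errors + 1)
    hi = (
        1.0
        if n_errors == n_screened
        else stats.beta.ppf(1 - alpha / 2, n_errors + 1, n_screened - n_errors)
    )
    return float(lo), float(hi)
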