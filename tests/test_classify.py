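"""A/B/C classification and adherence summaries."""

from __future__ import annotations

import numpy as np
import pytest

from stewardaudit.classify import (
    AdherenceCategory,
    adherence_summary,
    benchmark_table,
    classify_regimen,
)
from stewardaudit.model import Route
from stewardaudit.therapy import Regimen


def reg(sub, *agents, admission="A1"):
    return Regimen(
        admission_id=admission,
        sub_indication=sub,
        agents=frozenset(agents),
        source_record_ids=tuple(f"r{i}" for i in range(len(agents))),
    )


def test_cefuroxime_for_cystitis_is_discordant(guideline):
    r = reg("cystitis", ("J01DC02", Route.iv))
    assert classify_regimen(r, guideline) is AdherenceCategory.C


def test_ceftriaxone_for_complicated_uti_is_recommended(guideline):
    r = reg("complicated-UTI", ("J01DD04", Route.iv))
    assert classify_regimen(r, guideline) is not AdherenceCategory.C


def test_other_sub_indication_not_assessed(guideline):
    r = reg("other-RTI", ("J01CA04", Route.iv))
    assert classify_regimen(r, guideline) is AdherenceCategory.NOT_ASSESSED


def test_first_choice_match_is_A_never_B(guideline):
    r = reg("CAP-m", ("J01CA04", Route.iv))
    assert classify_regimen(r, guideline) is AdherenceCategory.A


def test_second_choice_match_is_B(guideline):
    r = reg("CAP-m", ("J01AA02", Route.oral))
    assert classify_regimen(r, guideline) is AdherenceCategory.B


def test_combination_first_choice_matches_as_set(guideline):
    r = reg("CAP-s", ("J01FA01", Route.iv), ("J01DD04", Route.iv))
    assert classify_regimen(r, guideline) is AdherenceCategory.A


def test_superset_of_recommendation_is_discordant(guideline):
    r = reg("CAP-m", ("J01CA04", Route.iv), ("J01GB03", Route.iv))
    assert classify_regimen(r, guideline) is AdherenceCategory.C
    assert classify_regimen(r, guideline, allow_superset=True) is AdherenceCategory.A


def test_route_constraint_only_enforced_when_strict(guideline):
    iv_nitrofurantoin = reg("cystitis", ("J01XE01", Route.iv))
    assert classify_regimen(iv_nitrofurantoin, guideline) is AdherenceCategory.A
    assert (
        classify_regimen(iv_nitrofurantoin, guideline, route_strict=True)
        is AdherenceCategory.C
    )
    oral = reg("cystitis", ("J01XE01", Route.oral))
    assert classify_regimen(oral, guideline, route_strict=True) is AdherenceCategory.A


def test_unknown_sub_indication_raises_with_code(guideline):
    r = reg("CAP-m", ("J01CA04", Route.iv))
    object.__setattr__(r, "sub_indication", "no-such")
    with pytest.raises(KeyError, match="no-such"):
        classify_regimen(r, guideline)


def test_duplication_and_order_insensitive(guideline):
    a = reg("CAP-s", ("J01DD04", Route.iv), ("J01FA01", Route.iv))
    b = reg("CAP-s", ("J01FA01", Route.iv), ("J01DD04", Route.iv))
    assert classify_regimen(a, guideline) == classify_regimen(b, guideline)


# ---------------------------------------------------------------------------
# summaries


def test_adherence_summary_arithmetic(guideline):
    regimens = (
        [reg("CAP-m", ("J01CA04", Route.iv), admission=f"A{i}") for i in range(6)]
        + [reg("CAP-m", ("J01AA02", Route.oral), admission=f"B{i}") for i in range(2)]
        + [reg("CAP-m", ("J01DC02", Route.iv), admission=f"C{i}") for i in range(2)]
    )
    cats = [classify_regimen(r, guideline) for r in regimens]
    report = adherence_summary(regimens, cats, hospital="X")
    s = report.summaries["CAP-m"]
    assert (s.proportion_a, s.proportion_b, s.proportion_c) == (0.6, 0.2, 0.2)
    assert s.adherence_rate == pytest.approx(0.8)
    assert abs(s.proportion_a + s.proportion_b + s.proportion_c - 1.0) < 1e-9


def test_adherence_tier_A_only(guideline):
    regimens = [reg("CAP-m", ("J01CA04", Route.iv)), reg("CAP-m", ("J01AA02", Route.oral), admission="A2")]
    cats = [classify_regimen(r, guideline) for r in regimens]
    report = adherence_summary(regimens, cats, adherence_tier="A")
    assert report.summaries["CAP-m"].adherence_rate == pytest.approx(0.5)


def test_rare_combinations_pooled_as_other(guideline):
    regimens = [reg("CAP-m", ("J01CA04", Route.iv), admission=f"A{i}") for i in range(97)]
    regimens += [reg("CAP-m", ("J01DC02", Route.iv), admission=f"B{i}") for i in range(3)]
    cats = [classify_regimen(r, guideline) for r in regimens]
    s = adherence_summary(regimens, cats).summaries["CAP-m"]
    labels = dict(s.combination_frequencies)
    assert "J01DC02" not in labels  # 3% < 5% display threshold
    assert labels["other"] == pytest.approx(0.03)
    assert sum(labels.values()) == pytest.approx(1.0)


def test_planted_adherent_fraction_recovered(guideline):
    """Seeded cohort with 50% adherent regimens: the A+B rate stays inside
    the 99% binomial interval around 0.5."""
    rng = np.random.default_rng(2024)
    n = 400
    regimens, cats = [], []
    for i in range(n):
        if rng.random() < 0.5:
            r = reg("CAP-m", ("J01CA04", Route.iv), admission=f"A{i}")
        else:
            r = reg("CAP-m", ("J01DC02", Route.iv), admission=f"A{i}")
        regimens.append(r)
        cats.append(classify_regimen(r, guideline))
    rate = adherence_summary(regimens, cats).summaries["CAP-m"].adherence_rate
    half_width = 2.576 * np.sqrt(0.5 * 0.5 / n)
    assert abs(rate - 0.5) < half_width


def test_benchmark_table_single_hospital_range_collapses(guideline):
    regimens = [reg("CAP-m", ("J01CA04", Route.iv))]
    cats = [classify_regimen(r, guideline) for r in regimens]
    df = benchmark_table([adherence_summary(regimens, cats, hospital="A")])
    row = df.iloc[0]
    assert row["adherence_min"] == row["adherence_max"] == row["adherence_pct"]


def test_benchmark_table_brackets_planted_rates(guideline):
    rng = np.random.default_rng(7)
    reports = []
    for hospital, p in (("A", 0.3), ("B", 0.6)):
        regimens, cats = [], []
        for i in range(300):
            agent = "J01CA04" if rng.random() < p else "J01DC02"
            r = reg("CAP-m", (agent, Route.iv), admission=f"{hospital}{i}")
            regimens.append(r)
            cats.append(classify_regimen(r, guideline))
        reports.append(adherence_summary(regimens, cats, hospital=hospital))
    df = benchmark_table(reports)
    lo = df["adherence_min"].iloc[0] / 100
    hi = df["adherence_max"].iloc[0] / 100
    assert abs(lo - 0.3) < 0.1 and abs(hi - 0.6) < 0.1
    assert lo < hi


def test_benchmark_table_tolerates_missing_cap_split(guideline):
    """A hospital whose EMR does not split CAP by severity contributes a CAP
    row and simply no CAP-m/CAP-s rows."""
    unsplit = [reg("CAP", ("J01CA04", Route.iv))]
    split = [reg("CAP-m", ("J01CA04", Route.iv)), reg("CAP-s", ("J01DD04", Route.iv), admission="A2")]
    reports = [
        adherence_summary(unsplit, [classify_regimen(r, guideline) for r in unsplit], hospital="A"),
        adherence_summary(split, [classify_regimen(r, guideline) for r in split], hospital="B"),
    ]
    df = benchmark_table(reports)
    by_hospital = df.groupby("hospital")["sub_indication"].apply(set)
    assert by_hospital["A"] == {"CAP"}
    assert by_hospital["B"] == {"CAP-m", "CAP-s"}
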