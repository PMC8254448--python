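# stewardaudit

Antibiotic stewardship teams need to know how much antibiotic is
prescribed and whether it follows the guideline, but point prevalence
surveys — manually reviewing every prescription at one time point — are
too slow to run more than occasionally. When the EMR forces prescribers
to register an indication with every systemic-antibiotic order
(empiric / targeted / prophylaxis, focus of infection, sub-indication),
that registration can replace most of the manual work. `stewardaudit`
turns such a prescription-indication extract into an audit of empiric
antibiotic use for respiratory and urinary tract infections (RTI/UTI):

1. **Ingest** — read the prescription extract (ATC class J01) and the
   admissions table, with per-hospital column and value maps; rows that
   fail parsing are returned as rejects, never dropped.
2. **Cohort selection** — adults (≥ 18 y) on general wards hospitalized
   ≥ 12 h; the *empiric* regimen is the antibiotic (combination) therapy
   active 24 h after admission, or the last therapy before discharge for
   12–24 h stays. Readmissions within 30 days, ICU stays, prophylaxis
   orders, prescriptions starting before admission, admissions registered
   with both RTI and UTI, and configurable tract/date windows are
   excluded, each counted once in a conservation-checked flowchart.
3. **Regimen assembly** — simultaneous prescriptions for the same
   sub-indication merge into one combination regimen, the unit of
   assessment.
4. **Classification** — each regimen is compared by exact agent-set
   equality against a guideline table: **A** = first choice, **B** =
   second choice, **C** = discordant; the adherence rate is the A+B
   share. Sub-indications registered as "other" are not assessed.
5. **Validation** — stratified chart-review sampling (RTI / UTI / random
   other) and scoring of agreement between the selected and documented
   indication, with exact (Clopper–Pearson) intervals on the error rate.

A synthetic-data module generates extracts with planted ground truth
(anomalies, mis-selections, adherence), so the full pipeline is testable
without access to hospital data.

## Worked example

```sh
stewardaudit simulate --seed 3 --n-patients 250 --out-dir sim
stewardaudit select --extract sim/extract.csv --admissions sim/admissions.csv \
    --out-records empiric.csv --out-flowchart flowchart.csv
stewardaudit classify --records empiric.csv --guideline sim/guideline.yaml \
    --out classified.csv
```

which prints

```text
wrote 279 prescriptions / 264 admissions to sim
kept 57 empiric RTI/UTI prescriptions
46 assessable regimens; overall adherence 54.3%
```

279 generated J01 prescriptions reduce to 57 empiric RTI/UTI
prescriptions after the flowchart exclusions (the other orders are
non-RTI/UTI, prophylaxis, on excluded admissions, or not active at the
24 h snapshot); merging combinations leaves one regimen per admission
and sub-indication, of which 46 have an assessable sub-indication, and
54.3% match a recommended first- or second-choice regimen of the demo
guideline table. `flowchart.csv` lists every exclusion stage with
`input = kept + excluded` enforced.

The packaged guideline table (`stewardaudit/data/guideline_demo.yaml`)
is an illustrative synthetic stand-in; real audits must supply the
current national table in the same YAML layout.

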