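# Methods

## The audit model

`stewardaudit` operationalises an EMR-based audit of empiric antibiotic
use. The observational unit moves through three levels:

* **prescription** — one systemic-antibiotic order (ATC class J01) with a
  registered indication: class (empiric / targeted / prophylaxis), focus
  tract (RTI, UTI, other) and, for RTI/UTI, a sub-indication code;
* **regimen** — the set of agents prescribed simultaneously for the same
  sub-indication of one admission (combination therapy), the unit of
  appropriateness assessment;
* **admission** — the hospital stay, which determines eligibility and the
  evaluation instant.

Empiric therapy is defined *by time*, not by the registered class: it is
the therapy active 24 h after admission. Febrile patients are often
started on antibiotics immediately at presentation and the initial choice
is frequently revised once first diagnostics return, while after ~24 h
therapy tends to switch to targeted treatment; the 24 h snapshot is the
compromise that best reflects the deliberate empiric choice. For stays of
12–24 h the last prescribed therapy before discharge is used instead, and
stays under 12 h do not count as clinical admissions.

### Interval semantics

Prescription activity is the half-open interval `[start_ts, stop_ts)`;
an absent stop means active through discharge. A record stopping exactly
at hour 24 is therefore *not* active at the snapshot, one starting
exactly at hour 24 *is*. The source data carry dates or timestamps
depending on the EMR; the schema demands datetimes because the 12 h and
24 h rules are sub-day. In the 12–24 h branch, "last prescribed" is the
maximal `start_ts`; ties all survive and form a combination, since
simultaneous starts for the same indication are exactly what combination
therapy looks like in order data.

### Exclusions and the flowchart

Each excluded prescription is counted once, under the first failing rule
in a fixed order:

```
linked → tract (RTI/UTI only) → indication class (prophylaxis) →
age → ward (general only) → stay (≥ 12 h) → readmission (30 d) →
empiric snapshot → erroneous start → dual tract → indication windows
```

The tract filter sits early so the flowchart's second stage directly
gives the RTI/UTI share of the raw extract. Prophylaxis-registered
orders are removed before snapshotting; targeted-registered orders are
kept by default because the empiric definition is time-based (a
params toggle drops them). Readmission excludes only the later
admission — guideline-recommended empiric treatment still applies to the
index stay. "Erroneous" prescriptions are those starting before
admission (data-entry artefacts). The dual-tract rule removes all
RTI/UTI records of an admission whose empiric set spans both tracts,
because the therapy can then be attributed to neither indication.
Indication windows exclude a tract within a date interval keyed on the
prescription start date (e.g. respiratory prescriptions from March 2020
onward, when no guideline covered COVID-19 pneumonia). Every stage
satisfies `input = kept + excluded` and chains into the next; a violated
flowchart is a hard error, never rendered.

Two ambiguities the definition leaves open are resolved as: the 24 h
clock starts at the ward admission timestamp in the admissions table
(hospital presentation time is not in the extract), and exclusion
windows key on the prescription start date rather than the admission
date.

## Classification

A regimen is **A** if its ATC-code set equals (order- and
duplication-insensitive) any first-choice recommendation for its
sub-indication, **B** if it equals a second-choice recommendation, **C**
otherwise; first choice is tested before second. Sub-indications flagged
non-assessable (the "other" codes) yield NOT_ASSESSED. Matching is exact
set equality: a recommended agent *plus* anything else is discordant.
That is the stricter reading of "in accordance with the guideline", and
the auditable one — a subset rule would silently bless add-ons; an
`allow_superset` flag relaxes it. Route constraints (e.g. oral
nitrofurantoin for cystitis) only participate when `route_strict` is on,
off by default because registration data rarely support route-level
adjudication reliably. The adherence rate defaults to the A+B share,
configurable to A-only.

The packaged guideline table is an illustrative synthetic stand-in with
the structural features that matter (single agents, a combination
recommendation for severe CAP, a route constraint, non-assessable
"other" codes). Real audits must supply the national table.

## Chart-review validation

Registration accuracy is the fraction of reviewed records whose selected
indication equals the documented one *at sub-indication level* —
registering cystitis for a documented complicated UTI is an error even
though both are urinary, because the two have different recommended
regimens. Sampling is stratified on the selected indication (RTI, UTI,
and a random draw of everything else, which estimates how many true
RTI/UTI prescriptions the registration missed), without replacement,
reproducible by seed; a request at or above the stratum population
returns the whole stratum as a census. Records whose chart supports no
verdict are removed from the denominator rather than counted as errors.
Error rates carry Clopper–Pearson exact intervals (Beta-quantile form),
suited to the small yearly re-validation samples the workflow expects.

## Synthetic data

The generator emulates the extract of a mid-sized general hospital over
one year. Defaults (per admission unless noted): ~30% of prescriptions
registered under RTI/UTI (18% RTI, 12% UTI); half of regimens
guideline-adherent, 60% of those first-choice; 10% sub-indication
mis-selection with the dominant confusion mass on cystitis registered
for a documented complicated UTI; 2% underage, 5% ICU, 4% sub-12 h
stays, 5% planted 30-day readmissions, 8% stays in the 12–24 h band to
stress the discharge branch; 4% erroneous starts and 3% dual-tract
registrations on otherwise clean admissions; 1% whole-tract misses;
log-normal length of stay around four days. Anomalies are planted
disjointly, with a precedence mirroring the pipeline's attribution
order, so every planted exclusion maps to exactly one flowchart stage
and recovery can be asserted exactly.

One deliberate modelling choice: prescribed agents are drawn from the
guideline entry of the *registered* (possibly mis-selected)
sub-indication, i.e. mis-selection is a registration-time error and the
therapy follows the registration. In real data the therapy more likely
follows the documented diagnosis — that is why mis-registered cystitis
rows show complicated-UTI drugs — but coupling the adherence draw to the
mis-selection draw would leave no well-defined planted adherent
fraction to recover. Passing tests therefore demonstrate that the
pipeline recovers planted registration errors and planted adherence
separately, not how the two interact in real hospitals.

Other simplifications: at most two admissions per patient (a planted
readmission within 30 days, or a benign second stay 45–90 days later);
one infection episode per admission; no microbiology, dosing or
free-text; a single pseudo-random stream with a fixed draw order makes
runs byte-reproducible.

## Test and acceptance problem sizes

Worked examples re-score the published three-hospital chart-review
tallies (300/243/298 assessable records) and the extract share
arithmetic, both closed-form. The selection rules are verified against a
brute-force per-admission re-derivation on 200 random instances of up to
50 admissions. Parameter recovery uses 100 seeded cohorts of ~1,000
prescriptions each (900 patients): per-stage exclusion counts must equal
the planted truth exactly, and the recovered mis-selection rate and
adherent fraction must fall inside the 99% binomial interval of their
planted values in at least 95 of the 100 seeds — per quantity, since a
joint all-quantities-per-seed criterion would compound roughly eight
simultaneous 99% intervals and fail by construction. These sizes give
stable recovery statistics while keeping the full suite under a minute
on one CPU.

## Known limitations

* The extract's registered indication is the only signal; the tool
  validates registration against documentation but never judges the
  provider's diagnosis.
* Treatment duration, dosing and allergy- or culture-justified
  deviations are out of scope; such prescriptions classify as discordant.
* Admission boundaries come from the admissions table; the tool never
  infers them from prescription timing.
* The patient age required by the eligibility rule is not part of the
  canonical extract parameter list; it must be supplied in the
  admissions table.
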