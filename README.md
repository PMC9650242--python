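# icusepsis

Sepsis-3 cohort phenotyping over AmsterdamUMCdb-shaped ICU tables: daily SOFA
scores, antibiotic-escalation-based suspected infection, and per-window
sepsis-episode / septic-shock indicators, as a tested and configurable
pipeline with a synthetic-data generator.

## Who this is for

Critical-care researchers who need a reproducible, auditable sepsis cohort
definition over long-format electronic-health-record event tables
(admissions, drug administrations, numeric measurements, list/choice
observations in CSV). Because access to the real database is restricted, the
package ships a synthetic cohort generator that emulates the relational
structure and plants known ground-truth episodes, so every stage of the
pipeline is verifiable without any data download. Users with real data
access supply their own concept map (raw item identifier → clinical concept)
and, if desired, their own SOFA thresholds and antibiotic formulary — all
scoring cut-offs and drug ranks are YAML configuration, not code.

## The method

For each admission, time is partitioned into half-open 24 h windows
("days") relative to the admission instant: day *d* covers
[*d*·24 h, (*d*+1)·24 h), with negative days for pre-admission events.

**Daily SOFA.** Each of the six organ systems (respiration, coagulation,
liver, cardiovascular, CNS, renal) is scored 0–4 per window from the worst
value observed in it (minimum for PaO₂/FiO₂, platelets, MAP, GCS, urine
output; maximum for bilirubin, creatinine, vasopressor dose). Missing
components contribute 0 to the total and are counted; vasopressor use is
inferred from any dose event, assuming vasopressors are titrated to keep
MAP ≥ 65 mmHg.

**Suspected infection = antibiotic escalation.** Every antibiotic carries a
configurable rank (1 = narrow … 4 = reserve). Window *d* escalates iff at
least one agent that day is intravenous and either max-rank(*d*) >
max-rank(*d*−1), or the rank is unchanged and the number of distinct agents
at that rank increased. Routine prophylaxis is excluded: cefotaxime given
for selective digestive decontamination in days 0–3, and — for admissions
after elective surgery — the escalation accompanying admission and its
subsequent window.

**Sepsis episode.** Window *d* is a sepsis episode iff it has a
non-prophylactic escalation and total SOFA rises by ≥ 2 points between the
previous/current, previous/subsequent, or current/subsequent windows
(absent windows in range count 0). Post-admission windows with ≥ 3 missing
SOFA components are discarded as indeterminate. **Septic shock** is the
subset with cardiovascular SOFA ≥ 3 and worst-window lactate ≥ 2 mmol/L.

A comparison module implements the four legacy admission-sepsis criteria
(admission-form flag, severe-infection diagnosis, non-prophylactic
post-surgical antibiotics, antibiotics + cultures within 6 h) and tabulates
them against Sepsis-3 at admission as a confusion matrix over unique first
admissions.

## Worked example

```sh
icusepsis synth --out data --preset tables23
icusepsis sepsis --tables data --out results --days -3 1
```

prints

```
wrote sofa.csv (11 rows) and sepsis.csv (12 rows) to results; sepsis windows: 2, septic shock windows: 0
```

`results/sepsis.csv` contains, for admission 2:

```
admissionid,time,sofa_total_score,antibiotic_escalation,prophylaxis,infection,sepsis_episode,septic_shock
2,-2,0,NaN,False,False,False,False
2,-1,1,True,False,True,True,False
2,0,6,False,False,False,False,False
```

Day −2 has no antibiotics, so no escalation determination is made (`NaN`).
On day −1 a new intravenous ceftriaxone starts (escalation `True`, not
prophylactic, hence `infection` `True`) while the total SOFA trajectory
0 → 1 → 6 rises by ≥ 2 points into the admission window, so day −1 is a
sepsis episode; the cardiovascular score that day is unknown
(no vasopressors pre-admission), so it is not septic shock. Admissions 0
and 1 are elective surgical: their day −1 cefazolin escalation is flagged
`prophylaxis` `True` and never becomes infection.

The same flow on a random planted cohort:

```sh
icusepsis synth --out data2 --seed 7 --n 250 --days -1 5
icusepsis sepsis --tables data2 --out results2 --days -1 5
icusepsis compare --tables data2 --out results2 --days -1 5
```

`results2/sepsis.csv` equals `data2/ground_truth_sepsis.csv` row for row,
and `compare` writes the confusion matrix with sensitivity/specificity of
the legacy criteria against Sepsis-3.

## Layout

| Module | Role |
| --- | --- |
| `icusepsis.schema_io` | CSV readers/writers, data model, 24 h windowing |
| `icusepsis.config` | thresholds, shock criteria, antibiotic ranks, concept map (YAML) |
| `icusepsis.sofa` | worst-in-window aggregation and SOFA component/total scoring |
| `icusepsis.antibiotics` | SDD filtering, day profiles, escalation detection |
| `icusepsis.sepsis` | delta rule, episode and shock detection, full pipeline |
| `icusepsis.baseline` | legacy admission criteria and confusion matrix |
| `icusepsis.synthetic` | scenario specs, band inversion, ground truth, random cohorts |
| `icusepsis.cli` | `icusepsis sofa \| sepsis \| synth \| compare` |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
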