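# Methods

## Data model and windowing

The pipeline consumes long-format CSV tables shaped like the AmsterdamUMCdb
exports: one `admissions` table (admission and patient identifiers, admission
timestamp, urgency flag, surgical status, ICU/MCU location, first-admission
flag) plus timestamped event tables `drugitems`, `numericitems` and
`listitems`. All event timestamps are integer milliseconds **relative to the
admission instant**, which removes calendar and timezone logic entirely; day
*d* is the half-open window [*d*·86,400,000 ms, (*d*+1)·86,400,000 ms) and the
offset→day map is floor division, so pre-admission events land on negative
days. Windows are anchored at the admission instant, not at midnight; the
observation range [d_min, d_max] must contain day 0 and defaults to (−1, 7) —
one pre-admission window captures emergency-department/operating-room events
immediately before ICU admission, and the first week covers the large
majority of new episodes.

Raw item names are resolved to clinical concepts (PaO₂, FiO₂, platelets,
bilirubin, MAP, GCS, creatinine, urine output, lactate, ventilation status,
vasopressor, antibiotic, culture, admission-form flag, admission diagnosis)
through a user-editable YAML concept map; rows with unmapped items are
dropped with a logged count rather than failing, because real exports always
contain items irrelevant to scoring. Referential integrity (every event's
admission exists; exactly one first admission per patient) is enforced at
read time.

## SOFA scoring

Each component is scored from the *worst* value in the window — minimum for
PaO₂/FiO₂ ratio, platelets, MAP, GCS and urine output, maximum for
bilirubin, creatinine and vasopressor dose. Urine-output events are treated
as daily totals (mL/day), so the minimum is the worst. The respiratory ratio
is formed from the per-concept extrema (minimum PaO₂ over maximum FiO₂)
rather than from paired simultaneous measurements; this is a conservative
(worst-case) ratio and keeps aggregation uniform across concepts. FiO₂
values above 1 are interpreted as percentages.

Default cut-offs follow the 1996 consensus in AmsterdamUMCdb units and are
entirely config-exposed (`icusepsis/data/sofa_thresholds.yaml`):

| Component | Input, unit | Bands (score 1/2/3/4) |
| --- | --- | --- |
| respiration | PaO₂/FiO₂, kPa | < 53.3 / 40 / 26.7 / 13.3; scores ≥ 3 require ventilation, otherwise capped at 2 |
| coagulation | platelets, 10⁹/L | < 150 / 100 / 50 / 20 |
| liver | bilirubin, µmol/L | ≥ 20 / 33 / 102 / 205 |
| cardiovascular | MAP mmHg; doses µg/kg/min | MAP < 70 → 1; any dopamine ≤ 5 or dobutamine → 2; dopamine > 5 or norepinephrine/epinephrine ≤ 0.1 → 3; dopamine > 15 or norepinephrine/epinephrine > 0.1 → 4 |
| cns | GCS | < 15 / 13 / 10 / 6 |
| renal | creatinine µmol/L; urine mL/day | creatinine ≥ 110 / 171 / 300 / 441; urine < 500 → ≥ 3, < 200 → 4 |

Vasopressor use is inferred from the existence of a dose event, under the
assumption that vasopressors are only administered to maintain MAP ≥ 65 mmHg
with adequate fluids; consequently any dose event forces the cardiovascular
score to at least 2, and an agent outside the configured classes scores 2
(presence known, dose rules inapplicable). A component is missing iff every
input it needs is absent from the window (respiration needs both PaO₂ and
FiO₂; cardiovascular either MAP or a dose event; renal either creatinine or
urine output). Missing components contribute 0 to the total in *all*
windows — this matches the published worked example, where every printed
total equals the sum of its non-missing cells — and the missing count is
carried separately so episode detection can apply its discard rule. No
values are carried forward across windows and nothing beyond the zero
assumption is imputed; slowly-sampled labs therefore produce missing
components on unmeasured days by design.

The SOFA table contains one row per window with at least one scoring-relevant
event, plus day 0 for every admission (so an admission with no data still
appears once, fully missing).

## Antibiotic escalation

The escalation rank of each agent (1 narrow … 4 reserve) is data: the
shipped formulary (`icusepsis/data/antibiotic_ranks.yaml`) is an
illustrative classification and explicitly replaceable; the algebra is the
method. Names are normalized by case-folding and whitespace collapse, then
passed through a synonym table; there is no fuzzy matching, for determinism.
Unknown names are collected into a report and skipped.

Window *d* (with at least one non-excluded administration) escalates iff at
least one of its agents is intravenous and either the maximum rank exceeds
window *d*−1's, or it equals it and the number of *distinct agent names* at
that rank increased. An antibiotic-free or unobserved previous window counts
as rank zero, so any IV start is an escalation; a window with no
administrations yields no determination and serializes as `NaN`. Counting
distinct agents (not administrations) at the maximum rank makes repeated
dosing of one drug inert.

Two prophylaxis rules suppress the infection proxy:

* **SDD**: cefotaxime (configurable) administered in post-admission windows
  0–3 is excluded from escalation input — four 24 h windows, matching the
  routine 16-dose decontamination course — and a window whose only
  administrations were excluded is flagged `prophylaxis`. Pre-admission
  cefotaxime is not excluded: the decontamination protocol starts at
  admission. Ceftriaxone, the agent substituted on actual suspicion of
  infection, is never excluded.
* **Elective surgery**: for planned admissions with surgical status
  (urgency false ∧ surgical true), the earliest escalation in a window at or
  before day 0 is deemed to accompany admission; that window and the
  subsequent one cannot be infection. The flag column records `True` only on
  windows where an escalation was actually suppressed (a continuation window
  with no escalation shows `False`), while the sepsis suppression covers
  both windows; later escalations in the same admission count normally.

## Episode and shock detection

A window *d* is a **sepsis episode** iff it has a non-prophylactic
escalation and the total SOFA rises by at least 2 points between the
previous/current, previous/subsequent, or current/subsequent windows. Days
inside the observation range without rows count 0 (consistent with the
pre-admission zero assumption), and clauses referring to days outside the
range are skipped — so at the range edges the rule degrades to the available
comparisons rather than failing.

Post-admission windows (day ≥ 0) with ≥ 3 missing components are too poorly
observed to adjudicate: `sepsis_episode` is `False` in the serialized table
(which has no indeterminate state) and the returned frame carries an
`indeterminate` column, not serialized by default, so "no" and "unknown"
remain distinguishable in the API. Pre-admission windows are exempt because
their missing components are assumed zero; the worked example depends on
this (pre-admission sepsis windows with 5–6 missing components).

**Septic shock** is the subset of sepsis windows with cardiovascular score
≥ 3 (vasopressor support) and worst-window lactate meeting the threshold —
≥ 2.0 mmol/L by default, with the comparator (≥ vs >) config-exposed since
both conventions appear in the literature. Missing lactate or a missing
cardiovascular score never qualifies.

Consecutive qualifying windows are reported as separate rows; the package
deliberately does not merge them into episodes-as-intervals.

## Legacy criteria and comparison

The pre-existing admission-sepsis definition is the disjunction of: the
admission-form sepsis flag; an admission diagnosis in a configurable
severe-infection list (defaults: gastrointestinal perforation, cholangitis,
meningitis); non-prophylactic antibiotic use in the admission window after
surgery (reusing the SDD and elective-surgery rules above, so there is one
source of truth for prophylaxis); and antibiotics plus cultures both within
6 h (configurable) after admission — the window is [0 h, 6 h] post
admission. Sepsis-3 "at admission" means an episode at day −1 or day 0. The
confusion matrix is restricted to unique first admissions whose day-0 window
has < 3 missing components (the label is otherwise indeterminable), and
reports sensitivity tt/(tt+tf) and specificity ff/(ff+ft) with Sepsis-3 as
reference, returning `None` on empty denominators.

## Synthetic cohorts

The generator plants per-window component *scores* and inverts the active
threshold bands to raw values, drawn uniformly inside the band but away from
its edges by 1% of the band width (configurable), eliminating
threshold-edge ambiguity. Ventilation events accompany planted respiratory
scores ≥ 3; renal plants optionally add a urine-output value consistent with
(never exceeding) the planted score; event times are jittered uniformly
within the window.

Ground truth is computed at generation time by a second, direct
implementation of the rules operating on the planted scenario (set algebra
on the schedule, lexicographic (max-rank, count) comparison for escalation,
pairwise differences for the delta rule) — deliberately sharing no code
path with the pipeline, so the label-recovery test is a genuine
two-implementation cross-check rather than a tautology.

`random_cohort` mixes archetypes at fixed rates — healthy 30%, SDD
decontamination 15%, elective perioperative prophylaxis 20%, sepsis 25%,
septic shock 10% — with the episode day uniform over {−1, …, 3} (shock over
{0, …, 3}, so the shock-defining cardiovascular score and lactate fall in an
observed post-admission window). These rates make roughly a third of
admissions septic, typical of an ICU enriched for the phenotypes under
test rather than of general ICU prevalence. The generator emulates
relational structure and band-level physiology only: no realistic dynamics,
measurement cadence, unit heterogeneity, free-text noise or the real item
vocabulary. Passing recovery tests therefore demonstrates correctness of the
windowing/scoring/episode logic, not robustness to real-data messiness
(unit conversion errors, duplicated items, clock skew), which must be
handled through the concept map and configs.

## Numerical and serialization choices

All scores are exact integer arithmetic on floats compared against
configured cut-offs; there are no tolerances. Cut-off membership is
half-open exactly as tabulated above, and the generator's margins keep
planted values off the boundaries. Output CSVs are UTF-8,
comma-separated, `NaN` for missing, `True`/`False` for booleans, sorted by
(admissionid, time) with a stable sort; reruns on identical inputs are
byte-identical. The two output tables grow with admissions × observed days,
not with raw event counts, keeping them of the same order as the admissions
table.

## Test and verification sizes

The suite verifies the delta rule against a brute-force pairwise oracle on
all 15,625 total-SOFA triples in [0,24]³, the escalation algebra on all
531,441 ordered pairs of ≤ 3-agent profiles with ranks ≤ 4 and IV/oral
routes, and component scoring against an exhaustive band-scan oracle on
10,000 random windows; planted-label recovery uses a 250-admission seeded
cohort and the matched-baseline comparison a 200-admission cohort. These
sizes make the whole suite and the acceptance script run in well under a
minute while covering the full discrete rule space exhaustively where it is
finite.

## Known limitations

* Suspected infection is operationalised purely by antibiotic escalation —
  clinical judgement, not microbiological confirmation; culture results are
  never adjudicated.
* The shipped antibiotic ranks are illustrative; site-specific formularies
  will change escalation behaviour and must be supplied for real analyses.
* No carry-forward of labs means sparse sampling inflates missingness and
  can trigger the ≥ 3-missing discard on real data.
* The worst-case PaO₂/FiO₂ pairing can overstate respiratory severity when
  FiO₂ swings within a window.
* Elective-surgery identification (urgency false ∧ surgical true) is a
  field-logic choice; databases encoding planned admissions differently
  need an adapted admissions table.
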