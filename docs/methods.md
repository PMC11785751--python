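# Methods

## Diagnostic model

Both rule engines operate on day-granular creatinine series. All thresholds
live in `AlgorithmConfig` and are shared between engines:

| parameter | default | unit | meaning |
|---|---|---|---|
| `scr_abnormal_threshold` | 1.3 | mg/dL | alerting creatinine (strict >) |
| `aki_ratio_threshold` | 1.5 | — | fold-rise over baseline defining AKI |
| `egfr_threshold` | 60 | mL/min/1.73 m² | abnormal renal function (strict <) |
| `acute_window_days` | 7 | days | acute baseline lookback |
| `chronicity_days` | 90 | days | CKD chronicity horizon |
| `ratio_strict` | false | — | `false`: ≥ threshold; `true`: > threshold |
| `window_mode` | hierarchical | — | window precedence (see below) |
| `race_coefficient` | false | — | 1.159 multiplier of the 2009 equation |

**Ratio comparison.** The source rules print both "≥ 1.5 times" and
"> 1.5 times" in different places; KDIGO uses ≥. The default is ≥, and
`ratio_strict=true` (or `AlgorithmConfig.strict_rules()`) selects the strict
reading. At a ratio of exactly 1.5 the two differ; everywhere else they
agree.

**Window precedence.** The hierarchical order (lowest in days 1–7, else
lowest in days 8–90, else nearest beyond 90 days) mirrors the stated reviewer
procedure. A consequence worth noting: when testing is dense, the 1–7-day
window contains in-hospital mid-rise values and its *lowest* value governs
even if an 8–90-day baseline would have fired — this is precisely the
engine's documented false-negative mechanism, not a defect. An `any_window`
mode (global minimum across all three windows) is provided for sensitivity
analysis only.

**Assumed-normal baseline.** With no prior record anywhere, the baseline is a
categorical sentinel, never a fabricated creatinine value, and AKI is called
positive. This is conservative by design (a first-ever abnormal value is
never silently missed) and implies that a stable chronic patient whose first
database record is the in-hospital maximum will raise a spurious AKI alert.

**CKD chronicity.** The rules give contradictory outcomes when both abnormal
and normal eGFR records exist beyond 90 days; we decide by the *most recent*
record older than the horizon (least-stale evidence). The CKD index date is
the first in-episode date whose eGFR is abnormal; the AKI index is the
highest in-episode creatinine (earliest date on ties). AKI and CKD verdicts
are independent. Whether a single abnormal test beyond 90 days suffices (vs.
two abnormal tests spanning the interval) is ambiguous in the source; we
require one, matching the prose description.

**Ties and degenerate inputs.** Within a window the lowest value wins, with
the earliest date breaking value ties; for "nearest" selections the latest
date wins, with the lowest value breaking same-day ties. Sorting is internal
(by date, then value), so diagnoses are invariant under permutation and
duplication of input records — both properties are tested. The index day
itself (offset 0) is never part of a lookback window; whether same-day
repeat tests may serve as baseline is unstated in the source, and excluding
them is the deterministic choice. Undefined metrics (empty denominators,
degenerate 2×2 marginals) raise typed errors rather than yielding NaN.

**eGFR.** The 2009 CKD-EPI creatinine equation is implemented (the study era
predates the 2021 race-free refit); the race coefficient defaults to off —
appropriate for the East-Asian setting the rules were validated in — and is
a config flag because the original study does not state its choice. Age
enters as a real number of years. Dialysis patients are *not* auto-excluded
(`exclude_dialysis` exists but defaults off) so the dialysis false-positive
mechanism remains observable, matching the validated system's limitation.

## The adjudicator

The gold-standard engine scans every abnormal in-episode value, not only the
maximum. For each scanned value the baseline is the nearest **pre-admission**
record within the 7-day acute window of that value, else the nearest
pre-admission record at any distance, else assumed normal. Restricting the
baseline pool to pre-admission records models how a reviewer reasons — the
baseline is the patient's pre-event kidney function, not a mid-event
measurement — and is what makes the dense-testing divergence reproducible:
the algorithm ratios the peak against an in-hospital mid-rise minimum while
the reviewer ratios it against the outpatient baseline. The adjudicator does
not model knowledge from outside the database; a true-CKD patient with no
records is adjudicated by the same assumed-normal rule the algorithm uses.

## Synthetic cohorts

The simulator's purpose is structural: reproduce the four documented error
mechanisms at configurable rates so both engines can be validated without
real data. Defaults encode the validation study's conditions — AKI
prevalence 28.6%, CKD prevalence 1031/1551, 45/443 AKI events completed
pre-admission, 19/443 obscured by dense testing, 55/1031 CKD cases without
history, 56.6% emergency admissions, 20% of patients on dialysis.

Trajectory distributions are modelling choices, each a named constant:
log-normal baseline creatinine (median 1.0 mg/dL non-CKD, 2.0 CKD, σ_log
0.15; median 6.0 pre-dialysis), exponential outpatient test cadence (mean 45
days over 360 days), one hospitalization of 5–20 days with daily tests,
uniform [1.6, 4.0] multiplicative AKI rise over 2–5 days, thrice-weekly
dialysis sawtooth, and multiplicative log-normal measurement noise (σ 0.03).
Baselines are clamped away from the eGFR threshold (≤48 for CKD, ≥62 with
noise headroom for non-CKD) so that generated labels are consistent with the
trajectories even at 4σ noise.

Mechanism constructions and their guarantees:

* **Pre-admission AKI** — the rise (completed 10–14 days before admission)
  is followed by a sustained plateau; the outpatient visit that led to
  admission leaves an elevated value 1–4 days pre-admission, so every value
  any acute or subacute window can select is already elevated. Algorithm
  verdict: always negative (verified over 300 seeds).
* **Dense testing** — the rise is stretched over 15 daily steps with factor
  ≤ 1.75, so the 7-day window ratio is at most 1.75^(7/15) ≈ 1.30 and noise
  cannot lift it to 1.5, while the total rise ≥ 1.6× fires the adjudicator's
  pre-admission comparison.
* **Dialysis fluctuation** — an alert-triggering sawtooth (trough/peak in
  [0.50, 0.65]) is assigned to the fraction of non-AKI patients that matches
  the observed false-positive rate (13/1108); remaining dialysis patients
  receive attenuated fluctuation (trough/peak in [0.85, 0.95]) that cannot
  trip the 1.5-fold rule. Applying the full sawtooth to all 20% dialysis
  patients would contradict the observed specificity, so amplitude is the
  mechanism selector.
* **Missing history** — all pre-admission records are suppressed; CKD can
  then never be established. (Pre-admission AKI is never combined with
  missing history, since the pre-admission event is itself a record.)

With these constructions the expected recovery rates follow in closed form
from the scenario: AKI sensitivity 1 − (45+19)/443 ≈ 85.6%, specificity
1 − 13/1108 ≈ 98.8%, CKD sensitivity 1 − 55/1031 ≈ 94.7%. Two small,
deliberate deviations remain: (i) a stable chronic patient whose in-episode
maximum falls on a day with no visible prior record is called AKI by the
assumed-normal rule (the engine's own conservative behaviour), which costs
roughly half a point of simulated specificity; (ii) measurement noise very
occasionally flips a marginal mechanism case. Observed values at n = 2000
sit within three binomial standard errors of the expectations across seeds.

Per-patient RNG substreams are spawned from the master seed
(`numpy.random.SeedSequence`), so cohorts are byte-identical across runs and
independent of generation order. Clinician discharge diagnoses are simulated
as truth labels flipped at the study's observed clinician accuracy (57.0%
AKI, 73.6% CKD) — a convenience for exercising the comparison machinery, not
a model of clinician behaviour.

What passing simulation tests does *not* show: the generator produces neither
realistic comorbidity structure, nor inter-current AKI episodes, nor
unit-conversion or assay artefacts, and its trajectory shapes are idealized.
Recovery of the configured rates demonstrates that the engines implement the
rules faithfully, not that the rates themselves generalize to any real
population.

## Evaluation arithmetic

Contingency cells are exact integers; sensitivity (TP/(TP+FN)), specificity
(TN/(FP+TN)) and accuracy ((TP+TN)/N) are computed with `decimal` division
and rounded half-up to one decimal on the percentage scale only at
formatting. This reproduces every printed percentage of the validation
study's tables from their integer cells. Two printed figures in the source
deviate from exact rounding (19/64 = 29.69% printed as 29.6%;
12/1551 = 0.77% printed as 0.7%); the evaluator reproduces the correctly
rounded values (29.7, 0.8) and the discrepancy is documented here rather
than imitated. The accuracy comparison is a Pearson chi-square on the 2×2
correct/incorrect table without continuity correction (a Yates flag exists);
both reported comparisons are significant far below 0.001 under either.

## Problem sizes

The shipped checks use cohorts of 500 (confounder-free recovery), 1000–2000
(study-rate recovery) and 1000 random small timelines for oracle
equivalence; the full suite runs in a few seconds and the acceptance script
in under two, so larger cohorts are available to users who want tighter
binomial intervals simply by raising `n_patients`.
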