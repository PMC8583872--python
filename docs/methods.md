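# Methods

## Instruments and scoring

The RPQ asks for 16 symptoms on a 5-point Likert scale (0 = not experienced
at all … 4 = a severe problem; total 0–64); the SCAT symptom evaluation asks
for 22 symptoms on a 7-point scale (0 = none … 6 = severe; total 0–132).
Totals are raw severity sums; the symptom count is the number of items rated
above zero — the only reading consistent with the anchors, under which a
rating of 1 is an endorsed symptom. The classical RPQ convention of recoding
ratings of 1 to 0 before summing is available as `recode_mild=True` but off
by default, because anchoring 0 at "not experienced at all" implies raw
summation to the 64-point maximum.

Domain subscores follow the somatic / cognitive / emotional / sleep grouping
shipped in `data/scale_items.csv`. The grouping covers 12 of 16 RPQ items
and 19 of 22 SCAT items; the remainder (RPQ fatigue, blurred vision, double
vision, restlessness; SCAT blurred vision, "feeling slowed down", "don't
feel right") are `unclassified`: they count toward totals and symptom counts
but not toward any named subscore, so the four named subscores plus the
unclassified remainder always partition the total. The single
convention-dependent assignment is SCAT fatigue, somatic by default and
movable to unclassified via `fatigue_in_somatic=False`; somatic agreement is
reported under both conventions. The two optional self-disclosed RPQ items
are excluded outright (their content need not be concussion-related). A
"sensory" sub-grouping sometimes mentioned alongside these domains has no
published membership and is not implemented.

Assessment weeks are validated only as positive integers. The canonical
follow-up schedule (weeks 1–8, 12, 16) is exported as
`scales.WEEK_SCHEDULE` and is the simulator default, but cohort files with
other schedules are legal — the schedule is a property of a study design,
not of an assessment.

## Conversion equations

* **eq1 (RPQ → SCAT)**: `7·((RPQ_total/16)/5) · ((RPQ_symptoms/16)·22)` —
  mean item intensity rescaled to the SCAT's 7-point range times the
  endorsement fraction rescaled to 22 items. Its raw output tops out at
  123.2 < 132 over the whole valid domain: the published equation cannot
  reach the SCAT maximum, a documented property rather than a bug. The
  published worked example prints 55.7 for inputs (33, 14) while the formula
  as printed yields 55.584; both round to 56. The formula is implemented
  exactly as printed and the discrepancy left alone.
* **eq2 (SCAT → RPQ)**: the direct proportion `(SCAT_total/132)·64`, which
  maps the scale maxima onto each other exactly.
* Two rejected RPQ → SCAT candidates are retained for comparison only: a
  direct proportion `(RPQ_total/80)·132` (implemented literally, including
  the 80-point divisor — plausibly 16 items × 5 Likert levels rather than
  the 64-point maximum) and a domain-weighted sum of subscores rescaled by
  the ratio of domain maxima. Domain-level and single-symptom conversions
  are deliberately not offered as supported outputs: their accuracy was too
  low to stand behind.

Rounding is half-away-from-zero to the nearest integer (the published
examples only show "rounded to 56"/"rounded to 22", which both conventions
satisfy; half-away is the convention spreadsheet and SAS users expect). Raw
values are always reported alongside. Outputs are clamped into the target
range with a `clamped` flag; clamping never triggers for validated inputs.
Whether the original work clamped is unstated. Valid eq1 inputs must satisfy
`count ≤ total ≤ 4·count` with `total = 0 ⇔ count = 0`; violations raise
rather than silently extrapolate.

SCAT totals are banded low 0–25, moderate 26–75, high 76–132. The published
prose leaves 76 unassigned (moderate "26–75" but high ">76"); 76 is assigned
to the high zone, keeping the moderate band's printed upper bound intact.

## Synthetic cohorts

`simulate_cohort` emulates a rapid-access concussion clinic cohort: 215
adults, scheduled visits at weeks 1–8, 12, 16, both checklists at every
visit, declining participation. Per subject *i*: a log-scale baseline
severity `b_i ~ N(0.75, 1.25²)`, a recovery rate `r_i ~ Gamma(mean 0.40,
sd 0.32)` per week, and per visit a latent log-severity
`u = b_i − r_i·(week−1) + N(0, 0.25²)`. Each scale observes `u` plus its own
`N(0, 0.40²)` perturbation (`cross_scale_noise`, the dial that decouples the
two instruments), and each item discretizes
`discrimination·u_scale + N(0,1)` at its ordered thresholds — a
graded-response-style model. Item discriminations (≈0.8–1.2) and threshold
shifts are a fixed per-item jitter around per-scale base cutpoints, shipped
as data in the default config. After any visit with both totals zero the
subject leaves with probability 0.85 ("deemed recovered"); everyone faces a
9.5 % per-visit random attrition. Dropout is
absorbing, so weekly pair counts are nonincreasing by construction.

The defaults were calibrated once, by simulation, against the reference
cohort's pooled moments, and then frozen: across 10 seeds they give ≈1270
matched pairs (target 1168), RPQ mean total 20.5 (target 21.0), SCAT mean
total 29.1 (target 30.0, SD 27.6 vs 28.6), mean symptom counts 10.3/12.2
(targets 10.2/11.5), and per-seed paired-total Spearman ρ of 0.90–0.92
(target 0.91). Known mismatches: the simulated RPQ SD (≈16.4) runs about
18 % above the reference 13.9, and no per-week score distributions exist to
calibrate against, so the within-study time course is constrained only to
decline monotonically. The simulator also does not emulate: demographic
covariates (age/sex carry no effect), order-of-administration bias between
the two checklists, partially missing questionnaires, or the reference
cohort's non-monotone week-8/12 visit counts (a scheduling artifact).
Passing tests on simulated cohorts therefore demonstrate the *pipeline* and
the statistical structure it assumes, not clinical properties of real data.

One global seed drives everything; each subject uses an independent stream
keyed by `(seed, subject_index)`, so a cohort's first *k* subjects are
identical to a *k*-subject cohort at the same seed.

Because the conversion equations were fit to the original clinic data and
not to these synthetic cohorts, prediction-error statistics on simulated
data (e.g. eq1 mean error ≈ +6 points at the defaults) are not expected to
reproduce the original ±3-point confidence intervals; the error machinery
is validated instead on cohorts constructed to have known errors.

## Agreement analyses

Spearman correlations (mid-ranks for ties, via `scipy.stats.spearmanr`) are
computed between the instruments' totals, symptom counts, named-domain
subscores (somatic with and without fatigue), per week, and within SCAT
severity zones; zone stratification uses the *actual* SCAT total. Constant
input raises an error rather than returning a silent zero; within strata,
undefined or under-sized (< 3 pairs) entries are omitted from the report,
never fabricated. The count correlation is `None` on (degenerate) cohorts
where one count is constant. Raw p-values are reported and never gated on;
no multiple-testing correction, matching how the validation was originally
reported.

Prediction error is rounded prediction minus actual, on the target scale.
"Confidence interval of the predicted score" is interpreted as the 95 %
normal-approximation CI of the mean signed error (`mean ± 1.96·SD/√n`);
because that phrase is ambiguous, empirical ±3- and ±5-point coverage are
reported alongside. A least-squares slope of error on actual score captures
the documented tendency to over-predict low scores and under-predict high
ones. The published AUC has no recoverable ROC construction, so it is
reinterpreted as threshold concordance — the Mann–Whitney probability that
a randomly chosen above-threshold subject-week outranks a below-threshold
one on the predicted score, ties counting ½ — at the severity-zone
boundaries (25 and 75 on the SCAT; their eq2 images 12 and 36 on the RPQ).
Published AUC values are accordingly not treated as reproducible targets.

`compare_candidates` ranks the three RPQ → SCAT candidates by CI half-width,
then ±5-point coverage, with ties broken by the fixed order (eq1, direct
proportion, domain-weighted); the domain-weighted candidate is skipped with
a warning when the cohort lacks domain subscores. Equation coefficients are
never refit.

## File formats

Cohorts are plain UTF-8 CSV, one row per matched subject-week, in an
item-level schema (one column per item, `rpq_`/`scat_`-prefixed) or a
score-level schema (totals, counts, optional domain subscores). The first
line is a `#` comment carrying `schema_version` and the scoring-convention
flags, making `read(write(x)) == x` exact; files without it are accepted
with defaults inferred. Missing assessments are absent rows — a blank
severity cell is an error naming the row and column, as is any out-of-range
value. Unknown columns ride along as passthrough metadata. Simulation
configs serialize to YAML mirroring `SimulationConfig`, including the full
per-item parameter set.

## Numerical and testing notes

All scoring and conversion arithmetic is exact integer or small-float work;
tolerances in tests are `pytest.approx` defaults except where a property is
stochastic, where windows come from the calibration targets (ρ ∈
[0.85, 0.95]; means within ±25 % of the reference moments, averaged over
10–20 seeds) or from the null distribution of the statistic (|ρ| < 0.05 on
~5 000 pooled stationary pairs). Test problem sizes — a 215-subject default
cohort, a 50-subject cohort for quadratic-cost oracle checks, the full
64×16 (total, count) lattice — keep the whole suite under half a minute
while leaving the brute-force oracles exhaustive where they are exhaustive.
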