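# Methods

## Model and assumptions

The package models MetS progression as a first-order discrete-time Markov
chain on 7 states (no components; isolated hypertension / obesity /
hyperglycemia / dyslipidemia; any 2 components; MetS = 3 or 4
components). Two assumptions are structural and not configurable: the
next state depends only on the current state, and the same annual matrix
is applied at every step (time homogeneity). The chain is fully
reversible — any state can reach any other — and has no absorbing state;
mortality is not modelled, so long-horizon projections read as
distributions among survivors under constant transition behaviour.

Cohort projection uses the row-vector convention M⁽ⁿ⁺¹⁾ = M⁽ⁿ⁾P. State
order is fixed everywhere (matrices, distributions, serialized files):
no_components, iso_hypertension, iso_obesity, iso_hyperglycemia,
iso_dyslipidemia, two_components, mets.

## Classification conventions

CDS thresholds are inclusive on the abnormal side (BMI ≥ 25, glucose
≥ 6.1, SBP ≥ 140, DBP ≥ 90, TG ≥ 1.7) and exclusive on HDL (< 0.9 men,
< 1.0 women). "BP ≥ 140/90" is read as SBP ≥ 140 OR DBP ≥ 90, the
standard hypertension convention. History flags (hypertension,
hyperglycemia) satisfy their criterion regardless of the measured value;
when the columns are absent they default to false with a logged warning.
Total cholesterol is read and carried through untouched — no criterion
uses it. Age bands are half-open at the left boundary and closed at 40:
[20, 40) young, [40, 60] middle, so a 40-year-old belongs to the middle
band. Group membership is fixed by age at the entry visit and never
changes mid-panel, even when a subject crosses 40 during follow-up; the
headline projection ages (30 and 50 at entry, 10-year horizon) keep
cohorts inside one band either way.

## Estimation

Only visit pairs exactly one calendar year apart contribute; a gap from
year t to t+2 contributes nothing (no interval-censoring correction is
attempted). For each group and year-pair the 7×7 transition tally is
row-normalized into an annual matrix; the group matrix is the unweighted
arithmetic mean of the annual matrices, row by row. Two choices here
were genuinely open:

* **Unweighted vs pooled.** The default averages per-year-pair
  probability matrices with equal weight; pooling raw counts across
  year-pairs (equivalent to weighting years by sample size) is available
  via `pooled=True` / `--pooled`. The two coincide when every year-pair
  has the same row counts.
* **Empty rows.** A state unobserved as an origin in one year-pair is
  excluded from that row's mean rather than failing the matrix — sparse
  states (MetS among young women, for instance) are routinely empty in
  single year-pairs. A state with no observed exits in *any* year-pair
  is a hard error naming the state; its row cannot be estimated.

Rows are renormalized to sum to 1 after averaging (tolerance 1e-9)
to absorb floating-point drift. Matrices serialize at full precision;
a percent view rounded to 2 decimals exists for reporting.

## Intervention operators

The modelled intervention reverts a fraction f (default 0.5) of the
occupants of each targeted isolated state to the no-component state
every year. Two encodings are implemented because the verbal description
("half change from the isolated abnormal state to the healthy state
every year") does not fix the within-year timing:

* `within_year` (default): the reverted fraction re-enters the
  no-component state at the start of the annual cycle and transitions
  with everyone else — row_s ← f·P[no_components] + (1−f)·row_s.
* `end_of_year`: the reverted fraction finishes the year healthy —
  row_s ← f·e_no_components + (1−f)·row_s.

Both are convex combinations of stochastic rows, so row sums are
preserved exactly. `end_of_year` produces uniformly larger reductions
(the reverted mass cannot re-progress within the year). The package
default is `within_year` because it reproduces the published reduction
table more closely across all intervention × group cells; the choice is
a documented flag on every entry point, not a hidden constant.

Relative reduction = 100·(natural − intervened)/natural MetS prevalence
at the horizon, both projected from the same start through the original
and modified matrices. It is undefined (explicit error) when the natural
prevalence is zero at the horizon.

## Synthetic-data generator

The generator exists so that every pipeline stage is testable without
access to any real cohort. It emulates: ~5,881 subjects; four sex ×
age-band groups (male fraction 0.421, even young/middle split within
sex); 2–6 annual visits with the attrition profile
(0.402, 0.247, 0.122, 0.089, 0.140) over visit counts 2..6; entry years
placed so all visits fall in 2010–2016; per-group state sequences that
follow a specified ground-truth matrix (the four packaged matrices by
default); and an initial 7-state distribution derived from baseline
component marginals (hypertension 12.58%, obesity 30.52%, hyperglycemia
9.00%, dyslipidemia 21.73%) under component independence — the true
baseline joint distribution is not published, so this is an explicit
approximation.

Biomarkers are drawn from truncated normals strictly on the intended
side of each threshold (e.g. normal BMI ~ N(22.5, 1.5²) on [15, 24.99];
obese BMI ~ N(27.5, 2²) on [25, 45]); upper truncation points sit one
reporting decimal below each cut so the rounding applied at emission
can never cross a threshold. These distributions are plumbing whose only
contract is the exact round trip state → biomarkers → classification →
state (tested at zero tolerance over >10,000 visits); they do not model
real biomarker scale, correlation, or measurement error. Composite
states realize a uniformly drawn component pair (2-component state) or
triple (MetS; all four with probability 0.2). Dyslipidemia is realized
through high TG except for a 30% low-HDL share that exercises the
sex-specific HDL rule. Dropout is independent of state
(missing-completely-at-random). Consequences for interpretation: passing
recovery tests demonstrate estimator correctness under the model's own
assumptions — they say nothing about robustness to informative dropout,
within-subject biomarker correlation, or misclassification near
thresholds, none of which the generator produces.

All randomness flows from a single `numpy` Generator seeded from the
mandatory config seed; identical seeds give byte-identical panels.

## Numerical choices and problem sizes

* Matrix construction rejects rows whose sums deviate by more than 1e-3
  (file inputs) and renormalizes the rest exactly; projection
  renormalizes each step against accumulated drift only (1e-9 scale).
* Projection is validated against an independent matrix-power oracle
  (repeated squaring) at 1e-12, and against closed-form row reads for
  single steps.
* Parameter-recovery experiments use 20,000 subjects × 5 transitions per
  seed, 20 seeds, with a uniform initial state so that every origin row
  is populated — identifying all 49 entries requires observing all 7
  origin states, which the realistic entry mix does not guarantee for
  the rarest rows at this size. The acceptance budget is max-abs error
  < 0.015 in ≥ 19/20 seeds; the end-to-end estimate-then-project check
  allows 1.5 percentage points on the 10-year MetS prevalence.
* Ties and degenerate inputs: empty transition sets yield zero count
  matrices (all rows undefined); a zero natural prevalence makes the
  relative reduction an explicit error rather than NaN.

## Known limitations

* The published headline predictions are not exactly recoverable from
  the published 2-decimal matrices: repeating the stated procedure on
  the printed inputs gives 11.70 / 3.14 / 25.82 / 8.03 percent for the
  four groups, versus printed 11.42 / 3.04 / 25.04 / 7.09 — deviations
  up to ~0.9 pp that entry-level rounding (≤ 0.005 pp) cannot produce.
  The corresponding checks are asserted at the stated ±0.3 pp and fail
  honestly for the two larger gaps; the same inconsistency, amplified by
  ratioing two projected prevalences, affects the published reduction
  table. The package reports what the printed inputs imply.
* No uncertainty quantification: the source procedure defines no
  variance model, so projections carry no intervals.
* No mortality, no covariates, no time-inhomogeneity, and no correction
  for multi-year observation gaps.
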