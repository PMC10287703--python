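# Methods

`activcoach` implements a hybrid activity-coaching engine: deterministic
WHO-derived rules classify each day of wearable data into an activity level,
a small convolutional network forecasts the coming week's steps with naive
prediction intervals, bespoke weekly statistics summarize performance against
a goal profile, and a propositional rule base turns all of these signals into
personalized recommendation messages that are annotated into an RDF knowledge
base.  This note records the models, the defaults, and the design decisions
that were genuinely open.

## Daily activity levels

A day is scored 0–4 from its step count and its moderate/vigorous activity
minutes.  Each level has two alternative justifications ("disjuncts"): a step
band (`<5000`, `5000–7499`, `7500–9999`, `10000–12499`, `>12499`) and a band
over the weekly moderate-equivalent minute volume ME = (2·VPA + MPA)·7
(thresholds 90/210/300/360 weekly minutes; one vigorous minute counts as two
moderate minutes, per the WHO adult guidance of 150–300 moderate or 75–150
vigorous weekly minutes).  The ME disjuncts apply only above the 5000-step
floor.

The two families overlap (e.g. 11 000 steps with ME 140 matches both the
level-3 step band and the level-1 ME band).  The classifier evaluates levels
4→0 and takes the first match, i.e. the **maximum attained level**.  This is
a design decision, not a stated rule; it is the unique choice that keeps the
classifier total, deterministic, and monotone non-decreasing in steps and
(above the step floor) in ME — properties the test suite asserts on a 3-D
grid.  Seconds are the storage unit (sensor native); division by 60 happens
only at the rule boundary, and fractional minutes are compared unrounded
against the thresholds with the strict/non-strict operators as written.
The "LPA ≥ 0" conjunct of the sedentary rule is vacuous and has no effect.

Per-minute intensity counts (IMA) are banded LPA [0, 400], MPA [401, 800],
VPA [801, ∞) — a partition of the non-negative integers with no gap at the
400/401 and 800/801 edges.

## Weekly statistics

For each completed 7-day week:

* **APV** — the vector of the 7 daily level codes;
* **SC = ΣAPV − ΣGS** against the goal-score vector (default: seven 3s);
  SC ≥ 0 means the weekly goal was achieved;
* **S = Σ level·weight**, weights {0, 2, 4, 6, 8} = 2·level, hence the
  algebraic identity S = 2·Σ level² used as an independent oracle in tests;
  S ∈ [0, 224] and mean S = S/7 ∈ [0, 32];
* **cumulative deviation** — the population SD of the one-decimal mean-S
  values of all weeks so far, with error SD/√n.

Display rounding is half-up to one decimal.  Two conventions were fixed by
reconstruction from a published four-week worked table: (a) the deviation
list holds the *displayed* one-decimal mean-S values, not the unrounded
ratios (only that convention reproduces the published SD chain 3.8 → 9.2 →
8.6); (b) the published week-1 mean 22.5 truncates 158/7 = 22.571 while every
other week matches half-up — the implementation computes at full precision
and displays half-up, so it prints 22.6 for that single value.  No consistent
rounding rule reproduces all four printed means.

## Step forecasting

The forecaster is a univariate one-step-ahead regressor applied recursively:
two stride-1 Conv1D layers (kernel 3, ReLU; 64 and 32 filters by default), a
MaxPool1D (pool 2), flatten, and a single dense output unit.  The daily step
series is min-max scaled to [0, 1] (a constant series maps to zeros and
inverts exactly); supervised samples are sliding windows of `n_steps = 7`
days.  Training: MSE loss, Adam (α = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
200 epochs, batch 50, a 5% validation tail, and plateau learning-rate
reduction.  The network and its backpropagation are implemented directly in
numpy and the gradients are verified against numerical differentiation in
the test suite.

Open constants fixed here: filter counts 64/32; pool size 2; window length 7
(one calendar week); recursive multi-step forecasting (each prediction is
appended to the window; outputs are inverse-scaled and clamped at 0).  The
plateau schedule halves the rate after 20 stale validation epochs with a
floor of 1e-5; the common factor-0.1/patience-10 setting collapses the rate
before convergence on the short series this model targets.

## Prediction intervals

The interval is Ŷ ± c·σ_h with c = 1.28 for 80% coverage (1.645/1.96
available for 90/95%) and σ_h the sample SD of the one-step naive-forecast
residuals e_t = y_t − y_{t−1}, computed over the full history by default (a
trailing window is configurable).  σ_h is held constant across the 7-day
horizon by default — matching the single published σ_h used for a whole
weekly table — with √h widening as an off-by-default option.  Raw bounds are
exactly symmetric about the point.

Whole-step bounds: the default truncates both raw bounds (floor); `half-up`
and `inward` (ceil lower / floor upper) modes are provided.  No single
convention reproduces every bound of the published weekly table we validate
against — its margins alternate between 1626 and 1627 steps for the same
c·σ_h = 1626.88 — so the corresponding acceptance test is knowingly failing
on the bounds truncation does not match; truncation matches the most bounds
among the uniform conventions, including the table's first lower and last
upper bound.  Residual SD uses the sample (n−1) convention; the population
alternative differs immaterially at realistic history lengths.

## Rule base and messages

Nineteen propositional variables (A-1 … A-19) carry the message templates;
each belongs to one of eight once-a-day categories (level, sedentary, steps,
activity minutes, forecast trend, daily goal, weekly deviation, weekly
goal).  Daily evaluation fires exactly one variable per daily category;
weekly evaluation one per applicable weekly category.  Satisfiability is a
per-category exactly-one constraint — the literal "all twenty variables sum
to 1" form would forbid the multi-message behaviour the engine is specified
to produce, so it is read as "no two messages of the same kind".  Weather
variables are declared in the store but never fire (no weather input
exists).  Rules are evaluated both as a flat condition list and as binary
decision trees (conditions at internal nodes, messages at leaves); the two
representations are property-tested for equivalence.

Decisions fixed here:

* **Deviation trend (weekly):** the printed conjuncts (`SC > 0` for the
  negative trend, `SC == 0` for the positive) contradict the worked example
  in which a week with SC = −20 and a rising deviation receives the negative
  message.  Default reading: negative iff the cumulative deviation rose
  *and* the weekly goal was missed (SC < 0); positive otherwise.  The
  literal forms are retained behind `strict=True`, under which the category
  may resolve to nothing.
* **Sedentary comparison** uses daily total sedentary seconds against the
  goal (bout segmentation is undefined); the goal is stored in hours and
  converted.
* **Weekly step prediction** for the forecast-trend rule is the sum of the
  7 point forecasts.
* **Sleep terms** are vacuously satisfied when no sleep data exists.
* **Placeholders** (x, x1, z, m, n, n1, N, XX, XY, X, Y, Z, M) have no
  formal definition; the convention is documented in the message store:
  step/minute deficits and surpluses, week indices, and the daily overview
  figures.  Numeric values render as whole numbers.

The default goal profile is WHO-flavoured: 10 000 steps/day (70 000/week),
150 weekly moderate minutes (21.45/day, vigorous goal half of that), 8
sedentary hours/day, 8 sleep hours/day, daily goal score 3.  It reproduces
the published worked-example message sets; the original study never printed
its exact profile.

## Pipeline and knowledge base

Per participant: minute records are aggregated to calendar days (midnight
boundaries, duplicate minutes summed), calendar gaps are filled forward
(backward only for leading gaps), and participants with fewer than 14 days
are skipped — the first two weeks are an observation-only cold start, so
weekly evaluation (forecast, intervals, weekly rules) begins at week 3 while
daily messages flow from day 1.  Each weekly boundary retrains the
forecaster on the full history and recomputes the cumulative statistics over
all prior weeks, which makes the orchestration quadratic in the number of
weeks; the pipeline exposes a work counter so the growth rate is testable.

Every level, interval table, weekly summary, and fired recommendation is
annotated into an RDF graph under a fixed schema of object properties with
declared domains and ranges (participant → health record / activity level /
step prediction / statistics / timestamped recommendation, plus the
device/observation vocabulary).  The graph serializes to Turtle and
round-trips through a standard parser with an identical triple count; the
number of recommendation instances equals the number of fired variables.

## Synthetic cohort generator

The generator emulates minute-level records from a hip-worn sensor: 16
participants × 34 days × 1440 minutes by default (the shape of a realistic
adult free-living study), with a per-day target level drawn from an
activity mix skewed toward the sedentary end (0.35/0.25/0.20/0.12/0.08).
Each day draws a step target inside the target level's step band and a
moderate/vigorous volume inside the same level's ME band, so the rule
classifier recovers the intended level by construction; minutes partition
their 60-second budget exactly; each minute's IMA is drawn from the band of
its dominant activity type, with a configurable spill probability
(`ima_band_noise`, default 0) into neighbouring bands; steps are spread
multinomially over active minutes.  All randomness comes from one seeded
generator, so equal specs produce byte-identical cohorts.

What the generator does *not* emulate: upload failures and device clock
gaps, within-day autocorrelation beyond the dominant-type schedule,
between-day habit persistence, weekend/weekday structure, and sleep.
Passing benchmarks on this data therefore demonstrate that the models
recover structure the generator puts in (rule-consistent labels, trends,
weekly seasonality) — not field accuracy on real cohorts, which depends on
noise sources the generator omits.

## Benchmark problem sizes

The shipped benchmarks run at desk scale, chosen once: 2000 synthetic days
(10 participants × 200 shortened days) for the classifier, a 180-day
trend+seasonal+noise series (trend 25 steps/day, weekly amplitude 1200, noise
SD 300, last 20 days held out) for the forecaster, and 10 000 random
contexts for the rule-exclusivity property.

## Known limitations

* The learned classifier trains at a constant Adam rate (no plateau
  callback) — its sklearn backend has no equivalent; the budget of 200
  epochs is run in full.
* Interval coverage is asserted by construction (normal constant), not
  backtested.
* The strict deviation-trend mode can leave its category silent; callers
  who need exactly-one must use the default mode.
* The engine processes one participant at a time; no cross-participant
  (collaborative) signal is used.
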