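# Methods

`unprofit` implements an end-to-end analysis of whether prescription-drug
utilization indicators predict health-insurance enrollee *unprofitability*
under Marketplace-style plan payment, using a convex super learner
evaluated by nested cross-validation, exercised on a synthetic claims
cohort.  This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic experiments do and
do not establish.

## The outcome: unprofitability under risk adjustment

Each enrollee has an annual total cost `C_i` and a diagnosis-based risk
score `S_i > 0`.  Under community rating with competitive pricing, every
plan charges the market-average premium `M_i = C̄`.  Risk adjustment
transfers `A_i = (S_i/S̄ − 1)·C̄` move revenue toward plans with sicker
enrollees; revenue is `R_i = M_i + A_i`, profit `F_i = R_i − C_i`, and the
prediction target is unprofitability

    U_i = −F_i = C_i − C̄·S_i/S̄ .

Three identities follow algebraically and are enforced as tests: the
transfers sum to zero, `mean(U) = 0` for every cohort (the plan breaks even
in aggregate), and `F_i = −U_i` exactly.  Premium variation by age,
geography or smoking status is deliberately excluded — it would break the
mean-zero identity that makes the outcome interpretable as *relative*
profitability — and no configuration option is offered.  A single-enrollee
cohort is allowed (with a warning); its unprofitability is identically
zero.  Monetary arithmetic is double precision; identity tests use a
relative tolerance of 1e−8 on the cohort's cost scale.

## The prediction machinery

### Candidate library

Five algorithms are crossed with three variable sets, giving K = 15
candidates with field-style ids `<tag>.<set>` (`nnet`, `lasso`, `ridge`,
`tree`, `glm` × `f`/`g`/`l`):

* **nnet** — a neural network with a single hidden layer of two units
  (L-BFGS, max 100 iterations, weight decay 1e−4).  Inputs are binary and
  are not standardized; the dollar-scale outcome is centered and scaled
  internally for optimizer stability and predictions are back-transformed.
  Initialization is seeded from the run seed.
* **lasso** — L1-penalized regression with the penalty chosen by internal
  10-fold cross-validation over a 100-knot log grid, taken at the CV
  minimum (not one standard error).
* **ridge** — L2-penalized regression with the penalty chosen by exact
  leave-one-out cross-validation over a 17-point log grid (1e−2…1e6).
  LOO was chosen over 10-fold because the closed form (one Gram
  eigendecomposition shared by the whole grid) is several times faster at
  the scale of the nested evaluation and is itself a cross-validation; the
  selected penalties agree closely in practice.
* **tree** — a regression tree with ANOVA (variance-reduction) splitting
  and rpart-style controls: complexity parameter `cp = 0.01` (a split must
  reduce total SSE by 1% of the root SSE), minimum split size 20, minimum
  leaf size 7.
* **glm** — main-terms linear regression; collinear columns are resolved
  by a pseudoinverse least-squares solution.

Any learner that fails (or faces a constant outcome) degrades to a
mean-predicting fit with a warning rather than aborting a run.

### Variable sets

The *full* set contains every atomic indicator: therapeutic-class
indicators plus generic-status and maintenance-category flags (252 columns
under the default vocabulary).  The *groups* set is the parsimonious
alternative: therapeutic-group indicators (the OR of their member classes)
plus the same generic and maintenance flags (44 columns).  The *screened*
set is selected per fold by the capped lasso below.  Placing the generic
and maintenance flags in the screener's candidate pool mirrors the
published analysis, whose screened set contained generic indicators
alongside therapeutic classes.

### Capped lasso screener

The screener walks the lasso regularization path (100 knots, log-spaced
from the smallest penalty with an empty active set down to 1e−3 of it) from
large penalties downward and returns the largest active set of size at
most ten.  When several variables enter simultaneously and jump the active
set past the cap, the screener backs off to the larger-penalty knot — the
tied entrants are the excluded variables; in the extreme case where the
first entrants already exceed the cap, the selection is empty.  The
selection is then unioned with the forced indicators (HIV antivirals and
multiple-sclerosis biologicals), so the post-augmentation set has at most
`cap + 2` columns.  The intercept is unpenalized and never counts against
the cap; binary predictors share a scale and are not standardized.  The
screener involves no randomness: it is a pure function of the fold's
training data.  One screened set is computed per cross-validation fold and
shared by the three `.l` learners — the screener defines a variable set,
not a per-learner step — and the full-data refit re-screens on all rows.

### Stacking

Out-of-fold predictions from V = 10 stacking folds form the n×K matrix Z.
The ensemble weights solve the simplex-constrained least squares

    α̂ = argmin ‖U − Zα‖²  s.t.  α ≥ 0, Σα = 1,

via SLSQP on the precomputed Gram with an analytic gradient, a uniform
start, and an exact post-check that the solution beats every single-learner
vertex (the convexity guarantee is therefore assertable, not approximate).
Columns that are all identical yield uniform weights with a warning.
NNLS-plus-normalization, the other common metalearner, coincides with this
solution in the well-behaved cases but not in general; the constrained QP
is the form that exactly honors the convex-combination definition.  The
final predictor refits all K learners on the full data and combines them
with α̂.  Fold assignment is simple random with balanced sizes (differing
by at most one), not stratified.

### Nested evaluation

Because the weights are themselves data-adaptive, performance is measured
by wrapping the *entire* super learner in an outer 10-fold CV: each outer
training set runs inner folds, per-fold screening, weight estimation and
refits, then predicts its outer validation fold.  Pooled out-of-fold
predictions give `CV MSE = Σ(U_i − Z_i)²/n` and
`CV R² = 1 − Σ(U_i − Z_i)²/Σ(U_i − Ū)²` for the ensemble and every
candidate (each candidate's outer-fold refit predictions come from the
same pass), plus relative efficiencies `CV R²_k / CV R²_SL`.  R² is pooled
across folds, not averaged per fold; negative values are reported as-is.
The falsification harness replaces the outcome with a Gaussian draw
matching the empirical mean and SD of U but independent of every
predictor — its nested-CV R² must be indistinguishable from zero, making
it a leakage alarm for the whole pipeline.  The Gaussian marginal is a
documented choice; any predictor-independent outcome would do.

Residual diagnostics flag observations whose residual lies more than six
scaled MADs (1.4826 × median absolute deviation) from the median residual,
surfacing the catastrophic-cost outliers the generator plants.

## The synthetic cohort generator

The generator emulates the structure of a large commercial-claims cohort
so that every stage is testable without proprietary data.

**Vocabulary.** 239 therapeutic classes partitioned into 31 groups
(contiguous blocks, sizes differing by at most one), 8 generic-status and
5 maintenance-category flags, each class mapped to one flag of each kind.
Two classes are designated forced: HIV antivirals and MS biologicals.
All sizes are configurable; construction is deterministic.

**Drug use.** An enrollee is a drug user with probability 0.7 (so ~30%
have no drug utilization at all).  Within each group a latent "condition"
Bernoulli(0.3) induces positive within-group correlation: class `c` fires
with probability `p_c(1 − ρ + ρ·L_g/0.3)`, preserving the marginal rate
`p_c` (defaults: geometric from 0.12 down to 0.002 among drug users,
ρ = 0.4).  Group indicators are the OR of member classes.

**Costs.** Total cost is a sum of non-negative parts: a zero-inflated
lognormal base (positive with probability 0.85, mean $3,800 shifted
mildly by age and sex, σ = 1.6), a lognormal drug-user baseline (mean
$500), additive class effects `δ_c` with mean-one Gamma(2) noise, and a
rare Pareto catastrophe (rate 2e−6, minimum $2M, tail index 2.5) standing
in for the multi-million-dollar spenders seen in real claims.  Default
`δ_c` runs geometrically from $60 to $2,500, with twelve designated
residual-signal classes at $3,000 and HIV/MS at $24,000/$42,000.  Under
these defaults mean cost is ≈ $6,600 with SD ≈ $13,500, and
drug-attributable spending (the drug baseline plus 30% of class effects)
is ≈ 18% of total spending.

**Risk scores.** The risk index is the enrollee's expected cost with each
class effect attenuated by its *capture* `κ_c ∈ [0,1]` — the fraction of
that class's cost effect the risk-adjustment formula "sees" — plus
Gaussian noise (SD $1,500), floored at $100 and rescaled to mean one.
With `κ_c = 1` everywhere and no noise, users and non-users of any class
have equal expected unprofitability: risk adjustment fully neutralizes
selection.  With `κ_c < 1` a class carries residual signal
`≈ (1 − κ_c·C̄/s̄)·δ_c` — the phenomenon the pipeline exists to detect.
Defaults: κ = 0.97 for most classes, 0.30 for the twelve residual classes,
0.50 for HIV/MS, giving a predictable share of Var(U) of roughly 2% —
deliberately the regime the analysis targets: risk adjustment that works
well but imperfectly.  The external diagnosis-to-score formula is not
reimplemented; it is regulation, not part of this analysis.

**Demographics** (age ≈ N(42,13) clipped to 18–64, 49% female) shift the
cost base and are fully captured by the risk index; they are emitted for
summary reporting only and never used as predictors.

**Data preparation** mirrors the study: indicator columns with no positive
claims are dropped, as are group indicators that aggregate a single
surviving class (duplicates of that class).  The class→group mapping
survives; only the redundant indicator column is removed.

All randomness flows from one integer seed through named substreams
(demographics, drug use, latents, classes, costs, outliers, risk noise,
inner folds, outer folds, net initialization, falsification outcome), so
cohorts and entire runs are bit-reproducible.

### What the generator does and does not establish

Passing tests on this generator show the *pipeline* is correct: the
payment identities hold, screening respects its cap and leaks nothing,
the stacking weights solve the stated program, nested CV is leakage-free,
and planted effects are recovered at the configured magnitude.  They do
not show anything about real claims data: the generator's class effects
are additive, its within-group dependence is a single latent factor, its
cost tail is a parametric mixture, and its risk scores derive from the
same linear index as its costs.  Real diagnosis-based risk scores,
utilization dependence and cost dynamics are richer; headline real-data
quantities (e.g. the published ensemble R²) are not reproduction targets
here.

## Problem sizes

Test and demonstration runs use cohorts of a few hundred to 20,000
enrollees with the full 15-learner library, and 200,000 enrollees for
moment-recovery checks that need tight simulation error; these sizes give
stable estimates of every tested quantity on a single CPU.  The
falsification experiment is run at n = 20,000 with both CV layers at 10
folds, with additional smaller-cohort replications across seeds.

## Known limitations

* The generator's correlation structure is exchangeable within groups; it
  cannot represent cross-group comorbidity patterns.
* The screener's "back off past simultaneous entrants" rule is exercised
  only on constructed ties; with continuous-ish data the path almost
  always passes through an active set of every size up to the cap.
* The two-unit network is trained once per fit (no restarts); with a
  fixed seed this is reproducible but can land in a poor local optimum on
  small folds — the stacking weights then simply down-weight it.
* Relative efficiency is undefined when the ensemble's CV R² is zero; it
  is reported as missing rather than clipped.
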