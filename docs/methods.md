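# Methods

`playcog` re-implements, as a tested and reusable pipeline, the analysis
of a tablet-based gamified cognitive assessment for preschool children:
raw touch telemetry from nine mini-games is turned into a feature matrix,
a stacked ensemble trained with repeated cross-validation predicts the
child's raw benchmark cognitive score (the cognitive subscale of a
standardized developmental instrument, administered concurrently), and
the predicted score is evaluated for agreement, discrimination and bias.
Because no public telemetry of this kind exists, the package ships a
first-class synthetic-cohort generator with a known latent ability, so
every stage is testable end to end and calibration properties (parameter
recovery, null behaviour) can be asserted rather than assumed.

## The game schema

Nine games, each with 2–6 difficulty levels and 40 levels in total.  A
level has a timer (default 60 s) and an advance threshold (default 5
correct responses); completing a level unlocks the next, so attrition is
informative.  The per-game level counts are not publicly documented; the
defaults (2, 2, 4, 6, 6, 6, 3, 5, 6 for single tap, alternate tap, pop
the balloons, grouping, hidden objects, odd one out, matching shapes,
jigsaw, left–right) satisfy every published constraint — nine games, 2–6
levels each, 40 total, matching shapes reaching at least level 3 and
jigsaw at least level 5, since named features reference those levels.
All of this is configurable through a YAML override.  Telemetry
timestamps are milliseconds from level start; event logs are JSON-lines
(one level session per line) because the original backend format is
undisclosed.

## The generative model (synthetic cohorts)

The generator is intentionally the simplest model producing every
statistical structure the downstream analysis relies on:

* **Latent ability** `theta ~ N(0, 1)` per child.
* **Correctness**: each gesture is correct with probability
  `logistic(a * theta - b_l)`, a one-parameter item-response curve with
  game discrimination `a` (default 1.2) and level difficulty
  `b_l = -1.0 + 0.8 (l - 1)` increasing with level index.  Together with
  the unlock rule this yields ability-graded accuracy *and* attrition.
* **Tempo**: inter-gesture gaps are lognormal with mean
  `1.5 * exp(-0.25 * theta)` seconds (sigma 0.5) — stronger children play
  faster, so latency/playtime/activity features carry signal.  8% of
  events are stray "background" touches.
* **Engagement**: a child is engaged with probability
  `logistic(c + theta)`; engaged children attempt every game,
  non-engaged ones only a short prefix (geometric, capped at eight
  games).  The intercept `c` is solved numerically (Gauss–Hermite
  quadrature + Brent root) so the population fraction attempting all
  nine games is 0.955, the observed engagement rate in the field study
  this emulates.  Whole-game non-attempt therefore concentrates in
  low-ability children.
* **Outcome map**: `score = round(clamp(70 + 5.5 (rho * theta +
  sqrt(1 - rho^2) eps)))` on the integer support [57, 88] — a 31-point
  raw-score range.  Default `rho = 0.75`, chosen so the fitted pipeline
  lands in the observed r ≈ 0.67 regime; this is a calibration knob, not
  a claim about the instrument.  A fine-motor score is generated
  analogously with `rho = 0.5`, and a smartphone-exposure flag is
  Bernoulli(0.57), independent of everything else — the null that the
  downstream exposure-bias test is calibrated against.

Event-level sampling uses sub-streams keyed per (child, game, level), so
with a fixed input generator state the same uniforms drive outcomes at
every ability value — a common-random-numbers coupling under which
correct counts, completions and levels played are provably non-decreasing
in `theta` (asserted by tests).

What the generator does **not** emulate: demo-mode assistance, assessor
behaviour, household context, real tap-rate distributions (no public
distributional facts exist for those), or any dependence of exposure on
gameplay.  Passing tests therefore demonstrate that the *pipeline*
recovers structure it is pointed at, not that the real instrument has any
particular accuracy.

## Feature engineering

Stages, in fixed order (all counts reported per run in a composition
report):

1. **Tablet stage**: per level — counts of correct/incorrect
   clicks/drags (by the game's gesture), background events, first/last
   event timestamps, latency (first correct response, ms) and the
   timestamp at which the advance threshold was met.
2. **Derived stage**: per level — `accuracy_cbyi` (correct / (correct +
   incorrect)), `accuracy_cbyt` (correct / all events), `correctrate`
   (correct per second of playtime), `playtime`, `completion_time`
   (threshold time, else the level timer), `activity` (events per
   second); per game — `levels_played`, `av_*` means and `total_*` sums
   over levels; a pair aggregate for the two drag-heavy puzzle games
   (`msjig_*`); across games — `sum_all_levels_played`,
   `sum_completion_time`, `sum_total_accuracy_cbyt` and related sums.
3. **Imputation** of unattempted levels: accuracy-family and rate
   features 0, completion time and latency the level timer, counts 0;
   aggregates are then recomputed from the filled per-level values, so a
   missed level contributes the maximum completion time to
   `sum_completion_time`, as the assessment scoring intends.
4. **Skew transform**: adjusted Fisher–Pearson skewness; columns with
   skew > 1 are square-rooted after shifting the minimum to zero
   (renamed `*_sqrt`), skew < −1 squared (`*_sq`); applied once, never
   iterated.
5. **Correlation pruning** at |r| > 0.9, greedy left-to-right in column
   order (the published rule states only that correlated features were
   dropped; a deterministic order is required for reproducibility).
   Zero-variance columns correlate with nothing and are retained with a
   warning.
6. **Interaction terms**: all pairwise products and both-direction
   ratios of a 20-feature subset (default: the 20 training features most
   correlated with the outcome; the original subset came from an
   exploratory run that is not reproducible).  Candidates undefined
   (zero denominator) in ≥15% of fit rows, or with |r| > 0.9 against any
   retained column, are dropped; "null" is interpreted as
   undefined-before-imputation, and surviving ratios have residual
   undefined cells filled with 0.
7. **mas-o-menos**: the sign-averaged standardized composite — each
   column standardized with training statistics, weighted ±1 by the sign
   of its training correlation with the outcome, averaged.
8. **PCA**: components fitted on standardized training rows; the
   smallest number of leading components reaching 70% cumulative
   explained variance is appended (capped at the matrix rank).
9. Final standardization with training statistics.

**Leakage policy.** Every data-dependent fit (interaction subset,
mas-o-menos weights, PCA loadings, scaling, pruning correlations) is
computed on the training rows of the 70/30 split and applied unchanged to
held-out rows.  The original description applies these steps before
mentioning the split, which is ambiguous; the default here is the sound
choice, and `paperlike=True` reproduces whole-dataset fitting for
replication.  A test asserts that perturbing held-out children never
changes training-row feature values.

## The stacked ensemble

* **Split**: random 70/30 by seed (140/60 at n = 200).
* **Grid**: 7 feature selectors × 5 learners.  The original selector
  list is unpublished; the registry defaults are univariate-correlation
  top-k, lasso path, elastic-net path, random-forest importance,
  gradient-boosting importance, recursive feature elimination with a
  linear model, and greedy mRMR — each capped at 15 features.  Learners:
  linear regression, random forest, RBF support-vector regression,
  gradient boosting (xgboost), and logistic regression.  The logistic
  learner's role in a score regression is not documented; here the
  outcome is dichotomized at the training 25th percentile and the fitted
  probability of scoring above it is rescaled linearly onto the score
  support.  Hyperparameters are fixed, recorded defaults; there is no
  per-fold tuning because none is described.
* **Repeated CV**: k-fold (default 10×10; the heavy acceptance runs use
  2 repeats) with fold-specific selector runs shared by all learners in
  the fold.  Out-of-fold predictions are averaged over repeats (the
  standard stabilizer implied by repeating for stability), and each grid
  cell is scored by the Pearson correlation of those predictions with
  the outcome.  A failing selector or learner marks its cell failed and
  excluded from ranking.
* **Top-5** by holdout correlation; ties broken by fewer selected
  features, then lexicographic name.
* **Stacking**: the 5 out-of-fold prediction vectors form the design
  matrix for three meta-learners — linear regression, a depth-limited
  random forest, and a shallow gradient-boosted model — fitted against
  the training outcome.  Base models are refit on the full training set
  for test-time prediction (the alternative, fold-ensembles, is not
  used).  The final score is the fixed weighted average
  `0.25 * LR + 0.25 * RF + 0.50 * XGB`, clamped to the score support.
* **Exclusion rule**: a child who never attempted a game that
  contributes any feature to the five base models cannot be scored and
  is listed as excluded rather than imputed (mirroring the 195/200
  behaviour of the original cohort); within-game missing levels are
  imputed normally.
* **Training-set scores**: the stacker stage is itself cross-validated
  (10-fold over the out-of-fold design) when producing training
  predictions, because the gradient-boosted stacker's in-sample fit
  would otherwise inflate the reported training agreement.  Test-time
  prediction uses the stackers fitted on the full design.

## Evaluation

* Pearson r with the Fisher-z interval; ICC(2,1) — two-way random
  effects, absolute agreement, single measures — from the explicit
  two-way ANOVA mean squares, with the F-based confidence interval (the
  original reports only "95% CI"; the F-based interval is the standard
  choice, and the implementation is cross-checked against both a
  brute-force ANOVA oracle and an independent statistics package).
* MAE, RMSE and mean bias (prediction − benchmark), each with the sample
  SD of the per-child quantity it averages (absolute errors, squared
  errors, signed errors); the published "(SD)" column is ambiguous for
  RMSE and this choice is documented rather than guessed at.
* Bland–Altman points and 1.96-SD limits of agreement.
* ROC: the positive class is a benchmark score strictly below the
  training-sample 25th percentile (nearest-rank); the decision threshold
  maximizes sensitivity + specificity on the training scores (ties → the
  lower threshold); AUC uses the Mann–Whitney midrank construction (ties
  count one half), cross-checked against all-pairs counting and
  trapezoidal integration.
* Exposure bias: pooled-variance two-sample t-test of prediction errors
  by smartphone exposure.  Fine-motor bias: Pearson correlation of
  errors with the fine-motor score, with r² as variance explained.
* Floor/ceiling: levels-played distributions of the <25th and >90th
  percentile benchmark groups, with the two headline counts (low scorers
  playing <10 levels; high scorers not attempting all 40).

## Acceptance-scale choices

The published headline numbers were computed on an unreleased 200-child
cohort, so the acceptance suite asserts structural and calibration
properties instead, at sizes chosen for useful power at desk scale:

* parameter recovery and train/test comparability run at the study's
  n = 200 with 2 CV repeats over the full 7×5 grid (seeds 0–9);
* the null-calibration runs (outcome independent of gameplay) use
  n = 500 cohorts and a reduced 3-selector × 2-learner grid with
  5-fold CV, because the property under test — held-out correlation near
  zero — does not depend on grid size, while the larger cohort shrinks
  the null sampling error of r (SD ≈ 0.08 at 150 test children) enough
  that the ±0.25 band is a ≈3-sigma statement per seed;
* the engagement calibration and the type-I-rate check use 2,000
  children and 1,000 replicate cohorts respectively.

## Known limitations

* Every behavioural default of the generator (tap tempo, background
  rate, difficulty ladder) is unconstrained by published data; only the
  calibration targets (engagement 95.5%, exposure 57%, 31-point score
  support, r ≈ 0.67 regime) are anchored.
* The exact published feature counts per stage (262/709/412/83/26) are
  data- and schema-dependent and are reported, not asserted; the default
  pipeline lands at the same order of magnitude (~500 final features).
* The selector and stacker protocols reconstruct undisclosed machinery
  from its outputs; they are reasonable standard choices, not a claimed
  replication of the originals.
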