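# Methods

## The formal PTFR estimator

The estimand is the ratio of observed to potential person-time at a horizon
τ: η = Σ min(T_i, C_i, τ) / Σ min(T_i, τ). The numerator is the recorded
person-time capped at τ. The denominator needs the event time of every
subject who dropped out before τ; we reconstruct it with the restricted-mean
construction: a subject censored at *c* < τ contributes
*c* + ∫_c^τ Ŝ(t)dt / Ŝ(c), a subject censored at or after τ contributes τ,
and an observed event contributes min(t, τ). When Ŝ(c) = 0 the conditional
integral is 0/0; the subject then contributes *c* (no survival mass remains
beyond *c*, so no further expected time). Because each subject's expected
contribution is at least its observed one, η ∈ (0, 1] by construction.

Ŝ comes from one of two estimators:

* **Kaplan–Meier** (default): the NPMLE for right-censored data. Jumps sit
  at event times only; censorings tied with an event are resolved after the
  event (the standard risk-set convention, which also matches the tied
  integer days in clinical tables).
* **Turnbull self-consistency EM** for general interval censoring: exact
  events are encoded as (t⁻, t], right censorings as (c, ∞); probability
  mass lives only on the innermost intervals, and the EM redistributes mass
  until the sup-norm change is below 1e−8 (at most 10 000 iterations,
  non-convergence is an error reporting the last change). On right-censored
  encodings this reproduces Kaplan–Meier to well below 1e−6, which the test
  suite asserts on random cohorts; a direct likelihood maximisation over the
  innermost-interval simplex serves as an independent oracle for genuinely
  overlapping intervals.

**Tail rule.** When the largest observation is censored the estimate never
reaches zero, and ∫_c^τ Ŝ needs a convention beyond the last jump:
`carry_last` (default, Kaplan–Meier convention) or `drop_to_zero`, which
lower-bounds the expected person-time and hence upper-bounds η. Both are
exposed and both are exercised in tests; on the default synthetic cohort
the spread between all estimator/tail-rule combinations is about 0.005 in
η, so the choice is reported rather than agonised over.

## Follow-up rescaling

The simulator multiplies every follow-up time by one constant *k*, leaving
event indicators and covariates untouched. τ must stay at its original
value: η is *exactly* invariant when times and τ are scaled together (every
Kaplan–Meier jump scales along), a property asserted to 1e−12 in the tests.
Only a fixed horizon lets longer follow-up register as improved adequacy.

Two factor-finding strategies are shipped because the naive reading of
"compute the target person-time, scale to reach it" differs from actually
achieving the target rate once capping at τ interacts:

* `person_time_factor`: k = target η / current η (the literal person-time
  ratio). Sublinearity of Σ min(k·t, τ) in *k* makes this undershoot — on
  the seed-1 cohort it reaches 0.554 instead of 0.672.
* `solve_factor_for_target_ptfr` (default): bisection on the achieved
  formal PTFR over k ∈ [1, 50], preceded by a 20-point monotonicity scan of
  the bracket; tolerance 1e−4 on η. Any target below 1 is reachable since
  η → 1 as all capped times reach τ.

Scaled times are not re-rounded to whole days; rounding would perturb the
achieved rate.

**A consequence worth stating plainly:** a constant rescaling preserves
every ordering of observed times. Cox partial likelihood, forest splits,
C-index and the log-rank ranks are all rank-based, so models refit on the
rescaled cohort reproduce the original discrimination exactly when
evaluated at the corresponding quantile of follow-up. Differences between
the original and rescaled analyses therefore come from quantities that are
*not* scale-free — evaluation times for the time-dependent AUC, Brier grids,
at-risk tables, and the KM curves compared by the log-rank test — which is
precisely where follow-up adequacy bites.

## Synthetic cohorts

The generator emulates a heart-failure clinical-records table: continuous
covariates with truncated-normal or lognormal distributions (age on
[40, 95], ejection fraction on [14, 80], right-skewed serum creatinine and
creatine phosphokinase, platelets, serum sodium) and Bernoulli binaries
(sex, anaemia, diabetes, high blood pressure, smoking). Event times follow
a Weibull proportional-hazards model sampled by inverse transform — exact
and closed-form — with cumulative hazard (t/scale)^shape · exp((x−m)ᵀβ),
centred at the covariate means so the baseline describes the average
subject. Dropout is exponential and independent of covariates by default
(the non-informative-censoring assumption behind the PTFR formula); an
informative-dropout option (rate scaled by exp(xᵀγ)) exists to probe
robustness but is off by default. Administrative censoring caps observation
at the study horizon.

Defaults were chosen once to match the study conditions: baseline
exponential hazard 1/740 per day (≈ 32% marginal event risk by day 285),
dropout rate 0.0072 per day, horizon 285 days. Under the no-covariate
exponential reduction these give a true PTFR of 0.451 at τ = 285 via the
closed form [(1−e^{−(λ+μ)τ})/(λ+μ)] / [(1−e^{−λτ})/λ], matching the
follow-up adequacy of the motivating data. The observed-event fraction
(≈ 19%) is lower than the motivating table's 32% because heavy dropout
censors some events; matching both simultaneously would need a higher
baseline hazard, and the PTFR condition was given priority since it is the
study's quantity of interest. Hazard-ratio defaults point the way clinical
experience does (age ↑, ejection fraction ↓, serum creatinine ↑, anaemia ↑,
high blood pressure ↑).

What the generator does **not** emulate: joint covariate correlations of
real heart-failure data, informative censoring (by default), time-varying
covariates, or competing risks. Tests passing on these cohorts therefore
validate the estimators under their stated assumptions, not the clinical
conclusions one would draw from real data.

## Models

* **Cox PH** delegates to lifelines (Efron tie handling — the dominant
  default and the right choice for integer-day ties), with Wald intervals
  and p-values. Collinear columns are detected up front and named.
* **Random survival forest** delegates to scikit-survival with log-rank
  splitting; defaults n_trees = 1000, mtry = ⌈√p⌉, minimum node size 15,
  fixed seed. No hyperparameter search is attempted.
* **Schoenfeld global test**: implemented here because lifelines exposes
  only per-covariate checks. It is the Grambsch–Therneau score test for a
  common time-varying coefficient with the Kaplan–Meier time transform
  g(t) = 1 − Ŝ_KM(t): with Schoenfeld residuals s_k at the d event times,
  centred transformed times z_k and V the coefficient covariance,
  χ² = d·uᵀVu / Σz_k², u = Σ z_k s_k, on p degrees of freedom. The averaged
  per-event information is used in place of the exact one; a simulation
  under exact proportional hazards shows a 3.5% type-I error at the nominal
  5% level (200 replicates), and a one-off comparison against R's
  `survival::cox.zph` on the same data agrees to about 0.01 in p.
* **Permutation importance**: metric drop (C-index) when one covariate is
  shuffled, averaged over permutations, sorted descending.

## Evaluation metrics

All metrics are implemented from first principles and cross-checked in the
test suite against independent references (scikit-survival's concordance,
cumulative/dynamic AUC and Brier score; lifelines' log-rank) to machine
precision on random data:

* Harrell's C over comparable pairs, ties in risk = 1/2; SE by the
  pair-count (Noether-type) estimator √(c(1−c)/N_pairs). This SE treats
  pairs as independent and understates the sampling noise of C — it is
  reported because it is the conventional companion number, not used for
  inference.
* Cumulative/dynamic AUC at time t with IPCW weights 1/Ĝ(T⁻) for cases and
  1/Ĝ(t) for controls, Ĝ the Kaplan–Meier estimate of the censoring
  distribution. The evaluation time defaults to the median observed
  follow-up of the evaluation cohort and is always printed alongside the
  value; single-number AUCs are not comparable across studies without it.
* IPCW Brier curves on a 31-point grid over [0, 90% quantile of follow-up];
  the apparent error AppErr is the trapezoidal time-average over that grid.
  The grid must not extend beyond the last observable time.
* .632 bootstrap: err632 = 0.368·AppErr + 0.632·mean out-of-bag integrated
  Brier error over B resamples (default B = 100; the report scripts use
  B = 50, and small test fixtures less). Resamples without events are
  redrawn with a cap. err632 lies between AppErr and the out-of-bag error
  by construction.

## Pipeline conventions

One 70/30 split, stratified on the event indicator (prevents eventless test
sets in small cohorts; allocation by largest remainder so stratum counts add
to the overall 70% target), is shared between the original and rescaled
cohorts — the rescaled cohort inherits membership so performance changes are
attributable to follow-up, not resampling. Both models are evaluated on the
same held-out 30%. The hazard-ratio table is fitted on each full cohort with
all covariates. Every random element derives from the single run seed.

## Numerical choices and degenerate inputs

Bisection tolerance 1e−4 on η; Turnbull EM tolerance 1e−8 (sup-norm on
masses) with 10 000 iteration cap; Ŝ(c) = 0 dropouts contribute *c*; step
functions evaluate right-continuously and integrate exactly (no quadrature);
cohorts reject missing values rather than impute; zero-event cohorts are
errors for every estimator; a split that strands all events on one side is
an error advising a different seed.

## Known limitations

No competing risks, left truncation, or covariate-adjusted PTFR. The
rescaling simulator extends follow-up by a global constant only — it cannot
represent per-subject follow-up extension or events newly observed during
the added time, which is exactly why its effect on rank-based metrics is
nil (see above). AUC values depend on the chosen evaluation time and the
.632 error on the bootstrap seed and grid, so these are reported with their
settings rather than treated as portable constants. The problem sizes used
by the report scripts (n = 299 cohort, n = 5000 recovery check, B = 50
bootstrap, 1000 trees) were chosen as the smallest that make the estimates
stable to the precision discussed here.
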