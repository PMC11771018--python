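# Methods

This note documents the models, estimators, and simulation experiments
implemented in `landmarker`: what is computed, under which assumptions,
and which design choices were made where several defensible options
exist.

## The landmark supermodel

For landmarks `s ∈ {s₀,…,s_L}` and a prediction window `w`, the
cause-specific hazard from prediction origin `s` is modeled as

    h_j(t | Z(s), s) = h_{j0}(t) exp( α_j(s) + β_j(s)ᵀ Z(s) ),   s ≤ t ≤ s+w,

for causes `j = 1..J`, with `Z(s)` the covariates carried forward (LOCF,
boundary inclusive) to `s`. The cohort is transformed into one dataset
per landmark — subjects with event time strictly greater than `s`, with
administrative censoring at `s+w` — and the datasets are concatenated
into a stacked dataset of counting-process rows `(entry=s,
exit=min(T, s+w), status)`.

`α_j(s)` and `β_j(s)` are basis expansions in `s`. Defaults: `β(s)`
spanned by `{1, s}` (main plus linear time-dependent effect) and `α(s)`
by `{(s−s₀), (s−s₀)²}`. The alpha basis is shifted so each function
vanishes at the first landmark: the baseline hazard then absorbs the
level at `s₀` and the expansion is identified; an unshifted quadratic
basis would only be identified when `s₀ = 0`.

### Estimation

One model per cause is fitted (other causes censored at their exit) by
minimizing the penalized negative log pseudo-partial likelihood

    −log ipl*(b) + λ [ m‖b‖₁ + (1−m)/2 ‖b‖₂² ],   m ∈ [0,1],

with optional per-column penalty factors (both β and α columns are
penalized by default; factors of 0 exempt columns). Risk sets are pooled
across landmark rows — a row is in the denominator at event time `t` iff
`entry < t ≤ exit` — matching the double sum over landmarks in the
stacked pseudo-likelihood; this is left truncation, not stratification
by landmark. "Pseudo" refers to the same subject contributing several
rows; point estimation is unaffected, and no standard errors for
coefficients are produced. Ties are handled with the Breslow
approximation, which is the convention consistent with pooled risk sets
(the same subject's repeated event rows produce exact ties across
landmarks).

Numerics: design columns are standardized (mean 0, unit variance over
stacked rows) before penalization and coefficients back-transformed;
constant columns are dropped and restored as zeros. The optimizer is an
outer iteratively-reweighted least-squares loop on the quadratic
approximation of the partial likelihood. When the L1 part is active the
inner problem is solved by cyclic coordinate descent; for smooth
penalties (ridge, λ=0) the inner step uses the exact Hessian in
coefficient space and a linear solve — both have the same fixed point,
the stationarity condition of the true penalized objective. Steps are
capped at 20 per coordinate on the standardized scale (ill-conditioned
quadratic models can propose wild steps) and backtracked until the
penalized objective decreases; the objective path is therefore monotone
by construction. Convergence: maximum relative coefficient change below
`tol = 1e-7` (cap 10 000 iterations). Divergent coefficients at λ=0
raise an error suggesting a positive penalty (separation).

Risk-set sums at all event times are computed by sorted cumulative sums
over entries and exits (O(n log n) per evaluation), with linear
predictors recentred by their maximum before exponentiation.

λ can be chosen by subject-grouped V-fold cross-validation
(`cv_lambda`): all landmark rows of a subject share a fold, the
criterion is the held-out pseudo-partial-likelihood deviance evaluated
on the validation fold's own risk sets, and ties prefer the larger λ.
The default grid is 100 log-spaced points spanning four decades below
the data-derived λ_max (the smallest λ with all penalized coefficients
zero, from the score at 0).

### Prediction

Baseline cumulative hazards use the Breslow estimator,
`dĤ_{j0}(t) = d_j(t) / Σ_{at risk} exp(lp)`, with the same pooled risk
sets. Given covariates at a landmark `s` the per-cause linear predictor
`lp_j = α_j(s) + β_j(s)ᵀZ(s)` is frozen over the whole window (the
landmarking convention; no within-window covariate or basis updating).
Cumulative incidence is accumulated over the baseline jump times
`t_k ∈ (s, s+w]`: with total jump hazard `λ_k = Σ_j exp(lp_j) dĤ_{j0}(t_k)`
and survival `S(t_k⁻) = exp(−Σ_{l<k} λ_l)`, the event probability at the
jump, `S(t_k⁻)(1−e^{−λ_k})`, is allocated to causes proportionally to
their hazard contribution. With this exponential-within-jump convention
the predicted incidences and the overall survival sum to one exactly for
any J, and a single jump of mass `u` yields the closed form `1−e^{−u}`.
Horizons beyond the last observed event time are computed on the
available support with a logged warning.

## Evaluation metrics

For a landmark `s`, window `w`, and predicted cause-1 risks `π_i`, the
package computes IPCW versions of the time-dependent AUC and Brier
score over subjects at risk at `s` (`T̃ > s`):

- cases: cause-1 events in `(s, s+w]`, weight `1/Ĝ(T̃⁻|s)`;
- controls: subjects event-free at `s+w` (weight `1/Ĝ((s+w)⁻|s)`) plus,
  by default, competing-cause events in the window (weight `1/Ĝ(T̃⁻|s)`);
  competing events can be excluded (`include_competing=False`);
- AUC: weighted proportion of case-control pairs ranked concordantly,
  ties counting one half. Brier: weighted mean of `(1{case} − π_i)²`
  (competing events and survivors count as non-events).

`Ĝ` is the Kaplan-Meier estimator of the censoring distribution on the
pooled test sample (events censor the censoring process), and the
conditional weights use the ratio `Ĝ(t)/Ĝ(s)`. Because every subject at
risk after `s` survived past `s`, this ratio coincides exactly with the
censoring KM computed within the at-risk subsample, which is how the
implementation organizes the computation. All evaluations of `Ĝ` use
left limits; this matters when follow-up ends administratively exactly
at a landmark horizon, where the right-continuous KM drops to zero.
Validity requires censoring independent of both event times and
covariates (no covariate-adjusted weights).

### Influence values and the summary metrics

Each per-landmark estimator is linearized as a mean of per-subject
influence values over the at-risk subsample: the empirical (Hajek)
projection of the weighted mean or two-sample U-statistic, plus the
first-order term from estimating `Ĝ` — the integral of the subject's
censoring martingale against the accumulated weight mass (the usual
Kaplan-Meier expansion). The censoring-martingale terms sum to exactly
zero over the subsample, so influence values are centered by
construction. They are embedded into full-test-sample vectors (zero for
subjects not at risk at `s`, scale factor n/n_s), which puts all
landmarks on one common empirical measure.

The summary metric is the unweighted mean of the landmark estimates.
Its variance uses the cross-landmark covariance of the influence
vectors divided by n; the CI is Wald with normal quantiles, truncated
to [0,1] (no variance-stabilizing transform). With a single landmark
this reduces exactly to the usual single-time IPCW standard error.

Model comparison on shared test subjects uses the per-subject influence
values of the difference, averaged over landmarks: `z = Δθ̄ / SE(Δθ̄)`
with a two-sided normal p-value. Per-landmark difference tests are also
available, with Bonferroni and Benjamini-Hochberg adjustments
(`adjust_pvalues`); a family rejects when any adjusted p-value is below
the level.

## Synthetic-data generator

`SimScenario` defines the simulation conditions; `simulate_cohort` draws
from a landmark-form model:

- fixed covariates `Z₁, Z₂ ~ N(0,1)`, `Z₃ ~ Bernoulli(0.5)`;
- longitudinal covariate `X(s_m) = X(s₀) + ρ·s_m + e_m` with
  `X(s₀) ~ N(0,1)`, `e_m ~ N(0, 0.25)`, at landmarks `s_m = m·lmi`,
  `m = 0..k−1`;
- hazard piecewise constant between landmarks:
  `h(t) = h₀·exp((β + β_t·s_m)ᵀ(Z, X(s_m)))` on `(s_m, s_{m+1}]`, the
  last piece open-ended; event times by inversion of the piecewise
  cumulative hazard;
- defaults `β = (0.5, −0.5, 0.3, 0.7)`, `β_t = (0, 0, 0, −0.05)` (the
  time-dependent effect on the longitudinal covariate), `h₀ = 0.05`,
  `ρ = 0.2`, `w = 5` — chosen to give non-degenerate event fractions
  (roughly 40–60% events before the administrative cutoff) across all
  censoring settings;
- censoring: administrative at `s_L + w` always; random censoring is
  exponential with the rate calibrated by root finding on a fixed
  100 000-subject pre-run so that the target fraction of subjects is cut
  by the random censoring process before `min(T, s_L + w)`.
  `censor_rate = 0` means no random censoring (administrative censoring
  remains — it is part of the design, not of the censoring target,
  since long-interval scenarios would otherwise make low total-censoring
  targets unattainable).

Everything is deterministic given the scenario seed / a supplied
generator; experiment replicates use `numpy.random.SeedSequence`
spawning keyed by (seed, scenario, replicate).

What the generator does not emulate: covariate measurement error or
informative observation times, dependent censoring, competing causes
(the validation experiments are single-cause), non-linear covariate
effects, and cohorts where covariates update between landmarks. Passing
tests therefore certify the estimators and their inference under
independent censoring and a correctly structured landmark data stream,
not robustness to those violations.

## Validation experiments and problem sizes

*Coverage* (`run_coverage_experiment`): per replicate, independent
train/test cohorts are drawn, the supermodel (unpenalized, linear beta
basis, quadratic alpha basis) fitted on train, 95% CIs for the summary
AUC and Brier score formed on test, and scored against the oracle truth
of the fitted model — its uncensored empirical summary metric on a
Monte-Carlo cohort of 100 000 shared within a scenario. The package's
default experiment sizes are scaled down from a full 500-replicate
factorial: the acceptance script runs six scenarios spanning
n ∈ {500, 750, 1500}, landmark interval ∈ {2, 4, 6} and censoring
∈ {0, 15, 30, 50}% at 120 replicates each; the test suite runs a
two-scenario smoke version at 200 replicates. For AUC the oracle uses
the linear predictor directly (risk is monotone in it); for the Brier
score risks are interpolated from a 2048-point grid of the monotone
lp→risk map (interpolation error ≪ Monte-Carlo error).

*Type I error* (`run_type1_experiment`): two supermodels of identical
specification are fitted to independent training draws and compared on
one shared test draw; rejection rates of the summary-difference test are
tabulated at levels 0.01/0.05/0.10. The default scenario uses n = 3000
and landmark interval 6 with window 5, so that the prediction window
lies inside one inter-update interval: the generator then follows the
fitted model's own form within every window, and the two independently
trained models are equivalent in population value up to second order.
See the calibration caveat below.

*Power* (`run_power_experiment`): the full model M₁ is compared against
M₂, which omits the longitudinal covariate; both are fitted on the same
training draw and evaluated on a shared test draw. Per replicate the
summary-difference p-value is recorded alongside the family of
per-landmark difference tests adjusted by Bonferroni and by
Benjamini-Hochberg (family rejects if any adjusted p < α). The design
varies k ∈ {3, 5, 7} at n = 750 and n ∈ {500, 750, 1500} at k = 5,
100 replicates per scenario.

### Calibration caveat for the comparison test between refitted models

The comparison test is conditional on the two fitted models: its
standard error captures test-sampling variation only. When the two
models are *refit on independent training draws*, their true metric
values differ by a training-noise term — first order in the coefficient
error when the working model is misspecified (e.g. when the window
spans covariate-update times, the landmark model is an approximation
and the metric gradient at the fitted limit is nonzero), second order
(curvature × squared coefficient noise) even under correct
specification. With training and test sets of equal size this term does
not vanish and inflates the type-I error of the refitted-equivalent-
models experiment above its nominal level, most visibly for the Brier
score; diagnostics with a fixed model pair confirm that the standard
error itself is calibrated (z ≈ N(0,1) across repeated test draws).
The comparison test is therefore exact for its stated null — two fixed
prediction rules of equal summary performance — and conservative use is
recommended when the compared models were refit on small training sets.

### When does the summary test beat the landmark family?

The summary test aggregates the per-landmark differences by averaging;
the adjusted landmark family is a max-type procedure. Averaging wins
when the model difference is reasonably homogeneous across landmarks —
the regime the summary metrics are designed for — and loses power when
the difference is concentrated at one or two landmarks. The default
generator produces the second regime at large k: the longitudinal
covariate's effect `0.7 − 0.05·s` decays to zero by `s ≈ 10`, so the
full-vs-reduced difference lives almost entirely at early landmarks and
the Bonferroni/BH family can dominate the summary test there. The power
experiment reports all three procedures so the regime is visible in the
output rather than averaged away.

## Known limitations

- No coefficient standard errors or selection inference for the
  penalized fits.
- Independent censoring is assumed everywhere; weights are not
  covariate-adjusted.
- The metric influence functions are first-order; very small at-risk
  sets at late landmarks (few cases or controls) make a landmark
  estimate undefined and the replicate is excluded and counted.
- Wald CIs on the probability scale can touch the [0,1] boundary for
  extreme metrics; logit-scale CIs are a possible alternative not
  implemented.
- `cv_lambda` uses basic held-out deviance on the validation fold's own
  risk sets, which can be noisy in small folds with few events.
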