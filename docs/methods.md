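# Methods

## Model

Each taxon is analyzed separately.  Counts for subject *i* at occasion
*j* follow a negative binomial with a shared per-taxon dispersion,

    y_ij ~ NB(mu_ij, theta),      Var(y_ij) = mu_ij + mu_ij^2 / theta,

and a log-linear mean with a library-size offset,

    log(mu_ij) = log(T_ij) + X_ij beta + Z_ij b_i,
    b_i ~ N(0, Psi).

The default fixed design is `(1, group, time, group x time)` plus any
extra covariates; the random design is a subject intercept or an
intercept plus time slope.  Psi is either a general positive-definite
matrix (log-Cholesky parameterization) or diagonal (log standard
deviations).  A `time_basis` hook accepts any mapping of raw time to
several columns (polynomials, splines); it is exposed but deliberately
untested.

Binary group variables are coded 0/1 by sorted level order, so the group
coefficient is the log fold change of the second level relative to the
first at time zero, and the interaction is the additional log fold change
per unit of time.

## Fitting: IWLS / penalized quasi-likelihood

The NB mixed model is fitted by iterating two steps until the linear
predictor stabilizes:

1. **Dispersion.**  theta maximizes the NB log likelihood with the means
   held at the current conditional fit, by Newton-Raphson on log(theta)
   (analytic digamma/trigamma derivatives; a unit gradient-sign step with
   halving replaces any non-descent Newton step).  Convergence is
   |delta log theta| < 1e-6; theta is confined to [1e-4, 1e8] and results
   pinned at a cap are flagged `at_bound` (under-dispersed data converge
   to the Poisson limit at the upper cap).

2. **Working LMM.**  The PQL linearization for the log link gives the
   working response and weights

       z_ij = eta_ij + (y_ij - mu_ij)/mu_ij,
       w_ij = mu_ij theta / (mu_ij + theta),

   i.e. w is the inverse of V(mu) g'(mu)^2 for V(mu) = mu + mu^2/theta and
   g'(mu) = 1/mu.  The weighted linear mixed model

       z_i = X_i beta + Z_i b_i + W_i^{-1/2} e_i,   e_i ~ N(0, sigma^2 R_i)

   is fitted by maximum likelihood.  R_i is the identity, order-based
   AR(1) (rho^|j-k|, rho in (-1,1)) or continuous-time AR(1)
   (rho^|t_j - t_k|, rho in (0,1)); the free scale sigma^2 absorbs the
   usual PQL over/under-dispersion of the working residuals.

The loop is initialized by a fixed-effects-only NB IRLS fit at theta = 1
(cheap, deterministic and scale-aware) and stops when the largest
absolute change in the linear predictor is below 1e-6 — a criterion
invariant to reparameterization — or after 50 outer iterations, in which
case the fit is returned flagged unconverged.  The LMM variance-parameter
search is warm-started from the previous outer iteration.

### The working LMM

With Psi = sigma^2 G, beta and sigma^2 are profiled out: for a candidate
(G, rho) the per-subject relative covariance
C_i = Z_i G Z_i' + W_i^{-1/2} R_i W_i^{-1/2} is Cholesky-factored, beta is
the GLS solution on the whitened data, and sigma^2 = RSS/N in closed
form.  Only the log-Cholesky (or log-sd) parameters of G and a
transformed rho (tanh for AR(1), logit for continuous AR(1)) are
optimized, with L-BFGS-B on numerically differenced gradients
(`ftol` 1e-12, `gtol` 1e-8), parameters bounded in [-12, 12], and two
randomly perturbed restarts if the first search fails.  Subjects are
batched by group size so every per-subject operation is a single stacked
numpy call; a full fit of 100 subjects x 5 observations takes about 10 ms,
which is what makes 1,000-replicate calibration studies routine.
Subjects with a single observation participate normally (their C_i is
1 x 1).  A REML variant of the profiled objective is available; the IWLS
loop itself always uses ML (pseudo-data change between iterations, so
only the final fit's criterion matters) and `FitControl(final_reml=True)`
re-fits the last working model by REML for inference.  On matched data
the engine agrees with independent LMM software to ~1e-6 in
log-likelihood for both ML and REML.

### Inference

Each fixed effect is tested with a Wald t-statistic.  Degrees of freedom
follow the containment (inner-outer) rule used by the standard
longitudinal LMM software: terms varying within subjects — time, the
interaction, and the intercept — are tested against
N - n_subjects - p_within df; subject-constant terms (the group effect)
against n_subjects - 1 - p_between df.  Under ML the fixed-effect
covariance carries the same N/(N-p) finite-sample factor that software
applies, so p-values are directly comparable with it.  A likelihood-ratio
test is deliberately not offered: PQL working likelihoods are not
comparable across dispersion updates.

### Known bias of the plug-in dispersion

The theta step evaluates the NB likelihood at conditional means that
include the predicted (BLUP) random effects.  Because predictions are fit
to the same observations, residual dispersion is understated and theta is
overestimated — the parameter-recovery test computes a mean theta-hat near
2.5 when the truth is 2.0 with 150 subjects x 5 occasions and tau = 0.7.
This is a property of the alternating scheme itself, not of this
implementation: an independent reconstruction of the same alternation on
top of reference LMM software reproduces theta to seven significant
digits on shared data.  Evaluating the likelihood instead at
leave-one-observation-out predictions (available as
`FitControl(dispersion_means="loo")`, computed by a closed-form
partitioned-inverse downdate) removes the self-fitting term but absorbs
prediction error as extra dispersion and overshoots downward, so the
conventional plug-in remains the default.  Fixed-effect estimates are
essentially unaffected (recovery within Monte-Carlo error); the main
consequence is mild anticonservativeness of the within-subject Wald tests
at extreme over-dispersion (see Limitations).

## The arcsine-LMM comparator

The transformation baseline fits the identical fixed/random/correlation
structure to `arcsin(sqrt(y_ij / T_ij))` with unit weights and no offset
(responses 0 at y = 0 and pi/2 at y = T).  It shares every downstream
component (engine, Wald tests, df), so power comparisons isolate the
modeling choice rather than implementation differences.

## Per-taxon scans

`scan_taxa` fits each taxon independently, records the group and
interaction terms, captures per-taxon failures as NA rows rather than
raising (an all-zero taxon is a failure; `filter_taxa` removes rare taxa
first — the conventional prevalence filter keeps taxa observed in at
least a fraction q of samples, default interpretation of "present in more
than 25%"), and optionally appends Benjamini-Hochberg adjusted p-values
per term across taxa.  Unconverged fits keep their estimates but report
NA p-values.  No adjustment is the default, matching per-alpha
significance counting.

## Simulation framework

The generator emulates a two-group longitudinal 16S/shotgun study, one
taxon at a time:

- subjects n in {50, 100, 150}, half cases (x_i = 1);
- per-observation log library sizes log(T_ij) ~ Unif[7.1, 10.5] against a
  fixed intercept beta0 = -7, so baseline log means span [0.1, 3.5] —
  counts from ~1 to a few tens, as in real OTU tables;
- dispersion theta ~ Unif[0.1, 5] (strong to moderate over-dispersion),
  random-effect sd tau ~ Unif[0.5, 1], AR(1) parameters
  rho ~ Unif[0.1, 0.5] and marginal sd sigma ~ Unif[0.1, 0.5] (all
  redrawn each replicate; rho and sigma enter only layout B);
- four layouts: A (5 time points, random intercept), B (10 points,
  random intercept, AR(1) disturbance), C (5 points, independent random
  intercept and slope), D (4 or 5 points per subject, probability 1/2
  each, random intercept);
- effect scenarios: null (all zero); a/b interaction-only with
  beta3 ~ Unif[0.2, 0.35] / Unif[0.35, 0.8]; c/d with all three effects
  from the same ranges.

Choices the sources leave open, fixed here once: measurement times are
equally spaced on [0, 1] per subject, so effect sizes read as log fold
changes over the study span; the group indicator is 0/1; the AR(1)
disturbance is generated with the drawn *marginal* sd and enters on the
linear-predictor (log-mean) scale, keeping the NB mean positive.

A power study draws parameters, simulates a dataset, fits each method
with the layout-matched (correctly specified) model, and records Wald
rejections of beta1 = 0 and beta3 = 0 at alpha = 0.05.  Replicates whose
fit raises, returns non-finite p-values, or fails to converge are
excluded from the denominator and counted.  Replication streams are
spawned from a single seed (`SeedSequence.spawn`), so results are
bit-reproducible and independent of the number of methods fitted.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: excess (structural) zeros beyond the NB,
compositional coupling between taxa, irregular or informative sampling
times, dropout, covariate-dependent dispersion, and sequencing batch
effects.

## Problem sizes

The packaged studies use 1,000 replicates for null calibration, 500 for
power comparisons and 200 for parameter recovery — large enough that
3-SE Monte-Carlo bands are a few percentage points wide, and all
desk-scale (each NBMM fit is ~0.1-0.3 s).  Larger runs are a
configuration change (`n_reps`).

## Numerical choices

- theta in [1e-4, 1e8]; fitted means floored at 1e-10 with a warning;
  exp overflow in the linear predictor raises with advice to rescale.
- Working-LMM non-PD covariances return a large penalized objective so
  the optimizer retreats rather than crashing; a singular fixed design
  raises, naming the collinear columns.
- AR(1) at rho = 0 reproduces the independent model exactly (identity
  correlation short-circuit), which the structural-identity tests verify
  through the full pipeline.
- Duplicated (subject, time) pairs are rejected at construction; rows are
  sorted by (subject, time) so order-based AR(1) follows measurement
  order.

## Limitations

- PQL inference is approximate.  At extreme over-dispersion
  (theta below ~0.5, where half the counts can be zeros) the Gaussian
  working model understates the tails and the within-subject Wald tests
  reject somewhat above nominal; the null-calibration test quantifies the
  aggregate effect over the full nuisance ranges.  At moderate dispersion
  calibration is close to nominal.
- The plug-in dispersion is upward-biased (see above); treat theta-hat as
  a working quantity, not an unbiased estimate.
- Zero-inflated counts are out of scope; heavily zero-inflated taxa
  should be filtered or handled with a zero-inflated extension.
- One taxon at a time: no compositional constraint or between-taxon
  information sharing.
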