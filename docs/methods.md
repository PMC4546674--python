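# Methods

This note records the statistical model behind `ettmachine`, the defaults
and why they were chosen, the numerical details that matter for
reproducibility, and what the synthetic validation does and does not
establish.

## Estimand and identification

The parameter is the effect of treatment among the treated,

psi = E[ E(Y | S=1, C) − E(Y | S=0, C) | S=1 ],

for a binary center-level exposure S (1 = large-volume center). The treated
subgroup is the natural reference population for two reasons: large- and
small-site patient populations differ enough that a whole-population average
refers to an artificial mixture, and the matched-cohort estimator targets
the same subgroup, making the four estimators comparable.

Identification requires (i) no unmeasured confounding given the observed
information and (ii) positivity, P(S=1 | C) bounded away from 0 and 1 on
the support of C among the treated. With missing covariates the conditioning
set is the observed information W = (Delta, Delta·C, fully observed C): the
indicator basis makes the assumption explicit — the combination of observed
values and observedness patterns must suffice to block all confounding
paths. Missingness not at random can never be excluded in observational
clinical data; the generator therefore includes an MNAR switch
(`MissingnessModel.self_coefficient`) for sensitivity experiments, off by
default.

## Nuisance estimation

**Design basis.** Each sometimes-missing covariate contributes
(Delta_j, Delta_j·C_j); never-missing covariates a single column;
categorical covariates are reference-coded (modal category as reference)
before the indicator step. Delta columns enter *both* the outcome and the
propensity model as candidate predictors; whether the original analysis did
the latter is not documented anywhere we know of, so it is configurable, but
including them is the coherent version of the indicator method (the
propensity must condition on the same information set as the outcome model).

**SuperLearner.** V = 10 cross-validation folds by default; the convex
weight vector minimizes cross-validated risk over the simplex. The
meta-learning losses are squared error (weights by non-negative least
squares, normalized) and Bernoulli negative log-likelihood (projected
SLSQP over the simplex with predictions pre-bounded at 0.001/0.999).
Because the simplex contains the vertices, the solver falls back to the best
single learner whenever optimization fails to beat it, which enforces the
oracle inequality exactly in finite samples; ties prefer the simpler
learner (library order = simplicity order). The default library is
mean-only, main-terms GLM, L1-penalized GLM (penalty by inner CV), shallow
gradient-boosted trees, and 20-nearest-neighbors; replicate studies use the
reduced {mean-only, GLM} library so that hundreds of cohorts fit in
minutes. For binary outcomes with prevalence below 5% the folds are
stratified on the outcome — a deliberate deviation from plain random
splitting, since at cohort scale (n≈1250, prevalence ≈1.4%) unstratified
folds are regularly empty of events. A learner that throws on any training
split receives infinite CV risk and zero weight rather than aborting the
fit.

**Propensity scores** are truncated to [0.025, 0.975] by default
(positivity protection; configurable).

## Estimators

**Substitution.** psi-hat = mean over treated of [Y_i − Qbar(0, C_i)].
The counterfactual is evaluated by switching the treated to the *small*-site
value, which is the direction the estimand formula dictates. Inference by
nonparametric bootstrap (below).

**TMLE.** Iterative dual fluctuation. Per cycle: (1) intercept-free
logistic regression of Y on H_Y(S,C) = 1{S=1} − 1{S=0}·g/(1−g) with offset
logit Qbar(S,C), giving eps_Q; update both counterfactual predictions on
the logit scale. (2) Recompute psi; intercept-free logistic regression of S
on H_S(C) = Qbar(1,C) − Qbar(0,C) − psi with offset logit g, giving eps_g;
update and re-truncate g. The canonical ETT clever covariates carry a
constant 1/P(S=1) factor; it is absorbed into the fluctuation coefficients,
which changes nothing about the submodel's span or the fixed point.
Convergence: max(|eps_Q|, |eps_g|) < 1e-5, at most 50 iterations (typically
2–5); non-convergence returns the last state with a warning and no EIF
standard error (the bootstrap is the fallback). Continuous outcomes are
mapped to [0,1] by (Y−a)/(b−a) with (a,b) the observed minimum/maximum (no
padding), targeted on that scale, and back-transformed; this makes the
estimate equivariant under affine relabeling of Y. Probabilities entering
logits are floored at 1e-3.

**Matching.** Nearest small-site neighbor on the truncated propensity
score, with replacement; controls tied at exactly the minimal distance are
all retained and their outcomes averaged. The caliper is 0.05 × SD of the
pooled truncated scores; treated patients with no control inside the
caliper are discarded and reported, so the estimand silently narrows to the
matchable treated — the price of refusing to extrapolate.

## Inference

* Unadjusted: unpooled binomial (binary) or Welch (continuous) two-sample
  variance; Wald interval.
* Substitution: nonparametric bootstrap, resampling rows unconditionally
  (a site-stratified option exists), **refitting the entire model** —
  including SuperLearner — on every resample; the interval is Wald,
  centered at the full-data estimate with the replicate SD as SE, matching
  the reported interval style rather than percentile intervals. A
  fixed-learner fast mode exists and is flagged approximate. Replicates
  that fail are skipped and counted; >10% failures is an error. B defaults
  to 1000 for reports; the replicate studies use B = 200.
* TMLE: efficient-influence-curve variance,
  D_i = (S_i/p1)(Q1_i − Q0_i − psi) + [S_i/p1 − (1−S_i)g_i/((1−g_i)p1)](Y_i − Qbar(S_i,C_i)),
  SE = sqrt(Var(D)/n), back-scaled for continuous outcomes. At the targeted
  solution the empirical mean of D is numerically zero, which the suite
  asserts.
* Matching: no established closed form was being mirrored, so the package
  uses a reuse-weighted paired variance: Var(d)/m plus a penalty
  sum_j max(K_j² − K_j, 0)·sigma²_j/m² over controls with reuse weight
  K_j = sum_i 1{j in M_i}/|M_i|, where sigma²_j is a nearest-control-
  neighbor variance proxy (Y_j − Y_nn(j))²/2. With no reuse this reduces
  exactly to the ordinary paired-difference SE; reuse can only inflate it
  (fractional-K reductions are clamped at zero to keep the estimator
  conservative). This is a documented stand-in, not a canonical formula.

## Diagnostics

Counterfactual residuals r_i = Y_i − Qbar(1−S_i, C_i); their mean over the
treated *is* the substitution estimate (asserted to 1e-12). The risk axis
is predicted overall mortality with S set to "large" for every patient: one
common counterfactual scale, so the two site groups are comparable at the
same x. Predicting at the factual site is a switchable alternative; the
common-scale choice was made because mixed scales make the two curves
answer different questions.

The loess is local-linear with tricube weights, span 0.75 (0.3–0.5 in
change-point settings), evaluated on a 100-point grid, with exploratory
pointwise bands from the local weighted residual variance — the bands are
rendered with an explicit caption that they are not reliable post-hoc
inference. The divergence cutoff is the smallest grid point whose
|smoothed value| exceeds a threshold (default: half the median band
half-width) with at least 10% of the remaining grid also exceeding it; the
persistence requirement keeps a single noisy spike from opening a region.
Flagged-vs-unflagged subgroup tables use Welch t for ordered and Pearson
chi-square (no continuity correction) for binary variables. Matched-set
balance uses Euclidean average-linkage hierarchical clustering of the
scaled covariates (continuous z-scored, binary and Delta columns left
unscaled so distances and heatmaps stay interpretable) and a 2-cluster
chi-square association with site; standardized mean differences use the
pre-match pooled SD in both columns so the pre/post values are comparable,
with reused controls weighted by their reuse count.

## The synthetic mechanism

The generator emulates the statistical structure of a ~1,242-patient
multi-center transfusion cohort with a 551/691 large/small split. Seven
covariates with marginals chosen to resemble published trauma summary
tables: age ~ N(41, 18.5) truncated to [16, 90]; male ~ Bern(0.74);
penetrating injury ~ Bern(0.35); injury severity score ~ Gamma(mean 26,
SD 15) truncated to [1, 75]; ED systolic BP ~ N(108, 31); hemoglobin ~
N(11.7, 2.3); base deficit ~ N(−7, 5.6). Site assignment is logistic on
standardized covariates (large sites younger, more penetrating injury,
higher hemoglobin). Outcomes: overall mortality (logit, marginal ≈21%,
protective site main effect plus a site-by-penetrating interaction so the
ETT differs from the ATE), multiple organ failure (logit, ≈1.4%), and
plasma volume infused (gamma log-linear, large-site means ≈8 vs ≈5 units).
Intercepts were calibrated once by Monte Carlo against those marginal
targets and frozen. Missingness is MAR given site and severity: base
deficit missing ≈27%/17% (small/large, severity-dependent), hemoglobin
≈2.5%/5%, systolic BP ≈2.5%; outcomes are generated from the complete
covariates and never masked, mirroring the near-zero outcome missingness of
real registries. A master seed feeds separate substreams for covariates,
site, missingness, and outcomes, so switching missingness on or off leaves
everything else bit-identical.

Two structural choices deserve emphasis. First, the confounding is strong
(crude mortality difference ≈ −0.112 against a true ETT ≈ −0.058), because
the phenomenon the machinery exists for — adjusted and unadjusted answers
differing materially — should be present at full strength in validation.
Second, the site model's covariates are fully observed or nearly so, while
the heavily missing covariate (base deficit) is prognostic but not a
determinant of site; this keeps the observed-information adjustment set
sufficient for identification, so estimator bias measured against the
generator truth reflects the estimators, not an identification gap built
into the mechanism. Real data offer no such guarantee — that is precisely
the MNAR caveat above.

The truth is computed by Monte Carlo with n_mc = 10^6 draws (ETT MC SE
≈ 7e-5 on the mortality scale); a deterministic quadrature oracle
cross-checks it in the test suite on one-confounder mechanisms. The
`make_discrete_toy` fixture (one binary covariate, all probabilities inside
(0.1, 0.9)) has a closed-form ETT and a saturated parametrization, giving
machine-precision oracles for the substitution estimator and the TMLE fixed
point.

## What the validation shows — and does not

Replicate studies at cohort scale (200 replicates of n = 1250 for bias,
coverage and type-I error; 100 of n = 2000 for double robustness; 50 for
balance; sizes chosen to keep the full suite in minutes while leaving the
binomial noise on a coverage proportion near ±1.5%) establish: TMLE bias
indistinguishable from zero with EIF-Wald coverage near nominal; TMLE
unbiasedness when exactly one nuisance model is ruined, while the
substitution estimator fails with a ruined outcome model and matching fails
with a ruined propensity; 95% intervals excluding zero 2–9% of the time
under a randomized null; and matching reliably improving covariate balance.

These results are internal to the emulator's assumptions: correct MAR
missingness, independent covariates, no within-center clustering, logistic/
log-linear outcome surfaces. They do not certify performance under MNAR
missingness, center-level random effects, time-to-event structure, or
informatively censored outcomes — all out of scope. The learner library and
meta-loss of the original analysis workflow this package generalizes are
unreported, so the default library is a reasonable stand-in, and results on
real data will depend on that choice. Matching's standard error is a
pragmatic construction (above), and its target parameter conditions on the
random matchable subset, which complicates interpretation whenever patients
are discarded.
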