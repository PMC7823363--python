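# Methods

This document describes the statistical model implemented in `dietlta`, the
estimation procedure, the synthetic-data generator, and the numerical
choices and limitations. Everything stated here is either a mathematical
property of the model or a behaviour of the code; no empirical claim is made
beyond what the package itself computes.

## 1. Data model

The input is a two-day short-term dietary record: for each subject `i`,
recall day `d in {1, 2}`, and food group `j in {1, …, J}`, an intake amount
`A[i, d, j] >= 0`, plus subject covariates age (years) and sex (0/1).

### 1.1 Preparation

- **Complete cases.** Subjects missing covariates are dropped (with a
  warning reporting the count).
- **Densification.** Food groups not reported on a person-day are treated
  as nil intake for that day, so every subject has a full `J x 2` grid.
- **Rare food groups.** A food group whose fraction of nil person-days is
  greater than or equal to a threshold (default 0.95) is excluded. The
  boundary is inclusive: exactly 95 % nil is excluded at the default.
- **Ordinal coding.** Each retained amount is coded into three categories:
  `0` = nil; `1` = positive but at or below the consumer median; `2` = above
  the consumer median. The consumer median of a food group is the median of
  its *positive* amounts pooled over both days, so the same cut-point
  applies to both days. Values exactly equal to the median code to category
  `1` (ties go low). The fitted cut-points can be reused to code new data.
- **Day-to-day reliability.** A one-way random-effects intraclass
  correlation per food group, `ICC = (MSB - MSW) / (MSB + MSW)` from the
  one-way ANOVA decomposition over subjects, floored at 0. Identical days
  give exactly 1; zero total variance gives `NaN` with a warning.

## 2. Latent class measurement model

Pattern membership is a latent variable `Z in {1, …, K}`. Given membership,
the `J` ordinal responses of a day are independent (local independence),
with item-response probabilities

```
rho[j, k, c] = P(Y_j = c | Z = k),   sum_c rho[j, k, c] = 1.
```

Day-1 membership follows a multinomial-logistic (softmax) model in the
covariates `x = (1, z_age, sex)`, where `z_age` is age standardized by the
sample mean and standard deviation:

```
P(Z_1 = k | x) = exp(beta_k' x) / sum_m exp(beta_m' x),   beta_K = 0.
```

The last class is the reference with a zero linear predictor. The
single-day model (`lca_em_fit`) uses only this block; the log-likelihood
marginalizes `Z` per subject.

## 3. Latent transition model

With two days, each subject has a latent path `(Z_1, Z_2)`. Day-2
membership follows a row-wise softmax transition model:

```
P(Z_2 = l | Z_1 = k, x) = exp(a[k, l] + gamma_l' w) / sum_m exp(a[k, m] + gamma_m' w),
```

with `w = (z_age, sex)`, reference column `l = K` fixed at zero
(`a[k, K] = 0`, `gamma_K = 0`). The same `rho` applies to both days
(measurement invariance), so patterns are comparable across days and the
transition matrix is interpretable.

**Covariate constraint.** By default the covariate slopes of the transition
block are tied to the day-1 membership slopes, `gamma = beta1[:, 1:]`: the
same age/sex gradient that shapes who starts in a pattern also shapes where
people move. This halves the structural slope count and stabilizes
estimation with only two occasions; it can be released with
`constrain_covariate_effects=False`.

### 3.1 Estimation

Both models are fitted by EM over random starts:

- **E-step.** Posterior probabilities of the latent class (LCA) or of all
  `K x K` paths (LTA), computed in log space with `logsumexp`.
- **M-step, measurement.** `rho` is the posterior-weighted category
  frequency, pooled over both days in the LTA.
- **M-step, structural.** The membership and transition logit blocks are
  maximized jointly with L-BFGS-B using analytic gradients. The result is
  accepted only if it improves the M-step objective, so the outer iteration
  is a generalized EM and the log-likelihood is non-decreasing by
  construction (asserted in the tests to a relative tolerance of 1e-8).
- **Starts and convergence.** Default 20 random starts, convergence when
  the log-likelihood gain drops below `tol = 1e-8`, cap of 1000 iterations.
  The best start is kept; per-start final log-likelihoods are recorded.
- **Canonical labelling.** Classes are relabelled in descending order of
  expected size, with the logit blocks re-referenced accordingly, so runs
  are comparable.

### 3.2 Standard errors and odds ratios

The observed-data score is computed by the Fisher identity (the
posterior-expected complete-data score), implemented as an analytic
gradient of the packed parameter vector. The observed information matrix is
the negative central-difference Jacobian of that gradient (step 1e-5).
Wald standard errors come from its inverse; if inversion fails (boundary
`rho` entries, weak separation), a nonparametric subject-level bootstrap
(default 200 replicates) is used instead, and the output labels which
method produced each interval. Age effects are rescaled from the internal
z-score to per-year units (dividing the slope and its standard error by the
age standard deviation) before exponentiating to odds ratios.

## 4. Model selection

For each `K` in a user-specified range, the package reports:

- `AIC = 2p - 2 logL` and `BIC = p log N - 2 logL`, with `N` the number of
  subjects and `p` the free-parameter count
  `p_LCA = J·K·(C-1) + (K-1)(1+q)` and
  `p_LTA = p_LCA + K(K-1) [+ (K-1)q if unconstrained]`, `q` = number of
  covariates. The counts are verified in the tests against the length of
  the packed parameter vector.
- **Relative entropy** `1 - (mean posterior entropy) / log K`, a
  classification-sharpness index in [0, 1]: exactly 1 for degenerate
  posteriors, 0 for uniform ones. It is a diagnostic, not a selection
  criterion.

The minimum-BIC row is flagged as selected. BIC is consistent but
conservative in this family: with weakly separated classes or moderate `N`
it can prefer fewer classes than generated the data, which is visible in
the package's own acceptance script output.

## 5. Markov extrapolation to usual prevalence

Treating recall days as steps of a time-homogeneous Markov chain with the
fitted transition matrix:

- **Regularity.** `is_regular(P)` searches for a power `m` with all entries
  of `P^m` strictly positive, up to the Wielandt bound `(K-1)^2 + 1`; beyond
  it no power can become positive. Non-regular chains (e.g. the identity,
  periodic chains, chains with absorbing states) have no unique limiting
  distribution, and `stationary` refuses them with `NotRegularError`.
- **Stationary distribution.** Power iteration on `S <- S P` to a fixed
  point (tolerance 1e-12), cross-checked internally against the left
  eigenvector of eigenvalue 1.
- **Propagation.** `propagate(S1, P, d) = S1 P^(d-1)` gives the state
  distribution on day `d`; the day-2 check `S2 = S1 P` is written by the
  pipeline.
- **Usual prevalence.** Two modes:
  - `individual` (default): each subject's covariate-specific transition
    matrix is iterated to its stationary vector; the sample average of
    these is the usual prevalence. If any subject's matrix is not regular,
    the error lists the offending subjects.
  - `aggregate`: the stationary distribution of the single
    posterior-weighted average transition matrix.

  These do not coincide in general (the stationary map is nonlinear in
  `P`), and the pipeline reports both. The individual mode is the primary
  estimate because it respects covariate heterogeneity.

## 6. Synthetic-data generator

`GeneratorConfig` fixes a ground truth (`rho`, `beta1`, transition
intercepts, `gamma`, covariate law) and `generate_population(config, seed)`
draws a cohort:

- Age is uniform on a configurable range (default 18–84); sex is Bernoulli
  (default 0.47). The generator's internal covariate scaler uses the
  theoretical uniform mean and standard deviation so truth summaries do not
  depend on the realized sample.
- Day-1 classes, day-2 classes, and both days' ordinal responses are drawn
  from the exact model above, using independent substreams of a
  `SeedSequence` so each layer is reproducible in isolation.
- An optional continuous layer draws intake *amounts* (zero-inflated gamma
  per food group and class) whose nil probabilities and medians are chosen
  so that the package's own ordinal coding reproduces the configured
  three-category system; this exercises the full preparation path.
- Truth summaries integrate over the covariate law by Gauss–Legendre
  quadrature (41 age nodes × 2 sexes): `true_initial_prevalence`,
  `true_aggregate_transition` (membership-weighted covariate-averaged
  transition matrix), and `true_usual_prevalence` (covariate-averaged
  per-subject stationary vector, matching the `individual` estimator's
  estimand). The quadrature is verified in the tests against a 200,000-draw
  Monte-Carlo oracle.
- `paper_like_config` bundles a survey-like default: 28 food groups with
  nil fractions spanning 0.10–0.93, three patterns of realistic (moderate)
  separation, and covariate effects of plausible magnitude. It is a
  demonstration regime, not a fit to any dataset.

**Scope.** The generator produces data exactly from the fitted model family
(local independence, measurement invariance, softmax structure). It is
designed for verifying estimator correctness — parameter recovery, interval
coverage, selection consistency — not for simulating violations such as
differential item functioning, serial dependence beyond first order, or
reporting error.

## 7. Numerical choices

- All mixture arithmetic is in log space; `rho` is floored at 1e-6 inside
  log-emission evaluation to keep the E-step finite when categories empty
  out (the stored `rho` itself is not floored).
- EM tolerance 1e-8 (relative log-likelihood gain), maximum 1000
  iterations, 20 random starts by default.
- The structural M-step uses analytic gradients; the softmax is always
  evaluated through a log-sum-exp with the reference category appended as a
  zero column.
- Seeds: every stochastic routine takes an integer seed; derived seeds are
  produced with `numpy` `SeedSequence`/generator spawning and stay below
  2^31.
- Observed information uses central differences with step 1e-5 on the
  packed vector; `rho` is packed as reference-category logits so the packed
  dimension equals the free-parameter count.

## 8. Limitations

- Two occasions identify the transition model only with measurement
  invariance and (by default) shared covariate slopes; with `K` large or
  items weakly separated the likelihood surface is multimodal and more
  starts are needed.
- The Markov extrapolation assumes time homogeneity: the day-1 → day-2
  transition law is taken to govern all future days. Two recall days cannot
  test this assumption.
- Usual prevalence in `individual` mode averages stationary distributions
  over the *sampled* covariates; it is a sample-average estimand, not a
  superpopulation integral, unless the sample is representative.
- Standard errors assume a correctly specified model; the bootstrap
  fallback is nonparametric over subjects but still conditions on the
  selected `K`.
- BIC selection is conservative at moderate sample sizes and weak
  separation (see §4).
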