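# dietlta

Latent transition modelling of short-term dietary pattern data, with
Markov-chain extrapolation to the *usual* (long-run) prevalence of each
pattern.

## The problem

National dietary surveys typically collect two 24-hour recalls per
participant. A latent class model applied to a single day classifies people
by what they ate *that day*, which mixes stable dietary habit with large
day-to-day variation: a single recall day is a noisy snapshot, not a habit.
`dietlta` addresses this in three steps:

1. **Measurement model.** Food-group intakes from each recall day are coded
   into three ordinal categories (nil, at or below the consumer median, above
   it). A latent class model with item-response probabilities `rho[j, k, c]`
   describes the probability that a member of pattern `k` falls in category
   `c` of food group `j` on a given day. The same `rho` applies to both days
   (measurement invariance), so a pattern means the same thing on day 1 and
   day 2.
2. **Transition model.** A latent transition model links the two days: each
   subject has a day-1 pattern drawn from a multinomial-logistic model on
   age and sex, and a day-2 pattern drawn from a transition matrix whose
   rows are multinomial-logistic in the same covariates. Both structural
   blocks and the measurement block are estimated jointly by EM over all
   `K x K` latent paths.
3. **Usual prevalence.** Treating days as steps of a time-homogeneous Markov
   chain, each subject's covariate-specific transition matrix is iterated to
   its stationary distribution; averaging these over the sample gives the
   usual prevalence of each pattern — the share of the population whose
   long-run day draw lands in each pattern once single-day noise has been
   integrated out.

The package also provides the supporting machinery: data preparation
(rare-food-group exclusion, consumer-median ordinal coding, day-to-day
intraclass correlations), model selection (AIC/BIC/relative entropy over a
range of `K`), covariate odds ratios with standard errors from the observed
information matrix, a synthetic-cohort generator with known ground truth,
and a YAML-configured end-to-end pipeline with a command-line interface.

## Worked example

Generate a synthetic two-day cohort with known truth, fit a two-pattern
transition model, and extrapolate to usual prevalence:

```python
import numpy as np
from dietlta import (GeneratorConfig, generate_population, lta_em_fit,
                     aggregate_transition_matrix, usual_prevalence,
                     membership_odds_ratios)

rho = np.full((6, 2, 3), 0.1)        # 6 food groups, 2 patterns, 3 categories
rho[:, 0, 0] = 0.8                   # pattern 1: mostly nil
rho[:, 1, 2] = 0.8                   # pattern 2: mostly above-median
config = GeneratorConfig(
    n_subjects=800,
    rho=rho,
    beta1=np.array([[0.4, -0.5, 0.7]]),       # day-1 membership logit
    trans_intercepts=np.array([[2.0], [-1.8]]),
    gamma=np.array([[-0.5, 0.7]]),            # covariate effects on transitions
)
cohort = generate_population(config, seed=42)

fit = lta_em_fit(cohort.ordinal, cohort.covariates, K=2, n_starts=4, seed=0)
print(f"log-likelihood: {fit.loglik:.2f}  BIC: {fit.bic:.2f}  "
      f"entropy: {fit.relative_entropy:.3f}")

P = aggregate_transition_matrix(fit, cohort.covariates)
prev = usual_prevalence(fit, cohort.covariates, mode="individual")
print("day-1 prevalence:", np.round(fit.posterior.mean(axis=0), 3))
print("usual prevalence:", np.round(prev.usual, 3))
print(P.round(3))

ors = membership_odds_ratios(fit, cohort.ordinal, cohort.covariates, seed=0)
print(ors[["class", "covariate", "or", "ci_low", "ci_high"]].round(3))
```

Output:

```
log-likelihood: -6899.61  BIC: 13993.08  entropy: 0.970
day-1 prevalence: [0.652 0.348]
usual prevalence: [0.625 0.375]
[[0.906 0.094]
 [0.162 0.838]]
 class    covariate    or  ci_low  ci_high
     1 age_per_year 0.967   0.960    0.974
     1          sex 1.545   1.196    1.995
```

The generating truth for this configuration is a day-1 prevalence of
(0.662, 0.338) and a usual prevalence of (0.644, 0.356); the per-year age
odds ratio of membership in pattern 1 is 0.974 (estimated 0.967) and the
sex odds ratio is 2.01 (estimated 1.55 in this single replicate). Because
the diagonal of the transition matrix is below one, the usual prevalence
differs from the day-1 snapshot: the less stable pattern loses ground in
the long run.

The same analysis is available from the command line:

```bash
dietlta simulate --seed 42 --n-subjects 800 --out-dir sim/
cat > run.yaml <<'YAML'
recalls_csv: sim/recalls.csv
covariates_csv: sim/covariates.csv
out_dir: results/
lca_k_range: [1, 2, 3]
lta_k_range: [2, 3]
n_starts: 5
seed: 1
YAML
dietlta run --config run.yaml
```

`dietlta run` writes selection tables, fitted parameters, pattern profiles,
the aggregate transition matrix, day-1/day-2/usual prevalence, covariate
odds ratios, and a Markdown summary. See `dietlta --help` for the individual
stages (`prepare`, `fit-lca`, `fit-lta`, `select`, `prevalence`,
`stationary`).

## Documentation

`docs/methods.md` describes the model, its assumptions, the estimation
details, the synthetic-data generator, and the numerical choices and
limitations.
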