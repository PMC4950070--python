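# Methods

## The model

`surrometa` evaluates multiple surrogate endpoints at the study level by
multivariate random-effects meta-analysis. Study *i* reports treatment-effect
estimates `Y_ji` on outcomes *j* = 1..N (in the RRMS example: log MRI
lesion-count rate ratio, log annualised relapse-rate ratio, log odds ratio of
disability progression), with a known within-study covariance

    Y_i ~ N(mu_i, Sigma_i),   Sigma_i[j,k] = sigma_ji sigma_ki rho_w[j,k],

where the `sigma_ji` are the squared-error-derived SEs of the estimates and
`rho_w` the within-study correlations induced by shared patients. The true
effects follow a between-study model `mu_i ~ N(beta, T)` with
`T[j,k] = tau_j tau_k rho_b[j,k]`, written as a *product-normal chain*:

    mu_1i ~ N(eta1, psi_1^2)
    mu_ji | parents ~ N(lambda_j0 + sum_k lambda_jk mu_ki, psi_j^2).

Three covariance structures are supported: *unstructured* (every effect
conditions on all predecessors — any positive-definite `T`), *sequential*
(each on its immediate predecessor — tridiagonal precision matrix, so
`rho_b13 = rho_b12 * rho_b23`), and *custom* (arbitrary parent sets, zeroing
exactly the declared conditional independences).

Slopes are the multivariate-normal regression coefficients of a child on its
parents and `psi_j^2` is the exact Schur-complement conditional variance, so
the chain's marginal covariance reproduces `T` entry-for-entry for every
modelled correlation (verified by a Monte-Carlo property test). A commonly
printed shortcut, `psi_j^2 = tau_j^2 - sum_k lambda_jk^2 tau_k^2`, drops the
parent cross-covariance terms and is inconsistent with positive-definiteness
when parents are correlated; it is available behind `legacy_psi=True` for
audit only.

### Priors

Between-study correlations `rho_b ~ uniform(-1, 1)` (on the declared pairs);
between-study SDs `tau_j` half-normal with variance 10 (essentially flat over
the plausible 0–2 range for log-scale effects); `eta1` and the intercepts
`lambda_j0` normal with variance 1000; a missing within-study *variance*
uniform(0.001, 1000). States whose implied `T` is not positive definite
(equivalently any `psi_j^2 <= 0`) carry zero prior density, which for the
unstructured model induces mild non-uniformity in the marginal correlation
priors; for the sequential model every `|rho| < 1` is valid and the marginals
stay uniform (checked by a prior-predictive test).

### Computation

Both levels are normal with fixed `Sigma_i`, so the true effects integrate
out exactly: each study contributes `Y_i,obs ~ N(beta_obs, (T + Sigma_i)_obs)`
over its observed components, and missing estimates simply drop out of the
likelihood. MCMC therefore only explores the 5–9 hyperparameters, using an
affine-invariant ensemble sampler (emcee) on the transformed scale
`(eta1, lambda_j0, log tau, atanh rho)` with Jacobians. `iterations` and
`burn_in` count draws summed over walkers (defaults 50,000 / 20,000,
mirroring a conventional single-chain run); convergence is monitored by
split-R-hat over walker groups with a 1.05 warning threshold. Latent
quantities — per-study true effects, imputed missing estimates, predictions —
are recovered per retained draw from the exact conditional normals, so
nothing is lost relative to sampling them explicitly, and the usual
autocorrelation problems of Gibbs sampling the centred hierarchy (for which
centring of true effects is offered as a flag) do not arise.

## Within-study correlations from Prentice criteria

When IPD are unavailable, the correlation between two effect estimates is
derived from published individual-level surrogacy coefficients. The
adjusted association `rho_Z = (beta - beta_S)/alpha * sqrt(omega_SS/omega_FF)`
equals the residual correlation of surrogate and final responses given
treatment, and converts to the estimate-level correlation through the
arm-level variances (`within_correlation`). Published coefficient tables
often omit the residual variances; the variance ratio then defaults to 1
with a prominent warning, and user-supplied correlations are the
authoritative path — the RRMS fixture ships the published constants
(0.25, 0.09, 0.09), which depend on unavailable single-study arm-level
algebra and are not re-derivable from the printed coefficients alone.

## Effect scales for the RRMS data

MRI lesion counts: log ratio of arm means with the delta-method SE
`sqrt((se_t/m_t)^2 + (se_c/m_c)^2)`. Relapse rate: log annualised rate
ratio; the tabulated counts are *annualised*, so the Poisson count behind
the SE is the total over follow-up (`count * followup_years`), giving
`se = sqrt(1/total_t + 1/total_c)`. This calibration reproduces the
precision moments used to parameterise the simulation gamma laws
(E = 30/150/25, V = 420/15000/275 across the three outcomes).
Disability progression: log OR with `sqrt(sum of reciprocal cells)`; an
optional 0.5 continuity correction (off by default — the example data have
no zero cells). All three scales are antisymmetric under arm swap and their
delta-method SEs are validated against 10^6-draw simulation oracles.

## Cross-validation

Take-one-out validation masks only the final-outcome estimate *and its SD*
of one study per fold; the study's surrogate estimates stay in the
likelihood. The predicted *estimate* adds within-study noise to the
conditional true-effect draw: the observed SE is used when forming the
interval compared against the observed estimate (masking the SD during
fitting is exact — it never enters the observed-data likelihood); for a
genuinely new study the variance is drawn from its uniform prior. Width
comparisons use log-scale interval widths (symmetric, invariant to
exponentiating the endpoints); exponentiated-scale widths are also emitted.
Folds are seeded deterministically from the master seed and the study index,
so results are independent of fold order and fully reproducible.

## Synthetic data generator

The generator emulates a 15-study meta-analysis calibrated to the RRMS
data: `tau = 0.5` on all outcomes, `rho_b = 0.8` on modelled pairs,
`eta1 = -0.3`, zero intercepts, within-study correlations
(0.25, 0.09, 0.09), and within-study variances `1/P` with per-outcome gamma
precisions (shapes 2.14/1.5/2.3, rates 0.07/0.01/0.09 by method of
moments). Precisions implying variances above 2 are redrawn one at a time;
per-draw, per-study and per-dataset incidences are recorded (analytically
~0.03%, ~0.09% and ~1.3% respectively under these parameters). Families:
normal; location-scale t chains with `nu_j = psi_j^2 (df-2)/df`, df = 4
(variance-matched to the normal chain) and multivariate-t estimates with
scale `Sigma_i`; and a first-outcome three-component normal mixture
(weights 0.5/0.3/0.2, component means `eta1` and `eta1 -/+ 4 psi_1`).

What the generator does *not* emulate: arm-level count data (effects are
drawn directly on the log scales), non-exchangeable studies, outcome
reporting biases, or per-study within-correlation heterogeneity. Passing
simulation tests therefore demonstrate correct inference under the stated
generative conditions, not robustness to those real-data features.

## The simulation study

Per replicate, one dataset is generated, the last study's final outcome is
masked, each model (bivariate reference plus trivariate variants) is
fitted, and the predicted *true* held-out effect is scored against the
simulated truth: bias, RMSE, 95%-interval coverage, and the median
trivariate/bivariate interval-width ratio. Desk-scale runs use ~100
replicates with ~13k retained draws per fit; the full-scale option is the
same code at 1000 replicates and larger draw counts.

A structural observation worth stating: with the calibrated precisions the
relapse-rate estimate is nearly noiseless (mean precision 150), so under a
sequential-truth scenario the conditional variance of the final-outcome
effect given both surrogates essentially equals that given the relapse
surrogate alone. Exact inference therefore yields trivariate/bivariate
width ratios close to 1.0 under sequential generative conditions, modest
gains (ratio ~0.92–0.96) only under unstructured truth where the first
surrogate carries direct information (`rho_b13 > rho_b12 rho_b23`), and
cross-validation width reductions on the RRMS data near zero. Coverage sits
at the nominal 0.95 (inflated under the mixture family, where a single
normal approximates three components), and bias is within Monte-Carlo error
of zero.

## Numerical choices and edge cases

- Ensemble size: `max(24, 2*dim + 6)` walkers, initialised in a small ball
  around data-driven marginal means with heterogeneity SD 0.3; initial
  positions are resampled until all walkers have finite posterior density.
- Chain construction rejects states with any `psi_j^2 <= 0`; batched 3x3
  covariance algebra uses `slogdet`/`solve`, flagging non-PD within-study
  sums as zero-likelihood.
- Quantile summaries are equal-tailed 2.5/50/97.5 percentiles; exponentiated
  summaries are computed draw-by-draw, so log-scale and ratio-scale interval
  endpoints agree up to quantile interpolation.
- Degenerate single-outcome models reduce to the normal-normal
  random-effects meta-analysis (validated against the conditional
  closed-form pooled mean).
- Studies contributing no observed outcome are dropped with a warning; an
  outcome observed in no study, fewer than 3 usable studies, or a constant
  treatment indicator in the IPD fit raise errors.
- Cross-validation folds that fail to fit are flagged and excluded from
  summaries with a count; simulation replicates likewise.

## Known limitations

- Within-study covariances are treated as known; correlation uncertainty
  (e.g. via double bootstrap) is out of scope.
- Normal within-study likelihoods only; exact binomial/Poisson likelihoods
  are not implemented.
- The bivariate-vs-trivariate precision comparisons depend on the reference
  model's predictive spread; alternative comparator implementations
  (different parameterisations or samplers) can report larger apparent
  gains than exact inference produces under these conditions.
- DIC-style model comparison is deliberately omitted (definition-sensitive
  across samplers).
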