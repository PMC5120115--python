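# Methods note

## Causal model and estimands

The package targets a life-course mediation question: how much of the effect
of childhood socioeconomic status (CSES, an ordinal exposure coded 1–4 from
affluent to poor) on adult health runs through childhood abuse (two coupled
binary mediators, psychological and physical)?

Effects are estimated by the **difference method**:

- Total effect `TE`: coefficient on the exposure in
  `outcome ~ exposure + confounders`.
- Direct effect `DE`: coefficient on the exposure when both mediators are
  added jointly.
- Indirect effect `IE = TE − DE`; proportion mediated `PM = IE / TE × 100`.

`PM` is reported signed, not truncated: `PM < 0` or `PM > 100` flags
inconsistent mediation, and `PM` is set to NaN (with a warning) when
`|TE| < 1e-6`, where the ratio is numerically meaningless.

Identification assumes no unmeasured exposure–outcome or mediator–outcome
confounding and — critical for the difference method — **no
intermediate confounding**: no descendant of the exposure may be a common
cause of a mediator and the outcome. The generator's dependency graph is
exported by `SimulationParams.dependency_edges()` and this property is
verified structurally in the test suite. The co-occurrence of the two
mediators is modelled as a *bidirected* (non-causal) coupling precisely so
that neither mediator is an ancestor of the other.

For binary endpoints (abuse reports), associations are expressed as relative
risks from **modified Poisson regression**: a log-link Poisson GLM with HC0
sandwich standard errors, which consistently estimates the RR for binary
outcomes without the non-collapsibility of odds ratios. Continuous endpoints
use OLS.

## Differential recall bias

Two recalled versions of the exposure exist:

- `cses_t4` (early report): nondifferential misclassification — each report
  moves ±1 category symmetrically with probability `p_misclass_t4`.
- `cses_t6` (late report): differential misclassification — the probability
  of recalling a *worse* childhood is `expit(κ0 + δ·z)` and a *better* one
  `expit(κ0 − δ·z)`, where `z` is the standardized mean of the subject's
  latent health outcomes and `κ0 = logit(p_misclass_t4 / 2)` so the overall
  error rate matches the early wave at `δ = 0`. The contamination slope
  `δ = delta_recall` is the key study dial; `δ = 0` recovers a
  nondifferential late report.

Bias is quantified by percent differences taking the late report as
reference:

- linear scale: `(TE_t6 − TE_t4) / TE_t6 × 100` (and the same for DE);
- RR scale: `(ln RR_t6 − ln RR_t4) / ln RR_t6 × 100`, because RRs are
  multiplicative and percent changes on the raw RR scale depend on the
  arbitrary baseline.

Inference on these contrasts uses a *paired* bootstrap: both wave models are
refit on the same resample so the contrast's sampling correlation is
respected.

## Synthetic cohort generator

Defaults are the study conditions, chosen to emulate a population-based
Norwegian-style cohort; they are not free tuning dials.

| parameter | default | rationale |
|---|---|---|
| `n` | 10,000 | order of a large population survey |
| `p_female` | 0.54 | typical survey sex balance |
| `age_range` | (25, 74) | adult survey window |
| `confounder_prevalences` | (0.065, 0.025, 0.735, 0.979) | parental psychiatric history (mother/father), childhood passive smoking, native-born — plausible registry prevalences |
| `cses_category_probs` | (0.037, 0.626, 0.313, 0.024) | very good / good / difficult / very difficult childhood finances |
| `log_rr_psych`, `log_rr_phys` | ln 1.85, ln 1.60 | per-category abuse risk gradients |
| `baseline_abuse_risk` | (0.033, 0.028) | abuse risk in the most affluent category |
| `mediator_coupling` | 3.5 (log OR) | strong psychological/physical abuse co-occurrence |
| `beta_direct` | 0.15 | direct CSES effect per category on the 0–10 outcome |
| `beta_psych`, `beta_phys` | 0.40, 0.30 | mediator effects on outcomes |
| `noise_sd` | 1.2 | residual outcome SD |
| `p_misclass_t4` | 0.26 | calibrated so the early report's linearly weighted kappa against true CSES is ≈ 0.63 under the default category distribution (bisection in `calibrate_misclassification`) |
| `delta_recall` | 0.5 | moderate outcome contamination of the late report |

Generation steps: confounders and demographics are drawn independently; true
CSES follows a proportional-odds model shifted by confounder loadings; the
two abuse indicators are drawn jointly from a **Plackett copula** (a joint
Bernoulli distribution with the specified marginal risks and log odds-ratio
coupling), so the marginal per-category RRs are preserved exactly while
co-occurrence is realistic; outcomes are linear in exposure, mediators,
confounders and gender terms plus Gaussian noise, clipped to the 0–10
instrument range (the unclipped latent values are kept in `*_latent` columns,
and a warning is emitted if more than 1% of values clip); finally the two
recall waves are produced as above. Missingness, when requested, is missing
at random given gender and age, with the marginal rate hit by bisection on
the logistic intercept.

## Numerical and algorithmic choices

- **BCa bootstrap**: bias correction `z0 = Φ⁻¹(#{θ* < θ̂}/B)`; acceleration
  `a` from the jackknife third-moment formula. Jackknife refits are capped
  at 200 **delete-groups** (exact leave-one-out when `n ≤ 200`) to bound
  cost on large cohorts; grouping slightly smooths `a`, which is second
  order for the interval. Quantiles use the nearest-order-statistic
  (type-1) rule, matching the discrete bootstrap distribution. Degenerate
  replicate distributions (constant, or all on one side) trigger a
  **percentile fallback** with a warning instead of undefined BCa formulas.
- **Shared resampling plans**: all statistics in one table reuse the same
  resample-index matrix, so contrasts between them are computed on paired
  replicates. Resampling can be stratified (default: by gender).
- **Fast bootstrap path**: inside the bootstrap loop, OLS decompositions are
  computed with `numpy.linalg.lstsq` on prebuilt design matrices; the point
  estimate is cross-checked against the full statsmodels fit to 1e-8 at
  every call.
- **Modified Poisson**: `statsmodels` GLM with `cov_type="HC0"`; convergence
  failure raises, fitted risks approaching 1 warn (RR interpretation
  unstable), rank deficiency raises naming the collinear terms.
- **MICE**: chained equations with proper Bayesian draws (scaled
  inverse-χ² variance, multivariate-normal coefficients) for continuous
  columns, posterior-draw logistic imputation for binary columns, and
  rounded/clipped linear draws for small-integer ordinal columns.
  Predictive mean matching is intentionally out of scope. Rubin's rules:
  pooled variance `W + (1 + 1/m)·B`.
- **Determinism**: every stochastic routine takes an explicit seed; derived
  seeds are drawn below 2³¹; identical configurations give byte-identical
  CSV output (asserted in the test suite).

## Limitations

- The generator's outcome model is linear-additive with Gaussian noise;
  clipping to the instrument range introduces mild floor/ceiling distortion
  relative to the latent scale (both scales are exposed so the distortion
  can be measured).
- The difference method assumes no exposure–mediator interaction on the
  outcome scale used; `screen_interactions` tests this but the decomposition
  does not model interactions.
- Recall contamination is driven by a single latent-health index; real
  recall processes may depend on specific symptoms, social desirability, or
  interview mode.
- The percent-difference estimand has unbounded sampling noise when the
  reference-wave effect is near zero; point estimates should be read with
  their bootstrap CIs (the pipeline always reports both).
- Grouped jackknife acceleration and the B used in table production trade a
  small amount of interval accuracy for runtime; for publication-grade CIs
  increase `B` in `RunConfig`.
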