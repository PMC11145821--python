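# Methods

This note documents the statistical recipe implemented in `hdmediation`:
the models, the four-stage procedure, every tunable that matters, the
synthetic-data generator behind the benchmark, and the numerical and
design choices made where the construction was genuinely open.

## Models and estimands

For individual i with binary exposure X_i, continuous outcome Y_i,
mediators M_i ∈ R^p (p ≫ n) and confounders C_i ∈ R^q:

    M_ki = a_k + α_k X_i + φ_kᵀ C_i + e_ki,     k = 1..p
    Y_i  = a + γ X_i + βᵀ M_i + ηᵀ C_i + ε_i

The indirect effect of mediator k is α_k β_k (product-of-coefficients
definition); γ is the direct effect.  Identification relies on the usual
sequential-ignorability conditions: parallel (causally non-interacting)
mediators, no unmeasured confounding of any of the three edges, no
exposure-induced mediator–outcome confounding, consistency and
positivity.  The package tests H₀: α_k β_k = 0 per mediator and reports
the share of the total effect, %TE_k = 100·α̂_k β̂_k / (γ̂ + Σ_j α̂_j β̂_j)
with the sum over significant mediators (an absolute-value variant is
available for reports with sign-mixed effects).

## Stage 1 — propensity scores and adjustment schemes

The propensity score π_i = P(X_i = 1 | C_i) is fit by maximum-likelihood
logistic regression with intercept (statsmodels `Logit`; constant
confounder columns are dropped; separation or non-convergence is flagged
and the scores are clipped to [1e−6, 1−1e−6]).  Four adjustment schemes
share one weighted-least-squares engine:

| scheme | mechanism | weights |
|--------|-----------|---------|
| `ra`   | confounders as covariates | none |
| `psr`  | fitted score as the single covariate (its coefficient estimated) | none |
| `ipw`  | inverse probability weighting | X/π + (1−X)/(1−π), ≥ 1, unbounded |
| `ow`   | overlap weighting | 1−π if exposed else π, in (0,1) |

Weighted fits default to heteroskedasticity-robust (HC0 sandwich)
standard errors, because balancing weights are not precision weights;
naive WLS errors are available (`robust=False`).  Overlap weights balance
every covariate of the score model exactly at the logistic MLE, a
property the tests verify to 1e−6.  Diagnostics report the weight range
and effective sample size (Σw)²/Σw².

## Stage 2 — confounding-controlled screening

Screening keeps the d = ⌊2n/log n⌋ (natural log; capped at p) mediators
with the largest adjusted |β̂_k|.  Under `ra`/`psr`, β̂_k comes from OLS
of Y on (1, X, M_k, C) or (1, X, M_k, PS).  Under `ipw`/`ow`, a two-step
estimator is used: a weighted fit of Y on (1, X, M_k) yields γ̂_k, and
the exposure-adjusted outcome Y − γ̂_k X is regressed on M_k without
weights.  Both paths are vectorised over mediators (partitioned
regression for the covariate paths, batched 3×3 solves for the two-step
path) and verified against per-mediator statsmodels fits.

Two caveats are deliberate and documented: (i) the marginal two-step
statistic absorbs a confounding offset through the shared
confounder→mediator effect; because the offset is common to all
mediators it does not disturb the ranking, which is all screening uses
(the tests pin both the offset's uniformity and the estimator's
consistency in the no-direct-confounding regime); (ii) ranking by the
product |α̂_k β̂_k| is available (`basis="alpha_beta"`) but non-default —
with confounding it is a markedly weaker screen.  Ties are broken by
ascending mediator index for cross-platform determinism.

## Stage 3 — penalized estimation

Both second-stage fits run on (X, M_screened, covariates) with X and
covariates unpenalized and all columns standardized internally; estimates
return on the original scale.  The core solver is a numba coordinate
descent on the Gram formulation with active-set iteration; its
single-coordinate solution equals the firm-thresholding closed form, its
objective is non-increasing across sweeps, and at δ → ∞ it recovers the
Lasso (checked against an independent proximal-gradient oracle).

**MCP selection** (`hima` path).  Minimax concave penalty
P_{λ,δ}(b) = λ(|b| − b²/(2λδ)) for |b| < δλ, else λ²δ/2, with δ = 3
(conventional) and λ chosen by BIC (default; AIC available) over 100
log-spaced values from λ_max down to λ_max/1000 with warm starts.

**De-biased Lasso** (`mhima2` path).  Initial Lasso with λ by 10-fold
cross-validation (deterministic folds from the pipeline seed; mediator
columns penalized, X and C not), then the nodewise-regression correction:
for each target column j, a Lasso of that column on the others yields the
j-th row of the approximate precision matrix, and

    b̂ = β̂_init + Θ̂ Xᵀ(y − Xβ̂_init)/n,
    se_j = σ̂ · sqrt([Θ̂ Σ̂ Θ̂ᵀ]_jj / n),   p_j = 2{1 − Φ(|b̂_j|/se_j)}.

Design choices here, where the construction is genuinely open:

* the nodewise penalty is a single shared universal value
  λ_node = sqrt(2 log P / n) on standardized columns rather than per-node
  cross-validation — on the benchmark cells per-node CV changes estimates
  negligibly while costing ~50× the runtime; a `cv` option retains it;
* the noise level σ̂ is the scaled-Lasso estimate (iterate σ² = RSS/n
  with a Lasso at λ = σ·λ_node to a fixed point); the df-corrected
  RSS/(n − #nonzero) is available as `noise_estimator="df"`;
* the outcome model is unweighted with C entered unpenalized under every
  adjustment scheme (PS replaces C under `psr`): the weights serve the
  screening and α-inference stages.  A weighted variant is exposed.

De-biased estimates are scale-equivariant in each mediator column and
reduce to OLS z-tests in low dimension; both properties are under test.

## Stage 4 — mediation testing

α-inference per candidate: OLS of M_k on (1, X, C) (`ra`), on (1, X, PS)
(`psr`), or the weighted analogue with sandwich errors (`ipw`/`ow`),
vectorised over candidates.  β-inference: the de-biased Lasso p-values
(`mhima2`), or, on the MCP-selected set, the joint OLS refit of Y on
(1, X, M_selected, covariates) (`hima`).  The raw statistic is
P_raw,k = max(P_α,k, P_β,k).

**JS-uniform + BH** (`hima`).  Benjamini–Hochberg step-up on P_raw.  The
multiplier defaults to the candidate count, but the classic workflow
corrects against the full mediator universe p — the behaviour that
reproduces the reference operating characteristics (near-zero FDP with
moderate power) and the reason this route is conservative.

**JS-mixture** (`mhima2`).  The composite null has three components:
H00 (both effects null), H01 (α null, β non-null), H10 (α non-null,
β null).  Marginal null fractions are estimated from each p-value set by
the Storey estimator with λ = 0.5 and combined under cross-independence:
π̂00 = π̂_α0 π̂_β0, π̂01 = π̂_α0(1−π̂_β0), π̂10 = (1−π̂_α0)π̂_β0.  The
pointwise FDR at threshold t uses Pr(P_max ≤ t | H00) = t² and ≈ t under
H01/H10 (the non-null p-value treated as stochastically dominated by
uniform — the estimator's defining, conservative approximation):

    FDR̂(t) = q·(π̂00 t² + π̂01 t + π̂10 t) / max(R(t), 1),  clipped to [0,1],

evaluated at each candidate's own P_raw, followed by a step-up
monotonicity correction (cumulative minimum from the largest threshold)
so calls are threshold-consistent.  Significance level 0.05 throughout,
exposed as a flag.

## Synthetic-data generator

The generator emulates a confounded observational epigenetic study and
defines the benchmark conditions:

* 8 confounders: C1–C4 multivariate normal, zero mean, unit variance,
  pairwise covariance 0.3; C5–C8 independent Bernoulli(0.3);
* exposure: X ~ Bernoulli(expit(θᵀC)) with no intercept,
  θ = (0.2, 0.2, 0.3, 0.3, 0.2, 0.2, 0.3, 0.3) (exposure prevalence
  ≈ 0.57);
* mediators: a_k ~ U(0,1) drawn once per mediator per replication;
  φ_k = θ shared across k; α = (0.4, 0.4, 0.5, 0.5, 0.5, 0.5, 0, …);
  errors e_k i.i.d. N(0, 1.2) (variance reading; the SD reading is a
  config switch) for ρ = 0, or AR(1) with covariance ρ^|k−k′| and unit
  diagonal for ρ ∈ (0,1), generated by the exact AR recursion;
* outcome: γ = 0.5, a = 0.5, η = θ, β = (0.4, 0.5, 0.5, 0.6, 0, 0, 0.5,
  0.5, 0, …), ε ~ N(0,1).

True mediators are M1–M4 with indirect effects (0.16, 0.20, 0.25, 0.30);
M5–M6 are α-only, M7–M8 β-only decoys.  The variance reading of the
error scale puts null-mediator pairwise correlations near 0.31 (inside
the intended 0.15–0.35 band) and the unit-diagonal AR(1) choice puts
adjacent-mediator correlations near 0.35/0.51/0.68/0.84 for
ρ = 0/0.25/0.5/0.75.  RNG streams are split per component (confounders,
exposure, intercepts, errors), so changing p leaves X and C untouched.

What the generator does *not* emulate about real methylation data:
beta-value boundedness ([0,1] with heteroskedastic variance), probe-level
measurement error, batch effects, cell-type composition, and non-AR
correlation structure (co-methylated blocks).  Passing benchmarks
therefore demonstrate the statistical machinery under the stated model,
not robustness to array artefacts.

## Benchmark and metrics

`run_benchmark` replays `reps` independent replications per scenario ×
(workflow, adjustment) cell; all methods see identical datasets.
Per-replication seeds are a counter-based split of the master seed, so
parallel and serial execution agree and any cell reproduces in
isolation.  Metrics: TPR_k = fraction of replications with true mediator
k significant; overall TPR = mean over the four; FDP = mean of
(#false / max(#significant, 1)) with 0/0 → 0; Mean/MSE of α̂_k β̂_k are
reported both conditional on a significant call (primary, matching how
an estimate only exists when the mediator survives the pipeline) and
over all replications where the mediator reaches the candidate stage.
Monte-Carlo SE of a rate is sqrt(q(1−q)/reps).

The shipped acceptance suite uses the p = 1000 cells at 100 replications
(and 200 for the global-null calibration check) — sizes chosen so the
whole suite replays in minutes on a single CPU while keeping Monte-Carlo
SEs near 0.02–0.03; the full-scale study design (500 replications,
p up to 10,000) runs through the same `benchmark` entry point.

## Numerical details and edge cases

* Coordinate descent: tolerance 1e−8 on the maximum coefficient change
  (1e−5 inside CV folds), descending-λ warm starts, active-set inner
  loops; unpenalized coordinates update by exact least squares.
* Degenerate inputs raise early with specific messages: empty exposure
  class, constant mediator columns, rank-deficient designs (the offending
  columns are named), d ≥ n, invalid p-values or null proportions.
* An empty post-MCP candidate set returns an empty report, not an error.
* The propensity separation path falls back to IRLS via GLM, flags
  `converged=False` and clips scores; downstream weights stay finite.
* %TE is reported only from significant calls; with γ̂ + Σα̂β̂ = 0 the
  column is NaN rather than infinite.

## Known limitations

* Continuous outcomes only; no binary/survival outcome models.
* Parallel-mediator assumption: no causal ordering among mediators.
* The two-step screening statistic is a ranking device, not an unbiased
  effect estimate, under direct confounder→outcome effects.
* The mixture-null FDR relies on cross-independence of the two p-value
  sets and the stochastic-dominance approximation for non-null
  components; under strong dependence between the α and β test statistics
  its calibration degrades.
* No unmeasured-confounding sensitivity analysis, PS matching or
  stratification, machine-learning PS estimators, or iterative/conditional
  screening variants.
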