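# Methods

This note documents the models, algorithms and numerical choices behind
`tailorfit`, what the simulations do and do not emulate, and the problem
sizes used in the shipped tests and reproduction script.

## Population models and data generation

All population models are standardized: factors have unit variance,
continuous latent responses have unit variance, and residual variances are
derived as θⱼ = 1 − (λ²ⱼ₁ + λ²ⱼ₂ + 2 λⱼ₁ λⱼ₂ Cov(F₁,F₂)).  Four scenario
families are built in:

- **dim_correct** — one factor, fitted as one factor (correct);
- **dim_misspec** — two factors correlated at r ∈ {.70, .50, .30}, fitted as
  one factor; the lower r, the larger the misspecification (parameter
  difference 1 − r from the one-factor view);
- **cross_correct** — two factors (r ∈ {.00, .30}), fitted as two factors
  with the correlation estimated (or fixed to zero when the population is
  uncorrelated);
- **cross_misspec** — as cross_correct plus standardized cross-loadings of
  .20 or .30 on 17% or 33% of indicators, omitted from the analysis model.
  Proportions map to counts by rounding (6 indicators → 1 or 2; 12 → 2 or
  4), and the cross-loadings sit on the *first* indicators of factor 2,
  loading on factor 1.  These two conventions (rounding, placement) are our
  fixed interpretation of the design; any order-preserving placement is
  statistically equivalent under the exchangeable indicator design.

Ordinal responses are produced by cutting each latent response at K−1
thresholds.  The design prescribes moments of the categorical score
distribution, not thresholds: skewness 0 (symmetric) or 0.65 (asymmetric),
excess kurtosis ≈ −0.80.  We parameterize the K category probabilities by a
softmax over free log-weights — mirror-symmetric by construction when the
target skewness is zero — and minimize the squared moment deviation
(Nelder–Mead, four deterministic starts, accepted only below 1e−6 residual).
Thresholds are the normal quantiles of the cumulative probabilities.  For
K > 3 the moment conditions do not pin the distribution down uniquely; the
solver's deterministic start sequence fixes one solution.  Reference cutoff
values were produced under one such categorization whose exact thresholds
are not available, so quantities that depend on categorization detail
(mainly low-loading asymmetric cells) are compared with extra tolerance.

A dataset is accepted only if every response option of every indicator has
at least five observations — the estimation of thresholds requires occupied
categories — and is otherwise re-simulated *wholesale* from the next random
substream (the sparsity rule is read as a dataset-level acceptance rule).
The resample count is recorded; the rate concentrates where expected
(small N, many options, asymmetric distributions).  A cap (default 1000
attempts) turns pathological cells into logged, skipped replications
instead of livelock.

## Estimation

**ML.** Codes 1..K are treated as numeric.  With S the divisor-N sample
covariance, we minimize F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p over loadings
(first per factor fixed at 1), factor variances, the factor covariance and
residual variances; T = N·F.  Variances are optimized on the log scale and
the factor covariance through an atanh-scale correlation, which keeps the
covariance matrix admissible; a residual variance pinned at the lower bound
is retained and flagged as a Heywood solution rather than culled.  Gradients
are analytic (trace identities through the parameter transform); L-BFGS-B
with two start vectors (the documented defaults — loadings .5, variance 1,
correlation 0 — then moment-informed values).  Only optimizer failures
count as non-converged and are culled downstream.

**MLR.** The ML statistic is divided by c = tr(U Γ)/df, with Γ the
fourth-moment (asymptotically distribution-free) covariance of vech(S)
computed with divisor N (consistent with T = N·F), and
U = W − WΔ(ΔᵀWΔ)⁻¹ΔᵀW built from the normal-theory weight
W = ½Dᵀ(Σ̂⁻¹⊗Σ̂⁻¹)D at the fitted Σ̂ and the model Jacobian Δ.  The
independence baseline is scaled the same way with its own (diagonal)
Jacobian.  Standard errors beyond what the statistic requires are out of
scope.

**Polychorics.** Two-step estimation: thresholds from normal quantiles of
cumulative margins; each pairwise correlation by maximizing the
bivariate-normal likelihood of the contingency table with thresholds held
fixed (bounded scalar search on |ρ| ≤ .999; hitting the bound is flagged).
Bivariate normal rectangle probabilities use Genz's quadrature scheme
(vectorized, ~1e−14 absolute accuracy, dedicated high-|ρ| branch).  The
asymptotic covariance Γ of √N(ρ̂ − ρ) is assembled from per-observation
influence functions of the two-step estimator: the correlation score plus
the propagated influence of the estimated thresholds
(g = [s_ρ − Σ i_ρτ δ_τ]/i_ρρ per contingency cell), whose empirical
covariance across observations estimates Γ — including covariances across
indicator pairs.  A Monte Carlo test confirms the diagonal tracks the
sampling variance of ρ̂.

**DWLS / WLSMV.** Theta parameterization: latent-response residual
variances fixed at 1, first loading per factor at 1, so the implied matrix
is the correlation matrix of ΛΨΛᵀ + I.  Thresholds are saturated and drop
out of the fit; the correlation vector is fitted by least squares weighted
by diag(Γ)⁻¹ (Levenberg–Marquardt with analytic Jacobian).  T = N·F̂.
DWLS reports T unadjusted.  WLSMV applies the mean-and-variance-adjusted
(scaled-and-shifted, df-preserving) transform aT + b with
a = √(df/tr(M²)), b = df − a·tr(M), M = UΓ,
U = V − VΔ(ΔᵀVΔ)⁻¹ΔᵀV, V = diag(Γ)⁻¹ — the adjustment modern SEM software
reports by default; the older Satterthwaite-df variant is not implemented.
The baseline is the zero-correlation model adjusted the same way (U = V).  DWLS and WLSMV share parameter estimates; only the statistic
differs.

## Fit indices

CFI = 1 − max(T−df, 0)/max(T_b−df_b, T−df, 0) (1 when the denominator is
0), RMSEA = √(max(T−df,0)/(df·N)) (undefined at df = 0), SRMR = RMS of
standardized residuals over the lower triangle including the diagonal
(zero diagonal contribution for correlation-matrix fits).  For MLR/WLSMV,
CFI and RMSEA are computed from the adjusted statistics of both target and
baseline — the "scaled" convention that standard SEM software reports by
default; the alternative "robust" index variants are not implemented.
RMSEA uses N, T uses N·F — the N versus N−1 choices shift results by well
under the stated tolerances.

## Engine and seeding

Replication (scenario, r) draws its generator from
SeedSequence(master, spawn_key=(crc32(scenario_id), r)), so results are
independent of execution order and sharding.  Resampling attempts consume
the same per-replication stream sequentially.  Records are tidy rows (one
per replication) with convergence, scaling and resampling accounting.

## Cutoffs

Tailored cutoffs are empirical quantiles over converged replications of
correctly specified scenarios: 95% for χ², χ²/df, RMSEA, SRMR; 5% for CFI;
α configurable.  Quantiles use linear interpolation between order
statistics (the common default; tail quantiles at 1000 replications differ
slightly across quantile types, which is part of the stated tolerance).
Type-I rates score correct-specification records against their own
cutoffs; Type-II rates score misspecified records against the cutoffs of
the correct-specification twin cell agreeing on all non-misspecification
characteristics.

The cutoff-prediction regression takes per-scenario cutoffs as responses
and regresses them, separately per index, on raw uncentered
characteristics: estimator dummies (ML reference), indicator count,
response options (+ square), asymmetry, loading (+ square), sample size
divided by 1000 (+ square), number of factors, their two-way interactions,
and correlated-factors only through its interaction with the factor count
— 74 terms.  Cells are unweighted.  SRMR is fitted on ML/DWLS cells only
and predicted for MLR/WLSMV by mapping to ML/DWLS, since the index is
unchanged by the statistic corrections.  The shipped coefficient file
(`tailorfit/data/cutoff_regression_coefficients.csv`) holds the published
full-scale estimates (per-index R² between .810 and .970, 1296 cells, 648
for SRMR); `fit_cutoff_regression` re-estimates the same structure from any
user-derived cutoff table.  χ² cutoff predictions always carry a warning:
they depend on the model df and travel poorly to other model shapes.

## Susceptibility analyses

Before regression, χ², χ²/df, RMSEA and SRMR are multiplied by −1 so lower
always means worse fit.  Characteristics enter with the design's reference
levels (ML, symmetric, uncorrelated), quadratics for >2-level numeric
characteristics, and all two-way interactions — no higher-order terms.
Characteristics held constant in a reduced run are dropped with a warning;
an aliased design raises with the offending terms.  Kendall tau-b (tie
corrections in both margins) measures bivariate associations.  Note that
with uncentered quadratics and interactions, individual linear coefficients
are not marginal effects; directional claims in the tests therefore use
tau-b or grouped medians.

## What the simulations do and do not emulate

The generator reproduces the design conditions: normal factors, standardized
indicators, moment-matched categorization, the five-per-cell resampling
rule.  It does not emulate missing data, non-normal latent distributions,
unmodeled residual covariances, more than two factors, or sampling designs
(clustering, weights).  Passing tests therefore demonstrate calibration of
the machinery under these idealized conditions, not robustness of the
indices in arbitrary real data — indeed the package's point is that index
distributions shift with the scenario.

## Problem sizes and tolerances in the shipped checks

The worked-example checks use the design's own scale (1000 replications,
N = 200).  Grid-level checks (factor-correlation inflation, Type-I
self-consistency, sensitivity signs) use stratified subsets of cells with
20–30 replications each — enough for medians and directional effects; the
full 6048-cell × 1000-replication design is supported by the engine but is
a multi-CPU-day computation and is not re-run.  Full-scale aggregates (overall non-convergence and resampling rates, the
cutoff-regression R² row) are consequently checked directionally or via
the embedded coefficient table, not re-estimated.  Parameter recovery
checks run at N = 2000 (±.05); the polychoric estimator is checked against
a 1e−3 grid-search oracle and the predictor against a term-by-term
summation oracle at 1e−10.

## Known limitations

- ML variances are log-parameterized, so Heywood cases surface as
  boundary solutions (flagged) rather than negative estimates; test
  statistics agree with unconstrained estimation to well within the Monte
  Carlo tolerances, but parameter estimates at the boundary differ from
  software that permits inadmissible values.
- The two-step polychoric Γ uses expected (model-evaluated) information at
  the estimates; in very sparse tables its finite-sample accuracy degrades
  (mitigated by the five-per-cell rule).
- The threshold solver fixes one of the moment-equivalent categorizations;
  cutoffs in cells sensitive to categorization detail inherit that choice.
- Delta parameterization (unit-variance latent responses with free
  residuals) is not offered; all categorical fits use the theta convention
  (latent-response residual variances fixed at one), which is what the
  identification scheme and the residual-variance formula assume.
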