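# Methods

This note documents the statistical model, the algorithmic choices, and the
limitations of `medhaz`, in the spirit of the model documentation shipped by
packages such as statsmodels or msprime.

## Model and estimating equations

The hazard of subject *i* is additive in the regressors,

    λᵢ(t) = λ₀(t) + γXᵢ + θᵀZᵢ + Σₖ βₖ Mₖᵢ ,

with an unspecified common baseline λ₀. Writing N(t) for the observed-failure
counting process and Y(t) for the at-risk indicator, the Lin–Ying
pseudo-score is U(P) = b − VP with

    b = (1/n) Σᵢ ∫ (Qᵢ − Q̄(t)) dNᵢ(t),
    V = (1/n) Σᵢ ∫ Yᵢ(t) (Qᵢ − Q̄(t))^⊗2 dt,

and Q̄(t) the at-risk average. Both integrands are piecewise constant
between observed times, so `hazard_statistics` evaluates them **exactly** as
finite sums over the ordered distinct times (no quadrature grid): the V
integral reduces to Qᵀdiag(T)Q minus a weighted sum of risk-set mean outer
products, which is three BLAS products and keeps a p = 10,000-column naive
analysis tractable. Subjects tied on time share a risk set; integration runs
over [0, max observed time], beyond which every Yᵢ = 0.

The unpenalized estimator solves VP = b (equivalently minimises
L(P) = ½PᵀVP − bᵀP; the solver asserts ‖VP̂ − b‖∞ ≤ 1e−8·(1+‖b‖∞)).
**Variance estimator:** the model's originating literature does not pin down
σ̂²_{βₖ}; we use the standard Lin–Ying sandwich V⁻¹DV⁻¹/n with D the average
squared centred score increment at event times. This is the one degree of
freedom most likely to produce small numeric differences from other
implementations of the same pipeline. A condition-number guard (10¹²)
refuses ill-conditioned designs and names the columns implicated by the
smallest singular vector; there is deliberately no pseudo-inverse fallback,
because silently dropped rank would corrupt the downstream Sobel standard
errors.

## Screening

Default utility: raw Pearson correlation between exposure and each mediator,
keeping the top d = [2n/log n] (round half up — the convention that maps
n = 833 to d = 248). Correlation screening targets the exposure leg of the
pathway; the outcome-side alternative (standardized marginal
additive-hazards coefficient, `statistic="marginal_hazard"`) is available
for sensitivity analysis. Ties in |score| break by ascending index so
rankings are platform-independent, and the screened set at size d is a
prefix of the set at any larger d.

## Penalized selection

Stage 2 minimises ½βᵀVβ − bᵀβ + Σⱼ p_λ(|βⱼ|) over the screened design with
the SCAD penalty (a = 3.7, the Fan–Li standard; only mediator columns are
penalized — the exposure and covariates stay in the model throughout,
mirroring the structural model. `penalize_all=True` exists for sensitivity
checks).

Two solvers are implemented:

* **stepwise (default):** the one-step local linear approximation. At each
  λ the penalty is linearised at the univariate estimates bⱼ/Vⱼⱼ, giving a
  per-column weighted lasso (weights p′_λ(|βⱼ,init|)) solved exactly by
  cyclic coordinate descent. Strong columns get near-zero weight and enter
  almost unpenalized; weak columns get full lasso shrinkage. This matches
  the "stepwise SCAD" algorithm of the R `ahaz` package, the reference
  implementation for penalized additive-hazards regression.
* **exact:** fully iterated coordinate descent where every update solves the
  exact univariate three-branch SCAD problem in closed form (candidates:
  the stationary point of each branch clipped to its region, plus the
  region boundaries; ties prefer the smaller coefficient). The objective is
  non-increasing across sweeps (asserted in debug mode) and the solution
  matches dense grid search on small problems.

The solvers differ materially on screened designs: exposure-correlation
screening makes every screened mediator a proxy of X, and the exact solver's
unshrunken jumps cause the cross-validated λ to collapse to the top of the
path (a near-empty model). The stepwise solver's lasso-like shrinkage of
weak columns yields the familiar U-shaped CV curve and stable selection of
the true mediators, and is therefore the default; the exact solver remains
available as `solver="exact"`.

λ is tuned on a 50-point log-spaced grid from λ_max (the smallest λ that
zeroes every penalized coefficient — computed per solver, since the
stepwise weights change the entry threshold) down to 10⁻³·λ_max, by K-fold
cross-validation (default 5) of the held-out quadratic loss
½βᵀV_test β − bᵀ_test β, the natural analogue of cross-validated partial
likelihood for this least-squares-type objective. Folds are a seeded
partition stratified by event status, redrawn (up to 10 times) if a fold
lacks events; the path is warm-started from zero at λ_max; ties in the CV
minimum resolve to the largest λ. The final coefficients come from a
full-data refit at λ*, and S₂ is the set of mediators with nonzero
coefficient.

## Testing and decomposition

Inference never uses the shrunken coefficients: the procedure refits the
unpenalized model jointly on (X, Z, M_S₂), which supplies β̂ₖ and sandwich
SEs (penalized estimates are biased and carry no tractable SE — refitting is
standard post-selection practice). The exposure leg α̂ₖ and its classical SE
come from per-mediator OLS of Mₖ on (1, X, Z). Each H₀: αₖβₖ = 0 is tested
with the Sobel statistic; BH and BY adjusted p-values are both computed over
the |S₂| hypotheses (the selected set, not all p), with significance
declared at 0.05 on the configured adjustment. Wald intervals use ±1.96·σ̂.

The decomposition TE = DE + IE holds exactly by construction
(DE = γ̂(x*−x), IE = Σₖ α̂ₖβ̂ₖ(x*−x), γ̂ from the same joint refit). The
exposure coefficient of the mediator-free fit is reported alongside as an
alternative total-effect estimate; the two differ in finite samples and the
gap is a useful diagnostic. The default contrast for a binary exposure is
x = 0 → x* = 1.

Baselines: the *naive* method runs the marginal analysis (X, Z, Mₖ) for
every mediator with BH over all p hypotheses (vectorised across mediators
by sharing the (X, Z) blocks of b, V, D — O(np) instead of p separate
fits); the *joint-significance* variant replaces the Sobel p-value with
max(p_α, p_β).

## Simulator

`generate` draws X ~ Bernoulli(0.6), Z₁ ~ Bernoulli(0.3), Z₂ ~ U(0,1),
mediator intercepts cₖ ~ U(0, 0.5) (fresh per cohort), errors e ~ N(0,1)
(optionally equicorrelated at ρ for the dependent-mediator setting), effect
vectors α = (1,1,1,1,0.5,0.5,0,…) and β = (1,1,1,1,0,0,0.5,0.5,0,…) — so
the true mediators are the first four — and hazard
5t + X + 0.4Z₁ + 0.4Z₂ + βᵀM. Event times invert the cumulative hazard
Λ(t) = 2.5t² + ηt against a unit exponential via the positive quadratic
root. A linear predictor η < 0 makes the hazard negative near t = 0; the
inversion is accepted whenever Λ is nonnegative at the solution (always
true for this quadratic, so redraws of the mediator errors are a guarded
corner case that is counted and logged rather than a practical concern).

Censoring is U(0, c) with c calibrated by root-finding on a fixed
20,000-draw Monte-Carlo sample of event times: the censoring probability is
E[min(D, c)]/c, monotone in c. The calibration sample draws the mediator
intercepts per subject so that it follows the *marginal* event-time law
across cohorts (each cohort redraws its own intercepts); the residual
calibration error is the Monte-Carlo error of that sample, well under one
percentage point. Only the mediator columns with βₖ ≠ 0 are generated for
calibration — the others cannot affect event times.

`run_study` replicates a scenario with per-replicate generators seeded as
(scenario seed, replicate index), so results are independent of worker
count and replicate order; failures are recorded and excluded, with >5%
failures aborting. Selection is scored against {k : αₖβₖ ≠ 0} (TPR; FP
count; FDP with the 0/0 := 0 convention, averaged over all replicates), and
per-mediator estimation metrics (mean IE estimate, 95% CI coverage,
empirical SD, mean Sobel SE) aggregate over the replicates in which that
mediator entered S₂.

What the simulator does *not* emulate: beta-value boundedness ([0,1] with
heteroscedastic noise), probe-level correlation structure beyond
equicorrelated errors, batch effects, informative censoring, and
time-varying mediators. Passing benchmarks therefore demonstrate
correctness of the pipeline under its own generating model, not robustness
to real methylation data pathologies.

## Problem sizes and numerical choices

The shipped benchmark studies use p = 10,000 mediators with 100–400
replicates per scenario, more where a target is estimated from a single
mediator (the original-scale study used 500 replicates);
at this scale a full pipeline replicate takes ~0.5 s (n = 500) to ~1.2 s
(n = 1,000) on one CPU, and replicate-mean TPR has Monte-Carlo SD ≈ 0.015.
Coordinate descent runs in a numba-compiled kernel (tolerance 10⁻⁷ on the
max coefficient change, 500 sweep cap, warning on non-convergence);
degenerate penalized columns (Vⱼⱼ = 0) are pinned at zero. Zero-variance
mediators score 0 in screening with a logged warning. The Sobel SE may be
exactly zero only at the null point (p := 1); a zero SE with a nonzero
estimate is an error, as is a constant exposure or a collinear (X, Z)
design.

## Known limitations

* The additive hazards model can imply negative hazards for extreme
  covariate values; neither estimation nor simulation enforces positivity.
* No unmeasured-confounding adjustments (propensity scores etc.); the causal
  reading of DE/IE rests on the usual sequential-ignorability assumptions.
* Post-selection inference is the pragmatic refit-and-test convention;
  p-values do not account for the selection event itself.
* SCAD's non-convexity means the exact solver finds a local solution that
  depends on the (fixed) sweep order and warm starts; the stepwise solver
  is a convex relaxation at each λ and is reproducible by construction.
* Baseline hazard estimation, time-varying coefficients, left truncation,
  and competing risks are out of scope.
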