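# Methods

## Model and estimands

The package implements a structural quantile mediation model.  Mediators
follow linear regressions on the exposure and covariates,
`M_k = c_k + α_k X + ζ_k'Z + e_k`, while the outcome is modeled through its
conditional quantile, `Q_τ(Y|X, M, Z) = c_τ + γ_τ X + β_τ'M + η_τ'Z`.  The
quantity of interest per mediator is the pathway product `α_k β_{k,τ}`; the
controlled direct and indirect effects of an exposure shift x* → x are
`γ_τ (x − x*)` and `Σ_k α_k β_{k,τ} (x − x*)`.  The products are invariant
to affine rescaling of the mediators (the scale cancels between the two
regressions), which the tests assert numerically.

Identification requires the usual no-unmeasured-confounding conditions and
that mediators do not cause one another; the package estimates the
descriptive regression quantities and leaves those assumptions to the
study design.

## The three-step selection procedure

**Step 1 — marginal screening.**  Mediators are standardized to mean 0 and
sample sd 1 (denominator n−1) so the marginal coefficients are
rank-comparable; exposure, covariates and outcome stay on their raw scales,
keeping γ_τ interpretable per exposure unit.  Each mediator enters its own
model `Y ~ 1 + X + M_k + Z` at level τ, and the top
`d = 2⌊n/ln n⌋` mediators by |β̃_k| are retained (natural logarithm, floor;
ties broken toward the lower column index).  `d` is additionally capped at
`p` and at `n − q − 3` so later joint fits stay overdetermined.

**Step 2 — MCP-penalized quantile regression.**  On the screened design
`[1, X, M_I, Z]` the smoothed check loss plus an MCP penalty on the
mediator coefficients is minimized.  Penalizing only the mediator block is
deliberate: shrinking the exposure coefficient would bias the direct
effect, and intercept/covariates are nuisance adjustments rather than
selection targets.  MCP concavity is δ = 3 by default (the conventional
choice; the model is insensitive to moderate variation).  The penalty
level λ runs over a 20-point log-spaced grid from λ_max (the analytic
threshold at which the mediator-free fit is stationary, verified by
probing) down to 0.01·λ_max, warm-starting each fit from the previous,
sparser one.  The first fit starts from the mediator-free quantile fit:
because MCP is flat beyond δλ, a dense start can leave large coefficients
stranded in nonzero local minima at arbitrarily large λ, which corrupts
both the λ_max probe and the path (this was observed, and is why the
sparse-to-dense convention standard for non-convex penalties is used).
λ is selected by a high-dimensional BIC,
`log(check loss) + |S_τ| · log(d+q+2) · log(log n) / (2n)`, with ties going
to the sparser fit.  HBIC is the standard consistent tuning rule for
non-convex penalties with p ≫ n; the original method's tuning rule is not
published.

**Step 3 — joint-significance selection.**  The unpenalized quantile model
is refit on the survivors `S_τ`; α̂_k comes from OLS of M_k on [1, X, Z].
Two-sided p-values use the standard normal reference (no small-sample t
correction, matching the procedure's printed form).  The decision statistic
`D_k = min(d_τ · max(P_αk, P_βk), 1)` with `d_τ = |S_τ|` is compared
strictly against 0.05 (both the survivor-count scaling and the strict
inequality are as printed; the level is a config knob).  Reported α̂, β̂
are back-transformed to the raw mediator scale; standardized-scale values
are also emitted.  An empty `S_τ` yields a valid direct-effect-only result.

## Quantile regression solver

All quantile fits minimize a Gaussian-convolution-smoothed check loss
`ℓ_h(r) = h φ(r/h) + r(Φ(r/h) − 1 + τ)` by damped Newton iterations, with
the bandwidth initialized at `h₀ = max(0.05, ((k + log n)/n)^{2/5})` times
a robust residual spread from an OLS pilot (the spread factor makes every
fit affine-equivariant; the rate mirrors the smoothed-QR literature).

* **Single fits** (Step 3 refits, auxiliary fits) anneal the bandwidth
  geometrically to 1e−2 of the residual spread, then polish with
  iteratively reweighted least squares on the ε-perturbed absolute loss and
  finally a simplex-type vertex descent (the exact optimum interpolates k
  observations; edge directions are scanned and followed to the
  weighted-median breakpoint).  The result agrees with the linear-programming
  formulation of quantile regression to machine precision on random test
  instances — i.e. the refit behaves like an exact solver, as the classical
  estimator requires.
* **Marginal screening fits** (p per dataset, vectorized across mediators)
  stop at the initial bandwidth: they feed a magnitude ranking, for which
  the plain smoothed estimate is the intended quantity, and annealing all p
  fits would dominate the runtime.
* **The penalized fit** also keeps the fixed bandwidth (here scaled by the
  residual spread of OLS on the full screened design), iterating an outer
  quadratic approximation of the smoothed loss with inner cyclic coordinate
  descent; mediator coordinates apply the closed-form scalar MCP proximal
  rule (firm thresholding), and every outer step is accepted only if the
  exact smoothed penalized objective decreases.  The whole path is
  deterministic.

Convergence is declared at a relative coefficient change below 1e−8 (500
iterations maximum, stage-capped during annealing); rank-deficient designs
and degenerate bandwidths raise errors rather than returning garbage.

Standard errors use Powell's kernel sandwich: `H⁻¹ J H⁻¹ / n` with
`J = τ(1−τ) X'X/n` and the density-weighted Hessian estimated with a
Gaussian kernel at the Hall–Sheather-rate bandwidth
`spread · (Φ⁻¹(τ+h_s) − Φ⁻¹(τ−h_s))`.  This estimator is mildly
conservative at small n and converges at larger n (the test suite checks
it against the Gaussian closed form at n = 5000 and against a pair
bootstrap at n = 1000); the Monte-Carlo selection results indicate that a
comparable degree of conservatism characterizes the reference results.  A
Hall–Sheather difference-quotient variant (`method="nid"`, two auxiliary
fits) and the pair bootstrap are available; the nid variant is better
calibrated pointwise but makes mediator selection visibly more liberal
than the reference results.  At extreme quantile levels the kernel
density estimate smooths the tail upward, which makes selection slightly
more, rather than less, liberal there; see the acceptance results for the
τ = 0.05 cell.

## Synthetic data

The generator reproduces the benchmark designs.  Exposure and two
covariates are N(0, 4) — "4" read as the variance, the conventional
N(mean, variance) notation; both sds are config knobs.  Mediator errors
are jointly Gaussian with AR covariance `Σ_ij = 0.25^{|i−j|}`, drawn by
the exactly equivalent stationary AR(1) recursion (coefficient 0.25,
innovation sd √(1−0.0625)).  True coefficients: α has seven leading
nonzeros (0.85, 1.2, 1, 0.15, −0.25, 0.65, −0.5), β has
(0.85, 1.2, 1, 0.25, −0.15, 0, 0, 0.75, −0.5), ϕ = (0.1, 0.1, 0.1, 0, …);
γ = 0.5, θ = 0.1, ζ_k = (0.3, 0.3)', η = (0.5, 0.5)' (the last printed
ambiguously in the source material; the symmetric reading is used and the
value is configurable).  Exactly five pathway products are nonzero
(mediators 1–5); mediators 6–9 realize the two one-sided null
configurations.  Outcomes: Case I adds ε ~ N(0,1); Case II multiplies ε by
(θX + ϕ'M), making the τ-level slope β_k + Φ⁻¹(τ)ϕ_k.  The multiplier can
be negative, in which case the closed-form conditional-quantile expression
is not pointwise exact; the generator implements the data equation
literally and the ground-truth module implements the closed form literally,
matching the benchmark's own convention.  Generation is a pure function of
the config seed (fixed draw order: X, Z, mediator innovations, ε).

What the generator does *not* emulate: bounded [0,1] methylation scales,
non-Gaussian or heavy-tailed noise, batch structure, cell-type composition,
or mediator-on-mediator causal paths.  Passing simulations therefore
demonstrate correctness of the procedure under its stated model, not
robustness to real-data pathologies.

## Monte-Carlo harness

Per repetition, the effect estimate for mediator k is `α̂_k β̂_{k,τ}` from
the Step-3 refit when k survives Step 2 and exactly 0 otherwise.  Reported
metrics: per-mediator bias (mean estimate − truth) and SSE (sd across
repetitions); per-cell MS (mean |Ω̂|), TPP (mean |Ω̂ ∩ Ω₀|/|Ω₀|) and FDP
(mean |Ω̂ \ Ω₀|/|Ω̂|, zero for empty selections).  Each metric carries a
Monte-Carlo standard error (sd/√reps).  Repetition seeds derive from
(base seed, cell, repetition) via `numpy.random.SeedSequence`, so any
repetition can be reproduced in isolation and parallel execution cannot
change results.  Failed repetitions are logged, counted and excluded —
never silently dropped.

The acceptance suite and `scripts/acceptance.py` run the four benchmark
cells at p = 3000 with 100 repetitions — enough for roughly ±0.05 on MS
and ±0.01 on TPP at one MC standard error, while keeping the full study
under ten minutes on a single CPU.  Tolerances in the acceptance tests
combine the MC standard error of the 100-repetition estimate with that of
the 500-repetition reference; rare-event proportions (FDP) use a
Jeffreys-floored standard error because the plug-in estimate degenerates
at zero observed events.

The one-mediator comparator scan (marginal models plus Bonferroni-adjusted
joint-significance p-values) is a reduced-fidelity stand-in for the two
published single-mediator methods it imitates: it implements their shared
marginal structure, not either method's full internals, and its numbers
are sanity ranges rather than benchmarked quantities.

## Known limitations

* The λ grid, δ, and HBIC constants are defensible defaults, not tuned
  optima; the reference method's own tuning rule is unpublished.
* The weakest benchmark pathway (α₅β₅ = 0.0375) is essentially never
  detected at n ≤ 300 — its marginal coefficient is ≈ −0.09 against a
  conditional outcome spread of ≈ 2.4 — so its "bias" is minus the truth.
  This matches the reference results and is a property of the design, not
  a defect of the implementation.
* Multiple-τ runs are fit independently; no quantile-crossing adjustment
  or joint inference across τ.
* Confidence intervals for the products α̂β̂ are not provided (point
  products only, as in the reference procedure).
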