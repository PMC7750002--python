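# Methods

## The model and the estimand

`bmdkit` estimates the benchmark dose (BMD): the dose `d` at which a
fitted dose-response curve `f(d, β)` reaches a predefined small change —
the benchmark response (BMR) — relative to the background level. The
lower limit of a one-sided confidence interval for the BMD is the BMDL,
the quantity regulators use as a point of departure.

A parametric curve is fitted by maximum likelihood under one of four
response distributions:

* **normal** (continuous endpoints) with a single pooled residual SD σ
  profiled out of the likelihood (equal variance across dose groups);
  optionally the response is log-transformed first, which changes the
  interpretation of the BMD to a change on the log scale;
* **binomial** for grouped quantal rows (`events` of `trials`);
* **Poisson** and **negative binomial** (NB2, variance `μ + μ²/θ`) for
  counts, optionally with an observation weight (e.g. lifespan-days)
  entering as a multiplicative exposure.

Curve families use the drc-style log-dose kernel
`z = b(log d − log e)`: log-logistic `c + (d_up − c)/(1 + e^z)`,
log-normal `c + (d_up − c)Φ(z)`, Weibull type 1 `c + (d_up − c)e^{−e^z}`,
Weibull type 2 with the complementary kernel, exponential decay
`c + (d_up − c)e^{−d/e}`, and multistage
`c + (1 − c)(1 − e^{−Σ b_m d^m})` with `b_m ≥ 0`. The value at dose 0 is
always the analytic limit of the kernel, never an evaluation at `d = 0`.
String codes (`LL.3`, `W1.4`, `EXD.2`, `MS.2`, …) fix the conventional
parameters; any parameter can also be fixed explicitly, e.g. an upper
limit of 1 with a free lower limit for quantal data whose control group
shows natural mortality (`LL.3u`/`LN.3u`).

## BMD definitions

For an increasing curve (signs flip for decreasing / decreasing-adverse
endpoints):

| definition | target level `y*` with `f(BMD) = y*` |
|---|---|
| additional risk | `p0 + BMR` |
| excess risk | `p0 + BMR(1 − p0)` |
| hybrid additional | `x0 − σ Φ⁻¹(1 − BMR − p0)` |
| hybrid excess | `x0 − σ Φ⁻¹(1 − BMR(1 − p0) − p0)` |
| added | `f(0) + BMR` |
| extra | `f(0) + BMR(f(∞) − f(0))` |
| relative | `f(0)(1 + BMR)` |
| point | `BMR` itself |

The background risk `p0` is model-based (`f(0)`), user-specified, or —
for the hybrid approach, which converts a continuous endpoint into the
probability of crossing an adversity cutoff `x0` under a normal model —
derived from `p0 = 1 − Φ((x0 − f(0))/σ)`. The cutoff may be an absolute
response level or `k` standard deviations from the control mean
(`k = 1` is a common regulatory choice; `k = 2` appears in the examples
here). Two consequences worth asserting, and asserted in the tests:
additional and excess risk coincide when `p0 = 0`, and extra response
coincides with excess risk when the curve limits are 0 and 1.

σ in the hybrid formulas defaults to the pooled residual SD of the fit
(the fit already assumes variance homogeneity); `sigma_source="control"`
uses the control-group sample SD instead, for users who prefer the
stricter reading of the cutoff as a control-population quantity.

The adverse direction is inferred from the fitted curve and can be
overridden (`adverse_direction=`) for continuous endpoints where the
lower tail is the adverse one against an increasing trend.

## Estimation and uncertainty

**After-fitting.** The model is fitted once in its natural, numerically
robust parameterisation; BMD and its SE are derived afterwards. The
solver inverts the kernel in closed form where possible and otherwise
uses Brent bracketing on the log-dose scale over
`[1e−12·d_max, 100·d_max]`, flagging (not refusing) extrapolation beyond
the observed range. The delta-method SE uses the implicit-function
theorem on `h(d, β) = f(d, β) − y*(β)` with central-difference
derivatives; a test cross-checks it against a model re-parameterised to
contain the BMD as a parameter.

**Optimiser.** Nelder-Mead simplex from self-started initial values
(location from the dose bracketing the half-range response by log-linear
interpolation; slope from a linearised kernel regression; limits from
extreme group means), refined by BFGS when the observed-information
covariance is required. Bootstrap refits skip the quasi-Newton polish —
at the simplex tolerances used (1e−8 on parameters, 1e−10 on the
objective) the refinement changes the optimum only at or below those
tolerances, and the simplex alone keeps a replicate at about 5 ms.
A perfect interpolation of continuous data makes the profiled normal
likelihood diverge; such fits are treated as converged with σ = 0.
Covariances come from the numeric central-difference Hessian; a singular
information matrix falls back to the pseudo-inverse with a warning.

**BMDL methods.**

* *Wald/delta*: `max(0, BMD − z·se)` on the natural scale (truncated at
  zero) or `BMD·exp(−z·se/BMD)` on the log scale, which stays positive.
* *Inverse regression*: the smallest dose at which the one-sided
  pointwise delta-method confidence limit of the predicted response
  reaches `y*`. The band is pointwise, not simultaneous.
* *Bootstrap* (default 1000 replicates, one-sided 0.95): nonparametric
  (resampling within dose groups; grouped quantal rows draw
  `Binom(N_i, Y_i/N_i)`), parametric (normal with dose-group means and a
  common SD for continuous data; binomial with shrunken proportions
  `(Y + 1/4)/(N + 1/2)` for all-event/no-event groups so resampling does
  not degenerate; the fitted Poisson/NB model for counts), and
  semiparametric (fitted values plus recentred resampled residuals,
  continuous only — recentring keeps the residuals exchangeable).
  The BMDL is the type-7 empirical `(1 − level)` quantile of converged
  replicate BMDs. Replicates are restarted from the self-starter, failed
  ones are dropped and counted, and more than 20% failures aborts rather
  than silently hiding instability. Reproducibility comes from one seed
  expanded into independent per-replicate substreams. The parametric
  continuous SD is pooled within-group by default (`sd_source="control"`
  is available) — the pooled choice follows directly from the
  equal-variance premise of the scheme.

**Sandwich covariance.** `A⁻¹B(A⁻¹)ᵀ` with `A` the observed information
and `B` the outer-product sum of per-observation scores, summed within
clusters when cluster-robust. Point estimates are untouched. Under
overdispersion the sandwich SEs grow, which lowers the BMDL — the
diagnostic signature tested on NB-generated counts fitted as Poisson.
Overdispersion itself is flagged by residual deviance / residual df > 1
or by comparing Poisson and NB fits on AIC.

## Model averaging

AIC (or BIC, or user) weights `w_k = exp(−Δ_k/2)/Σ exp(−Δ_i/2)`.
An alternative `exp(−Δ)` kernel is available (`kernel="delta"`): the
published four-model example this package's averaging test mirrors
prints weights that are consistent with `exp(−Δ)` applied to its AICs,
so both conventions are exposed and neither is asserted as canonical.
The MA BMD is either the weighted mean of per-model BMDs or the BMD
solved on the weighted mean curve (backgrounds recomputed from the
averaged curve). MA BMDL options: the Buckland variance-inequality SE
`Σ w_k sqrt(var_k + (BMD_k − BMD_MA)²)` in a one-sided Wald limit, a
weighted mean of per-model BMDLs, or a bootstrap that refits every
candidate and recomputes the weights inside each replicate — the only
correct way to propagate model-selection uncertainty, and the only
option at all for curve averaging. Candidates that fail on the original
data are excluded with a warning; mixed increasing/decreasing candidate
sets are refused.

AIC counts σ (normal) and θ (NB) as parameters. Whether σ is counted is
a convention; the constant cancels in the AIC differences that drive the
weights.

## Isotonic alternative

`pava` projects the dose-group means onto monotone sequences by weighted
least squares (pool-adjacent-violators); the BMD is read off the step
means by linear interpolation on the natural dose scale (log-dose
interpolation would be a one-line variant but the natural scale is the
documented default). The direction comes from the sign of the weighted
Spearman correlation between dose and group mean; a zero correlation
asks for an explicit direction. Hybrid definitions are excluded — they
need a parametric residual SD that the isotonic fit does not provide.
Uncertainty is bootstrap-only (no SE exists for the interpolated step
estimate).

## Hierarchical designs

Independent sub-experiments are handled by a two-step meta-analysis:
fit the curve per cluster, extract BMD and delta SE, combine by
DerSimonian-Laird: `τ² = max(0, (Q − (K−1))/(Σw − Σw²/Σw))` with fixed
weights `w_i = 1/se_i²`, final weights `1/(se_i² + τ²)`. Combination is
on the natural BMD scale by default; `scale="log"` combines log-BMDs and
exponentiates, which is preferable when per-cluster BMDs span an order
of magnitude. The one-sided BMDL uses the normal approximation without a
Knapp-Hartung adjustment (a documented limitation; with few clusters the
interval is anti-conservative). Clusters without a usable fit are
excluded with a warning; fewer than two usable clusters is an error.

## Synthetic data

The generators produce quantal (grouped binomial), count (Poisson/NB2)
and continuous (normal, equal SD) responses from any supported family,
optionally across clusters whose location parameter varies log-normally.
The continuous validation design is a four-parameter log-logistic truth
with limits 2 and 10 at doses (0.1, 0.5, 1, 5, 10), SD 1 or 0.1, and 10
or 3 replicates per dose; location `e = 2` and shape `b = 1` are this
package's own (documented) choice. Each dataset carries a truth record
whose true BMD is found by plain bisection at relative tolerance 1e−12 —
deliberately a different algorithm from the package solver so tests
never compare an implementation with itself.

What the generators do *not* emulate: missing values, heterogeneous
variances, non-normal continuous noise, within-cluster correlation
beyond a shared location shift, and litter effects. Passing tests
therefore demonstrate correctness of the estimators under their stated
assumptions, not robustness to the messiness of real bioassays — except
where a test deliberately misspecifies (NB counts fitted as Poisson).

## Test problem sizes

The coverage check runs 300 simulated quantal studies (six dose groups
of 50) with 250 bootstrap replicates each, and the overdispersion check
100 simulated count studies — sizes chosen to keep Monte-Carlo error on
a coverage proportion near ±1.7% while the whole suite stays a
desk-scale run. Worked-example and closed-form checks are exact.

## Known limitations

Profile-likelihood BMDLs, simultaneous multi-endpoint BMDs,
transform-both-sides estimation, mixed-effects dose-response models,
fractional-polynomial and hormesis families, and Bayesian model
averaging are out of scope. The `extra` definition errors when `f(∞)`
is not finite rather than guessing an asymptote. Correlations between
candidate-model BMDs are ignored by the Buckland bound (it is an upper
bound on the MA variance, so the resulting BMDL is conservative in that
respect).
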