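# Methods

This note documents the statistical models, the derivations, the numerical
choices and the synthetic-data design behind `multimeta`, at the level of
detail a user would need to judge what the package's tests do and do not
demonstrate.

## Effect derivation from 2×2 tables

For one study arm with `a` events among `n` patients, the log odds is
`log(a/(n−a))`. The log odds ratio of treatment vs control and its
large-sample variance are

    y = log[(a/b)/(c/d)],   s² = 1/a + 1/b + 1/c + 1/d,

with `b`, `d` the non-event counts. Zero cells are handled with the usual
two-step policy: if **neither** arm has events the study carries no
information about the odds ratio for that outcome and it is marked missing
(zero weight); if a study is all-missing across analysed outcomes it is
dropped entirely. Otherwise any zero cell triggers a continuity correction
of +0.5 to **all four** cells before `y` and `s²` are computed, and the
estimate is flagged `correction_applied`.

## Within-study correlations for structurally related outcomes

When two binary outcomes are measured on the same patients, their log odds
ratios are correlated within the trial. For two *structural* relations the
correlation is available in closed form by the delta method, because the
per-arm event counts are jointly multinomial:

- **Mutually exclusive outcomes** (cells `(a, b, n−a−b)`):
  `Cov(a, b) = −ab/n`, which propagates to a per-arm covariance of the two
  log odds of `−n/((n−a)(n−b))`. Always negative.
- **Subset outcomes** (cells `(a_sub, a_sup−a_sub, n−a_sup)`):
  `Cov(a_sub, a_sup) = a_sub(n−a_sup)/n`, giving per-arm covariance
  `n/(a_sup (n−a_sub))`. Always positive, and the normalised correlation
  is exactly +1 when the subset and superset counts coincide in both arms
  (the two log odds are then the same random variable).

Study-level covariance is the sum over the two independent arms, and the
correlation divides by `√(s_a² s_b²)`. Both formulas are validated in the
test-suite against a Monte-Carlo oracle that draws ≥10⁵ multinomial
replicates per arm at the observed proportions, reapplies the zero-cell
policy per replicate, and correlates the resulting log odds ratios; the
agreement requirement is 0.02 absolute over a 20-configuration grid.

When a continuity correction was applied to a table, the correlation
formulas reuse the *corrected* cells (and the average of the two outcomes'
effective totals in the numerator), so the diagonal and off-diagonal
entries of the assembled within-study covariance matrix are mutually
consistent. The correction policy is per-table: a zero cell in one outcome
does not trigger correction of the paired outcome's table.

### Covariance assembly

Per study, `S_i` runs over the study's non-missing outcomes: diagonal =
`s_ij²`; off-diagonals from the analytic formulas for structurally related
pairs, from user-supplied fixed values where given, otherwise 0 and
flagged `unavailable`. A dataset-level flag records whether every `S_i`
is complete; if not, the hierarchical model is not applicable and the
dataset is routed to the overall-correlation model. Correlations are
clamped to ±0.999999 at assembly (raw values preserved) so `S_i` is never
exactly singular. A non-PSD assembled matrix — possible only with fixed
external correlations on three or more outcomes — is repaired by uniformly
shrinking the off-diagonals by the minimal factor (bisection, eigenvalue
floor 10⁻⁸ relative) that restores PSD, with a logged warning. Notably,
the published fixed-correlation triple (0.60, 0.93, 0) used in
sensitivity analyses of this kind is itself non-PSD; a likelihood with
such values is exactly computable only when no single study observes all
three outcomes (then only 2×2 principal minors enter), which is how the
packaged selective-reporting scenario is laid out.

## Univariate model

`y_i ~ N(μ, s_i² + τ²)` per outcome, fitted by REML: the restricted
negative log-likelihood

    ½ [ Σ log(s_i²+τ²) + log Σ w_i + Σ w_i (y_i − μ̂)² ],  w_i = 1/(s_i²+τ²)

is minimised over `log τ²` (bounded scalar minimisation, `xatol 1e−12`)
with an explicit comparison against the τ² = 0 boundary. `μ̂` is the
inverse-variance weighted mean at the fitted τ². The standard error of μ
comes from the observed information of the joint restricted objective in
(μ, τ²) (numerical Hessian), which is never smaller than the plain GLS
standard error `1/√Σw_i` and accounts for the uncertainty in τ̂²; the GLS
value is also exposed (`se_mu_gls`), and is used at the τ² = 0 boundary
where the joint information is one-sided. CIs are Wald with the normal
0.975 quantile (no Knapp–Hartung), matching the reporting convention of
the comparison this package implements.

## Multivariate models

Both multivariate models share one likelihood engine. Study *i*
contributes its observed sub-vector `y_i` with covariance `V_i`; the
profiled REML objective is

    ½ [ Σ log|V_i| + log|Σ X_i' V_i⁻¹ X_i| + Σ r_i' V_i⁻¹ r_i ],

with `X_i` the selection matrix onto observed outcomes and `r_i` the GLS
residuals. Studies are grouped by missingness pattern and the linear
algebra batched per pattern.

- **Hierarchical**: `V_i = S_i + Σ[obs, obs]`. `Σ` is parameterised by its
  Cholesky factor with log-transformed diagonal (bounds ±50 on
  off-diagonal elements, `log diag ∈ [−12, 3.5]`). Variants fix the
  between-study correlation matrix (free log-SDs — this is how the
  correlations-fixed-at-zero reduction to univariate fits is exercised),
  fix the SDs (free Fisher-z correlations — used for the grid-search
  oracle), or fix everything (pure GLS — used for the missing-data
  efficiency property).
- **Riley (overall correlation)**: `V_i[j,j] = s_ij² + ψ_j²`,
  `V_i[j,k] = ρ_jk √(V_i[j,j] V_i[k,k])`, parameterised by `log ψ_j²` and
  Fisher-z `ρ_jk` (one per pair by default; a single shared ρ is an
  option). `fix_correlations` (matrix with NaN = free, or a pair-keyed
  dict) holds ρ entries fixed (`model = "riley_fixed"`). Non-PD proposals
  are rejected with a large objective value, never an exception.

Estimates of ρ within 10⁻⁴ of ±1 are reported at the boundary with a
`boundary_flags` entry and remain `converged`; between-study SDs below
10⁻⁵ are reported as 0.

`cov_mu` is the μ-block of the inverse observed information of the joint
objective in (μ, free variance parameters), with parameters pinned at a
box boundary excluded; it falls back to the GLS covariance
`(Σ X' V⁻¹ X)⁻¹` when the joint Hessian is not invertible or on request
(`gls_cov=True`), and always when no variance parameters are free.

### Optimisation and convergence policy

Each start runs bounded L-BFGS-B (`ftol 1e−14`, `gtol 1e−9`) followed by
Nelder–Mead polish rounds (`xatol 1e−10`) until the polish gains less than
the objective tolerance (default 10⁻⁸). A run counts as **converged** when
(1) the final polish improvement is below tolerance, (2) the central-
difference gradient is below 10⁻⁵ (relative to the objective scale) on
every parameter not at a box boundary, and (3) the observed information
restricted to non-boundary parameters is positive definite with minimum
eigenvalue above 10⁻⁴. The last criterion deliberately treats a *flat*
direction (eigenvalue ≈ 0) as failure: a likelihood that does not depend
on a parameter — e.g. an overall correlation with no study reporting both
outcomes — is non-identified, and reporting such a fit as converged would
be misleading. On failure the optimiser retries from seeded random
perturbations of the initial point (default 10 starts); if all fail the
fit returns `status = "failed_convergence"` with its diagnostics (final
objective, gradient norm, minimum eigenvalue, starts used) — downstream
tables render it as `FC`. Identical seeds and options give identical
results. Initial values come from per-outcome DerSimonian–Laird moment
estimates with correlations at 0.

The policy's thresholds are this package's own reconstruction of standard
practice for these models; they are deliberately explicit and logged so a
user can audit any convergence decision.

## Comparison and small-study diagnostics

The comparison layer produces one row per (outcome, model) with OR, 95%
CI, between-study SD and status (failed fits as `FC`), plus a change
summary listing outcomes whose 5%-level significance flag differs between
the univariate fit and any converged multivariate fit. The significance
flag is computed on the log-OR scale (`|μ| > 1.96 se`), which is exactly
the OR-scale CI-excludes-1 rule. Rendered tables round OR and τ to 2
decimals; JSON retains full precision. No multiplicity adjustment is
applied.

Funnel diagnostics return per-study `(y, se)` coordinates with a contour
band classification from the two-sided Wald p-value (bands at 0.10, 0.05,
0.01) and contour polylines `±z_q·se` over an se grid. Asymmetry is
summarised descriptively — band counts within study-size terciles (size
proxied by 1/se) — because the intended assessment is visual; an
Egger-type regression is available behind a flag but off by default.

## Synthetic data generator

`generate_dataset` draws, per study: per-arm sizes uniform on `n_range`
(shared across outcomes within an arm, as in a real trial); a study-level
true log OR vector `θ_i ~ N(μ, D(τ) R_B D(τ))`; treatment-arm risks
`expit(logit(p_c) + θ_i)` (the random effect acts on the contrast, not on
arm risks, matching the contrast-level models above); and correlated event
counts respecting the declared structure — multinomial cells for mutually
exclusive pairs, nested draws (subset events sampled among superset
events) for subset pairs, independent binomials otherwise. Each outcome
may take part in at most one structural relation. If treatment-shifted
risks of an exclusive pair sum past 1 they are rescaled below 1; a subset
conditional probability is capped at 1. All randomness flows from a single
integer seed through one `numpy` generator.

Missingness mechanisms: `mcar(p)` drops each (study, outcome) cell
independently; `selective(threshold, drop_prob)` deletes a designated
outcome's result with probability 0.8 (default) when its two-sided Wald
p-value exceeds 0.05 (default) *and* the study's mean per-arm size is
below the dataset median — small null results go unreported. This is one
plausible, testable mechanism for small-study effects, not a claim about
how any particular review's data arose.

### Packaged scenarios

- `recovery_subset`: the parameter-recovery conditions (k = 20,
  μ = (−0.7, −0.4), τ = 0.3, ρ_B = 0.7, subset-structured within-study
  correlations). Arm sizes are large (1000–5000) with baseline risks
  0.20/0.40 so that the within-study log-OR estimates sit in their
  asymptotic regime and the recovery test measures the REML estimator
  itself rather than finite-count bias of the log odds ratio; at these
  sizes 500 replicates give |bias| < 0.005 and CI coverage ≈ 0.93
  (slightly below nominal, as expected for Wald intervals with k = 20).
  With small trials and rare outcomes, coverage degrades for reasons
  unrelated to the estimator (finite-count bias, boundary correlation
  estimates) — a documented limitation, not a property the tests hide.
- `riley_recovery`: k = 50 with τ = 0.5, ρ_B = 0.9 and within-study
  variances ≈ 0.06, so the implied *overall* correlation is ≈ 0.7.
- `review7`: four outcomes reported by 8/≤7/4/5 of 11 studies with
  significance-driven selective reporting on outcome 2 — the pattern of
  the review in which a multivariate re-analysis flagged small-study
  effects. Between-study correlation is strong and shared (0.95) and
  heterogeneity moderate (τ = 0.45, trials of 30–150 per arm): a regime
  chosen so the prescribed mechanism actually manifests (the selection
  must leave mostly-significant small studies *and* the correlated
  outcomes must carry usable information). No study reports outcomes
  1, 2, 3 jointly, which keeps fixed-correlation trivariate fits
  well-defined (see above). `amalgamated_correlation` converts the
  scenario's between-study correlations into the consistent overall
  values to fix in a Riley fit, evaluated at mid-range arm sizes.

What the generator does *not* emulate: patient-level association between
non-structurally-related outcomes (they are conditionally independent
given θ_i, so their within-study correlation is ≈ 0 and all cross-outcome
correlation is between-study), arm-level random effects, non-uniform size
distributions, and real reviews' exact counts. Passing tests therefore
demonstrate the estimators' behaviour under the stated generating
mechanisms, not under every mechanism real data might exhibit.

## Problem sizes in the test-suite

The simulation-backed tests use 100–500 replicates at k = 11–50 studies
(500 for recovery/coverage, 200 for the selective-reporting mechanism and
the Riley correlation recovery, 100–120 for efficiency and funnel
properties), sizes at which the Monte-Carlo error of each checked quantity
is small against its acceptance margin while the whole suite stays
comfortably runnable on one CPU.

## Known limitations

- Within-study variances are treated as known; for rare outcomes or tiny
  trials their sampling error biases weights (a generic feature of
  inverse-variance meta-analysis of log odds ratios).
- Wald CIs undercover slightly at small k; no Knapp–Hartung or
  Kenward–Roger small-sample adjustment is offered because the comparison
  this package implements is defined in terms of Wald intervals.
- The Riley model's single correlation per pair is an approximation to
  the hierarchical decomposition; with d > 2 the free-correlation variant
  can propose non-PD matrices, which the optimiser simply rejects, so
  heavily missing data can legitimately end in `failed_convergence`.
- Structural relations in the generator are pairwise only (no chains of
  three nested outcomes).
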