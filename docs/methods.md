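# Methods

## The model

`spataft` fits right-censored Weibull accelerated-failure-time models
with two clustering levels. Event times are
`T_i ~ Weibull(k, λ_i)` with survivor function
`S(t) = exp(−(t/λ_i)^k)`, density
`f(t) = (k/λ_i)(t/λ_i)^{k−1} S(t)`, and
`λ_i = exp(η_i)`. Events contribute `log f(t_i)` to the likelihood and
censored records `log S(t_i)`. Equivalently, `log T_i = η_i + σW` with
`σ = 1/k` and `W` standard extreme-value distributed: covariates act
multiplicatively on the time scale, and `exp(β_j)` is a time ratio
(TR > 1 ⇒ longer time to the event). The same Weibull model can be
written in proportional-hazards form with log-hazard-ratio `−kβ_j`;
the AFT form is used throughout because the time-ratio scale is the
reporting convention of the analyses this package supports, where the
event is sexual debut at or below a threshold age and TR < 1 therefore
means an earlier debut.

The linear predictor is additive:

```
η_i = β₀ + x_i'β + u_{h(i)} + s_{g(i)}
```

* `x_i` is a dummy-expanded design: metric covariates enter linearly
  and each categorical factor contributes one indicator per
  non-reference level. The bundled default schema reproduces a
  national household survey's coding (age of household head metric;
  sex of head, marital status, recent sexual activity, education,
  internet use, wealth quintile, religion, residence type and region
  categorical, with the survey's reference categories).
* `u_h ~ Normal(0, 1/τ_u)` are IID household frailties.
* `s` is a Besag intrinsic CAR field on the state adjacency graph:
  conditionally, `s_g` is normal around the weighted mean of its
  neighbours with precision `τ_s Σ_j w_gj`. The joint density is the
  pairwise-difference form

  ```
  log π(s|τ_s) = ((n−c)/2)(log τ_s − log 2π) + ½ logdet⁺(L)
                 − (τ_s/2) Σ_{g~j} w_gj (s_g − s_j)²
  ```

  where `L` is the weighted graph Laplacian, `c` the number of
  connected components and `logdet⁺` the product of nonzero
  eigenvalues. The density is proper only on the sum-to-zero subspace
  (one constraint per component), which is where the package evaluates
  and samples it. The full normalising constant is computed (and
  cached per graph) rather than dropped: it is constant during MCMC
  but exposes indexing and rank-handling bugs in tests that an
  unnormalised kernel would hide. A hyperparameter written as a
  squared symbol in the originating literature is ambiguous between a
  variance and a precision; it is treated as a precision here.

Priors: `β₀, β ~ Normal(0, 10²)`, `log k ~ Normal(0, 1)`,
`τ_u, τ_s ~ Gamma(shape 1, rate 5·10⁻⁵)` (a diffuse, INLA-like
default). All are overridable through `ModelSpec`. The four
`(include_iid, include_icar)` combinations give the nested variants
compared in model selection: no clustering, IID only, Besag ICAR only,
and both ("IID and Besag ICAR").

## Inference

The published analysis this package re-implements used a nested
Laplace approximation engine; the model contract is the posterior, not
the algorithm, so `spataft` ships its own MCMC sampler
(Metropolis-within-Gibbs with adaptation frozen at the end of
burn-in):

* **(β₀, β) block** — random-walk Metropolis with a Haario-style
  empirical proposal covariance learned during burn-in; target
  acceptance 0.234 (0.44 when the block is one-dimensional).
* **log k** — scalar random walk (target 0.44), skipped when the shape
  is held fixed.
* **Frailties** — scalar random walks for every household, proposed and
  accepted simultaneously: given everything else, the household
  conditionals are mutually independent, so the vectorised sweep is an
  exact composition of scalar Metropolis updates. Each household keeps
  its own adapted step size.
* **Spatial field** — sampled in the non-null eigenbasis of the
  weighted Laplacian. In that basis the constrained ICAR prior is a
  diagonal Gaussian (coordinate `j` has variance `1/(τ_s λ_j)`), each
  coordinate gets a scalar adaptive update, and every reconstructed
  field satisfies the per-component zero-sum constraint exactly, by
  construction. This was chosen over the common per-state update
  followed by re-centering: re-centering perturbs the likelihood by
  the subtracted component means, which cannot all be absorbed into a
  single intercept when the graph has several components, so that
  scheme is only approximately invariant. (`center_spatial` is still
  exported for projecting externally supplied fields.)
* **Precisions** — conjugate draws:
  `τ_u ~ Gamma(a + H/2, b + Σu²/2)` and
  `τ_s ~ Gamma(a + (n−c)/2, b + ½Σ w (s_g−s_j)²)`.

Initialisation: `β` from a censoring-naive least-squares fit of
`log t`, `u = s = 0`, `k = 1`, `τ_u = τ_s = 1`. The precisions are
*not* started at the prior mean — the diffuse default prior has mean
2·10⁴, and a precision that large pins the effects at zero while the
conjugate update keeps the precision large, a mutually reinforcing
trap the sampler can take very long to escape.

A per-draw × per-record log-likelihood matrix is stored with every fit.
Chains are fully reproducible given the seed. `convergence_summary`
reports rank-normalised split-R̂ and effective sample size per scalar
parameter (via ArviZ), flagging R̂ > 1.01 and degenerate cases
(identical chains, held parameters) explicitly.

## Model comparison

DIC uses the classic mean-deviance decomposition:
`pD = D̄ − D(θ̄)`, `DIC = D̄ + pD`, with `θ̄` the component-wise
posterior mean on the sampled scale (the shape is averaged as a
log-shape). WAIC is `−2(lppd − p_waic)` with the log-pointwise
predictive density computed by log-sum-exp and
`p_waic = Σ_i var_d(ℓ_{di})`; records with pointwise variance above
0.4 trigger the standard reliability warning. With per-household
random effects and few records per household that warning fires
routinely — it marks records whose WAIC contribution is dominated by
frailty uncertainty, and the criterion should be read comparatively
across the variants, not absolutely. Different software families
define the DIC penalty differently (some use half the posterior
variance of the deviance); numeric DIC values are therefore comparable
within this package, not across packages.

## Proportional-hazards diagnostics

`cox_fit` maximises the Breslow partial likelihood by Newton–Raphson
with step-halving, converging on the log-likelihood change with a
step-size guard (a monotone likelihood also produces vanishing
improvements while a coefficient marches to infinity; that case is
reported as separation, naming the covariate). `ph_test` is the
Grambsch–Therneau test: with Schoenfeld residuals `r_k` at the `d`
events, `Iinv` the estimated covariance and centred transformed event
times `g_k` (default transform `1 − KM(t)`; identity available),
`q = d (Σ g_k r_k) Iinv` and each term's statistic is
`q_J' [c·d·Iinv_JJ]⁻¹ q_J` with `c = Σ g_k²`, `df = |J|`. Categorical
factors are tested jointly (df = levels − 1) and the global row uses
all coefficients. Per-covariate statistics agree with the reference
implementation in `lifelines` to ~10⁻³ relative (the residual
difference is the evaluation of the Kaplan–Meier transform at tied
times).

## Synthetic data

The generator emulates the survey's structure, not any particular
realisation of it:

* respondents are allocated to households and households to states,
  balanced by default (Dirichlet-random sizes optional); households
  are strictly nested within states, as in cluster sampling;
* covariates are drawn independently from configurable marginal
  frequency tables whose defaults approximate the published
  descriptive margins (combined over event status); joint dependence
  between covariates is deliberately not emulated;
* the region covariate is derived from the state allocation (states
  are partitioned into contiguous blocks), mirroring the real nesting
  of states in regions, so its margins follow the allocation rather
  than a frequency table;
* event times use the inverse-CDF construction
  `T = exp(η)(−log U)^{1/k}` with `U` uniform, and censoring is
  administrative at the threshold age (17 years), matching the event
  definition "debut at ≤ 17". Whether the real survey's censoring
  occurred exactly at the threshold or at interview age is not
  documented; the threshold is configurable.

Default effect sizes are the published posterior means and the default
intercept the published baseline (2.895 on the log-year scale); the
shape default is k = 2 (an increasing hazard through adolescence — the
source analysis does not report its fitted shape). Default precisions
are τ_u = 4 (household sd 0.5) and τ_s = 2, the values used throughout
the recovery experiments; default problem size is 5000 respondents in
500 households on a 6×6 lattice (a stand-in for a 37-area contiguity
map). One seed governs the whole draw through per-stage sub-streams.

What passing the simulation-based tests does and does not show: the
generator shares the model's own likelihood, so recovery and
model-selection results certify the estimator against its generating
process — they do not certify robustness to covariate dependence,
informative censoring, survey weights or reporting error, none of
which the generator produces.

## Identifiability

Two soft non-identifiabilities are inherent to the model and worth
knowing when reading fitted decompositions. First, fixed effects that
are constant within states (the region dummies, and the intercept) are
confounded with the spatial field: the zero-sum constraint removes
only one degree of freedom per graph component, so region-level shifts
can be traded between `β_region` and `s`, resolved only softly by the
ICAR smoothness prior. Second, with households nested in states, the
frailties can absorb state-level structure. The linear predictor `η`
is well identified (in the bundled full-schema experiment the fitted
`η` correlates ≈ 0.98 with the truth while individual region
coefficients do not recover); comparisons of DIC/WAIC and the
covariate contrasts that vary within states are unaffected.

## Numerical and design choices

* The time ratio reported in tables is `exp(posterior mean)`, matching
  the arithmetic of the published tables, not the posterior mean of
  `exp(β)`.
* Choropleth bins are left-closed/right-open on the TR scale; a value
  exactly on a break goes to the upper bin. Defaults are the clean
  symmetric breaks (0.80, 0.95, 1.05, 1.25); the `FIG_PRESET_BREAKS`
  preset approximates the irregular figure-derived bins of the source
  maps and is marked approximate because their exact break values are
  not printed.
* The ICAR constraint check uses an absolute tolerance of 10⁻⁶ per
  node; isolated graph nodes are allowed, receive a spatial effect of
  exactly zero, and are flagged with a warning.
* Graph files map node names to indices in sorted order,
  deterministically; lattice labels are zero-padded so the sorted
  order is row-major.
* Posterior draws persist as a compressed array archive plus a JSON
  manifest; all CSV/GeoJSON outputs are serialised deterministically,
  and the test suite checks byte-identical re-runs under a fixed seed.

## Problem sizes used in the shipped experiments

The recovery and model-selection experiments run at 2000 respondents,
100 households and a 5×5 lattice with true coefficients (0.3, −0.5),
k = 2, τ_u = 4, τ_s = 2 — 20 replicates in the test suite, 10 by
default in `scripts/acceptance.py`. Chain lengths (3000–3500
iterations, half burn-in; 22000 for the quadrature-calibration check)
were chosen so Monte-Carlo error is small relative to the margins
being tested; DIC/WAIC near-ties between the IID-only and combined
variants are decided by the data rather than sampler noise at these
lengths, which shorter chains do not guarantee.

## Known limitations

* No survey weights, stratified two-stage sampling, nonresponse,
  left truncation, interval censoring or time-varying covariates.
* Spline/smooth covariate effects are out of scope: the only metric
  covariate in the target schema enters linearly.
* The sampler is single-chain per call; run several seeds and use
  `convergence_summary` for R̂/ESS.
* Published headline criteria values from the original restricted
  microdata are not reproducible here; the package targets the
  *structure* of those analyses (orderings, operating characteristics,
  worked-example arithmetic), as its tests document.
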