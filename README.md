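# spataft

Bayesian spatial survival analysis for clustered survey data: Weibull
accelerated-failure-time (AFT) models whose linear predictor combines
fixed covariate effects, an IID household frailty, and a Besag intrinsic
conditional autoregressive (ICAR) spatial effect on a state adjacency
graph.

The package is built for analyses of age at sexual debut in national
household surveys (DHS-style data: respondents nested in households,
households nested in states), where an *event* is a debut at or below a
threshold age (17 years by default) and later debuts are
administratively censored. The same machinery applies to any
right-censored outcome with two levels of clustering, one of them
spatial.

## Model

For respondent *i* with covariates `x_i`, household `h(i)` and state
`g(i)`, the event time follows a Weibull AFT model

```
T_i ~ Weibull(shape k, scale λ_i),     λ_i = exp(η_i)
η_i = β₀ + x_i'β + u_{h(i)} + s_{g(i)}
```

with

* `u_h ~ Normal(0, 1/τ_u)` — IID household frailties,
* `s` — a Besag ICAR field on the state contiguity graph: each state's
  effect is conditionally normal around the weighted mean of its
  neighbours, with precision `τ_s`; the improper joint density is
  evaluated on the sum-to-zero subspace (per connected component) with
  the generalized log-determinant of the weighted graph Laplacian,
* Normal priors on `β₀`, `β` and `log k`; Gamma priors on the
  precisions.

Because the model is AFT, `exp(β_j)` is a **time ratio** (TR): TR > 1
means the covariate stretches time to the event (later debut), TR < 1
shortens it. Posterior inference is by an adaptive
Metropolis-within-Gibbs sampler (conjugate Gamma updates for the
precisions; the spatial field is sampled in the Laplacian eigenbasis so
the sum-to-zero constraint holds exactly at every draw). The four
nested variants — no clustering, IID only, ICAR only, both — are
compared by DIC and WAIC from the stored pointwise log-likelihood
matrix. A Cox proportional-hazards fit with the Grambsch–Therneau
scaled-Schoenfeld-residual test is included as the diagnostic that
motivates the AFT choice, and a synthetic-data generator emulates the
survey's structure with known ground truth.

## Worked example

```python
import spataft as sp

# a small synthetic survey: 2000 respondents, 100 households, 5x5 state map
factors = {
    "education": sp.FactorSpec(("none", "some"), (0.5, 0.5), (0.3,)),
    "wealth": sp.FactorSpec(("poor", "rich"), (0.6, 0.4), (-0.5,)),
}
config = sp.SimulationConfig(
    n_subjects=2000, n_households=100, graph=sp.make_lattice_graph(5, 5),
    intercept=2.9, shape=2.0, tau_u=4.0, tau_s=2.0,
    metric={}, factors=factors, region=None, seed=42)
dataset, truth = sp.simulate_dataset(config)

est = sp.BayesianWeibullAFT(iterations=4000, burnin=2000, seed=0)
est.fit(dataset, config.graph)
print(est.fixed_effects_.round(3).to_string(index=False))
```

```
          label   mean    sd  ci_low  ci_high  time_ratio
    (Intercept)  2.957 0.064   2.808    3.068         NaN
education[some]  0.272 0.032   0.209    0.340       1.313
   wealth[rich] -0.540 0.032  -0.600   -0.476       0.583
```

The posterior means sit on the generating values (0.3 and −0.5): having
some education multiplies time to debut by ≈ 1.31 (a delay), the wealth
contrast shortens it to ≈ 0.58 of the reference. Fitting all four
variants and ranking them:

```python
fits = []
for iid, icar in [(False, False), (True, False), (False, True), (True, True)]:
    spec = sp.ModelSpec(include_iid=iid, include_icar=icar)
    samples = sp.run_mcmc(dataset, spec, config.graph,
                          sp.SamplerSettings(iterations=3000, burnin=1500, seed=1))
    fits.append((spec.label, samples))
print(sp.compare_models(fits, dataset, config.graph))
```

```
             model      dic       p_d     waic    p_waic
     No clustering  9064.55  4.113400  9064.50  4.044534
    IID clustering  7546.48 96.951281  7549.95 93.970330
        Besag ICAR  8303.56 26.086288  8305.70 27.675659
IID and Besag ICAR 7546.16* 94.448404 7549.30* 91.400547
```

The data carry both effects, and the combined model attains the lowest
DIC and WAIC (starred).

The same pipeline is available from the shell:

```sh
spataft simulate --seed 5 --out run/
spataft fit --data run/dataset.csv --graph run/graph.csv \
        --model iid_besag --seed 5 --out run/fit/
spataft ph-test --data run/dataset.csv --out run/ph.csv
spataft report --fit run/fit --graph run/graph.csv --out run/report/
```

`report` writes per-state time ratios binned for choropleth mapping and
can join them onto any user-supplied GeoJSON (`--geojson`,
`--key-field`).

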