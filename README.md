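# dynocc — dynamic multi-scale occupancy models

`dynocc` fits occupancy models for species monitored under nested survey
designs whose distributions shift from year to year — nomadic grassland
songbirds being the motivating case. Monitoring programs such as IMBCR
survey 1-km² grid cells, each subsampled by 16 point-count stations, each
surveyed with three 2-minute removal intervals, and repeat the whole design
annually. Standard occupancy models either handle the spatial nesting
(multi-scale models) or the temporal dynamics (colonization–extinction
models), but not both at once. `dynocc` implements the joint model, for
ecologists and biometricians who need landscape-scale vital rates and
local-scale habitat effects from the same data.

## The model

For unit *i*, station *j*, interval *k* and year *t*:

```
z_i1 ~ Bernoulli(ψ_i)                                   initial occupancy
z_it ~ Bernoulli((1 − ε_i,t−1) z_i,t−1 + γ_i,t−1 (1 − z_i,t−1))
u_ijt ~ Bernoulli(θ_ijt · z_it)                         availability
y_ijkt ~ Bernoulli(p_t · u_ijt)                          detection
```

ψ (initial occupancy), ε (extinction), γ (colonization) and θ (local-scale
occupancy) are logit-linear in covariates — `logit(ψ_i) = x_i,1 β`,
`logit(ε_it) = x_i,t+1 η`, `logit(γ_it) = x_i,t+1 δ`,
`logit(θ_ijt) = w_ij,t+1 α` — while detection p gets one free probability
per year. Under the removal protocol a station-year's occasions stop at
the first detection, so P(first detection at k | u = 1) = (1 − p)^{k−1} p.

Derived quantities follow from the primaries: year-specific occupancy via
`ψ_t = ψ_{t−1}(1 − ε_{t−1}) + (1 − ψ_{t−1}) γ_{t−1}`, unconditional
local-scale occupancy `δ_t = ψ_t θ_t`, and turnover
`τ_t = γ_{t−1}(1 − ψ_{t−1}) / [γ_{t−1}(1 − ψ_{t−1}) + (1 − ε_{t−1}) ψ_{t−1}]`.

The likelihood is evaluated **exactly**: station states u are summed out
analytically and the year-to-year chain z by a 2-state hidden-Markov
forward recursion, all in log space. Fitting is by maximum marginal
likelihood (Wald intervals from the numerical Hessian) or by adaptive
block Metropolis MCMC on the same marginal posterior with vague priors
(Normal(0, variance 100) coefficients, Beta(1, 1) detection). Because the
likelihood is marginal, no latent-state data augmentation is needed and a
desk-scale fit takes seconds.

## Worked example

```python
import dynocc as dy

design = dy.paper_scale_design()        # 252 grids × 16 stations × 3 intervals × 7 years
covs   = dy.simulate_covariates(design, rng_seed=1)
params = dy.default_params(design)      # grassland-songbird-like effect structure
real   = dy.simulate_realization(params, covs, design, rng_seed=2)

result = dy.fit_mle(real.y, covs, design)
print(result.summary().round(2).head(8))
```

```
                 estimate  lower95  upper95    se
beta[intercept]      0.13    -1.11     1.37  0.63
beta[grassland]      1.37    -0.17     2.92  0.79
beta[shrubland]     -0.51    -4.67     3.65  2.12
beta[ndvi]          -0.09    -0.38     0.19  0.14
eta[intercept]       0.58    -0.14     1.31  0.37
eta[grassland]      -1.88    -2.76    -0.99  0.45
eta[shrubland]      -1.53    -3.80     0.74  1.16
eta[ndvi]           -0.63    -0.80    -0.47  0.08
```

`beta` rows are initial-occupancy coefficients (logit scale): occupancy
rises with grassland cover, though a single year of 252 grids leaves the
landscape-composition effects imprecise — their intervals are honest about
that. `eta` rows are extinction coefficients: grids with more grassland
and greener-than-average years lose the species less often. Detection
enters as `logit_p[t]` rows (here ≈ 0.76–0.87 on the probability scale).

Derived trajectories:

```python
traj = dy.derive_posterior(result, covs, design)
print(traj.to_frame().query("quantity == 'tau'").round(3))
```

```
 year quantity  mean
    2      tau 0.199
    3      tau 0.306
    4      tau 0.329
    ...
```

i.e. roughly a fifth to a third of occupied grids in any year are new
occupants — high turnover despite stable year-to-year occupancy, the
signature of a nomadic species.

The same workflows run from the shell: `dynocc simulate`, `dynocc fit`,
`dynocc derive`, `dynocc validate` operate on a delimited-text dataset
bundle (long-format detections CSV, unit- and station-covariate CSVs, JSON
manifest); see `dynocc --help`.

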