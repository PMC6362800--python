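# Methods

## Model and assumptions

The model couples two classical occupancy extensions in one hierarchy:
colonization–extinction dynamics at the sampling-unit (grid) scale and a
multi-scale availability layer at the station (point-count) scale, with a
removal-design detection process underneath. The latent structure is

* unit occupancy `z_it`: a 2-state Markov chain per unit, initialized at
  `ψ_i` and driven by extinction `ε_it` and colonization `γ_it`;
* station occupancy `u_ijt`: conditionally independent Bernoulli draws
  with probability `θ_ijt z_it` — stations are re-drawn each year given
  the unit state (no station-level memory);
* detection `y_ijkt`: Bernoulli with probability `p_t u_ijt` per interval;
  under the removal protocol surveying stops at the first detection.

Assumptions inherited from this structure: closure of the unit state
within a year; conditional independence of stations given `z` and of
intervals given `u` (no overdispersion correction); no false positives; no
spatial autocorrelation between units; detection varies by year only.

## Exact marginal likelihood

All latent states are integrated out analytically, which is the package's
computational core. For one station-year the history mass given `z = 1` is
the two-branch mixture `θ·P(h | u=1) + (1−θ)·1[h empty]`; given `z = 0` it
is the indicator that nothing was detected. The removal mass
`(1−p)^{k−1} p` for a first detection at interval `k` equals the Bernoulli
product over the surveyed prefix, so both protocols reduce to
`p^{#detections}(1−p)^{#surveyed zeros}` over surveyed intervals — the
protocol distinction matters for data validity and simulation, not for the
mass function. Station factors multiply into per-unit-year emission
probabilities, and a 2-state forward recursion over years yields the unit
likelihood. Everything runs in log space with `logaddexp`; impossible
events are a proper `-inf`, and a unit whose total likelihood is zero
raises an error naming the unit rather than returning `-inf` silently.

Missing data (unsurveyed intervals, stations, or whole unit-years,
including the intervals blanked by the removal rule) contribute likelihood
1, i.e. they are treated as missing at random.

A brute-force oracle (`brute_force_loglik`) enumerates all `2^T` unit
state sequences with direct linear-space arithmetic and is used only for
validation; it is guarded to `T ≤ 12`, `R ≤ 8`.

## Parameters, links, defaults

Coefficient vectors β (initial occupancy), η (extinction), δ
(colonization) and α (availability) act through logit links on design
matrices with explicit intercept columns; transitions into year `t+1` use
the covariates of the destination year. Detection is one free probability
per year, sampled/optimized on the logit scale. Year-specific NDVI is
standardized within year across units (mean 0, sd 1), so its coefficient
is per-sd-of-greenness-anomaly. Point vegetation covariates are used in
their field units — percent cover on [0, 1] snapped to observer bins
(0, 1, 5, 10 … 100%) and grass height in cm with a raw squared column —
which is why a quadratic height coefficient of order 10⁻³–10⁻⁴ is the
expected magnitude.

## Fitting

**Maximum likelihood.** L-BFGS-B on the negative marginal log-likelihood
over the unconstrained parameter vector. Design-matrix columns are
standardized internally to their root-mean-square (intercepts and logit-p
unaffected) and coefficients mapped back afterwards; without this, the
cm-scale height and height² columns condition the problem so badly that a
quasi-Newton run from a neutral start can stall short of the optimum.
Wald 95% intervals come from the inverse numerical Hessian
(forward-difference first, centered-difference retry if the result is not
positive definite; flat directions fall back to a pseudo-inverse and are
reported as missing SEs). Fits with zero detections, boundary estimates,
or optimizer failure are returned flagged, never silently.

**Bayesian MCMC.** Adaptive random-walk Metropolis on the marginalized
posterior — the latent states never appear, so this samples the same
posterior over (β, η, δ, α, p) that a data-augmented Gibbs sampler would,
at far lower cost. Blocks: one per coefficient vector plus one for logit
p. Proposal scales adapt toward ≈30% acceptance in windows of 50
iterations during burn-in and are frozen afterwards, preserving the
stationary target. Priors: Normal(mean 0, **variance** 100) on every
coefficient (the common JAGS-style reporting convention; configurable via
`PriorSpec`) and Beta(1, 1) on each `p_t`, applied on the logit scale with
the Jacobian so the prior is exactly uniform in probability. Defaults are
25,000 iterations per chain with 12,500 burn-in and 4 chains; convergence
is summarized by split-R̂ (flag threshold 1.1) and bulk ESS via ArviZ, with
R̂ reported as unavailable (not fabricated) for single-chain runs. Chain
count, thinning (none) and the sampler family are engineering choices —
any correct sampler passing the calibration experiments is acceptable.

**Missing covariates.** Cells are imputed from empirical distributions:
columns with ≤20 distinct observed values (the binned cover measurements)
from the observed category frequencies, continuous columns from a normal
with the observed mean/sd truncated to the observed range; squared columns
are recomputed from their imputed linear partner. Inside `fit_mcmc` a
fresh imputation is drawn every iteration, so imputation uncertainty
propagates into the posterior. A column with no observed values at all is
an error.

## Derived quantities

`ψ_t` follows the occupancy recursion; `δ_t = ψ_t θ_t`; turnover `τ_t` is
the newly-colonized fraction of currently occupied units. With covariates
these are unit-specific, so they are computed per unit — with `θ_t` taken
as the within-unit mean of `θ_ijt` across stations — and the across-unit
mean is offered as the population summary. From a posterior, trajectories
are computed per draw (subsampled to 2,000 draws for speed) and
summarized by the mean and draw-wise 2.5/97.5% quantiles; `τ_t` is
undefined when no unit can be occupied and is reported as missing.

## Synthetic data

No public dataset accompanies the monitoring design, so the simulator is
a first-class module emulating its structure: N = 252 grids × R = 16
stations × K = 3 removal intervals × T = 7 years by default, with a small
preset (20 × 4 × 3 × 4) for fast tests. Covariate distributions are
plausible for a grass-dominated Great Plains landscape but are **not**
calibrated to any real dataset: grassland proportion ~ Beta(2.5, 1.2),
shrubland a Beta(1.5, 5) fraction of the remainder, NDVI Gaussian with
year-varying means before within-year standardization, point cover
Beta-distributed then snapped to observer bins, grass height Gamma with
mean 25 cm and sd 10. Default "true" parameters mirror the qualitative
structure reported for grassland songbirds — grassland raises initial
occupancy and colonization and lowers extinction, greener years lower
extinction, grass cover raises availability with a concave height effect,
and detection is high (0.76–0.87).

What passing tests therefore show: the estimators recover the parameters
of *this* generative process at these sample sizes, and the likelihood is
exactly the probability mass of that process. What they do not show:
robustness to spatial autocorrelation, observer heterogeneity, abundance-
induced detection variation, or covariate measurement error, none of which
the generator produces.

## Numerical choices and problem sizes

Log-zero is `-inf`, never a large negative float; `0·log 0` terms are
defined as 0 so degenerate probabilities stay exact. The forward pass and
emission computation are fully vectorized over units and stations (≈2 ms
per likelihood evaluation at the 252 × 16 × 3 × 7 scale). Verification
experiments use: 100 random tiny designs for the enumeration-oracle
comparison (tolerance 1e-10); exhaustive dataset enumeration on
1 × 1 × 2 × 2 for normalization; 10,000 units for simulator frequency
checks (3 binomial SEs); 50 replicate MLE fits at the full design and 50
replicate single-chain MCMC fits (2,600 iterations, 1,100 burn-in) at a
100 × 8 × 3 × 5 preset for interval calibration — sizes chosen to give
stable Monte-Carlo verdicts at desk scale.

## Known limitations

* Station occupancy is independently re-drawn each year given the unit
  state; station-level persistence (Markovian stations) is out of scope.
* Detection covariates are deliberately not supported (year effects only).
* The Wald intervals for weakly identified landscape-composition effects
  at a single year of data can be very wide or fall back to pseudo-inverse
  SEs; this is reported, not repaired.
* Real-data coefficient estimates from the motivating study are not
  reproducible here because those data are available only on request; they
  serve as qualitative sanity references (effect signs, high detection,
  high turnover) in one scenario-level test.
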