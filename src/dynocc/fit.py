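"""Model fitting: maximum marginal likelihood and Bayesian MCMC.

Both routes work on the marginal likelihood — latent unit and station
states are integrated out analytically by the forward algorithm — so the
free parameters are just the coefficient vectors (beta, eta, delta_coef,
alpha) and the year-specific detection probabilities on the logit scale.
The MCMC sampler therefore targets the same posterior a data-augmented
Gibbs sampler over explicit z and u would, at a fraction of the cost.

Default priors are vague: Normal(mean 0, variance 100) on every
coefficient and Beta(1, 1) on each p_t (sampled on the logit scale with
the Jacobian, so the prior is exactly uniform on the probability scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .likelihood import DetectionStats, detection_stats, loglik
from .model import CovariateSet, ModelParams, StudyDesign

__all__ = [
    "PriorSpec",
    "ParamStructure",
    "FitResult",
    "fit_mle",
    "fit_mcmc",
    "impute_missing_covariates",
    "diagnostics",
]

log = logging.getLogger("dynocc")

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class PriorSpec:
    """Priors: Normal(0, coef_var) on coefficients, Beta(1,1) on each p_t.

    ``coef_var`` is a variance (default 100, i.e. sd 10). ``p_beta`` can
    tighten the detection prior; (1, 1) is uniform.
    """

    coef_var: float = 100.0
    p_beta: tuple[float, float] = (1.0, 1.0)


@dataclass(frozen=True)
class ParamStructure:
    """Block layout of the packed working-scale parameter vector:
    [beta | eta | delta_coef | alpha | logit p_1..p_T]."""

    p_psi: int
    p_dyn: int
    p_theta: int
    n_years: int

    @classmethod
    def from_covs(cls, covs: CovariateSet, design: StudyDesign) -> "ParamStructure":
        return cls(covs.x_init.shape[1], covs.x_dyn.shape[2], covs.w_local.shape[3], design.n_years)

    @property
    def size(self) -> int:
        return self.p_psi + 2 * self.p_dyn + self.p_theta + self.n_years

    @property
    def blocks(self) -> dict[str, slice]:
        a = 0
        out = {}
        for name, width in (
            ("beta", self.p_psi),
            ("eta", self.p_dyn),
            ("delta_coef", self.p_dyn),
            ("alpha", self.p_theta),
            ("logit_p", self.n_years),
        ):
            out[name] = slice(a, a + width)
            a += width
        return out

    def names(self, covs: CovariateSet | None = None) -> list[str]:
        def cols(n, prefix, given):
            return list(given) if given else [f"{prefix}{i}" for i in range(n)]

        out = []
        init = cols(self.p_psi, "x", covs.init_names if covs else None)
        dyn = cols(self.p_dyn, "x", covs.dyn_names if covs else None)
        loc = cols(self.p_theta, "w", covs.local_names if covs else None)
        out += [f"beta[{c}]" for c in init]
        out += [f"eta[{c}]" for c in dyn]
        out += [f"delta[{c}]" for c in dyn]
        out += [f"alpha[{c}]" for c in loc]
        out += [f"logit_p[{t + 1}]" for t in range(self.n_years)]
        return out

    def pack(self, params: ModelParams) -> np.ndarray:
        return np.concatenate(
            [params.beta, params.eta, params.delta_coef, params.alpha, logit(params.p_year)]
        )

    def unpack(self, vec: np.ndarray) -> ModelParams:
        b = self.blocks
        return ModelParams(
            beta=vec[b["beta"]],
            eta=vec[b["eta"]],
            delta_coef=vec[b["delta_coef"]],
            alpha=vec[b["alpha"]],
            p_year=expit(vec[b["logit_p"]]),
        )


@dataclass
class FitResult:
    """Point estimates or posterior draws plus uncertainty and diagnostics.

    Everything is stored on the working (unconstrained) scale; ``params``
    maps the point estimate back to probabilities.
    """

    method: str  # "mle" or "mcmc"
    structure: ParamStructure
    param_names: list[str]
    estimates: np.ndarray  # working scale: MLE or posterior mean
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    se: np.ndarray | None = None
    draws: np.ndarray | None = None  # (chains, kept, P)
    loglik: float | None = None
    loglik_trace: np.ndarray | None = None
    acceptance: dict[str, float] | None = None
    rhat: np.ndarray | None = None
    ess: np.ndarray | None = None
    converged: bool = True
    warnings: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    imputation_log: dict | None = None

    def __post_init__(self) -> None:
        bad = ~(
            (self.ci_lower <= self.estimates + 1e-12)
            & (self.estimates <= self.ci_upper + 1e-12)
        )
        if bad.any():
            raise ValueError("interval bounds do not bracket the point estimate")

    @property
    def params(self) -> ModelParams:
        return self.structure.unpack(self.estimates)

    def params_from_vector(self, vec: np.ndarray) -> ModelParams:
        return self.structure.unpack(np.asarray(vec, dtype=float))

    def draw_matrix(self) -> np.ndarray | None:
        """All kept draws pooled across chains, (n_draws, P), or None."""
        if self.draws is None:
            return None
        return self.draws.reshape(-1, self.draws.shape[-1])

    def summary(self):
        import pandas as pd

        d = {
            "estimate": self.estimates,
            "lower95": self.ci_lower,
            "upper95": self.ci_upper,
        }
        if self.se is not None:
            d["se"] = self.se
        if self.rhat is not None:
            d["rhat"] = self.rhat
        if self.ess is not None:
            d["ess"] = self.ess
        return pd.DataFrame(d, index=self.param_names)


def _dataset_is_empty(stats: DetectionStats) -> bool:
    return bool(((stats.ndet + stats.nzero) == 0).all())


def _column_scales(covs: CovariateSet, structure: ParamStructure) -> np.ndarray:
    """Per-parameter scale factors (RMS of each design-matrix column).

    Covariates can live on wildly different scales (grass height in cm and
    its square versus 0/1 intercepts), which wrecks both quasi-Newton
    optimization and scalar-step random-walk proposals. Fitting happens on
    columns divided by these scales; coefficients map back as b = b_s / s.
    Intercepts and logit-p entries keep scale 1.
    """

    def rms(arr):
        if arr.size == 0:
            return np.ones(arr.shape[-1])
        flat = arr.reshape(-1, arr.shape[-1])
        with np.errstate(invalid="ignore"):
            s = np.sqrt(np.nanmean(flat**2, axis=0))
        s = np.where(np.isfinite(s) & (s > 0), s, 1.0)
        return s

    s_init, s_dyn, s_theta = rms(covs.x_init), rms(covs.x_dyn), rms(covs.w_local)
    return np.concatenate([s_init, s_dyn, s_dyn, s_theta, np.ones(structure.n_years)])


def _scale_covs(covs: CovariateSet, structure: ParamStructure, scales: np.ndarray) -> CovariateSet:
    b = structure.blocks
    return replace(
        covs,
        x_init=covs.x_init / scales[b["beta"]],
        x_dyn=covs.x_dyn / scales[b["eta"]] if covs.x_dyn.size else covs.x_dyn,
        w_local=covs.w_local / scales[b["alpha"]],
    )


def _make_objective(stats, covs, design, structure):
    def negloglik(vec):
        params = structure.unpack(vec)
        try:
            return -loglik(stats, params, covs, design)
        except FloatingPointError:
            return np.inf

    return negloglik


def fit_mle(
    y: np.ndarray,
    covs: CovariateSet,
    design: StudyDesign,
    start: ModelParams | str = "auto",
    n_starts: int = 1,
    rng_seed: int = 0,
    maxiter: int = 1000,
) -> FitResult:
    """Maximize the marginal likelihood; Wald 95% CIs from the numerical
    Hessian at the optimum.

    ``start="auto"`` begins at zero coefficients and p_t = 0.5; extra
    ``n_starts`` jitter the start to guard against local optima. Boundary
    or non-converged solutions are flagged in ``warnings``, never silently
    returned.
    """
    structure = ParamStructure.from_covs(covs, design)
    stats = detection_stats(y, design)
    scales = _column_scales(covs, structure)
    covs_s = _scale_covs(covs, structure, scales)
    obj = _make_objective(stats, covs_s, design, structure)
    rng = np.random.default_rng(rng_seed)

    if isinstance(start, ModelParams):
        x0 = structure.pack(start) * scales
    else:
        x0 = np.zeros(structure.size)
    starts = [x0] + [x0 + 0.5 * rng.standard_normal(structure.size) for _ in range(n_starts - 1)]

    best = None
    for s in starts:
        res = minimize(obj, s, method="L-BFGS-B", options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res

    warnings = []
    converged = bool(best.success)
    if not converged:
        warnings.append(f"optimizer did not converge: {best.message}")
    if stats.ndet.sum() == 0:
        warnings.append(
            "dataset contains no detections; occupancy and detection "
            "parameters are driven to the boundary and are not identified"
        )
        converged = False
    if np.abs(best.x).max() > 15:
        warnings.append(
            "estimate at or near the boundary (|working parameter| > 15); "
            "Wald intervals unreliable"
        )
        converged = False

    from statsmodels.tools.numdiff import approx_hess1, approx_hess3

    def hess_diag(H):
        try:
            return np.diag(np.linalg.inv(H)), False
        except np.linalg.LinAlgError:
            return np.diag(np.linalg.pinv(H)), True

    diag, singular = hess_diag(approx_hess1(best.x, obj))
    if (diag <= 0).any() or singular:
        # forward differences are noisy near flat ridges; retry centered
        diag, singular = hess_diag(approx_hess3(best.x, obj))
    if singular:
        warnings.append("singular Hessian (flat directions); SEs from pseudo-inverse")
    if (diag <= 0).any():
        warnings.append("Hessian not positive definite; some SEs unavailable")
    se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)

    # map back from the column-standardized space to original covariate units
    estimates = best.x / scales
    se = se / scales
    half = 1.959963984540054 * np.where(np.isfinite(se), se, np.inf)
    result = FitResult(
        method="mle",
        structure=structure,
        param_names=structure.names(covs),
        estimates=estimates,
        ci_lower=estimates - half,
        ci_upper=estimates + half,
        se=se,
        loglik=-float(best.fun),
        converged=converged,
        warnings=warnings,
        settings={"n_starts": n_starts, "maxiter": maxiter, "seed": int(rng_seed)},
    )
    for w in warnings:
        log.warning("fit_mle: %s", w)
    return result


def _log_prior(vec: np.ndarray, structure: ParamStructure, priors: PriorSpec) -> float:
    b = structure.blocks
    coefs = vec[: b["logit_p"].start]
    lp = -0.5 * float(coefs @ coefs) / priors.coef_var
    x = vec[b["logit_p"]]
    # Beta(a, b) on p, transformed to the logit scale (Jacobian p(1-p)):
    # log density ∝ a*log p + b*log(1-p) evaluated via stable softplus.
    a, bb = priors.p_beta
    softplus = np.logaddexp(0.0, x)  # -log(1 - p) = log(1 + e^x)
    lp += float((a * (x - softplus) - bb * softplus).sum())
    return lp


def fit_mcmc(
    y: np.ndarray,
    covs: CovariateSet,
    design: StudyDesign,
    priors: PriorSpec = PriorSpec(),
    n_samples: int = 25_000,
    burn_in: int = 12_500,
    chains: int = 4,
    rng_seed: int = 0,
    start: ModelParams | None = None,
    impute: bool = True,
) -> FitResult:
    """Adaptive block random-walk Metropolis on the marginalized posterior.

    One block per coefficient vector plus one for logit p; per-block
    proposal scales adapt toward ~30% acceptance during burn-in and are
    frozen afterwards. ``n_samples`` counts total iterations per chain and
    ``burn_in`` of those are discarded, so the default keeps
    25,000 − 12,500 = 12,500 draws per chain. Missing covariates (NaN) are
    re-imputed from their empirical distributions at every iteration,
    propagating imputation uncertainty into the posterior.
    """
    if n_samples <= burn_in:
        raise ValueError("n_samples must exceed burn_in")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    if chains < 1:
        raise ValueError("chains must be >= 1")
    structure = ParamStructure.from_covs(covs, design)

    imputation_log = None
    imputer = None
    if covs.n_missing:
        if not impute:
            raise ValueError("covariates contain missing values and impute=False")
        imputer = _CovariateImputer(covs)
        imputation_log = imputer.report()

    stats = detection_stats(y, design)
    empty = _dataset_is_empty(stats)
    scales = _column_scales(covs, structure)

    def log_post(vec, cur_covs):
        # vec lives in column-standardized space; the prior applies to the
        # original-scale coefficients vec / scales
        lp = _log_prior(vec / scales, structure, priors)
        if not np.isfinite(lp):
            return -np.inf
        if empty:
            return lp
        try:
            return lp + loglik(stats, structure.unpack(vec), cur_covs, design)
        except FloatingPointError:
            return -np.inf

    blocks = list(structure.blocks.items())
    P = structure.size
    n_keep = n_samples - burn_in
    kept = np.empty((chains, n_keep, P))
    ll_trace = np.empty((chains, n_keep))
    acc_counts = {name: 0 for name, _ in blocks}
    prop_counts = {name: 0 for name, _ in blocks}

    master = np.random.default_rng(rng_seed)
    chain_seeds = master.integers(0, 2**31 - 1, size=chains)

    covs_s = _scale_covs(covs, structure, scales)
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        if start is not None:
            vec = structure.pack(start).astype(float) * scales
        else:
            vec = 0.3 * rng.standard_normal(P)
        cur_covs = covs_s if imputer is None else _scale_covs(imputer.draw(rng), structure, scales)
        step = {name: 2.38 / np.sqrt(sl.stop - sl.start) * 0.3 for name, sl in blocks}
        acc_window = {name: 0 for name, _ in blocks}
        n_window = 0
        cur_lp = log_post(vec, cur_covs)

        for it in range(n_samples):
            if imputer is not None:
                cur_covs = _scale_covs(imputer.draw(rng), structure, scales)
                cur_lp = log_post(vec, cur_covs)
            for name, sl in blocks:
                prop = vec.copy()
                prop[sl] = prop[sl] + step[name] * rng.standard_normal(sl.stop - sl.start)
                new_lp = log_post(prop, cur_covs)
                if np.log(rng.random()) < new_lp - cur_lp:
                    vec, cur_lp = prop, new_lp
                    acc_window[name] += 1
                    if it >= burn_in:
                        acc_counts[name] += 1
                if it >= burn_in:
                    prop_counts[name] += 1
            n_window += 1
            if it < burn_in and n_window == 50:
                for name, _ in blocks:
                    rate = acc_window[name] / n_window
                    step[name] *= float(np.exp(rate - 0.3))
                    acc_window[name] = 0
                n_window = 0
            if it >= burn_in:
                kept[c, it - burn_in] = vec / scales  # original covariate units
                ll_trace[c, it - burn_in] = cur_lp

    acceptance = {
        name: (acc_counts[name] / prop_counts[name]) if prop_counts[name] else np.nan
        for name, _ in blocks
    }
    pooled = kept.reshape(-1, P)
    est = pooled.mean(axis=0)
    lo = np.quantile(pooled, 0.025, axis=0)
    hi = np.quantile(pooled, 0.975, axis=0)
    # posterior mean can fall outside draw quantiles only pathologically
    lo = np.minimum(lo, est)
    hi = np.maximum(hi, est)

    warnings = []
    rhat = ess = None
    if chains >= 2:
        rhat, ess = _rhat_ess(kept)
        worst = np.nanmax(rhat)
        if worst > RHAT_THRESHOLD:
            warnings.append(
                f"potential scale reduction up to {worst:.3f} exceeds {RHAT_THRESHOLD}"
            )
    result = FitResult(
        method="mcmc",
        structure=structure,
        param_names=structure.names(covs),
        estimates=est,
        ci_lower=lo,
        ci_upper=hi,
        draws=kept,
        loglik_trace=ll_trace,
        acceptance=acceptance,
        rhat=rhat,
        ess=ess,
        converged=not warnings,
        warnings=warnings,
        settings={
            "n_samples": n_samples,
            "burn_in": burn_in,
            "chains": chains,
            "seed": int(rng_seed),
            "coef_var": priors.coef_var,
            "p_beta": list(priors.p_beta),
        },
        imputation_log=imputation_log,
    )
    for w in warnings:
        log.warning("fit_mcmc: %s", w)
    return result


def _rhat_ess(kept: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split-R̂ and bulk ESS via arviz."""
    import arviz as az

    idata = az.from_dict(posterior={"x": kept})
    rhat = az.rhat(idata).x.values
    ess = az.ess(idata).x.values
    return np.atleast_1d(rhat), np.atleast_1d(ess)


class _CovariateImputer:
    """Empirical-distribution imputation for missing covariate cells.

    Columns with few distinct observed values (the binned percent-cover
    measurements) are drawn from the empirical category frequencies;
    continuous columns from a normal with the observed mean/sd truncated
    to the observed range. Squared columns named in ``quadratic_pairs``
    are recomputed from their imputed linear column.
    """

    BINNED_MAX_UNIQUE = 20

    def __init__(self, covs: CovariateSet):
        self.covs = covs
        self.plans = []  # (attr, column index, mask, sampler description)
        self.squared = {}  # attr -> {squared_col_idx: linear_col_idx}
        for attr, names in (
            ("x_init", covs.init_names),
            ("x_dyn", covs.dyn_names),
            ("w_local", covs.local_names),
        ):
            arr = getattr(covs, attr)
            sq_idx = {}
            for lin, sq in covs.quadratic_pairs:
                if lin in names and sq in names:
                    sq_idx[names.index(sq)] = names.index(lin)
            self.squared[attr] = sq_idx
            for col in range(arr.shape[-1]):
                vals = arr[..., col]
                mask = np.isnan(vals)
                if col in sq_idx:
                    continue  # recomputed from the linear column
                if not mask.any():
                    continue
                obs = vals[~mask]
                if obs.size == 0:
                    raise ValueError(
                        f"column {col} of {attr} is entirely missing; nothing to impute from"
                    )
                uniq = np.unique(obs)
                if uniq.size <= self.BINNED_MAX_UNIQUE:
                    freq = np.array([(obs == v).sum() for v in uniq], dtype=float)
                    plan = ("categorical", uniq, freq / freq.sum())
                else:
                    mu, sd = obs.mean(), obs.std(ddof=1)
                    plan = ("truncnorm", mu, max(sd, 1e-12), obs.min(), obs.max())
                self.plans.append((attr, col, mask, plan))

    def report(self) -> dict:
        total = sum(m.size for _, _, m, _ in self.plans) or 1
        missing = sum(int(m.sum()) for _, _, m, _ in self.plans)
        return {
            "n_missing_cells": missing,
            "columns": [(attr, col, int(m.sum())) for attr, col, m, _ in self.plans],
        }

    def draw(self, rng: np.random.Generator) -> CovariateSet:
        new = replace(
            self.covs,
            x_init=self.covs.x_init.copy(),
            x_dyn=self.covs.x_dyn.copy(),
            w_local=self.covs.w_local.copy(),
        )
        for attr, col, mask, plan in self.plans:
            arr = getattr(new, attr)
            n = int(mask.sum())
            if plan[0] == "categorical":
                _, vals, pr = plan
                fill = rng.choice(vals, size=n, p=pr)
            else:
                _, mu, sd, lo, hi = plan
                a, b = (lo - mu) / sd, (hi - mu) / sd
                fill = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
            arr[..., col][mask] = fill
        for attr, sq_idx in self.squared.items():
            arr = getattr(new, attr)
            for sq, lin in sq_idx.items():
                m = np.isnan(arr[..., sq])
                if m.any():
                    arr[..., sq][m] = arr[..., lin][m] ** 2
        return new


def impute_missing_covariates(
    covs: CovariateSet, method: str = "empirical", rng: np.random.Generator | int = 0
) -> tuple[CovariateSet, dict]:
    """Single imputation draw for missing covariate cells.

    Returns the completed CovariateSet and a log of what was filled.
    With no missing values the input is returned unchanged. Inside
    :func:`fit_mcmc` a fresh draw is taken every iteration instead, so the
    posterior reflects imputation uncertainty.
    """
    if method != "empirical":
        raise ValueError(f"unknown imputation method {method!r}")
    if covs.n_missing == 0:
        return covs, {"n_missing_cells": 0, "columns": []}
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    imputer = _CovariateImputer(covs)
    return imputer.draw(rng), imputer.report()


def diagnostics(result: FitResult):
    """Per-parameter convergence report for an MCMC fit.

    Columns: posterior mean/sd, split-R̂, bulk ESS, and a flag for R̂ above
    1.1. With a single chain R̂ is reported as missing, never fabricated.
    """
    import pandas as pd

    if result.draws is None:
        raise ValueError("diagnostics requires an MCMC result with draws")
    pooled = result.draw_matrix()
    out = pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1),
        },
        index=result.param_names,
    )
    if result.draws.shape[0] >= 2:
        rhat, ess = (result.rhat, result.ess)
        if rhat is None:
            rhat, ess = _rhat_ess(result.draws)
        out["rhat"] = rhat
        out["ess"] = ess
        out["flagged"] = out["rhat"] > RHAT_THRESHOLD
    else:
        import arviz as az

        out["rhat"] = np.nan  # undefined for a single chain
        out["ess"] = np.atleast_1d(
            az.ess(az.from_dict(posterior={"x": result.draws})).x.values
        )
        out["flagged"] = False
    return out
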