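"""Derived occupancy quantities: year-specific occupancy psi_t, the
unconditional local-scale occupancy delta_t = psi_t * theta_t, and the
turnover probability tau_t (the chance a currently occupied unit was
unoccupied the year before).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CovariateSet, StudyDesign, resolve_probabilities

__all__ = [
    "DerivedTrajectory",
    "occupancy_recursion",
    "local_occupancy",
    "turnover",
    "derive_posterior",
]


@dataclass
class DerivedTrajectory:
    """Trajectories of derived quantities with 95% interval bands.

    When built from a posterior, ``*_lower``/``*_upper`` are draw-wise
    2.5/97.5% quantiles; from a point estimate they collapse onto the mean.
    """

    psi_t: np.ndarray  # (T,)
    delta_t: np.ndarray  # (T,)
    tau_t: np.ndarray  # (T-1,) turnover into years 2..T
    aggregation_level: str = "population_mean"
    psi_lower: np.ndarray | None = None
    psi_upper: np.ndarray | None = None
    delta_lower: np.ndarray | None = None
    delta_upper: np.ndarray | None = None
    tau_lower: np.ndarray | None = None
    tau_upper: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        rows = []
        T = len(self.psi_t)
        for name, mean, lo, hi, years in (
            ("psi", self.psi_t, self.psi_lower, self.psi_upper, range(1, T + 1)),
            ("delta", self.delta_t, self.delta_lower, self.delta_upper, range(1, T + 1)),
            ("tau", self.tau_t, self.tau_lower, self.tau_upper, range(2, T + 1)),
        ):
            for idx, yr in enumerate(years):
                rows.append(
                    (
                        yr,
                        name,
                        mean[idx],
                        mean[idx] if lo is None else lo[idx],
                        mean[idx] if hi is None else hi[idx],
                    )
                )
        return pd.DataFrame(rows, columns=["year", "quantity", "mean", "lower95", "upper95"])


def occupancy_recursion(psi1, eps, gam) -> np.ndarray:
    """Propagate occupancy through time:
    psi_t = psi_{t-1} (1 - eps_{t-1}) + (1 - psi_{t-1}) gam_{t-1}.

    ``psi1`` may be scalar or an array of leading shape (...,); ``eps`` and
    ``gam`` then have shape (..., T-1). Returns (..., T).
    """
    psi1 = np.asarray(psi1, dtype=float)
    eps = np.asarray(eps, dtype=float)
    gam = np.asarray(gam, dtype=float)
    if eps.shape != gam.shape:
        raise ValueError(f"eps shape {eps.shape} != gam shape {gam.shape}")
    if eps.shape[:-1] != psi1.shape and not (psi1.ndim == 0):
        raise ValueError("psi1 leading shape must match eps/gam")
    n_trans = eps.shape[-1] if eps.ndim else 0
    out = np.empty(np.broadcast_shapes(psi1.shape, eps.shape[:-1]) + (n_trans + 1,))
    out[..., 0] = psi1
    for t in range(n_trans):
        prev = out[..., t]
        out[..., t + 1] = prev * (1.0 - eps[..., t]) + (1.0 - prev) * gam[..., t]
    return out


def local_occupancy(psi_t, theta_t) -> np.ndarray:
    """Unconditional station-scale occupancy, delta_t = psi_t * theta_t."""
    psi_t = np.asarray(psi_t, dtype=float)
    theta_t = np.asarray(theta_t, dtype=float)
    if psi_t.shape != theta_t.shape:
        raise ValueError(f"psi_t shape {psi_t.shape} != theta_t shape {theta_t.shape}")
    return psi_t * theta_t


def turnover(psi_prev, eps, gam) -> np.ndarray | float:
    """Probability an occupied unit is newly occupied:
    tau = gam (1 - psi) / [gam (1 - psi) + (1 - eps) psi].

    Undefined denominators (no occupied units possible) yield NaN.
    """
    psi_prev = np.asarray(psi_prev, dtype=float)
    eps = np.asarray(eps, dtype=float)
    gam = np.asarray(gam, dtype=float)
    num = gam * (1.0 - psi_prev)
    den = num + (1.0 - eps) * psi_prev
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def _trajectories_one_draw(params, covs, design, level):
    """psi_t, delta_t, tau_t for one parameter draw, resolved per unit.

    theta_t within a unit is the across-station mean of theta_{i,j,t}; the
    population summary averages unit trajectories across units.
    """
    probs = resolve_probabilities(params, covs, design)
    psi = occupancy_recursion(probs.psi_init, probs.eps, probs.gam)  # (N, T)
    theta_unit = probs.theta.mean(axis=1)  # (N, T)
    delta = local_occupancy(psi, theta_unit)
    tau = turnover(psi[:, :-1], probs.eps, probs.gam)  # (N, T-1)
    if level == "population_mean":
        return psi.mean(axis=0), delta.mean(axis=0), np.nanmean(tau, axis=0) if tau.size else tau.mean(axis=0)
    return psi, delta, tau


def derive_posterior(
    result,
    covs: CovariateSet,
    design: StudyDesign,
    level: str = "population_mean",
    max_draws: int = 2000,
    rng_seed: int = 0,
) -> DerivedTrajectory:
    """Derived trajectories per posterior draw (or at point estimates).

    ``result`` is a FitResult. With draws, computes psi_t/delta_t/tau_t for
    each (subsampled to ``max_draws``) and summarizes with the mean and
    draw-wise 95% quantiles; MLE results yield zero-width bands at the
    point estimate.
    """
    if level not in ("population_mean", "per_unit"):
        raise ValueError("level must be 'population_mean' or 'per_unit'")
    draws = result.draw_matrix()
    if draws is None:
        params = result.params
        psi, delta, tau = _trajectories_one_draw(params, covs, design, level)
        return DerivedTrajectory(psi, delta, tau, aggregation_level=level)
    if draws.shape[0] > max_draws:
        idx = np.random.default_rng(rng_seed).choice(draws.shape[0], max_draws, replace=False)
        idx.sort()
        draws = draws[idx]
    psis, deltas, taus = [], [], []
    for vec in draws:
        params = result.params_from_vector(vec)
        psi, delta, tau = _trajectories_one_draw(params, covs, design, level)
        psis.append(psi)
        deltas.append(delta)
        taus.append(tau)
    psis, deltas, taus = np.array(psis), np.array(deltas), np.array(taus)

    def q(a, qq):
        return np.nanquantile(a, qq, axis=0)

    return DerivedTrajectory(
        psi_t=psis.mean(axis=0),
        delta_t=deltas.mean(axis=0),
        tau_t=np.nanmean(taus, axis=0),
        aggregation_level=level,
        psi_lower=q(psis, 0.025),
        psi_upper=q(psis, 0.975),
        delta_lower=q(deltas, 0.025),
        delta_upper=q(deltas, 0.975),
        tau_lower=q(taus, 0.025),
        tau_upper=q(taus, 0.975),
    )
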