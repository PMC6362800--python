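"""Core domain types and link-function machinery.

The model is a dynamic multi-scale occupancy model. A landscape of ``N``
sampling units (1-km² grids) is surveyed at ``R`` stations (point-count
plots) per unit over ``T`` primary periods (years), with ``K`` secondary
occasions (removal intervals) per station. Five parameter classes govern
the data:

* ``psi`` — initial unit-scale occupancy probability, year 1;
* ``gamma`` — colonization: P(occupied at t | unoccupied at t-1);
* ``epsilon`` — extinction: P(unoccupied at t | occupied at t-1);
* ``theta`` — availability / local-scale occupancy: P(station occupied |
  unit occupied), station- and year-specific;
* ``p`` — per-interval detection probability, year-specific.

All but ``p`` are modeled on the logit scale as linear functions of
covariates; ``p`` carries one free probability per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import expit, logit as _logit

__all__ = [
    "Protocol",
    "StudyDesign",
    "CovariateSet",
    "ModelParams",
    "ResolvedProbabilities",
    "inv_logit",
    "logit",
    "resolve_probabilities",
]


class Protocol(str, Enum):
    """Secondary-occasion survey protocol.

    ``removal``: occasions at a station cease after the first detection
    (the IMBCR point-count usage); ``repeated``: all K occasions are
    surveyed regardless of detections.
    """

    removal = "removal"
    repeated = "repeated"


@dataclass(frozen=True)
class StudyDesign:
    """Dimensions and protocol of the nested sampling design."""

    n_units: int
    n_stations: int
    n_intervals: int
    n_years: int
    protocol: Protocol = Protocol.removal

    def __post_init__(self) -> None:
        for name in ("n_units", "n_stations", "n_intervals", "n_years"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        object.__setattr__(self, "protocol", Protocol(self.protocol))

    @property
    def shape_y(self) -> tuple[int, int, int, int]:
        return (self.n_units, self.n_stations, self.n_intervals, self.n_years)


@dataclass
class CovariateSet:
    """Design matrices for the four logit-linear parameter classes.

    Intercept columns are stored explicitly. ``x_dyn[:, t, :]`` holds the
    covariates of the *destination* year t+1 and drives the transition from
    year t to t+1 (0-based transition row t).

    ``quadratic_pairs`` names (linear, squared) column pairs in the
    station-level matrix whose squared column must equal the square of the
    linear one — kept consistent by the imputation machinery.
    """

    x_init: np.ndarray  # (N, P_psi)
    x_dyn: np.ndarray  # (N, T-1, P_dyn)
    w_local: np.ndarray  # (N, R, T, P_theta)
    init_names: list[str] = field(default_factory=list)
    dyn_names: list[str] = field(default_factory=list)
    local_names: list[str] = field(default_factory=list)
    quadratic_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x_init = np.asarray(self.x_init, dtype=float)
        self.x_dyn = np.asarray(self.x_dyn, dtype=float)
        self.w_local = np.asarray(self.w_local, dtype=float)
        if self.x_init.ndim != 2 or self.x_dyn.ndim != 3 or self.w_local.ndim != 4:
            raise ValueError(
                "x_init must be 2-d (units × columns), x_dyn 3-d "
                "(units × transitions × columns), w_local 4-d "
                "(units × stations × years × columns)"
            )
        if not self.init_names:
            self.init_names = [f"x{i}" for i in range(self.x_init.shape[1])]
        if not self.dyn_names:
            self.dyn_names = [f"x{i}" for i in range(self.x_dyn.shape[2])]
        if not self.local_names:
            self.local_names = [f"w{i}" for i in range(self.w_local.shape[3])]

    @property
    def n_missing(self) -> int:
        return int(
            np.isnan(self.x_init).sum()
            + np.isnan(self.x_dyn).sum()
            + np.isnan(self.w_local).sum()
        )

    def validate(self, design: StudyDesign | None = None, allow_missing: bool = False) -> None:
        if not allow_missing and self.n_missing:
            raise ValueError(
                f"covariates contain {self.n_missing} missing (NaN) entries; "
                "impute before resolving probabilities"
            )
        for name, arr in (("x_init", self.x_init), ("x_dyn", self.x_dyn), ("w_local", self.w_local)):
            if np.isinf(arr).any():
                raise ValueError(f"{name} contains non-finite (inf) entries")
        if design is not None:
            N, R, T = design.n_units, design.n_stations, design.n_years
            if self.x_init.shape[0] != N:
                raise ValueError(f"x_init has {self.x_init.shape[0]} rows, design has {N} units")
            if T > 1 and self.x_dyn.shape[:2] != (N, T - 1):
                raise ValueError(
                    f"x_dyn has shape {self.x_dyn.shape[:2]}, expected ({N}, {T - 1})"
                )
            if self.w_local.shape[:3] != (N, R, T):
                raise ValueError(
                    f"w_local has shape {self.w_local.shape[:3]}, expected ({N}, {R}, {T})"
                )


@dataclass
class ModelParams:
    """Coefficient vectors and year-specific detection probabilities.

    ``delta_coef`` holds the colonization coefficients (the derived
    quantity delta_t = psi_t * theta_t is a different object).
    """

    beta: np.ndarray  # initial occupancy, (P_psi,)
    eta: np.ndarray  # extinction, (P_dyn,)
    delta_coef: np.ndarray  # colonization, (P_dyn,)
    alpha: np.ndarray  # availability, (P_theta,)
    p_year: np.ndarray  # detection, (T,)

    def __post_init__(self) -> None:
        for name in ("beta", "eta", "delta_coef", "alpha", "p_year"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite entries")
        if not ((self.p_year > 0) & (self.p_year < 1)).all():
            raise ValueError("p_year entries must lie strictly in (0, 1)")


@dataclass
class ResolvedProbabilities:
    """Per-unit probabilities obtained by applying the logit links."""

    psi_init: np.ndarray  # (N,)
    eps: np.ndarray  # (N, T-1)
    gam: np.ndarray  # (N, T-1)
    theta: np.ndarray  # (N, R, T)
    p: np.ndarray  # (T,), broadcastable to (N, R, K, T)


def inv_logit(x):
    """Inverse-logit (logistic) link, 1 / (1 + exp(-x)).

    Stable for |x| up to the float overflow limit; rejects non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("inv_logit requires finite input")
    out = expit(x)
    return out if out.ndim else float(out)


def logit(p):
    """Log-odds, inverse of :func:`inv_logit`."""
    out = _logit(np.asarray(p, dtype=float))
    return out if out.ndim else float(out)


def _check_len(name: str, coef: np.ndarray, ncols: int) -> None:
    if coef.shape[0] != ncols:
        raise ValueError(
            f"coefficient vector {name!r} has length {coef.shape[0]} but its "
            f"design matrix has {ncols} columns"
        )


def resolve_probabilities(
    params: ModelParams, covs: CovariateSet, design: StudyDesign
) -> ResolvedProbabilities:
    """Resolve coefficients into per-unit probabilities via the logit link.

    psi_i = inv_logit(x_init[i] · beta); eps/gam use the destination-year
    rows of ``x_dyn`` with eta / delta_coef; theta uses station-year rows
    of ``w_local`` with alpha; p is replicated from ``p_year``.
    """
    covs.validate(design)
    _check_len("beta", params.beta, covs.x_init.shape[1])
    _check_len("eta", params.eta, covs.x_dyn.shape[2])
    _check_len("delta_coef", params.delta_coef, covs.x_dyn.shape[2])
    _check_len("alpha", params.alpha, covs.w_local.shape[3])
    if params.p_year.shape[0] != design.n_years:
        raise ValueError(
            f"p_year has length {params.p_year.shape[0]} but the design has "
            f"{design.n_years} years"
        )
    psi = expit(covs.x_init @ params.beta)
    if design.n_years > 1:
        eps = expit(covs.x_dyn @ params.eta)
        gam = expit(covs.x_dyn @ params.delta_coef)
    else:
        eps = np.empty((design.n_units, 0))
        gam = np.empty((design.n_units, 0))
    theta = expit(covs.w_local @ params.alpha)
    return ResolvedProbabilities(
        psi_init=psi, eps=eps, gam=gam, theta=theta, p=params.p_year.copy()
    )
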