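"""Exact marginal likelihood of detection histories.

All latent states are summed out analytically: station occupancy ``u`` by
the two-branch mixture theta·P(h|u=1) + (1-theta)·1[h empty], and the
year-to-year unit chain ``z`` by a 2-state hidden-Markov forward recursion.
Everything runs in log space; impossible events carry a proper -inf.

A key simplification: the removal-design mass for a history with first
detection at interval k, (1-p)^{k-1} p, equals the Bernoulli product over
the surveyed prefix. P(h | u=1) is therefore computed uniformly as
p^{#detections} (1-p)^{#surveyed zeros} for both protocols; the protocol
only constrains which histories are valid. Unsurveyed intervals (NaN)
contribute probability 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .model import (
    CovariateSet,
    ModelParams,
    Protocol,
    ResolvedProbabilities,
    StudyDesign,
    resolve_probabilities,
)

__all__ = [
    "EmissionTable",
    "DetectionStats",
    "station_history_logprob",
    "detection_stats",
    "emission_logprobs",
    "forward_loglik",
    "loglik",
    "brute_force_loglik",
]

LOG_ZERO = -np.inf


@dataclass
class EmissionTable:
    """log P(all station histories in unit i, year t | z_{i,t} = s).

    ``log_e`` has shape (n_units, n_years, 2) with s ∈ {0, 1} on the last
    axis; any detection in a unit-year forces log_e[i, t, 0] = -inf.
    """

    log_e: np.ndarray


@dataclass
class DetectionStats:
    """Sufficient statistics of the detection array for the likelihood:
    per station-year, the number of detections and of surveyed zeros."""

    ndet: np.ndarray  # (N, R, T)
    nzero: np.ndarray  # (N, R, T)

    @property
    def any_detection(self) -> np.ndarray:  # (N, T)
        return self.ndet.sum(axis=1) > 0


def _validate_removal(y: np.ndarray) -> None:
    """Removal validity: within a station-year nothing is surveyed after a
    detection, and at most one detection occurs."""
    N, R, K, T = y.shape
    seen = np.zeros((N, R, T), dtype=bool)
    for k in range(K):
        yk = y[:, :, k, :]
        bad = seen & np.isfinite(yk)
        if bad.any():
            i, j, t = (int(v[0]) for v in np.nonzero(bad))
            raise ValueError(
                f"removal protocol violated: unit {i}, station {j}, year {t} "
                f"has a surveyed interval after a detection"
            )
        seen |= np.nan_to_num(yk) == 1


def station_history_logprob(
    history, theta: float, p: float, protocol: Protocol | str = Protocol.removal,
    condition: str = "z1",
) -> float:
    """Log-probability of one station-year history given the unit state.

    Given z=1 the station is occupied with probability ``theta``:
    P = theta·P(h|u=1) + (1-theta)·1[h has no detection]. Given z=0 no
    detection is possible: P = 1[h has no detection]. NaN entries are
    unsurveyed intervals and contribute probability 1.
    """
    h = np.asarray(history, dtype=float).ravel()
    if condition not in ("z1", "z0"):
        raise ValueError("condition must be 'z1' or 'z0'")
    if Protocol(protocol) is Protocol.removal:
        _validate_removal(h.reshape(1, 1, -1, 1))
    surveyed = np.isfinite(h)
    ndet = int((h[surveyed] == 1).sum())
    nzero = int((h[surveyed] == 0).sum())
    if condition == "z0":
        return 0.0 if ndet == 0 else LOG_ZERO
    ph_u1 = p**ndet * (1.0 - p) ** nzero
    prob = theta * ph_u1 + (1.0 - theta) * (ndet == 0)
    with np.errstate(divide="ignore"):
        return float(np.log(prob))


def detection_stats(y: np.ndarray, design: StudyDesign | None = None) -> DetectionStats:
    """Reduce the detection array to its sufficient statistics, validating
    removal structure when the design says so."""
    y = np.asarray(y, dtype=float)
    if design is not None:
        if y.shape != design.shape_y:
            raise ValueError(f"y has shape {y.shape}, design expects {design.shape_y}")
        if design.protocol is Protocol.removal:
            _validate_removal(y)
    surveyed = np.isfinite(y)
    ndet = np.where(surveyed, y, 0.0).sum(axis=2)
    nzero = (surveyed & (np.nan_to_num(y) == 0)).sum(axis=2).astype(float)
    return DetectionStats(ndet=ndet, nzero=nzero)


def _emission_from_stats(stats: DetectionStats, probs: ResolvedProbabilities) -> np.ndarray:
    """(N, T, 2) log emission array from sufficient statistics."""
    p = probs.p[None, None, :]  # broadcast over (N, R, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        # 0 * log(0) -> 0 so degenerate p in {0, 1} stays exact
        log_ph_u1 = np.where(stats.ndet > 0, stats.ndet * np.log(p), 0.0) + np.where(
            stats.nzero > 0, stats.nzero * np.log1p(-p), 0.0
        )
    e1 = probs.theta * np.exp(log_ph_u1) + (1.0 - probs.theta) * (stats.ndet == 0)
    with np.errstate(divide="ignore"):
        log_e1 = np.log(e1).sum(axis=1)  # (N, T)
    log_e0 = np.where(stats.any_detection, LOG_ZERO, 0.0)
    return np.stack([log_e0, log_e1], axis=-1)


def emission_logprobs(
    y: np.ndarray, probs: ResolvedProbabilities, design: StudyDesign
) -> EmissionTable:
    """Per unit-year log emission probabilities, stations multiplied out.

    Stations are conditionally independent given the unit state, so the
    log emission is a sum over stations; fully unsurveyed stations (all
    NaN) contribute 0.
    """
    return EmissionTable(log_e=_emission_from_stats(detection_stats(y, design), probs))


def forward_loglik(emissions: EmissionTable, probs: ResolvedProbabilities) -> float:
    """Total log-likelihood via the 2-state forward recursion over years.

    alpha_1(s) = P(z_1 = s) e_1(s); alpha_t(s') = sum_s alpha_{t-1}(s)
    T_t(s -> s') e_t(s') with T(0->1) = gamma, T(1->0) = epsilon; the
    result sums log sum_s alpha_T(s) over units.
    """
    log_e = emissions.log_e
    N, T, _ = log_e.shape
    psi = probs.psi_init
    with np.errstate(divide="ignore"):
        la0 = np.log1p(-psi) + log_e[:, 0, 0]
        la1 = np.log(psi) + log_e[:, 0, 1]
        for t in range(1, T):
            eps = probs.eps[:, t - 1]
            gam = probs.gam[:, t - 1]
            new0 = np.logaddexp(la0 + np.log1p(-gam), la1 + np.log(eps)) + log_e[:, t, 0]
            new1 = np.logaddexp(la0 + np.log(gam), la1 + np.log1p(-eps)) + log_e[:, t, 1]
            la0, la1 = new0, new1
    unit_ll = np.logaddexp(la0, la1)
    bad = ~np.isfinite(unit_ll)
    if bad.any():
        raise FloatingPointError(
            f"likelihood is zero (all latent paths impossible) for unit(s) "
            f"{np.nonzero(bad)[0].tolist()}"
        )
    return float(unit_ll.sum())


def loglik(
    y: np.ndarray | DetectionStats,
    params: ModelParams,
    covs: CovariateSet,
    design: StudyDesign,
) -> float:
    """Convenience wrapper: resolve, build emissions, run the forward pass."""
    probs = resolve_probabilities(params, covs, design)
    stats = y if isinstance(y, DetectionStats) else detection_stats(y, design)
    return forward_loglik(EmissionTable(_emission_from_stats(stats, probs)), probs)


def _station_prob(h: np.ndarray, theta: float, p: float, z: int) -> float:
    """Linear-space station-year probability; independent code path used by
    the enumeration oracle."""
    surveyed = np.isfinite(h)
    ndet = int((h[surveyed] == 1).sum())
    nzero = int((h[surveyed] == 0).sum())
    if z == 0:
        return 1.0 if ndet == 0 else 0.0
    ph_u1 = p**ndet * (1.0 - p) ** nzero
    return theta * ph_u1 + (1.0 - theta) * (1.0 if ndet == 0 else 0.0)


def brute_force_loglik(
    y: np.ndarray, probs: ResolvedProbabilities, design: StudyDesign
) -> float:
    """Marginal log-likelihood by exhaustive enumeration of z-sequences.

    Validation oracle only: cost grows as 2^T per unit, so designs are
    guarded to T ≤ 12 and R ≤ 8.
    """
    N, R, K, T = design.shape_y
    if T > 12 or R > 8:
        raise ValueError(
            f"enumeration over 2^{T} sequences with R={R} is infeasible; "
            "use forward_loglik"
        )
    y = np.asarray(y, dtype=float)
    total = 0.0
    for i in range(N):
        unit_prob = 0.0
        for zseq in product((0, 1), repeat=T):
            pr = probs.psi_init[i] if zseq[0] else 1.0 - probs.psi_init[i]
            for t in range(1, T):
                if zseq[t - 1] == 1:
                    pr *= (1.0 - probs.eps[i, t - 1]) if zseq[t] else probs.eps[i, t - 1]
                else:
                    pr *= probs.gam[i, t - 1] if zseq[t] else 1.0 - probs.gam[i, t - 1]
            if pr == 0.0:
                continue
            for t in range(T):
                for j in range(R):
                    pr *= _station_prob(
                        y[i, j, :, t], probs.theta[i, j, t], probs.p[t], zseq[t]
                    )
                    if pr == 0.0:
                        break
                if pr == 0.0:
                    break
            unit_prob += pr
        with np.errstate(divide="ignore"):
            unit_ll = np.log(unit_prob)
        if not np.isfinite(unit_ll):
            raise FloatingPointError(f"likelihood is zero for unit {i}")
        total += float(unit_ll)
    return total
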