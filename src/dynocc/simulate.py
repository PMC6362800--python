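"""Synthetic covariates and data from the generative occupancy model.

Emulates the IMBCR nested design: 1-km² grids holding 16 point-count
stations surveyed with three 2-min removal intervals, repeated over years.
Grid covariates are fixed landscape composition (proportion grassland and
shrubland) plus annually standardized NDVI; station covariates are ocular
vegetation measurements (percent grass/shrub cover binned the way field
observers record them, and mean grass height in cm with a quadratic term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

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
    "Scenario",
    "OccupancyRealization",
    "paper_scale_design",
    "small_design",
    "default_params",
    "simulate_covariates",
    "simulate_realization",
    "empirical_rates",
    "COVER_BINS",
]

# Percent-cover bins used by IMBCR observers: 0, 1, 5, then 10% steps.
COVER_BINS = np.array([0.0, 0.01, 0.05] + [k / 10 for k in range(1, 11)])


def paper_scale_design(protocol: str = "removal") -> StudyDesign:
    """Study-scale design: 252 grids × 16 stations × 3 intervals × 7 years."""
    return StudyDesign(252, 16, 3, 7, Protocol(protocol))


def small_design(protocol: str = "removal") -> StudyDesign:
    """Small preset for fast tests: 20 units × 4 stations × 3 × 4 years."""
    return StudyDesign(20, 4, 3, 4, Protocol(protocol))


@dataclass
class Scenario:
    """Distributional knobs for covariate generation.

    Defaults sketch a grass-dominated Great Plains landscape; all are
    configurable because the source monitoring data do not publish the
    marginal covariate distributions.
    """

    grassland_beta: tuple[float, float] = (2.5, 1.2)  # mean ≈ 0.68
    shrub_frac_beta: tuple[float, float] = (1.5, 5.0)  # shrub share of the rest
    ndvi_mean: float = 0.45
    ndvi_sd: float = 0.08
    ndvi_year_sd: float = 0.05  # year-to-year shift of mean greenness
    grass_cover_beta: tuple[float, float] = (2.5, 1.5)
    shrub_cover_beta: tuple[float, float] = (1.2, 6.0)
    grass_height_mean_cm: float = 25.0
    grass_height_sd_cm: float = 10.0
    constant: dict[str, float] = field(default_factory=dict)  # override: name -> value


@dataclass
class OccupancyRealization:
    """Latent states and observations from one simulated study.

    ``y`` is float with NaN marking "not surveyed" (under the removal
    protocol, intervals after the first detection in a station-year).
    """

    z: np.ndarray  # (N, T) unit occupancy
    u: np.ndarray  # (N, R, T) station occupancy
    y: np.ndarray  # (N, R, K, T) detections, NaN = not surveyed
    seed: int


def default_params(design: StudyDesign) -> ModelParams:
    """True parameters for the default scenario, with the qualitative
    structure reported for grassland songbirds: grassland raises initial
    occupancy and colonization, lowers extinction; greener years lower
    extinction; grass cover raises and tall grass (quadratically) lowers
    station availability; detection is high (0.76–0.87)."""
    p = np.linspace(0.76, 0.87, design.n_years)
    return ModelParams(
        beta=[-0.5, 2.0, 0.5, 0.0],
        eta=[0.0, -1.1, 0.0, -0.7],
        delta_coef=[-1.0, 0.95, 1.5, 0.3],
        alpha=[-1.0, 0.57, 0.5, 0.08, -0.0016],
        p_year=p,
    )


def _snap_to_bins(x: np.ndarray) -> np.ndarray:
    idx = np.abs(x[..., None] - COVER_BINS).argmin(axis=-1)
    return COVER_BINS[idx]


def simulate_covariates(
    design: StudyDesign, scenario: Scenario | None = None, rng_seed: int = 0
) -> CovariateSet:
    """Draw covariates and assemble design matrices.

    NDVI is standardized within year across units (mean 0, sd 1 per year).
    Unit matrices carry [intercept, grassland, shrubland, ndvi]; the
    initial-occupancy matrix uses year-1 NDVI and transition row t uses the
    NDVI of destination year t+1. Station matrices carry [intercept,
    grass_cover, shrub_cover, grass_height, grass_height_sq].
    """
    scenario = scenario or Scenario()
    rng = np.random.default_rng(rng_seed)
    N, R, T = design.n_units, design.n_stations, design.n_years
    c = scenario.constant

    def draw_beta(shape, ab, name):
        if name in c:
            val = float(c[name])
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"constant {name}={val} outside [0, 1]")
            return np.full(shape, val)
        return rng.beta(*ab, size=shape)

    grassland = draw_beta(N, scenario.grassland_beta, "grassland")
    shrub_frac = draw_beta(N, scenario.shrub_frac_beta, "shrub_frac")
    shrubland = (1.0 - grassland) * shrub_frac
    if ((grassland < 0) | (grassland > 1) | (shrubland < 0) | (grassland + shrubland > 1 + 1e-12)).any():
        raise ValueError("cover proportions outside [0, 1]")

    year_means = scenario.ndvi_mean + scenario.ndvi_year_sd * rng.standard_normal(T)
    ndvi_raw = year_means[None, :] + scenario.ndvi_sd * rng.standard_normal((N, T))
    if N > 1:
        ndvi = (ndvi_raw - ndvi_raw.mean(axis=0)) / ndvi_raw.std(axis=0, ddof=0)
    else:
        ndvi = np.zeros_like(ndvi_raw)

    grass_cover = _snap_to_bins(draw_beta((N, R, T), scenario.grass_cover_beta, "grass_cover"))
    shrub_cover = _snap_to_bins(draw_beta((N, R, T), scenario.shrub_cover_beta, "shrub_cover"))
    if "grass_height" in c:
        height = np.full((N, R, T), float(c["grass_height"]))
    else:
        m, s = scenario.grass_height_mean_cm, scenario.grass_height_sd_cm
        shape = (m / s) ** 2
        height = rng.gamma(shape, m / shape, size=(N, R, T))

    ones_u = np.ones(N)
    x_init = np.column_stack([ones_u, grassland, shrubland, ndvi[:, 0]])
    x_dyn = np.empty((N, max(T - 1, 0), 4))
    for t in range(T - 1):
        x_dyn[:, t, :] = np.column_stack([ones_u, grassland, shrubland, ndvi[:, t + 1]])
    w_local = np.stack(
        [np.ones((N, R, T)), grass_cover, shrub_cover, height, height**2], axis=-1
    )
    return CovariateSet(
        x_init=x_init,
        x_dyn=x_dyn,
        w_local=w_local,
        init_names=["intercept", "grassland", "shrubland", "ndvi"],
        dyn_names=["intercept", "grassland", "shrubland", "ndvi"],
        local_names=["intercept", "grass_cover", "shrub_cover", "grass_height", "grass_height_sq"],
        quadratic_pairs=[("grass_height", "grass_height_sq")],
    )


def simulate_realization(
    params: ModelParams | ResolvedProbabilities,
    covs: CovariateSet | None,
    design: StudyDesign,
    rng_seed: int = 0,
) -> OccupancyRealization:
    """Simulate latent states and detections.

    z_{i,1} ~ Bern(psi_i); z_{i,t} ~ Bern((1-eps) z + gam (1-z));
    u_{i,j,t} ~ Bern(theta z); detections per protocol: ``repeated`` draws
    Bern(p u) at every interval, ``removal`` stops surveying a station-year
    after its first detection (later intervals become NaN).

    ``params`` may be pre-resolved probabilities (``covs`` then ignored).
    """
    if not isinstance(rng_seed, (int, np.integer)):
        raise TypeError(f"rng_seed must be an integer, got {type(rng_seed).__name__}")
    probs = (
        params
        if isinstance(params, ResolvedProbabilities)
        else resolve_probabilities(params, covs, design)
    )
    N, R, K, T = design.shape_y
    rng = np.random.default_rng(rng_seed)
    state_rng, obs_rng = rng.spawn(2)

    z = np.empty((N, T), dtype=np.int8)
    z[:, 0] = state_rng.random(N) < probs.psi_init
    for t in range(1, T):
        persist = 1.0 - probs.eps[:, t - 1]
        stay = np.where(z[:, t - 1] == 1, persist, probs.gam[:, t - 1])
        z[:, t] = state_rng.random(N) < stay
    u = (state_rng.random((N, R, T)) < probs.theta * z[:, None, :]).astype(np.int8)

    p_full = np.broadcast_to(probs.p, (N, R, K, T))
    raw = (obs_rng.random((N, R, K, T)) < p_full * u[:, :, None, :]).astype(float)
    if design.protocol is Protocol.removal:
        detected_before = np.zeros((N, R, T), dtype=bool)
        y = raw.copy()
        for k in range(K):
            y[:, :, k, :][detected_before] = np.nan
            detected_before |= np.nan_to_num(y[:, :, k, :]) == 1
    else:
        y = raw
    return OccupancyRealization(z=z, u=u, y=y, seed=int(rng_seed))


def empirical_rates(realization: OccupancyRealization) -> "pd.DataFrame":
    """Observed frequencies for simulator validation.

    Returns a tidy table of unit occupancy per year, station occupancy
    among occupied units, per-interval detection among occupied stations
    (first-detection fractions under removal), and realized transitions.
    Conditioning on an empty set yields NaN, never 0.
    """
    import pandas as pd

    z, u, y = realization.z, realization.u, realization.y
    N, R, K, T = y.shape
    rows = []
    for t in range(T):
        rows.append(("unit_occupancy", t, None, z[:, t].mean(), N))
        occ = z[:, t] == 1
        n_occ_stations = int(occ.sum()) * R
        rows.append(
            (
                "station_occupancy_given_unit",
                t,
                None,
                u[occ, :, t].mean() if occ.any() else np.nan,
                n_occ_stations,
            )
        )
        st_occ = u[:, :, t] == 1
        n_st = int(st_occ.sum())
        for k in range(K):
            yk = y[:, :, k, t][st_occ]
            rows.append(
                (
                    "detection_given_station",
                    t,
                    k,
                    np.nanmean(yk) if n_st and np.isfinite(yk).any() else np.nan,
                    int(np.isfinite(yk).sum()),
                )
            )
    for t in range(1, T):
        was = z[:, t - 1] == 1
        rows.append(
            ("persistence", t, None, z[was, t].mean() if was.any() else np.nan, int(was.sum()))
        )
        rows.append(
            (
                "colonization",
                t,
                None,
                z[~was, t].mean() if (~was).any() else np.nan,
                int((~was).sum()),
            )
        )
        now = z[:, t] == 1
        rows.append(
            (
                "turnover",
                t,
                None,
                (~was[now]).mean() if now.any() else np.nan,
                int(now.sum()),
            )
        )
    return pd.DataFrame(rows, columns=["quantity", "year", "interval", "value", "n"])
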