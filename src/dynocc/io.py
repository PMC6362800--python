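"""Dataset bundle format: delimited text tables plus a JSON manifest.

A bundle is a directory holding

* ``detections.csv`` — long format, one row per surveyed interval:
  unit_id, station_id, year, interval, observed (0/1; blank = not
  surveyed). Absent (unit, station, year, interval) rows are likewise
  treated as not surveyed.
* ``unit_covariates.csv`` — unit_id, year, one column per unit-year
  covariate (intercept column explicit).
* ``station_covariates.csv`` — unit_id, station_id, year, one column per
  station-year covariate.
* ``manifest.json`` — design dimensions and protocol, plus covariate
  roles: which columns enter the initial-occupancy, dynamics and
  availability design matrices.

Long format is canonical: one row per survey interval is robust to ragged
missingness and self-documenting. IDs are 1-based in the files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import _validate_removal
from .model import CovariateSet, ModelParams, Protocol, StudyDesign

__all__ = ["write_bundle", "read_bundle", "write_params", "read_params"]

log = logging.getLogger("dynocc")

_IGNORED_DETECTION_COLS = {"distance", "easting", "northing", "latitude", "longitude"}


def write_params(path, params: ModelParams) -> None:
    Path(path).write_text(
        json.dumps({k: np.asarray(v).tolist() for k, v in asdict(params).items()}, indent=1)
    )


def read_params(path) -> ModelParams:
    d = json.loads(Path(path).read_text())
    return ModelParams(**d)


def write_bundle(
    path,
    y: np.ndarray,
    covs: CovariateSet,
    design: StudyDesign,
    true_params: ModelParams | None = None,
) -> Path:
    """Write a dataset bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    N, R, K, T = design.shape_y
    if y.shape != design.shape_y:
        raise ValueError(f"y has shape {y.shape}, design expects {design.shape_y}")

    unit, station, interval, year = np.meshgrid(
        np.arange(1, N + 1), np.arange(1, R + 1), np.arange(1, K + 1), np.arange(1, T + 1),
        indexing="ij",
    )
    obs = y.ravel()
    det = pd.DataFrame(
        {
            "unit_id": unit.ravel(),
            "station_id": station.ravel(),
            "year": year.ravel(),
            "interval": interval.ravel(),
            "observed": obs,
        }
    )
    det["observed"] = det["observed"].astype("Int64")  # NaN -> <NA> (not surveyed)
    det.to_csv(path / "detections.csv", index=False)

    cols = list(dict.fromkeys(covs.init_names + covs.dyn_names))
    rows = []
    for i in range(N):
        for t in range(T):
            row = {"unit_id": i + 1, "year": t + 1}
            for c in cols:
                if t == 0 and c in covs.init_names:
                    row[c] = covs.x_init[i, covs.init_names.index(c)]
                elif t > 0 and c in covs.dyn_names:
                    row[c] = covs.x_dyn[i, t - 1, covs.dyn_names.index(c)]
                else:
                    row[c] = np.nan
            rows.append(row)
    pd.DataFrame(rows).to_csv(path / "unit_covariates.csv", index=False)

    w = covs.w_local
    ui, si, ti = np.meshgrid(
        np.arange(1, N + 1), np.arange(1, R + 1), np.arange(1, T + 1), indexing="ij"
    )
    st = pd.DataFrame({"unit_id": ui.ravel(), "station_id": si.ravel(), "year": ti.ravel()})
    for c_idx, c in enumerate(covs.local_names):
        st[c] = w[..., c_idx].ravel()
    st.to_csv(path / "station_covariates.csv", index=False)

    manifest = {
        "design": {
            "n_units": N,
            "n_stations": R,
            "n_intervals": K,
            "n_years": T,
            "protocol": design.protocol.value,
        },
        "covariate_roles": {
            "psi_columns": covs.init_names,
            "dyn_columns": covs.dyn_names,
            "theta_columns": covs.local_names,
        },
        "quadratic_pairs": [list(p) for p in covs.quadratic_pairs],
        "format_version": 1,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if true_params is not None:
        write_params(path / "true_params.json", true_params)
    return path


class BundleError(ValueError):
    """Raised when a dataset bundle fails validation on load."""


def read_bundle(path) -> tuple[np.ndarray, CovariateSet, StudyDesign, dict]:
    """Load and validate a bundle.

    Returns (y, covariates, design, load_report). The report carries
    covariate missingness percentages and survey coverage. Any structural
    problem — duplicate keys, removal-order violations, unknown covariate
    roles, missing manifest — fails the load with a row-level message.
    """
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise BundleError(f"bundle {path} has no manifest.json; refusing partial load")
    manifest = json.loads(mpath.read_text())
    d = manifest["design"]
    design = StudyDesign(
        d["n_units"], d["n_stations"], d["n_intervals"], d["n_years"], Protocol(d["protocol"])
    )
    N, R, K, T = design.shape_y

    det = pd.read_csv(path / "detections.csv", float_precision="round_trip")
    ignored = [c for c in det.columns if c.lower() in _IGNORED_DETECTION_COLS]
    if ignored:
        log.info("ignoring detection columns %s (distance-sampling fields)", ignored)
    keys = det[["unit_id", "station_id", "year", "interval"]]
    dup = keys.duplicated()
    if dup.any():
        first = det[dup].iloc[0]
        raise BundleError(
            f"duplicate detection key (unit {first.unit_id}, station "
            f"{first.station_id}, year {first.year}, interval {first.interval})"
        )
    for col, upper in (("unit_id", N), ("station_id", R), ("year", T), ("interval", K)):
        v = det[col]
        if ((v < 1) | (v > upper)).any():
            bad = det[(v < 1) | (v > upper)].iloc[0]
            raise BundleError(f"{col} out of range 1..{upper} at row {bad.to_dict()}")

    y = np.full(design.shape_y, np.nan)
    obs = det["observed"]
    surveyed = obs.notna()
    vals = obs[surveyed].astype(float)
    if (~vals.isin([0.0, 1.0])).any():
        raise BundleError("observed must be 0, 1 or blank")
    idx = det[surveyed]
    y[idx.unit_id - 1, idx.station_id - 1, idx.interval - 1, idx.year - 1] = vals
    if design.protocol is Protocol.removal:
        try:
            _validate_removal(y)
        except ValueError as e:
            raise BundleError(str(e)) from e

    roles = manifest["covariate_roles"]
    unit_tab = pd.read_csv(path / "unit_covariates.csv", float_precision="round_trip")
    st_tab = pd.read_csv(path / "station_covariates.csv", float_precision="round_trip")
    for role, table, tname in (
        ("psi_columns", unit_tab, "unit_covariates"),
        ("dyn_columns", unit_tab, "unit_covariates"),
        ("theta_columns", st_tab, "station_covariates"),
    ):
        missing_cols = [c for c in roles[role] if c not in table.columns]
        if missing_cols:
            raise BundleError(f"{role} name columns {missing_cols} absent from {tname}.csv")

    unit_tab = unit_tab.set_index(["unit_id", "year"]).sort_index()
    x_init = np.full((N, len(roles["psi_columns"])), np.nan)
    x_dyn = np.full((N, max(T - 1, 0), len(roles["dyn_columns"])), np.nan)
    for (uid, yr), row in unit_tab.iterrows():
        if yr == 1:
            x_init[uid - 1] = row[roles["psi_columns"]].to_numpy(dtype=float)
        if yr > 1:
            x_dyn[uid - 1, yr - 2] = row[roles["dyn_columns"]].to_numpy(dtype=float)

    st_tab = st_tab.set_index(["unit_id", "station_id", "year"]).sort_index()
    w_local = np.full((N, R, T, len(roles["theta_columns"])), np.nan)
    arr = st_tab[roles["theta_columns"]].to_numpy(dtype=float)
    uids = st_tab.index.get_level_values(0).to_numpy()
    sids = st_tab.index.get_level_values(1).to_numpy()
    yrs = st_tab.index.get_level_values(2).to_numpy()
    w_local[uids - 1, sids - 1, yrs - 1] = arr

    covs = CovariateSet(
        x_init=x_init,
        x_dyn=x_dyn,
        w_local=w_local,
        init_names=list(roles["psi_columns"]),
        dyn_names=list(roles["dyn_columns"]),
        local_names=list(roles["theta_columns"]),
        quadratic_pairs=[tuple(p) for p in manifest.get("quadratic_pairs", [])],
    )
    n_cells = covs.x_init.size + covs.x_dyn.size + covs.w_local.size
    report = {
        "n_surveyed_intervals": int(surveyed.sum()),
        "survey_coverage": float(surveyed.sum() / (N * R * K * T)),
        "covariate_missing_fraction": covs.n_missing / n_cells if n_cells else 0.0,
        "ignored_columns": ignored,
    }
    log.info(
        "loaded bundle %s: %.1f%% of intervals surveyed, %.2f%% covariates missing",
        path,
        100 * report["survey_coverage"],
        100 * report["covariate_missing_fraction"],
    )
    return y, covs, design, report
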