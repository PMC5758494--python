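"""Bridging layer: fit a co-kriging model from a covariate table.

A ``KrigingSpec`` names the primary indicator (a species' invasion status)
and two secondary covariates, plus the variogram/neighborhood parameters.
``fit_model`` estimates all direct and cross semivariograms at the waterbody
locations and fits the linear model of coregionalization; ``build_data`` /
``score_waterbodies`` drive prediction.

The ``zeros`` policy controls how waterbodies without an infestation report
enter the primary variable: ``include`` (default) uses them all as indicator
0 data; ``exclude-subsample`` keeps every infested location but only a
seeded subsample of the zeros (an alternative reading of "sampled locations
= confirmed infested" under heavy under-reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import stream
from .cokriging import CoKrigingModel, CoKrigingPredictor, fit_lmc, indicator
from .errors import InsufficientDataError
from .variogram import empirical_cross_semivariogram, empirical_semivariogram

__all__ = ["KrigingSpec", "auto_lag_size", "fit_model", "build_data", "score_waterbodies"]


def auto_lag_size(xy: np.ndarray, n_bins: int = 25) -> float:
    """Default lag: the larger extent dimension split into ``n_bins``."""
    xy = np.asarray(xy, dtype=float)
    span = float(max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1])))
    return span / n_bins if span > 0 else 0.04


@dataclass(frozen=True)
class KrigingSpec:
    """Everything needed to fit and apply one co-kriging model."""

    primary: str  # "v1_zm" or "v2_ewm"
    secondaries: tuple[str, str]
    lag_size: float | None = None  # None -> auto from the data extent
    n_lags: int = 12
    family: str = "spherical"
    anis_factor: float = 1.0
    anis_angle: float = 0.0
    max_points: int = 32
    search_radius_lags: float = 12.0  # search radius in units of lag_size
    zeros: str = "include"  # or "exclude-subsample"
    zeros_ratio: float = 3.0  # zeros kept per positive under subsampling
    zeros_seed: int = 0

    def with_secondaries(self, secondaries) -> "KrigingSpec":
        return replace(self, secondaries=tuple(secondaries))


def _resolved_lag(spec: KrigingSpec, xy: np.ndarray) -> float:
    return spec.lag_size if spec.lag_size is not None else auto_lag_size(xy)


def build_data(
    table: pd.DataFrame, spec: KrigingSpec
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-variable (locations, values) arrays for the prediction engine."""
    xy = table[["x", "y"]].to_numpy(float)
    prim = indicator(table[spec.primary].to_numpy())
    if spec.zeros == "include":
        keep = np.ones(len(table), dtype=bool)
    elif spec.zeros == "exclude-subsample":
        rng = stream(spec.zeros_seed, "zeros_subsample")
        pos = prim > 0
        n_keep = min(int(round(spec.zeros_ratio * pos.sum())), int((~pos).sum()))
        keep = pos.copy()
        zeros_idx = np.flatnonzero(~pos)
        if n_keep:
            keep[rng.choice(zeros_idx, size=n_keep, replace=False)] = True
    else:
        raise ValueError("zeros policy must be 'include' or 'exclude-subsample'")
    data = {spec.primary: (xy[keep], prim[keep])}
    for sec in spec.secondaries:
        data[sec] = (xy, table[sec].to_numpy(float))
    return data


def fit_model(table: pd.DataFrame, spec: KrigingSpec) -> CoKrigingModel:
    """Estimate direct + cross variograms and fit the LMC."""
    data = build_data(table, spec)
    lag = _resolved_lag(spec, table[["x", "y"]].to_numpy(float))
    kw = dict(
        lag_size=lag,
        n_lags=spec.n_lags,
        anis_factor=spec.anis_factor,
        anis_angle=spec.anis_angle,
    )
    directs = {
        v: empirical_semivariogram(xy, vals, name=v, **kw)
        for v, (xy, vals) in data.items()
    }
    variables = list(data)
    crosses = {}
    # cross variograms need co-located observations: use the locations common
    # to both variables (under zero subsampling the primary is the subset)
    for i, va in enumerate(variables):
        for vb in variables[i + 1 :]:
            xa, vala = data[va]
            xb, valb = data[vb]
            if len(xa) <= len(xb):
                common_xy, a_vals = xa, vala
                idx = _match_locations(xa, xb)
                b_vals = valb[idx]
            else:
                common_xy, b_vals = xb, valb
                idx = _match_locations(xb, xa)
                a_vals = vala[idx]
            crosses[(va, vb)] = empirical_cross_semivariogram(
                common_xy, a_vals, b_vals, name_a=va, name_b=vb, **kw
            )
    return fit_lmc(
        directs,
        crosses,
        family=spec.family,
        primary=spec.primary,
        max_points=spec.max_points,
        search_radius=spec.search_radius_lags * lag,
    )


def _match_locations(sub: np.ndarray, full: np.ndarray) -> np.ndarray:
    """Indices in ``full`` of each row of ``sub`` (exact coordinate match)."""
    from scipy.spatial import cKDTree

    d, idx = cKDTree(full).query(sub, k=1)
    if np.any(d > 1e-9):
        raise InsufficientDataError("no co-located observations for cross variogram")
    return idx


def score_waterbodies(
    table: pd.DataFrame,
    model: CoKrigingModel,
    spec: KrigingSpec,
    target_ids=None,
    exclude_colocated_primary: bool = True,
    data: dict | None = None,
) -> pd.Series:
    """Predict introduction probability at waterbody locations.

    By default each target's own primary indicator datum is left out
    (leave-one-out), so a waterbody's score reflects its neighbors and its
    secondary covariates rather than its own absence-of-report; co-located
    secondary data are retained (collocated co-kriging).  Scores are clamped
    to [0, 1].
    """
    if data is None:
        data = build_data(table, spec)
    predictor = CoKrigingPredictor(model, data)
    sub = table if target_ids is None else table[table["id"].isin(set(target_ids))]
    xy = sub[["x", "y"]].to_numpy(float)
    preds, _ = predictor.predict(xy, exclude_colocated_primary=exclude_colocated_primary)
    return pd.Series(np.clip(preds, 0.0, 1.0), index=sub["id"].to_numpy(object))
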