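"""Empirical (cross-)semivariograms and variogram-model fitting.

The semivariogram γ(h) is half the mean squared difference of a variable at
two locations lag h apart; the cross-semivariogram is the analogous product
moment between two variables.  Estimates use the classical Matheron
estimator over distance bins of width ``lag_size``.  Anisotropy is handled
by an elliptical transform of the separation vectors (factor >= 1 stretches
the range along the ``angle`` direction) applied before binning and inside
the fitted model.

Model families use the *practical range* convention: the exponential and
Gaussian structures reach 95 % of their sill at h = range, matching the
spherical structure which reaches its sill exactly there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError

__all__ = [
    "FAMILIES",
    "EmpiricalVariogram",
    "VariogramModel",
    "structure_correlogram",
    "anisotropic_distance",
    "empirical_semivariogram",
    "empirical_cross_semivariogram",
    "fit_variogram_model",
]

FAMILIES = ("spherical", "exponential", "gaussian")


def _structure_gamma(family: str, h: np.ndarray, range_: float) -> np.ndarray:
    """Unit-sill structural semivariogram g(h) in [0, 1]."""
    h = np.asarray(h, dtype=float)
    u = h / range_
    if family == "spherical":
        g = np.where(u < 1.0, 1.5 * u - 0.5 * u**3, 1.0)
    elif family == "exponential":
        g = 1.0 - np.exp(-3.0 * u)
    elif family == "gaussian":
        g = 1.0 - np.exp(-3.0 * u**2)
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    return np.where(h <= 0, 0.0, g)


def structure_correlogram(family: str, h: np.ndarray, range_: float) -> np.ndarray:
    """Unit-sill structural covariance 1 - g(h); 1 at h = 0."""
    return 1.0 - _structure_gamma(family, h, range_)


def anisotropic_distance(
    dxy: np.ndarray, factor: float = 1.0, angle_deg: float = 0.0
) -> np.ndarray:
    """Effective isotropic separation under an elliptical anisotropy.

    ``angle_deg`` is the azimuth (degrees counter-clockwise from +x) of the
    major (longest-range) axis; separations along the minor axis are
    inflated by ``factor`` so a single isotropic range applies afterwards.
    """
    dxy = np.asarray(dxy, dtype=float)
    if factor == 1.0:
        return np.hypot(dxy[..., 0], dxy[..., 1])
    th = np.deg2rad(angle_deg)
    major = dxy[..., 0] * np.cos(th) + dxy[..., 1] * np.sin(th)
    minor = -dxy[..., 0] * np.sin(th) + dxy[..., 1] * np.cos(th)
    return np.hypot(major, factor * minor)


@dataclass(frozen=True)
class VariogramModel:
    """A fitted single-structure variogram: nugget + partial sill * g(h)."""

    family: str
    nugget: float
    psill: float
    range_: float
    anis_factor: float = 1.0
    anis_angle: float = 0.0

    def __post_init__(self):
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("nugget/psill must be >= 0 and range > 0")
        if self.anis_factor < 1.0:
            raise ValueError("anisotropy factor must be >= 1")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h) -> np.ndarray:
        """Semivariogram value at (effective) scalar distance h."""
        h = np.asarray(h, dtype=float)
        g = _structure_gamma(self.family, h, self.range_)
        return np.where(h <= 0, 0.0, self.nugget + self.psill * g)

    def covariance(self, h) -> np.ndarray:
        """Sill - gamma(h); includes the nugget only at h = 0."""
        return self.sill - self(h)


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned Matheron estimates of a direct or cross semivariogram."""

    lag_size: float
    n_lags: int
    lag_mean: np.ndarray  # mean separation of pairs in each bin (NaN if empty)
    gamma: np.ndarray  # estimate per bin (NaN if empty)
    counts: np.ndarray  # pair count per bin
    kind: str  # "direct:<var>" or "cross:<a>:<b>"
    anis_factor: float = 1.0
    anis_angle: float = 0.0

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def _pair_bins(
    xy: np.ndarray, lag_size: float, n_lags: int, anis_factor: float, anis_angle: float
):
    n = len(xy)
    i, j = np.triu_indices(n, k=1)
    h = anisotropic_distance(xy[i] - xy[j], anis_factor, anis_angle)
    keep = h < lag_size * n_lags
    i, j, h = i[keep], j[keep], h[keep]
    bins = np.floor(h / lag_size).astype(int)
    return i, j, h, bins


def _binned(kind, h, bins, halfsq, lag_size, n_lags, anis_factor, anis_angle):
    counts = np.bincount(bins, minlength=n_lags)[:n_lags]
    ssum = np.bincount(bins, weights=halfsq, minlength=n_lags)[:n_lags]
    hsum = np.bincount(bins, weights=h, minlength=n_lags)[:n_lags]
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, ssum / counts, np.nan)
        lag_mean = np.where(counts > 0, hsum / counts, np.nan)
    return EmpiricalVariogram(
        lag_size=lag_size,
        n_lags=n_lags,
        lag_mean=lag_mean,
        gamma=gamma,
        counts=counts,
        kind=kind,
        anis_factor=anis_factor,
        anis_angle=anis_angle,
    )


def empirical_semivariogram(
    xy: np.ndarray,
    values: np.ndarray,
    lag_size: float = 0.04,
    n_lags: int = 12,
    anis_factor: float = 1.0,
    anis_angle: float = 0.0,
    name: str = "z",
) -> EmpiricalVariogram:
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 N(h)) per lag bin.

    Bins are [k * lag_size, (k+1) * lag_size) on the (possibly anisotropic)
    effective separation.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(xy) < 2:
        raise InsufficientDataError("need at least 2 points for a semivariogram")
    if lag_size <= 0:
        raise ValueError("lag_size must be positive")
    i, j, h, bins = _pair_bins(xy, lag_size, n_lags, anis_factor, anis_angle)
    halfsq = 0.5 * (values[i] - values[j]) ** 2
    return _binned(
        f"direct:{name}", h, bins, halfsq, lag_size, n_lags, anis_factor, anis_angle
    )


def empirical_cross_semivariogram(
    xy: np.ndarray,
    values_a: np.ndarray,
    values_b: np.ndarray,
    lag_size: float = 0.04,
    n_lags: int = 12,
    anis_factor: float = 1.0,
    anis_angle: float = 0.0,
    name_a: str = "a",
    name_b: str = "b",
) -> EmpiricalVariogram:
    """Cross estimator gamma_ab(h) = sum (a_i - a_j)(b_i - b_j) / (2 N(h)).

    Requires both variables observed at the same (co-located) points.
    """
    xy = np.asarray(xy, dtype=float)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(xy) < 2:
        raise InsufficientDataError("need at least 2 co-located points")
    i, j, h, bins = _pair_bins(xy, lag_size, n_lags, anis_factor, anis_angle)
    halfsq = 0.5 * (a[i] - a[j]) * (b[i] - b[j])
    return _binned(
        f"cross:{name_a}:{name_b}",
        h,
        bins,
        halfsq,
        lag_size,
        n_lags,
        anis_factor,
        anis_angle,
    )


def fit_variogram_model(
    empirical: EmpiricalVariogram,
    family: str = "spherical",
    n_weight_iterations: int = 4,
) -> VariogramModel:
    """Fit (nugget, partial sill, range) by iterated weighted least squares.

    Weights are Cressie's N(h) / gamma_model(h)^2, re-evaluated at the
    current fit for a few iterations.  The range is bounded to
    [lag_size, 4 * max lag]; nugget and partial sill are non-negative.
    """
    occ = empirical.occupied
    if occ.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 occupied lags to fit, got {int(occ.sum())}"
        )
    h = empirical.lag_mean[occ]
    g = empirical.gamma[occ]
    n = empirical.counts[occ].astype(float)

    if np.allclose(g, 0.0):
        return VariogramModel(
            family=family,
            nugget=0.0,
            psill=0.0,
            range_=empirical.lag_size,
            anis_factor=empirical.anis_factor,
            anis_angle=empirical.anis_angle,
        )

    hi_range = 4.0 * empirical.lag_size * empirical.n_lags
    lo_range = empirical.lag_size
    sill0 = max(float(np.mean(g[-max(1, len(g) // 3):])), 1e-12)
    nug0 = float(np.clip(g[0], 0.0, sill0))
    rng0 = float(np.clip(np.median(h), lo_range, hi_range))
    x0 = np.array([nug0, max(sill0 - nug0, 1e-12), rng0])

    weights = np.sqrt(n)
    model_eps = 1e-12

    def residuals(p):
        nugget, psill, a = p
        gm = nugget + psill * _structure_gamma(family, h, a)
        return weights * (gm - g)

    lb = np.array([0.0, 0.0, lo_range])
    ub = np.array([np.inf, np.inf, hi_range])
    p = x0
    for _ in range(max(1, n_weight_iterations)):
        sol = least_squares(
            residuals, np.clip(p, lb, ub), bounds=(lb, ub), xtol=1e-14, ftol=1e-14
        )
        p = sol.x
        gm = p[0] + p[1] * _structure_gamma(family, h, p[2])
        weights = np.sqrt(n) / np.maximum(np.abs(gm), model_eps)
    nugget, psill, a = p
    return VariogramModel(
        family=family,
        nugget=float(nugget),
        psill=float(psill),
        range_=float(a),
        anis_factor=empirical.anis_factor,
        anis_angle=empirical.anis_angle,
    )
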