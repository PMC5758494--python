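"""Probability (indicator) co-kriging under a linear model of coregionalization.

The invasion status of a species is a 0/1 indicator: kriging it yields the
conditional probability of presence.  Ordinary co-kriging augments the
indicator with correlated secondary variables; weights minimize the
prediction-error variance subject to unbiasedness constraints (primary
weights sum to one, each secondary's to zero) enforced through Lagrange
multipliers.

Joint validity of all direct and cross covariances is guaranteed by a
linear model of coregionalization (LMC): every (cross-)variogram is a
combination of shared structures — a nugget and one bounded structure with
a common range — whose coefficient matrices are projected to the nearest
positive-semidefinite matrix, so every co-kriging system is solvable.

Predictions on a grid are clamped to [0, 1] and a water mask zeroes cells
containing no waterbody: invasion probability is only defined where there is
water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    EmptyInputError,
    InsufficientDataError,
    NoDataError,
    OutOfExtentError,
    SingularSystemError,
)
from .variogram import (
    EmpiricalVariogram,
    anisotropic_distance,
    fit_variogram_model,
    structure_correlogram,
    _structure_gamma,
)

__all__ = [
    "indicator",
    "LMCStructure",
    "CoKrigingModel",
    "fit_lmc",
    "CoKrigingPredictor",
    "cokrige_point",
    "GridSpec",
    "RiskSurface",
    "water_mask_from_points",
    "predict_surface",
    "extract_at_waterbodies",
]

_COLOCATED_TOL = 1e-9  # km: two points closer than this are the same place


def indicator(status) -> np.ndarray:
    """Presence indicator for the primary variable.

    Confirmed-infested waterbodies are 1; waterbodies without an infestation
    report enter as plain 0 (the surveillance system confirms reports, so
    false positives are not expected; false negatives are what co-kriging's
    secondary variables compensate for).
    """
    return (np.asarray(status, dtype=float) > 0).astype(float)


@dataclass(frozen=True)
class LMCStructure:
    """One shared structure: a family, a common range, and a PSD coefficient
    matrix ``b`` over the modelled variables (``b[i, j]`` scales the
    structure's contribution to the i-j cross covariance)."""

    family: str  # "nugget" or a variogram family
    range_: float | None
    b: np.ndarray

    def gamma(self, h: np.ndarray, i: int, j: int) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "nugget":
            return np.where(h > 0, self.b[i, j], 0.0)
        return self.b[i, j] * _structure_gamma(self.family, h, self.range_)

    def cov(self, h: np.ndarray, i: int, j: int) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "nugget":
            return np.where(h <= _COLOCATED_TOL, self.b[i, j], 0.0)
        return self.b[i, j] * structure_correlogram(self.family, h, self.range_)


@dataclass(frozen=True)
class CoKrigingModel:
    """Fitted joint spatial-dependence model for primary + secondaries."""

    variables: tuple[str, ...]  # primary first
    structures: tuple[LMCStructure, ...]
    anis_factor: float = 1.0
    anis_angle: float = 0.0
    max_points: int = 32
    search_radius: float | None = None

    @property
    def primary(self) -> str:
        return self.variables[0]

    def index(self, var: str) -> int:
        return self.variables.index(var)

    def covariance(self, h, i: int, j: int) -> np.ndarray:
        return sum(s.cov(h, i, j) for s in self.structures)

    def gamma(self, h, i: int, j: int) -> np.ndarray:
        return sum(s.gamma(h, i, j) for s in self.structures)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "anisotropy": {"factor": self.anis_factor, "angle": self.anis_angle},
            "neighborhood": {
                "max_points": self.max_points,
                "search_radius": self.search_radius,
            },
            "structures": [
                {
                    "family": s.family,
                    "range": s.range_,
                    "b": np.asarray(s.b).tolist(),
                }
                for s in self.structures
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoKrigingModel":
        return cls(
            variables=tuple(d["variables"]),
            structures=tuple(
                LMCStructure(s["family"], s["range"], np.asarray(s["b"], float))
                for s in d["structures"]
            ),
            anis_factor=d.get("anisotropy", {}).get("factor", 1.0),
            anis_angle=d.get("anisotropy", {}).get("angle", 0.0),
            max_points=d.get("neighborhood", {}).get("max_points", 32),
            search_radius=d.get("neighborhood", {}).get("search_radius"),
        )


def _nearest_psd(m: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone by eigenvalue clipping."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def fit_lmc(
    directs: dict[str, EmpiricalVariogram],
    crosses: dict[tuple[str, str], EmpiricalVariogram],
    family: str = "spherical",
    primary: str | None = None,
    max_points: int = 32,
    search_radius: float | None = None,
) -> CoKrigingModel:
    """Fit a two-structure LMC (nugget + one bounded structure, shared range).

    The shared range is taken from an independent single-variogram fit of the
    primary variable (the primary's spatial scale drives prediction); each
    direct/cross variogram then gets per-structure coefficients by weighted
    least squares (weights = pair counts), linear in the coefficients.
    Coefficient matrices are finally projected to the nearest positive
    semidefinite matrix so that every co-kriging system assembled from the
    model is valid.
    """
    if not directs:
        raise EmptyInputError("no direct variograms supplied")
    variables = list(directs)
    if primary is None:
        primary = variables[0]
    elif primary not in variables:
        raise EmptyInputError(f"primary {primary!r} has no direct variogram")
    variables = [primary] + [v for v in variables if v != primary]
    p = len(variables)

    ref = fit_variogram_model(directs[primary], family=family)
    a = ref.range_
    anis_factor = directs[primary].anis_factor
    anis_angle = directs[primary].anis_angle

    def coeffs(emp: EmpiricalVariogram, nonneg: bool) -> tuple[float, float]:
        occ = emp.occupied
        if occ.sum() < 2:
            raise InsufficientDataError(f"too few occupied lags for {emp.kind}")
        h = emp.lag_mean[occ]
        g = emp.gamma[occ]
        w = np.sqrt(emp.counts[occ].astype(float))
        design = np.column_stack([np.ones_like(h), _structure_gamma(family, h, a)])
        if nonneg:
            from scipy.optimize import nnls

            sol, _ = nnls(design * w[:, None], g * w)
        else:
            sol, *_ = np.linalg.lstsq(design * w[:, None], g * w, rcond=None)
        return float(sol[0]), float(sol[1])

    b0 = np.zeros((p, p))
    b1 = np.zeros((p, p))
    for i, v in enumerate(variables):
        b0[i, i], b1[i, i] = coeffs(directs[v], nonneg=True)
    for (va, vb), emp in crosses.items():
        if va not in variables or vb not in variables:
            continue
        i, j = variables.index(va), variables.index(vb)
        c0, c1 = coeffs(emp, nonneg=False)
        b0[i, j] = b0[j, i] = c0
        b1[i, j] = b1[j, i] = c1

    b0 = _nearest_psd(b0)
    b1 = _nearest_psd(b1)
    return CoKrigingModel(
        variables=tuple(variables),
        structures=(
            LMCStructure("nugget", None, b0),
            LMCStructure(family, a, b1),
        ),
        anis_factor=anis_factor,
        anis_angle=anis_angle,
        max_points=max_points,
        search_radius=search_radius,
    )


class CoKrigingPredictor:
    """Ordinary co-kriging prediction engine over a fixed data set.

    ``data`` maps variable name -> (xy array (n, 2), values array (n,)).
    The primary variable must be present.  Neighborhoods are the nearest
    ``max_points`` data of each variable within ``search_radius`` (None =
    unbounded, i.e. global kriging when max_points >= n).
    """

    def __init__(
        self,
        model: CoKrigingModel,
        data: dict[str, tuple[np.ndarray, np.ndarray]],
        max_points: int | None = None,
        search_radius: float | None = ...,
    ):
        if model.primary not in data:
            raise NoDataError(f"no data for primary variable {model.primary!r}")
        self.model = model
        self.max_points = model.max_points if max_points is None else max_points
        self.search_radius = (
            model.search_radius if search_radius is ... else search_radius
        )
        self._vars = [v for v in model.variables if v in data]
        self._xy = {}
        self._vals = {}
        self._trees = {}
        for v in self._vars:
            xy, vals = data[v]
            xy = np.asarray(xy, dtype=float)
            vals = np.asarray(vals, dtype=float)
            if len(xy) != len(vals):
                raise InsufficientDataError(f"misaligned data for {v!r}")
            self._xy[v] = xy
            self._vals[v] = vals
            self._trees[v] = cKDTree(xy)

    def _h(self, dxy: np.ndarray) -> np.ndarray:
        return anisotropic_distance(dxy, self.model.anis_factor, self.model.anis_angle)

    def _neighborhood(self, target: np.ndarray, exclude_colocated_primary: bool):
        sel: list[tuple[int, np.ndarray, np.ndarray]] = []
        for v in self._vars:
            tree = self._trees[v]
            k = min(self.max_points, len(self._vals[v]))
            d, idx = tree.query(target, k=k)
            d = np.atleast_1d(d)
            idx = np.atleast_1d(idx)
            keep = np.isfinite(d)
            if self.search_radius is not None:
                keep &= d <= self.search_radius
            if exclude_colocated_primary and v == self.model.primary:
                keep &= d > _COLOCATED_TOL
            idx = idx[keep]
            if len(idx) == 0:
                continue
            vi = self.model.index(v)
            sel.append((vi, self._xy[v][idx], self._vals[v][idx]))
        return sel

    def predict_one(
        self, target, exclude_colocated_primary: bool = False, full_output: bool = False
    ):
        """Co-kriging prediction and kriging variance at one location.

        With ``full_output`` also returns a dict holding the solved weights,
        each datum's variable index, the data values, and the per-variable
        weight sums (primary must be 1, secondaries 0).
        """
        target = np.asarray(target, dtype=float)
        sel = self._neighborhood(target, exclude_colocated_primary)
        prim_idx = self.model.index(self.model.primary)
        var_ids = [vi for vi, _, _ in sel]
        if prim_idx not in var_ids:
            raise NoDataError("no primary data in the search neighborhood")

        pts = np.vstack([xy for _, xy, _ in sel])
        vals = np.concatenate([vv for _, _, vv in sel])
        owner = np.concatenate(
            [np.full(len(vv), vi) for vi, _, vv in sel]
        )
        m = len(vals)
        # one unbiasedness constraint per variable present in the neighborhood
        cons_vars = sorted(set(var_ids))
        k = len(cons_vars)

        h = self._h(pts[:, None, :] - pts[None, :, :])
        cmat = np.zeros((m, m))
        for vi in cons_vars:
            for vj in cons_vars:
                mask = (owner[:, None] == vi) & (owner[None, :] == vj)
                if mask.any():
                    cmat[mask] = self.model.covariance(h[mask], vi, vj)

        h0 = self._h(pts - target[None, :])
        rhs_c = np.empty(m)
        for vi in cons_vars:
            msk = owner == vi
            rhs_c[msk] = self.model.covariance(h0[msk], vi, prim_idx)

        a = np.zeros((m + k, m + k))
        a[:m, :m] = cmat
        for ci, vi in enumerate(cons_vars):
            a[:m, m + ci] = (owner == vi).astype(float)
            a[m + ci, :m] = (owner == vi).astype(float)
        b = np.zeros(m + k)
        b[:m] = rhs_c
        b[m + cons_vars.index(prim_idx)] = 1.0

        try:
            sol = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            a2 = a.copy()
            di = np.arange(m)
            a2[di, di] += 1e-10
            try:
                sol = np.linalg.solve(a2, b)
            except np.linalg.LinAlgError as exc:
                raise SingularSystemError("co-kriging system is singular") from exc

        lam = sol[:m]
        pred = float(lam @ vals)
        c00 = float(self.model.covariance(np.array(0.0), prim_idx, prim_idx))
        variance = float(c00 - sol @ b)
        if full_output:
            sums = {
                self.model.variables[vi]: float(lam[owner == vi].sum())
                for vi in cons_vars
            }
            return pred, max(variance, 0.0), {
                "weights": lam,
                "owner": owner,
                "values": vals,
                "points": pts,
                "weight_sums": sums,
                "system": (a, b),
            }
        return pred, max(variance, 0.0)

    def predict(
        self, targets: np.ndarray, exclude_colocated_primary: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        preds = np.empty(len(targets))
        varis = np.empty(len(targets))
        for i, t in enumerate(targets):
            preds[i], varis[i] = self.predict_one(t, exclude_colocated_primary)
        return preds, varis


def cokrige_point(
    model: CoKrigingModel,
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    target,
    max_points: int | None = None,
    search_radius: float | None = ...,
    exclude_colocated_primary: bool = False,
) -> tuple[float, float]:
    """One-shot co-kriging at a single target (see ``CoKrigingPredictor``)."""
    return CoKrigingPredictor(
        model, data, max_points=max_points, search_radius=search_radius
    ).predict_one(target, exclude_colocated_primary)


@dataclass(frozen=True)
class GridSpec:
    """A regular prediction grid: lower-left origin, square cells (km)."""

    origin: tuple[float, float]
    cell: float
    nx: int
    ny: int

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.arange(self.nx) + 0.5) * self.cell
        y = self.origin[1] + (np.arange(self.ny) + 0.5) * self.cell
        return x, y

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        eps = 1e-9
        ix = int(np.floor((x - self.origin[0]) / self.cell))
        iy = int(np.floor((y - self.origin[1]) / self.cell))
        # points sitting exactly on the upper/right edge belong to the last cell
        if ix == self.nx and x <= self.origin[0] + self.nx * self.cell + eps:
            ix -= 1
        if iy == self.ny and y <= self.origin[1] + self.ny * self.cell + eps:
            iy -= 1
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise OutOfExtentError(f"point ({x}, {y}) falls outside the grid")
        return ix, iy

    @classmethod
    def covering(cls, xy: np.ndarray, cell: float, pad: float = 0.0) -> "GridSpec":
        xy = np.asarray(xy, dtype=float)
        x0, y0 = xy.min(axis=0) - pad
        x1, y1 = xy.max(axis=0) + pad
        nx = max(1, int(np.ceil((x1 - x0) / cell)))
        ny = max(1, int(np.ceil((y1 - y0) / cell)))
        return cls(origin=(float(x0), float(y0)), cell=float(cell), nx=nx, ny=ny)


@dataclass
class RiskSurface:
    """Gridded introduction probability with a water mask.

    ``values[iy, ix]`` is the probability for the cell; cells whose mask is
    False contain no waterbody and are exactly 0.
    """

    grid: GridSpec
    values: np.ndarray  # (ny, nx) in [0, 1]
    mask: np.ndarray  # (ny, nx) bool, True = water present


def water_mask_from_points(grid: GridSpec, xy: np.ndarray) -> np.ndarray:
    """True for cells containing at least one waterbody point."""
    mask = np.zeros((grid.ny, grid.nx), dtype=bool)
    for x, y in np.asarray(xy, dtype=float):
        try:
            ix, iy = grid.cell_index(x, y)
        except OutOfExtentError:
            continue
        mask[iy, ix] = True
    return mask


def predict_surface(
    predictor: CoKrigingPredictor, grid: GridSpec, mask: np.ndarray
) -> RiskSurface:
    """Co-krige every water cell's center; clamp to [0, 1]; dry cells are 0."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.ny, grid.nx):
        raise OutOfExtentError("mask shape does not match the grid")
    values = np.zeros((grid.ny, grid.nx))
    xs, ys = grid.centers()
    for iy, ix in zip(*np.nonzero(mask)):
        pred, _ = predictor.predict_one((xs[ix], ys[iy]))
        values[iy, ix] = float(np.clip(pred, 0.0, 1.0))
    return RiskSurface(grid=grid, values=values, mask=mask)


def extract_at_waterbodies(surface: RiskSurface, waterbodies) -> np.ndarray:
    """Probability of the grid cell containing each waterbody point."""
    out = np.empty(len(waterbodies))
    for i, row in enumerate(waterbodies.itertuples(index=False)):
        ix, iy = surface.grid.cell_index(row.x, row.y)
        out[i] = surface.values[iy, ix]
    return out
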