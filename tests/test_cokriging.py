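"""Co-kriging solver against dense hand-assembled oracles; LMC fitting;
surface prediction and extraction."""

import numpy as np
import pytest

from aisrisk.cokriging import (
    CoKrigingModel,
    CoKrigingPredictor,
    GridSpec,
    LMCStructure,
    extract_at_waterbodies,
    fit_lmc,
    indicator,
    predict_surface,
    water_mask_from_points,
)
from aisrisk.errors import NoDataError, OutOfExtentError
from aisrisk.variogram import (
    VariogramModel,
    empirical_cross_semivariogram,
    empirical_semivariogram,
    structure_correlogram,
)
from conftest import random_points


def make_model(b0, b1, variables, range_=1.0, family="spherical", **kw):
    return CoKrigingModel(
        variables=tuple(variables),
        structures=(
            LMCStructure("nugget", None, np.atleast_2d(np.asarray(b0, float))),
            LMCStructure(family, range_, np.atleast_2d(np.asarray(b1, float))),
        ),
        **kw,
    )


class TestIndicator:
    def test_values_and_count(self):
        status = [0, 1, 1, 0, 1]
        ind = indicator(status)
        assert set(ind) == {0.0, 1.0}
        assert ind.sum() == 3


class TestSolver:
    def test_exact_interpolation_at_datum_with_zero_nugget(self):
        rng = np.random.default_rng(4)
        xy = random_points(rng, 12)
        vals = rng.random(12)
        model = make_model([[0.0]], [[1.0]], ["p"], range_=0.8)
        pred, var = CoKrigingPredictor(model, {"p": (xy, vals)}).predict_one(xy[3])
        assert pred == pytest.approx(vals[3], abs=1e-9)
        assert var == pytest.approx(0.0, abs=1e-9)

    def test_weight_constraint_sums(self):
        rng = np.random.default_rng(5)
        xy_p = random_points(rng, 15)
        xy_s = random_points(rng, 20)
        b0 = [[0.05, 0.0], [0.0, 0.05]]
        b1 = [[1.0, 0.5], [0.5, 1.0]]
        model = make_model(b0, b1, ["p", "s"], range_=0.7)
        data = {"p": (xy_p, rng.random(15)), "s": (xy_s, rng.random(20))}
        for target in random_points(rng, 5):
            _, _, info = CoKrigingPredictor(model, data).predict_one(
                target, full_output=True
            )
            assert info["weight_sums"]["p"] == pytest.approx(1.0, abs=1e-12)
            assert info["weight_sums"]["s"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_hand_assembled_solve(self):
        """4-point, 2-variable system solved independently from covariance
        first principles."""
        xy_p = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        v_p = np.array([0.2, 0.8, 0.5])
        xy_s = np.array([[0.5, 0.5]])
        v_s = np.array([1.3])
        b0 = np.array([[0.1, 0.0], [0.0, 0.1]])
        b1 = np.array([[1.0, 0.4], [0.4, 0.6]])
        range_ = 1.5
        model = make_model(b0, b1, ["p", "s"], range_=range_)
        target = np.array([0.3, 0.3])

        def cov(h, i, j):
            nug = b0[i, j] if h <= 1e-9 else 0.0
            return nug + b1[i, j] * structure_correlogram("spherical", np.array(h), range_)

        pts = np.vstack([xy_p, xy_s])
        owner = np.array([0, 0, 0, 1])
        m = 4
        A = np.zeros((m + 2, m + 2))
        for i in range(m):
            for j in range(m):
                A[i, j] = cov(np.hypot(*(pts[i] - pts[j])), owner[i], owner[j])
        A[:m, m] = (owner == 0).astype(float)
        A[:m, m + 1] = (owner == 1).astype(float)
        A[m, :m] = A[:m, m]
        A[m + 1, :m] = A[:m, m + 1]
        rhs = np.zeros(m + 2)
        for i in range(m):
            rhs[i] = cov(np.hypot(*(pts[i] - target)), owner[i], 0)
        rhs[m] = 1.0
        sol = np.linalg.solve(A, rhs)
        oracle_pred = sol[:m] @ np.concatenate([v_p, v_s])

        pred, _, info = CoKrigingPredictor(
            model, {"p": (xy_p, v_p), "s": (xy_s, v_s)}
        ).predict_one(target, full_output=True)
        # weight comparison requires matching data order: primary then secondary
        got = np.empty(m)
        got[info["owner"] == 0] = info["weights"][info["owner"] == 0]
        np.testing.assert_allclose(np.sort(info["weights"]), np.sort(sol[:m]), atol=1e-10)
        assert pred == pytest.approx(oracle_pred, abs=1e-10)

    def test_zero_cross_structure_reduces_to_ordinary_kriging(self):
        rng = np.random.default_rng(6)
        xy = random_points(rng, 10)
        v_p = rng.random(10)
        v_s = rng.random(10)
        b0 = np.diag([0.1, 0.2])
        b1 = np.diag([1.0, 0.5])
        model = make_model(b0, b1, ["p", "s"], range_=0.9)
        target = np.array([0.4, 0.6])
        pred_ck, _ = CoKrigingPredictor(
            model, {"p": (xy, v_p), "s": (xy, v_s)}
        ).predict_one(target)

        # independent single-variable ordinary-kriging solve
        vm = VariogramModel("spherical", nugget=0.1, psill=1.0, range_=0.9)
        h = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        C = vm.covariance(h)
        np.fill_diagonal(C, vm.sill)
        A = np.zeros((11, 11))
        A[:10, :10] = C
        A[10, :10] = A[:10, 10] = 1.0
        rhs = np.append(vm.covariance(np.hypot(*(xy - target).T)), 1.0)
        lam = np.linalg.solve(A, rhs)[:10]
        assert pred_ck == pytest.approx(float(lam @ v_p), abs=1e-9)

    def test_single_datum_returns_it(self):
        model = make_model([[0.0]], [[1.0]], ["p"])
        pred, _ = CoKrigingPredictor(
            model, {"p": (np.array([[0.0, 0.0]]), np.array([0.7]))}
        ).predict_one((0.2, 0.1))
        assert pred == pytest.approx(0.7)

    def test_empty_neighborhood_rejected(self):
        model = make_model([[0.0]], [[1.0]], ["p"], search_radius=0.1)
        with pytest.raises(NoDataError):
            CoKrigingPredictor(
                model, {"p": (np.array([[0.0, 0.0]]), np.array([1.0]))}
            ).predict_one((5.0, 5.0))

    def test_prediction_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        xy = random_points(rng, 15)
        v = rng.random(15)
        model = make_model([[0.05]], [[1.0]], ["p"], range_=0.6)
        target = np.array([0.5, 0.5])
        p0, _ = CoKrigingPredictor(model, {"p": (xy, v)}).predict_one(target)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([3.0, -2.0])
        p1, _ = CoKrigingPredictor(model, {"p": (xy @ R.T + shift, v)}).predict_one(
            R @ target + shift
        )
        assert p1 == pytest.approx(p0, abs=1e-9)


class TestFitLMC:
    def _variograms(self, xy, fields, lag_size=0.08, n_lags=12):
        names = sorted(fields)
        directs = {
            v: empirical_semivariogram(xy, fields[v], lag_size, n_lags, name=v)
            for v in names
        }
        crosses = {
            (a, b): empirical_cross_semivariogram(
                xy, fields[a], fields[b], lag_size, n_lags, name_a=a, name_b=b
            )
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        }
        return directs, crosses

    def test_zero_cross_gives_zero_off_diagonal(self):
        rng = np.random.default_rng(8)
        xy = random_points(rng, 60)
        a = rng.normal(size=60)
        directs, _ = self._variograms(xy, {"p": a, "s": rng.normal(size=60)})
        crosses = {
            ("p", "s"): empirical_semivariogram(xy, a, 0.08, 12, name="x")
        }
        # force a strictly zero cross estimate
        zero = crosses[("p", "s")]
        object.__setattr__(zero, "gamma", np.zeros_like(zero.gamma))
        model = fit_lmc(directs, crosses, primary="p")
        for s in model.structures:
            assert s.b[0, 1] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_coefficient_matrices_psd(self, seed):
        rng = np.random.default_rng(seed)
        xy = random_points(rng, 50)
        fields = {v: rng.normal(size=50) for v in ("p", "s1", "s2")}
        directs, crosses = self._variograms(xy, fields)
        model = fit_lmc(directs, crosses, primary="p")
        for s in model.structures:
            w = np.linalg.eigvalsh(s.b)
            assert w.min() >= -1e-10

    def test_known_lmc_recovered(self):
        """Coregionalized fields from a known coefficient matrix: fitted
        structure coefficients recovered within 15 % (n=500, 5 seeds)."""
        A = np.array([[1.0, 0.0], [0.6, 0.8]])  # B = A A^T
        B_true = A @ A.T
        range_ = 0.3
        ests = []
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            xy = random_points(rng, 500, span=1.0)
            h = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
            c = structure_correlogram("spherical", h, range_)
            L = np.linalg.cholesky(c + 1e-8 * np.eye(500))
            g = np.column_stack([L @ rng.normal(size=500), L @ rng.normal(size=500)])
            z = g @ A.T
            directs, crosses = self._variograms(
                xy, {"p": z[:, 0], "s": z[:, 1]}, lag_size=0.05, n_lags=12
            )
            model = fit_lmc(directs, crosses, primary="p")
            ests.append(model.structures[1].b)
        med = np.median(ests, axis=0)
        np.testing.assert_allclose(med, B_true, rtol=0.15)


class TestSurface:
    def test_all_ones_data_gives_unit_surface(self):
        rng = np.random.default_rng(9)
        xy = random_points(rng, 20, span=2.0)
        model = make_model([[0.0]], [[1.0]], ["p"], range_=1.0)
        predictor = CoKrigingPredictor(model, {"p": (xy, np.ones(20))})
        grid = GridSpec((0.0, 0.0), 0.5, 4, 4)
        mask = np.ones((4, 4), dtype=bool)
        surf = predict_surface(predictor, grid, mask)
        np.testing.assert_allclose(surf.values, 1.0, atol=1e-9)

    def test_dry_cells_zero_regardless_of_neighbors(self):
        rng = np.random.default_rng(10)
        xy = random_points(rng, 20, span=2.0)
        model = make_model([[0.0]], [[1.0]], ["p"])
        predictor = CoKrigingPredictor(model, {"p": (xy, np.ones(20))})
        grid = GridSpec((0.0, 0.0), 0.5, 4, 4)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        surf = predict_surface(predictor, grid, mask)
        assert surf.values[1, 1] == pytest.approx(1.0)
        assert (surf.values[~mask] == 0.0).all()

    def test_raw_predictions_clamped_to_unit_interval(self):
        class Stub(CoKrigingPredictor):
            def predict_one(self, target, **kw):
                return -0.03, 0.0

        model = make_model([[0.0]], [[1.0]], ["p"])
        stub = Stub(model, {"p": (np.zeros((1, 2)), np.ones(1))})
        grid = GridSpec((0.0, 0.0), 1.0, 2, 1)
        surf = predict_surface(stub, grid, np.ones((1, 2), dtype=bool))
        assert (surf.values == 0.0).all()

    def test_water_mask_marks_occupied_cells(self):
        grid = GridSpec((0.0, 0.0), 1.0, 3, 3)
        mask = water_mask_from_points(grid, np.array([[0.5, 0.5], [2.9, 0.1]]))
        assert mask[0, 0] and mask[0, 2]
        assert mask.sum() == 2


class TestExtraction:
    def _surface(self):
        grid = GridSpec((0.0, 0.0), 1.0, 3, 2)
        values = np.arange(6, dtype=float).reshape(2, 3) / 10
        return type("S", (), {"grid": grid, "values": values, "mask": values > -1})()

    def _wb(self, points):
        import pandas as pd

        return pd.DataFrame(
            [(f"W{i}", x, y) for i, (x, y) in enumerate(points)],
            columns=["id", "x", "y"],
        )

    def test_cell_center_value(self):
        surf = self._surface()
        out = extract_at_waterbodies(surf, self._wb([(1.5, 0.5)]))
        assert out[0] == pytest.approx(0.1)

    def test_same_cell_same_value(self):
        surf = self._surface()
        out = extract_at_waterbodies(surf, self._wb([(2.2, 1.3), (2.8, 1.9)]))
        assert out[0] == out[1] == pytest.approx(0.5)

    def test_out_of_extent_rejected(self):
        with pytest.raises(OutOfExtentError):
            extract_at_waterbodies(self._surface(), self._wb([(9.0, 9.0)]))
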