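"""Tests for the ridge-regression response model family."""

import numpy as np
import pytest

from voxencode.hrf import canonical_hrf, toeplitz_convolve
from voxencode.ridge import (
    build_design,
    default_lambda_grid,
    fit_ridge_from_dataset,
    predict_ridge,
    ridge_solve,
    select_lambda,
)

from conftest import make_dataset


class TestBuildDesign:
    def test_column_counts_per_variant(self, rng):
        blocks = [rng.standard_normal((40, 300))]
        assert build_design(blocks, "R-C").n_columns == 300
        assert build_design(blocks, "R-CTD").n_columns == 900
        blocks512 = [rng.standard_normal((40, 512))]
        assert build_design(blocks512, "R-F").n_columns == 2048

    def test_fir_rows_before_first_lag_are_zero(self, rng):
        blocks = [rng.standard_normal((10, 4))]
        design = build_design(blocks, "R-F")
        np.testing.assert_array_equal(design.matrix[:3], 0)  # lags 3..6 all precede start

    def test_fir_lag_content(self, rng):
        b = rng.standard_normal((12, 2))
        design = build_design([b], "R-F")
        np.testing.assert_array_equal(design.matrix[5, 0:2], b[2])  # lag 3
        np.testing.assert_array_equal(design.matrix[11, 6:8], b[5])  # lag 6

    def test_convolution_is_block_local(self, rng):
        b1, b2 = rng.standard_normal((25, 2)), rng.standard_normal((25, 2))
        design = build_design([b1, b2], "R-C")
        single = build_design([b2], "R-C")
        np.testing.assert_allclose(design.matrix[25:], single.matrix, atol=1e-12)

    def test_unknown_variant_rejected(self, rng):
        with pytest.raises(ValueError, match="variant"):
            build_design([rng.standard_normal((5, 2))], "R-X")


class TestRidgeSolve:
    def test_matches_normal_equation_oracle(self, rng):
        """20 random problems: solution equals a direct (X'X + lam I) solve."""
        for _ in range(20):
            X = rng.standard_normal((200, 50))
            y = rng.standard_normal((200, 3))
            lam = float(rng.uniform(0.1, 10))
            model = ridge_solve(X, y, lam)
            direct = np.linalg.solve(X.T @ X + lam * np.eye(50), X.T @ y).T
            err = np.linalg.norm(model.B - direct) / np.linalg.norm(direct)
            assert err < 1e-8

    def test_huge_lambda_shrinks_to_zero(self, rng):
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        model = ridge_solve(X, y, 1e12)
        assert np.linalg.norm(model.B) < 1e-6

    def test_zero_lambda_equals_least_squares(self, rng):
        X = rng.standard_normal((80, 6))
        y = rng.standard_normal(80)
        model = ridge_solve(X, y, 0.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(model.B[0], ols, atol=1e-8)

    def test_per_voxel_lambdas(self, rng):
        X = rng.standard_normal((100, 8))
        Y = rng.standard_normal((100, 2))
        both = ridge_solve(X, Y, np.array([0.5, 50.0]))
        one = ridge_solve(X, Y[:, :1], 0.5)
        np.testing.assert_allclose(both.B[0], one.B[0], atol=1e-10)

    def test_nan_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.full(10, np.nan)
        with pytest.raises(ValueError, match="NaN"):
            ridge_solve(X, y, 1.0)

    def test_nested_designs_reduce_training_residual(self, rng):
        """R-CTD's columns contain R-C's, so its training fit is at least as good."""
        blocks = [rng.standard_normal((120, 4))]
        Y = rng.standard_normal((120, 3))
        lam = 1.0
        for variant in ("R-C", "R-CTD"):
            design = build_design(blocks, variant)
            model = ridge_solve(design, Y, lam)
            resid = np.linalg.norm(Y - predict_ridge(model, design), axis=0)
            if variant == "R-C":
                resid_rc = resid
        assert np.all(resid <= resid_rc + 1e-8)


class TestSelectLambda:
    def _planted(self, rng, noise=0.0):
        X = rng.standard_normal((300, 6))
        B = rng.standard_normal((2, 6))
        Y = X @ B.T + noise * rng.standard_normal((300, 2))
        Xv = rng.standard_normal((100, 6))
        Yv = Xv @ B.T + noise * rng.standard_normal((100, 2))
        from voxencode.ridge import RidgeDesign

        mk = lambda M: RidgeDesign("R-C", M, tuple())
        return mk(X), Y, mk(Xv), Yv

    def test_noiseless_data_selects_small_lambda(self, rng):
        train_d, Y, val_d, Yv = self._planted(rng)
        lam = select_lambda(train_d, Y, val_d, Yv)
        grid = default_lambda_grid()
        assert np.all(lam <= grid[3])
        model = ridge_solve(train_d, Y, lam)
        pred = predict_ridge(model, val_d)
        for v in range(2):
            assert np.corrcoef(pred[:, v], Yv[:, v])[0, 1] > 0.99

    def test_selected_lambda_is_grid_optimal(self, rng):
        train_d, Y, val_d, Yv = self._planted(rng, noise=2.0)
        grid = default_lambda_grid()
        lam = select_lambda(train_d, Y, val_d, Yv, grid)
        for v in range(2):
            best = -np.inf
            for g in grid:
                model = ridge_solve(train_d, Y[:, v], g)
                r = np.corrcoef(predict_ridge(model, val_d)[:, 0], Yv[:, v])[0, 1]
                best = max(best, r)
            model = ridge_solve(train_d, Y[:, v], lam[v])
            r_sel = np.corrcoef(predict_ridge(model, val_d)[:, 0], Yv[:, v])[0, 1]
            assert r_sel >= best - 1e-12

    def test_ties_pick_larger_lambda(self, rng):
        # orthogonal single-column design: validation r is lambda-invariant
        from voxencode.ridge import RidgeDesign

        X = rng.standard_normal((50, 1))
        Y = X.copy()
        d = RidgeDesign("R-C", X, tuple())
        grid = np.array([1.0, 10.0])
        lam = select_lambda(d, Y, d, Y, grid)
        assert lam[0] == 10.0

    def test_constant_validation_response_warns(self, rng):
        from voxencode.ridge import RidgeDesign

        X = rng.standard_normal((50, 2))
        Y = rng.standard_normal((50, 1))
        d = RidgeDesign("R-C", X, tuple())
        Yv = np.ones((50, 1))
        with pytest.warns(UserWarning, match="constant"):
            lam = select_lambda(d, Y, d, Yv)
        assert lam[0] == default_lambda_grid()[-1]

    def test_empty_grid_rejected(self, rng):
        from voxencode.ridge import RidgeDesign

        X = rng.standard_normal((10, 2))
        d = RidgeDesign("R-C", X, tuple())
        with pytest.raises(ValueError, match="grid"):
            select_lambda(d, X[:, :1], d, X[:, :1], np.array([]))


class TestPredict:
    def test_zero_coefficients_predict_zero(self, rng):
        from voxencode.ridge import RidgeModel

        design = build_design([rng.standard_normal((10, 2))], "R-C")
        model = RidgeModel("R-C", np.zeros((3, 2)), np.zeros(3))
        np.testing.assert_array_equal(predict_ridge(model, design), 0)

    def test_planted_model_reconstructed_noiselessly(self, rng):
        blocks = [rng.standard_normal((150, 4))]
        design = build_design(blocks, "R-C")
        B = rng.standard_normal((2, 4))
        Y = design.matrix @ B.T
        model = ridge_solve(design, Y, 0.0)
        np.testing.assert_allclose(predict_ridge(model, design), Y, atol=1e-10)

    def test_variant_mismatch_rejected(self, rng):
        from voxencode.ridge import RidgeModel

        design = build_design([rng.standard_normal((10, 2))], "R-C")
        model = RidgeModel("R-F", np.zeros((1, 8)), np.zeros(1))
        with pytest.raises(ValueError, match="variant"):
            predict_ridge(model, design)


class TestDatasetFit:
    def test_planted_canonical_linear_data_is_recovered(self, rng):
        """R-C on data generated by the canonical-HRF linear model fits well."""
        k = canonical_hrf(1.0)
        ds = make_dataset(rng, T_train=200, T_test=80, p=3, m=2, n_train=2, n_test=1)
        # overwrite responses with noiseless canonical convolutions
        from voxencode.data import EncodingDataset, ResponseBlock

        W = np.abs(rng.standard_normal((2, 3)))
        resps = []
        for fb in ds.features:
            drive = fb.values @ W.T
            sig = np.column_stack(
                [toeplitz_convolve(k, drive[:, v]) for v in range(2)]
            )
            resps.append(ResponseBlock(sig, fb.block_id))
        ds = EncodingDataset(ds.features, resps, ds.voxel_groups)
        model, pred, obs = fit_ridge_from_dataset(ds, "R-C", tail_seconds=40)
        for v in range(2):
            assert np.corrcoef(pred[:, v], obs[:, v])[0, 1] > 0.999
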