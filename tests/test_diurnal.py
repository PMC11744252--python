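import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from emadyn import (
    HarmonicCurve,
    build_bspline_basis,
    build_difference_penalty,
    build_tensor_basis,
    compare_models,
    fit_gam,
    predict_surface,
    simulate_dataset,
)
from emadyn.diurnal import (
    NotConvergedError,
    _assemble_penalty,
    _design_for_item,
    _fit_fixed_lambda,
    difference_penalty_parts,
)

from conftest import single_item_config


@pytest.fixture(scope="module")
def small_fit_data():
    cfg = single_item_config(n_participants=40, seed=13, missing_rate=0.0)
    records, truth = simulate_dataset(cfg)
    return records, truth, cfg


class TestBSplineBasis:
    def test_partition_of_unity_before_centering(self):
        x = np.linspace(0.0, 10.0, 57)
        _, spec = build_bspline_basis(x, basis_dim=10)
        raw = spec.design(x, center=False)
        np.testing.assert_allclose(raw.sum(axis=1), 1.0, atol=1e-12)

    def test_dimensions_and_knots(self):
        x = np.linspace(0.0, 1.0, 30)
        B, spec = build_bspline_basis(x, basis_dim=10, degree=3)
        assert B.shape == (30, 10)
        interior = spec.knots[(spec.knots > 0.0) & (spec.knots < 1.0)]
        assert len(interior) == 6

    def test_columns_sum_to_zero_after_centering(self):
        x = np.sort(np.random.default_rng(0).uniform(0, 5, size=40))
        B, _ = build_bspline_basis(x, basis_dim=8)
        np.testing.assert_allclose(B.sum(axis=0), 0.0, atol=1e-10)

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_bspline_basis(np.full(10, 2.0), basis_dim=8)

    def test_basis_dim_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_bspline_basis(np.linspace(0, 1, 10), basis_dim=4, degree=3)


class TestDifferencePenalty:
    def test_linear_sequence_unpenalized(self):
        S = build_difference_penalty(8, order=2, shrink=0.0)
        beta = 0.3 + 1.7 * np.arange(8)
        assert beta @ S @ beta == pytest.approx(0.0, abs=1e-10)

    def test_shrink_makes_positive_definite(self):
        S = build_difference_penalty(8, order=2, shrink=0.5)
        assert np.linalg.eigvalsh(S).min() > 0

    def test_rank_of_second_difference_penalty(self):
        S, _ = difference_penalty_parts(5, order=2)
        assert np.linalg.matrix_rank(S) == 3

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            build_difference_penalty(3, order=3)


class TestTensorBasis:
    def _margins(self, n=300):
        # independent draws: a joint 2-D design, not co-monotone margins
        rng = np.random.default_rng(5)
        x1 = rng.uniform(0, 28, n)
        x2 = rng.uniform(8, 24, n)
        B1, _ = build_bspline_basis(x1, basis_dim=10)
        B2, _ = build_bspline_basis(x2, basis_dim=10)
        return B1, B2

    def test_kronecker_dimension(self):
        B1, B2 = self._margins()
        S = np.eye(10)
        T, (P1, P2) = build_tensor_basis(B1, B2, S, S)
        assert T.shape == (300, 100)
        assert P1.shape == P2.shape == (100, 100)

    def test_zero_margins_give_zero_block(self):
        Z = np.zeros((20, 5))
        T, _ = build_tensor_basis(Z, Z, np.eye(5), np.eye(5))
        assert not T.any()

    def test_cannot_absorb_pure_time_main_effect(self):
        B1, B2 = self._margins()
        S = np.eye(10)
        T, _ = build_tensor_basis(B1, B2, S, S)
        rng = np.random.default_rng(2)
        g = B2 @ rng.normal(size=10)  # a pure function of the second margin
        proj, *_ = np.linalg.lstsq(T, g, rcond=None)
        resid = g - T @ proj
        assert np.linalg.norm(resid) > 1e-6 * np.linalg.norm(g)

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError):
            build_tensor_basis(
                np.zeros((10, 4)), np.zeros((12, 4)), np.eye(4), np.eye(4)
            )


class TestSolverAgainstAugmentationOracle:
    def test_penalized_solution_matches_ridge_augmentation(self, small_fit_data):
        records, _, _ = small_fit_data
        df = records[records["item"] == "anxious"]
        design = _design_for_item(
            df, basis_dim=8, degree=3, penalty_order=2, include_interaction=True
        )
        keys = {
            "ridge": 3.0,
            "isi": 0.7,
            "isi_null": 0.2,
            "time": 5.0,
            "time_null": 0.1,
            "tensor_isi": 2.0,
            "tensor_time": 4.0,
            "tensor_null": 1.0,
        }
        res = _fit_fixed_lambda(design, "gaussian", keys, 200, 1e-8)
        X, y = design["X"], design["y"]
        S = _assemble_penalty(X.shape[1], design["blocks"], keys)
        vals, vecs = np.linalg.eigh(S)
        vals = np.clip(vals, 0.0, None)
        L = (vecs * np.sqrt(vals)) @ vecs.T  # symmetric square root
        X_aug = np.vstack([X, L])
        y_aug = np.concatenate([y, np.zeros(X.shape[1])])
        beta_aug, *_ = np.linalg.lstsq(X_aug, y_aug, rcond=None)
        np.testing.assert_allclose(res["beta"], beta_aug, atol=1e-8)


class TestFitGam:
    def test_lambda_to_infinity_collapses_to_linear_ols(self, small_fit_data):
        records, _, _ = small_fit_data
        big = 1e9
        lam = {
            "ridge": big,
            "isi": big,
            "time": big,
            "isi_null": 0.0,
            "time_null": 0.0,
        }
        fit = fit_gam(records, "anxious", lambdas=lam, include_interaction=False)
        df = records[records["item"] == "anxious"]
        design = _design_for_item(df, 10, 3, 2, False)
        fitted = design["X"] @ fit.coef
        # reference: plain OLS on {intercept, linear ISI, linear time}
        M = np.column_stack(
            [np.ones(len(df)), df["isi"].to_numpy(), df["time_of_day"].to_numpy()]
        )
        coef, *_ = np.linalg.lstsq(M, design["y"], rcond=None)
        np.testing.assert_allclose(fitted, M @ coef, atol=1e-5)

    def test_small_lambda_interpolates_small_fixture(self):
        rng = np.random.default_rng(17)
        rows = []
        for pid in range(1, 4):
            for j, t in enumerate(np.linspace(8, 24, 4) + 0.3 * pid, start=1):
                rows.append(
                    {
                        "participant_id": pid,
                        "isi": int(rng.integers(0, 29)),
                        "assessment_index": j,
                        "time_of_day": float(t),
                        "item": "anxious",
                        "rating": float(rng.integers(0, 9)),
                    }
                )
        records = pd.DataFrame(rows)
        lam = {k: 1e-6 for k in ("ridge", "isi", "isi_null", "time", "time_null")}
        fit = fit_gam(records, "anxious", lambdas=lam, basis_dim=10)
        design = _design_for_item(records, 10, 3, 2, False)
        resid = design["y"] - design["X"] @ fit.coef
        assert np.max(np.abs(resid)) < 1e-3

    def test_edf_monotone_in_lambda(self, small_fit_data):
        records, _, _ = small_fit_data
        df = records[records["item"] == "anxious"]
        design = _design_for_item(df, 10, 3, 2, False)
        edfs = []
        for lam_time in [1e-3, 1e-1, 1e1, 1e3, 1e5]:
            lam = {
                "ridge": 1.0,
                "isi": 1.0,
                "isi_null": 1.0,
                "time": lam_time,
                "time_null": 1.0,
            }
            res = _fit_fixed_lambda(design, "gaussian", lam, 200, 1e-8)
            edfs.append(res["edf_by_block"]["s(time)"])
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))

    def test_constant_data_recovered(self):
        cfg = single_item_config(
            n_participants=30,
            seed=1,
            baseline_curve={"anxious": HarmonicCurve(3.0, ())},
            isi_level_slope={"anxious": 0.0},
            random_intercept_sd=0.0,
            innovation_sd_base=0.0,
            innovation_sd_isi_slope=0.0,
            missing_rate=0.0,
        )
        records, _ = simulate_dataset(cfg)
        fit = fit_gam(records, "anxious")
        surface = predict_surface(fit, n_grid=8)
        assert np.max(np.abs(surface.predicted - 3.0)) < 0.05

    def test_poisson_recovers_loglinear_slope(self):
        rng = np.random.default_rng(23)
        n = 900
        t = rng.uniform(8, 24, n)
        isi = rng.integers(0, 29, n).astype(float)
        mu = np.exp(-0.5 + 0.1 * t)
        rows = pd.DataFrame(
            {
                "participant_id": np.arange(n) % 15 + 1,
                "isi": isi.astype(int),
                "assessment_index": np.arange(n) % 6 + 1,
                "time_of_day": t,
                "item": "sleepy",
                "rating": rng.poisson(mu).astype(float),
            }
        )
        big = 1e7
        lam = {
            "ridge": big,
            "isi": big,
            "time": big,
            "isi_null": 0.0,
            "time_null": 0.0,
        }
        fit = fit_gam(rows, "sleepy", family="poisson_log", lambdas=lam)
        design = _design_for_item(rows, 10, 3, 2, False)
        eta = design["X"] @ fit.coef
        slope = np.polyfit(t, eta, 1)[0]
        assert slope == pytest.approx(0.1, rel=0.05)

    def test_poisson_predictions_nonnegative(self, small_fit_data):
        records, _, _ = small_fit_data
        fit = fit_gam(records, "anxious", family="poisson_log")
        assert fit.converged
        surface = predict_surface(fit, n_grid=6)
        assert (surface.predicted >= 0).all()

    def test_missing_ratings_rejected(self):
        cfg = single_item_config(n_participants=10, seed=4, missing_rate=0.3)
        records, _ = simulate_dataset(cfg)
        with pytest.raises(ValueError, match="[Mm]issing"):
            fit_gam(records, "anxious")

    def test_unknown_family_rejected(self, small_fit_data):
        records, _, _ = small_fit_data
        with pytest.raises(ValueError, match="family"):
            fit_gam(records, "anxious", family="gamma")


class TestModelComparison:
    def test_tie_keeps_first(self, small_fit_data):
        records, _, _ = small_fit_data
        lam = {"ridge": 1.0, "isi": 1.0, "isi_null": 1.0, "time": 1.0, "time_null": 1.0}
        f1 = fit_gam(records, "anxious", lambdas=lam)
        f2 = fit_gam(records, "anxious", lambdas=lam)
        best, table = compare_models(f1, f2)
        assert best is f1
        assert len(table) == 2

    def test_different_data_rejected(self, small_fit_data):
        records, _, _ = small_fit_data
        lam = {"ridge": 1.0, "isi": 1.0, "isi_null": 1.0, "time": 1.0, "time_null": 1.0}
        f1 = fit_gam(records, "anxious", lambdas=lam)
        other = records.copy()
        other.loc[other["item"] == "anxious", "rating"] = (
            8.0 - other.loc[other["item"] == "anxious", "rating"]
        )
        f2 = fit_gam(other, "anxious", lambdas=lam)
        with pytest.raises(ValueError, match="identical data"):
            compare_models(f1, f2)


class TestPredictSurface:
    def test_nonconverged_fit_rejected(self, small_fit_data):
        records, _, _ = small_fit_data
        lam = {"ridge": 1.0, "isi": 1.0, "isi_null": 1.0, "time": 1.0, "time_null": 1.0}
        fit = fit_gam(records, "anxious", lambdas=lam)
        broken = dataclasses.replace(fit, converged=False)
        with pytest.raises(NotConvergedError):
            predict_surface(broken)

    def test_extrapolation_warns(self, small_fit_data):
        records, _, _ = small_fit_data
        lam = {"ridge": 1.0, "isi": 1.0, "isi_null": 1.0, "time": 1.0, "time_null": 1.0}
        fit = fit_gam(records, "anxious", lambdas=lam)
        with pytest.warns(UserWarning, match="extend"):
            predict_surface(fit, isi_values=np.array([0.0, 40.0]))

    def test_grid_shapes_and_finiteness(self, small_fit_data):
        records, _, _ = small_fit_data
        lam = {"ridge": 1.0, "isi": 1.0, "isi_null": 1.0, "time": 1.0, "time_null": 1.0}
        fit = fit_gam(records, "anxious", lambdas=lam)
        surface = predict_surface(fit, n_grid=12)
        assert surface.predicted.shape == (12, 12)
        assert surface.se.shape == (12, 12)
        assert np.isfinite(surface.predicted).all()
        assert (surface.se >= 0).all()
        frame = surface.to_frame()
        assert len(frame) == 144
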