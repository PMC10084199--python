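"""The five estimation strategies and their structural relationships."""

import subprocess
import shutil

import numpy as np
import pandas as pd
import pytest

from spatialplus import (
    EstimatorSpec,
    GSEMRegressor,
    NullRegressor,
    RSRRegressor,
    SimConfig,
    SpatialDataset,
    SpatialPlusRegressor,
    SpatialRegressor,
    build_basis,
    fit_gsem,
    fit_null,
    fit_rsr,
    fit_spatial,
    fit_spatialplus,
    generate_replicate,
    residualize_covariate,
)
from spatialplus.estimators import FullySpatialCovariateError


class TestResidualize:
    def test_decomposition_identity_exact(self, replicate_small):
        rep = replicate_small
        basis = build_basis(rep.locs, k=40)
        res = residualize_covariate(rep.x, basis)
        np.testing.assert_allclose(res.f_x_hat + res.r_x, rep.x, atol=1e-12)

    def test_residual_variance_recovers_covariate_noise(self):
        # x = 0.5 z + eps_x with sd(eps_x) = 0.1: the spatial residuals at a
        # GCV-selected first stage recover roughly Var(eps_x) = 0.01
        vars_ = []
        for seed in range(5):
            rep = generate_replicate(SimConfig(n=300, grid=50, k=100), seed=seed)
            basis = build_basis(rep.locs, k=100)
            vars_.append(np.var(residualize_covariate(rep.x, basis).r_x))
        assert np.mean(vars_) == pytest.approx(0.01, rel=0.35)

    def test_polynomial_trend_covariate_is_fully_spatial(self, replicate_small):
        rep = replicate_small
        basis = build_basis(rep.locs, k=40)
        trend = 1.0 + 0.5 * rep.locs.coords[:, 0] - 0.2 * rep.locs.coords[:, 1]
        # exactly representable: zero residuals -> hard error
        with pytest.raises(FullySpatialCovariateError):
            residualize_covariate(trend, basis)
        # almost fully spatial (tiny noise) -> warning
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="fully determined"):
            residualize_covariate(trend + 1e-3 * rng.normal(size=rep.locs.n), basis)

    def test_constant_covariate_rejected(self, replicate_small):
        basis = build_basis(replicate_small.locs, k=40)
        with pytest.raises(ValueError, match="constant"):
            residualize_covariate(np.ones(replicate_small.locs.n), basis)


class TestNull:
    def test_exact_linear_relationship(self, replicate_small):
        rep = replicate_small
        ds = SpatialDataset(rep.locs.coords, rep.x, 2.0 * rep.x)
        est = fit_null(ds)
        assert est.coef_[0] == pytest.approx(2.0, abs=1e-10)
        assert est.intercept_ == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 30
        coords = rng.uniform(0, 10, (n, 2))
        x = rng.normal(size=n)
        y = 1.0 + 0.7 * x + rng.normal(size=n)
        est = fit_null(SpatialDataset(coords, x, y))
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose([est.intercept_, est.coef_[0]], beta, atol=1e-10)


class TestStructuralIdentities:
    def test_rsr_slope_equals_null_for_any_lambda(self):
        # the defining property of restricted spatial regression
        for seed in range(10):
            rep = generate_replicate(SimConfig(n=80, grid=30, k=30), seed=seed)
            ds = SpatialDataset(rep.locs.coords, rep.x, rep.y)
            b_null = fit_null(ds).coef_[0]
            rng = np.random.default_rng(seed)
            for lam in 10.0 ** rng.uniform(-8, 8, 20):
                b_rsr = fit_rsr(ds, k=30, lam=float(lam)).coef_[0]
                assert b_rsr == pytest.approx(b_null, abs=1e-8)

    def test_unsmoothed_models_identical(self, replicate_small, dataset_small):
        # lambda = lambda_x = 0 with reduced rank: spatial, gSEM and spatial+
        # are reparameterizations with identical slope and fitted values
        ds = dataset_small
        sp0 = fit_spatial(ds, k=40, lam=0.0)
        g0 = fit_gsem(ds, k=40, lam=0.0, lam_x=0.0)
        p0 = fit_spatialplus(ds, k=40, lam=0.0, lam_x=0.0)
        assert g0.coef_[0] == pytest.approx(sp0.coef_[0], rel=1e-6)
        assert p0.coef_[0] == pytest.approx(sp0.coef_[0], rel=1e-6)
        np.testing.assert_allclose(p0.fit_.fitted, sp0.fit_.fitted, atol=1e-8)
        np.testing.assert_allclose(g0.fitted_composed_, sp0.fit_.fitted, atol=1e-8)
        r0 = fit_rsr(ds, k=40, lam=0.0)
        np.testing.assert_allclose(r0.fit_.fitted, sp0.fit_.fitted, atol=1e-8)

    def test_spatialplus_preserves_model_column_space(self, dataset_small):
        # projection matrices onto the spatial and spatial+ model-matrix
        # spans agree for any first-stage smoothing amount
        ds = dataset_small
        sp = fit_spatial(ds, k=40, lam=0.1)
        A1 = np.hstack([sp.fit_.X_par, sp.fit_.basis.design])
        for lam_x in (0.0, 1e-2, 10.0):
            pl = fit_spatialplus(ds, k=40, lam=0.1, lam_x=lam_x)
            A2 = np.hstack([pl.fit_.X_par, pl.fit_.basis.design])
            H1 = A1 @ np.linalg.pinv(A1)
            H2 = A2 @ np.linalg.pinv(A2)
            np.testing.assert_allclose(H1, H2, atol=1e-8)

    def test_gsem_stage2_is_plain_ols(self, rng):
        # stage-2 regression on synthetic residual-like inputs equals a
        # hand-computed no-intercept OLS even when orthogonality is broken
        from spatialplus.penalized import solve_penalized

        r_y = rng.normal(size=50)
        R = rng.normal(size=(50, 2))
        fit = solve_penalized(r_y, R, None, 0.0)
        beta = np.linalg.solve(R.T @ R, R.T @ r_y)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)

    def test_gsem_requires_gaussian(self, dataset_small):
        with pytest.raises(ValueError, match="[Gg]aussian"):
            EstimatorSpec(method="gsem", family="poisson")
        est = GSEMRegressor(k=40, family="poisson")
        with pytest.raises(ValueError, match="[Gg]aussian"):
            est.fit(np.hstack([dataset_small.coords, dataset_small.X]),
                    dataset_small.y)

    def test_glm_spatialplus_gaussian_family_matches_gaussian_path(self, dataset_small):
        ds = dataset_small
        a = fit_spatialplus(ds, k=40)
        b = SpatialPlusRegressor(k=40, family="gaussian")
        b.fit(np.hstack([ds.coords, ds.X]), ds.y)
        assert a.coef_[0] == pytest.approx(b.coef_[0], rel=1e-10)


class TestBiasBehaviour:
    def test_smoothing_biases_spatial_but_not_spatialplus(self):
        # small replicated check of the headline behaviour (the full-size
        # version lives in the acceptance suite)
        b = {"null": [], "spatial": [], "spatialplus": [], "gsem": []}
        for seed in range(12):
            rep = generate_replicate(SimConfig(n=300, grid=50, k=100), seed=500 + seed)
            ds = SpatialDataset(rep.locs.coords, rep.x, rep.y)
            b["null"].append(fit_null(ds).coef_[0])
            b["spatial"].append(fit_spatial(ds, k=100).coef_[0])
            b["spatialplus"].append(fit_spatialplus(ds, k=100).coef_[0])
            b["gsem"].append(fit_gsem(ds, k=100).coef_[0])
        bias = {k: abs(np.mean(v) - 3.0) for k, v in b.items()}
        assert bias["spatialplus"] < bias["spatial"] < bias["null"]
        assert bias["gsem"] < bias["spatial"]


class TestSklearnAPI:
    def test_get_set_params_and_clone(self):
        from sklearn.base import clone

        est = SpatialPlusRegressor(k=50, lam="select", family="poisson")
        params = est.get_params()
        assert params["k"] == 50 and params["family"] == "poisson"
        est2 = clone(est).set_params(k=25)
        assert est2.k == 25 and est2.family == "poisson"

    def test_predict_at_training_points_matches_fitted(self, dataset_small):
        ds = dataset_small
        X = np.hstack([ds.coords, ds.X])
        for cls in (NullRegressor, SpatialRegressor):
            est = cls(k=40).fit(X, ds.y)
            np.testing.assert_allclose(est.predict(X), est.fit_.fitted, atol=1e-6)
        est = SpatialPlusRegressor(k=40).fit(X, ds.y)
        # spatial+ predictions recombine residualized pieces; at the training
        # points they reproduce the fit
        np.testing.assert_allclose(est.predict(X), est.fit_.fitted, atol=1e-6)

    def test_rsr_prediction_unsupported(self, dataset_small):
        ds = dataset_small
        X = np.hstack([ds.coords, ds.X])
        est = RSRRegressor(k=40).fit(X, ds.y)
        with pytest.raises(NotImplementedError):
            est.predict(X)

    def test_invalid_layout_rejected(self, dataset_small):
        with pytest.raises(ValueError, match="columns"):
            SpatialRegressor().fit(dataset_small.coords, dataset_small.y)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestMgcvCrossCheck:
    """Independent-oracle check against mgcv's thin plate regression splines."""

    def test_lambda_zero_slope_matches_mgcv(self, tmp_path, rng):
        n, k = 80, 20
        coords = rng.uniform(0, 10, (n, 2))
        x = rng.normal(size=n)
        y = 2.0 * x + np.sin(coords[:, 0]) + 0.5 * coords[:, 1] + 0.3 * rng.normal(size=n)
        csv = tmp_path / "d.csv"
        pd.DataFrame(
            {"c1": coords[:, 0], "c2": coords[:, 1], "x": x, "y": y}
        ).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(mgcv))
            d <- read.csv('{csv}')
            m0 <- gam(y ~ x + s(c1, c2, k={k}, fx=TRUE), data=d)
            m1 <- gam(y ~ x + s(c1, c2, k={k}), data=d, method='GCV.Cp')
            cat(sprintf('%.12f %.12f %.6f', coef(m0)['x'], coef(m1)['x'], sum(m1$edf)))
            """
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=300, check=True,
        )
        b0_mgcv, b1_mgcv, edf_mgcv = map(float, out.stdout.split())

        ds = SpatialDataset(coords, x, y)
        b0 = fit_spatial(ds, k=k, lam=0.0).coef_[0]
        gcv_fit = fit_spatial(ds, k=k)
        # identical column space -> identical unpenalized estimate
        assert b0 == pytest.approx(b0_mgcv, abs=1e-6)
        # GCV-selected fits agree closely (same criterion, same basis)
        assert gcv_fit.coef_[0] == pytest.approx(b1_mgcv, rel=1e-3)
        assert gcv_fit.edf_ == pytest.approx(edf_mgcv, rel=0.02)
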