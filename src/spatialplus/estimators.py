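"""The five estimation strategies compared for spatially confounded regression.

All estimators share the data layout ``X = [coord_1, coord_2, covariates...]``
(scikit-learn convention: one matrix, coordinates in the first ``n_coords``
columns) and fit a linear covariate effect in the presence of a residual
spatial surface:

``NullRegressor``
    no spatial term — the ordinary (G)LM of y on the covariates.
``SpatialRegressor``
    partial thin plate spline model: covariates parametric, one spatial
    TPRS smooth, smoothing by GCV (or fixed).
``RSRRegressor``
    restricted spatial regression: the spatial basis is projected onto the
    orthogonal complement of the covariates before fitting, which preserves
    the null-model slope by construction.
``GSEMRegressor``
    geoadditive structural equation model: spatial smooths are fitted to the
    covariates and to the response, and the response residuals are regressed
    on the covariate residuals (Gaussian only).
``SpatialPlusRegressor``
    spatial+: each covariate is replaced by its residual after a spatial
    smooth has been regressed away, then the spatial model is fitted to the
    original response.  For exponential-family responses the residualization
    is done in the working-weight inner product of a preliminary spatial
    PIRLS fit.

The slope of interest is reported in ``coef_``; because spatial+ and gSEM
only reparameterize the covariate, ``coef_`` estimates the same generative
effect in every model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .basis import SpatialLocations, TPRSBasis, build_basis
from .families import Family, get_family, pirls_fit
from .penalized import (
    PartialSplineFit,
    select_lambda,
    solve_penalized,
    summarize_fit,
)

__all__ = [
    "SpatialDataset",
    "EstimatorSpec",
    "ResidualizedCovariate",
    "residualize_covariate",
    "NullRegressor",
    "SpatialRegressor",
    "RSRRegressor",
    "GSEMRegressor",
    "SpatialPlusRegressor",
    "make_estimator",
    "fit_null",
    "fit_spatial",
    "fit_rsr",
    "fit_gsem",
    "fit_spatialplus",
    "FullySpatialCovariateError",
]

METHODS = ("null", "spatial", "rsr", "gsem", "spatialplus")


class FullySpatialCovariateError(ValueError):
    """Covariate has (numerically) no nonspatial variation."""


@dataclass
class SpatialDataset:
    """One row per observation: 2-D coordinates, covariates, response."""

    coords: np.ndarray
    X: np.ndarray
    y: np.ndarray
    family: str = "gaussian"
    covariate_names: Optional[list] = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        X = np.asarray(self.X, dtype=float)
        self.X = X.reshape(-1, 1) if X.ndim == 1 else X
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.coords.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("coords, X and y must have matching row counts")
        if self.covariate_names is None:
            self.covariate_names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class EstimatorSpec:
    """Which method to fit and with what smoothing configuration."""

    method: str = "spatialplus"
    k: int = 300
    k_x: Optional[int] = None
    lam: object = "select"      # "select" or a fixed nonnegative value
    lam_x: object = "select"
    family: str = "gaussian"
    binomial_size: int = 10
    m: int = 2

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.method == "gsem" and self.family != "gaussian":
            raise ValueError(
                "gSEM is only defined for Gaussian responses (no clear "
                "generalization to other exponential families)"
            )


@dataclass
class ResidualizedCovariate:
    """Spatial decomposition x = f_x_hat + r_x of one covariate."""

    r_x: np.ndarray
    f_x_hat: np.ndarray
    lambda_x: float
    deviance_explained: float
    first_stage: PartialSplineFit


def residualize_covariate(x, basis: TPRSBasis, weights=None, lambda_x="select"):
    """Regress spatial location out of a covariate; return residual + surface.

    Fits an intercept + spatial smooth to ``x`` (GCV-selected or fixed
    smoothing, optionally in a weighted inner product) and returns the
    decomposition ``x = f_x_hat + r_x``.  Warns when the covariate is almost
    fully spatial (first-stage deviance explained > 0.99): spatial+ needs
    genuine nonspatial variation in the covariate to identify its effect.
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise ValueError("cannot residualize a constant covariate")
    n = x.size
    ones = np.ones((n, 1))
    cb = basis.absorb_intercept()
    if lambda_x == "select":
        fit = select_lambda(x, ones, cb, weights=weights)
    else:
        fit = solve_penalized(x, ones, cb, float(lambda_x), weights=weights)
    f_hat = fit.fitted
    r = x - f_hat
    if np.max(np.abs(r)) < 1e-10 * max(1.0, np.max(np.abs(x))):
        raise FullySpatialCovariateError(
            "first-stage fit interpolates the covariate (zero residuals); "
            "reduce the residualization basis size k_x"
        )
    if fit.deviance_explained > 0.99:
        warnings.warn(
            "covariate is almost fully determined by spatial location "
            f"(first-stage deviance explained {fit.deviance_explained:.3f}); "
            "spatial+ estimates may be unreliable",
            UserWarning,
        )
    return ResidualizedCovariate(
        r_x=r,
        f_x_hat=f_hat,
        lambda_x=fit.lam,
        deviance_explained=fit.deviance_explained,
        first_stage=fit,
    )


def _glm_wald(fit: PartialSplineFit, p: int):
    """Fixed-dispersion Wald z-tests for the parametric block of a GLM fit."""
    from scipy import stats

    Vb = fit.cov_coefs / fit.sigma2  # (A'WA + n lam P)^{-1}
    se = np.sqrt(np.maximum(np.diag(Vb)[:p], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fit.beta[:p] / se, np.inf)
    return se, 2 * stats.norm.sf(np.abs(z))


class _BaseSpatialRegressor(BaseEstimator, RegressorMixin):
    """Shared machinery: input layout, basis construction, fit bookkeeping."""

    method: str = None

    def __init__(
        self,
        k=300,
        k_x=None,
        lam="select",
        lam_x="select",
        family="gaussian",
        binomial_size=10,
        m=2,
        n_coords=2,
    ):
        self.k = k
        self.k_x = k_x
        self.lam = lam
        self.lam_x = lam_x
        self.family = family
        self.binomial_size = binomial_size
        self.m = m
        self.n_coords = n_coords

    # -- helpers -----------------------------------------------------------
    def _split(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] <= self.n_coords:
            raise ValueError(
                f"X must have > {self.n_coords} columns: "
                f"{self.n_coords} coordinates followed by covariates"
            )
        return X[:, : self.n_coords], X[:, self.n_coords :]

    def _family(self) -> Family:
        return get_family(self.family, n_bin=self.binomial_size)

    def _basis(self, coords, k) -> TPRSBasis:
        locs = SpatialLocations(coords)
        return build_basis(locs, k=min(k, locs.n_knots + locs_null(locs, self.m)), m=self.m)

    def _record(self, fit: PartialSplineFit, p_cov, names):
        fam = self._family()
        self.fit_ = fit
        self.intercept_ = float(fit.beta[0])
        self.coef_ = fit.beta[1 : 1 + p_cov].copy()
        if fam.name == "gaussian":
            self.se_ = fit.se_beta[1 : 1 + p_cov].copy()
            self.pvalues_ = fit.pvals_beta[1 : 1 + p_cov].copy()
        else:
            se, pv = _glm_wald(fit, 1 + p_cov)
            self.se_ = se[1:]
            self.pvalues_ = pv[1:]
        self.lambda_ = fit.lam
        self.edf_ = fit.edf
        self.edf_smooth_ = fit.edf_smooth
        self.sigma2_ = fit.sigma2
        self.gcv_ = fit.gcv
        self.aic_ = fit.aic
        self.deviance_explained_ = fit.deviance_explained
        self.covariate_names_ = list(names)

    def summary(self) -> dict:
        check_is_fitted(self, "fit_")
        out = summarize_fit(self.fit_, ["(intercept)"] + self.covariate_names_)
        out["method"] = self.method
        for j, nm in enumerate(self.covariate_names_):
            out["terms"][nm]["se"] = float(self.se_[j])
            out["terms"][nm]["p_value"] = float(self.pvalues_[j])
        return out

    def fit_dataset(self, data: SpatialDataset):
        X = np.hstack([data.coords, data.X])
        self.fit(X, data.y)
        self.covariate_names_ = list(data.covariate_names)
        return self

    # -- default predict: parametric part + spatial surface ----------------
    def predict(self, X):
        check_is_fitted(self, "fit_")
        coords, Xc = self._split(X)
        eta = self.intercept_ + Xc @ self.coef_ + self._spatial_surface(coords)
        return self._family().inverse_link(eta)

    def _spatial_surface(self, coords):
        return self.fit_.smooth_values(coords)


def locs_null(locs, m):
    from .basis import null_space_dim

    return null_space_dim(m, locs.d)


class NullRegressor(_BaseSpatialRegressor):
    """Ordinary (G)LM of the response on the covariates; no spatial term."""

    method = "null"

    def fit(self, X, y):
        coords, Xc = self._split(X)
        y = np.asarray(y, dtype=float).ravel()
        fam = self._family()
        Xpar = np.hstack([np.ones((len(y), 1)), Xc])
        fit, state = pirls_fit(y, Xpar, None, fam, lam=0.0)
        self.pirls_ = state
        self._record(fit, Xc.shape[1], [f"x{j}" for j in range(Xc.shape[1])])
        return self

    def _spatial_surface(self, coords):
        return 0.0


class SpatialRegressor(_BaseSpatialRegressor):
    """Partial thin plate spline model: covariates + spatial TPRS smooth."""

    method = "spatial"

    def _model_basis(self, coords):
        return self._basis(coords, self.k).absorb_intercept()

    def fit(self, X, y):
        coords, Xc = self._split(X)
        y = np.asarray(y, dtype=float).ravel()
        fam = self._family()
        basis = self._model_basis(coords)
        Xpar = np.hstack([np.ones((len(y), 1)), Xc])
        fit, state = pirls_fit(y, Xpar, basis, fam, lam=self.lam)
        self.pirls_ = state
        self._record(fit, Xc.shape[1], [f"x{j}" for j in range(Xc.shape[1])])
        return self


class RSRRegressor(SpatialRegressor):
    """Restricted spatial regression: spatial basis projected off the covariates.

    The smooth's columns B are replaced by (I - Q(Q'Q)^{-1}Q')B where Q is
    the covariate block including the intercept, so the slope estimate
    coincides with the null model's (exactly, in the Gaussian case) while the
    model's column space matches the spatial model's.
    """

    method = "rsr"

    def fit(self, X, y):
        coords, Xc = self._split(X)
        y = np.asarray(y, dtype=float).ravel()
        fam = self._family()
        basis = self._basis(coords, self.k).absorb_intercept()
        Xpar = np.hstack([np.ones((len(y), 1)), Xc])
        # Euclidean projection, also reused unchanged inside PIRLS
        Q, _ = np.linalg.qr(Xpar)
        B = basis.design
        basis_proj = TPRSBasis(
            locs=basis.locs,
            design=B - Q @ (Q.T @ B),
            penalty=basis.penalty,
            m=basis.m,
            M=basis.M,
            k=basis.k,
            _delta=basis._delta,
            _powers=basis._powers,
            centered=True,
            _col_means=basis._col_means,
        )
        fit, state = pirls_fit(y, Xpar, basis_proj, fam, lam=self.lam)
        self.pirls_ = state
        self._record(fit, Xc.shape[1], [f"x{j}" for j in range(Xc.shape[1])])
        return self

    def _spatial_surface(self, coords):
        raise NotImplementedError(
            "RSR's projected basis is tied to the training covariates; "
            "out-of-sample prediction is not defined"
        )

    def predict(self, X):
        check_is_fitted(self, "fit_")
        raise NotImplementedError(
            "RSR supports in-sample fitted values only (fit_.fitted)"
        )


class GSEMRegressor(_BaseSpatialRegressor):
    """Geoadditive SEM: regress spatial residuals of y on those of x.

    Stage one fits an intercept + spatial smooth (GCV) to the response and
    to each covariate; stage two is an OLS, with no intercept, of the
    response residuals on the covariate residuals.  Composed fitted values
    f_y_hat + stage-two fitted residuals are recorded for MSE comparisons.
    Gaussian responses only.
    """

    method = "gsem"

    def fit(self, X, y):
        if self.family != "gaussian":
            raise ValueError("gSEM supports only the Gaussian family")
        coords, Xc = self._split(X)
        y = np.asarray(y, dtype=float).ravel()
        basis = self._basis(coords, self.k)
        res_x = [
            residualize_covariate(Xc[:, j], basis, lambda_x=self._stage1_lam())
            for j in range(Xc.shape[1])
        ]
        res_y = residualize_covariate(y, basis, lambda_x=self._stage1_lam())
        R = np.column_stack([r.r_x for r in res_x])
        # stage 2: no intercept (both sides are smooth-fit residuals)
        fit2 = solve_penalized(res_y.r_x, R, None, 0.0)
        self.stage1_x_ = res_x
        self.stage1_y_ = res_y
        self.fit_ = fit2
        self.coef_ = fit2.beta.copy()
        self.intercept_ = 0.0
        self.se_ = fit2.se_beta.copy()
        self.pvalues_ = fit2.pvals_beta.copy()
        self.lambda_ = res_y.lambda_x
        self.lambda_x_ = [r.lambda_x for r in res_x]
        self.edf_ = fit2.edf
        self.edf_smooth_ = 0.0
        self.sigma2_ = fit2.sigma2
        self.gcv_ = fit2.gcv
        self.aic_ = fit2.aic
        self.deviance_explained_ = fit2.deviance_explained
        self.covariate_names_ = [f"x{j}" for j in range(Xc.shape[1])]
        # composed fitted values f_y_hat + r_y_hat, on the original y scale
        self.fitted_composed_ = res_y.f_x_hat + fit2.fitted
        return self

    def _stage1_lam(self):
        # "unsmoothed" gSEM fixes every smoothing parameter at zero
        return self.lam if self.lam != "select" else "select"

    def summary(self) -> dict:
        check_is_fitted(self, "fit_")
        out = summarize_fit(self.fit_, self.covariate_names_)
        out["method"] = self.method
        out["note"] = (
            "response is the spatial residual of y; fit statistics are not "
            "comparable with the null/spatial/spatial+ models"
        )
        return out

    def predict(self, X):
        check_is_fitted(self, "fit_")
        raise NotImplementedError(
            "gSEM composed predictions are in-sample (fitted_composed_)"
        )


class SpatialPlusRegressor(_BaseSpatialRegressor):
    """Spatial+: covariates replaced by their spatial residuals before fitting.

    Each covariate is residualized separately against a spatial smooth (GCV
    smoothing by default); the spatial model is then fitted with the
    residualized covariates, leaving the response — and hence model
    comparison criteria — unchanged.  For exponential-family responses the
    residualization is weighted by the working weights of a preliminary
    spatial PIRLS fit.  The reconstructed spatial surface
    f+_hat - beta_hat * f_x_hat (which estimates the original f) is stored in
    ``f_plus_``.
    """

    method = "spatialplus"

    def fit(self, X, y):
        coords, Xc = self._split(X)
        y = np.asarray(y, dtype=float).ravel()
        fam = self._family()
        locs = SpatialLocations(coords)
        basis = self._basis(coords, self.k)
        basis_x = basis if (self.k_x is None or self.k_x == self.k) else self._basis(
            coords, self.k_x
        )
        cb = basis.absorb_intercept()

        if fam.name == "gaussian":
            w = None
        else:
            # preliminary spatial fit for the working weights at convergence
            Xpar0 = np.hstack([np.ones((len(y), 1)), Xc])
            _, state0 = pirls_fit(y, Xpar0, cb, fam, lam=self.lam)
            w = state0.weights
            self.prelim_pirls_ = state0

        res = [
            residualize_covariate(Xc[:, j], basis_x, weights=w, lambda_x=self.lam_x)
            for j in range(Xc.shape[1])
        ]
        R = np.column_stack([r.r_x for r in res])
        Xpar = np.hstack([np.ones((len(y), 1)), R])
        fit, state = pirls_fit(y, Xpar, cb, fam, lam=self.lam)
        self.pirls_ = state
        self.residualized_ = res
        self._record(fit, Xc.shape[1], [f"x{j}" for j in range(Xc.shape[1])])
        self.lambda_x_ = [r.lambda_x for r in res]
        # reconstruction of the original spatial surface f from the spatial+
        # fit: subtract the part of each covariate's spatial surface that the
        # slope re-absorbs
        fhat_plus = fit.smooth_values()
        self.f_plus_ = fhat_plus.copy()
        self.f_reconstructed_ = fhat_plus - sum(
            b * r.f_x_hat for b, r in zip(self.coef_, res)
        )
        return self

    def predict(self, X):
        """Predict on the linear-predictor's mean scale at new rows.

        Uses the reconstructed surface and the original-covariate slope, so
        predictions take raw covariate values (not residuals).
        """
        check_is_fitted(self, "fit_")
        coords, Xc = self._split(X)
        # f+ surface at new coords minus the re-absorbed covariate surfaces
        f_plus = self.fit_.smooth_values(coords)
        fx = [
            r.first_stage.beta[0] + r.first_stage.smooth_values(coords)
            for r in self.residualized_
        ]
        eta = (
            self.intercept_
            + Xc @ self.coef_
            + f_plus
            - sum(b * f for b, f in zip(self.coef_, fx))
        )
        return self._family().inverse_link(eta)


_CLASSES = {
    "null": NullRegressor,
    "spatial": SpatialRegressor,
    "rsr": RSRRegressor,
    "gsem": GSEMRegressor,
    "spatialplus": SpatialPlusRegressor,
}


def make_estimator(spec: EstimatorSpec, n=None) -> _BaseSpatialRegressor:
    cls = _CLASSES[spec.method]
    return cls(
        k=spec.k,
        k_x=spec.k_x,
        lam=spec.lam,
        lam_x=spec.lam_x,
        family=spec.family,
        binomial_size=spec.binomial_size,
        m=spec.m,
    )


def _fit_method(method, data: SpatialDataset, spec: EstimatorSpec = None, **kw):
    if spec is None:
        kw.setdefault("family", data.family)
        spec = EstimatorSpec(method=method, **kw)
    else:
        spec = EstimatorSpec(**{**spec.__dict__, "method": method})
    est = make_estimator(spec)
    est.fit_dataset(data)
    return est


def fit_null(data, spec=None, **kw):
    return _fit_method("null", data, spec, **kw)


def fit_spatial(data, spec=None, **kw):
    return _fit_method("spatial", data, spec, **kw)


def fit_rsr(data, spec=None, **kw):
    return _fit_method("rsr", data, spec, **kw)


def fit_gsem(data, spec=None, **kw):
    return _fit_method("gsem", data, spec, **kw)


def fit_spatialplus(data, spec=None, **kw):
    return _fit_method("spatialplus", data, spec, **kw)
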