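"""Penalized least squares for partial spline models and GCV smoothing selection.

The model is ``y = X_par beta + B gamma + eps`` with ``B`` a (possibly
centred) thin plate regression spline design and objective

    || sqrt(W) (y - X_par beta - B gamma) ||^2 + n * lambda * gamma' P gamma

i.e. the public smoothing parameter multiplies ``n`` times the thin plate
energy.  The smoothing parameter is chosen by generalized cross-validation,

    GCV(lambda) = n * RSS_w / (n - EDF_total)^2 ,

minimised over ``log10 lambda in [-8, 8]`` by a coarse grid followed by
golden-section refinement (deterministic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import linalg, stats

from .basis import TPRSBasis

__all__ = [
    "PartialSplineFit",
    "solve_penalized",
    "smoother_matrix",
    "gcv_score",
    "select_lambda",
    "summarize_fit",
    "RankDeficiencyError",
]

LOG10_LAMBDA_RANGE = (-8.0, 8.0)
_GRID_POINTS = 40


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


@dataclass
class PartialSplineFit:
    """Result of a (weighted) penalized partial spline fit at fixed lambda."""

    beta: np.ndarray            # parametric coefficients (incl. intercept if supplied)
    smooth_coefs: np.ndarray
    lam: float
    fitted: np.ndarray
    edf: float                  # total effective degrees of freedom
    edf_par: np.ndarray         # per parametric column
    edf_smooth: float
    sigma2: float
    gcv: float
    rss: float
    se_beta: np.ndarray
    pvals_beta: np.ndarray
    deviance_explained: float
    aic: float
    n: int
    basis: TPRSBasis = None
    X_par: np.ndarray = None
    weights: np.ndarray = None
    cov_coefs: np.ndarray = None
    extras: dict = dc_field(default_factory=dict)

    @property
    def coefs(self) -> np.ndarray:
        return np.concatenate([self.beta, self.smooth_coefs])

    def smooth_values(self, coords_new=None) -> np.ndarray:
        """Fitted smooth surface at the data (or new) locations."""
        B = self.basis.design if coords_new is None else self.basis.evaluate(coords_new)
        return B @ self.smooth_coefs


def _assemble(y, X_par, basis, weights):
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X_par is None:
        X_par = np.empty((n, 0))
    X_par = np.atleast_2d(np.asarray(X_par, dtype=float))
    if X_par.shape[0] != n:
        X_par = X_par.T
    B = basis.design if basis is not None else np.empty((n, 0))
    P = basis.penalty if basis is not None else np.empty((0, 0))
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    A = np.hstack([X_par, B])
    p = X_par.shape[1]
    Pfull = np.zeros((A.shape[1], A.shape[1]))
    if P.size:
        Pfull[p:, p:] = P
    return y, X_par, A, Pfull, p, w, n


def _penalty_root(Pfull):
    """L with Pfull = L L' (eigen square root, tiny negatives clipped)."""
    if Pfull.size == 0 or not np.any(Pfull):
        return np.empty((Pfull.shape[0], 0))
    evals, evecs = np.linalg.eigh(Pfull)
    keep = evals > max(evals.max(), 0) * 1e-14
    return evecs[:, keep] * np.sqrt(evals[keep])


def _penalized_core(Aw, yw, L, n, lam, need_edf_split=False):
    """Stable penalized WLS via QR of the augmented system.

    Minimizes ||Aw c - yw||^2 + n lam ||L' c||^2 by QR-factorizing
    [Aw ; sqrt(n lam) L'].  Returns coefficients, EDF pieces and the
    triangular factor R (with R'R = A'WA + n lam P).
    """
    k = Aw.shape[1]
    if lam > 0 and L.shape[1]:
        Aug = np.vstack([Aw, np.sqrt(n * lam) * L.T])
        rhs = np.concatenate([yw, np.zeros(L.shape[1])])
    else:
        Aug, rhs = Aw, yw
    Q, R = np.linalg.qr(Aug)
    dR = np.abs(np.diag(R))
    if dR.min() <= 1e-12 * max(dR.max(), 1.0):
        _, _, piv = linalg.qr(Aug, mode="economic", pivoting=True)
        r = int(np.linalg.matrix_rank(Aug))
        bad = sorted(piv[r:].tolist())
        raise RankDeficiencyError(
            f"penalized system singular; columns {bad} are collinear with the rest"
        )
    coefs = linalg.solve_triangular(R, Q.T @ rhs, check_finite=False)
    G = linalg.solve_triangular(R, Aw.T, trans="T", check_finite=False).T  # Aw R^{-1}
    edf_total = float(np.sum(G * G))
    edf_diag = None
    if need_edf_split:
        # diag of (A'WA + n lam P)^{-1} A'WA = R^{-1} (G' Aw)
        F = linalg.solve_triangular(R, G.T @ Aw, check_finite=False)
        edf_diag = np.diag(F).copy()
    return coefs, edf_total, edf_diag, R


def solve_penalized(y, X_par, basis, lam, weights=None):
    """Minimize the penalized (weighted) sum of squares at fixed ``lam``.

    Parameters
    ----------
    y : (n,) response
    X_par : (n, p) parametric design (include an intercept column explicitly),
        or None
    basis : TPRSBasis (use ``absorb_intercept()``'d basis when X_par has an
        intercept), or None for a purely parametric fit
    lam : nonnegative smoothing parameter (public nλ·energy convention)
    weights : optional positive working weights
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    y, X_par, A, Pfull, p, w, n = _assemble(y, X_par, basis, weights)
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    L = _penalty_root(Pfull)
    coefs, edf_total, edf_diag, R = _penalized_core(
        Aw, sw * y, L, n, lam, need_edf_split=True
    )
    fitted = A @ coefs
    resid = y - fitted
    rss = float(resid @ (w * resid))
    denom = n - edf_total
    sigma2 = rss / denom if denom > 0 else np.inf
    gcv = n * rss / denom**2 if denom > 0 else np.inf

    Rinv = linalg.solve_triangular(R, np.eye(R.shape[0]), check_finite=False)
    cov = (Rinv @ Rinv.T) * sigma2
    se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    beta = coefs[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf)
    df_resid = max(denom, 1.0)
    pvals = 2 * stats.t.sf(np.abs(tval), df_resid)

    wbar = y - (np.sum(w * y) / np.sum(w))
    tss = float(wbar @ (w * wbar))
    dev_expl = 1.0 - rss / tss if tss > 0 else np.nan
    aic = n * np.log(rss / n) + 2 * (edf_total + 1) if rss > 0 else -np.inf

    return PartialSplineFit(
        beta=beta,
        smooth_coefs=coefs[p:],
        lam=float(lam),
        fitted=fitted,
        edf=edf_total,
        edf_par=edf_diag[:p],
        edf_smooth=float(edf_total - np.sum(edf_diag[:p])),
        sigma2=sigma2,
        gcv=gcv,
        rss=rss,
        se_beta=se,
        pvals_beta=pvals,
        deviance_explained=dev_expl,
        aic=aic,
        n=n,
        basis=basis,
        X_par=X_par,
        weights=None if weights is None else w,
        cov_coefs=cov,
    )


def smoother_matrix(basis, lam, weights=None):
    """Dense influence matrix S mapping y to the smooth-only fitted values.

    ``S = B (B' W B + n lam P)^{-1} B' W`` in the reduced-rank
    parameterisation; its trace is the smooth's effective degrees of freedom.
    Intended for small-n diagnostics and oracle checks.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    B = basis.design
    P = basis.penalty
    n = B.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    BtWB = (B * w[:, None]).T @ B
    Mmat = BtWB + n * lam * P
    return B @ linalg.solve(Mmat, (B * w[:, None]).T, assume_a="pos")


def gcv_score(y, X_par, basis, lam, weights=None):
    """GCV(lambda) = n RSS_w / (n - EDF_total)^2 (gamma = 1)."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    y, X_par, A, Pfull, p, w, n = _assemble(y, X_par, basis, weights)
    sw = np.sqrt(w)
    return _gcv_from_parts(sw * y, A * sw[:, None], _penalty_root(Pfull), n, lam)


def _gcv_from_parts(yw, Aw, L, n, lam):
    coefs, edf_total, _, _ = _penalized_core(Aw, yw, L, n, lam)
    rss = float(np.sum((yw - Aw @ coefs) ** 2))
    denom = n - edf_total
    return n * rss / denom**2 if denom > 0 else np.inf


def select_lambda(y, X_par, basis, weights=None):
    """Fit with the GCV-minimising smoothing parameter.

    Coarse 40-point grid on log10 lambda in [-8, 8], then golden-section
    refinement on the bracketing interval.  Deterministic.
    """
    y_, X_par_, A, Pfull, p, w, n = _assemble(y, X_par, basis, weights)
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    yw = sw * y_
    L = _penalty_root(Pfull)

    lo, hi = LOG10_LAMBDA_RANGE
    grid = np.linspace(lo, hi, _GRID_POINTS)
    scores = np.array([_gcv_from_parts(yw, Aw, L, n, 10.0**g) for g in grid])
    i = int(np.argmin(scores))
    if np.ptp(scores[np.isfinite(scores)]) <= 1e-12 * max(1.0, abs(scores[i])):
        warnings.warn(
            "GCV profile is flat; returning boundary smoothing parameter",
            RuntimeWarning,
        )
    if i in (0, len(grid) - 1):
        best = grid[i]
    else:
        a, b = grid[i - 1], grid[i + 1]
        invphi = (np.sqrt(5.0) - 1) / 2
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = _gcv_from_parts(yw, Aw, L, n, 10.0**c)
        fd = _gcv_from_parts(yw, Aw, L, n, 10.0**d)
        for _ in range(40):
            if b - a < 1e-4:
                break
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = _gcv_from_parts(yw, Aw, L, n, 10.0**c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = _gcv_from_parts(yw, Aw, L, n, 10.0**d)
        best = 0.5 * (a + b)
    return solve_penalized(y, X_par, basis, 10.0**best, weights=weights)


def summarize_fit(fit: PartialSplineFit, names=None) -> dict:
    """Summary statistics in the layout of a GAM fit table.

    Deviance explained, sigma-hat, AIC, per-term Wald tests for the
    parametric part (t reference with n - EDF residual df), and an
    approximate Wald test for the smooth block (labelled approximate).
    """
    p = fit.beta.size
    names = names or [f"b{j}" for j in range(p)]
    out = {
        "n": fit.n,
        "lambda": fit.lam,
        "edf_total": fit.edf,
        "edf_smooth": fit.edf_smooth,
        "deviance_explained": fit.deviance_explained,
        "sigma_hat": float(np.sqrt(fit.sigma2)) if np.isfinite(fit.sigma2) else np.nan,
        "aic": fit.aic,
        "terms": {},
    }
    for j, nm in enumerate(names):
        out["terms"][nm] = {
            "estimate": float(fit.beta[j]),
            "se": float(fit.se_beta[j]),
            "p_value": float(fit.pvals_beta[j]),
        }
    if fit.basis is not None and fit.smooth_coefs.size and fit.cov_coefs is not None:
        # approximate Wald test on the smooth block (pseudoinverse reference)
        g = fit.smooth_coefs
        V = fit.cov_coefs[p:, p:]
        Vinv = np.linalg.pinv(V, rcond=1e-10)
        stat = float(g @ Vinv @ g)
        df = max(fit.edf_smooth, 1.0)
        out["smooth_term"] = {
            "edf": fit.edf_smooth,
            "wald_stat": stat,
            "p_value_approx": float(stats.chi2.sf(stat, df)),
        }
    return out
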