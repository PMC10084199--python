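"""Thin plate spline radial bases and their low-rank (TPRS) approximation.

A thin plate spline of order ``m`` on ``d``-dimensional locations represents a
smooth surface as a linear combination of radial Green's-function terms
centred at the data points plus a polynomial of total degree below ``m``.  The
wiggliness penalty is the integrated squared ``m``-th derivative of the
surface, which for functions in the natural spline span reduces to a quadratic
form in the radial coefficients.  The low-rank variant used here keeps the
leading eigenvectors of the radial kernel matrix (the construction introduced
by Wood for regression splines), which preserves the dominant low-frequency
spatial patterns while reducing the number of coefficients.

The basis object produced by :func:`build_basis` exposes

``design``
    ``n x k`` model-matrix block for the smooth: ``M`` unpenalised polynomial
    columns followed by ``k - M`` penalised columns.
``penalty``
    ``k x k`` symmetric positive semi-definite penalty with an ``M``
    dimensional null space, scaled so that ``coefs @ penalty @ coefs`` equals
    the thin plate energy of the represented surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, factorial, pi
from itertools import combinations_with_replacement

import numpy as np
from scipy.linalg import null_space
from scipy.special import gamma as gamma_fn

__all__ = [
    "tps_kernel",
    "null_space_dim",
    "SpatialLocations",
    "TPRSBasis",
    "build_basis",
    "build_full_basis",
    "reduce_rank",
    "DegenerateLocationsError",
]


class DegenerateLocationsError(ValueError):
    """Raised when the locations cannot support the requested basis."""


def null_space_dim(m: int, d: int) -> int:
    """Dimension M = C(m+d-1, d) of the polynomial null space."""
    return comb(m + d - 1, d)


def tps_kernel(r, m: int = 2, d: int = 2):
    """Thin plate spline radial Green's function eta_{m,d}(r).

    For even ``d``::

        eta(r) = (-1)^(m+1+d/2) / (2^(2m-1) pi^(d/2) (m-1)! (m-d/2)!) r^(2m-d) log r

    and for odd ``d``::

        eta(r) = Gamma(d/2 - m) / (2^(2m) pi^(d/2) (m-1)!) r^(2m-d).

    Requires ``2m > d`` for the penalty functional to be well defined.
    ``eta(0) = 0`` by convention (the limit for the even-``d`` form).
    """
    if 2 * m <= d:
        raise ValueError(f"thin plate spline requires 2m > d, got m={m}, d={d}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be nonnegative")
    if d % 2 == 0:
        const = ((-1) ** (m + 1 + d // 2)) / (
            2 ** (2 * m - 1) * pi ** (d / 2) * factorial(m - 1) * factorial(m - d // 2)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            out = const * np.where(r > 0, r ** (2 * m - d) * np.log(np.where(r > 0, r, 1.0)), 0.0)
    else:
        const = gamma_fn(d / 2 - m) / (2 ** (2 * m) * pi ** (d / 2) * factorial(m - 1))
        out = const * r ** (2 * m - d)
    return out if out.shape else float(out)


def _poly_powers(m: int, d: int) -> list[tuple[int, ...]]:
    """Exponent tuples of the d-variate monomials of total degree < m."""
    pows = []
    for deg in range(m):
        for c in combinations_with_replacement(range(d), deg):
            p = [0] * d
            for i in c:
                p[i] += 1
            pows.append(tuple(p))
    return pows


def _poly_matrix(coords: np.ndarray, powers) -> np.ndarray:
    T = np.ones((coords.shape[0], len(powers)))
    for j, p in enumerate(powers):
        for axis, e in enumerate(p):
            if e:
                T[:, j] *= coords[:, axis] ** e
    return T


@dataclass
class SpatialLocations:
    """Observation coordinates with duplicate-aware knot bookkeeping.

    Duplicated rows are allowed: the radial kernel is built on the unique
    points (the knots) while the design keeps one row per observation.
    """

    coords: np.ndarray
    knots: np.ndarray = field(init=False)
    knot_index: np.ndarray = field(init=False)

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2:
            raise ValueError("coords must be an n x d array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.coords = coords
        uniq, idx = np.unique(coords, axis=0, return_inverse=True)
        self.knots = uniq
        self.knot_index = idx

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @property
    def n_knots(self) -> int:
        return self.knots.shape[0]

    @property
    def has_duplicates(self) -> bool:
        return self.n_knots < self.n


@dataclass
class TPRSBasis:
    """Reduced-rank thin plate spline basis evaluated at the data locations.

    ``design`` holds the M polynomial columns first, then the k-M penalised
    columns; ``penalty`` is zero on the polynomial block.  ``centered`` marks
    a copy whose constant column was removed and whose remaining columns were
    mean-centred (sum-to-zero constraint, used when the model has its own
    intercept).
    """

    locs: SpatialLocations
    design: np.ndarray
    penalty: np.ndarray
    m: int
    M: int
    k: int
    # evaluation machinery: radial coefficients per penalised column and the
    # monomial exponents of the polynomial block
    _delta: np.ndarray = None
    _powers: list = None
    centered: bool = False
    _col_means: np.ndarray = None

    @property
    def n(self) -> int:
        return self.locs.n

    @property
    def n_penalized(self) -> int:
        return self.design.shape[1] - (self.M - 1 if self.centered else self.M)

    def evaluate(self, coords_new: np.ndarray) -> np.ndarray:
        """Evaluate the basis columns at new locations (rows of the design)."""
        coords_new = np.atleast_2d(np.asarray(coords_new, dtype=float))
        T = _poly_matrix(coords_new, self._powers)
        dist = np.linalg.norm(
            coords_new[:, None, :] - self.locs.knots[None, :, :], axis=2
        )
        E = tps_kernel(dist, self.m, self.locs.d)
        X = np.hstack([T, E @ self._delta])
        if self.centered:
            X = X[:, 1:] - self._col_means
        return X

    def absorb_intercept(self) -> "TPRSBasis":
        """Drop the constant column and centre; for models with an intercept."""
        if self.centered:
            return self
        X = self.design[:, 1:]
        means = X.mean(axis=0)
        return TPRSBasis(
            locs=self.locs,
            design=X - means,
            penalty=self.penalty[1:, 1:],
            m=self.m,
            M=self.M,
            k=self.k,
            _delta=self._delta,
            _powers=self._powers,
            centered=True,
            _col_means=means,
        )

    @property
    def null_dim(self) -> int:
        """Null-space dimension of the penalty in this parameterisation."""
        return self.M - 1 if self.centered else self.M


def build_basis(locs, k: int, m: int = 2) -> TPRSBasis:
    """Construct the rank-``k`` thin plate regression spline basis.

    ``k`` counts the smooth's columns: ``M`` polynomial plus ``k - M``
    penalised columns built from the leading (largest magnitude) eigenvectors
    of the radial kernel matrix over the knots, with the polynomial
    orthogonality side conditions absorbed.  ``k = n_knots + M`` (or any
    ``k >= n_knots``) requests the full natural-spline span, which
    interpolates the knots.
    """
    if not isinstance(locs, SpatialLocations):
        locs = SpatialLocations(locs)
    d = locs.d
    if 2 * m <= d:
        raise ValueError(f"penalty order m={m} too low for d={d}: need 2m > d")
    M = null_space_dim(m, d)
    nu = locs.n_knots
    if nu < M + 1:
        raise DegenerateLocationsError(
            f"need at least M+1={M + 1} distinct locations, got {nu}"
        )
    # k >= nu means "use every kernel eigenvector": the natural spline span.
    q = min(int(k), nu)
    if q <= M:
        raise ValueError(f"basis size k={k} must exceed the null space dimension M={M}")

    powers = _poly_powers(m, d)
    Tk = _poly_matrix(locs.knots, powers)
    if np.linalg.matrix_rank(Tk) < M:
        raise DegenerateLocationsError(
            "locations are collinear/degenerate: polynomial block is rank deficient"
        )
    dist = np.linalg.norm(locs.knots[:, None, :] - locs.knots[None, :, :], axis=2)
    E = tps_kernel(dist, m, d)
    E = 0.5 * (E + E.T)

    evals, evecs = np.linalg.eigh(E)
    order = np.argsort(-np.abs(evals))[:q]
    Dq = evals[order]
    Uq = evecs[:, order]

    # absorb the side conditions T' delta = 0 within the retained eigen-space
    Z = null_space(Tk.T @ Uq)
    if Z.shape[1] != q - M:
        raise DegenerateLocationsError("side-condition absorption failed (degenerate kernel)")
    Xp_knots = Uq @ (Dq[:, None] * Z)  # = E Uq Z
    P = Z.T @ (Dq[:, None] * Z)
    P = 0.5 * (P + P.T)
    delta = Uq @ Z  # radial coefficients per penalised column

    idx = locs.knot_index
    Xp = Xp_knots[idx]
    Trows = Tk[idx]

    # rescale penalised columns to unit norm (pure reparameterisation; the
    # penalty quadratic form of any represented surface is unchanged)
    scale = np.linalg.norm(Xp, axis=0)
    if np.any(scale == 0):
        raise DegenerateLocationsError("zero penalised basis column (degenerate kernel)")
    Xp = Xp / scale
    P = P / np.outer(scale, scale)
    delta = delta / scale

    k_out = M + (q - M)
    design = np.hstack([Trows, Xp])
    penalty = np.zeros((k_out, k_out))
    penalty[M:, M:] = P
    return TPRSBasis(
        locs=locs,
        design=design,
        penalty=penalty,
        m=m,
        M=M,
        k=k_out,
        _delta=delta,
        _powers=powers,
    )


def build_full_basis(locs, m: int = 2) -> TPRSBasis:
    """Full-rank natural thin plate spline basis (interpolating at the knots)."""
    if not isinstance(locs, SpatialLocations):
        locs = SpatialLocations(locs)
    return build_basis(locs, k=locs.n_knots + null_space_dim(m, locs.d), m=m)


def reduce_rank(full: TPRSBasis, k: int) -> TPRSBasis:
    """Rank-``k`` basis over the same locations (recomputed eigen-truncation)."""
    if k <= full.M:
        raise ValueError(f"k={k} leaves no penalised part (M={full.M})")
    if k > full.locs.n_knots + full.M:
        raise ValueError("k exceeds the natural basis dimension")
    return build_basis(full.locs, k=k, m=full.m)
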