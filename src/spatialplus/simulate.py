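"""Synthetic spatially confounded data: Gaussian random fields on a lattice.

The generator emulates a study design in which a covariate shares its spatial
pattern with the residual spatial effect, the situation in which spatial
confounding arises.  Two independent mean-zero Gaussian random fields are
drawn at n locations sampled from a regular grid over [0, extent]^2:

* ``z``  with exponential correlation  C(h) = exp(-(h/R)^p), R = 5, p = 1;
* ``z'`` with spherical correlation    C(h) = 1 - 1.5 h/R + 0.5 (h/R)^3 for
  h <= R (0 beyond), R = 1.

Both fields are replaced by the fitted values of a GCV-smoothed thin plate
regression spline so they lie exactly in the spatial-basis span used by the
fitted models.  Data are then built as

    x = 0.5 z + eps_x,            eps_x ~ N(0, sigma_x^2 I),  sigma_x = 0.1
    eta = beta x + f,             f = -z - z',  beta = 3
    Gaussian: y = eta + eps_y,    eps_y ~ N(0, sigma_y^2 I),  sigma_y = 1
    GLM:      y_i ~ family with mean g^{-1}(eta_i)

so x and f are negatively correlated through z, sigma_x is small (near
collinear model matrix) and sigma_y comparatively large (encouraging
smoothing) — the regime where spatial confounding bias is expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import linalg

from .basis import SpatialLocations, build_basis, null_space_dim
from .penalized import select_lambda

__all__ = [
    "CovarianceSpec",
    "SimConfig",
    "SimReplicate",
    "PRESETS",
    "covariance_matrix",
    "sample_locations",
    "sample_field",
    "smooth_project",
    "generate_replicate",
]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


@dataclass(frozen=True)
class CovarianceSpec:
    """Isotropic correlation function: exponential exp(-(h/R)^p) or spherical."""

    kind: str = "exponential"
    R: float = 5.0
    p: float = 1.0

    def __post_init__(self):
        if self.kind not in ("exponential", "spherical"):
            raise ValueError("kind must be 'exponential' or 'spherical'")
        if self.R <= 0 or self.p <= 0:
            raise ValueError("range R and power p must be positive")

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        if self.kind == "exponential":
            return np.exp(-((h / self.R) ** self.p))
        u = h / self.R
        return np.where(u <= 1.0, 1.0 - 1.5 * u + 0.5 * u**3, 0.0)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the defaults are the study conditions."""

    n: int = 1000
    grid: int = 50
    extent: float = 10.0
    beta: float = 3.0
    sigma_x: float = 0.1
    sigma_y: float = 1.0
    k: int = 300
    family: str = "gaussian"
    n_bin: int = 10
    cov_z: CovarianceSpec = field(default_factory=CovarianceSpec)
    cov_zprime: CovarianceSpec = field(
        default_factory=lambda: CovarianceSpec(kind="spherical", R=1.0)
    )
    fixed_fields: bool = False       # reuse fields/locations across replicates
    resample_locations: bool = True  # new locations each replicate


# moderate-sample presets used for desk-scale runs of the study
PRESETS = {
    "default": SimConfig(),
    "n300": SimConfig(n=300, grid=50, k=100),
    "n150": SimConfig(n=150, grid=50, k=100),
    "n50": SimConfig(n=50, grid=50, k=30),
}


@dataclass
class SimReplicate:
    """One simulated dataset with its generative ground truth."""

    locs: SpatialLocations
    z: np.ndarray
    zprime: np.ndarray
    f_true: np.ndarray
    x: np.ndarray
    y: np.ndarray
    beta_true: float
    family: str
    seed: int
    eps_x: np.ndarray = None
    eps_y: np.ndarray = None
    config: SimConfig = None

    @property
    def eta_true(self) -> np.ndarray:
        return self.beta_true * self.x + self.f_true


def covariance_matrix(locs, spec: CovarianceSpec) -> np.ndarray:
    """Pairwise correlation matrix C(||t_i - t_j||); unit diagonal."""
    coords = locs.coords if isinstance(locs, SpatialLocations) else np.asarray(locs, float)
    h = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    return spec(h)


def sample_locations(n, grid=50, extent=10.0, seed=None):
    """n distinct cells drawn uniformly without replacement from a grid."""
    if n > grid**2:
        raise ValueError(f"cannot place n={n} distinct points on a {grid}x{grid} grid")
    rng = np.random.default_rng(seed)
    cells = rng.choice(grid**2, size=n, replace=False)
    step = extent / grid
    # cell centres of the lattice over [0, extent]^2
    xs = (cells % grid + 0.5) * step
    ys = (cells // grid + 0.5) * step
    return SpatialLocations(np.column_stack([xs, ys]))


def sample_field(locs, spec: CovarianceSpec, seed=None) -> np.ndarray:
    """One mean-zero Gaussian field draw via Cholesky with a jitter ladder."""
    C = covariance_matrix(locs, spec)
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(C.shape[0])
    for jit in _JITTERS:
        try:
            L = linalg.cholesky(C + jit * np.eye(C.shape[0]), lower=True)
            return L @ u
        except linalg.LinAlgError:
            continue
    raise linalg.LinAlgError(
        "covariance matrix not positive definite even after jitter 1e-6"
    )


def smooth_project(field, locs, k, m=2) -> np.ndarray:
    """GCV-smoothed TPRS fitted values: projects a field into the basis span."""
    if not isinstance(locs, SpatialLocations):
        locs = SpatialLocations(locs)
    k = min(k, locs.n_knots + null_space_dim(m, locs.d))
    basis = build_basis(locs, k=k, m=m)
    ones = np.ones((locs.n, 1))
    fit = select_lambda(np.asarray(field, float), ones, basis.absorb_intercept())
    return fit.fitted


def generate_replicate(config: SimConfig = None, seed: int = 0, _cache={}) -> SimReplicate:
    """Draw one replicate of (locations, fields, covariate, response).

    Everything is deterministic given ``(config, seed)``.  With
    ``fixed_fields=True`` the locations and smoothed fields are generated
    once (from the seed floor of the cache key) and shared across seeds,
    mirroring a fixed-field variant of the study.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    loc_seed, z_seed, zp_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 3))

    if config.fixed_fields:
        key = (config.n, config.grid, config.extent, config.k,
               config.cov_z, config.cov_zprime)
        if key not in _cache:
            locs = sample_locations(config.n, config.grid, config.extent, seed=0)
            z = smooth_project(sample_field(locs, config.cov_z, seed=1), locs, config.k)
            zp = smooth_project(
                sample_field(locs, config.cov_zprime, seed=2), locs, config.k
            )
            _cache[key] = (locs, z, zp)
        locs, z, zp = _cache[key]
    else:
        locs = sample_locations(config.n, config.grid, config.extent, seed=loc_seed)
        z = smooth_project(sample_field(locs, config.cov_z, seed=z_seed), locs, config.k)
        zp = smooth_project(
            sample_field(locs, config.cov_zprime, seed=zp_seed), locs, config.k
        )

    f = -z - zp
    eps_x = config.sigma_x * rng.standard_normal(config.n)
    x = 0.5 * z + eps_x
    eta = config.beta * x + f

    fam = config.family.lower()
    eps_y = None
    if fam == "gaussian":
        eps_y = config.sigma_y * rng.standard_normal(config.n)
        y = eta + eps_y
    elif fam == "poisson":
        y = rng.poisson(np.exp(eta)).astype(float)
    elif fam == "exponential":
        y = rng.exponential(np.exp(eta))
    elif fam == "binomial":
        mu = config.n_bin / (1.0 + np.exp(-eta))
        y = rng.binomial(config.n_bin, mu / config.n_bin).astype(float)
    else:
        raise ValueError(f"unknown family '{config.family}'")

    return SimReplicate(
        locs=locs,
        z=z,
        zprime=zp,
        f_true=f,
        x=x,
        y=y,
        beta_true=config.beta,
        family=fam,
        seed=seed,
        eps_x=eps_x,
        eps_y=eps_y,
        config=config,
    )
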