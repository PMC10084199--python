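# Methods

This note documents the models, algorithms and numerical choices behind
`spatialplus`, in enough detail to judge what the tests do and do not
establish.

## Partial thin plate spline model

The spatial model is $y_i = \beta^\top x_i + f(t_i) + \varepsilon_i$ with
$f$ a thin plate spline of order $m$ over locations $t_i \in \mathbb{R}^d$
($m=2$, $d=2$ throughout unless stated). The estimate minimizes

$$\lVert \sqrt{W}(y - X\beta - f)\rVert^2 + n\lambda\, J_m(f),$$

where $J_m$ is the integrated squared $m$-th derivative and $W$ optional
(working) weights. Note the **$n\lambda$ convention**: the public smoothing
parameter multiplies $n$ times the thin plate energy. Other software scales
the penalty differently (often normalizing the penalty matrix), so numeric
$\lambda$ values are not transferable across packages even when the
selected fits coincide.

### Basis construction (reduced rank)

The natural spline span is $f(t) = \sum_j \delta_j \eta(\lVert t - t_j
\rVert) + \text{poly}_{<m}(t)$ with side conditions $T^\top\delta = 0$,
where $\eta_{2,2}(r) = r^2 \log r / (8\pi)$ and $T$ holds the $M =
\binom{m+d-1}{d}$ monomials of degree below $m$ ($M=3$: constant, two
linear terms). The reduced-rank basis retains the $k$ eigenvectors of the
radial kernel matrix $E$ with largest absolute eigenvalue, absorbs the $M$
side conditions inside that eigen-space, and exposes

* a design block of $M$ polynomial plus $k-M$ penalized columns, and
* a $k \times k$ penalty, zero on the polynomial block and positive
  semi-definite with exactly $M$ zero eigenvalues.

`k` therefore counts the smooth's columns; requesting `k >= n_knots` gives
the full natural-spline span, which interpolates distinct locations at
$\lambda = 0$. Penalized columns are rescaled to unit norm (a pure
reparameterization — penalty transformed consistently) to keep the design
well conditioned across the $\lambda$ grid. Duplicate locations are
deduplicated for the kernel ("knots") while the design keeps one row per
observation. When the enclosing model supplies an intercept the constant
column is dropped and the remaining smooth columns are mean-centred
(sum-to-zero constraint), leaving a penalty null space of dimension $M-1$.

This construction was validated against an independent implementation of
the same reduced-rank family (mgcv's thin plate regression splines):
unpenalized slope estimates agree to ~10 decimal places and GCV-selected
fits to several decimals, confirming span-for-span equivalence.

### Solving and smoothness selection

The penalized weighted least-squares problem is solved by QR factorization
of the augmented matrix $[\sqrt{W}A ;\ \sqrt{n\lambda}\,L^\top]$ with
$P = LL^\top$ an eigen square root of the penalty. The augmented form is
used deliberately: forming normal equations squares the condition number,
and with the extreme working weights that arise in exponential-family
fitting the resulting coefficient error is large enough to break the IRLS
iteration (steps stop being descent directions). Effective degrees of
freedom come from the same factorization,
$\mathrm{EDF} = \lVert \sqrt{W}A R^{-1}\rVert_F^2$, with per-term EDF from
the diagonal of $R^{-1}(G^\top \sqrt{W}A)$.

$\lambda$ minimizes $\mathrm{GCV}(\lambda) = n\,\mathrm{RSS}_w /
(n - \mathrm{EDF})^2$ (no inflation factor) over a deterministic 40-point
grid on $\log_{10}\lambda \in [-8, 8]$ followed by golden-section
refinement of the bracketing interval; there are no random restarts, so
selection is exactly reproducible. A flat profile triggers a warning and
returns the boundary.

### Summaries

$\hat\sigma^2 = \mathrm{RSS}/(n-\mathrm{EDF})$; parametric standard errors
use the Bayesian covariance $(A^\top WA + n\lambda P)^{-1}\hat\sigma^2$
with a $t(n-\mathrm{EDF})$ reference for Gaussian fits and fixed-dispersion
normal reference for Poisson/binomial/exponential. Gaussian AIC is the
conditional form $n\log(\mathrm{RSS}/n) + 2(\mathrm{EDF}+1)$, counting EDF
as parameters plus one for the scale — AIC conventions differ across
software by additive constants and EDF definitions, so cross-package AIC
comparisons are only loose. The smooth-term test reported by
`summarize_fit` is a plain Wald quadratic form on the penalized block with
a $\chi^2_{\mathrm{EDF}}$ reference; it is labelled approximate and should
not be used for borderline decisions.

## Exponential families and PIRLS

Supported families: Gaussian/identity; Poisson/log; **exponential** —
implemented exactly as the gamma family with shape fixed at 1 ($V(\mu) =
\mu^2$, dispersion 1) and log link, which is the exponential distribution;
binomial counts with known size $n_{\mathrm{bin}}$ (default 10) on the
count-mean logit $g(\mu) = \log(\mu/(n_{\mathrm{bin}}-\mu))$, $V(\mu) =
\mu(n_{\mathrm{bin}}-\mu)/n_{\mathrm{bin}}$.

Penalized IRLS iterates weighted penalized least squares on the working
response $z = \eta + (y-\mu)g'(\mu)$ with weights $1/(V(\mu)g'(\mu)^2)$.
When $\lambda$ is estimated, GCV is minimized on each working model
(performance iteration). Numerical safeguards:

* initialization $\mu^0 = y + 0.5$ for counts, clamped for binomial;
* the first step is always taken in full — the initialization is closer to
  saturation than any model fit, so an initial deviance rise is expected;
* thereafter, step halving (up to 30 halvings) when the deviance worsens;
* convergence when the relative deviance change falls below $10^{-9}$ *or*
  the linear predictor reaches a fixed point (max change $< 10^{-7}$
  relative) — with per-iteration GCV reselection the deviance retains a
  tiny oscillation at the reselection tolerance that the pure deviance
  criterion never crosses;
* $|\eta| > 25$ anywhere is treated as divergence to a mean-space boundary
  (e.g. complete separation with all-zero binomial counts) and raises a
  clean error rather than returning a boundary fit.

At convergence the working weights $W$ and pseudodata $z$ are returned;
the generalized spatial+ construction residualizes the covariates in the
$W$-weighted inner product, with $W$ frozen from the preliminary spatial
fit (no re-iteration of the weights after residualization).

## The five estimators

All include an intercept. For the simulation generator the generative
model has none; the fitted intercept simply absorbs ≈0.

* **null** — (G)LM of $y$ on covariates only.
* **spatial** — partial spline fit, $\lambda$ by GCV or fixed.
* **RSR** — the whole smooth block $B$ is replaced by $(I-Q(Q^\top
  Q)^{-1}Q^\top)B$ with $Q = [1, X]$, penalty unchanged. The projection is
  Euclidean and is reused unchanged inside PIRLS for non-Gaussian
  responses (a documented convention; a working-weighted generalized
  projection would be equally defensible). Gaussian slope equals the null
  slope exactly for every $\lambda$; out-of-sample prediction is undefined
  (the projected basis is tied to the training covariates) and raises.
* **gSEM** — stage 1: intercept + spatial smooth (GCV) fitted to $y$ and
  to each covariate; stage 2: OLS of the $y$-residuals on the covariate
  residuals with no intercept (both sides are smooth-fit residuals, hence
  centred; an intercept changes nothing testable). Composed fitted values
  $\hat f_y + \hat r_y$ are recorded for fitted-value comparisons.
  Gaussian only — there is no clear generalization of the residual
  response to other families.
* **spatial+** — each covariate residualized *separately* against space
  (multi-covariate models residualize one at a time, matching the
  construction used in multi-predictor applications), then the spatial
  model fitted on the residualized covariates. The first stage warns when
  it explains > 99% of a covariate's deviance (a fully spatial covariate
  leaves nothing to identify the slope) and errors when the residuals are
  numerically zero.

Structural identities maintained by construction and enforced in tests:
with $\lambda = \lambda_x = 0$ and a reduced-rank basis, spatial, gSEM and
spatial+ return the same slope and the same fitted values; spatial+ and
spatial share their model-matrix column space for every $\lambda_x$; RSR
shares the spatial model's column space, hence its fitted values at
matched $\lambda$.

## Synthetic data generator

The generator emulates a spatially confounded survey: $n$ locations
sampled without replacement from a `grid`×`grid` lattice over
$[0,\text{extent}]^2$ (defaults 50×50 over $[0,10]^2$); two independent
mean-zero unit-variance Gaussian random fields — $z$ with exponential
correlation $\exp(-(h/R)^p)$, $R=5$, $p=1$, and $z'$ with spherical
correlation, $R=1$ — each replaced by its GCV-smoothed thin plate fit so
the truth lies in the model basis span; then

$$x = 0.5z + \varepsilon_x,\quad \sigma_x = 0.1; \qquad
\eta = \beta x + f,\quad f = -z-z',\ \beta = 3;$$

Gaussian responses add $\varepsilon_y$ with $\sigma_y = 1$; GLM responses
are sampled with mean $g^{-1}(\eta)$. The spherical correlation uses the
standard form $1 - 1.5h/R + 0.5(h/R)^3$ for $h \le R$ (any correlation
function must satisfy $C(0)=1$). Sampling uses Cholesky with a jitter
ladder ($0, 10^{-10}, 10^{-8}, 10^{-6}$).
Fields and locations are redrawn each replicate by default (a
`fixed_fields` flag shares one draw across replicates); everything is
deterministic given `(config, seed)`.

The regime is deliberate: $\sigma_x$ small makes the model matrix nearly
collinear, $\sigma_y$ comparatively large encourages smoothing — exactly
when spatial confounding bias appears. What the generator does **not**
emulate: anisotropy or non-stationarity, covariate measurement error,
non-smooth (e.g. discontinuous) spatial structure, irregular survey
designs, or spatial correlation in the response noise beyond $f$. Passing
tests therefore demonstrate the estimator's behavior under smooth,
isotropic, basis-representable spatial truth, not robustness to
misspecified spatial structure.

## Study metrics

Per replicate and estimator the study records the slope and the squared
distance of fitted values from the true mean $\beta x + f$ (for gSEM, the
composed $\hat f_y + \hat r_y$). For exponential-family studies the
comparison is on the **linear-predictor scale** ($\hat\eta$ vs
$\beta x + f$), which keeps the truth directly comparable across families;
this choice is recorded in the study's output metadata. The
bias–variance decomposition diagnostic computes, for a linear smoother
$S_\lambda$ and known truth, $B^2 = \lVert (S-I)f\rVert^2/n$ and $V =
\sigma^2\,\mathrm{tr}(SS^\top)/n$ from the dense smoother matrix (small-n
use only).

## Problem sizes and defaults

The generator's defaults are the study conditions ($n=1000$, $k=300$, 100
replicates). Replicated test-suite checks and the acceptance script use
the moderate-sample preset $n=300$, $k=100$ (presets at $n=300/150/50$ are
provided for moderate-sample behavior), which exhibits the same bias
ordering with higher per-replicate variance; the GLM recovery checks use
30–40 replicates. Single-replicate slope estimates at this preset have
spread of roughly ±0.8 around their mean, which is why headline
comparisons are always made on replicate averages.

## Known limitations

* Smoothness selection is GCV only (the restricted-likelihood variant is
  reported elsewhere to behave similarly but is not implemented).
* One spatial smooth per model; covariate effects must be linear — the
  residualization argument requires it.
* No uncertainty bands for the reconstructed spatial surface in spatial+.
* The binomial spatial+ slope retains a small finite-sample offset (GLMs
  are only asymptotically unbiased; the effective parameter count here is
  large), clearly smaller than the spatial model's smoothing bias.
* RSR and gSEM are provided as comparators at the fidelity the comparison
  needs, not as production estimators (no prediction API).
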