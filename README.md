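# spatialplus

Covariate-effect estimation in spatial regression that is robust to
**spatial confounding** — the bias that arises when a spatial smooth
competes with spatially structured covariates for the same signal.

## The problem

A spatial regression ("partial thin plate spline model") for observations
at locations $t_1,\dots,t_n$ is

$$y_i = \beta x_i + f(t_i) + \varepsilon_i, \qquad \varepsilon_i \sim N(0,\sigma^2),$$

fitted by minimizing $\lVert y - \beta x - f \rVert^2 + n\lambda\, J(f)$
where $J$ is the thin plate wiggliness penalty and $\lambda$ is chosen by
GCV. Without the penalty the estimates are unbiased, but penalization
shrinks the spatial term, and when the covariate $x$ is itself spatially
structured the shrinkage leaks spatial signal into $\hat\beta$: the effect
estimate can be badly biased even though the model "controls for space".

**Spatial+** removes this sensitivity for covariates that are spatially
dependent but not fully determined by location. First regress space out of
the covariate, $x = \hat f_x + r_x$ with $\hat f_x = S_{\lambda_x} x$ a
GCV-smoothed thin plate fit; then fit the spatial model with $r_x$ in
place of $x$:

$$y_i = \beta r^x_i + f^+(t_i) + \varepsilon_i .$$

This is a pure reparameterization — same response, same model-matrix
column space, so fitted values and model-selection criteria are unchanged
— but the slope now rides on the nonspatial part of the covariate and is
largely decorrelated from the smooth, so spatial smoothing no longer
biases it. The construction extends to exponential-family responses via
penalized IRLS, with the covariate residualized in the working-weight
inner product of a preliminary spatial fit.

The package also implements the comparator estimators used to study the
phenomenon: the **null** model (no spatial term), the **spatial** model,
**RSR** (restricted spatial regression: spatial basis projected off the
covariates; preserves the null slope by construction), and the **gSEM**
(regress spatial residuals of $y$ on spatial residuals of $x$; Gaussian
only), plus a Gaussian-random-field simulation suite that reproduces the
spatially confounded study design.

## Worked example

```python
import numpy as np
from spatialplus import SimConfig, SpatialPlusRegressor, SpatialRegressor, generate_replicate

rep = generate_replicate(SimConfig(n=300, grid=50, k=100), seed=5)   # true slope = 3
X = np.hstack([rep.locs.coords, rep.x[:, None]])                      # [coords | covariate]

spatial = SpatialRegressor(k=100).fit(X, rep.y)
splus   = SpatialPlusRegressor(k=100).fit(X, rep.y)
print(f"spatial  beta = {spatial.coef_[0]:.3f}  (edf {spatial.edf_smooth_:.1f})")
print(f"spatial+ beta = {splus.coef_[0]:.3f}  (edf {splus.edf_smooth_:.1f})")
```

prints

```
spatial  beta = 2.123  (edf 53.8)
spatial+ beta = 3.099  (edf 55.5)
```

On this draw the covariate shares its spatial pattern with the residual
spatial effect (negatively correlated, $\sigma_x = 0.1$), so the smoothed
spatial model is biased well below the generative slope 3 while spatial+
recovers it; both models use essentially the same amount of spatial
smoothing. Estimators follow the scikit-learn API (`fit`, `predict`,
`get_params`, fitted attributes `coef_`, `se_`, `pvalues_`, `lambda_`,
`edf_smooth_`, …) and compose with sklearn tooling; `fit_null`,
`fit_spatial`, `fit_rsr`, `fit_gsem`, `fit_spatialplus` are functional
shortcuts. A `spatialplus` command-line tool wraps the library
(`simulate`, `study`, `fit`, `application` subcommands) for CSV-based
workflows; see `spatialplus --help`.

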