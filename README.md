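# arealepi

Spatial analysis of small-area (areal) mortality for epidemiologists
working with administrative-unit maps: who dies where, is the pattern
spatially clustered, and which municipal characteristics — here tobacco
production, a composite development index, diagnostic-exam coverage and
accessibility to specialized care — move the rate, globally and
locally.

The package provides, as composable scikit-learn-style estimators with
a thin CLI on top:

- **Queen contiguity weights** over polygon layers (binary or
  row-standardized), with island handling and a plain-text exchange
  format;
- **Rates**: crude mortality per 100,000 person-years of the 40+
  population (or direct age standardization), exam rates per 1,000
  aged 15+, and Marshall *local empirical Bayes* smoothing, which
  shrinks each unit's crude rate toward its queen-neighborhood rate
  with weight κ_i = a_i/(a_i + m_i/P_i);
- **Spatial autocorrelation**: global Moran's
  I = (n/S0)·Σ w_ij z_i z_j / Σ z_i² with permutation inference, and
  local Moran (LISA) with conditional permutation, classifying units
  into high-high (hot spot), low-low (cold spot) and HL/LH outliers;
- **Accessibility**: the two-step floating catchment area index
  (2SFCA) — step 1, provider-to-reachable-population ratios
  R_j = S_j/ΣP_i within a 60 km catchment; step 2, A_i = Σ R_j over
  reachable providers;
- **Spatial regression**: OLS with condition-number and residual-Moran
  diagnostics, |t| > 1.96 variable screening, then geographically
  weighted regression (GWR, adaptive bisquare kernel, AICc-optimal
  bandwidth by golden-section search) and a model-comparison report
  (AIC/AICc, adjusted R², residual sum of squares, residual Moran's I);
- **A synthetic-municipality generator** — Voronoi maps, Poisson
  deaths over a SAR-correlated log-rate surface, covariates with known
  (optionally spatially varying) effects, clustered providers — with
  stored ground truth, so the whole chain is testable end to end with
  no external data.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
import numpy as np, pandas as pd
from arealepi import (SyntheticConfig, generate_dataset, queen_weights,
                      mortality_rate, eb_smooth_spatial, global_moran,
                      local_moran, exam_rate, SpatialOLS, GWR,
                      screen_variables, compare_models)

cfg = SyntheticConfig(n_units=200, seed=7, spatial_rho=0.9, varying_coeff=True)
ds = generate_dataset(cfg)

wb = queen_weights(ds.areas, mode="binary")
wr = wb.to_mode("row_standardized")
rates = eb_smooth_spatial(mortality_rate(ds.areas, period=5.0), wb)
y = rates["smoothed_rate"].to_numpy()

m = global_moran(y, wr, n_perm=999, seed=1)
print(f"global Moran's I = {m.I_:.3f} (E[I] = {m.expected_I_:.4f}, "
      f"pseudo p = {m.p_sim_:.3f})")

l = local_moran(y, wr, n_perm=999, alpha=0.05, seed=1)
lab = pd.Series(l.labels_).value_counts()
print(f"LISA: {lab.get('hot_spot', 0)} hot spots, {lab.get('cold_spot', 0)} cold spots")

X = pd.DataFrame({"tpr": ds.areas.tpr, "exam_rate": exam_rate(ds.areas),
                  "access": ds.areas.access, "ipdm": ds.areas.ipdm})
ols = SpatialOLS(weights=wr, seed=1).fit(X, y)
print(ols.summary_frame().round(3))
sel = screen_variables(ols)          # covariates with |t| > 1.96
coords = np.array([[g.centroid.x, g.centroid.y] for g in ds.areas.geometry])
gwr = GWR(weights=wr, seed=1).fit(X[sel], y, coords)
rep = compare_models(SpatialOLS(weights=wr, seed=1).fit(X[sel], y), gwr)
print(rep.summary.round(3))
print("verdict:", rep.verdict, f"(adaptive bandwidth = {gwr.bandwidth_:.0f} neighbors)")
```

Output:

```
global Moran's I = 0.545 (E[I] = -0.0050, pseudo p = 0.001)
LISA: 21 hot spots, 27 cold spots
           Coefficient     SD  t-value  p-value
Constant        58.845  6.514    9.034    0.000
tpr              0.110  0.044    2.497    0.013
exam_rate       -1.093  0.557   -1.961    0.051
access           7.020  0.932    7.530    0.000
ipdm           -21.767  8.489   -2.564    0.011
                               OLS        GWR
AIC                       1778.105   1676.522
Adjusted R²                  0.259      0.670
Sum of residual squares  80094.764  28531.214
Moran's I (residual)         0.503      0.233
verdict: local (adaptive bandwidth = 50 neighbors)
```

Reading it: the smoothed mortality surface is strongly and
significantly clustered (I = 0.545 against an expectation of ≈ 0, the
smallest attainable pseudo p at 999 permutations), with contiguous
hot- and cold-spot clusters. All four covariates clear the ±1.96
screening; tobacco production and accessibility raise recorded
mortality while exam coverage and the development index lower it —
the directions planted by the generator. GWR beats OLS on every
criterion (lower AICc, adjusted R² 0.26 → 0.67, residual
autocorrelation 0.50 → 0.23), as expected when the true
tobacco-production coefficient varies across the map.

The same run, end to end with file artifacts (rates CSV, cluster and
coefficient-surface GeoJSON, model report, manifest):

```bash
arealepi run -c config.yaml     # see `arealepi --help` for per-stage commands
```

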