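# Methods

`arealepi` implements the standard analysis chain for areal (choropleth)
epidemiology of small-area mortality: contiguity weights, rate
construction with empirical Bayes smoothing, global/local spatial
autocorrelation with permutation inference, a floating-catchment
accessibility index, and global-vs-local spatial regression. This note
records the models, conventions, numerical choices and limitations.

## Data model

An *area table* is a pandas DataFrame with one row per administrative
unit: a `unit_id`, a shapely polygon in a metric (projected, meters)
CRS, populations (`pop_total`, `pop_40plus`, `pop_15plus`, with
15+ ⊇ 40+), event counts (`deaths`), and covariates (`tpr` in
tons/hectare, `ipdm` in [0, 1], `exam_count`, `access`). Provider
tables carry point locations and positive integer capacities
(registered services per site). Layers in geographic degrees can be
reprojected on read by a built-in WGS84 UTM forward projection
(validated against a haversine oracle to 0.5%).

## Queen contiguity weights

Two units are neighbors iff their polygons share at least one boundary
point (edge or vertex). The predicate is exact (`intersects` on the
STRtree candidates); an optional snapping buffer (default 0 m) absorbs
imperfect digitization. Binary weights (w_ij ∈ {0, 1}) are used for
empirical-Bayes neighborhoods; row-standardized weights (rows sum to 1)
are the default for Moran, LISA and residual diagnostics — both are
explicit parameters everywhere. Units with no neighbors ("islands")
stay in the table, are flagged, get missing spatial lags, and are
excluded from permutation pools; dropping them would corrupt rate
denominators downstream.

## Rates and empirical Bayes smoothing

The crude mortality rate is events per person-year of the 40+
population, reported per 100,000: `r_i = deaths_i / (pop40_i · period)
× 1e5`. Restricting the denominator to the 40+ population is the
default age adjustment; direct standardization over age bands with
user-supplied standard weights is available as an alternative.

Small-area rates are unstable, so the outcome (never the covariates) is
smoothed with the Marshall *local* ("spatial") empirical Bayes
estimator: for each unit the reference set is the unit plus its queen
neighbors; the neighborhood rate m_i and its population-weighted
variance s²_i give a prior variance a_i = max(0, s²_i − m_i/P̄_i) and a
shrinkage weight κ_i = a_i / (a_i + m_i/P_i). The smoothed rate
κ_i r_i + (1−κ_i) m_i always lies between the crude and neighborhood
rates; populous units keep their crude rate, sparse units borrow
strength. Islands shrink to themselves (smoothed = crude). When both
the prior variance and the noise term vanish (an all-zero
neighborhood), κ is set to 1, which leaves the crude rate unchanged.

By default the smoothed rate is the dependent variable of the
downstream analysis (consistent with mapping smoothed rates); a config
flag switches to crude.

## Global and local Moran

Global Moran's I = (n/S0) · Σ_ij w_ij z_i z_j / Σ_i z_i² with
z = x − x̄ and S0 the total weight. Inference is by random relabelling
(default 999 permutations, explicit seed): the two-sided pseudo
p-value counts permuted statistics at least as far from
E[I] = −1/(n−1) as the observed one, p = (1 + exceedances)/(1 + n_perm)
≥ 1/(n_perm+1). No normal-approximation inference is used. The
statistic is not clamped to [−1, 1]: its true bounds depend on the
weights' eigenstructure (the 2×2 checkerboard under rook weights
attains exactly −1).

Local Moran I_i = (z_i/m₂) Σ_j w_ij z_j with m₂ = Σ z²/n; with
row-standardized weights Σ_i I_i / n equals the global I (checked to
1e-10). Inference is conditional permutation: z_i is held fixed and its
neighbor values are drawn without replacement from the other n−1
observations. Because queen rows have equal weights within a row, the
permuted lag is the row weight times the sum of the sampled values;
sampling uses an argpartition of uniform keys (a uniform random
d-subset).

The per-unit pseudo p is **two-sided** by default (twice the smaller
conditional tail, capped at 1), so flagging at α holds the per-unit
false-flag rate at α under spatial randomness — the calibration the
analysis quotes ("significance of 5%"). The direction-matched
one-sided convention of classical desktop LISA software is available
as `alternative="directed"`; note its null flagging rate is ≈ 2α,
which is why it is not the default. Significant units are classified
by the signs of (z_i, lag z_i) into high-high (hot spot), low-low
(cold spot) and high-low/low-high outliers. No multiplicity correction
is applied across units by default, matching common practice in this
literature; a Benjamini–Hochberg mode is available.

## 2SFCA accessibility

Step 1: each provider j gets R_j = S_j / Σ_{d(i,j) ≤ d0} P_i, the
capacity per person it can reach within the catchment radius
(default d0 = 60 km, straight-line centroid-to-provider distance in
the metric CRS). Step 2: A_i = Σ_{d(i,j) ≤ d0} R_j, in service units
per person. Catchments are dichotomous (no distance decay) by default;
a truncated Gaussian decay and a pluggable distance function (or a
precomputed matrix, e.g. network distances) are provided for
sensitivity analysis. Providers reaching no population get R_j = 0
with a warning. The implementation satisfies the conservation identity
Σ_i P_i A_i = Σ_j S_j over providers with nonzero reach, for any
layout (checked to 1e-9); enlarging d0 never shrinks the set of
reached units but can lower individual A_i through larger step-1
denominators.

## OLS, screening, GWR

The global model is OLS with intercept, fitted by least squares.
Diagnostics: coefficient SDs, t and two-sided p-values; the condition
number of the column-scaled design (multicollinearity check); Moran's
I of the residuals under the analysis weights; and

    AIC = n ln(SSR/n) + n ln 2π + n + 2(k + 2)

(full Gaussian likelihood; k covariates + intercept + error variance).
Covariates with |t| strictly above 1.96 are carried into GWR (the
intercept always stays; if nothing passes, the full design is kept and
flagged).

GWR solves a weighted least-squares problem at every unit with kernel
weights around it. The default kernel is adaptive bisquare,
w_ij = (1 − (d_ij/b_i)²)² for d_ij < b_i, where b_i is the distance to
the B-th nearest other unit; a uniform adaptive window (whose full-
bandwidth limit reproduces OLS exactly, checked to 1e-8) and a fixed
Gaussian kernel are alternatives. The neighbor count B is chosen by
golden-section search over [k+2, n−1] minimizing

    AICc = n ln(SSR/n) + n ln 2π + n (n + tr S)/(n − 2 − tr S),

with tr S the trace of the GWR hat matrix (effective parameters);
candidates with singular local designs or tr S ≥ n−2 are discarded as
infeasible. The search assumes a unimodal AICc profile — the bracket
starts at the full feasible range, and all probed candidates are kept
so the returned bandwidth is the best value actually evaluated. Local
coefficient variances use σ̂² = SSR/(n − tr S) times
diag(A⁻¹ XᵀW² X A⁻¹), A = XᵀWX; local fits are solved by Cholesky
factorization. OLS AIC and GWR AICc are on the same likelihood scale
by construction; the comparison report (coefficients, SD, t, p; AIC,
adjusted R², residual sum of squares, residual Moran's I for both
models) declares the local model preferred when AICc(GWR) <
AIC(OLS) − 2. Coefficient-surface maps classify units by the sign of
the local coefficient where |local t| > 1.96.

## Synthetic study region

The generator emulates the data structure of a state-wide ecological
mortality study without any external data. Defaults define the
reference study conditions; they are the generator's design, chosen
once:

- **Map**: 200 Voronoi cells of uniform random seeds in a 500 × 400 km
  frame (mirror-reflection construction, so cells tile the frame
  exactly); irregular queen topology like a real municipality map. A
  square-grid generator exists for hand-checkable oracles. Degenerate
  tessellations are regenerated with fresh points (bounded retries).
- **Populations**: totals uniform in 3,000–40,000 (predominantly small
  municipalities); 40+ share 35–50%, 15+ share 70–80% (≥ the 40+
  count by construction).
- **Latent surface**: annual log-rate λ_i = ln(50) + ρ·u_i +
  Σ_k β_k(s_i)(x_ik − x̄_k), where u is the SAR field
  (I − ρW_row)⁻¹ε standardized to sd 0.3 and ρ = 0.9 by default —
  smoothly clustered mortality with annualized rates spanning roughly
  20–90 per 100,000, the realistic range for lung-cancer mortality in
  a 40+ population. Covariates are centered in the link so the
  baseline (50/100,000/yr) is the rate at average covariates.
- **Deaths**: Poisson with mean pop40 · exp(λ)/1e5 · period over a
  5-year window (≈ 5–60 deaths per unit).
- **Covariates**: tobacco production rate ~ Gamma(2, 25) tons/ha;
  development index ~ U(0.3, 0.9); exam counts from U(1, 10) exams per
  1,000 aged 15+; accessibility computed by the package's own 2SFCA
  from the simulated providers (12 sites at population-weighted
  sampled centroids, capacities 1–6), expressed per 100,000 population
  so typical values are order 1. Planted effects (log-rate units):
  +0.004 per ton/ha, −0.03 per exam/1,000, +0.1 per access unit,
  −0.8 per index unit — each contributing ~0.1–0.15 sd on the log
  scale, i.e. individually detectable but not dominant at n = 200.
- **Spatially varying coefficient** (optional): the tobacco
  coefficient follows a smooth west-east gradient
  β(s) = β_tpr · (−1 + 4·x_norm), spanning −β to +3β and flipping
  sign across the region — mirroring local-coefficient maps in which
  a covariate's association is positive in some areas and negative in
  others. The mean over space equals β_tpr, and the gradient is large
  enough that a correctly working GWR recovers the surface
  (correlation ≈ 0.8–0.95 at n = 200) while a global OLS cannot.
- Ground truth (latent field, per-unit coefficient surfaces, expected
  rates) is stored alongside the table for recovery tests.

What the generator does **not** emulate: realistic age pyramids,
spatio-temporal dynamics, reporting artifacts (underreporting,
boundary changes), network travel distances, or covariate
measurement error. Tests passing on synthetic data therefore
demonstrate the correctness and calibration of the *methods*, not the
epidemiology of any real region.

## Determinism and numerics

Every stochastic step takes an explicit seed (NumPy `default_rng`);
the generator is bit-reproducible (full-table equality) and the full
pipeline writes byte-identical data artifacts across runs with the
same config. Wall-clock timings are written only to `run.log`, which
is not part of the reproducible artifact set. Rates are handled
internally on the per-person scale and reported per 100,000.
Row-standardized rows sum to 1 within 1e-12; Moran statistics match
naive double-loop evaluation within 1e-10; EB smoothing matches direct
formula evaluation within 1e-10; 2SFCA matches a brute-force double
loop exactly.

Problem sizes in the test suite (maps of 30–200 units, 199–999
permutations, 50–200 Monte-Carlo seeds) are chosen so the full
statistical validation — oracle equivalence, analytic limits,
conservation, null calibration and power — runs on a single CPU in
well under half an hour while keeping Monte-Carlo error comfortably
inside the asserted bands.

## Known limitations

- Only first-order queen contiguity; no k-nearest-neighbor,
  distance-band or higher-order weights.
- GWR is Gaussian-response only (no Poisson GWR, no multiscale GWR);
  predictions are available at fitted locations only.
- No spatial lag/error (SAR/CAR maximum-likelihood) regression — the
  global-vs-local comparison is OLS vs GWR.
- The UTM projection covers the forward direction only and assumes
  WGS84; layers spanning several UTM zones are projected into the
  zone of the mean longitude.
- Shapefile I/O is not provided; use GeoJSON.
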