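"""Synthetic municipality maps with known spatial-epidemiological structure.

The generator emulates the kind of areal dataset used in ecological
studies of cancer mortality over a state's municipality map: an
irregular tessellation of a few hundred polygons, heterogeneous
populations, Poisson death counts over several years driven by a
spatially autocorrelated latent rate surface, covariates with known
(optionally spatially varying) effects, and clustered point providers
with service capacities.  Ground truth (latent field, coefficient
surfaces, expected rates) is returned alongside the table so parameter
recovery can be tested downstream.

The latent annual log-rate for unit *i* is

    lambda_i = log(rate_baseline) + rho * u_i + sum_k beta_k(s_i) * (x_ik - mean_k)

where ``u`` is a simultaneous-autoregressive (SAR) Gaussian field
``(I - rho * W_row)^-1 eps`` standardized to sd ``field_sd``, and deaths
are Poisson with mean ``pop40_i * exp(lambda_i) / 100000 * period``.
Covariates are centered in the link so ``rate_baseline`` is the annual
rate per 100,000 of the 40+ population at average covariate values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .weights import queen_weights

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_tessellation",
    "regular_grid",
    "simulate_attributes",
    "generate_dataset",
]

# Planted covariate effects on the annual log-rate scale, per covariate
# unit.  Signs mirror the qualitative epidemiological pattern: tobacco
# production and accessibility raise recorded mortality; development
# index and diagnostic-exam coverage lower it.
DEFAULT_BETA = {
    "tpr": 0.004,        # per ton/hectare
    "exam_rate": -0.03,  # per exam per 1,000 over-15 population
    "access": 0.1,       # per service unit per 100,000 population
    "ipdm": -0.8,        # per index unit in [0, 1]
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study region.

    Defaults describe the reference study conditions: 200 contiguous
    municipalities in a 500 x 400 km frame, a strongly autocorrelated
    (rho = 0.9) mortality surface at 50 annual deaths per 100,000 of the
    40+ population, observed over a 5-year window.
    """

    n_units: int = 200
    seed: int = 0
    rate_baseline: float = 50.0          # annual deaths per 100,000 (40+ pop)
    spatial_rho: float = 0.9             # SAR autocorrelation strength in [0, 1)
    beta_truth: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    varying_coeff: bool = False          # spatially varying tpr coefficient
    varying_range: tuple = (-1.0, 3.0)   # multiplier west -> east (sign-flipping)
    pop_range: tuple = (3_000, 40_000)   # total population per unit
    n_providers: int = 12
    provider_capacity_range: tuple = (1, 6)  # registered services per site
    period_years: float = 5.0
    field_sd: float = 0.3                # sd of the standardized latent field
    frame: tuple = (0.0, 0.0, 500_000.0, 400_000.0)  # metric bounding box
    catchment_m: float = 60_000.0        # 2SFCA radius for the access covariate

    def __post_init__(self) -> None:
        if self.n_units < 4:
            raise ValueError("n_units must be >= 4")
        if not (0.0 <= self.spatial_rho < 1.0):
            raise ValueError("spatial_rho must lie in [0, 1)")
        if self.pop_range[0] <= 0 or self.pop_range[1] < self.pop_range[0]:
            raise ValueError("pop_range must satisfy 0 < min <= max")
        if self.provider_capacity_range[0] <= 0:
            raise ValueError("provider capacities must be positive")
        if self.period_years <= 0:
            raise ValueError("period_years must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_truth"] = dict(self.beta_truth)
        return d


@dataclass
class SyntheticDataset:
    """Areas + providers + ground truth from one generator run."""

    areas: pd.DataFrame
    providers: pd.DataFrame
    truth: dict
    config: SyntheticConfig


def _voronoi_cells(points: np.ndarray, frame: tuple) -> list:
    """Bounded Voronoi cells of ``points`` clipped to ``frame``.

    Mirrors the points across all four frame edges so every original
    cell is finite, then clips to the frame; the cells tile it exactly.
    """
    x0, y0, x1, y1 = frame
    pts = points
    mirrored = np.vstack(
        [
            pts,
            np.column_stack([2 * x0 - pts[:, 0], pts[:, 1]]),
            np.column_stack([2 * x1 - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * y0 - pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * y1 - pts[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    rect = box(x0, y0, x1, y1)
    cells = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            return []  # degenerate; caller retries
        poly = Polygon(vor.vertices[region]).intersection(rect)
        if poly.is_empty or poly.geom_type != "Polygon" or poly.area <= 0:
            return []
        cells.append(poly)
    return cells


def generate_tessellation(config: SyntheticConfig, max_retries: int = 10) -> pd.DataFrame:
    """Tile the frame with ``n_units`` Voronoi cells of uniform random seeds.

    Returns a DataFrame with ``unit_id`` ("M0001", ...) and shapely
    ``geometry`` columns.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    x0, y0, x1, y1 = config.frame
    for _ in range(max_retries):
        pts = np.column_stack(
            [rng.uniform(x0, x1, config.n_units), rng.uniform(y0, y1, config.n_units)]
        )
        cells = _voronoi_cells(pts, config.frame)
        if cells:
            ids = [f"M{i + 1:04d}" for i in range(config.n_units)]
            return pd.DataFrame({"unit_id": ids, "geometry": cells})
    raise RuntimeError(
        f"failed to build a non-degenerate Voronoi tessellation of "
        f"{config.n_units} cells after {max_retries} attempts"
    )


def regular_grid(nx: int, ny: int, cell: float = 10_000.0) -> pd.DataFrame:
    """Square-grid tessellation for hand-checkable contiguity oracles."""
    rows = []
    for j in range(ny):
        for i in range(nx):
            rows.append(
                {
                    "unit_id": f"G{j * nx + i:04d}",
                    "geometry": box(i * cell, j * cell, (i + 1) * cell, (j + 1) * cell),
                }
            )
    return pd.DataFrame(rows)


def _sar_field(rng: np.random.Generator, w_row, rho: float, sd: float) -> np.ndarray:
    """Simultaneous-autoregressive Gaussian field standardized to ``sd``."""
    n = w_row.n
    eps = rng.standard_normal(n)
    if rho == 0.0:
        u = eps
    else:
        A = np.eye(n) - rho * w_row.matrix.toarray()
        u = np.linalg.solve(A, eps)
    s = u.std()
    if s > 0:
        u = (u - u.mean()) / s * sd
    return u


def simulate_attributes(geoms: pd.DataFrame, config: SyntheticConfig):
    """Populate a tessellation with populations, covariates, providers, deaths.

    Returns ``(areas, providers, truth)``.  ``truth`` records the latent
    field, per-unit coefficient surfaces and expected annual rates for
    parameter-recovery tests.
    """
    from .access import two_step_fca  # local import: access is downstream-agnostic

    rng = np.random.default_rng([config.seed, 1])
    n = len(geoms)
    areas = geoms.copy().reset_index(drop=True)

    # populations and age bands: 15+ contains 40+ by construction
    pop_total = rng.integers(config.pop_range[0], config.pop_range[1] + 1, n)
    frac40 = rng.uniform(0.35, 0.50, n)
    frac15 = rng.uniform(0.70, 0.80, n)
    pop40 = np.maximum(1, np.round(pop_total * frac40)).astype(int)
    pop15 = np.maximum(pop40, np.round(pop_total * frac15)).astype(int)
    areas["pop_total"] = pop_total
    areas["pop_40plus"] = pop40
    areas["pop_15plus"] = pop15

    # covariates
    tpr = rng.gamma(shape=2.0, scale=25.0, size=n)           # tons per hectare
    ipdm = rng.uniform(0.3, 0.9, n)                          # composite index
    exam_per_1000 = rng.uniform(1.0, 10.0, n)
    exam_count = np.round(exam_per_1000 * pop15 / 1000.0).astype(int)
    areas["tpr"] = tpr
    areas["ipdm"] = ipdm
    areas["exam_count"] = exam_count

    # clustered providers: population-weighted sample of unit centroids
    k = min(config.n_providers, n)
    prob = pop_total / pop_total.sum()
    sites = rng.choice(n, size=k, replace=False, p=prob)
    centroids = np.array([[g.centroid.x, g.centroid.y] for g in areas["geometry"]])
    providers = pd.DataFrame(
        {
            "provider_id": [f"P{i + 1:03d}" for i in range(k)],
            "x": centroids[sites, 0],
            "y": centroids[sites, 1],
            "capacity": rng.integers(
                config.provider_capacity_range[0],
                config.provider_capacity_range[1] + 1,
                k,
            ),
            "unit_id": areas["unit_id"].to_numpy()[sites],
        }
    )

    # accessibility covariate from the generator's own provider layout,
    # expressed per 100,000 population so typical values are order 1
    access = two_step_fca(areas, providers, d0=config.catchment_m)
    access_scaled = access * 100_000.0
    areas["access"] = access_scaled

    # latent log-rate surface
    w_row = queen_weights(areas, mode="row_standardized")
    u = _sar_field(rng, w_row, config.spatial_rho, config.field_sd)
    exam_rate_real = exam_count / pop15 * 1000.0
    covs = {
        "tpr": tpr,
        "exam_rate": exam_rate_real,
        "access": access_scaled,
        "ipdm": ipdm,
    }
    xnorm = (centroids[:, 0] - centroids[:, 0].min()) / max(
        float(np.ptp(centroids[:, 0])), 1.0
    )
    beta_surfaces = {}
    lam = np.full(n, np.log(config.rate_baseline)) + config.spatial_rho * u
    for name, x in covs.items():
        b = config.beta_truth.get(name, 0.0)
        surface = np.full(n, float(b))
        if config.varying_coeff and name == "tpr":
            lo, hi = config.varying_range
            surface = b * (lo + (hi - lo) * xnorm)
        beta_surfaces[name] = surface
        lam += surface * (x - x.mean())

    mu = pop40 * np.exp(lam) / 100_000.0 * config.period_years
    areas["deaths"] = rng.poisson(mu)

    truth = {
        "beta_truth": dict(config.beta_truth),
        "beta_surfaces": {k_: v.tolist() for k_, v in beta_surfaces.items()},
        "latent_field": u.tolist(),
        "log_rate": lam.tolist(),
        "expected_rate": np.exp(lam).tolist(),
        "covariate_means": {k_: float(v.mean()) for k_, v in covs.items()},
        "seed": config.seed,
    }
    return areas, providers, truth


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Tessellate and simulate in one call."""
    geoms = generate_tessellation(config)
    areas, providers, truth = simulate_attributes(geoms, config)
    return SyntheticDataset(areas=areas, providers=providers, truth=truth, config=config)


def write_truth(truth: dict, config: SyntheticConfig, path) -> None:
    """Sidecar JSON with ground-truth parameters of a generator run."""
    payload = {"config": config.to_dict(), "truth": truth}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
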