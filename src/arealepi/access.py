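"""Two-step floating catchment area (2SFCA) accessibility index.

Step 1: each provider *j* with capacity S_j gets a provider-to-population
ratio R_j = S_j / sum of populations P_i of all demand units whose
centroid lies within the catchment radius d0.  Step 2: each unit sums the
ratios of the providers it can reach: A_i = sum_{j: d(i,j) <= d0} R_j.

The index is in service units per person.  Catchments are dichotomous by
default (no distance decay), with straight-line centroid-to-provider
distance in the metric CRS; an optional Gaussian decay and a pluggable
distance function (or precomputed matrix) are provided for sensitivity
analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = ["TwoStepFCA", "two_step_fca"]


def _centroid_coords(areas: pd.DataFrame) -> np.ndarray:
    return np.array([[g.centroid.x, g.centroid.y] for g in areas["geometry"]])


def _provider_coords(providers: pd.DataFrame) -> np.ndarray:
    if "geometry" in providers.columns:
        return np.array([[p.x, p.y] for p in providers["geometry"]])
    return providers[["x", "y"]].to_numpy(dtype=float)


class TwoStepFCA(BaseEstimator):
    """2SFCA accessibility estimator.

    Parameters
    ----------
    d0 : catchment radius in map units (meters), default 60 km.
    demand : population column used as the step-1 denominator.
    decay : ``None`` for dichotomous catchments (default) or
        ``"gaussian"`` for exp(-0.5 (d / (d0/2))^2) weights truncated at d0.
    distance_fn : optional callable ``(unit_xy, provider_xy) -> (n, m)``
        distance matrix, or a precomputed (n, m) array; defaults to
        Euclidean distance between projected coordinates.

    Attributes (after ``fit``)
    --------------------------
    access_ : (n,) accessibility score per unit, service units per person.
    provider_ratio_ : (m,) step-1 ratio R_j per provider.
    reach_ : (n, m) boolean matrix of which providers serve which units.
    """

    def __init__(self, d0: float = 60_000.0, demand: str = "pop_total",
                 decay=None, distance_fn=None):
        self.d0 = d0
        self.demand = demand
        self.decay = decay
        self.distance_fn = distance_fn

    def fit(self, areas: pd.DataFrame, providers: pd.DataFrame) -> "TwoStepFCA":
        if self.d0 <= 0:
            raise ValueError("catchment radius d0 must be positive")
        pop = areas[self.demand].to_numpy(dtype=float)
        if (pop <= 0).any():
            raise ValueError("demand populations must be positive")
        n = len(areas)
        if len(providers) == 0:
            warnings.warn("no providers: accessibility surface is all zero")
            self.access_ = np.zeros(n)
            self.provider_ratio_ = np.zeros(0)
            self.reach_ = np.zeros((n, 0), dtype=bool)
            return self

        if isinstance(self.distance_fn, np.ndarray):
            d = self.distance_fn
        elif callable(self.distance_fn):
            d = np.asarray(self.distance_fn(_centroid_coords(areas),
                                            _provider_coords(providers)), dtype=float)
        else:
            d = cdist(_centroid_coords(areas), _provider_coords(providers))
        if d.shape != (n, len(providers)):
            raise ValueError(f"distance matrix has shape {d.shape}, expected {(n, len(providers))}")

        within = d <= self.d0
        if self.decay is None:
            g = within.astype(float)
        elif self.decay == "gaussian":
            g = np.where(within, np.exp(-0.5 * (d / (self.d0 / 2.0)) ** 2), 0.0)
        else:
            raise ValueError(f"unknown decay {self.decay!r}")

        cap = providers["capacity"].to_numpy(dtype=float)
        if (cap <= 0).any():
            raise ValueError("provider capacities must be positive")
        denom = g.T @ pop                       # reachable population per provider
        ratio = np.zeros_like(cap)
        served = denom > 0
        ratio[served] = cap[served] / denom[served]
        if (~served).any():
            warnings.warn(
                f"{(~served).sum()} provider(s) reach no population; ratio set to 0"
            )
        self.access_ = g @ ratio
        self.provider_ratio_ = ratio
        self.reach_ = within
        return self

    def fit_transform(self, areas: pd.DataFrame, providers: pd.DataFrame) -> np.ndarray:
        return self.fit(areas, providers).access_


def two_step_fca(areas: pd.DataFrame, providers: pd.DataFrame, d0: float = 60_000.0,
                 demand: str = "pop_total", decay=None, distance_fn=None) -> np.ndarray:
    """Per-unit 2SFCA accessibility scores (service units per person)."""
    return TwoStepFCA(d0=d0, demand=demand, decay=decay,
                      distance_fn=distance_fn).fit_transform(areas, providers)
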