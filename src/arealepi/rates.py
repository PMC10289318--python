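"""Mortality / exam rates and local ("spatial") empirical Bayes smoothing.

Crude mortality rates are events over person-years of the 40+
population, reported per 100,000.  Small-area rates computed from few
events are unstable, so the Marshall local empirical Bayes estimator
shrinks each unit's crude rate toward the rate of its queen
neighborhood (the unit together with its contiguity neighbors), with a
shrinkage weight that grows with the unit's own population: populous
units keep their crude rate, sparse units borrow strength from their
neighbors.  Only the outcome is ever smoothed; covariates are not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .weights import SpatialWeights

__all__ = [
    "mortality_rate",
    "exam_rate",
    "EmpiricalBayesSmoother",
    "eb_smooth_spatial",
]


def mortality_rate(
    areas: pd.DataFrame,
    scale: float = 100_000.0,
    period: float = 1.0,
    events: str = "deaths",
    denom: str = "pop_40plus",
    age_bands: dict | None = None,
    std_weights: dict | None = None,
) -> pd.DataFrame:
    """Crude mortality rate per ``scale`` person-years of the 40+ population.

    crude_rate_i = events_i / (denom_i * period) * scale.  Restriction of
    the denominator to the 40+ population is the default age adjustment.

    Direct standardization is available instead: pass ``age_bands``
    mapping band name -> (events_column, population_column) and
    ``std_weights`` mapping band name -> standard-population weight
    (weights must sum to 1); the rate is then the weighted sum of
    band-specific rates.

    Returns a DataFrame with unit_id, events, denom, crude_rate.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if age_bands is not None:
        if std_weights is None:
            raise ValueError("direct standardization requires std_weights")
        wsum = sum(std_weights.values())
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"standard weights must sum to 1, got {wsum}")
        rate = np.zeros(len(areas))
        ev_total = np.zeros(len(areas))
        den_total = np.zeros(len(areas))
        for band, (ev_col, pop_col) in age_bands.items():
            pop = areas[pop_col].to_numpy(dtype=float)
            _check_denominator(areas, pop, pop_col)
            ev = areas[ev_col].to_numpy(dtype=float)
            rate += std_weights[band] * ev / (pop * period) * scale
            ev_total += ev
            den_total += pop
        return pd.DataFrame(
            {
                "unit_id": areas["unit_id"],
                "events": ev_total,
                "denom": den_total * period,
                "crude_rate": rate,
            }
        )
    pop = areas[denom].to_numpy(dtype=float)
    _check_denominator(areas, pop, denom)
    ev = areas[events].to_numpy(dtype=float)
    if (ev < 0).any():
        raise ValueError("event counts must be non-negative")
    return pd.DataFrame(
        {
            "unit_id": areas["unit_id"],
            "events": ev,
            "denom": pop * period,
            "crude_rate": ev / (pop * period) * scale,
        }
    )


def _check_denominator(areas: pd.DataFrame, pop: np.ndarray, name: str) -> None:
    bad = np.flatnonzero(pop <= 0)
    if bad.size:
        uid = areas["unit_id"].iloc[bad[0]]
        raise ValueError(f"zero/negative denominator {name!r} for unit {uid!r}")


def exam_rate(areas: pd.DataFrame, exams: str = "exam_count",
              denom: str = "pop_15plus") -> np.ndarray:
    """Diagnostic exams per 1,000 persons aged 15+."""
    pop = areas[denom].to_numpy(dtype=float)
    _check_denominator(areas, pop, denom)
    return areas[exams].to_numpy(dtype=float) / pop * 1000.0


class EmpiricalBayesSmoother(BaseEstimator):
    """Marshall local (spatial) empirical Bayes rate smoother.

    For unit *i* with reference set N+(i) = {i} union queen-neighbors(i),
    events O and person-year denominators P, and crude rates r = O/P:

        m_i   = sum O_j / sum P_j              over N+(i)
        s2_i  = sum P_j (r_j - m_i)^2 / sum P_j
        a_i   = max(0, s2_i - m_i / Pbar_i),   Pbar_i = mean P over N+(i)
        k_i   = a_i / (a_i + m_i / P_i)
        smoothed_i = k_i r_i + (1 - k_i) m_i

    The shrinkage weight ``k_i`` lies in [0, 1], so the smoothed rate is
    always between the crude rate and the neighborhood rate.  Islands
    shrink to themselves (smoothed = crude) and are flagged.

    Parameters
    ----------
    weights : binary-mode :class:`SpatialWeights` (queen contiguity).
    scale : reporting scale, default per 100,000.

    Attributes (after ``fit``)
    --------------------------
    smoothed_rate_, crude_rate_ : per-unit rates on the ``scale`` scale.
    shrinkage_weight_ : k_i in [0, 1].
    reference_rate_ : neighborhood rate m_i on the ``scale`` scale.
    islands_ : ids of units with no neighbors.
    """

    def __init__(self, weights: SpatialWeights | None = None, scale: float = 100_000.0):
        self.weights = weights
        self.scale = scale

    def fit(self, rates: pd.DataFrame, weights: SpatialWeights | None = None
            ) -> "EmpiricalBayesSmoother":
        w = weights if weights is not None else self.weights
        if w is None:
            raise ValueError("spatial weights are required")
        if w.mode != "binary":
            raise ValueError("EB smoothing expects binary-mode queen weights")
        if list(rates["unit_id"]) != list(w.ids):
            raise ValueError("rates and weights index different units")
        O = rates["events"].to_numpy(dtype=float)
        P = rates["denom"].to_numpy(dtype=float)
        if (O < 0).any() or (P <= 0).any():
            raise ValueError("events must be >= 0 and denominators > 0")
        r = O / P
        n = len(O)
        pos = {u: i for i, u in enumerate(w.ids)}
        kappa = np.empty(n)
        m_ref = np.empty(n)
        for i, u in enumerate(w.ids):
            ref = [i] + [pos[v] for v in w.neighbors[u]]
            Psum = P[ref].sum()
            m = O[ref].sum() / Psum
            s2 = (P[ref] * (r[ref] - m) ** 2).sum() / Psum
            pbar = P[ref].mean()
            a = max(0.0, s2 - m / pbar)
            noise = m / P[i]
            kappa[i] = 1.0 if (a + noise) == 0 else a / (a + noise)
            m_ref[i] = m
        smoothed = kappa * r + (1.0 - kappa) * m_ref
        self.crude_rate_ = r * self.scale
        self.smoothed_rate_ = smoothed * self.scale
        self.reference_rate_ = m_ref * self.scale
        self.shrinkage_weight_ = kappa
        self.islands_ = list(w.islands)
        return self

    def fit_transform(self, rates: pd.DataFrame,
                      weights: SpatialWeights | None = None) -> np.ndarray:
        return self.fit(rates, weights).smoothed_rate_


def eb_smooth_spatial(rates: pd.DataFrame, w: SpatialWeights,
                      scale: float = 100_000.0) -> pd.DataFrame:
    """Spatially empirical-Bayes-smoothed rate surface.

    ``rates`` must carry unit_id, events, denom and crude_rate (as
    produced by :func:`mortality_rate`); returns that table with
    smoothed_rate and shrinkage_weight columns appended.
    """
    est = EmpiricalBayesSmoother(weights=w, scale=scale).fit(rates)
    out = rates.copy()
    out["smoothed_rate"] = est.smoothed_rate_
    out["shrinkage_weight"] = est.shrinkage_weight_
    return out
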