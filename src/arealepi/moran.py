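"""Global Moran's I and local Moran (LISA) with permutation inference.

Global Moran's I measures whether a surface over areal units is
spatially clustered (I > E[I]), dispersed (I < E[I]) or random, where
E[I] = -1/(n-1) under random relabelling.  Inference is by permutation:
the observed values are randomly reassigned to units and the statistic
recomputed, giving a pseudo p-value (1 + exceedances) / (1 + permutations).

The local Moran statistic decomposes the global I into per-unit
contributions; conditional permutation (holding the unit's own value
fixed and permuting the rest among its neighbors) gives per-unit pseudo
p-values, and significant units are classified by the signs of their
deviation and its spatial lag into high-high (hot spot), low-low (cold
spot) and high-low / low-high spatial outliers.

Islands are excluded from the global statistic and get missing local
statistics.  All randomness is driven by an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .weights import SpatialWeights

__all__ = ["Moran", "LocalMoran", "global_moran", "local_moran"]

_QUADRANT_LABEL = {
    "HH": "hot_spot",
    "LL": "cold_spot",
    "HL": "outlier_HL",
    "LH": "outlier_LH",
}


def _moran_stat(z: np.ndarray, W, s0: float) -> float:
    n = z.shape[0]
    return float(n / s0 * (z @ (W @ z)) / (z @ z))


class Moran(BaseEstimator):
    """Global Moran's I with permutation inference.

    Parameters
    ----------
    weights : :class:`SpatialWeights`; row-standardized is conventional.
    permutations : number of random relabellings (default 999).
    alternative : "two-sided" (default), "greater" or "less"; two-sided
        distances are measured from E[I] = -1/(n-1).
    seed : RNG seed for the permutation draw.

    Attributes (after ``fit``)
    --------------------------
    I_ : observed statistic.
    expected_I_ : -1/(n-1), n counting non-island units.
    p_sim_ : permutation pseudo p-value, >= 1/(permutations+1).
    z_sim_ : (I_ - mean(sims)) / std(sims).
    sims_ : permutation replicates.
    """

    def __init__(self, weights: SpatialWeights | None = None, permutations: int = 999,
                 alternative: str = "two-sided", seed: int | None = None):
        self.weights = weights
        self.permutations = permutations
        self.alternative = alternative
        self.seed = seed

    def fit(self, x, weights: SpatialWeights | None = None) -> "Moran":
        w = weights if weights is not None else self.weights
        if w is None:
            raise ValueError("spatial weights are required")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.alternative not in ("two-sided", "greater", "less"):
            raise ValueError(f"unknown alternative {self.alternative!r}")
        x = np.asarray(x, dtype=float)
        if x.shape[0] != w.n:
            raise ValueError("x and weights index different numbers of units")
        if w.islands:
            keep = ~w.island_mask
            x = x[keep]
            w = w.subset([u for u, k in zip(w.ids, keep) if k])
        n = x.shape[0]
        if n < 3:
            raise ValueError("Moran's I needs at least 3 connected units")
        if np.ptp(x) == 0:
            raise ValueError("x is constant; Moran's I is undefined")

        z = x - x.mean()
        W = w.matrix
        s0 = w.s0
        self.I_ = _moran_stat(z, W, s0)
        self.expected_I_ = -1.0 / (n - 1)

        rng = np.random.default_rng(self.seed)
        keys = rng.random((self.permutations, n))
        perms = np.argsort(keys, axis=1)
        Zp = z[perms]                                # (nperm, n)
        num = np.einsum("pn,pn->p", Zp, (W @ Zp.T).T)
        sims = n / s0 * num / (z @ z)
        self.sims_ = sims
        e = self.expected_I_
        if self.alternative == "two-sided":
            exceed = np.abs(sims - e) >= np.abs(self.I_ - e)
        elif self.alternative == "greater":
            exceed = sims >= self.I_
        else:
            exceed = sims <= self.I_
        self.p_sim_ = (1.0 + exceed.sum()) / (self.permutations + 1.0)
        sd = sims.std()
        self.z_sim_ = (self.I_ - sims.mean()) / sd if sd > 0 else np.nan
        self.n_ = n
        return self


class LocalMoran(BaseEstimator):
    """Local Moran (LISA) with conditional permutation inference.

    I_i = (z_i / m2) * sum_j w_ij z_j with m2 = sum z^2 / n.  The
    conditional permutation holds z_i fixed and draws the neighbor
    values from the remaining n-1 observations.

    The default pseudo p-value is two-sided (twice the smaller
    conditional tail, capped at 1), so flagging units at ``alpha``
    holds the per-unit size at ``alpha`` under spatial randomness.
    ``alternative="directed"`` instead reports the one-sided tail
    matching the sign of the observed deviation from
    E[I_i] = -(sum_j w_ij)/(n-1) — the convention of classical desktop
    LISA software; note its effective null flagging rate is about
    2 * alpha.

    No multiple-testing correction is applied across units by default
    (``fdr=True`` switches to Benjamini-Hochberg adjusted labels).

    Attributes (after ``fit``)
    --------------------------
    Is_ : local statistics (NaN for islands).
    p_sim_ : per-unit pseudo p-values (1.0 for islands).
    quadrant_ : "HH" / "LL" / "HL" / "LH" per unit.
    labels_ : hot_spot / cold_spot / outlier_HL / outlier_LH /
        not_significant.
    """

    def __init__(self, weights: SpatialWeights | None = None, permutations: int = 999,
                 alpha: float = 0.05, seed: int | None = None, fdr: bool = False,
                 alternative: str = "two-sided"):
        self.weights = weights
        self.permutations = permutations
        self.alpha = alpha
        self.seed = seed
        self.fdr = fdr
        self.alternative = alternative

    def fit(self, x, weights: SpatialWeights | None = None) -> "LocalMoran":
        w = weights if weights is not None else self.weights
        if w is None:
            raise ValueError("spatial weights are required")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.alternative not in ("two-sided", "directed"):
            raise ValueError(f"unknown alternative {self.alternative!r}")
        x = np.asarray(x, dtype=float)
        n = x.shape[0]
        if n != w.n:
            raise ValueError("x and weights index different numbers of units")
        if np.ptp(x) == 0:
            raise ValueError("x is constant; local Moran is undefined")

        z = x - x.mean()
        m2 = (z @ z) / n
        W = w.matrix
        lag = W @ z
        Is = z / m2 * lag
        island = w.island_mask
        Is[island] = np.nan

        degrees = w.degrees
        rowsum = np.asarray(W.sum(axis=1)).ravel()
        expected = -rowsum / (n - 1)

        rng = np.random.default_rng(self.seed)
        p = np.ones(n)
        nperm = self.permutations
        all_idx = np.arange(n)
        for i in range(n):
            d = degrees[i]
            if d == 0:
                continue
            others = z[all_idx != i]
            keys = rng.random((nperm, n - 1))
            # smallest-d keys form a uniform random d-subset without replacement
            pick = np.argpartition(keys, d - 1, axis=1)[:, :d]
            # queen rows have equal weights, so the lag is weight * sum(sample)
            wval = 1.0 if w.mode == "binary" else 1.0 / d
            sim_lag = wval * others[pick].sum(axis=1)
            sims = z[i] / m2 * sim_lag
            p_up = (1.0 + (sims >= Is[i]).sum()) / (nperm + 1.0)
            p_low = (1.0 + (sims <= Is[i]).sum()) / (nperm + 1.0)
            if self.alternative == "two-sided":
                p[i] = min(1.0, 2.0 * min(p_up, p_low))
            else:
                p[i] = p_up if Is[i] >= expected[i] else p_low

        lag_display = lag.astype(float)
        lag_display[island] = np.nan
        quad = np.where(z > 0,
                        np.where(lag_display > 0, "HH", "HL"),
                        np.where(lag_display > 0, "LH", "LL")).astype(object)
        quad[island] = "NA"

        p_eff = p.copy()
        if self.fdr:
            from scipy.stats import false_discovery_control
            mask = ~island
            p_eff[mask] = false_discovery_control(p[mask], method="bh")
        labels = np.array(
            [
                _QUADRANT_LABEL[q] if (q != "NA" and pe < self.alpha) else "not_significant"
                for q, pe in zip(quad, p_eff)
            ],
            dtype=object,
        )

        self.Is_ = Is
        self.p_sim_ = p
        self.expected_Is_ = expected
        self.quadrant_ = quad
        self.labels_ = labels
        self.islands_ = list(w.islands)
        return self

    def to_frame(self, ids=None) -> pd.DataFrame:
        ids = list(ids) if ids is not None else list(range(len(self.Is_)))
        return pd.DataFrame(
            {
                "unit_id": ids,
                "I_local": self.Is_,
                "pseudo_p": self.p_sim_,
                "quadrant": self.quadrant_,
                "label": self.labels_,
            }
        )


def global_moran(x, w: SpatialWeights, n_perm: int = 999, seed: int | None = None,
                 alternative: str = "two-sided") -> Moran:
    """Fitted global :class:`Moran` for ``x`` under weights ``w``."""
    return Moran(weights=w, permutations=n_perm, seed=seed,
                 alternative=alternative).fit(x)


def local_moran(x, w: SpatialWeights, n_perm: int = 999, alpha: float = 0.05,
                seed: int | None = None, fdr: bool = False) -> LocalMoran:
    """Fitted :class:`LocalMoran` for ``x`` under weights ``w``."""
    return LocalMoran(weights=w, permutations=n_perm, alpha=alpha, seed=seed,
                      fdr=fdr).fit(x)
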