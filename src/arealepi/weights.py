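"""Queen contiguity spatial weights over areal units.

Two polygons are queen neighbors when they share at least one boundary
point (an edge or a single vertex).  Weights come in two modes:

``binary``
    w_ij = 1 for neighbors, 0 otherwise — used for empirical-Bayes
    smoothing neighborhoods.
``row_standardized``
    each row divided by its degree, so the spatial lag is the neighbor
    mean — the default for Moran / LISA / residual diagnostics.

Units with no neighbors ("islands") are kept in the index, flagged, and
receive missing spatial lags; they are never silently dropped.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from shapely.strtree import STRtree

__all__ = [
    "SpatialWeights",
    "queen_weights",
    "spatial_lag",
    "IslandWarning",
]


class IslandWarning(UserWarning):
    """A unit has no queen neighbors."""


class SpatialWeights:
    """Sparse neighbor structure over a fixed, ordered set of unit ids.

    Parameters
    ----------
    neighbors : mapping of unit id -> sequence of neighbor ids
        Must be symmetric (``j in neighbors[i]`` iff ``i in neighbors[j]``)
        and free of self-neighbors.
    mode : {"binary", "row_standardized"}
    ids : explicit unit ordering; defaults to the mapping's key order.
    """

    def __init__(self, neighbors: Mapping, mode: str = "binary", ids: Sequence | None = None):
        if mode not in ("binary", "row_standardized"):
            raise ValueError(f"unknown weights mode {mode!r}")
        self.ids = list(ids) if ids is not None else list(neighbors.keys())
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("unit ids are not unique")
        self._pos = {u: i for i, u in enumerate(self.ids)}
        self.neighbors = {u: list(neighbors.get(u, ())) for u in self.ids}
        self.mode = mode
        self._validate()
        self._matrix = None

    def _validate(self) -> None:
        for u, nbrs in self.neighbors.items():
            if u in nbrs:
                raise ValueError(f"unit {u!r} listed as its own neighbor")
            for v in nbrs:
                if v not in self._pos:
                    raise ValueError(f"neighbor {v!r} of {u!r} is not a unit id")
                if u not in self.neighbors[v]:
                    raise ValueError(f"asymmetric adjacency between {u!r} and {v!r}")

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(self.neighbors[u]) for u in self.ids])

    @property
    def islands(self) -> list:
        return [u for u in self.ids if not self.neighbors[u]]

    @property
    def island_mask(self) -> np.ndarray:
        return self.degrees == 0

    @property
    def s0(self) -> float:
        """Total weight sum Σ_ij w_ij."""
        return float(self.matrix.sum())

    @property
    def matrix(self) -> sparse.csr_matrix:
        """Weights as a CSR matrix in the order of ``ids``."""
        if self._matrix is None:
            rows, cols, vals = [], [], []
            for u, nbrs in self.neighbors.items():
                i = self._pos[u]
                d = len(nbrs)
                w = 1.0 if self.mode == "binary" else (1.0 / d if d else 0.0)
                for v in nbrs:
                    rows.append(i)
                    cols.append(self._pos[v])
                    vals.append(w)
            self._matrix = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(self.n, self.n)
            )
        return self._matrix

    # -- transformations --------------------------------------------------
    def to_mode(self, mode: str) -> "SpatialWeights":
        if mode == self.mode:
            return self
        return SpatialWeights(self.neighbors, mode=mode, ids=self.ids)

    def subset(self, keep: Sequence) -> "SpatialWeights":
        """Restrict to ``keep`` units, dropping edges to removed units."""
        keep_set = set(keep)
        nbrs = {
            u: [v for v in self.neighbors[u] if v in keep_set]
            for u in self.ids
            if u in keep_set
        }
        return SpatialWeights(nbrs, mode=self.mode, ids=[u for u in self.ids if u in keep_set])

    # -- operations --------------------------------------------------------
    def lag(self, x) -> np.ndarray:
        """Spatial lag (Wx)_i = Σ_j w_ij x_j; islands get NaN."""
        arr = np.asarray(x, dtype=float)
        if arr.shape[0] != self.n:
            raise ValueError(f"x has length {arr.shape[0]}, weights have {self.n} units")
        out = self.matrix @ arr
        out[self.island_mask] = np.nan
        return out

    # -- adjacency-list text format (GAL-like) ----------------------------
    def to_adjlist_text(self) -> str:
        """One line per unit: ``id n_neighbors nbr1 nbr2 ...``."""
        lines = [f"{self.n}"]
        for u in self.ids:
            nbrs = self.neighbors[u]
            lines.append(" ".join([str(u), str(len(nbrs))] + [str(v) for v in nbrs]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_adjlist_text(cls, text: str, mode: str = "binary") -> "SpatialWeights":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        n = int(lines[0])
        neighbors, ids = {}, []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            u, k = parts[0], int(parts[1])
            ids.append(u)
            neighbors[u] = parts[2 : 2 + k]
        return cls(neighbors, mode=mode, ids=ids)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpatialWeights(n={self.n}, mode={self.mode!r}, islands={len(self.islands)})"


def queen_weights(areas, mode: str = "binary", snap_tolerance: float = 0.0) -> SpatialWeights:
    """Build queen contiguity weights from an area table.

    Parameters
    ----------
    areas : DataFrame with ``unit_id`` and shapely ``geometry`` columns,
        or a sequence of shapely polygons (ids become 0..n-1).
    mode : "binary" or "row_standardized".
    snap_tolerance : buffer distance (map units) applied before the
        contiguity test, to absorb imperfect digitization.  Default 0
        (exact shared-boundary-point predicate).
    """
    if isinstance(areas, pd.DataFrame):
        ids = list(areas["unit_id"])
        geoms = list(areas["geometry"])
    else:
        geoms = list(areas)
        ids = list(range(len(geoms)))
    probe = geoms if snap_tolerance == 0 else [g.buffer(snap_tolerance) for g in geoms]
    tree = STRtree(probe)
    neighbors = {u: [] for u in ids}
    for i, g in enumerate(probe):
        hits = tree.query(g, predicate="intersects")
        for j in sorted(hits):
            if j != i:
                neighbors[ids[i]].append(ids[j])
    w = SpatialWeights(neighbors, mode=mode, ids=ids)
    if w.islands:
        warnings.warn(
            f"{len(w.islands)} island unit(s) with no queen neighbors: "
            f"{w.islands[:5]}{'...' if len(w.islands) > 5 else ''}",
            IslandWarning,
            stacklevel=2,
        )
    return w


def spatial_lag(w: SpatialWeights, x) -> np.ndarray:
    """Spatial lag of ``x`` under weights ``w``; islands get NaN."""
    return w.lag(x)
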