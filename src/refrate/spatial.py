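"""Areal lattice construction, Leroux precision algebra and spatio-temporal
residual diagnostics.

The analysis treats the study region as lattice data: a set of N
non-overlapping small areas together with a binary neighbourhood matrix W
(w_ij = 1 when areas i and j share a border).  Spatial smoothing is
expressed through the Leroux precision matrix

    Q(rho_s, W) = rho_s * (diag(W 1) - W) + (1 - rho_s) * I,

which interpolates between independence (rho_s = 0, Q = I) and the
intrinsic CAR model (rho_s = 1, Q = graph Laplacian, singular).

Two diagnostics justify spatio-temporal random effects in the
population-adjustment model: global Moran's I computed on regression
residuals year by year (with a permutation p-value) and the lag-1 temporal
autocorrelation of each area's residual series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AreaLattice",
    "PrecisionMatrix",
    "build_grid_lattice",
    "leroux_precision",
    "morans_i",
    "lag1_autocorrelation",
    "read_edge_list",
    "write_edge_list",
    "read_dense_adjacency",
    "write_dense_adjacency",
]


@dataclass(frozen=True)
class AreaLattice:
    """N small areas and their symmetric binary neighbourhood matrix."""

    area_ids: tuple
    W: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        n = len(self.area_ids)
        if W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {W.shape}")
        if not np.array_equal(W, W.T):
            raise ValueError("neighbourhood matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("neighbourhood matrix must have a zero diagonal")
        if not np.all(np.isin(W, (0.0, 1.0))):
            raise ValueError("neighbourhood matrix entries must be 0 or 1")
        if np.any(W.sum(axis=1) == 0):
            raise ValueError("every area must have at least one neighbour")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "area_ids", tuple(self.area_ids))

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Number of neighbours of each area (row sums of W)."""
        return self.W.sum(axis=1)


@dataclass(frozen=True)
class PrecisionMatrix:
    """Leroux precision matrix for a given spatial dependency parameter."""

    Q: np.ndarray = field(repr=False)
    rho_s: float = 0.0

    @property
    def is_singular(self) -> bool:
        return bool(self.rho_s >= 1.0)


def build_grid_lattice(rows: int, cols: int, contiguity: str = "queen") -> AreaLattice:
    """Regular rows x cols grid lattice with rook or queen contiguity.

    Rook neighbours share an edge (interior degree 4); queen neighbours
    additionally share a corner (interior degree 8).  Area ids are
    ``"A{r:02d}{c:02d}"`` in row-major order.
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice must contain at least two cells")
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"unknown contiguity {contiguity!r}")
    n = rows * cols
    if contiguity == "rook":
        g = nx.grid_2d_graph(rows, cols)
    else:
        g = nx.grid_2d_graph(rows, cols)
        for r in range(rows - 1):
            for c in range(cols):
                if c + 1 < cols:
                    g.add_edge((r, c), (r + 1, c + 1))
                if c - 1 >= 0:
                    g.add_edge((r, c), (r + 1, c - 1))
    W = np.zeros((n, n))
    idx = {(r, c): r * cols + c for r in range(rows) for c in range(cols)}
    for a, b in g.edges():
        W[idx[a], idx[b]] = 1.0
        W[idx[b], idx[a]] = 1.0
    ids = tuple(f"A{r:02d}{c:02d}" for r in range(rows) for c in range(cols))
    return AreaLattice(area_ids=ids, W=W)


def leroux_precision(rho_s: float, lattice: AreaLattice) -> PrecisionMatrix:
    """Q = rho_s (diag(W 1) - W) + (1 - rho_s) I.

    Positive definite for ``0 <= rho_s < 1``; at ``rho_s = 1`` the matrix is
    the graph Laplacian, which is singular (row sums zero).
    """
    if not 0.0 <= rho_s <= 1.0:
        raise ValueError(f"rho_s must lie in [0, 1], got {rho_s}")
    W = lattice.W
    Q = rho_s * (np.diag(W.sum(axis=1)) - W) + (1.0 - rho_s) * np.eye(lattice.n_areas)
    return PrecisionMatrix(Q=Q, rho_s=float(rho_s))


def morans_i(
    values: Sequence[float],
    lattice: AreaLattice,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Global Moran's I with a two-sided permutation p-value.

    I = (N / S0) * sum_ij w_ij (v_i - vbar)(v_j - vbar) / sum_i (v_i - vbar)^2
    with S0 = sum_ij w_ij, using the binary (non-row-standardised) W.  The
    p-value is (1 + #{|I*| >= |I|}) / (n_perm + 1) over random relabellings
    of the areas.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (lattice.n_areas,):
        raise ValueError("values must be a length-N vector")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    z = v - v.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for a constant vector")
    W = lattice.W
    s0 = W.sum()
    scale = lattice.n_areas / s0

    def stat(zv: np.ndarray) -> float:
        return scale * float(zv @ W @ zv) / denom

    observed = stat(z)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += abs(stat(rng.permutation(z))) >= abs(observed)
    pvalue = (1.0 + count) / (n_perm + 1.0)
    return observed, pvalue


def lag1_autocorrelation(series_by_area: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-area lag-1 sample autocorrelation and its unweighted mean.

    For each row z_1..z_T the plug-in estimator

        r_1 = sum_{t<T} (z_t - zbar)(z_{t+1} - zbar) / sum_t (z_t - zbar)^2

    is used (autocovariance normalised by T in both numerator and
    denominator, about the full-series mean).  Constant rows have an
    undefined autocorrelation: they are returned as NaN, excluded from the
    mean, and a warning is logged.
    """
    z = np.asarray(series_by_area, dtype=float)
    if z.ndim != 2 or z.shape[1] < 3:
        raise ValueError("need an N x T matrix with T >= 3")
    centred = z - z.mean(axis=1, keepdims=True)
    denom = (centred**2).sum(axis=1)
    numer = (centred[:, :-1] * centred[:, 1:]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        acf = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)
    n_bad = int(np.sum(denom == 0))
    if n_bad:
        logger.warning(
            "%d constant series excluded from the mean lag-1 autocorrelation", n_bad
        )
        warnings.warn(
            f"{n_bad} constant series excluded from mean lag-1 autocorrelation",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.all(np.isnan(acf)):
        raise ValueError("every series is constant; mean lag-1 ACF undefined")
    return acf, float(np.nanmean(acf))


# ---------------------------------------------------------------------------
# adjacency import / export


def write_edge_list(lattice: AreaLattice, path: str | Path) -> None:
    """Write W as a 3-column edge list (area_i, area_j, weight), i < j."""
    ids = lattice.area_ids
    rows = [
        {"area_i": ids[i], "area_j": ids[j], "weight": 1}
        for i, j in zip(*np.nonzero(np.triu(lattice.W)))
    ]
    pd.DataFrame(rows, columns=["area_i", "area_j", "weight"]).to_csv(path, index=False)


def read_edge_list(path: str | Path, area_ids: Sequence) -> AreaLattice:
    """Read a 3-column edge-list CSV; area order is given by ``area_ids``."""
    df = pd.read_csv(path)
    ids = list(area_ids)
    pos = {a: k for k, a in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for _, row in df.iterrows():
        i, j = pos[row["area_i"]], pos[row["area_j"]]
        w = float(row.get("weight", 1))
        W[i, j] = w
        W[j, i] = w
    return AreaLattice(area_ids=tuple(ids), W=W)


def write_dense_adjacency(lattice: AreaLattice, path: str | Path) -> None:
    pd.DataFrame(
        lattice.W.astype(int), index=lattice.area_ids, columns=lattice.area_ids
    ).to_csv(path)


def read_dense_adjacency(path: str | Path) -> AreaLattice:
    df = pd.read_csv(path, index_col=0)
    return AreaLattice(area_ids=tuple(df.index), W=df.to_numpy(dtype=float))
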