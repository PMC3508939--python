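"""Pair temporal sources with spatial sources within one realization.

Each temporal source row is pushed through the transfer (convolve + decimate)
and absolute-Pearson-correlated with every column of the spatial mixing
matrix. Pairs are then assigned greedily and without degeneracy: the largest
remaining absolute correlation fixes a (temporal, spatial) pair, whose row and
column leave the pool, until every temporal source has a unique spatial pair.
Because spatial mixing column j belongs to spatial source row j, the pairing
of mixing columns induces the pairing of spatial sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .transfer import TransferConfig, apply_transfer
from .unmixing import Decomposition

__all__ = [
    "MatchResult",
    "match_realization",
    "correlation_matrix",
    "greedy_assign",
    "abs_pearson",
]


def abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson correlation| of two vectors; 0 if either is constant."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(min(1.0, abs(xc @ yc) / (nx * ny)))


@dataclass(frozen=True)
class MatchResult:
    """Greedy pairing of temporal sources to spatial sources.

    ``permutation[r]`` is the spatial source index paired with temporal source
    r; ``pairing_order`` lists temporal indices in the order they were fixed,
    with ``match_correlations`` the |rho| values at pairing time (non-increasing
    by the greedy property).
    """

    permutation: np.ndarray
    match_correlations: np.ndarray
    pairing_order: np.ndarray
    realization_index: int

    def __post_init__(self) -> None:
        n = self.permutation.size
        if sorted(self.permutation.tolist()) != list(range(n)):
            raise ValueError("permutation is not a bijection")

    @property
    def permutation_matrix(self) -> np.ndarray:
        """Row-permutation matrix P with (P @ S_S)[r] = S_S[permutation[r]]."""
        n = self.permutation.size
        P = np.zeros((n, n))
        P[np.arange(n), self.permutation] = 1.0
        return P


def correlation_matrix(transformed_sources: np.ndarray, mixing: np.ndarray) -> np.ndarray:
    """Matrix of |Pearson rho| between source rows and mixing columns.

    Entry (r, c) correlates transformed temporal source r with spatial mixing
    column c. Zero-variance vectors give entry 0 with a warning.
    """
    T = np.asarray(transformed_sources, dtype=float)
    M = np.asarray(mixing, dtype=float)
    if np.any(~np.isfinite(T)) or np.any(~np.isfinite(M)):
        raise ValueError("correlation inputs contain non-finite values")
    if T.shape[1] != M.shape[0]:
        raise ValueError(
            f"sample-count mismatch: rows have {T.shape[1]} samples, "
            f"columns have {M.shape[0]}"
        )
    Tc = T - T.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=0, keepdims=True)
    tn = np.linalg.norm(Tc, axis=1)
    mn = np.linalg.norm(Mc, axis=0)
    if np.any(tn == 0) or np.any(mn == 0):
        warnings.warn("zero-variance vector in correlation; entries set to 0", RuntimeWarning)
    tn_safe = np.where(tn == 0, 1.0, tn)
    mn_safe = np.where(mn == 0, 1.0, mn)
    C = np.minimum(np.abs(Tc @ Mc) / np.outer(tn_safe, mn_safe), 1.0)
    C[tn == 0, :] = 0.0
    C[:, mn == 0] = 0.0
    return C


def greedy_assign(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nondegenerate greedy assignment on an absolute-correlation matrix.

    Repeatedly takes the global maximum of the remaining submatrix (ties break
    to the lexicographically smallest (row, col) index, which is what argmax on
    the row-major flattened matrix yields) and removes its row and column.
    Returns (permutation, correlations-in-pairing-order, row pairing order).
    """
    C = np.array(corr, dtype=float)
    n = C.shape[0]
    if C.shape[1] != n:
        raise ValueError("greedy assignment requires a square matrix")
    perm = np.full(n, -1, dtype=int)
    corrs = np.empty(n)
    order = np.empty(n, dtype=int)
    work = C.copy()
    for step in range(n):
        r, c = np.unravel_index(np.argmax(work), work.shape)
        perm[r] = c
        corrs[step] = C[r, c]
        order[step] = r
        work[r, :] = -np.inf
        work[:, c] = -np.inf
    return perm, corrs, order


def match_realization(
    temporal: Decomposition, spatial: Decomposition, cfg: TransferConfig
) -> MatchResult:
    """Pair the sources of one temporal and one spatial realization."""
    if temporal.n_components != spatial.n_components:
        raise ValueError(
            f"component-count mismatch: temporal has {temporal.n_components}, "
            f"spatial has {spatial.n_components}"
        )
    n_st = spatial.mixing.shape[0]
    transformed = np.vstack([apply_transfer(row, cfg) for row in temporal.sources])
    if transformed.shape[1] != n_st:
        raise ValueError(
            f"transformed temporal sources have length {transformed.shape[1]} "
            f"(decimation q={cfg.q}) but spatial mixing columns have length {n_st}"
        )
    C = correlation_matrix(transformed, spatial.mixing)
    perm, corrs, order = greedy_assign(C)
    return MatchResult(
        permutation=perm,
        match_correlations=corrs,
        pairing_order=order,
        realization_index=temporal.realization_index,
    )
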