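"""Cross-realization fusion of matched source pairs.

Given K matched (temporal, spatial) decompositions, this module computes the
K(K-1)/2 cross-realization correlation matrices (CRCMs), aligns similar
super-sources across realizations by repeated greedy search of the CRCMs,
canonicalizes signs within each aligned group, and collapses every group to a
single component by weighted averaging. Components are ranked by
reproducibility: the mean of the unique intra-group pairwise similarities,
which lies in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .matching import MatchResult, abs_pearson, match_realization
from .transfer import TransferConfig
from .unmixing import DataMatrix, Decomposition, run_realizations, spawn_seeds

__all__ = [
    "CRCMSet",
    "SuperSource",
    "SuperSourceGroup",
    "BICARResult",
    "compute_crcms",
    "align",
    "canonicalize_signs",
    "aggregate",
    "run_bicar",
]


def _signed_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(xc @ yc / (nx * ny))


def _abs_cross_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|Pearson| between all row pairs of two (N_C x n) matrices."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    an = np.linalg.norm(Ac, axis=1)
    bn = np.linalg.norm(Bc, axis=1)
    an = np.where(an == 0, np.inf, an)
    bn = np.where(bn == 0, np.inf, bn)
    return np.minimum(np.abs(Ac @ Bc.T) / np.outer(an, bn), 1.0)


@dataclass
class CRCMSet:
    """The K(K-1)/2 cross-realization correlation matrices.

    ``matrices[(i, j)]`` (i < j) holds the N_C x N_C matrix whose (r, c) entry
    is w_T*|rho(temporal source r of realization i, temporal source c of j)|
    + w_S*|rho(matched spatial source r of i, matched spatial source c of j)|.
    Row/column indices follow the temporal-source numbering; the spatial parts
    are re-ordered by each realization's match permutation first.
    """

    matrices: dict[tuple[int, int], np.ndarray]
    w_T: float
    w_S: float
    n_realizations: int
    n_components: int


@dataclass
class SuperSource:
    """One realization's matched (temporal, spatial) source pair."""

    realization_index: int
    source_index: int  # temporal-source numbering
    temporal_source: np.ndarray
    spatial_source: np.ndarray
    temporal_mixing: np.ndarray  # column of A_T, length N_TS
    spatial_mixing: np.ndarray  # column of A_S, length N_ST
    sign_temporal: int = 1
    sign_spatial: int = 1


@dataclass
class SuperSourceGroup:
    """K super-sources (one per realization) aligned across realizations."""

    members: list[SuperSource]
    seed_pair: tuple[tuple[int, int], tuple[int, int]]  # ((real a, src r), (real b, src c))
    weights: np.ndarray | None = None

    def member_for_realization(self, k: int) -> SuperSource:
        for m in self.members:
            if m.realization_index == k:
                return m
        raise KeyError(f"no member for realization {k}")


@dataclass
class BICARResult:
    """Fused components ranked by descending reproducibility."""

    temporal_sources: np.ndarray  # N_C x N_TT
    spatial_sources: np.ndarray  # N_C x N_SS
    temporal_mixing: np.ndarray  # N_TS x N_C
    spatial_mixing: np.ndarray  # N_ST x N_C
    reproducibility: np.ndarray  # length N_C, non-increasing
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = np.asarray(self.reproducibility, dtype=float)
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
            raise ValueError("reproducibility values must lie in [0, 1]")
        if np.any(np.diff(r) > 1e-12):
            raise ValueError("components must be sorted by non-increasing reproducibility")

    @property
    def n_components(self) -> int:
        return self.temporal_sources.shape[0]


def compute_crcms(
    temporal_decs: list[Decomposition],
    spatial_decs: list[Decomposition],
    matches: list[MatchResult],
    w_T: float = 0.5,
    w_S: float = 0.5,
) -> CRCMSet:
    """Weighted temporal+spatial absolute cross-correlations for all i < j."""
    if w_T < 0 or w_S < 0 or w_T + w_S <= 0:
        raise ValueError(f"weights must be nonnegative with positive sum, got ({w_T}, {w_S})")
    K = len(temporal_decs)
    if K < 2:
        raise ValueError("need at least 2 realizations")
    if not (len(spatial_decs) == len(matches) == K):
        raise ValueError("temporal, spatial and match lists must have equal length")
    n_c = temporal_decs[0].n_components
    # spatial sources re-ordered so row r pairs with temporal source r
    permuted_spatial = [
        spatial_decs[k].sources[matches[k].permutation, :] for k in range(K)
    ]
    matrices: dict[tuple[int, int], np.ndarray] = {}
    for i in range(K):
        for j in range(i + 1, K):
            rt = _abs_cross_corr(temporal_decs[i].sources, temporal_decs[j].sources)
            rs = _abs_cross_corr(permuted_spatial[i], permuted_spatial[j])
            matrices[(i, j)] = w_T * rt + w_S * rs
    return CRCMSet(
        matrices=matrices, w_T=w_T, w_S=w_S, n_realizations=K, n_components=n_c
    )


def _slice_max(
    work: dict[tuple[int, int], np.ndarray], a: int, r: int, k: int
) -> tuple[int, float]:
    """Best source of realization k linked to source r of realization a."""
    if a < k:
        row = work[(a, k)][r, :]
        s = int(np.argmax(row))
        return s, float(row[s])
    col = work[(k, a)][:, r]
    s = int(np.argmax(col))
    return s, float(col[s])


def align(
    crcms: CRCMSet,
    temporal_decs: list[Decomposition],
    spatial_decs: list[Decomposition],
    matches: list[MatchResult],
) -> list[SuperSourceGroup]:
    """Sort K sets of N_C super-sources into N_C groups of K super-sources.

    Greedy CRCM search: the global maximum over all matrices seeds a group
    with one source from each of two realizations; every other realization
    contributes the source best linked to either seed (the larger of the two
    link correlations decides when they disagree). Extracted sources are
    masked out and the search repeats until N_C groups exist.
    """
    K = crcms.n_realizations
    n_c = crcms.n_components
    work = {key: m.copy() for key, m in crcms.matrices.items()}
    groups: list[SuperSourceGroup] = []
    for _ in range(n_c):
        best_val = -np.inf
        best = None
        for (i, j), m in work.items():
            r, c = np.unravel_index(np.argmax(m), m.shape)
            if m[r, c] > best_val:
                best_val = float(m[r, c])
                best = (i, j, int(r), int(c))
        assert best is not None and np.isfinite(best_val), "CRCMs exhausted before N_C groups"
        a, b, r, c = best
        chosen: dict[int, int] = {a: r, b: c}
        for k in range(K):
            if k in chosen:
                continue
            s_row, v_row = _slice_max(work, a, r, k)
            s_col, v_col = _slice_max(work, b, c, k)
            if s_row == s_col:
                chosen[k] = s_row
            else:
                chosen[k] = s_row if v_row >= v_col else s_col
        # mask the extracted source of every realization in all matrices
        for k, s in chosen.items():
            for (i, j), m in work.items():
                if i == k:
                    m[s, :] = -np.inf
                if j == k:
                    m[:, s] = -np.inf
        members = []
        for k in sorted(chosen):
            s = chosen[k]
            sp = int(matches[k].permutation[s])
            members.append(
                SuperSource(
                    realization_index=k,
                    source_index=s,
                    temporal_source=temporal_decs[k].sources[s].copy(),
                    spatial_source=spatial_decs[k].sources[sp].copy(),
                    temporal_mixing=temporal_decs[k].mixing[:, s].copy(),
                    spatial_mixing=spatial_decs[k].mixing[:, sp].copy(),
                )
            )
        groups.append(SuperSourceGroup(members=members, seed_pair=((a, r), (b, c))))
    # partition check: every (realization, source) used exactly once
    used = sorted(
        (m.realization_index, m.source_index) for g in groups for m in g.members
    )
    expected = sorted((k, s) for k in range(K) for s in range(n_c))
    assert used == expected, "alignment did not partition the super-sources"
    return groups


def canonicalize_signs(group: SuperSourceGroup) -> SuperSourceGroup:
    """Flip member signs so the group shares the reference's orientation.

    The reference is the seed-pair member from the lower-indexed realization.
    Temporal and spatial parts are handled independently (the two ICA runs can
    flip independently); a flip negates both the source and its mixing column,
    leaving every member's reconstruction A @ S invariant.
    """
    (a, _), (b, _) = group.seed_pair
    ref = group.member_for_realization(min(a, b))
    for m in group.members:
        if m is ref:
            continue
        if _signed_pearson(ref.temporal_source, m.temporal_source) < 0:
            m.sign_temporal = -m.sign_temporal
            m.temporal_source = -m.temporal_source
            m.temporal_mixing = -m.temporal_mixing
        if _signed_pearson(ref.spatial_source, m.spatial_source) < 0:
            m.sign_spatial = -m.sign_spatial
            m.spatial_source = -m.spatial_source
            m.spatial_mixing = -m.spatial_mixing
    return group


def _group_similarity_matrix(
    group: SuperSourceGroup, w_T: float, w_S: float, mode: str
) -> np.ndarray:
    K = len(group.members)
    sim = np.zeros((K, K))
    for p in range(K):
        for q in range(p + 1, K):
            mp, mq = group.members[p], group.members[q]
            if mode == "concatenated":
                s = abs_pearson(
                    np.concatenate([mp.temporal_source, mp.spatial_source]),
                    np.concatenate([mq.temporal_source, mq.spatial_source]),
                )
            else:
                s = w_T * abs_pearson(mp.temporal_source, mq.temporal_source) + w_S * abs_pearson(
                    mp.spatial_source, mq.spatial_source
                )
            sim[p, q] = sim[q, p] = s
    return sim


def aggregate(
    groups: list[SuperSourceGroup],
    w_T: float = 0.5,
    w_S: float = 0.5,
    similarity: str = "weighted",
    provenance: dict | None = None,
) -> BICARResult:
    """Collapse each canonicalized group to one component; rank by reproducibility.

    Reproducibility R of a group is the sum of its K(K-1)/2 unique pairwise
    absolute similarities divided by K(K-1)/2. Each member's averaging weight
    is its mean absolute similarity to the other K-1 members, normalized to
    sum to one.
    """
    if not groups:
        raise ValueError("no groups to aggregate")
    K = len(groups[0].members)
    if K < 2:
        raise ValueError("aggregation requires K >= 2 members per group")
    if similarity not in ("weighted", "concatenated"):
        raise ValueError(f"unknown similarity mode {similarity!r}")
    reprod = np.empty(len(groups))
    t_sources, s_sources, t_mix, s_mix = [], [], [], []
    for gi, g in enumerate(groups):
        sim = _group_similarity_matrix(g, w_T, w_S, similarity)
        iu = np.triu_indices(K, k=1)
        reprod[gi] = sim[iu].sum() / (K * (K - 1) / 2)
        w = sim.sum(axis=1) / (K - 1)
        total = w.sum()
        w = np.full(K, 1.0 / K) if total == 0 else w / total
        g.weights = w
        t_sources.append(sum(wk * m.temporal_source for wk, m in zip(w, g.members)))
        s_sources.append(sum(wk * m.spatial_source for wk, m in zip(w, g.members)))
        t_mix.append(sum(wk * m.temporal_mixing for wk, m in zip(w, g.members)))
        s_mix.append(sum(wk * m.spatial_mixing for wk, m in zip(w, g.members)))
    order = np.argsort(-reprod, kind="stable")
    return BICARResult(
        temporal_sources=np.vstack([t_sources[i] for i in order]),
        spatial_sources=np.vstack([s_sources[i] for i in order]),
        temporal_mixing=np.column_stack([t_mix[i] for i in order]),
        spatial_mixing=np.column_stack([s_mix[i] for i in order]),
        reproducibility=np.clip(reprod[order], 0.0, 1.0),
        provenance=provenance or {},
    )


def run_bicar(
    X_T: DataMatrix,
    X_S: DataMatrix,
    n_components: int,
    transfer: TransferConfig,
    n_realizations: int = 30,
    master_seed: int = 0,
    w_T: float = 0.5,
    w_S: float = 0.5,
    similarity: str = "weighted",
) -> BICARResult:
    """End-to-end pipeline: unmix, match, correlate, align, canonicalize, average."""
    seed_t, seed_s = spawn_seeds(master_seed * 2 + 1, 2)
    temporal_decs = run_realizations(X_T, n_components, n_realizations, seed_t)
    spatial_decs = run_realizations(X_S, n_components, n_realizations, seed_s)
    matches = [
        match_realization(temporal_decs[k], spatial_decs[k], transfer)
        for k in range(n_realizations)
    ]
    crcms = compute_crcms(temporal_decs, spatial_decs, matches, w_T=w_T, w_S=w_S)
    groups = align(crcms, temporal_decs, spatial_decs, matches)
    groups = [canonicalize_signs(g) for g in groups]
    config = {
        "n_components": n_components,
        "n_realizations": n_realizations,
        "master_seed": master_seed,
        "w_T": w_T,
        "w_S": w_S,
        "similarity": similarity,
        "transfer": transfer.to_dict(),
    }
    prov = {
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "realization_seeds": {
            "temporal": [d.seed for d in temporal_decs],
            "spatial": [d.seed for d in spatial_decs],
        },
        "converged": {
            "temporal": [bool(d.converged) for d in temporal_decs],
            "spatial": [bool(d.converged) for d in spatial_decs],
        },
        "match_correlation_means": [float(m.match_correlations.mean()) for m in matches],
    }
    return aggregate(groups, w_T=w_T, w_S=w_S, similarity=similarity, provenance=prov)
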