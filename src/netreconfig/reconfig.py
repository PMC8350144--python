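"""Partition-similarity and reconfiguration statistics.

Window-to-window FC reconfiguration is 1 minus the mean adjusted mutual
information (AMI) between temporally adjacent window partitions; the
event-boundary variant compares non-overlapping window pairs straddling
narrative event boundaries.  The temporal participation coefficient
P_i = 1 - sum_m (k_i(m)/k_i)^2 measures how evenly a node's cross-window
co-assignments spread over the reference atlas communities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import logger
from .communities import PartitionSet


# ---------------------------------------------------------------------------
# Adjusted mutual information (exact permutation-model expectation)


def _contingency(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    _, pi = np.unique(p, return_inverse=True)
    _, qi = np.unique(q, return_inverse=True)
    r, c = pi.max() + 1, qi.max() + 1
    return np.bincount(pi * c + qi, minlength=r * c).reshape(r, c)


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def expected_mutual_information(a: np.ndarray, b: np.ndarray, n: int) -> float:
    """E[MI] of two fixed-margin partitions under the permutation model.

    Sums the hypergeometric probability of every feasible cell count n_ij
    given row margins ``a`` and column margins ``b``.
    """
    lg = gammaln(np.arange(n + 2))  # lg[k] = log((k-1)!)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            log_p = (
                lg[ai + 1]
                + lg[bj + 1]
                + lg[n - ai + 1]
                + lg[n - bj + 1]
                - lg[n + 1]
                - lg[nij + 1]
                - lg[ai - nij + 1]
                - lg[bj - nij + 1]
                - lg[n - ai - bj + nij + 1]
            )
            terms = (nij / n) * (np.log(n * nij) - np.log(float(ai) * bj))
            emi += float((np.exp(log_p) * terms).sum())
    return emi


def ami(p: Sequence[int], q: Sequence[int]) -> float:
    """Adjusted mutual information, chance-corrected, arithmetic-mean normalized.

    AMI = (MI - E[MI]) / (mean(H(p), H(q)) - E[MI]).  Relabeling-invariant;
    1 for identical partitions with at least two labels.  Degenerate cases:
    both partitions single-cluster -> 1; exactly one single-cluster -> 0.
    """
    p = np.asarray(p)
    q = np.asarray(q)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("partitions must be 1-D and of equal length")
    n = p.shape[0]
    cont = _contingency(p, q)
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    if a.size == 1 and b.size == 1:
        return 1.0
    if a.size == 1 or b.size == 1:
        logger.debug("ami: one single-cluster partition; returning 0 by convention")
        return 0.0
    if (
        a.size == b.size
        and ((cont > 0).sum(axis=1) == 1).all()
        and ((cont > 0).sum(axis=0) == 1).all()
    ):
        return 1.0  # identical up to relabeling
    nz = cont[cont > 0].astype(float)
    mi = float(
        (nz / n * (np.log(nz * n) - np.log(np.outer(a, b)[cont > 0].astype(float)))).sum()
    )
    emi = expected_mutual_information(a, b, n)
    denom = 0.5 * (_entropy(a, n) + _entropy(b, n)) - emi
    if abs(denom) < 1e-15:
        return 1.0 if mi >= emi else 0.0
    return float(min(1.0, (mi - emi) / denom))


# ---------------------------------------------------------------------------
# Reconfiguration indices


def adjacent_ami_series(partitions: np.ndarray) -> np.ndarray:
    """AMI between each pair of temporally adjacent window partitions."""
    partitions = np.asarray(partitions)
    if partitions.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    return np.array([ami(partitions[w], partitions[w + 1]) for w in range(partitions.shape[0] - 1)])


def w2w_index(partitions: np.ndarray | PartitionSet) -> float:
    """Window-to-window reconfiguration: 1 - mean adjacent-window AMI.

    Given a PartitionSet the index is computed per gamma and averaged.
    """
    if isinstance(partitions, PartitionSet):
        vals = [1.0 - adjacent_ami_series(partitions.by_gamma[g]).mean() for g in partitions.gammas]
        return float(np.mean(vals))
    return float(1.0 - adjacent_ami_series(partitions).mean())


@dataclass
class EventBoundarySet:
    """Narrative event-boundary onsets with the window-gap rule."""

    onsets_s: np.ndarray
    gap_range_s: Tuple[float, float] = (5.0, 7.0)

    def __post_init__(self) -> None:
        self.onsets_s = np.sort(np.atleast_1d(np.asarray(self.onsets_s, dtype=float)))
        lo, hi = self.gap_range_s
        if not 0 < lo <= hi:
            raise ValueError("gap range must satisfy 0 < low <= high")


def boundary_pairs(
    boundaries: EventBoundarySet,
    grid: List[Tuple[int, int]],
    tr: float,
) -> List[Tuple[int, int]]:
    """Window-index pairs straddling each boundary with a 5-7 s gap.

    For each boundary, the pre-window is the latest window ending at or
    before the boundary and the post-window the earliest starting at least
    gap_min seconds after the pre-window's end (and not before the
    boundary); the pair is kept only if the resulting gap does not exceed
    gap_max, so the windows never overlap and the boundary falls inside the
    gap.  Boundaries too close to the scan edges yield no pair.
    """
    gap_lo, gap_hi = boundaries.gap_range_s
    starts = np.array([s * tr for s, _ in grid])
    ends = np.array([e * tr for _, e in grid])
    pairs: List[Tuple[int, int]] = []
    for b in boundaries.onsets_s:
        pre_ok = np.flatnonzero(ends <= b)
        if pre_ok.size == 0:
            logger.info("boundary at %.1f s too close to scan start; skipped", b)
            continue
        pre = int(pre_ok[-1])
        post_ok = np.flatnonzero(starts >= max(ends[pre] + gap_lo, b))
        if post_ok.size == 0:
            logger.info("boundary at %.1f s too close to scan end; skipped", b)
            continue
        post = int(post_ok[0])
        gap = starts[post] - ends[pre]
        if gap > gap_hi:
            logger.info("boundary at %.1f s: no window pair with admissible gap", b)
            continue
        pairs.append((pre, post))
    return pairs


def boundary_index(partitions: np.ndarray | PartitionSet, pairs: List[Tuple[int, int]]) -> float:
    """Event-boundary reconfiguration: 1 - mean AMI over boundary pairs."""
    if not pairs:
        raise ValueError("need at least one boundary pair")
    if isinstance(partitions, PartitionSet):
        vals = []
        for g in partitions.gammas:
            P = partitions.by_gamma[g]
            vals.append(1.0 - np.mean([ami(P[i], P[j]) for i, j in pairs]))
        return float(np.mean(vals))
    P = np.asarray(partitions)
    return float(1.0 - np.mean([ami(P[i], P[j]) for i, j in pairs]))


# ---------------------------------------------------------------------------
# Temporal participation coefficient


@dataclass
class CoassignmentCounts:
    """Cross-window co-assignment counts: k_ij = #windows with c_i = c_j."""

    k: np.ndarray  # (nodes, nodes), zero diagonal
    n_windows: int


def coassignment(partitions: np.ndarray) -> CoassignmentCounts:
    partitions = np.asarray(partitions)
    if partitions.ndim != 2:
        raise ValueError("partitions must be (windows, nodes)")
    n = partitions.shape[1]
    k = np.zeros((n, n), dtype=np.int64)
    for p in partitions:
        k += p[:, None] == p[None, :]
    np.fill_diagonal(k, 0)
    return CoassignmentCounts(k=k, n_windows=partitions.shape[0])


def participation(counts: CoassignmentCounts, atlas: pd.DataFrame) -> np.ndarray:
    """Temporal participation coefficient P_i = 1 - sum_m (k_i(m)/k_i)^2.

    k_i(m) counts node i's co-assignments with nodes of atlas community m;
    nodes with no co-assignments get P_i = 0 by convention.
    """
    comm = np.asarray(atlas["atlas_community"])
    if comm.shape[0] != counts.k.shape[0]:
        raise ValueError("atlas does not cover all nodes")
    M = comm.max() + 1
    onehot = np.zeros((comm.shape[0], M))
    onehot[np.arange(comm.shape[0]), comm] = 1.0
    kim = counts.k @ onehot  # (nodes, M)
    ki = kim.sum(axis=1)
    P = np.zeros(comm.shape[0])
    nz = ki > 0
    if (~nz).any():
        logger.warning("participation: %d isolated nodes set to P=0", (~nz).sum())
    P[nz] = 1.0 - ((kim[nz] / ki[nz, None]) ** 2).sum(axis=1)
    return P


def network_participation(P: np.ndarray, atlas: pd.DataFrame) -> pd.Series:
    """Unweighted mean participation within each network label."""
    s = pd.Series(np.asarray(P, dtype=float), index=atlas.index)
    means = s.groupby(atlas["network"], observed=True).mean()
    empty = means.index[means.isna()]
    if len(empty):
        logger.warning("network_participation: empty networks %s", list(empty))
    return means


def subject_participation(pset: PartitionSet, atlas: pd.DataFrame) -> Tuple[np.ndarray, pd.Series]:
    """Gamma-averaged per-node participation and per-network means."""
    Ps = []
    for g in pset.gammas:
        Ps.append(participation(coassignment(pset.by_gamma[g]), atlas))
    P = np.mean(Ps, axis=0)
    return P, network_participation(P, atlas)
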