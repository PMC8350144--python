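"""Signed-modularity community detection and consensus clustering.

Window connectomes keep both correlation signs, so partitions maximize the
asymmetric signed quality function Q*: positive weights contribute through
their own normalizer v+ and are unaffected by negative weights, while the
negative-weight term is divided by the total weight v+ + v-, shrinking its
influence as positive connectivity grows:

    Q* = (1/v+) sum_ij (w+_ij - g*e+_ij) d(ci,cj)
       - (1/(v+ + v-)) sum_ij (w-_ij - g*e-_ij) d(ci,cj)

with configuration-model expectations e+-_ij = s+-_i s+-_j / v+- and the
resolution parameter g scaling both expectation terms.  Near-degeneracy of
the modularity landscape is handled by many seeded restarts followed by
agreement-matrix consensus clustering (threshold tau, iterated to a fixed
point).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from numba import njit

from .core import check_symmetric, logger
from .dynfc import WindowedConnectome

_EPS = 1e-12


@dataclass
class ModularityConfig:
    gammas: Tuple[float, ...] = (0.95, 1.00, 1.05)
    n_init: int = 100

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gammas):
            raise ValueError("gamma must be positive")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass
class ConsensusConfig:
    tau: float = 0.0
    reps: int = 100
    max_iter: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau < 1.0:
            raise ValueError("tau must lie in [0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


# ---------------------------------------------------------------------------
# Q* evaluation


def _signed_parts(W: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    return Wp, Wn


def modularity_signed(W: np.ndarray, partition: Sequence[int], gamma: float = 1.0) -> float:
    """Evaluate Q* for a given partition of a signed symmetric matrix."""
    W = check_symmetric(W, name="W")
    labels = np.asarray(partition)
    if labels.shape != (W.shape[0],):
        raise ValueError("partition length must equal number of nodes")
    Wp, Wn = _signed_parts(W)
    return _qstar(Wp, Wn, _canonical(labels), gamma)


def _qstar(Wp: np.ndarray, Wn: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    vp = Wp.sum()
    vn = Wn.sum()
    q = 0.0
    same = labels[:, None] == labels[None, :]
    if vp > 0:
        sp = Wp.sum(axis=1)
        Sp = np.bincount(labels, weights=sp)
        q += (Wp[same].sum() - gamma * (Sp**2).sum() / vp) / vp
    if vn > 0:
        sn = Wn.sum(axis=1)
        Sn = np.bincount(labels, weights=sn)
        q -= (Wn[same].sum() - gamma * (Sn**2).sum() / vn) / (vp + vn)
    return float(q)


# ---------------------------------------------------------------------------
# Louvain


@njit(cache=True)
def _sweep(Wp, Wn, gamma, vp, vn, comm, order):  # pragma: no cover - jitted
    """Greedy local moves maximizing Q* gain; repeats until no move helps.

    ``comm`` is modified in place.  A move is accepted only on a strict gain,
    so Q* increases monotonically and the loop terminates.
    """
    n = Wp.shape[0]
    vtot = vp + vn
    sp = np.zeros(n)
    sn = np.zeros(n)
    for i in range(n):
        for j in range(n):
            sp[i] += Wp[i, j]
            sn[i] += Wn[i, j]
    Sp = np.zeros(n)
    Sn = np.zeros(n)
    size = np.zeros(n, np.int64)
    for i in range(n):
        c = comm[i]
        Sp[c] += sp[i]
        Sn[c] += sn[i]
        size[c] += 1
    kp = np.zeros(n)
    kn = np.zeros(n)
    improved = False
    moved = True
    while moved:
        moved = False
        for oi in range(n):
            i = order[oi]
            ci = comm[i]
            for c in range(n):
                kp[c] = 0.0
                kn[c] = 0.0
            for j in range(n):
                if j != i:
                    cj = comm[j]
                    kp[cj] += Wp[i, j]
                    kn[cj] += Wn[i, j]
            Sp[ci] -= sp[i]
            Sn[ci] -= sn[i]
            size[ci] -= 1
            # gain of membership in community c, relative to i isolated
            best_c = ci
            best_g = 0.0
            if vp > 0.0:
                best_g += 2.0 * (kp[ci] - gamma * sp[i] * Sp[ci] / vp) / vp
            if vn > 0.0:
                best_g -= 2.0 * (kn[ci] - gamma * sn[i] * Sn[ci] / vn) / vtot
            stay_g = best_g
            empty = -1
            for c in range(n):
                if c == ci:
                    continue
                if size[c] == 0:
                    if empty < 0:
                        empty = c
                    continue
                g = 0.0
                if vp > 0.0:
                    g += 2.0 * (kp[c] - gamma * sp[i] * Sp[c] / vp) / vp
                if vn > 0.0:
                    g -= 2.0 * (kn[c] - gamma * sn[i] * Sn[c] / vn) / vtot
                if g > best_g + _EPS:
                    best_g = g
                    best_c = c
            if size[ci] > 0 and empty >= 0 and 0.0 > best_g + _EPS:
                best_g = 0.0
                best_c = empty
            if best_c != ci and best_g > stay_g + _EPS:
                moved = True
                improved = True
            else:
                best_c = ci
            comm[i] = best_c
            Sp[best_c] += sp[i]
            Sn[best_c] += sn[i]
            size[best_c] += 1
    return improved


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..k-1 in order of first appearance."""
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    mapping = {lab: k for k, lab in enumerate(order)}
    return np.array([mapping[lab] for lab in labels], dtype=np.int64)


def _louvain_signed(Wp: np.ndarray, Wn: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Two-phase Louvain on pre-split positive/negative parts (no checks)."""
    vp = float(Wp.sum())
    vn = float(Wn.sum())
    n = Wp.shape[0]
    labels = np.arange(n, dtype=np.int64)
    WpL, WnL = np.ascontiguousarray(Wp), np.ascontiguousarray(Wn)
    while True:
        m = WpL.shape[0]
        comm = np.arange(m, dtype=np.int64)
        order = rng.permutation(m).astype(np.int64)
        improved = _sweep(WpL, WnL, gamma, vp, vn, comm, order)
        comm = _canonical(comm)
        labels = comm[labels]
        ncomm = int(comm.max()) + 1
        if not improved or ncomm == m:
            break
        # aggregate communities into super-nodes (self-loops keep internal weight)
        M = np.zeros((m, ncomm))
        M[np.arange(m), comm] = 1.0
        WpL = np.ascontiguousarray(M.T @ WpL @ M)
        WnL = np.ascontiguousarray(M.T @ WnL @ M)
    return _canonical(labels)


def louvain(W: np.ndarray, gamma: float = 1.0, seed: int = 0) -> np.ndarray:
    """Seeded signed-modularity Louvain partition of a symmetric matrix.

    The node sweep order is drawn from the seed, so identical seeds give
    identical partitions.  An all-zero matrix yields all-singleton labels.
    """
    W = check_symmetric(W, name="W")
    Wp, Wn = _signed_parts(W)
    return _louvain_signed(Wp, Wn, gamma, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Agreement and consensus


def agreement(partitions: Sequence[np.ndarray]) -> np.ndarray:
    """Co-assignment probability matrix over a set of partitions."""
    parts = [np.asarray(p) for p in partitions]
    if not parts:
        raise ValueError("need at least one partition")
    n = parts[0].shape[0]
    if any(p.shape != (n,) for p in parts):
        raise ValueError("all partitions must have equal length")
    A = np.zeros((n, n))
    for p in parts:
        A += p[:, None] == p[None, :]
    return A / len(parts)


def consensus(
    agreement_matrix: np.ndarray,
    config: ConsensusConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Consensus partition of an agreement matrix (threshold tau, iterated).

    Entries at or below tau are zeroed, the thresholded matrix is clustered
    ``reps`` times, and the procedure recurses on the new agreement matrix
    until every repetition returns the same partition.
    """
    config = config or ConsensusConfig()
    A = check_symmetric(agreement_matrix, name="agreement matrix")
    rng = np.random.default_rng(seed)
    for _ in range(config.max_iter):
        At = np.where(A > config.tau, A, 0.0)
        np.fill_diagonal(At, 0.0)
        Zn = np.zeros_like(At)
        parts = [
            _canonical(_louvain_signed(At, Zn, 1.0, rng)) for _ in range(config.reps)
        ]
        first = parts[0]
        if all(np.array_equal(p, first) for p in parts[1:]):
            return first
        A = agreement(parts)
    logger.warning("consensus did not converge in %d iterations; returning modal partition", config.max_iter)
    keys = {}
    for p in parts:
        keys.setdefault(p.tobytes(), [p, 0])[1] += 1
    modal = max(keys.values(), key=lambda kv: kv[1])[0]
    return modal


@dataclass
class PartitionSet:
    """Consensus partitions per resolution gamma and window.

    ``by_gamma`` maps gamma -> (windows, nodes) integer label array.
    """

    by_gamma: Dict[float, np.ndarray]

    @property
    def gammas(self) -> List[float]:
        return sorted(self.by_gamma)

    @property
    def n_windows(self) -> int:
        return next(iter(self.by_gamma.values())).shape[0]

    @property
    def n_nodes(self) -> int:
        return next(iter(self.by_gamma.values())).shape[1]


def window_partitions(
    wc: WindowedConnectome,
    mcfg: ModularityConfig | None = None,
    ccfg: ConsensusConfig | None = None,
    seed: int = 0,
) -> PartitionSet:
    """Per-window consensus community structure at each resolution.

    For every gamma and window: ``n_init`` seeded Louvain runs on the signed
    z-matrix, their agreement matrix, then consensus clustering.  Windows are
    treated independently (single-layer procedure).
    """
    mcfg = mcfg or ModularityConfig()
    ccfg = ccfg or ConsensusConfig()
    ss = np.random.SeedSequence(seed)
    by_gamma: Dict[float, np.ndarray] = {}
    for gi, gamma in enumerate(mcfg.gammas):
        out = np.empty((wc.n_windows, wc.n_nodes), dtype=np.int64)
        for wi in range(wc.n_windows):
            child = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(gi, wi)
            )
            rng = np.random.default_rng(child)
            W = wc.z[wi]
            Wp, Wn = _signed_parts(W)
            parts = [
                _louvain_signed(Wp, Wn, gamma, rng) for _ in range(mcfg.n_init)
            ]
            A = agreement(parts)
            cons_seed = int(child.generate_state(1, np.uint32)[0])
            out[wi] = consensus(A, ccfg, seed=cons_seed)
        by_gamma[float(gamma)] = out
    return PartitionSet(by_gamma=by_gamma)
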