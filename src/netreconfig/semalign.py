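"""Movie semantic-feature processing and brain-environment coupling.

Binary per-frame semantic features (nouns = entities present, verbs =
actions) are averaged within each sliding window; the distinct averaged
values act as cluster labels so that window-to-window semantic similarity
can be indexed with the same AMI used for FC partitions.  Coupling is the
Spearman correlation between the FC-similarity and semantic-similarity
series; cohort-level residualization removes overall reconfiguration (and
optionally other couplings) before inference.

Window averages are kept as exact integer counts over a common denominator,
so "unique value" labeling is immune to floating-point equality artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .core import logger
from .communities import PartitionSet
from .reconfig import adjacent_ami_series, ami
from .synthdata import SemanticFeatureTable


@dataclass
class WindowSemanticProfile:
    """Per-window presence counts (exact rationals: counts / frames-in-window)."""

    counts: np.ndarray  # (windows, features) int
    frames_per_window: np.ndarray  # (windows,) int denominators
    classes: List[str]

    def fractions(self) -> np.ndarray:
        return self.counts / self.frames_per_window[:, None]

    def class_mask(self, cls: str) -> np.ndarray:
        return np.array([c == cls for c in self.classes])


def frames_for_windows(
    grid: Sequence[Tuple[int, int]], tr: float, frame_rate: float, n_frames: int
) -> List[Tuple[int, int]]:
    """Half-open frame ranges covering each window's volume-time span."""
    ranges = []
    for s, e in grid:
        f0 = int(np.ceil(s * tr * frame_rate - 1e-9))
        f1 = int(np.ceil(e * tr * frame_rate - 1e-9))
        ranges.append((max(0, f0), min(n_frames, f1)))
    return ranges


def window_feature_fractions(
    features: SemanticFeatureTable, window_frames: Sequence[Tuple[int, int]]
) -> WindowSemanticProfile:
    """Exact per-window presence fraction of every semantic feature."""
    n_frames = features.values.shape[0]
    counts = []
    denoms = []
    for f0, f1 in window_frames:
        if not (0 <= f0 < f1 <= n_frames):
            raise ValueError(f"empty or out-of-range window frame span [{f0},{f1})")
        counts.append(features.values[f0:f1].sum(axis=0))
        denoms.append(f1 - f0)
    return WindowSemanticProfile(
        counts=np.asarray(counts, dtype=np.int64),
        frames_per_window=np.asarray(denoms, dtype=np.int64),
        classes=list(features.classes),
    )


def semantic_labels(counts_row: np.ndarray) -> np.ndarray:
    """Cluster labels over features: one label per distinct averaged value.

    Within a window all fractions share a denominator, so grouping by the
    integer count is exact.
    """
    _, inverse = np.unique(np.asarray(counts_row), return_inverse=True)
    return inverse


def semantic_similarity_series(
    profile: WindowSemanticProfile, cls: Optional[str] = None
) -> np.ndarray:
    """Adjacent-window AMI of the per-window semantic label vectors."""
    counts = profile.counts
    if cls is not None:
        mask = profile.class_mask(cls)
        if not mask.any():
            raise ValueError(f"no features of class {cls!r}")
        counts = counts[:, mask]
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    labels = [semantic_labels(row) for row in counts]
    return np.array([ami(labels[w], labels[w + 1]) for w in range(len(labels) - 1)])


def fc_similarity_series(partitions: np.ndarray | PartitionSet) -> np.ndarray:
    """Adjacent-window AMI of consensus partitions, gamma-averaged."""
    if isinstance(partitions, PartitionSet):
        series = [adjacent_ami_series(partitions.by_gamma[g]) for g in partitions.gammas]
        return np.mean(series, axis=0)
    return adjacent_ami_series(np.asarray(partitions))


def coupling(fc_sims: np.ndarray, sem_sims: np.ndarray) -> float:
    """Spearman rank correlation between FC and semantic similarity series."""
    fc_sims = np.asarray(fc_sims, dtype=float)
    sem_sims = np.asarray(sem_sims, dtype=float)
    if fc_sims.shape != sem_sims.shape or fc_sims.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(fc_sims) == 0 or np.ptp(sem_sims) == 0:
        logger.warning("coupling undefined for a constant series")
        return float("nan")
    rho, _ = sstats.spearmanr(fc_sims, sem_sims)
    return float(rho)


def residualize_cohort(
    values: np.ndarray, covariate_vectors: Sequence[np.ndarray]
) -> np.ndarray:
    """Across-subject least-squares residuals on [intercept, covariates]."""
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    cols = [np.ones(n)] + [np.asarray(c, dtype=float) for c in covariate_vectors]
    X = np.column_stack(cols)
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need at least covariates + 2 subjects")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("residualize_cohort: rank-deficient covariates (%d < %d)", rank, X.shape[1])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def cronbach_alpha(
    items: np.ndarray, pre_regress: Optional[Sequence[np.ndarray]] = None
) -> float:
    """Cronbach's alpha internal-consistency reliability of item columns.

    alpha = K/(K-1) * (1 - sum of item variances / variance of item sum).
    ``pre_regress`` covariates are residualized out of every item first.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 subjects and >= 2 items")
    if pre_regress is not None:
        X = np.column_stack([residualize_cohort(X[:, j], pre_regress) for j in range(X.shape[1])])
    K = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        logger.warning("cronbach_alpha undefined: zero total variance")
        return float("nan")
    return float(K / (K - 1) * (1.0 - item_var.sum() / total_var))
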