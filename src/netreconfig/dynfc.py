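"""Tapered sliding-window Fisher-z connectomes.

Connectivity within each window is the Hann-weighted Pearson correlation
between every node pair, Fisher z-transformed.  No thresholding is applied;
positive and negative weights are both retained for the signed community
analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import RoiTimeSeries, logger

Z_CLIP = 1.0 - 1e-7


@dataclass
class WindowSpec:
    """Sliding-window geometry: 40 s windows advanced in ~2 s steps."""

    length_s: float = 40.0
    step_s: float = 2.0
    taper: str = "hann"

    def __post_init__(self) -> None:
        if not self.length_s > 0:
            raise ValueError("window length must be positive")
        if not self.step_s > 0:
            raise ValueError("window step must be positive")
        if self.taper not in ("hann", "uniform"):
            raise ValueError("taper must be 'hann' or 'uniform'")

    def vols_per_window(self, tr: float) -> int:
        n = int(np.floor(self.length_s / tr))
        if n < 2:
            raise ValueError("window shorter than 2 volumes at this TR")
        return n

    def step_vols(self, tr: float) -> int:
        return max(1, int(round(self.step_s / tr)))


@dataclass
class WindowedConnectome:
    """Stack of per-window symmetric zero-diagonal Fisher-z matrices."""

    z: np.ndarray  # (windows, nodes, nodes)
    windows: List[Tuple[int, int]]  # 0-based half-open volume ranges
    tr: float
    spec: WindowSpec
    node_ids: Optional[Sequence[str]] = None

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.z.shape[1]

    def window_times(self) -> np.ndarray:
        """(windows, 2) start/end times in seconds."""
        return np.array([(s * self.tr, e * self.tr) for s, e in self.windows])


def window_grid(
    n_volumes: int, tr: float, spec: WindowSpec | None = None
) -> List[Tuple[int, int]]:
    """0-based half-open volume ranges of all complete sliding windows.

    Volumes per window = floor(length_s / tr); step = round(step_s / tr),
    at least 1.  Windows advance until the last complete window fits.
    """
    spec = spec or WindowSpec()
    vpw = spec.vols_per_window(tr)
    if n_volumes < vpw:
        raise ValueError(
            f"scan of {n_volumes} volumes shorter than one {vpw}-volume window"
        )
    step = spec.step_vols(tr)
    return [(s, s + vpw) for s in range(0, n_volumes - vpw + 1, step)]


def hann_weights(n: int) -> np.ndarray:
    """Strictly positive Hann taper of length n, normalized to sum 1.

    Closed form sin^2(pi*(k+1)/(n+1)): the interior of a Hann window, so the
    end points carry small but non-zero weight.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    k = np.arange(n)
    w = np.sin(np.pi * (k + 1) / (n + 1)) ** 2
    return w / w.sum()


def weighted_corr(window_signal: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of the columns.

    r_ij = C_ij / sqrt(C_ii C_jj) with C the weighted covariance about the
    weighted mean.  Zero-variance columns get correlation 0 off-diagonal.
    """
    X = np.asarray(window_signal, dtype=float)
    w = np.asarray(w, dtype=float)
    if X.shape[0] != w.shape[0]:
        raise ValueError("weight length must match window volumes")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    if np.count_nonzero(w) < 2:
        raise ValueError("need at least 2 weight-supported time points")
    wn = w / w.sum()
    mean = wn @ X
    Xc = X - mean
    C = (Xc * wn[:, None]).T @ Xc
    var = np.diag(C).copy()
    scale = np.abs(X).max(axis=0) + 1.0
    bad = var <= (1e-8 * scale) ** 2
    if bad.any():
        logger.warning("weighted_corr: %d zero-variance columns set to r=0", bad.sum())
        var[bad] = 1.0
    denom = np.sqrt(np.outer(var, var))
    r = C / denom
    if bad.any():
        r[bad, :] = 0.0
        r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform with clipping away from |r| = 1."""
    return np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))


def compute_windowed_fc(
    ts: RoiTimeSeries,
    spec: WindowSpec | None = None,
    segments: Optional[List[Tuple[int, int]]] = None,
) -> WindowedConnectome:
    """Windowed Fisher-z connectome stack for one scan.

    ``segments`` (0-based half-open volume spans) window each movie segment
    independently so that no window straddles excluded rest periods; when
    omitted, a single segment covering the whole scan (or the volume_mask's
    contiguous True runs) is used.
    """
    spec = spec or WindowSpec()
    if segments is None:
        if ts.volume_mask is not None:
            segments = _mask_runs(ts.volume_mask)
        else:
            segments = [(0, ts.n_volumes)]
    vpw = spec.vols_per_window(ts.tr)
    if spec.taper == "hann":
        w = hann_weights(vpw)
    else:
        w = np.full(vpw, 1.0 / vpw)
    windows: List[Tuple[int, int]] = []
    mats = []
    for seg_start, seg_end in segments:
        if seg_end - seg_start < vpw:
            logger.warning(
                "segment [%d,%d) shorter than one window; skipped", seg_start, seg_end
            )
            continue
        for s, e in window_grid(seg_end - seg_start, ts.tr, spec):
            a, b = seg_start + s, seg_start + e
            r = weighted_corr(ts.data[a:b], w)
            z = fisher_z(r)
            z = 0.5 * (z + z.T)
            np.fill_diagonal(z, 0.0)
            windows.append((a, b))
            mats.append(z)
    if not mats:
        raise ValueError("no segment long enough for a single window")
    return WindowedConnectome(
        z=np.stack(mats), windows=windows, tr=ts.tr, spec=spec, node_ids=ts.node_ids
    )


def _mask_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Contiguous True runs of a boolean mask as half-open ranges."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]] + 1
    return list(zip(starts.tolist(), ends.tolist()))
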