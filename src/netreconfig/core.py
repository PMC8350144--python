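"""Shared containers and error types used across the pipeline."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("netreconfig")


class FormatError(ValueError):
    """A file did not match the expected on-disk dialect."""


@dataclass
class RoiTimeSeries:
    """Parcellated BOLD signal: one column per node/ROI, one row per volume.

    Parameters
    ----------
    data
        (volumes, nodes) float array, arbitrary BOLD units.
    tr
        Repetition time in seconds.
    node_ids
        Optional node identifiers matching the columns.
    volume_mask
        Optional boolean keep-mask (True = analysed); used to exclude
        rest periods between movie segments before windowing.
    """

    data: np.ndarray
    tr: float
    node_ids: Optional[Sequence[str]] = None
    subject_id: Optional[str] = None
    run_id: Optional[str] = None
    volume_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (volumes x nodes)")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 volumes")
        if not np.isfinite(self.data).all():
            raise ValueError("time-series values must be finite")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if self.node_ids is not None and len(self.node_ids) != self.data.shape[1]:
            raise ValueError("node_ids length does not match number of columns")
        if self.volume_mask is not None:
            self.volume_mask = np.asarray(self.volume_mask, dtype=bool)
            if self.volume_mask.shape != (self.data.shape[0],):
                raise ValueError("volume_mask length does not match volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        """Copy of this series with the signal matrix replaced."""
        return replace(self, data=np.asarray(data, dtype=float))


def check_symmetric(W: np.ndarray, tol: float = 1e-10, name: str = "matrix") -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(W, W.T, atol=tol):
        raise ValueError(f"{name} must be symmetric")
    return W
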