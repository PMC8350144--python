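"""Synthetic cohort generation with planted dynamic community structure.

Raw naturalistic-fMRI cohorts with the properties this pipeline analyses
are access-restricted, so every downstream stage is exercised on synthetic
data whose ground truth is known: community-structured BOLD-like signals
whose block covariance switches at planted change points, binary semantic
feature streams whose flips concentrate at those change points, behavioral
variables linearly loaded on planted brain indices, and motion/component
nuisance regressors.

Signal model: each community shares a Gaussian latent; the node signal is
sqrt(snr/(1+snr)) * latent + sqrt(1/(1+snr)) * idiosyncratic noise, giving
expected within-community correlation snr/(1+snr) and zero between
communities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import RoiTimeSeries
from .denoise import motion_expansion

DEFAULT_NETWORKS = ("DMN", "FPC", "CON", "SAL", "DAN", "VAN", "SM", "SUB", "AUD", "VIS")

#: additive flip-probability boost at a change-point frame at full coupling
SEMANTIC_BOOST = 0.25


def gen_node_table(n_nodes: int = 229, n_networks: int = 10, seed: int = 0) -> pd.DataFrame:
    """Node/atlas table: ids, MNI-like coordinates, balanced network labels."""
    if not 1 <= n_networks <= n_nodes:
        raise ValueError("need 1 <= n_networks <= n_nodes")
    rng = np.random.default_rng(seed)
    if n_networks <= len(DEFAULT_NETWORKS):
        names = list(DEFAULT_NETWORKS[:n_networks])
    else:
        names = list(DEFAULT_NETWORKS) + [
            f"NET{k:02d}" for k in range(len(DEFAULT_NETWORKS), n_networks)
        ]
    membership = np.resize(np.arange(n_networks), n_nodes)
    rng.shuffle(membership)
    coords = np.column_stack(
        [
            rng.uniform(-70, 70, n_nodes),
            rng.uniform(-100, 70, n_nodes),
            rng.uniform(-45, 75, n_nodes),
        ]
    ).round(1)
    return pd.DataFrame(
        {
            "node_id": [f"n{i:03d}" for i in range(n_nodes)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "network": [names[m] for m in membership],
            "atlas_community": membership,
        }
    )


@dataclass
class PlantedDynamics:
    """Ground-truth window partitions and where they switch.

    ``change_windows`` holds window indices w >= 1 at which partitions[w]
    differs from partitions[w-1]; conversion to volume indices or seconds
    requires the volumes-per-window / TR used by the signal generator.
    """

    partitions: np.ndarray  # (n_windows, n_nodes)
    change_windows: np.ndarray
    switch_rate: float
    n_communities: int

    def change_points_vol(self, vols_per_window: int) -> np.ndarray:
        return self.change_windows * vols_per_window

    def change_points_s(self, vols_per_window: int, tr: float) -> np.ndarray:
        return self.change_points_vol(vols_per_window) * tr


def gen_planted_dynamics(
    n_nodes: int,
    n_windows: int,
    switch_rate: float,
    n_communities: int,
    reassign_fraction: float = 1.0,
    seed: int = 0,
) -> PlantedDynamics:
    """Sequence of planted partitions switching at rate ``switch_rate``.

    Each adjacent window pair differs with probability switch_rate; when a
    switch occurs, ``reassign_fraction`` of nodes move to a different
    community (all nodes are redrawn into a fresh balanced partition when
    the fraction is 1).
    """
    if not 0.0 <= switch_rate <= 1.0:
        raise ValueError("switch_rate must lie in [0, 1]")
    if not 0.0 <= reassign_fraction <= 1.0:
        raise ValueError("reassign_fraction must lie in [0, 1]")
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    rng = np.random.default_rng(seed)

    def fresh() -> np.ndarray:
        lab = np.resize(np.arange(n_communities), n_nodes)
        rng.shuffle(lab)
        return lab

    parts = np.empty((n_windows, n_nodes), dtype=np.int64)
    parts[0] = fresh()
    changes = []
    for w in range(1, n_windows):
        prev = parts[w - 1]
        if switch_rate > 0 and rng.random() < switch_rate and n_communities > 1:
            if reassign_fraction >= 1.0:
                new = fresh()
                while np.array_equal(new, prev):  # pragma: no cover - astronomically rare
                    new = fresh()
            else:
                new = prev.copy()
                k = max(1, int(round(reassign_fraction * n_nodes)))
                movers = rng.choice(n_nodes, size=k, replace=False)
                shift = rng.integers(1, n_communities, size=k)
                new[movers] = (new[movers] + shift) % n_communities
            parts[w] = new
            changes.append(w)
        else:
            parts[w] = prev
    return PlantedDynamics(
        partitions=parts,
        change_windows=np.array(changes, dtype=np.int64),
        switch_rate=switch_rate,
        n_communities=n_communities,
    )


def gen_bold(
    dynamics: PlantedDynamics,
    tr: float = 1.0,
    vols_per_window: int = 16,
    snr: float = 3.0,
    seed: int = 0,
) -> RoiTimeSeries:
    """Community-structured BOLD-like signal following the planted partitions.

    Within each planted window, nodes of the same community share a latent
    signal; snr sets the latent-to-noise variance ratio (snr=inf gives
    within-community correlation 1).
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    n_windows, n_nodes = dynamics.partitions.shape
    n_vol = n_windows * vols_per_window
    if np.isinf(snr):
        a, b = 1.0, 0.0
    else:
        a = np.sqrt(snr / (1.0 + snr))
        b = np.sqrt(1.0 / (1.0 + snr))
    data = np.empty((n_vol, n_nodes))
    noise = rng.standard_normal((n_vol, n_nodes))
    for w in range(n_windows):
        rows = slice(w * vols_per_window, (w + 1) * vols_per_window)
        latents = rng.standard_normal((vols_per_window, dynamics.n_communities))
        data[rows] = a * latents[:, dynamics.partitions[w]] + b * noise[rows]
    return RoiTimeSeries(
        data=data, tr=tr, node_ids=[f"n{i:03d}" for i in range(n_nodes)]
    )


@dataclass
class SemanticFeatureTable:
    """Binary frame x feature presence matrix with per-feature word class."""

    values: np.ndarray  # (frames, features) of {0,1}
    classes: List[str]  # noun | verb | adjective per feature
    frame_rate: float  # frames per second

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("semantic features must be binary")
        if self.values.shape[1] != len(self.classes):
            raise ValueError("class list must match number of features")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    def class_mask(self, cls: str) -> np.ndarray:
        return np.array([c == cls for c in self.classes])


def gen_semantic(
    n_frames: int,
    n_nouns: int = 629,
    n_verbs: int = 229,
    change_points_frames: Sequence[int] = (),
    coupling_strength: float = 0.0,
    base_flip_rate: float = 0.01,
    seed: int = 0,
    n_adjectives: int = 1,
    frame_rate: float = 1.0,
) -> SemanticFeatureTable:
    """Binary feature streams whose flips concentrate at change points.

    At a change-point frame each feature flips with probability
    base_flip_rate + coupling_strength * SEMANTIC_BOOST; elsewhere with
    base_flip_rate.
    """
    if not 0.0 <= coupling_strength <= 1.0:
        raise ValueError("coupling_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_feat = n_nouns + n_verbs + n_adjectives
    classes = ["noun"] * n_nouns + ["verb"] * n_verbs + ["adjective"] * n_adjectives
    change = set(int(c) for c in change_points_frames)
    boosted = min(1.0, base_flip_rate + coupling_strength * SEMANTIC_BOOST)
    values = np.empty((n_frames, n_feat), dtype=np.int8)
    state = (rng.random(n_feat) < 0.2).astype(np.int8)
    values[0] = state
    for t in range(1, n_frames):
        p = boosted if t in change else base_flip_rate
        flips = rng.random(n_feat) < p
        state = state ^ flips
        values[t] = state
    return SemanticFeatureTable(values=values, classes=classes, frame_rate=frame_rate)


BEHAVIOR_NAMES = ("fluid_iq", "crystallized_iq", "anxiety", "depression", "negative_affect")


def gen_behavior(
    n_subjects: int,
    brain_indices: np.ndarray,
    loading_matrix: np.ndarray,
    noise_sd: float = 1.0,
    seed: int = 0,
    confounding: float = 0.0,
) -> pd.DataFrame:
    """Behavior table whose scored columns load linearly on brain indices.

    behavior = brain_indices @ loading_matrix + Gaussian noise; the named
    covariates (gender, handedness, education, motion, ROI homogeneity) are
    generated independently unless ``confounding`` > 0, which mixes the
    first brain index into age.
    """
    brain = np.asarray(brain_indices, dtype=float)
    L = np.asarray(loading_matrix, dtype=float)
    if brain.ndim != 2 or brain.shape[0] != n_subjects:
        raise ValueError("brain_indices must be (n_subjects, k)")
    if L.ndim != 2 or L.shape[0] != brain.shape[1]:
        raise ValueError("loading_matrix rows must match brain index count")
    if L.shape[1] > len(BEHAVIOR_NAMES):
        raise ValueError(f"at most {len(BEHAVIOR_NAMES)} scored behaviors supported")
    rng = np.random.default_rng(seed)
    scored = brain @ L + noise_sd * rng.standard_normal((n_subjects, L.shape[1]))
    df = pd.DataFrame({"subject_id": [f"sub-{i:04d}" for i in range(n_subjects)]})
    age = rng.uniform(18, 88, n_subjects)
    if confounding > 0:
        z = (brain[:, 0] - brain[:, 0].mean()) / (brain[:, 0].std() or 1.0)
        age = age + confounding * z * age.std()
    df["age"] = age.round(1)
    for j, name in enumerate(BEHAVIOR_NAMES):
        if j < L.shape[1]:
            df[name] = scored[:, j]
        else:
            df[name] = rng.standard_normal(n_subjects)
    df["gender"] = rng.integers(0, 2, n_subjects)
    df["handedness"] = (rng.random(n_subjects) < 0.9).astype(int)
    df["education_years"] = np.clip(rng.normal(14, 3, n_subjects), 6, 24).round(1)
    df["mean_relative_displacement"] = np.round(rng.lognormal(-2.5, 0.5, n_subjects), 4)
    df["roi_homogeneity"] = np.round(rng.normal(0.5, 0.05, n_subjects), 4)
    return df


def gen_nuisance(n_volumes: int, seed: int = 0) -> pd.DataFrame:
    """34 nuisance columns: 24 motion-derived + 10 smooth component regressors."""
    if n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    rng = np.random.default_rng(seed)
    motion6 = np.cumsum(rng.normal(0.0, 0.02, (n_volumes, 6)), axis=0)
    motion24 = motion_expansion(motion6)
    from scipy.ndimage import gaussian_filter1d

    comps = np.empty((n_volumes, 10))
    for c in range(10):
        smooth = gaussian_filter1d(rng.standard_normal(n_volumes), sigma=3.0, mode="reflect")
        comps[:, c] = (smooth - smooth.mean()) / (smooth.std() or 1.0)
    cols = (
        [f"mot_{k:02d}" for k in range(24)] + [f"comp_{k:02d}" for k in range(10)]
    )
    return pd.DataFrame(np.hstack([motion24, comps]), columns=cols)


def sphere_voxel_offsets(radius_mm: float, grid_mm: float) -> List[Tuple[int, int, int]]:
    """Integer lattice offsets within a sphere (ROI geometry check).

    All (i, j, k) with grid_mm * sqrt(i^2+j^2+k^2) <= radius_mm; a 5 mm
    radius on a 2 mm grid yields 81 voxels.
    """
    if not (radius_mm > 0 and grid_mm > 0):
        raise ValueError("radius and grid spacing must be positive")
    rmax = int(np.floor(radius_mm / grid_mm))
    lim = (radius_mm / grid_mm) ** 2 + 1e-12
    out: List[Tuple[int, int, int]] = []
    for i in range(-rmax, rmax + 1):
        for j in range(-rmax, rmax + 1):
            for k in range(-rmax, rmax + 1):
                if i * i + j * j + k * k <= lim:
                    out.append((i, j, k))
    return out
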