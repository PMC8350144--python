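"""End-to-end orchestration: simulate a cohort, run every stage, write results.

Stage order: denoise -> windowed FC -> community detection -> reconfiguration
metrics -> semantic coupling -> CCA / PLS inference.  All randomness is
derived from one cohort seed, so repeated runs with the same configuration
produce byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import logger
from . import io as nio
from .communities import ConsensusConfig, ModularityConfig, window_partitions
from .denoise import DenoiseConfig, denoise_pipeline
from .dynfc import WindowSpec, compute_windowed_fc
from .reconfig import (
    EventBoundarySet,
    boundary_index,
    boundary_pairs,
    subject_participation,
    w2w_index,
)
from .semalign import (
    coupling,
    fc_similarity_series,
    frames_for_windows,
    residualize_cohort,
    semantic_similarity_series,
    window_feature_fractions,
)
from .stats import StatsConfig, behavioral_pls, cv_cca
from .synthdata import (
    gen_behavior,
    gen_bold,
    gen_node_table,
    gen_nuisance,
    gen_planted_dynamics,
    gen_semantic,
)


@dataclass
class PipelineConfig:
    """Cohort, windowing, community, and inference settings in one place."""

    # synthetic cohort
    n_subjects: int = 30
    n_nodes: int = 60
    n_networks: int = 10
    n_communities: int = 4
    n_planted_windows: int = 20
    vols_per_window: int = 14
    tr: float = 1.0
    snr: float = 3.0
    switch_rate_range: Tuple[float, float] = (0.1, 0.9)
    reassign_fraction: float = 1.0
    coupling_strength: float = 0.6
    base_flip_rate: float = 0.01
    frame_rate: float = 1.0
    behavior_loadings: Tuple[float, ...] = (0.8, 0.5)
    behavior_noise_sd: float = 1.0
    # analysis
    window: WindowSpec = field(default_factory=WindowSpec)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    modularity: ModularityConfig = field(default_factory=ModularityConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    apply_denoise: bool = False  # synthetic signals carry no planted confounds
    x_cols: Tuple[str, ...] = (
        "w2w_reconfig",
        "noun_coupling",
        "verb_coupling",
        "participation_mean",
    )
    y_cols: Tuple[str, ...] = ("fluid_iq", "crystallized_iq")
    covar_cols: Tuple[str, ...] = ("age", "gender", "handedness", "mean_relative_displacement")
    pls_behavior_col: str = "fluid_iq"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("window", WindowSpec),
            ("denoise", DenoiseConfig),
            ("modularity", ModularityConfig),
            ("consensus", ConsensusConfig),
            ("stats", StatsConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        for key in ("switch_rate_range", "behavior_loadings", "x_cols", "y_cols", "covar_cols"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        if "modularity" in kwargs and isinstance(kwargs["modularity"], ModularityConfig):
            kwargs["modularity"].gammas = tuple(kwargs["modularity"].gammas)
        return cls(**kwargs)

    def to_dict(self) -> Dict:
        d = asdict(self)
        return d


def _subject_seed(cfg_seed: int, index: int, stream: int) -> int:
    ss = np.random.SeedSequence(entropy=cfg_seed, spawn_key=(stream, index))
    return int(ss.generate_state(1, np.uint32)[0])


def simulate_cohort(cfg: PipelineConfig, outdir: str) -> Dict:
    """Write a synthetic cohort (time series, nuisance, events, semantics,
    behavior, node table, ground truth) to ``outdir``.

    Each subject gets a planted switch rate drawn uniformly from
    ``switch_rate_range``; behavior loads on the standardized switch rates.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    nodes = gen_node_table(cfg.n_nodes, cfg.n_networks, seed=_subject_seed(cfg.seed, 0, 1))
    nio.write_node_table(nodes, os.path.join(outdir, "nodes.tsv"))
    switch_rates = rng.uniform(*cfg.switch_rate_range, cfg.n_subjects)
    n_vol = cfg.n_planted_windows * cfg.vols_per_window
    truth: Dict = {"switch_rates": switch_rates.tolist(), "subjects": []}
    for i in range(cfg.n_subjects):
        sid = f"sub-{i:04d}"
        dyn = gen_planted_dynamics(
            cfg.n_nodes,
            cfg.n_planted_windows,
            float(switch_rates[i]),
            cfg.n_communities,
            cfg.reassign_fraction,
            seed=_subject_seed(cfg.seed, i, 2),
        )
        ts = gen_bold(
            dyn, cfg.tr, cfg.vols_per_window, cfg.snr, seed=_subject_seed(cfg.seed, i, 3)
        )
        ts.subject_id = sid
        nio.write_timeseries(ts, os.path.join(outdir, f"{sid}_ts.tsv"))
        nuis = gen_nuisance(n_vol, seed=_subject_seed(cfg.seed, i, 4))
        nuis.to_csv(os.path.join(outdir, f"{sid}_nuisance.tsv"), sep="\t", index=False,
                    float_format=nio.FLOAT_FMT)
        onsets = dyn.change_points_s(cfg.vols_per_window, cfg.tr)
        nio.write_events(onsets, os.path.join(outdir, f"{sid}_events.tsv"))
        n_frames = int(round(n_vol * cfg.tr * cfg.frame_rate))
        sem = gen_semantic(
            n_frames,
            n_nouns=40,
            n_verbs=20,
            change_points_frames=[int(round(o * cfg.frame_rate)) for o in onsets],
            coupling_strength=cfg.coupling_strength,
            base_flip_rate=cfg.base_flip_rate,
            seed=_subject_seed(cfg.seed, i, 5),
            frame_rate=cfg.frame_rate,
        )
        nio.write_semantic(sem, os.path.join(outdir, f"{sid}_semantic.csv"))
        truth["subjects"].append(
            {"subject_id": sid, "n_changes": int(dyn.change_windows.size)}
        )
    z = (switch_rates - switch_rates.mean()) / switch_rates.std()
    loadings = np.array(cfg.behavior_loadings)[None, :]
    behavior = gen_behavior(
        cfg.n_subjects,
        z[:, None],
        loadings,
        noise_sd=cfg.behavior_noise_sd,
        seed=_subject_seed(cfg.seed, 0, 6),
    )
    nio.write_behavior(behavior, os.path.join(outdir, "behavior.csv"))
    truth["loadings"] = loadings.tolist()
    nio.write_json(truth, os.path.join(outdir, "ground_truth.json"))
    return truth


def subject_indices(
    cfg: PipelineConfig, data_dir: str, sid: str, nodes: pd.DataFrame
) -> Dict:
    """All per-subject scalar indices for one subject's files."""
    ts = nio.read_timeseries(os.path.join(data_dir, f"{sid}_ts.tsv"))
    nio.check_nodes_match(ts, nodes)
    if cfg.apply_denoise:
        nuis = pd.read_csv(os.path.join(data_dir, f"{sid}_nuisance.tsv"), sep="\t")
        ts = denoise_pipeline(ts, nuis.to_numpy(), cfg.denoise)
    wc = compute_windowed_fc(ts, cfg.window)
    pset = window_partitions(
        wc, cfg.modularity, cfg.consensus, seed=_subject_seed(cfg.seed, _sid_index(sid), 7)
    )
    out: Dict = {"subject_id": sid}
    out["w2w_reconfig"] = w2w_index(pset)
    events_path = os.path.join(data_dir, f"{sid}_events.tsv")
    out["boundary_reconfig"] = float("nan")
    if os.path.exists(events_path):
        onsets = nio.read_events(events_path)
        if onsets.size:
            pairs = boundary_pairs(EventBoundarySet(onsets), wc.windows, ts.tr)
            if pairs:
                out["boundary_reconfig"] = boundary_index(pset, pairs)
    fc_sims = fc_similarity_series(pset)
    sem_path = os.path.join(data_dir, f"{sid}_semantic.csv")
    out["noun_coupling"] = float("nan")
    out["verb_coupling"] = float("nan")
    if os.path.exists(sem_path):
        sem = nio.read_semantic(sem_path)
        frames = frames_for_windows(
            wc.windows, ts.tr, sem.frame_rate, sem.values.shape[0]
        )
        profile = window_feature_fractions(sem, frames)
        out["noun_coupling"] = coupling(fc_sims, semantic_similarity_series(profile, "noun"))
        out["verb_coupling"] = coupling(fc_sims, semantic_similarity_series(profile, "verb"))
    P, netP = subject_participation(pset, nodes)
    out["participation_mean"] = float(P.mean())
    for net, val in netP.items():
        out[f"part_{net}"] = float(val)
    out["_node_participation"] = P
    return out


def _sid_index(sid: str) -> int:
    return int(sid.rsplit("-", 1)[-1])


def run_pipeline(cfg: PipelineConfig, data_dir: str, out_dir: str) -> Dict:
    """Run every stage on a cohort directory and write the result bundle."""
    os.makedirs(out_dir, exist_ok=True)
    nodes = nio.read_node_table(os.path.join(data_dir, "nodes.tsv"))
    behavior = nio.read_behavior(
        os.path.join(data_dir, "behavior.csv"),
        required=list(cfg.y_cols) + list(cfg.covar_cols),
    )
    rows = []
    node_part = {}
    for sid in behavior["subject_id"]:
        logger.info("pipeline: subject %s", sid)
        row = subject_indices(cfg, data_dir, sid, nodes)
        node_part[sid] = row.pop("_node_participation")
        rows.append(row)
    idx = pd.DataFrame(rows)
    # cohort-level residualization: overall w2w reconfiguration out of couplings
    for col in ("noun_coupling", "verb_coupling"):
        if idx[col].notna().all():
            idx[col + "_resid"] = residualize_cohort(
                idx[col].to_numpy(), [idx["w2w_reconfig"].to_numpy()]
            )
        else:
            idx[col + "_resid"] = float("nan")
    idx_path = os.path.join(out_dir, "subject_indices.csv")
    idx.to_csv(idx_path, index=False, float_format=nio.FLOAT_FMT)
    wide = pd.DataFrame(
        {sid: node_part[sid] for sid in behavior["subject_id"]}
    ).T
    wide.columns = list(nodes["node_id"])
    wide.index.name = "subject_id"
    wide.to_csv(os.path.join(out_dir, "node_participation.csv"), float_format=nio.FLOAT_FMT)

    merged = idx.merge(behavior, on="subject_id", validate="one_to_one")
    needed = list(dict.fromkeys(list(cfg.x_cols) + list(cfg.y_cols) + list(cfg.covar_cols)))
    complete = merged[needed].notna().all(axis=1)
    if not complete.all():
        logger.warning(
            "dropping %d subjects with undefined indices before inference",
            int((~complete).sum()),
        )
        merged = merged[complete].reset_index(drop=True)
    X = merged[list(cfg.x_cols)].to_numpy()
    Y = merged[list(cfg.y_cols)].to_numpy()
    C = merged[list(cfg.covar_cols)].to_numpy(dtype=float)
    cca_res = cv_cca(X, Y, C, cfg.stats)
    echo = cfg.to_dict()
    nio.write_json(
        {
            "version": __version__,
            "config": echo,
            "r": cca_res.r,
            "p": cca_res.p,
            "x_cols": list(cfg.x_cols),
            "y_cols": list(cfg.y_cols),
            "x_loadings": cca_res.x_loadings.to_dict(orient="list"),
            "y_loadings": cca_res.y_loadings.to_dict(orient="list"),
            "folds": cca_res.folds,
        },
        os.path.join(out_dir, "cca.json"),
    )
    part_cols = [c for c in idx.columns if c.startswith("part_")]
    pls_res = behavioral_pls(
        merged[cfg.pls_behavior_col].to_numpy(), merged[part_cols].to_numpy(), cfg.stats
    )
    nio.write_json(
        {
            "version": __version__,
            "config": echo,
            "roi_cols": part_cols,
            "singular_values": pls_res.singular_values,
            "perm_p": pls_res.perm_p,
            "saliences": pls_res.saliences,
            "salience_se": pls_res.salience_se,
            "bsr": pls_res.bsr,
            "lv_behavior_corr": pls_res.lv_behavior_corr,
            "lv_behavior_corr_ci": pls_res.lv_behavior_corr_ci,
        },
        os.path.join(out_dir, "pls.json"),
    )
    return {"subject_indices": idx_path, "cca_r": cca_res.r, "cca_p": cca_res.p}
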