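"""On-disk formats: TSV time series, node/event tables, semantic CSV, JSON results.

All volume/window indices in files are 0-based half-open; event onsets are
seconds.  Numeric columns are written with 17 significant digits so that a
write-read round trip is exact.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .core import FormatError, RoiTimeSeries, logger
from .synthdata import SemanticFeatureTable

FLOAT_FMT = "%.17g"
SEMANTIC_CLASSES = ("noun", "verb", "adjective")


# ---------------------------------------------------------------------------
# time series


def write_timeseries(ts: RoiTimeSeries, path: str) -> None:
    node_ids = ts.node_ids or [f"n{i:03d}" for i in range(ts.n_nodes)]
    with open(path, "w") as fh:
        fh.write("\t".join(node_ids) + "\n")
        for row in ts.data:
            fh.write("\t".join(FLOAT_FMT % v for v in row) + "\n")
    sidecar = {"tr": ts.tr, "subject_id": ts.subject_id, "run_id": ts.run_id}
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, sort_keys=True)
        fh.write("\n")


def read_timeseries(path: str) -> RoiTimeSeries:
    sidecar_path = path + ".json"
    if not os.path.exists(sidecar_path):
        raise FormatError(f"{path}: missing metadata sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    if "tr" not in meta or meta["tr"] is None:
        raise FormatError(f"{sidecar_path}: missing tr")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise FormatError(
                    f"{path}: line {lineno}: expected {ncol} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric cell ({exc})")
    return RoiTimeSeries(
        data=np.array(rows),
        tr=float(meta["tr"]),
        node_ids=header,
        subject_id=meta.get("subject_id"),
        run_id=meta.get("run_id"),
    )


def check_nodes_match(ts: RoiTimeSeries, nodes: pd.DataFrame) -> None:
    """Raise naming the offending column if header and node table disagree."""
    ids = list(nodes["node_id"])
    header = list(ts.node_ids or [])
    extra = [c for c in header if c not in ids]
    missing = [c for c in ids if c not in header]
    if extra or missing:
        raise FormatError(
            f"time-series header does not match node table: "
            f"extra={extra[:3]} missing={missing[:3]}"
        )


# ---------------------------------------------------------------------------
# tables


def write_node_table(nodes: pd.DataFrame, path: str) -> None:
    nodes.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_node_table(path: str, allowed_networks: Optional[Sequence[str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"node_id", "x", "y", "z", "network", "atlas_community"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["node_id"].duplicated().any():
        dup = df.loc[df["node_id"].duplicated(), "node_id"].iloc[0]
        raise FormatError(f"{path}: duplicate node_id {dup!r}")
    if allowed_networks is not None:
        bad = set(df["network"]) - set(allowed_networks)
        if bad:
            raise FormatError(f"{path}: unknown network labels {sorted(bad)}")
    return df


def write_events(onsets_s: np.ndarray, path: str) -> None:
    pd.DataFrame({"onset_s": np.asarray(onsets_s, dtype=float)}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_events(path: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if "onset_s" not in df.columns:
        raise FormatError(f"{path}: missing onset_s column")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        logger.warning("%s: unsorted event onsets; sorting", path)
        onsets = np.sort(onsets)
    return onsets


def write_semantic(table: SemanticFeatureTable, path: str) -> None:
    """Dialect: row 1 feature ids, row 2 classes, row 3 frame_rate, then 0/1."""
    n_feat = table.values.shape[1]
    ids = [f"f{j:04d}" for j in range(n_feat)]
    with open(path, "w") as fh:
        fh.write(",".join(ids) + "\n")
        fh.write(",".join(table.classes) + "\n")
        fh.write(FLOAT_FMT % table.frame_rate + "," * (n_feat - 1) + "\n")
        for row in table.values:
            fh.write(",".join(str(int(v)) for v in row) + "\n")


def read_semantic(path: str) -> SemanticFeatureTable:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split(",")
        classes = fh.readline().rstrip("\n").split(",")
        rate_row = fh.readline().rstrip("\n").split(",")
        if not classes or classes == [""]:
            raise FormatError(f"{path}: missing feature-class row")
        bad = set(classes) - set(SEMANTIC_CLASSES)
        if bad:
            raise FormatError(f"{path}: row 2 must hold feature classes, found {sorted(bad)[:3]}")
        if len(classes) != len(ids):
            raise FormatError(f"{path}: class row length {len(classes)} != header {len(ids)}")
        try:
            frame_rate = float(rate_row[0])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: row 3 must start with frame_rate")
        rows = []
        for lineno, line in enumerate(fh, start=4):
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(ids):
                raise FormatError(f"{path}: line {lineno}: ragged row")
            try:
                rows.append([int(p) for p in parts])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-binary cell")
    return SemanticFeatureTable(values=np.array(rows), classes=classes, frame_rate=frame_rate)


def write_behavior(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_behavior(path: str, required: Optional[Sequence[str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: missing subject_id column")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise FormatError(f"{path}: missing values in column {col!r}")
    return df


# ---------------------------------------------------------------------------
# connectome / partition serialization


def write_connectome(wc, path: str) -> None:
    """Windowed connectome as an .npz archive with a JSON manifest inside."""
    manifest = {
        "windows": [list(w) for w in wc.windows],
        "tr": wc.tr,
        "spec": {"length_s": wc.spec.length_s, "step_s": wc.spec.step_s, "taper": wc.spec.taper},
        "node_ids": list(wc.node_ids) if wc.node_ids is not None else None,
    }
    np.savez_compressed(path, z=wc.z, manifest=json.dumps(manifest, sort_keys=True))


def read_connectome(path: str):
    from .dynfc import WindowSpec, WindowedConnectome

    with np.load(path, allow_pickle=False) as arc:
        z = arc["z"]
        manifest = json.loads(str(arc["manifest"]))
    return WindowedConnectome(
        z=z,
        windows=[tuple(w) for w in manifest["windows"]],
        tr=manifest["tr"],
        spec=WindowSpec(**manifest["spec"]),
        node_ids=manifest["node_ids"],
    )


def write_partitions(pset, path: str) -> None:
    payload = {str(g): pset.by_gamma[g].tolist() for g in pset.gammas}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
        fh.write("\n")


def read_partitions(path: str):
    from .communities import PartitionSet

    with open(path) as fh:
        payload = json.load(fh)
    return PartitionSet(
        by_gamma={float(g): np.array(v, dtype=np.int64) for g, v in payload.items()}
    )


def write_json(payload: Dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
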