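"""Reading and writing the pipeline's on-disk formats.

Signals: EDF (read via mne, optional dependency) or an npz numeric
container with a JSON sidecar carrying sampling rate and labels.
Annotations: 3-column TSV (start_s, end_s, label).  Networks: edge-list
CSV.  Window stacks: npz.  Configs and manifests: JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import WindowedFC
from .recording import Recording
from .simkit import GroundTruthNetwork, TaskSession

__all__ = [
    "read_recording", "write_recording",
    "read_annotations", "write_annotations",
    "read_network_csv", "write_network_csv",
    "read_windowed_fc", "write_windowed_fc",
    "write_session", "config_hash",
]

logger = logging.getLogger(__name__)


def write_recording(rec: Recording, path: str | Path) -> None:
    """npz container + .json sidecar (fs, channel labels)."""
    path = Path(path)
    np.savez_compressed(path, data=rec.data.astype(np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "bipolar_pairs": rec.bipolar_pairs,
    }, indent=2))


def _read_matrix_container(path: Path) -> Recording:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"{sidecar}: sampling rate 'fs' missing")
    with np.load(path) as z:
        data = np.asarray(z["data"], dtype=float)
    labels = meta.get("channel_labels") or []
    if labels and len(labels) != data.shape[0]:
        raise ValueError(
            f"{len(labels)} labels for {data.shape[0]} channels in {path}")
    if not np.isfinite(data).all():
        bad = [labels[i] if labels else str(i) for i in range(data.shape[0])
               if not np.isfinite(data[i]).all()]
        raise ValueError(f"NaN/inf samples in channel(s) {bad}")
    pairs = meta.get("bipolar_pairs")
    return Recording(data, float(meta["fs"]), labels,
                     [tuple(p) for p in pairs] if pairs else None)


def _read_edf(path: Path) -> Recording:
    try:
        from mne.io import read_raw_edf
    except ImportError as exc:       # pragma: no cover - mne is preinstalled
        raise ImportError("EDF support requires mne") from exc
    raw = read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data(), float(raw.info["sfreq"]),
                     list(raw.ch_names))


def read_recording(path: str | Path, apply_bipolar: bool = False) -> Recording:
    """Load a recording from EDF or the npz + JSON sidecar container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rec = _read_edf(path) if path.suffix.lower() == ".edf" \
        else _read_matrix_container(path)
    return rec.to_bipolar() if apply_bipolar else rec


def write_annotations(annotations: list[tuple[float, float, str]],
                      path: str | Path) -> None:
    pd.DataFrame(annotations, columns=["start_s", "end_s", "label"]
                 ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(float(r.start_s), float(r.end_s), str(r.label))
            for r in df.itertuples(index=False)]


def write_network_csv(net: GroundTruthNetwork, path: str | Path) -> None:
    rows = [(i, j, net.adjacency[i, j])
            for i in range(net.n_nodes) for j in range(net.n_nodes)
            if net.adjacency[i, j] > 0]
    pd.DataFrame(rows, columns=["source", "target", "weight"]
                 ).to_csv(path, index=False)


def read_network_csv(path: str | Path, n_nodes: int,
                     density: float = float("nan"),
                     seed: int = -1) -> GroundTruthNetwork:
    df = pd.read_csv(path)
    adjacency = np.zeros((n_nodes, n_nodes))
    for r in df.itertuples(index=False):
        adjacency[int(r.source), int(r.target)] = float(r.weight)
    return GroundTruthNetwork(n_nodes, adjacency, density, seed)


def write_session(session: TaskSession, out_dir: str | Path,
                  stem: str = "session") -> dict[str, Path]:
    """Recording + annotations + per-task truth networks under one directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"recording": out_dir / f"{stem}.npz",
             "annotations": out_dir / f"{stem}_annotations.tsv"}
    write_recording(session.recording, paths["recording"])
    write_annotations(session.annotations, paths["annotations"])
    for label, net in session.truth_networks.items():
        p = out_dir / f"{stem}_network_{label}.csv"
        write_network_csv(net, p)
        paths[f"network_{label}"] = p
    return paths


def write_windowed_fc(wfc: WindowedFC, path: str | Path) -> None:
    np.savez_compressed(
        Path(path),
        matrices=wfc.matrices,
        windows=np.array(wfc.windows),
        task_labels=np.array(wfc.task_labels),
        channel_labels=np.array(wfc.channel_labels),
    )


def read_windowed_fc(path: str | Path) -> WindowedFC:
    with np.load(path, allow_pickle=False) as z:
        return WindowedFC(
            [tuple(w) for w in z["windows"]],
            np.asarray(z["matrices"], dtype=float),
            [str(t) for t in z["task_labels"]],
            [str(c) for c in z["channel_labels"]],
        )


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
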