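"""Reading and writing the pipeline's standard file formats.

Raw recordings travel as Emotiv-style CSV (first row = channel names,
one sample per row, microvolts) with a JSON sidecar carrying session
metadata and the artifact ledger.  EDF input is supported through MNE
when it is installed.  Cleaned segments are stored in an HDF5 container;
matrices as labelled TSV; edge lists and feature tables as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .core import (
    ArtifactEvent, Montage, QCStatus, Recording, Segment, SessionMeta,
    emotiv_montage,
)

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "read_recording_edf",
    "write_segments_h5",
    "read_segments_h5",
    "write_matrix_tsv",
    "write_edge_list_csv",
    "write_brainnet_node_edge",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    """Emotiv-style CSV (samples x channels) plus a JSON sidecar.

    The sidecar stores fs, session metadata and the artifact ledger, so
    a round trip preserves everything but the montage coordinates (the
    standard template is re-attached on read).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rec.data.T, columns=list(rec.montage.channel_names))
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "fs": rec.fs,
        "subject": rec.meta.subject,
        "session": rec.meta.session,
        "task": rec.meta.task,
        "stage": rec.meta.stage,
        "artifacts": [dataclasses.asdict(ev) for ev in rec.artifacts],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_csv(
    path: str | Path,
    montage: Montage | None = None,
    fs: float = 128.0,
    meta: SessionMeta | None = None,
) -> Recording:
    """Read an Emotiv-style CSV; the JSON sidecar, when present, supplies
    fs, metadata and the artifact ledger."""
    path = Path(path)
    montage = montage or emotiv_montage()
    df = pd.read_csv(path)
    missing = [c for c in montage.channel_names if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing channels: {missing}")
    artifacts: tuple[ArtifactEvent, ...] = ()
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        fs = info.get("fs", fs)
        meta = SessionMeta(info["subject"], info["session"], info["task"])
        artifacts = tuple(ArtifactEvent(**ev) for ev in info.get("artifacts", []))
    if meta is None:
        raise ValueError("no sidecar found; pass meta explicitly")
    data = df[list(montage.channel_names)].to_numpy(float).T
    return Recording(data=data, fs=fs, montage=montage, meta=meta,
                     artifacts=artifacts)


def read_recording_edf(
    path: str | Path,
    meta: SessionMeta,
    montage: Montage | None = None,
) -> Recording:
    """Read an EDF export (requires the optional ``mne`` dependency).

    Channel names in the file must include the montage's 14 channels;
    voltages are converted from MNE's volts to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF input needs mne; install the 'edf' extra") from exc
    montage = montage or emotiv_montage()
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [raw.ch_names.index(c) for c in montage.channel_names]
    data = raw.get_data()[picks] * 1e6
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     montage=montage, meta=meta)


# ------------------------------------------------------------ segments

def write_segments_h5(segments: Sequence[Segment], path: str | Path) -> Path:
    """Cleaned segments and their QC labels in one HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for i, seg in enumerate(segments):
            g = f.create_group(f"segment_{i:05d}")
            g.create_dataset("data", data=seg.data, compression="gzip")
            g.attrs.update({
                "fs": seg.fs, "subject": seg.meta.subject,
                "session": seg.meta.session, "task": seg.meta.task,
                "index": seg.index, "start_sample": seg.start_sample,
                "qc": seg.qc.value,
                "corrections": json.dumps(seg.corrections),
            })
    return path


def read_segments_h5(
    path: str | Path, montage: Montage | None = None
) -> list[Segment]:
    montage = montage or emotiv_montage()
    segments = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            meta = SessionMeta(str(g.attrs["subject"]),
                               int(g.attrs["session"]),
                               str(g.attrs["task"]))
            segments.append(Segment(
                data=g["data"][()], fs=float(g.attrs["fs"]), montage=montage,
                meta=meta, index=int(g.attrs["index"]),
                start_sample=int(g.attrs["start_sample"]),
                qc=QCStatus(str(g.attrs["qc"])),
                corrections=json.loads(str(g.attrs["corrections"]))))
    return segments


# ------------------------------------------------------------ matrices

def write_matrix_tsv(
    values: np.ndarray, labels: Sequence[str], path: str | Path
) -> Path:
    """Square labelled matrix as TSV (row and column headers)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", float_format="%.6f")
    return path


def write_edge_list_csv(
    edges: Sequence[tuple[str, str, float]], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(edges, columns=["chan_a", "chan_b", "weight"]).to_csv(
        path, index=False, float_format="%.6f")
    return path


def write_brainnet_node_edge(
    montage: Montage,
    weights: np.ndarray,
    stem: str | Path,
    node_values: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """BrainNet-style plain-text ``.node`` and ``.edge`` files.

    Node lines: x y z color size label (template coordinates, z = 0).
    The edge file is the full weight matrix, whitespace-separated.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    node_path = stem.with_suffix(".node")
    edge_path = stem.with_suffix(".edge")
    vals = node_values if node_values is not None else np.ones(montage.n_channels)
    lines = []
    for c, v in zip(montage.channel_names, vals):
        x, y = montage.positions[c]
        lines.append(f"{x:.3f}\t{y:.3f}\t0.000\t1\t{v:.4f}\t{c}")
    node_path.write_text("\n".join(lines) + "\n")
    np.savetxt(edge_path, weights, fmt="%.6f", delimiter="\t")
    return node_path, edge_path
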