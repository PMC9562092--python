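"""Plain-text I/O: recordings as delimited matrix + JSON sidecar, event /
behavior / metric tables as TSV, adjacency matrices as labeled TSV, and
epoch sets as a binary array + JSON metadata.

EDF reading is delegated to MNE when it is installed; recordings written
by this package use the text format, which round-trips exactly and needs
no binary dependencies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, EpochSet


def write_recording(rec: EEGRecording, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (samples x channels) and ``<prefix>.json``."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".tsv")
    meta_path = prefix.with_suffix(".json")
    pd.DataFrame(rec.data.T, columns=rec.labels).to_csv(
        data_path, sep="\t", index=False, float_format="%.6f")
    meta = {
        "fs": rec.fs,
        "labels": list(rec.labels),
        "reference": rec.reference,
        "positions": None if rec.positions is None else rec.positions.tolist(),
        "unit": "uV",
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return data_path, meta_path


def read_recording(prefix) -> EEGRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    pos = meta.get("positions")
    return EEGRecording(
        data=df[meta["labels"]].to_numpy().T, fs=meta["fs"],
        labels=meta["labels"],
        positions=None if pos is None else np.asarray(pos),
        reference=meta.get("reference", "raw"))


def read_edf(path) -> EEGRecording:
    """Read an EDF recording via MNE (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                        labels=list(raw.ch_names))


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def write_adjacency(W: np.ndarray, labels: list[str], path) -> Path:
    """Channels x channels matrix with a channel-label header row/column."""
    path = Path(path)
    df = pd.DataFrame(W, index=labels, columns=labels)
    df.to_csv(path, sep="\t", index_label="channel")
    return path


def read_adjacency(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(Path(path), sep="\t", index_col="channel")
    return df.to_numpy(dtype=float), list(df.columns)


def write_epochs(epochs: EpochSet, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.npy`` (trials x channels x samples) plus JSON
    metadata."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".npy")
    meta_path = prefix.with_suffix(".json")
    np.save(data_path, epochs.data)
    meta = {
        "tmin": epochs.tmin, "tmax": epochs.tmax, "fs": epochs.fs,
        "condition": [str(c) for c in epochs.condition],
        "labels": list(epochs.labels),
        "positions": (None if epochs.positions is None
                      else epochs.positions.tolist()),
        "kept_mask": epochs.kept_mask.astype(int).tolist(),
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return data_path, meta_path


def read_epochs(prefix) -> EpochSet:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.load(prefix.with_suffix(".npy"))
    pos = meta.get("positions")
    return EpochSet(
        data=data, tmin=meta["tmin"], tmax=meta["tmax"], fs=meta["fs"],
        condition=np.asarray(meta["condition"], dtype=object),
        labels=meta["labels"],
        positions=None if pos is None else np.asarray(pos),
        kept_mask=np.asarray(meta["kept_mask"], dtype=bool))
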