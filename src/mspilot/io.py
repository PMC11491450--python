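"""Readers and writers.

The canonical on-disk format is plain text: a CSV potential matrix
(samples x channels, header row of channel names, µV) plus a JSON sidecar
carrying the sampling rate, channel names, sensor positions and reference
state.  BDF/EDF/FIF recordings are read through MNE and converted to the
same in-memory ``Recording``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import LabelSequence, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "write_maps",
    "read_maps",
    "write_labels",
    "read_labels",
    "file_sha256",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> list[Path]:
    """Write a recording as CSV matrix + JSON sidecar; returns the paths."""
    path = Path(path)
    if path.suffix.lower() != ".csv":
        raise ValueError("recordings are written as .csv (+ .json sidecar)")
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "positions": None if rec.positions is None else rec.positions.tolist(),
        "reference": rec.reference,
        "units": "uV",
        "schema_version": 1,
    }
    sc_path = _sidecar_path(path)
    sc_path.write_text(json.dumps(sidecar))
    return [path, sc_path]


def read_recording(path: str | Path) -> Recording:
    """Read a recording from CSV+sidecar, or BDF/EDF/FIF via MNE."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return _read_csv_recording(path)
    if suffix in (".edf", ".bdf", ".fif"):
        return _read_mne_recording(path, suffix)
    raise ValueError(f"unsupported recording format: {path.name}")


def _read_csv_recording(path: Path) -> Recording:
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise ValueError(f"missing JSON sidecar for {path.name}: {sc_path.name}")
    try:
        sidecar = json.loads(sc_path.read_text())
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise ValueError(f"could not parse {path.name}: {exc}") from exc
    names = sidecar["channel_names"]
    if list(df.columns) != list(names):
        raise ValueError(f"{path.name}: CSV header does not match sidecar channels")
    pos = sidecar.get("positions")
    return Recording(
        data=df.to_numpy(dtype=float).T,
        fs=float(sidecar["fs"]),
        channel_names=list(names),
        positions=None if pos is None else np.asarray(pos, dtype=float),
        reference=sidecar.get("reference", "other"),
    )


def _read_mne_recording(path: Path, suffix: str) -> Recording:
    import mne

    readers = {
        ".edf": mne.io.read_raw_edf,
        ".bdf": mne.io.read_raw_bdf,
        ".fif": mne.io.read_raw_fif,
    }
    try:
        raw = readers[suffix](path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"could not parse {path.name}: {exc}") from exc
    picks = mne.pick_types(raw.info, eeg=True, meg=False, exclude=[])
    data = raw.get_data(picks=picks) * 1e6  # volts -> µV
    names = [raw.ch_names[i] for i in picks]
    pos = None
    montage = raw.get_montage()
    if montage is not None:
        ch_pos = montage.get_positions()["ch_pos"]
        if all(n in ch_pos and np.isfinite(ch_pos[n]).all() for n in names):
            xyz = np.array([ch_pos[n] for n in names])
            norms = np.linalg.norm(xyz, axis=1, keepdims=True)
            if np.all(norms > 0):
                pos = xyz / norms
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        positions=pos,
        reference="other",
    )


def write_maps(maps: np.ndarray, channel_names: list[str], path: str | Path,
               class_labels: list[str] | None = None) -> Path:
    """Maps as CSV: one row per class, one column per channel."""
    path = Path(path)
    K = maps.shape[0]
    idx = class_labels if class_labels is not None else [str(k) for k in range(K)]
    pd.DataFrame(maps, index=pd.Index(idx, name="class"), columns=channel_names).to_csv(
        path, float_format="%.10g"
    )
    return path


def read_maps(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns)


def write_labels(seq: LabelSequence, path: str | Path) -> Path:
    path = Path(path)
    cols = {"label": seq.labels}
    if seq.corr is not None:
        cols["corr"] = seq.corr
    df = pd.DataFrame(cols)
    df.attrs["fs"] = seq.fs
    header = json.dumps(
        {"fs": seq.fs, "n_classes": seq.n_classes, "task_id": seq.task_id,
         "stage": seq.stage, "task_type": seq.task_type}
    )
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
    return path


def read_labels(path: str | Path) -> LabelSequence:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip())
        df = pd.read_csv(fh)
    return LabelSequence(
        labels=df["label"].to_numpy(dtype=int),
        fs=float(meta["fs"]),
        n_classes=int(meta["n_classes"]),
        corr=df["corr"].to_numpy(dtype=float) if "corr" in df else None,
        task_id=meta.get("task_id"),
        stage=meta.get("stage"),
        task_type=meta.get("task_type"),
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
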