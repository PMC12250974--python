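"""Readers and writers for recordings, paired-sample datasets and checkpoints.

Paired datasets use one HDF5 file with datasets ``/eeg [N x C x T]``,
``/emg [N x C x T]``, ``/label [N]``, ``/subject [N]``, ``/window [N]`` and
``/phase [N]``. Continuous recordings come from HDF5 or ``.npz`` archives with
a ``data`` array (channels x samples) and ``rate_hz`` / ``modality`` /
``subject_id`` attributes. Labels are CSV with columns ``subject_id``,
``segment_start_s``, ``segment_end_s``, ``label``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .model import ModelConfig, TRMMAAN, build_model
from .preprocessing import Modality, PairedSample, Recording

__all__ = ["read_recording", "read_labels_csv", "window_labels_from_segments",
           "save_paired_dataset", "load_paired_dataset", "save_checkpoint",
           "load_checkpoint"]


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return Recording(Modality(str(z["modality"])), z["data"],
                             float(z["rate_hz"]), str(z["subject_id"]))
    with h5py.File(path, "r") as f:
        d = f["data"]
        return Recording(Modality(str(d.attrs["modality"])), d[...],
                         float(d.attrs["rate_hz"]), str(d.attrs["subject_id"]))


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "segment_start_s", "segment_end_s", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label CSV missing columns: {sorted(missing)}")
    return df


def window_labels_from_segments(df: pd.DataFrame, subject_id: str,
                                n_windows: int, window_s: float = 1.0
                                ) -> np.ndarray:
    """One label per window, taken from the segment containing its midpoint.

    Windows outside any labeled segment get label -1 (dropped downstream).
    """
    sub = df[df.subject_id == subject_id]
    labels = np.full(n_windows, -1, dtype=np.int64)
    mid = (np.arange(n_windows) + 0.5) * window_s
    for _, row in sub.iterrows():
        inside = (mid >= row.segment_start_s) & (mid < row.segment_end_s)
        labels[inside] = int(row.label)
    return labels


def save_paired_dataset(path: str | Path, samples: list[PairedSample],
                        meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=np.stack([s.eeg for s in samples]))
        f.create_dataset("emg", data=np.stack([s.emg for s in samples]))
        f.create_dataset("label", data=np.array([s.label for s in samples]))
        f.create_dataset("subject", data=np.array(
            [s.subject_id for s in samples], dtype=h5py.string_dtype()))
        f.create_dataset("window", data=np.array(
            [s.window_index for s in samples]))
        f.create_dataset("phase", data=np.array(
            [s.eeg_phase for s in samples], dtype=h5py.string_dtype()))
        if meta:
            f.create_group("meta").attrs["json"] = json.dumps(meta)


def load_paired_dataset(path: str | Path) -> list[PairedSample]:
    with h5py.File(path, "r") as f:
        n = f["label"].shape[0]
        return [PairedSample(
            f["eeg"][i], f["emg"][i], int(f["label"][i]),
            f["subject"][i].decode(), int(f["window"][i]),
            f["phase"][i].decode()) for i in range(n)]


def save_checkpoint(path: str | Path, model: TRMMAAN,
                    history: list[dict] | None = None) -> None:
    """Single-file archive: config YAML + named parameter arrays."""
    payload = {f"param:{k}": v for k, v in model.state_dict().items()}
    meta = {
        "config": model.cfg.to_dict(),
        "n_channels": model.n_channels,
        "window_len": model.window_len,
        "history": history or [],
    }
    payload["meta_yaml"] = np.bytes_(yaml.safe_dump(meta).encode())
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> TRMMAAN:
    with np.load(path, allow_pickle=False) as z:
        meta = yaml.safe_load(bytes(z["meta_yaml"]).decode())
        cfg = ModelConfig.from_dict(meta["config"])
        model = build_model(cfg, meta["n_channels"], meta["window_len"], seed=0)
        state = {k[len("param:"):]: z[k] for k in z.files
                 if k.startswith("param:")}
    model.load_state_dict(state)
    return model
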