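"""Readers and writers.

Plain CSV is the interchange format (first column time in seconds, one
column per channel, header row with channel labels); an npz + JSON-sidecar
container gives exact binary replay of recordings.  Real EEG files (EDF,
BrainVision) are read through MNE; channel roles are assigned from the
caller's reference-label list.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from erase.scenario import MultichannelRecording

__all__ = ["read_recording", "write_recording_csv", "save_fixture",
           "load_fixture", "write_traces_csv", "read_traces_csv"]


def write_traces_csv(path, samples: np.ndarray, fs: float,
                     labels: list) -> None:
    """Channels x time array to CSV (time first column, labels as header)."""
    samples = np.atleast_2d(samples)
    t = np.arange(samples.shape[1]) / fs
    df = pd.DataFrame({"time_s": t})
    for lab, row in zip(labels, samples):
        df[lab] = row
    df.to_csv(path, index=False)


def read_traces_csv(path) -> tuple:
    """Read a channels-as-columns CSV; returns (samples, fs, labels)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("CSV must have a 'time_s' first column")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        fs = 1.0 / np.median(np.diff(t))
    else:
        fs = 1.0
    labels = [c for c in df.columns if c != "time_s"]
    return df[labels].to_numpy().T, float(fs), labels


def write_recording_csv(path, rec: MultichannelRecording) -> None:
    write_traces_csv(path, rec.stacked(), rec.fs,
                     list(rec.eeg_labels) + list(rec.ref_labels))


def _split_roles(samples, labels, ref_labels):
    ref_labels = list(ref_labels or [])
    eeg_idx = [i for i, l in enumerate(labels) if l not in ref_labels]
    ref_idx = [i for i, l in enumerate(labels) if l in ref_labels]
    return (samples[eeg_idx], samples[ref_idx] if ref_idx
            else np.zeros((0, samples.shape[1])),
            [labels[i] for i in eeg_idx], [labels[i] for i in ref_idx])


def read_recording(path, fmt: str | None = None,
                   ref_labels: list | None = None,
                   fs: float | None = None) -> MultichannelRecording:
    """Read a multichannel recording from CSV, EDF or BrainVision.

    ``ref_labels`` names the channels to treat as reference EMG; all other
    channels are EEG.  EDF/BrainVision amplitudes are converted to uV.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        samples, fs_read, labels = read_traces_csv(path)
        fs = fs or fs_read
    elif fmt in ("edf", "vhdr"):
        import mne
        reader = (mne.io.read_raw_edf if fmt == "edf"
                  else mne.io.read_raw_brainvision)
        raw = reader(str(path), preload=True, verbose="error")
        samples = raw.get_data() * 1e6
        labels = list(raw.ch_names)
        if fs is not None and abs(fs - raw.info["sfreq"]) > 1e-6:
            raise ValueError(f"sample rate mismatch: file has "
                             f"{raw.info['sfreq']} Hz, expected {fs}")
        fs = float(raw.info["sfreq"])
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    eeg, ref, eeg_labels, ref_names = _split_roles(samples, labels, ref_labels)
    return MultichannelRecording(eeg_block=eeg, ref_block=ref, fs=float(fs),
                                 eeg_labels=eeg_labels, ref_labels=ref_names)


def save_fixture(path, rec: MultichannelRecording, seed: int | None = None,
                 extra: dict | None = None) -> None:
    """Compressed array container with a JSON sidecar for exact replay."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), eeg=rec.eeg_block,
                        ref=rec.ref_block)
    meta = {"fs": rec.fs, "eeg_labels": list(rec.eeg_labels),
            "ref_labels": list(rec.ref_labels),
            "state_schedule": [list(s) for s in rec.state_schedule],
            "seed": seed,
            "truth": rec.truth.to_dict() if rec.truth is not None else None}
    meta.update(extra or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_fixture(path) -> MultichannelRecording:
    from erase.scenario import ScenarioSpec

    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    truth = (ScenarioSpec.from_dict(meta["truth"])
             if meta.get("truth") else None)
    return MultichannelRecording(
        eeg_block=arrays["eeg"], ref_block=arrays["ref"], fs=meta["fs"],
        state_schedule=[tuple(s) for s in meta["state_schedule"]],
        truth=truth, eeg_labels=meta["eeg_labels"],
        ref_labels=meta["ref_labels"])
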