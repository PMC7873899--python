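"""Electrode layouts, hat-band (outer-circumference) detection, and the
approximate head-edge positions of the reference EMG channels.

The hat band is the set of EEG electrodes on the outermost circumference of
the head: the IC-rejection rule flags components whose largest absolute
mixing coefficient lands on one of them, because myogenic sources project
most strongly onto the head's rim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["EEGMontage", "standard_montage", "STANDARD_32", "STANDARD_64"]

#: 32-channel subset of the 10-10 system (standard actiCap-style layout).
STANDARD_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]

#: 64-channel 10-10 layout used for real recordings.
STANDARD_64 = STANDARD_32 + [
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FT9", "FT7", "FC3",
    "FC4", "FT8", "FT10", "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4",
    "TP8", "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]

#: Approximate edge coordinates (unitless layout frame) of the reference EMG
#: channels, by muscle: polar angles around the head rim.
_EMG_EDGE_ANGLES = {
    "l_frontalis": 110.0, "r_frontalis": 70.0, "frontalis": 90.0,
    "l_temporalis": 160.0, "r_temporalis": 20.0, "temporalis": 160.0,
    "l_masseter": 195.0, "r_masseter": -15.0, "masseter": 195.0,
    "l_trapezius": 250.0, "r_trapezius": 290.0, "trapezius": 250.0,
    "eye_blink": 90.0,
}


@dataclass
class EEGMontage:
    """2-D projected electrode layout with hat-band annotation."""

    channel_labels: list
    positions: np.ndarray          # (n, 2) unitless layout coordinates
    hat_band: list                 # subset of channel_labels
    reference_emg_positions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        unknown = set(self.hat_band) - set(self.channel_labels)
        if unknown:
            raise ValueError(f"hat-band labels not in montage: {sorted(unknown)}")
        if len({tuple(p) for p in self.positions.round(9)}) != len(self.positions):
            raise ValueError("electrode positions must be unique")

    def index_of(self, label: str) -> int:
        return self.channel_labels.index(label)

    def is_hat_band(self, label: str) -> bool:
        return label in self.hat_band

    def to_yaml(self, path) -> None:
        rows = [{"label": lab, "x": float(x), "y": float(y),
                 "is_hat_band": lab in self.hat_band}
                for lab, (x, y) in zip(self.channel_labels, self.positions)]
        with open(path, "w") as fh:
            yaml.safe_dump(rows, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EEGMontage":
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        return cls(channel_labels=[r["label"] for r in rows],
                   positions=np.array([[r["x"], r["y"]] for r in rows]),
                   hat_band=[r["label"] for r in rows if r["is_hat_band"]])


def _hull_band(positions: np.ndarray, tol_frac: float = 0.08) -> np.ndarray:
    """Boolean mask of points on (or within tol of) the layout's convex hull."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(positions)
    scale = np.ptp(positions, axis=0).max()
    on_band = np.zeros(len(positions), dtype=bool)
    on_band[hull.vertices] = True
    # points close to a hull edge also count as rim electrodes
    verts = positions[np.append(hull.vertices, hull.vertices[0])]
    for a, b in zip(verts[:-1], verts[1:]):
        ab = b - a
        denom = ab @ ab
        for i, p in enumerate(positions):
            t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
            if np.linalg.norm(p - (a + t * ab)) < tol_frac * scale:
                on_band[i] = True
    return on_band


def standard_montage(n_channels: int = 32,
                     hat_band: list | None = None) -> EEGMontage:
    """Build the default 32- or 64-channel montage from the 10-10 system.

    Positions come from the standard MNE template montage projected to 2-D;
    the hat band defaults to the convex hull of the layout (plus electrodes
    within a small tolerance of it) and can be overridden explicitly.
    """
    import warnings

    import mne

    labels = {32: STANDARD_32, 64: STANDARD_64}.get(n_channels)
    if labels is None:
        raise ValueError("standard montages exist for 32 or 64 channels")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    pos3 = std.get_positions()["ch_pos"]
    positions = np.array([pos3[lab][:2] for lab in labels])
    if hat_band is None:
        hat_band = [lab for lab, on in zip(labels, _hull_band(positions)) if on]
    angles = np.deg2rad(list(_EMG_EDGE_ANGLES.values()))
    radius = 1.25 * np.linalg.norm(positions, axis=1).max()
    ref_pos = {m: (radius * np.cos(a), radius * np.sin(a))
               for m, a in zip(_EMG_EDGE_ANGLES, angles)}
    return EEGMontage(channel_labels=list(labels), positions=positions,
                      hat_band=list(hat_band),
                      reference_emg_positions=ref_pos)


def generic_montage(n_channels: int, hat_fraction: float = 0.45) -> EEGMontage:
    """A synthetic ring-plus-grid layout for arbitrary channel counts.

    Used in simulation when no anatomical montage applies: channels are laid
    out on concentric rings; the outermost ring is the hat band.
    """
    n_hat = min(n_channels, max(3, int(round(hat_fraction * n_channels))))
    labels = [f"ch{i+1}" for i in range(n_channels)]
    pos = np.zeros((n_channels, 2))
    angles_out = 2 * np.pi * np.arange(n_hat) / n_hat
    pos[:n_hat] = np.c_[np.cos(angles_out), np.sin(angles_out)]
    n_in = n_channels - n_hat
    if n_in:
        angles_in = 2 * np.pi * np.arange(n_in) / n_in + 0.1
        pos[n_hat:] = 0.55 * np.c_[np.cos(angles_in), np.sin(angles_in)]
    return EEGMontage(channel_labels=labels, positions=pos,
                      hat_band=labels[:n_hat])
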