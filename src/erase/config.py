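"""Serializable run configuration: a run is reproducible from config + seed."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a study driver needs, in one serializable object."""

    kind: str = "sensitivity"        # fp | sensitivity | effectiveness | session
    scenario: str = "S1"             # S1 | S2 (layout for fp/sensitivity)
    size: int = 2                    # S1: channels per type; S2: n types
    n_replicates: int = 20
    seed: int = 0
    duration: float = 60.0           # s of simulated record
    fs: float = 2000.0
    n_eeg_channels: int = 32
    # ICA
    max_iter: int = 200
    tol: float = 1e-4
    fit_decimate: int = 4
    # rejection
    gain: str | float = "auto"
    # band config
    bands: dict = field(default_factory=lambda: {"mu": [8.0, 12.0],
                                                 "hf": [40.0, 100.0]})
    montage: str | None = None       # path to a montage YAML, or None
    out_dir: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
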