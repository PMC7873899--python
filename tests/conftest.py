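"""Shared fixtures: small, seeded simulation objects reused across tests."""

import numpy as np
import pytest

from erase.emg import (FiberAP, SFAPGeometry, build_muap,
                       simulate_action_potential)
from erase.eeg import generate_simulated_eeg


@pytest.fixture(scope="session")
def action_potential() -> FiberAP:
    """One suprathreshold Hodgkin-Huxley action potential (default params)."""
    return simulate_action_potential()


@pytest.fixture(scope="session")
def coarse_ap(action_potential) -> FiberAP:
    """20 kHz copy of the AP used to keep SFAP/MUAP tests fast."""
    return FiberAP(samples=action_potential.samples[::5],
                   dt=action_potential.dt * 5)


@pytest.fixture(scope="session")
def geometry() -> SFAPGeometry:
    return SFAPGeometry()


@pytest.fixture(scope="session")
def small_muap(coarse_ap):
    """A 10-fiber motor-unit template (cheap stand-in for the 100-fiber one)."""
    return build_muap(n_fibers=10, seed=11, ap=coarse_ap)


@pytest.fixture(scope="session")
def short_eeg():
    """8-channel, 10 s surrogate EEG at 1 kHz."""
    return generate_simulated_eeg(n_channels=8, fs=1000.0, duration=10.0,
                                  seed=5)


@pytest.fixture(scope="session")
def schedule_10s():
    return [(0.0, 5.0, "idle"), (5.0, 7.0, "movement"), (7.0, 10.0, "idle")]
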