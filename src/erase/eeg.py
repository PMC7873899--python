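"""Surrogate EEG: band-structured noise with volume-conduction-like spatial
correlation.

Each channel is a linear mixture of five independent Gaussian noises,
band-passed to 1-30, 20-40, 40-80, 80-100 and 100-200 Hz, calibrated to a
target per-channel variance (default 30 uV^2).  Spatial correlation between
neighbouring channels is then introduced by a circular Gaussian smoothing
kernel across the channel index axis, mimicking volume conduction.  The
surrogate carries no physiological rhythms; it is structured noise only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from erase._rng import substream

__all__ = ["EEGArray", "EEG_BANDS", "generate_simulated_eeg", "spatial_smooth"]

#: The five generating bands (Hz).
EEG_BANDS = ((1.0, 30.0), (20.0, 40.0), (40.0, 80.0), (80.0, 100.0),
             (100.0, 200.0))


@dataclass
class EEGArray:
    """Multichannel EEG block (channels x time, uV)."""

    samples: np.ndarray
    fs: float
    channel_labels: list
    montage_ref: str = "sim32"

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _band_mixture(n_channels: int, n_samples: int, fs: float, weights,
                  rng) -> np.ndarray:
    """Sum of five band-limited unit-variance Gaussian noises per channel."""
    out = np.zeros((n_channels, n_samples))
    for (low, high), w in zip(EEG_BANDS, weights):
        noise = rng.standard_normal((n_channels, n_samples))
        sos = signal.butter(4, [low, high], btype="bandpass", fs=fs,
                            output="sos")
        band = signal.sosfiltfilt(sos, noise, axis=1)
        sd = band.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out += w * band / sd
    return out


def generate_simulated_eeg(n_channels: int = 32, fs: float = 2000.0,
                           duration: float = 300.0, max_amp: float = 60.0,
                           variance: float = 30.0, seed: int = 0,
                           band_weights=None,
                           smooth_sd_channels: float = 4.0) -> EEGArray:
    """Generate band-structured, spatially correlated surrogate EEG.

    Parameters
    ----------
    n_channels, fs, duration
        Array geometry; ``fs`` must exceed 400 Hz so the 100-200 Hz
        generating band fits under Nyquist.  Defaults: 32 channels at
        2,000 Hz, 5 minutes.
    max_amp, variance
        Amplitude calibration, uV and uV^2.  Channels are scaled to the
        target variance; if the global extreme then exceeds ``max_amp`` the
        whole array is rescaled down (clip-free cap).
    band_weights
        Relative weight of the five generating bands; default equal.
    smooth_sd_channels
        Standard deviation (in channel indices) of the circular Gaussian
        spatial-correlation kernel; 0 disables smoothing.
    """
    if fs <= 400:
        raise ValueError("fs must exceed 400 Hz to admit the 100-200 Hz band")
    n_samples = int(round(fs * duration))
    if n_samples == 0:
        return EEGArray(samples=np.zeros((n_channels, 0)), fs=fs,
                        channel_labels=[f"ch{i+1}" for i in range(n_channels)])
    weights = np.asarray(band_weights if band_weights is not None
                         else np.ones(len(EEG_BANDS)), dtype=float)
    rng = substream(seed, "eeg")
    x = _band_mixture(n_channels, n_samples, fs, weights, rng)

    eeg = EEGArray(samples=x, fs=fs,
                   channel_labels=[f"ch{i+1}" for i in range(n_channels)])
    if smooth_sd_channels > 0:
        eeg = spatial_smooth(eeg, smooth_sd_channels)
    x = eeg.samples

    # calibrate per-channel variance, then cap the global extreme
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x * (np.sqrt(variance) / sd)
    peak = np.abs(x).max()
    if peak > max_amp:
        x = x * (max_amp / peak)
    eeg.samples = x
    return eeg


def spatial_smooth(eeg: EEGArray, kernel_sd_channels: float) -> EEGArray:
    """Circular Gaussian smoothing across the channel index axis.

    The kernel wraps around (the last channels correlate with the first),
    its weights are normalized to sum to one, and the operation is linear
    and equivariant under rotation of the channel list.
    """
    if kernel_sd_channels <= 0:
        raise ValueError("kernel standard deviation must be positive")
    smoothed = ndimage.gaussian_filter1d(eeg.samples, kernel_sd_channels,
                                         axis=0, mode="wrap")
    return EEGArray(samples=smoothed, fs=eeg.fs,
                    channel_labels=list(eeg.channel_labels),
                    montage_ref=eeg.montage_ref)
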