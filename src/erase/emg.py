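"""Biophysically structured surface-EMG simulation.

The chain is: a Hodgkin-Huxley membrane action potential (the fiber source
waveform), propagated along a muscle fiber and observed through a
volume-conduction integral to give a single-fiber action potential (SFAP),
averaged over a population of fibers with Gaussian-scattered endplates and
conduction velocities to give a motor-unit action potential (MUAP), driven
by a piecewise-homogeneous Poisson firing process whose rate increases
during movement, and finally band-pass filtered to each muscle's spectral
profile.  The same chain produces both the "reference" traces appended to
the EEG before ICA and the "contaminant" traces mixed into EEG channels,
which guarantees the reference/contaminant dependence the decomposition
model requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from erase._rng import substream

__all__ = [
    "FiberAP", "SFAPGeometry", "MUAPTemplate", "FiringSchedule", "EMGTrace",
    "HH_SQUID_PARAMS", "MUSCLE_REGISTRY",
    "simulate_action_potential", "compute_sfap", "build_muap",
    "generate_firing_times", "synthesize_emg", "superpose_muaps",
    "simulate_muscle_emg",
]

# Classical squid-axon membrane constants at 6.3 degC (voltage convention:
# resting potential -65 mV).  Conductances mS/cm^2, potentials mV, C uF/cm^2.
HH_SQUID_PARAMS: dict = {
    "C_m": 1.0,
    "g_Na": 120.0,
    "g_K": 36.0,
    "g_L": 0.3,
    "E_Na": 50.0,
    "E_K": -77.0,
    "E_L": -54.387,
    "V_rest": -65.0,
    # stimulus: rectangular current pulse, uA/cm^2
    "stim_amplitude": 20.0,
    "stim_onset": 1e-3,      # s
    "stim_duration": 1e-3,   # s
}

#: Per-muscle spectral profile (low Hz, high Hz, filter order) and amplitude
#: calibration (target trace standard deviation, uV).  Facial/neck muscles
#: share a broad 20-100 Hz surface-EMG band and the 40/100 spikes/s
#: idle/movement motor-unit firing rates.  Eye blinks are a different kind
#: of event: sparse, large, slow 1-10 Hz transients occurring a few times
#: per minute (more often during effortful movement), so their event rate
#: replaces the motor-unit firing rate.
MUSCLE_REGISTRY: dict = {
    "frontalis": {"band": (20.0, 100.0), "order": 4, "amplitude": 30.0},
    "temporalis": {"band": (20.0, 100.0), "order": 4, "amplitude": 30.0},
    "masseter": {"band": (20.0, 100.0), "order": 4, "amplitude": 30.0},
    "trapezius": {"band": (20.0, 100.0), "order": 4, "amplitude": 30.0},
    "eye_blink": {"band": (1.0, 10.0), "order": 4, "amplitude": 100.0,
                  "rates": {"idle": 0.2, "movement": 0.5}},
}


def load_muscle_registry(path) -> dict:
    """Load a per-muscle config (band, order, amplitude, rates) from YAML."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    reg = {}
    for name, cfg in raw.items():
        cfg = dict(cfg)
        cfg["band"] = tuple(cfg["band"])
        reg[name] = cfg
    return reg


@dataclass
class FiberAP:
    """One membrane action-potential waveform on a uniform time grid."""

    samples: np.ndarray   # source waveform, mV relative to rest
    dt: float             # s

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("action potential contains non-finite values")


@dataclass
class SFAPGeometry:
    """Fiber/observation geometry for the volume-conduction integral.

    All lengths in metres; ``observation_point`` is (axial z, radial y)
    measured in the fiber's coordinate frame (z = 0 at one fiber end).
    """

    fiber_length: float = 0.12
    endplate_position: float = 0.06
    observation_point: tuple = (0.08, 0.005)
    conduction_velocity: float = 4.0
    spatial_step: float = 0.5e-3

    def __post_init__(self):
        if self.conduction_velocity <= 0:
            raise ValueError("conduction velocity must be positive")
        if not (0.0 <= self.endplate_position <= self.fiber_length):
            raise ValueError("endplate must lie within the fiber")
        if self.spatial_step <= 0:
            raise ValueError("spatial step must be positive")


@dataclass
class MUAPTemplate:
    """Motor-unit action potential: the average of many fiber SFAPs."""

    waveform: np.ndarray
    dt: float
    n_fibers: int
    endplate_sd: float
    velocity_mean: float
    velocity_sd: float

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.n_fibers < 1:
            raise ValueError("a motor unit needs at least one fiber")
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("MUAP waveform contains non-finite values")


@dataclass
class FiringSchedule:
    """Poisson motor-unit firing times under an idle/movement state schedule."""

    spike_times: np.ndarray                 # s, sorted ascending
    rate_by_state: dict                     # state -> spikes/s
    state_schedule: list                    # [(start_s, end_s, state), ...]

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)


@dataclass
class EMGTrace:
    """A synthesized surface-EMG channel."""

    samples: np.ndarray   # uV
    fs: float             # Hz
    muscle: str
    band: tuple           # (low Hz, high Hz)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG trace contains non-finite values")


# ---------------------------------------------------------------------------
# Step 1: Hodgkin-Huxley action potential
# ---------------------------------------------------------------------------

def _hh_rates(V):
    # rate constants in 1/ms, V in mV (rest at -65)
    an = 0.01 * (V + 55.0) / -np.expm1(-(V + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    am = 0.1 * (V + 40.0) / -np.expm1(-(V + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    return an, bn, am, bm, ah, bh


def hh_derivative(state, t_ms, p):
    """Right-hand side of the membrane equations (time in ms)."""
    V, m, h, n = state
    an, bn, am, bm, ah, bh = _hh_rates(V)
    I_stim = 0.0
    if p["stim_onset"] * 1e3 <= t_ms < (p["stim_onset"] + p["stim_duration"]) * 1e3:
        I_stim = p["stim_amplitude"]
    I_ion = (p["g_Na"] * m**3 * h * (V - p["E_Na"])
             + p["g_K"] * n**4 * (V - p["E_K"])
             + p["g_L"] * (V - p["E_L"]))
    dV = (I_stim - I_ion) / p["C_m"]
    dm = am * (1 - m) - bm * m
    dh = ah * (1 - h) - bh * h
    dn = an * (1 - n) - bn * n
    return np.array([dV, dm, dh, dn])


def hh_initial_state(p):
    V0 = p["V_rest"]
    an, bn, am, bm, ah, bh = _hh_rates(V0)
    return np.array([V0, am / (am + bm), ah / (ah + bh), an / (an + bn)])


def simulate_action_potential(membrane_params=None, duration: float = 0.03,
                              dt: float = 1e-5) -> FiberAP:
    """Integrate the Hodgkin-Huxley equations and return the AP waveform.

    Parameters
    ----------
    membrane_params
        Mapping of membrane constants and stimulus specification; defaults
        to :data:`HH_SQUID_PARAMS`.  Keys present override the defaults.
    duration, dt
        Simulation span and time step in seconds.  ``dt`` must be at most
        1e-5 s (0.01 ms) for stable fixed-step integration.

    Returns
    -------
    FiberAP
        Waveform is the membrane potential excursion from rest (mV), which
        serves as the fiber source term of the volume-conduction model.
    """
    if dt > 1e-5 + 1e-15:
        raise ValueError(f"time step {dt} s exceeds the 0.01 ms stability limit")
    p = dict(HH_SQUID_PARAMS)
    if membrane_params:
        p.update(membrane_params)

    n_steps = int(round(duration / dt))
    dt_ms = dt * 1e3
    state = hh_initial_state(p)
    out = np.empty(n_steps)
    for i in range(n_steps):
        t_ms = i * dt_ms
        out[i] = state[0]
        # classical fixed-step RK4
        k1 = hh_derivative(state, t_ms, p)
        k2 = hh_derivative(state + 0.5 * dt_ms * k1, t_ms + 0.5 * dt_ms, p)
        k3 = hh_derivative(state + 0.5 * dt_ms * k2, t_ms + 0.5 * dt_ms, p)
        k4 = hh_derivative(state + dt_ms * k3, t_ms + dt_ms, p)
        state = state + (dt_ms / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise RuntimeError(
                f"membrane integration diverged at step {i}; "
                f"reduce the step size (dt={dt} s)")
    return FiberAP(samples=out - p["V_rest"], dt=dt)


# ---------------------------------------------------------------------------
# Step 2: single-fiber action potential (volume conduction)
# ---------------------------------------------------------------------------

def compute_sfap(ap: FiberAP, geom: SFAPGeometry, K: float = 1.0) -> np.ndarray:
    """Evaluate the volume-conduction integral for one fiber.

    The source ``e(z, t)`` is the AP waveform propagating from the endplate
    toward both fiber ends at the geometry's conduction velocity.  The
    surface potential combines first-derivative terms at the two fiber end
    sections with the axial second-derivative integral over the fiber, each
    weighted by the reciprocal distance 1/r to the observation point.

    Discretization: integrating the volume term by parts twice moves all
    differentiation onto the 1/r kernel, whose z-derivatives are analytic,
    and cancels the end first-derivative terms exactly; what remains is
    ``e(0)u'(0) - e(L)u'(L) + integral e(z) u''(z) dz`` with ``u = 1/r``,
    evaluated by composite trapezoid quadrature on a uniform axial grid at
    ``geom.spatial_step``.  No numerical differentiation of the source is
    needed, so the scheme stays accurate for kinked waveforms.  ``K`` is
    the lumped conductivity/geometry proportionality constant; absolute
    amplitude is calibrated later per muscle.
    """
    z_obs, y_obs = geom.observation_point
    z = np.arange(0.0, geom.fiber_length + geom.spatial_step / 2,
                  geom.spatial_step)
    r = np.hypot(z - z_obs, y_obs)
    if np.any(r == 0):
        raise ValueError("observation point lies on the fiber axis (r = 0); "
                         "the 1/r kernel is singular there")

    w = ap.samples - ap.samples[0]
    delay = np.abs(z - geom.endplate_position) / geom.conduction_velocity
    n_t = len(w) + int(np.ceil(delay.max() / ap.dt)) + 1
    t = np.arange(n_t) * ap.dt
    ap_t = np.arange(len(w)) * ap.dt

    # e[t, z]: the AP delayed by the propagation time to each axial position
    tt = t[:, None] - delay[None, :]
    e = np.interp(tt.ravel(), ap_t, w, left=0.0, right=w[-1]).reshape(tt.shape)

    # analytic derivatives of the 1/r kernel along the fiber axis
    du = -(z - z_obs) / r**3
    d2u = -1.0 / r**3 + 3.0 * (z - z_obs) ** 2 / r**5

    boundary = e[:, 0] * du[0] - e[:, -1] * du[-1]
    volume = np.trapezoid(e * d2u[None, :], dx=geom.spatial_step, axis=1)
    return K * (boundary + volume)


# ---------------------------------------------------------------------------
# Step 3: motor-unit action potential
# ---------------------------------------------------------------------------

def build_muap(n_fibers: int = 100, endplate_sd: float = 2.5e-3,
               velocity_mean: float = 4.0, velocity_sd: float = 0.125,
               geom_base: SFAPGeometry | None = None, seed: int = 0,
               ap: FiberAP | None = None) -> MUAPTemplate:
    """Average ``n_fibers`` SFAPs into one motor-unit action potential.

    Endplate positions are drawn from N(base endplate, ``endplate_sd``) and
    conduction velocities from N(``velocity_mean``, ``velocity_sd``); the
    defaults (100 fibers, 2.5 mm endplate scatter, 4 +/- 0.125 m/s) are the
    standard literature values for limb/facial muscle motor units.
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    geom_base = geom_base or SFAPGeometry()
    ap = ap or simulate_action_potential()
    rng = substream(seed, "muap")

    endplates = geom_base.endplate_position + rng.normal(0.0, endplate_sd, n_fibers)
    endplates = np.clip(endplates, 0.0, geom_base.fiber_length)
    velocities = rng.normal(velocity_mean, velocity_sd, n_fibers)

    sfaps = []
    for ep, v in zip(endplates, velocities):
        geom = replace(geom_base, endplate_position=float(ep),
                       conduction_velocity=float(v))
        sfaps.append(compute_sfap(ap, geom))
    n_max = max(len(s) for s in sfaps)
    acc = np.zeros(n_max)
    for s in sfaps:
        acc[:len(s)] += s
        acc[len(s):] += s[-1]
    return MUAPTemplate(waveform=acc / n_fibers, dt=ap.dt, n_fibers=n_fibers,
                        endplate_sd=endplate_sd, velocity_mean=velocity_mean,
                        velocity_sd=velocity_sd)


# ---------------------------------------------------------------------------
# Step 4: Poisson firing process
# ---------------------------------------------------------------------------

def generate_firing_times(schedule: list, rate_by_state: dict | None = None,
                          initial_rate: float = 20.0, burn_in: float = 0.0,
                          seed: int = 0) -> FiringSchedule:
    """Draw motor-unit firing times from a piecewise-homogeneous Poisson process.

    Parameters
    ----------
    schedule
        Non-overlapping ``(start_s, end_s, state)`` intervals covering the
        record; states are typically ``"idle"`` and ``"movement"``.
    rate_by_state
        Spikes/s per state; default idle 40, movement 100.
    initial_rate, burn_in
        If ``burn_in`` > 0, the process is launched with a burn-in segment
        of that length at ``initial_rate`` (20 spikes/s by default) before
        the first interval; burn-in spikes are discarded from the output.
    """
    rate_by_state = rate_by_state or {"idle": 40.0, "movement": 100.0}
    if any(r < 0 for r in rate_by_state.values()) or initial_rate < 0:
        raise ValueError("firing rates must be non-negative")
    rng = substream(seed, "firing")

    segments = []
    if burn_in > 0:
        start0 = schedule[0][0] if schedule else 0.0
        segments.append((start0 - burn_in, start0, initial_rate, False))
    for start, end, state in schedule:
        segments.append((start, end, float(rate_by_state[state]), True))

    spikes = []
    for start, end, rate, keep in segments:
        if rate <= 0:
            continue
        t = start
        while True:
            t += rng.exponential(1.0 / rate)
            if t >= end:
                break
            if keep:
                spikes.append(t)
    return FiringSchedule(spike_times=np.sort(np.array(spikes)),
                          rate_by_state=dict(rate_by_state),
                          state_schedule=list(schedule))


# ---------------------------------------------------------------------------
# Step 5: trace synthesis
# ---------------------------------------------------------------------------

def _resample_muap(muap: MUAPTemplate, fs: float) -> np.ndarray:
    """Polyphase-resample the MUAP waveform from its grid to 1/fs."""
    ratio = Fraction(muap.dt * fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    if up == down:
        return muap.waveform.copy()
    return signal.resample_poly(muap.waveform, up, down)


def superpose_muaps(muap_fs: np.ndarray, spike_times: np.ndarray,
                    fs: float, n_samples: int) -> np.ndarray:
    """Linear superposition of one MUAP kernel at each spike time (no filter)."""
    train = np.zeros(n_samples)
    idx = np.round(np.asarray(spike_times) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n_samples)]
    np.add.at(train, idx, 1.0)
    if len(idx) == 0:
        return train
    return signal.fftconvolve(train, muap_fs)[:n_samples]


def synthesize_emg(muap: MUAPTemplate, firing: FiringSchedule, fs: float,
                   duration: float, band: tuple, muscle: str = "frontalis",
                   amplitude: float | None = None,
                   filter_order: int = 4) -> EMGTrace:
    """Superpose, band-limit and calibrate one muscle's EMG trace.

    The MUAP kernel is placed at every firing time, the superposition is
    band-pass filtered (zero-phase Butterworth) to the muscle's spectral
    profile, and the trace is scaled so its standard deviation matches the
    muscle's amplitude calibration (uV).  An empty firing schedule yields an
    all-zero trace.
    """
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band {band} must lie strictly inside (0, fs/2)")
    n = int(round(fs * duration))
    kern = _resample_muap(muap, fs)
    raw = superpose_muaps(kern, firing.spike_times, fs, n)
    if not np.any(raw):
        return EMGTrace(samples=raw, fs=fs, muscle=muscle, band=tuple(band))
    sos = signal.butter(filter_order, [low, high], btype="bandpass",
                        fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, raw)
    if amplitude is None:
        amplitude = MUSCLE_REGISTRY.get(muscle, {}).get("amplitude", 30.0)
    sd = filt.std()
    if sd > 0:
        filt = filt * (amplitude / sd)
    return EMGTrace(samples=filt, fs=fs, muscle=muscle, band=tuple(band))


def simulate_muscle_emg(muscle: str, schedule: list, fs: float,
                        duration: float, seed: int = 0,
                        muap: MUAPTemplate | None = None,
                        registry: dict | None = None) -> EMGTrace:
    """End-to-end EMG for one named muscle under a state schedule."""
    registry = registry or MUSCLE_REGISTRY
    if muscle not in registry:
        raise KeyError(f"unknown muscle {muscle!r}; known: {sorted(registry)}")
    cfg = registry[muscle]
    if muap is None:
        muap = build_muap(seed=seed)
    firing = generate_firing_times(schedule, rate_by_state=cfg.get("rates"),
                                   seed=seed)
    return synthesize_emg(muap, firing, fs, duration, band=cfg["band"],
                          muscle=muscle, amplitude=cfg["amplitude"],
                          filter_order=cfg.get("order", 4))
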