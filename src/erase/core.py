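"""The decomposition-and-rejection engine.

The EEG block and the (amplitude-standardized) reference EMG block are
stacked into one matrix and decomposed with a square symmetric FastICA.
Because the reference channels are *pure* artifact and statistically
dependent on the contaminant artifact inside the EEG, the myogenic variance
concentrates into the components that load on the reference rows of the
mixing matrix.  Those components are identified automatically from the
mixing matrix A:

* criterion 1 — any reference-row coefficient of the component exceeds a
  threshold, where the threshold is (mean reference-row RMS of A) x gain
  and the gain lies in the empirical range 0.4-3;
* criterion 2 — the component's largest absolute coefficient lands on a
  hat-band (outer-circumference) EEG electrode;
* simulation rule — with surrogate EEG no threshold is needed: for each
  reference row, the component with the largest absolute coefficient in
  that row is an artifact component.

Cleaned EEG is reconstructed by zeroing the flagged mixing columns and
back-projecting; the gain can be chosen automatically by sweeping 0.4-3 in
0.1 steps and minimizing movement-epoch high-frequency synchronization
(40-100 Hz, all channels) plus mu-band (8-12 Hz) power at the channel of
interest, i.e. rewarding mu desynchronization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from erase.montage import EEGMontage
from erase.scenario import MultichannelRecording

__all__ = [
    "ICADecomposition", "RejectionDecision", "run_reference_ica",
    "compute_rms_threshold", "select_artifact_ics",
    "select_artifact_ics_simulation", "sweep_gain", "reconstruct_clean",
    "GAIN_MIN", "GAIN_MAX",
]

GAIN_MIN, GAIN_MAX = 0.4, 3.0


@dataclass
class ICADecomposition:
    """Square ICA of the stacked EEG + reference matrix.

    ``mixing @ sources + mean`` reproduces the (standardized) input stack;
    the first rows of ``mixing`` correspond to EEG channels and the last
    rows to the reference EMG channels, in stack order.
    """

    mixing: np.ndarray          # (c, c) columns = per-IC channel loadings
    unmixing: np.ndarray        # (c, c)
    sources: np.ndarray         # (c, n) unit-variance IC time courses
    mean: np.ndarray            # (c,) per-channel mean removed before ICA
    row_roles: list             # "EEG" / "REF_EMG" per row
    fs: float
    converged: bool
    seed: int
    n_iter: int = 0
    ref_scale: np.ndarray | None = None   # std divided out of each ref row
    state_schedule: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    @property
    def eeg_rows(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.row_roles) if r == "EEG"])

    @property
    def ref_rows(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.row_roles)
                         if r == "REF_EMG"], dtype=int)

    def back_project(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Reconstruct the stack from the sources (optionally a column subset)."""
        A = self.mixing if keep is None else self.mixing[:, keep]
        S = self.sources if keep is None else self.sources[keep]
        return A @ S + self.mean[:, None]


@dataclass
class RejectionDecision:
    """Which components are artifacts, and why."""

    artifact_ics: list                      # sorted component indices
    rms: float | None = None
    gain: float | None = None
    threshold: float | None = None
    fired_criteria: dict = field(default_factory=dict)  # ic -> [criteria]
    objective: np.ndarray | None = None     # gain-sweep objective vector

    def __post_init__(self):
        self.artifact_ics = sorted(int(i) for i in set(self.artifact_ics))


def _check_rank(stack: np.ndarray, labels: list) -> None:
    sd = stack.std(axis=1)
    dead = [labels[i] for i in np.nonzero(sd == 0)[0]]
    if dead:
        raise ValueError(f"rank-deficient input: constant channels {dead}")
    c = np.corrcoef(stack)
    dup = [(labels[i], labels[j])
           for i in range(len(c)) for j in range(i + 1, len(c))
           if abs(c[i, j]) > 1 - 1e-10]
    if dup:
        raise ValueError(f"rank-deficient input: duplicate channels {dup}")


def run_reference_ica(rec: MultichannelRecording, seed: int = 0,
                      max_iter: int = 200, tol: float = 1e-4,
                      fit_decimate: int = 1,
                      standardize_refs: bool = True) -> ICADecomposition:
    """Square FastICA of the stacked EEG + reference matrix.

    Parameters
    ----------
    rec
        The recording; its reference rows are z-scored before stacking (so
        microvolt scale differences between EMG and EEG do not dominate the
        whitening) unless ``standardize_refs`` is False.
    seed, max_iter, tol
        FastICA initialisation seed and stopping rule (symmetric
        decorrelation, logcosh contrast).  Non-convergence is reported via
        the ``converged`` flag and a warning, never hidden.
    fit_decimate
        If > 1, the unmixing matrix is *fitted* on a polyphase-decimated
        copy of the data (the mixing matrix is time-invariant, so a few
        hundred samples per channel estimate it well) and then applied to
        the full-rate data.  Reconstruction remains exact at full rate.
    """
    stack = rec.stacked().astype(float)
    labels = list(rec.eeg_labels) + list(rec.ref_labels)
    n_ch, n_samp = stack.shape
    if n_samp < 20 * n_ch:
        raise ValueError(f"need at least {20 * n_ch} samples for {n_ch} "
                         f"channels; got {n_samp}")
    if not np.all(np.isfinite(stack)):
        raise ValueError("input contains non-finite values")
    _check_rank(stack, labels)

    # Standardize reference rows for numerical conditioning only: ICA is
    # scale-equivariant per channel, so the fitted model is converted back
    # to physical uV units below and every downstream criterion (RMS
    # threshold, hat-band maxima, detection inequality) sees the mixing
    # matrix in the recording's own units.
    d = np.ones(n_ch)
    c = np.zeros(n_ch)
    ref_scale = None
    if standardize_refs and rec.n_ref:
        refs = stack[rec.n_eeg:]
        ref_scale = refs.std(axis=1)
        if np.any(ref_scale == 0):
            raise ValueError("constant reference channel")
        d[rec.n_eeg:] = ref_scale
        c[rec.n_eeg:] = refs.mean(axis=1)
    std_stack = (stack - c[:, None]) / d[:, None]

    fit_data = std_stack
    if fit_decimate > 1:
        fit_data = _sig.resample_poly(std_stack, 1, fit_decimate, axis=1)

    ica = FastICA(whiten="unit-variance", fun="logcosh", algorithm="parallel",
                  max_iter=max_iter, tol=tol, random_state=int(seed))
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(fit_data.T)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn("FastICA did not converge within "
                          f"{max_iter} iterations; using the final iterate",
                          RuntimeWarning, stacklevel=2)

    # de-standardize: A_phys = diag(d) A_std, W_phys = W_std diag(1/d),
    # mean_phys = d * mean_std + c; sources are unchanged.  The mixing
    # matrix is recomputed as a float64 inverse so back-projection is exact.
    W_std = ica.components_.astype(np.float64)
    A_std = np.linalg.pinv(W_std)
    mean = d * ica.mean_.astype(np.float64) + c
    W = W_std / d[None, :]                # (c, c): S = W (X - mean)
    A = A_std * d[:, None]
    sources = W @ (stack - mean[:, None])
    return ICADecomposition(
        mixing=A, unmixing=W, sources=sources, mean=mean,
        row_roles=list(rec.roles), fs=rec.fs, converged=converged,
        seed=int(seed), n_iter=int(ica.n_iter_), ref_scale=ref_scale,
        state_schedule=list(rec.state_schedule))


def compute_rms_threshold(A: np.ndarray, row_roles: list,
                          gain: float) -> tuple:
    """Average reference-row RMS of the mixing matrix, times gain.

    Each reference row's RMS is sqrt(mean of squared coefficients across
    all columns); the average over reference rows is the base value and
    ``threshold = rms * gain`` with gain constrained to [0.4, 3].
    """
    if not GAIN_MIN <= gain <= GAIN_MAX:
        raise ValueError(f"gain {gain} outside the empirical range "
                         f"[{GAIN_MIN}, {GAIN_MAX}]")
    ref = [i for i, r in enumerate(row_roles) if r == "REF_EMG"]
    if not ref:
        raise ValueError("no reference EMG rows in the decomposition")
    row_rms = np.sqrt(np.mean(np.asarray(A)[ref] ** 2, axis=1))
    rms = float(row_rms.mean())
    return rms, rms * gain


def select_artifact_ics(A: np.ndarray, row_roles: list,
                        threshold: float | None,
                        montage: EEGMontage) -> RejectionDecision:
    """Flag artifact components by the threshold and hat-band criteria.

    Component j is flagged if any reference-row coefficient satisfies
    ``|A[ref, j]| > threshold`` (criterion 1; skipped when ``threshold`` is
    None, as in the conventional-ICA baseline), or if the row of the
    component's largest absolute coefficient is a hat-band EEG electrode
    (criterion 2; ties broken toward the lowest row index).
    """
    A = np.asarray(A)
    eeg_rows = [i for i, r in enumerate(row_roles) if r == "EEG"]
    ref_rows = [i for i, r in enumerate(row_roles) if r == "REF_EMG"]
    if len(eeg_rows) > len(montage.channel_labels):
        raise ValueError("montage does not cover all EEG rows")
    if threshold is not None and threshold < 0:
        raise ValueError("threshold must be non-negative")

    fired: dict = {}
    for j in range(A.shape[1]):
        crit = []
        if threshold is not None and ref_rows and \
                np.any(np.abs(A[ref_rows, j]) > threshold):
            crit.append("threshold")
        max_row = int(np.argmax(np.abs(A[:, j])))
        if max_row in eeg_rows and \
                montage.is_hat_band(montage.channel_labels[eeg_rows.index(max_row)]):
            crit.append("hat_band")
        if crit:
            fired[j] = crit
    return RejectionDecision(artifact_ics=list(fired), threshold=threshold,
                             fired_criteria=fired)


def select_artifact_ics_simulation(A: np.ndarray,
                                   row_roles: list) -> RejectionDecision:
    """Simulation rule: per reference row, flag its argmax-|coefficient| IC.

    Used in simulation scoring where the surrogate EEG carries no brain
    features and no threshold is needed.  k reference rows flag at most k
    components (duplicates merge); ties break toward the lowest column.
    """
    A = np.asarray(A)
    ref_rows = [i for i, r in enumerate(row_roles) if r == "REF_EMG"]
    if not ref_rows:
        raise ValueError("no reference EMG rows in the decomposition")
    fired: dict = {}
    for r in ref_rows:
        j = int(np.argmax(np.abs(A[r])))
        fired.setdefault(j, []).append("max_ref")
    return RejectionDecision(artifact_ics=list(fired), fired_criteria=fired)


def reconstruct_clean(decomp: ICADecomposition,
                      decision: RejectionDecision) -> MultichannelRecording:
    """Back-project with the flagged mixing columns zeroed; EEG rows only."""
    keep = np.setdiff1d(np.arange(decomp.n_components),
                        np.asarray(decision.artifact_ics, dtype=int))
    stack = decomp.back_project(keep=keep)
    eeg_rows = decomp.eeg_rows
    return MultichannelRecording(
        eeg_block=stack[eeg_rows], ref_block=np.zeros((0, stack.shape[1])),
        fs=decomp.fs, state_schedule=list(decomp.state_schedule))


def sweep_gain(rec: MultichannelRecording, decomp: ICADecomposition,
               montage: EEGMontage, gains: np.ndarray | None = None,
               band_cfg: dict | None = None,
               channel_of_interest: int = 0,
               epoch_layout: tuple = (1.0, 2.0)) -> tuple:
    """Choose the rejection gain automatically.

    For each candidate gain the threshold criteria are applied, the EEG is
    reconstructed without the flagged components, and the objective
    ``mean movement-epoch z-scored HF power over all channels
    + mean movement-epoch z-scored mu power at the channel of interest``
    is evaluated (z-scored against idle-epoch statistics, so negative mu
    values — desynchronization — lower the objective).  The argmin wins;
    ties break toward the lower gain.
    """
    from erase.bandpower import epoch_trials, stft_band_power

    if gains is None:
        gains = np.round(np.arange(GAIN_MIN, GAIN_MAX + 1e-9, 0.1), 10)
    band_cfg = band_cfg or {"mu": (8.0, 12.0), "hf": (40.0, 100.0)}
    if not rec.state_schedule:
        raise ValueError("gain sweep needs a state schedule (idle/movement)")
    onsets = [start for start, _end, state in rec.state_schedule
              if state == "movement"]
    idle_span, move_span = epoch_layout

    objective = np.full(len(gains), np.nan)
    decisions = []
    for k, g in enumerate(gains):
        _rms, thr = compute_rms_threshold(decomp.mixing, decomp.row_roles, g)
        decision = select_artifact_ics(decomp.mixing, decomp.row_roles, thr,
                                       montage)
        decision.gain = float(g)
        decision.rms = _rms
        decisions.append(decision)
        cleaned = reconstruct_clean(decomp, decision)
        if not np.all(np.isfinite(cleaned.eeg_block)):
            continue
        trials = epoch_trials(cleaned.eeg_block, rec.fs, onsets,
                              idle_span=idle_span, move_span=move_span)
        if trials.n_trials == 0:
            continue
        bp = stft_band_power(trials, bands=band_cfg)
        hf = bp.movement_mean("hf")                 # (channels,)
        mu = bp.movement_mean("mu")
        objective[k] = hf.mean() + mu[channel_of_interest]

    if np.all(np.isnan(objective)):
        raise RuntimeError("no candidate gain produced a usable reconstruction")
    best = int(np.nanargmin(objective))
    best_decision = decisions[best]
    best_decision.objective = objective
    return float(gains[best]), best_decision
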