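"""Seeded end-to-end study drivers.

Each driver wires simulate -> contaminate -> decompose -> reject -> score.
All randomness flows from one master seed through named substreams (EMG,
EEG, weights, ICA), so a study is reproducible from its config alone.  As
in the original simulation design, the EMG traces of a configuration are
generated once and reused across replicates, while the surrogate EEG, the
contamination weights/channels and the ICA initialisation are redrawn per
replicate.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from erase._rng import derive_int_seed, substream
from erase import emg as emg_mod
from erase.eeg import generate_simulated_eeg
from erase.montage import generic_montage
from erase.scenario import (SCENARIO1_TYPES, SCENARIO2_TYPES, ScenarioSpec,
                            MultichannelRecording, build_fp_scenario,
                            build_scenario2, build_sensitivity_scenario,
                            contaminate)
from erase.core import (run_reference_ica, select_artifact_ics,
                        select_artifact_ics_simulation, reconstruct_clean,
                        sweep_gain)
from erase.metrics import (EvaluationResult, artifact_index,
                           false_positive_event, sensitivity_test,
                           percent_reduction)
from erase.bandpower import (preprocess, epoch_trials, stft_band_power,
                             movement_hf_sum, TrialSet)
from erase.config import RunConfig

__all__ = [
    "alternating_schedule", "generate_emg_set", "run_fp_study",
    "run_sensitivity_study", "run_effectiveness_study", "run_session_study",
    "run_pipeline",
]


def alternating_schedule(duration: float, idle_span: float = 5.0,
                         move_span: float = 2.0) -> list:
    """Idle/movement state schedule covering [0, duration)."""
    schedule, t = [], 0.0
    while t < duration:
        idle_end = min(t + idle_span, duration)
        schedule.append((t, idle_end, "idle"))
        if idle_end >= duration:
            break
        move_end = min(idle_end + move_span, duration)
        schedule.append((idle_end, move_end, "movement"))
        t = move_end
    return schedule


def generate_emg_set(types: list, fs: float, duration: float,
                     schedule: list, seed: int) -> dict:
    """One EMG trace per artifact type (shared across a study's replicates).

    The membrane action potential is identical for every fiber, so it is
    simulated once and shared across muscles; the fiber populations
    (endplates, velocities) and firing processes stay muscle-specific.  The
    SFAP evaluation uses a 20 kHz copy of the AP — still an order of
    magnitude above the output rate.
    """
    ap_fine = emg_mod.simulate_action_potential()
    ap = emg_mod.FiberAP(samples=ap_fine.samples[::5], dt=ap_fine.dt * 5)
    traces = {}
    for k, muscle in enumerate(types):
        muap = emg_mod.build_muap(seed=derive_int_seed(seed, "muap", k),
                                  ap=ap)
        traces[muscle] = emg_mod.simulate_muscle_emg(
            muscle, schedule, fs, duration,
            seed=derive_int_seed(seed, "emg", k), muap=muap)
    return traces


def _replicate(spec: ScenarioSpec, emg_traces: dict, schedule: list,
               fs: float, duration: float, n_channels: int, rep_seed: int,
               max_iter: int, tol: float, fit_decimate: int):
    """Simulate one replicate and decompose it."""
    eeg = generate_simulated_eeg(n_channels, fs, duration,
                                 seed=derive_int_seed(rep_seed, "eeg"))
    rec = contaminate(eeg, emg_traces, spec, state_schedule=schedule)
    decomp = run_reference_ica(rec, seed=derive_int_seed(rep_seed, "ica"),
                               max_iter=max_iter, tol=tol,
                               fit_decimate=fit_decimate)
    decision = select_artifact_ics_simulation(decomp.mixing, decomp.row_roles)
    return rec, decomp, decision


def _study(kind: str, scenario: str, size: int, n_replicates: int, seed: int,
           duration: float, fs: float, n_channels: int, max_iter: int,
           tol: float, fit_decimate: int) -> EvaluationResult:
    schedule = alternating_schedule(duration)
    types = (SCENARIO1_TYPES if scenario == "S1"
             else SCENARIO2_TYPES[:size])
    emg_traces = generate_emg_set(types, fs, duration, schedule,
                                  derive_int_seed(seed, "emgset"))
    build = build_fp_scenario if kind == "fp" else build_sensitivity_scenario

    result = EvaluationResult(scenario_id=f"{kind}:{scenario}:{size}")
    for i in range(n_replicates):
        rep_seed = derive_int_seed(seed, "replicate", i)
        spec = build(scenario, size, seed=rep_seed,
                     n_eeg_channels=n_channels)
        rec, decomp, decision = _replicate(
            spec, emg_traces, schedule, fs, duration, n_channels, rep_seed,
            max_iter, tol, fit_decimate)
        ai = artifact_index(decomp.mixing, decision.artifact_ics,
                            spec.contaminated_channels,
                            spec.uncontaminated_channels)
        result.artifact_indices.append([float(v) for v in ai])
        result.ai_infinite += int(np.sum(np.isinf(ai)))
        result.seeds.append(rep_seed)
        if kind == "fp":
            result.fp_events.append(
                false_positive_event(decomp, decision, spec))
        else:
            result.sens_events.append(
                sensitivity_test(decomp, decision, spec))
    return result


def run_fp_study(scenario: str = "S1", size: int = 2,
                 n_replicates: int = 20, seed: int = 0,
                 duration: float = 60.0, fs: float = 2000.0,
                 n_channels: int = 32, max_iter: int = 200,
                 tol: float = 1e-4, fit_decimate: int = 4) -> EvaluationResult:
    """False-positive study: independent Gaussian contaminant, EMG references.

    Scores the fraction of replicates in which any flagged artifact
    component satisfies the detection inequality (which would wrongly claim
    the independent contaminant was captured).
    """
    return _study("fp", scenario, size, n_replicates, seed, duration, fs,
                  n_channels, max_iter, tol, fit_decimate)


def run_sensitivity_study(scenario: str = "S1", size: int = 2,
                          n_replicates: int = 20, seed: int = 0,
                          duration: float = 60.0, fs: float = 2000.0,
                          n_channels: int = 32, max_iter: int = 200,
                          tol: float = 1e-4,
                          fit_decimate: int = 4) -> EvaluationResult:
    """Sensitivity study: the same EMG is contaminant and reference.

    A replicate succeeds iff the detection inequality holds in *all*
    flagged artifact components.
    """
    return _study("sens", scenario, size, n_replicates, seed, duration, fs,
                  n_channels, max_iter, tol, fit_decimate)


def run_effectiveness_study(n_types: int = 3, n_replicates: int = 20,
                            seed: int = 0, duration: float = 60.0,
                            fs: float = 2000.0, n_channels: int = 32,
                            max_iter: int = 200, tol: float = 1e-4,
                            fit_decimate: int = 4) -> dict:
    """Paired artifact-index comparison: reference-augmented vs plain ICA.

    Each replicate is decomposed twice on the same contaminated EEG — once
    with the EMG reference channels appended (artifact components by the
    per-reference-row maximum rule) and once without them (conventional
    ICA; artifact components by the hat-band criterion only).  Returns the
    pooled per-column artifact indices for both conditions.
    """
    schedule = alternating_schedule(duration)
    types = SCENARIO2_TYPES[:n_types]
    emg_traces = generate_emg_set(types, fs, duration, schedule,
                                  derive_int_seed(seed, "emgset"))
    montage = generic_montage(n_channels)

    erase_ai, conventional_ai = [], []
    for i in range(n_replicates):
        rep_seed = derive_int_seed(seed, "replicate", i)
        spec = build_scenario2(n_types, seed=rep_seed,
                               n_eeg_channels=n_channels)
        eeg = generate_simulated_eeg(n_channels, fs, duration,
                                     seed=derive_int_seed(rep_seed, "eeg"))
        rec = contaminate(eeg, emg_traces, spec, state_schedule=schedule)

        decomp = run_reference_ica(rec, seed=derive_int_seed(rep_seed, "ica"),
                                   max_iter=max_iter, tol=tol,
                                   fit_decimate=fit_decimate)
        decision = select_artifact_ics_simulation(decomp.mixing,
                                                  decomp.row_roles)
        ai = artifact_index(decomp.mixing, decision.artifact_ics,
                            spec.contaminated_channels,
                            spec.uncontaminated_channels)
        erase_ai.extend(float(v) for v in ai)

        rec_plain = MultichannelRecording(
            eeg_block=rec.eeg_block,
            ref_block=np.zeros((0, rec.eeg_block.shape[1])), fs=fs,
            state_schedule=schedule, truth=spec)
        decomp_p = run_reference_ica(
            rec_plain, seed=derive_int_seed(rep_seed, "ica_plain"),
            max_iter=max_iter, tol=tol, fit_decimate=fit_decimate)
        decision_p = select_artifact_ics(decomp_p.mixing, decomp_p.row_roles,
                                         threshold=None, montage=montage)
        if decision_p.artifact_ics:
            ai_p = artifact_index(decomp_p.mixing, decision_p.artifact_ics,
                                  spec.contaminated_channels,
                                  spec.uncontaminated_channels)
            conventional_ai.extend(float(v) for v in ai_p)
    return {"erase_ai": erase_ai, "conventional_ai": conventional_ai,
            "n_replicates": n_replicates}


def _session_trials(block: np.ndarray, fs: float, n_trials: int,
                    trial_len: float, labels=None) -> TrialSet:
    """Cut a concatenated-trials block back into its contiguous trials."""
    n_t = int(round(trial_len * fs))
    trials = np.stack([block[:, k * n_t:(k + 1) * n_t]
                       for k in range(n_trials)])
    return TrialSet(trials=trials, fs=fs, epoch_layout=(1.0, 2.0),
                    channel_labels=labels)


def run_session_study(n_subjects: int = 2, n_trials: int = 8,
                      fs: float = 500.0, n_channels: int = 16,
                      n_types: int = 3, seed: int = 0,
                      gain="auto", max_iter: int = 200, tol: float = 1e-4,
                      fit_decimate: int = 1) -> pd.DataFrame:
    """Per-subject percent-reduction table on synthetic sessions.

    Reproduces the *form* of the real-data analysis — per subject, the
    movement-epoch z-scored HF and mu band power under baseline,
    reference-augmented cleaning and conventional ICA, with the percent
    reduction of summed HF power — on synthetic sessions of
    idle-5 s / move-2 s trials.  Real per-subject values require the
    original recordings, which are not released.
    """
    montage = generic_montage(n_channels)
    coi = n_channels - 1          # an inner (non-hat-band) channel
    trial_len = 3.0               # 1 s idle + 2 s movement per extracted trial
    rows = []
    for subj in range(n_subjects):
        s_seed = derive_int_seed(seed, "subject", subj)
        session_len = n_trials * 7.0
        schedule = alternating_schedule(session_len, 5.0, 2.0)
        types = SCENARIO2_TYPES[:n_types]
        emg_traces = generate_emg_set(types, fs, session_len, schedule,
                                      derive_int_seed(s_seed, "emgset"))
        spec = build_scenario2(n_types, seed=s_seed,
                               n_eeg_channels=n_channels,
                               n_per_type=max(2, n_channels // (2 * n_types)))
        eeg = generate_simulated_eeg(n_channels, fs, session_len, seed=s_seed)
        rec = contaminate(eeg, emg_traces, spec, state_schedule=schedule)

        stack = preprocess(rec.stacked(), fs)
        onsets = [s for s, _e, st in schedule
                  if st == "movement" and s >= 1.0 and s + 2.0 <= session_len]
        trials_all = epoch_trials(stack, fs, onsets)
        concat = trials_all.concatenated()
        n_kept = trials_all.n_trials
        concat_schedule = [(k * trial_len, k * trial_len + 1.0, "idle")
                           for k in range(n_kept)]
        concat_schedule += [(k * trial_len + 1.0, (k + 1) * trial_len,
                             "movement") for k in range(n_kept)]
        concat_schedule.sort()

        def bandpower_of(block):
            ts = _session_trials(block, fs, n_kept, trial_len)
            return stft_band_power(ts)

        bp_base = bandpower_of(concat[:n_channels])
        base_sum = movement_hf_sum(bp_base)

        # reference-augmented cleaning (simulated EMG references)
        rec_c = MultichannelRecording(
            eeg_block=concat[:n_channels], ref_block=concat[n_channels:],
            fs=fs, state_schedule=concat_schedule, truth=spec)
        decomp = run_reference_ica(rec_c, seed=derive_int_seed(s_seed, "ica"),
                                   max_iter=max_iter, tol=tol,
                                   fit_decimate=fit_decimate)
        if gain == "auto":
            _g, decision = sweep_gain(rec_c, decomp, montage,
                                      channel_of_interest=coi)
        else:
            from erase.core import compute_rms_threshold
            _rms, thr = compute_rms_threshold(decomp.mixing,
                                              decomp.row_roles, float(gain))
            decision = select_artifact_ics(decomp.mixing, decomp.row_roles,
                                           thr, montage)
        cleaned = reconstruct_clean(decomp, decision)
        bp_erase = bandpower_of(cleaned.eeg_block)

        # conventional ICA (no reference channels, hat-band criterion only)
        rec_p = MultichannelRecording(
            eeg_block=concat[:n_channels],
            ref_block=np.zeros((0, concat.shape[1])), fs=fs,
            state_schedule=concat_schedule)
        decomp_p = run_reference_ica(rec_p,
                                     seed=derive_int_seed(s_seed, "ica_p"),
                                     max_iter=max_iter, tol=tol,
                                     fit_decimate=fit_decimate)
        decision_p = select_artifact_ics(decomp_p.mixing, decomp_p.row_roles,
                                         threshold=None, montage=montage)
        cleaned_p = reconstruct_clean(decomp_p, decision_p)
        bp_conv = bandpower_of(cleaned_p.eeg_block)

        for cond, bp in (("baseline", bp_base),
                         ("erase_simulated_emg", bp_erase),
                         ("conventional_ica", bp_conv)):
            hf = bp.trial_movement_mean("hf").mean(axis=1)
            mu = bp.trial_movement_mean("mu")[:, coi]
            row = {"subject": f"S{subj+1}", "condition": cond,
                   "z_hf_mean": float(hf.mean()), "z_hf_sd": float(hf.std()),
                   "z_mu_mean": float(mu.mean()), "z_mu_sd": float(mu.std())}
            if cond == "baseline":
                row["reduction_pct"] = 0.0
            else:
                row["reduction_pct"] = percent_reduction(
                    base_sum, movement_hf_sum(bp))
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the study named by ``config.kind`` and (optionally) write reports.

    Reports are deterministic given config + seed: JSON with sorted keys and
    a CSV of replicate-level outcomes, byte-identical across reruns.
    """
    common = dict(seed=config.seed, duration=config.duration, fs=config.fs,
                  n_channels=config.n_eeg_channels, max_iter=config.max_iter,
                  tol=config.tol, fit_decimate=config.fit_decimate)
    if config.kind == "fp":
        result = run_fp_study(config.scenario, config.size,
                              config.n_replicates, **common)
        report = result.to_dict()
    elif config.kind == "sensitivity":
        result = run_sensitivity_study(config.scenario, config.size,
                                       config.n_replicates, **common)
        report = result.to_dict()
    elif config.kind == "effectiveness":
        report = run_effectiveness_study(config.size, config.n_replicates,
                                         **common)
    elif config.kind == "session":
        df = run_session_study(n_subjects=config.n_replicates,
                               seed=config.seed,
                               max_iter=config.max_iter, tol=config.tol)
        report = {"table": df.to_dict(orient="records")}
    else:
        raise ValueError(f"unknown study kind {config.kind!r}")

    report["config"] = {k: v for k, v in vars(config).items()}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{config.kind}_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        if "table" in report:
            pd.DataFrame(report["table"]).to_csv(
                out / f"{config.kind}_table.csv", index=False)
    return report
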