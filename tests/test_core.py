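"""Decomposition and rejection engine: recovery, criteria, reconstruction."""

import numpy as np
import pytest

from erase.core import (GAIN_MAX, GAIN_MIN, compute_rms_threshold,
                        reconstruct_clean, run_reference_ica,
                        select_artifact_ics, select_artifact_ics_simulation,
                        sweep_gain)
from erase.montage import generic_montage
from erase.scenario import MultichannelRecording


def _super_gaussian_mix(n_sources=3, n=20000, seed=0):
    rng = np.random.default_rng(seed)
    S = rng.laplace(size=(n_sources, n))
    A = rng.normal(size=(n_sources, n_sources))
    return A, S, A @ S


@pytest.fixture(scope="module")
def toy_decomp():
    _A, _S, X = _super_gaussian_mix()
    rec = MultichannelRecording(eeg_block=X, ref_block=np.zeros((0, X.shape[1])),
                                fs=1000.0)
    return run_reference_ica(rec, seed=3)


class TestDecomposition:
    def test_recovers_sources_of_exact_mix(self, toy_decomp):
        """Correlation matching against the known generators: each true
        source is recovered by some IC up to permutation/sign at
        |corr| > 0.99."""
        _A, S, _X = _super_gaussian_mix()
        c = np.corrcoef(np.vstack([S, toy_decomp.sources]))[:3, 3:]
        best = np.abs(c).max(axis=1)
        assert np.all(best > 0.99)

    def test_back_projection_round_trip(self, toy_decomp):
        _A, _S, X = _super_gaussian_mix()
        rebuilt = toy_decomp.back_project()
        rel = np.linalg.norm(rebuilt - X) / np.linalg.norm(X)
        assert rel < 1e-6

    def test_round_trip_with_reference_standardization(self):
        """De-standardization makes reconstruction exact in physical units
        even though the reference rows are rescaled internally."""
        rng = np.random.default_rng(1)
        S = rng.laplace(size=(4, 15000))
        A = rng.normal(size=(4, 4))
        X = A @ S
        rec = MultichannelRecording(eeg_block=X[:3] * 5.0,
                                    ref_block=X[3:] * 40.0, fs=500.0)
        d = run_reference_ica(rec, seed=2)
        rel = (np.linalg.norm(d.back_project() - rec.stacked())
               / np.linalg.norm(rec.stacked()))
        assert rel < 1e-6

    def test_rank_deficient_input_names_channels(self):
        x = np.random.default_rng(0).normal(size=(3, 2000))
        x[2] = x[1]
        rec = MultichannelRecording(eeg_block=x,
                                    ref_block=np.zeros((0, 2000)), fs=100.0,
                                    eeg_labels=["a", "b", "c"])
        with pytest.raises(ValueError, match="rank-deficient"):
            run_reference_ica(rec, seed=0)

    def test_too_few_samples_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 50))
        rec = MultichannelRecording(eeg_block=x,
                                    ref_block=np.zeros((0, 50)), fs=100.0)
        with pytest.raises(ValueError, match="samples"):
            run_reference_ica(rec, seed=0)

    def test_decimated_fit_matches_full_fit_up_to_sign_perm(self):
        _A, S, X = _super_gaussian_mix(seed=5)
        rec = MultichannelRecording(eeg_block=X,
                                    ref_block=np.zeros((0, X.shape[1])),
                                    fs=1000.0)
        d_full = run_reference_ica(rec, seed=3)
        d_dec = run_reference_ica(rec, seed=3, fit_decimate=4)
        c = np.corrcoef(np.vstack([d_full.sources, d_dec.sources]))[:3, 3:]
        assert np.all(np.abs(c).max(axis=1) > 0.99)


class TestRMSThreshold:
    def test_hand_computed_single_reference_row(self):
        A = np.zeros((5, 5))
        A[4] = [3, 4, 0, 0, 0]
        roles = ["EEG"] * 4 + ["REF_EMG"]
        rms, thr = compute_rms_threshold(A, roles, gain=1.0)
        assert rms == pytest.approx(np.sqrt(5.0))
        assert thr == pytest.approx(np.sqrt(5.0))

    def test_average_over_two_reference_rows(self):
        A = np.zeros((4, 4))
        A[2] = [2, 0, 0, 0]     # row RMS = 1
        A[3] = [0, 0, 4, 0]     # row RMS = 2
        roles = ["EEG", "EEG", "REF_EMG", "REF_EMG"]
        rms, thr = compute_rms_threshold(A, roles, gain=2.0)
        assert rms == pytest.approx(1.5)
        assert thr == pytest.approx(3.0)

    def test_zero_reference_rows_give_zero(self):
        A = np.zeros((3, 3))
        A[:2] = 1.0
        rms, thr = compute_rms_threshold(A, ["EEG", "EEG", "REF_EMG"], 0.5)
        assert rms == 0.0 and thr == 0.0

    def test_gain_outside_empirical_range_rejected(self):
        A = np.ones((2, 2))
        roles = ["EEG", "REF_EMG"]
        for bad in (0.39, 3.01, -1.0):
            with pytest.raises(ValueError, match="gain"):
                compute_rms_threshold(A, roles, bad)

    def test_no_reference_rows_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            compute_rms_threshold(np.ones((2, 2)), ["EEG", "EEG"], 1.0)


class TestSelection:
    def test_nothing_flagged_when_threshold_high_and_no_hat_maxima(self):
        mont = generic_montage(3, hat_fraction=0.0)
        mont.hat_band = []          # no rim electrodes at all
        A = np.eye(4)
        roles = ["EEG"] * 3 + ["REF_EMG"]
        d = select_artifact_ics(A, roles, threshold=10.0, montage=mont)
        assert d.artifact_ics == []

    def test_hat_band_maximum_flags_regardless_of_threshold(self):
        mont = generic_montage(3)   # ch1..ch3 on the rim by construction
        A = np.eye(4)
        A[0, 2] = 5.0               # column 2's max lands on EEG row 0
        roles = ["EEG"] * 3 + ["REF_EMG"]
        d = select_artifact_ics(A, roles, threshold=100.0, montage=mont)
        assert 2 in d.artifact_ics
        assert "hat_band" in d.fired_criteria[2]

    def test_threshold_criterion_fires_on_any_reference_row(self):
        mont = generic_montage(2, hat_fraction=0.0)
        mont.hat_band = []
        A = np.zeros((4, 4))
        A[0, 0] = 1.0               # keep EEG maxima off the hat band
        A[3, 1] = 0.6               # second reference row exceeds threshold
        roles = ["EEG", "EEG", "REF_EMG", "REF_EMG"]
        d = select_artifact_ics(A, roles, threshold=0.5, montage=mont)
        assert d.artifact_ics == [1]
        assert d.fired_criteria[1] == ["threshold"]

    def test_conventional_mode_uses_hat_band_only(self):
        mont = generic_montage(4)
        A = np.eye(4) * 0.1
        A[0, 1] = 1.0               # rim electrode carries column 1's max
        d = select_artifact_ics(A, ["EEG"] * 4, threshold=None, montage=mont)
        assert 1 in d.artifact_ics
        assert all("threshold" not in v for v in d.fired_criteria.values())

    def test_simulation_rule_equals_bruteforce_argmax(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(10, 10))
        roles = ["EEG"] * 7 + ["REF_EMG"] * 3
        d = select_artifact_ics_simulation(A, roles)
        expected = sorted({int(np.argmax(np.abs(A[r]))) for r in (7, 8, 9)})
        assert d.artifact_ics == expected

    def test_simulation_rule_identity_mixing(self):
        A = np.eye(5)
        roles = ["EEG"] * 3 + ["REF_EMG"] * 2
        d = select_artifact_ics_simulation(A, roles)
        assert d.artifact_ics == [3, 4]

    def test_at_most_k_components_for_k_references(self):
        A = np.zeros((6, 6))
        A[4, 2] = A[5, 2] = 1.0     # both references point at column 2
        A[0, 0] = 1.0
        roles = ["EEG"] * 4 + ["REF_EMG"] * 2
        d = select_artifact_ics_simulation(A, roles)
        assert d.artifact_ics == [2]

    def test_criterion1_artifact_set_monotone_in_gain(self):
        """Raising the gain (threshold) never flags more components."""
        rng = np.random.default_rng(3)
        A = rng.normal(size=(8, 8))
        roles = ["EEG"] * 6 + ["REF_EMG"] * 2
        mont = generic_montage(6, hat_fraction=0.0)
        mont.hat_band = []
        prev = None
        for gain in np.arange(GAIN_MIN, GAIN_MAX + 1e-9, 0.1):
            _rms, thr = compute_rms_threshold(A, roles, gain)
            flagged = set(select_artifact_ics(A, roles, thr, mont).artifact_ics)
            if prev is not None:
                assert flagged <= prev
            prev = flagged


class TestReconstruction:
    def test_empty_artifact_set_is_identity(self, toy_decomp):
        from erase.core import RejectionDecision

        _A, _S, X = _super_gaussian_mix()
        out = reconstruct_clean(toy_decomp, RejectionDecision(artifact_ics=[]))
        rel = np.linalg.norm(out.eeg_block - X) / np.linalg.norm(X)
        assert rel < 1e-6

    def test_rejecting_all_components_leaves_mean_only(self, toy_decomp):
        from erase.core import RejectionDecision

        out = reconstruct_clean(
            toy_decomp, RejectionDecision(artifact_ics=[0, 1, 2]))
        assert np.allclose(out.eeg_block,
                           toy_decomp.mean[:, None], atol=1e-9)

    def test_variance_never_increases_per_channel(self, toy_decomp):
        from erase.core import RejectionDecision

        _A, _S, X = _super_gaussian_mix()
        out = reconstruct_clean(toy_decomp,
                                RejectionDecision(artifact_ics=[1]))
        assert np.all(out.eeg_block.var(axis=1)
                      <= X.var(axis=1) * (1 + 1e-6))

    def test_cleaning_is_permutation_equivariant(self):
        """Permuting the EEG channel order permutes the cleaned output
        identically (same seed; up to whitening round-off)."""
        rng = np.random.default_rng(3)
        S = rng.laplace(size=(5, 20000))
        X = rng.normal(size=(5, 5)) @ S
        perm = np.array([3, 0, 2, 1])

        def clean(eeg):
            rec = MultichannelRecording(eeg_block=eeg, ref_block=X[4:],
                                        fs=1000.0)
            d = run_reference_ica(rec, seed=2)
            dec = select_artifact_ics_simulation(d.mixing, d.row_roles)
            return reconstruct_clean(d, dec).eeg_block

        c1, c2 = clean(X[:4]), clean(X[:4][perm])
        rel = np.linalg.norm(c2 - c1[perm]) / np.linalg.norm(c1)
        assert rel < 1e-2

    def test_reference_rows_dropped_from_output(self):
        rng = np.random.default_rng(2)
        S = rng.laplace(size=(4, 15000))
        A = rng.normal(size=(4, 4))
        X = A @ S
        rec = MultichannelRecording(eeg_block=X[:3], ref_block=X[3:],
                                    fs=500.0)
        d = run_reference_ica(rec, seed=1)
        out = reconstruct_clean(d, select_artifact_ics_simulation(
            d.mixing, d.row_roles))
        assert out.eeg_block.shape[0] == 3 and out.n_ref == 0


class TestGainSweep:
    def _artifact_session(self):
        """30 s session whose movement epochs carry a high-frequency
        artifact injected through one dedicated source."""
        from scipy import signal as sg

        rng = np.random.default_rng(12)
        fs, dur = 500.0, 30.0
        n = int(fs * dur)
        schedule = []
        t = np.arange(n) / fs
        move_mask = np.zeros(n, dtype=bool)
        step = 0
        while step * 3.0 < dur:
            s = step * 3.0
            schedule.append((s, s + 1.0, "idle"))
            schedule.append((s + 1.0, min(s + 3.0, dur), "movement"))
            move_mask[int((s + 1.0) * fs):int(min(s + 3.0, dur) * fs)] = True
            step += 1
        sos = sg.butter(4, [40, 100], btype="bandpass", fs=fs, output="sos")
        hf = sg.sosfiltfilt(sos, rng.laplace(size=n)) * np.where(move_mask, 30, 1)
        eeg = rng.normal(0, 5, size=(4, n))
        eeg += np.outer([1.0, 0.8, 0.6, 0.4], hf)
        rec = MultichannelRecording(eeg_block=eeg, ref_block=np.array([hf]),
                                    fs=fs, state_schedule=schedule)
        return rec

    def test_single_candidate_returned_trivially(self):
        rec = self._artifact_session()
        decomp = run_reference_ica(rec, seed=4)
        mont = generic_montage(4, hat_fraction=0.0)
        mont.hat_band = []
        g, dec = sweep_gain(rec, decomp, mont, gains=np.array([1.0]))
        assert g == 1.0 and dec.gain == 1.0

    def test_argmin_matches_bruteforce_over_grid(self):
        """The returned gain reproduces an exhaustive evaluation of the
        objective over all 27 candidates."""
        rec = self._artifact_session()
        decomp = run_reference_ica(rec, seed=4)
        mont = generic_montage(4, hat_fraction=0.0)
        mont.hat_band = []
        g, dec = sweep_gain(rec, decomp, mont)
        objective = dec.objective
        gains = np.round(np.arange(GAIN_MIN, GAIN_MAX + 1e-9, 0.1), 10)
        assert len(objective) == 27
        assert g == gains[int(np.nanargmin(objective))]
        # the HF-artifact component must be rejected at the chosen gain
        assert len(dec.artifact_ics) >= 1

    def test_missing_schedule_rejected(self):
        rec = self._artifact_session()
        rec.state_schedule = []
        decomp = run_reference_ica(rec, seed=4)
        with pytest.raises(ValueError, match="schedule"):
            sweep_gain(rec, decomp, generic_montage(4))
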