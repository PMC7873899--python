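"""EMG simulation chain: membrane AP, volume conduction, motor unit, firing."""

import numpy as np
import pytest
from scipy import signal
from scipy.integrate import solve_ivp

from erase.emg import (FiberAP, SFAPGeometry, build_muap, compute_sfap,
                       generate_firing_times, hh_derivative,
                       hh_initial_state, HH_SQUID_PARAMS,
                       simulate_action_potential, superpose_muaps,
                       synthesize_emg, simulate_muscle_emg, MUSCLE_REGISTRY)


class TestActionPotential:
    def test_zero_stimulus_stays_at_rest(self):
        ap = simulate_action_potential({"stim_amplitude": 0.0},
                                       duration=0.02)
        assert np.abs(ap.samples).max() < 0.01 * 100.0  # <1% of AP range

    def test_subthreshold_stimulus_no_spike(self):
        ap = simulate_action_potential({"stim_amplitude": 2.0,
                                        "stim_duration": 0.2e-3})
        assert ap.samples.max() < 20.0  # depolarizes but never fires

    def test_single_spike_peak_matches_fine_reference(self):
        """Peak of the fixed-step solution vs an independent adaptive
        integration of the same equations at 100x finer output grid."""
        ap = simulate_action_potential(duration=0.02)
        p = dict(HH_SQUID_PARAMS)
        sol = solve_ivp(lambda t, y: hh_derivative(y, t, p),
                        (0.0, 20.0), hh_initial_state(p), method="LSODA",
                        max_step=1e-3, rtol=1e-10, atol=1e-10,
                        t_eval=np.arange(0, 20.0, 1e-4))
        ref = sol.y[0] - p["V_rest"]
        peaks_ref, _ = signal.find_peaks(ref, height=50.0)
        peaks_ap, _ = signal.find_peaks(ap.samples, height=50.0)
        assert len(peaks_ref) == 1 and len(peaks_ap) == 1
        assert ap.samples.max() == pytest.approx(ref.max(), rel=0.01)

    def test_returns_to_baseline(self):
        ap = simulate_action_potential()
        assert abs(ap.samples[-1]) < 0.01 * ap.samples.max()

    def test_too_large_step_rejected(self):
        with pytest.raises(ValueError, match="0.01 ms"):
            simulate_action_potential(dt=1e-4)


def _oracle_sfap(ap, geom, refine=10):
    """Independent composite-trapezoid quadrature at ``refine``-x finer
    spatial resolution, with analytic-in-z interpolation of the source."""
    ds = geom.spatial_step / refine
    z = np.arange(0.0, geom.fiber_length + ds / 2, ds)
    z_obs, y_obs = geom.observation_point
    r = np.hypot(z - z_obs, y_obs)
    w = ap.samples - ap.samples[0]
    delay = np.abs(z - geom.endplate_position) / geom.conduction_velocity
    n_t = len(w) + int(np.ceil(delay.max() / ap.dt)) + 1
    t = np.arange(n_t) * ap.dt
    ap_t = np.arange(len(w)) * ap.dt
    tt = t[:, None] - delay[None, :]
    e = np.interp(tt.ravel(), ap_t, w, left=0.0,
                  right=w[-1]).reshape(tt.shape)
    dedz = np.gradient(e, ds, axis=1)
    d2edz2 = np.gradient(dedz, ds, axis=1)
    integral = np.zeros(n_t)
    for k in range(n_t):   # explicit composite trapezoid, on purpose
        f = d2edz2[k] / r
        integral[k] = ds * (f[0] / 2 + f[1:-1].sum() + f[-1] / 2)
    return dedz[:, 0] / r[0] + integral - dedz[:, -1] / r[-1]


class TestSFAP:
    def test_zero_source_gives_zero_potential(self, geometry):
        ap = FiberAP(samples=np.zeros(100), dt=1e-5)
        assert np.allclose(compute_sfap(ap, geometry), 0.0)

    def test_matches_fine_quadrature_on_toy_pulse(self, geometry):
        # single triangular pulse as the source waveform
        tri = np.concatenate([np.linspace(0, 1, 30),
                              np.linspace(1, 0, 30)[1:], np.zeros(40)])
        ap = FiberAP(samples=tri, dt=5e-5)
        mine = compute_sfap(ap, geometry)
        oracle = _oracle_sfap(ap, geometry, refine=10)
        n = min(len(mine), len(oracle))
        rel = (np.linalg.norm(mine[:n] - oracle[:n])
               / np.linalg.norm(oracle[:n]))
        assert rel < 0.005

    def test_amplitude_decays_with_radial_distance(self, coarse_ap, geometry):
        near = compute_sfap(coarse_ap, geometry)
        far_geom = SFAPGeometry(
            observation_point=(geometry.observation_point[0],
                               2 * geometry.observation_point[1]))
        far = compute_sfap(coarse_ap, far_geom)
        assert np.abs(far).max() < np.abs(near).max()

    def test_observation_on_axis_rejected(self, coarse_ap):
        geom = SFAPGeometry(observation_point=(0.08, 0.0))
        with pytest.raises(ValueError, match="r = 0"):
            compute_sfap(coarse_ap, geom)


class TestMUAP:
    def test_zero_spread_equals_single_sfap(self, coarse_ap, geometry):
        muap = build_muap(n_fibers=5, endplate_sd=0.0, velocity_sd=0.0,
                          geom_base=geometry, seed=3, ap=coarse_ap)
        single = compute_sfap(coarse_ap, geometry)
        assert np.allclose(muap.waveform[:len(single)], single)

    def test_average_peak_below_mean_of_individual_peaks(self, coarse_ap,
                                                         geometry):
        """Dispersion in endplate/velocity makes the average flatter than
        the individual SFAPs (brute-force recomputation as oracle)."""
        from dataclasses import replace
        from erase._rng import substream

        seed, n = 21, 12
        muap = build_muap(n_fibers=n, seed=seed, geom_base=geometry,
                          ap=coarse_ap)
        rng = substream(seed, "muap")
        endplates = geometry.endplate_position + rng.normal(0, 2.5e-3, n)
        velocities = rng.normal(4.0, 0.125, n)
        peaks = [np.abs(compute_sfap(coarse_ap, replace(
            geometry, endplate_position=float(ep),
            conduction_velocity=float(v)))).max()
            for ep, v in zip(endplates, velocities)]
        assert np.abs(muap.waveform).max() <= np.mean(peaks) + 1e-12

    def test_invalid_fiber_count(self):
        with pytest.raises(ValueError):
            build_muap(n_fibers=0)


class TestFiring:
    def test_zero_rates_give_empty_train(self):
        fs = generate_firing_times([(0, 10, "idle")],
                                   {"idle": 0.0, "movement": 0.0}, seed=1)
        assert len(fs.spike_times) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_firing_times([(0, 1, "idle")], {"idle": -1.0}, seed=1)

    def test_idle_rate_recovery(self):
        """Empirical mean count over 1,000 seeded 10 s idle segments is
        within 3 standard errors of rate x duration = 400."""
        counts = [len(generate_firing_times([(0, 10, "idle")],
                                            seed=s).spike_times)
                  for s in range(1000)]
        mean = np.mean(counts)
        se = np.sqrt(400) / np.sqrt(1000)
        assert abs(mean - 400) < 3 * se

    def test_movement_to_idle_density_ratio(self):
        """Movement/idle spike density approaches 100/40 = 2.5 over many
        seeded replicates."""
        sched = [(0, 5, "idle"), (5, 7, "movement")]
        idle_counts, move_counts = [], []
        for s in range(150):
            st = generate_firing_times(sched, seed=s).spike_times
            idle_counts.append(np.sum(st < 5))
            move_counts.append(np.sum(st >= 5))
        ratio = (np.mean(move_counts) / 2.0) / (np.mean(idle_counts) / 5.0)
        assert ratio == pytest.approx(2.5, rel=0.10)

    def test_spikes_within_schedule(self):
        fs = generate_firing_times([(2.0, 4.0, "movement")], seed=9)
        assert np.all((fs.spike_times >= 2.0) & (fs.spike_times < 4.0))

    def test_burn_in_spikes_discarded(self):
        fs = generate_firing_times([(0.0, 2.0, "idle")], burn_in=1.0, seed=4)
        assert np.all(fs.spike_times >= 0.0)


class TestSynthesis:
    def test_empty_schedule_zero_trace(self, small_muap, schedule_10s):
        firing = generate_firing_times(schedule_10s,
                                       {"idle": 0.0, "movement": 0.0}, seed=2)
        tr = synthesize_emg(small_muap, firing, fs=1000.0, duration=10.0,
                            band=(20, 100))
        assert np.allclose(tr.samples, 0.0)

    def test_superposition_is_linear_in_spike_sets(self, small_muap):
        from erase.emg import _resample_muap

        kern = _resample_muap(small_muap, 1000.0)
        rng = np.random.default_rng(0)
        a = np.sort(rng.uniform(0, 5, 40))
        b = np.sort(rng.uniform(5, 10, 40))
        joint = superpose_muaps(kern, np.sort(np.r_[a, b]), 1000.0, 10000)
        parts = (superpose_muaps(kern, a, 1000.0, 10000)
                 + superpose_muaps(kern, b, 1000.0, 10000))
        assert np.allclose(joint, parts, atol=1e-9)

    def test_out_of_band_power_below_5pct(self, small_muap, schedule_10s):
        tr = simulate_muscle_emg("frontalis", schedule_10s, fs=1000.0,
                                 duration=10.0, seed=3, muap=small_muap)
        f, p = signal.welch(tr.samples, fs=1000.0, nperseg=2048)
        low, high = tr.band
        trans = 5.0
        out = p[(f < low - trans) | (f > high + trans)].sum()
        assert out / p.sum() < 0.05

    def test_band_outside_nyquist_rejected(self, small_muap, schedule_10s):
        firing = generate_firing_times(schedule_10s, seed=1)
        with pytest.raises(ValueError, match="fs/2"):
            synthesize_emg(small_muap, firing, fs=200.0, duration=10.0,
                           band=(20, 150))

    def test_deterministic_under_seed(self, small_muap, schedule_10s):
        t1 = simulate_muscle_emg("masseter", schedule_10s, 1000.0, 10.0,
                                 seed=7, muap=small_muap)
        t2 = simulate_muscle_emg("masseter", schedule_10s, 1000.0, 10.0,
                                 seed=7, muap=small_muap)
        assert np.array_equal(t1.samples, t2.samples)

    def test_amplitude_calibration(self, small_muap, schedule_10s):
        tr = simulate_muscle_emg("trapezius", schedule_10s, 1000.0, 10.0,
                                 seed=5, muap=small_muap)
        assert tr.samples.std() == pytest.approx(
            MUSCLE_REGISTRY["trapezius"]["amplitude"], rel=1e-6)

    def test_unknown_muscle_rejected(self, schedule_10s):
        with pytest.raises(KeyError):
            simulate_muscle_emg("sternocleidomastoid", schedule_10s,
                                1000.0, 10.0)

    def test_registry_round_trips_through_yaml(self, tmp_path):
        import yaml

        from erase.emg import load_muscle_registry

        p = tmp_path / "muscles.yaml"
        dump = {m: {**cfg, "band": list(cfg["band"])}
                for m, cfg in MUSCLE_REGISTRY.items()}
        p.write_text(yaml.safe_dump(dump))
        assert load_muscle_registry(p) == MUSCLE_REGISTRY
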