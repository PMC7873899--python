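# erase-eeg

Automatic removal of muscle (EMG) artifact from EEG by **reference-augmented
ICA**: extra channels of pure muscle signal — co-recorded surface EMG, or
biophysically simulated EMG — are appended to the EEG before a square
FastICA decomposition, which forces the myogenic variance into a small
number of components that are identified and rejected automatically from
the mixing matrix. The package is aimed at EEG researchers analysing
movement tasks (motor physiology, BCI pilots), where EMG from frontalis,
temporalis, masseter and trapezius contaminates most channels and overlaps
the EEG spectrum above ~20 Hz, making manual component rejection slow and
subjective.

## The method in brief

Stack the `c_E` EEG channels and `c_M` reference EMG channels and decompose:

```
[ X + b·N ]         [ s ]
[   n*    ] =  A ·  [ m ],      A ∈ R^{(c_E+c_M)×(c_E+c_M)}
```

If the reference sources `n*` are independent of each other but dependent
on the contaminant `N` (same muscles), ICA must assign the contaminant to
the components that load on the reference rows of `A`. Artifact components
are then flagged from `A` alone:

* **threshold rule** — any reference-row loading above `R_ms × gain`,
  where `R_ms` is the mean reference-row RMS of `A` and the gain (0.4–3)
  is chosen automatically by minimizing movement-epoch 40–100 Hz power
  across channels while maximizing 8–12 Hz (mu) desynchronization at the
  channel of interest;
* **hat-band rule** — the component's largest loading falls on an
  outer-circumference electrode;
* **simulation rule** (surrogate data) — per reference row, the component
  with the largest absolute loading.

Cleaning zeroes the flagged columns and back-projects. Validation metrics:
artifact index `AI = mean|a*| / mean|a|` (contaminated vs clean rows of a
flagged column), the detection inequality
`mean|a*| − mean|a| > 0.05·max|ã|`, false-positive rate and sensitivity
over seeded replicates, and percent reduction of z-scored high-frequency
power on session data. See `docs/methods.md` for the full account.

## Worked example

Simulate a contaminated recording, decompose, and score — no external data
needed:

```python
import numpy as np
from erase import (build_sensitivity_scenario, contaminate,
                   generate_simulated_eeg, run_reference_ica,
                   select_artifact_ics_simulation, artifact_index)
from erase.pipeline import alternating_schedule, generate_emg_set

fs, duration = 2000.0, 60.0
schedule = alternating_schedule(duration)          # 5 s idle / 2 s movement
emg = generate_emg_set(["frontalis", "temporalis", "masseter"],
                       fs, duration, schedule, seed=0)
spec = build_sensitivity_scenario("S2", 3, seed=42)   # 3 muscles x 6 channels
eeg = generate_simulated_eeg(n_channels=32, fs=fs, duration=duration, seed=42)
rec = contaminate(eeg, emg, spec, state_schedule=schedule)

decomp = run_reference_ica(rec, seed=42, fit_decimate=4, max_iter=120)
decision = select_artifact_ics_simulation(decomp.mixing, decomp.row_roles)
ai = artifact_index(decomp.mixing, decision.artifact_ics,
                    spec.contaminated_channels, spec.uncontaminated_channels)
print("artifact components:", decision.artifact_ics)
print("artifact indices:", np.round(ai, 1))
```

prints

```
artifact components: [4, 6, 25]
artifact indices: [ 50.1  76.9 105.4]
```

Three of the 35 components (32 EEG + 3 reference channels) are flagged, one
per muscle, and each loads 50–105× more strongly on the contaminated than
on the clean channels — the EMG was concentrated into exactly the flagged
components. On the same data without reference channels (conventional ICA),
artifact indices are typically an order of magnitude smaller.

A command-line surface wraps the same drivers:

```
erase simulate-eeg --channels 32 --duration 60 --out eeg.csv
erase clean --input rec.csv --ref-labels emg1,emg2 --gain auto --out clean.csv
erase evaluate --kind sensitivity --scenario S2 --size 3 --replicates 20
erase replicate-paper --out-dir replication/
```

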