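# Methods

## The model

Scalp EEG recorded during movement is a linear mixture of cortical sources
and myogenic (EMG) artifact. Conventional ICA applied to the EEG alone
rarely isolates the EMG into a few components, because EMG from many
cranial/neck muscles overlaps the EEG both spatially and spectrally. This
package implements reference-augmented ICA: `c_M` extra channels containing
pure muscle signal — co-recorded surface EMG, or simulated EMG with matched
firing statistics — are stacked under the `c_E` EEG channels before a
square FastICA decomposition,

    [ X + b·N ]          [ s ]
    [   n*    ]  =  A ·  [ m ]  ,   A ∈ R^{(c_E+c_M)×(c_E+c_M)},

where `X` is clean EEG, `N` the contaminant EMG mixed into it with
coefficients `b`, and `n*` the reference EMG. When the reference sources
are mutually independent and statistically dependent on the contaminant
(they originate in the same muscles), the decomposition is forced to route
the myogenic variance into the components that load on the reference rows
of the mixing matrix `A`; the EEG-source components carry no contaminant.
The simulators below are built so that this dependence condition holds by
construction: the same MUAP/firing chain drives both the reference and the
contaminant role of a muscle.

## Artifact-component rejection

All rejection rules read only the mixing matrix (columns = per-component
channel loadings, in the recording's microvolt units):

* **Threshold (criterion 1).** `R_ms` is the mean, over reference rows, of
  the row-wise RMS of `A`; the threshold is `R_ms × gain` with gain in the
  empirical range 0.4–3. A component is flagged if **any** reference-row
  loading exceeds the threshold in absolute value. (The plural "reference
  rows" is read as *any row*; an aggregate rule would weaken the criterion
  when muscles load disjoint components.)
* **Hat band (criterion 2).** A component whose largest absolute loading
  falls on an outer-circumference ("hat band") EEG electrode is flagged:
  myogenic topographies peak at the head's rim. Ties break toward the
  lowest row index and are recorded. The conventional-ICA baseline uses
  this criterion alone.
* **Simulation rule.** On surrogate EEG (no brain features), no threshold
  is needed: for each reference row, the component with the largest
  absolute loading in that row is an artifact component ("highest
  coefficient" is read as highest **absolute** value, since IC signs are
  arbitrary). `k` references flag at most `k` components.

Cleaning zeroes the flagged columns of `A` and back-projects; reference
rows are dropped from the output.

**Automatic gain.** The gain is swept over 0.4–3 in 0.1 steps. For each
candidate the EEG is reconstructed and scored by
`mean movement-epoch z-scored 40–100 Hz power over all channels +
mean movement-epoch z-scored 8–12 Hz power at the channel of interest`;
the argmin wins. More-negative mu z-scores (stronger desynchronization)
lower the objective, so the chosen gain simultaneously suppresses
high-frequency (EMG-dominated) synchronization and preserves/maximizes mu
desynchronization. Epoch-averaged (not frame-wise) z-power enters the
objective, for stability at short sessions.

## EMG simulator

Chain: Hodgkin–Huxley membrane AP → single-fiber action potential (SFAP)
via volume conduction → motor-unit action potential (MUAP) as a 100-fiber
average → piecewise-homogeneous Poisson firing → per-muscle band-pass and
amplitude calibration.

* **Membrane AP.** Classical squid-axon constants at 6.3 °C (C_m = 1
  µF/cm², g_Na/g_K/g_L = 120/36/0.3 mS/cm², E_Na/E_K/E_L =
  50/−77/−54.387 mV, rest −65 mV), a 20 µA/cm², 1 ms stimulus pulse, and
  fixed-step RK4 at dt = 0.01 ms (a hard upper limit on the step; larger
  steps raise an error rather than integrating unstably). All constants are
  overridable through `membrane_params`.
* **SFAP.** The AP propagates from the endplate toward both fiber ends at
  the conduction velocity; the surface potential is the sum of end-surface
  first-derivative terms and the axial second-derivative integral, each
  weighted by 1/r to the observation point. The volume term is integrated
  by parts twice before discretization, which cancels the end
  first-derivative terms and puts all differentiation on the analytic 1/r
  kernel; the remaining integral uses composite trapezoid quadrature on a
  uniform axial grid (default 0.5 mm). This keeps the scheme accurate for
  waveforms with kinks (the propagating front is only C⁰ at the endplate).
  Geometry defaults — 120 mm fiber, endplate mid-fiber, observation point
  20 mm axial / 5 mm radial from the endplate — are modelling choices and
  are all configurable. The proportionality constant is 1; absolute scale
  is set by the per-muscle amplitude calibration.
* **MUAP.** 100 SFAPs with endplate positions N(0, 2.5 mm) around the base
  endplate and conduction velocities N(4, 0.125) m/s, averaged on a common
  time grid.
* **Firing.** Motor-unit firing is piecewise-homogeneous Poisson: 40
  spikes/s during idle, 100 spikes/s during movement. An optional burn-in
  segment at the 20 spikes/s initial rate can precede the first interval;
  its spikes are discarded from the output (this is how the stated initial
  rate is reconciled with the two per-state rates — it primes the process
  without appearing in the record; default off).
* **Muscles.** Frontalis, temporalis, masseter and trapezius (bilateral in
  session simulations) share a 20–100 Hz surface-EMG band (4th-order
  zero-phase Butterworth) and a 30 µV trace-SD calibration. **Eye blinks
  are not motor-unit trains:** they are sparse, large (100 µV SD), slow
  1–10 Hz transients, modelled by the same kernel/superposition machinery
  but with blink-like event rates (0.2/s idle, 0.5/s movement). A dense
  40–100/s train band-limited to 1–10 Hz would be near-Gaussian by the
  central limit theorem and therefore unseparable by ICA *in principle* —
  sparse events are both the physiologically right picture and the one
  that gives the blink source a well-defined non-Gaussian signature. The
  registry (band, order, amplitude, rates) is a plain dict, overridable
  and YAML-loadable.
* Amplitude modulation between states arises from the rate change
  (amplitude ∝ √rate for superposed trains); no separate per-state gain is
  applied.

## EEG simulator

Each channel is an equal-weight sum of five independent Gaussian noises
band-passed (4th-order zero-phase Butterworth) to 1–30, 20–40, 40–80,
80–100 and 100–200 Hz (per-band weights configurable). Spatial correlation
mimicking volume conduction is added by a circular Gaussian kernel (SD = 4
channel indices, wrap-around) across the channel axis. Channels are then
scaled to the target variance (30 µV² by default), and the whole array is
rescaled down only if its global extreme exceeds the 60 µV amplitude cap.
For band-limited Gaussian noise at this variance the extreme over 5
minutes stays near 26 µV, so the cap is normally inactive — a target
variance and a target maximum cannot both bind for Gaussian data, and the
variance is the quantity the validation metrics depend on. The surrogate
contains no physiological rhythms; what passing tests show is that the
*separation machinery* behaves as designed, not that real EEG statistics
are reproduced.

## Contamination scenarios

* **Scenario 1** (growing contamination extent): frontalis, temporalis,
  masseter; 2–10 channels per type out of 32, assigned sequentially
  (surrogate channels are exchangeable before smoothing-induced
  neighbour correlation, which is index-circular and unaffected by which
  indices are chosen).
* **Scenario 2** (growing number of muscles): 1–5 types (adding trapezius,
  then eye blinks), six randomly chosen channels per type, sampled without
  replacement across types so no channel carries two artifact types.
* Weights: per type, one N(0, 1) draw per contaminated channel,
  L2-normalized as a vector ("normalized" is read as unit L2 norm; signs
  are kept — a weight may be negative). Reference channels are appended
  unweighted.
* **FP construction**: the contaminant is a single Gaussian noise trace
  (mean 0, SD 30 µV) independent of the appended EMG references.
* **Sensitivity construction**: identical to Scenario 1/2 — the same EMG
  trace is both contaminant and reference.

Per the original study design, the EMG traces of a configuration are
generated once and reused across its replicates; surrogate EEG, channel
choices, weights and ICA initialisation are redrawn per replicate. The
ground truth always lives in the `ScenarioSpec`; scoring never inspects the
mixed data.

## Decomposition numerics

Symmetric FastICA, logcosh contrast, deterministic seed. Reference rows are
z-scored before stacking — pure numerical conditioning so that microvolt
scale differences do not dominate whitening — and the fitted model is
converted back to physical units afterwards (per-channel scaling commutes
with ICA up to exactly this diagonal transform), so every criterion and
metric sees `A` in µV and back-projection reproduces the original stack to
float64 precision (mixing is recomputed as a float64 inverse of the
unmixing rather than taken from the fitted pseudo-inverse). The unmixing
matrix is fitted on a 4× polyphase-decimated copy of the record (the
mixing is time-invariant and 30,000 samples vastly exceed the 37-channel
requirement) and applied at full rate. Fitting in float64 matters:
a float32 fit demonstrably degrades source separation at these problem
sizes. Non-convergence returns the final iterate with `converged=False`
and a warning — on Gaussian-subspace surrogates the symmetric update has
no fixed point to converge to, while the non-Gaussian artifact directions
settle within a few dozen iterations; study drivers therefore cap
iterations (120 in the shipped studies) as a compute choice. Rank-deficient
input fails loudly, naming the constant or duplicate channels.

## Validation metrics

For a flagged column of `A`, with contaminated rows `a*`, uncontaminated
rows `a` and reference rows `ã` (all from scenario truth):

* **Artifact index** `AI = mean|a*| / mean|a|`: how much more strongly the
  component loads on contaminated than clean channels. A zero denominator
  reports +inf with a flag, never an exception. The channel counts
  generalize to any array size (the 32-channel study is a special case);
  runs outside the original 6–30 contaminated range are simply reported.
* **Detection inequality**: `mean|a*| − mean|a| > 0.05 × max|ã|`.
* **False-positive rate**: fraction of replicates (independent-noise
  construction) in which *any* flagged column satisfies the inequality.
* **Sensitivity**: fraction of replicates (shared-EMG construction) in
  which *all* flagged columns satisfy it.
* Both rates carry exact (Clopper–Pearson) binomial intervals.
* **Percent reduction** `PD = |ΣP_before − ΣP_after| / ΣP_before × 100` on
  movement-epoch z-scored 40–100 Hz power summed over channels × trials:
  scalp high-frequency power is EMG-dominated, so its drop measures
  artifact removal.

## Band-power chain (session data)

Zero-phase 3rd-order Butterworth band-pass 3–100 Hz → trials of 1 s idle +
2 s movement extracted around each cue (edge-clipped trials dropped with a
warning) → trials concatenated per session for the decomposition → STFT
band power with a 0.25 s Hamming window at 50% overlap (window length is a
package choice; band power = mean squared magnitude over in-band bins) →
z-scoring of each channel/band against its own idle-epoch statistics →
Wilcoxon rank-sum comparisons (movement-epoch HF pooled over channels; mu
at the channel of interest, C3 for right-hand and C4 for left-hand tasks by
convention, overridable) → topographic maps with channels lacking a
significant idle/movement difference nulled (mu at α = 0.01, HF at
α = 0.05). In real-data mode EEG at 2,048 Hz and EMG at 4,000 Hz are
aligned by resampling the EMG to the EEG rate before stacking.

## Study sizes shipped with the package

The original simulation study used 200 replicates per configuration and
5-minute records. The shipped studies and the acceptance script use the
full parameter grid (Scenario 1 with 6/18/30 contaminated channels,
Scenario 2 with 1/3/5 reference types) at 20 seeded replicates per
configuration and 60 s records — sizes chosen so the whole validation runs
on a single CPU in minutes while keeping every configuration of the
original grid. 200 replicates remain available through configuration.

## Known limitations

* The real-EEG results (per-subject high-frequency reductions of roughly
  75% / 63% / 49% for reference-augmented cleaning with real EMG, with
  simulated EMG, and conventional ICA) **cannot be reproduced here**: the
  underlying 8-subject recordings were not released. The session driver
  reproduces the *form* of that analysis (per-subject condition table with
  band statistics and percent reduction) on synthetic sessions only, and
  numbers from synthetic sessions are not comparable to the real-data
  values.
* The surrogate EEG is structured noise; effect sizes measured on it say
  nothing about brain-rhythm preservation beyond what the mu-objective
  construction enforces.
* EDF/BrainVision files are read (via MNE) but not written; CSV and the
  npz/JSON fixture container are the output formats.
* No motor-unit recruitment hierarchy, fatigue, or anatomical volume
  conductor; no iterative/constrained ICA variants; no real-time path.
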