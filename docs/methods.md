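# Methods

This document records the models, parameter values, numerical choices and
known limitations of the `stancefit` package. All empirical figures quoted
here were computed with this code (seeds noted where relevant).

## 1. Single-inverted-pendulum mechanics

State: sway angle θ (rad, positive forward), angular velocity θ̇. The
platform translates horizontally by d(t). Angular-momentum balance about
the ankle:

```
m l² θ̈ = M_a + m g l sin θ − ḋ m l sin θ θ̇ + d̈ m l cos θ
```

- `M_a` — ankle moment, the physically applied (commanded) torque.
- `τ_d = −m g l sin θ + ḋ m l sin θ θ̇ − d̈ m l cos θ` — disturbance torque
  (gravity + base-motion inertial terms).
- `τ_c = M_a − τ_d = m l² θ̈` — active control torque, the identification
  output. This identity holds exactly by construction; the
  `TorqueSeries` type enforces it.

Default anthropometrics: m = 70 kg, l = 0.9 m, g = 9.81 m/s²
(cohort subjects draw m ∈ [45, 110] kg and l around these values).
Plate model: `M_a = COPx·Fz − h_ankle·Fx`, with h_ankle = 0 by default,
Fz = m g, Fx = m × (horizontal COM acceleration).

Integration: classical fixed-step RK4 at dt = 1 ms. A fall detector
raises once |θ| > π/2. Delayed feedback is supported through a
`StateHistory` ring buffer with linear interpolation, clamped at the
initial state for t < delay.

## 2. Platform perturbation

Minimum-jerk translation `d(s) = A (10 s³ − 15 s⁴ + 6 s⁵)`,
s = (t − t_on)/T, with A = 0.05 m, T = 0.3 s, onset t_on = 0.5 s.
Peak acceleration `A/T² · (10√3/3) ≈ 3.2075 m/s²` at
s = (3 ± √3)/6. Displacement, velocity and acceleration are analytic
(no differencing of the commanded profile).

## 3. Two-mode delayed controller

`M_a(t) = −K_p(σ) θ(t−δ) − K_d(σ) θ̇(t−δ) + noise`, with mode σ switching
once at t_on + 0.25 s (or, under the alternative rule, when platform
acceleration falls below 0.5 m/s² after its peak):

| condition | mode 1 (Kp, Kd) | mode 2 (Kp, Kd) | delay δ |
|---|---|---|---|
| EO | 2040, 510 | 1130, 340 | 0.15 s |
| EC | ×1.3 on all gains | ×1.3 | 0.15 s |
| DT | 2040, 510 | 1130, 340 | 0.12 s |

Motor noise: white torque noise (sd 1 N·m) drawn on a 100 Hz grid and
linearly interpolated to the 1 kHz simulation grid.

## 4. Surface EMG model

GA envelope ∝ max(τ_c, 0), TA ∝ max(−τ_c, 0), each delayed by an
electromechanical delay of 40 ms, scaled by gain 2×10⁻³, on a baseline of
0.02, multiplying a band-limited (30–450 Hz) unit-RMS carrier, plus white
measurement noise (sd 5×10⁻³).

## 5. Preprocessing

- Zero-phase Butterworth filters: order-2 sections applied
  forward–backward (`sosfiltfilt`, odd padding of 3·(order+1) samples).
  The effective squared-magnitude response is `1/(1 + (f/fc)⁴)`; e.g. a
  40 Hz tone through fc = 10 Hz retains amplitude 1/257 ≈ 0.39 %
  (measured 0.0038).
- Kinematics: low-pass at 10 Hz (100 Hz data).
- Kinetics: low-pass at 15 Hz, linear detrend (not applied to Fz),
  decimation 1 kHz → 100 Hz.
- EMG: moving-RMS envelope, 50 ms centered window, output at 100 Hz.
- Epoch: 100 samples (1 s) starting at perturbation onset; channels
  τ_c, θ, GA-RMS, TA-RMS.

## 6. Regression space and lag selection

From each epoch, rows k = 20…99 of an 80×80 lag matrix (4 signals ×
lags 1–20) with target τ_c(k). Per condition, the 7 training subjects'
matrices are pooled (560×80). mRMR selects n_d = 5 columns: plug-in
mutual information in nats over 8 equal-frequency bins, greedy
relevance-minus-mean-redundancy, first-maximum tie-break. Constant
columns receive zero relevance and are logged. Subject-level splits:
70/30 (fixes the lag choice), 60/40 and 50/50 nested inside it.

## 7. PWARX identification

1. **Clustering** — normalized-Laplacian spectral clustering of the
   standardized joint vectors [x; y], Gaussian affinity with scale =
   median pairwise distance, k-means on the embedding (seeded).
2. **Model order** — s = argmax over k ∈ {2…6} of mean silhouette width;
   ties to the smallest k.
3. **Boundaries** — pairwise soft-margin linear SVMs (C = 1, balanced
   class weights) in regressor space; sign fixed so w·x + b ≤ 0 selects
   the lower-indexed region. Region membership for s > 2 is a majority
   vote over the pairwise hyperplanes.
4. **Sub-models** — after boundary estimation, points are relabeled by
   the polyhedral region they fall in, points within tol·‖w‖ of any
   hyperplane are discarded, and each region is fit by affine least
   squares via the pseudo-inverse (minimum-norm under rank deficiency).

Goodness of fit: `fit% = 100·(1 − ‖y − ŷ‖/‖y − ȳ‖)` with one-step-ahead
prediction. Diagnostics: per-trial switching signal (region index vs.
time, with the (max_lag + row)/100 s time axis), residual autocorrelation
against the ±1.96/√N whiteness band, and the maximal inter-model
disagreement at user-supplied near-boundary points.

## 8. Determinism and seeds

Every stochastic step derives from a single master seed via
`numpy.random.SeedSequence` (spawned sub-seeds < 2³¹); spectral
clustering's k-means is seeded likewise. Two runs with identical
configuration produce byte-identical artifacts, including `report.json`
and the serialized models (verified by test and by the acceptance
script's `pipeline_rerun_identical`).

## 9. Measured behavior of the default study

All numbers below from pipeline seed 0 unless noted:

- 90 fit entries (3 conditions × 3 splits × 10 subjects); median held-out
  fit 97.78 %. Degrades monotonically with motor-noise level (medians
  97.11 / 97.78 / 97.85 % at torque-noise sd 2.0 / 1.0 / 0.5 N·m).
- Silhouette-selected s: EO 3, EC 2, DT 2.
- Median first-switch times of the identified switching signal:
  EO 0.21 s, EC 0.44 s, DT 0.30 s after onset (ground-truth controller
  switch: 0.25 s).
- GA/TA envelope area ratios per condition ≈ 1.2–1.3 (seed 1 acceptance
  run).

## 10. Known limitations

**Noise ceiling of fit% at 20 dB SNR.** For additive output noise at
signal-to-noise ratio SNR (in dB), the expected best achievable fit is
`100·(1 − 10^(−SNR/20))`, i.e. exactly 90 % at 20 dB. A fit-percentage
requirement above that (e.g. > 95 %) is unattainable at 20 dB regardless
of estimator quality; measured held-out fits on the benchmark system are
89.5–90.1 % at 20 dB and ≈ 99.0 % at 40 dB (10 seeds, n = 2000). The same
noise floor propagates into the per-coefficient least-squares standard
errors (≈ 0.056 for the affine offset at n = 1400), so the observed
maximal coefficient error at 20 dB (≈ 0.10 over 10 seeds) cannot be
driven below 0.05 at this sample size. The corresponding acceptance
assertions are left failing rather than weakened; structure selection
(s = 2 in 10/10 seeds) and boundary orientation (cosine > 0.9999) are
unaffected.

**Switching phenomenology of the end-to-end study.** The identified
regions partition the regressor space, not time; for this generator the
clusters follow the amplitude shell of the perturbation transient rather
than the controller's gain switch alone. Consequences (measured, seed 0,
also present with all noise sources disabled): EO selects s = 3
(silhouette 0.611 vs 0.605 for s = 2), splitting the transient arc;
EC's first boundary crossing occurs ≈ 0.44 s after onset (the stiffer
×1.3-gain transient settles late); and the lag-20 EMG coordinate
re-enters the pre-onset region late in the epoch, adding a second switch
in several trials. "Exactly one switch within 0.4 s of onset per test
trial" therefore does not hold; the diagnostic outputs report the actual
counts and times.

**Scope.** Single-segment sagittal-plane model, ankle strategy only; no
hip strategy, no foot lift-off, no muscle dynamics beyond a delayed
first-order envelope model; EMG carriers are synthetic and
amplitude-coded only. The identification assumes a polyhedral partition
with affine dynamics per region and one-step-ahead evaluation; long-range
simulation error is not assessed.
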