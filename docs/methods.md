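# Methods

This note documents the models and numerical choices behind `tremorkit`: what
is computed, under which assumptions, and what the synthetic test bed does and
does not establish about real recordings.

## Problem setting

A chain of 3 or 4 magnetic-inertial measurement units (MIMUs) is strapped to
the hand, distal forearm, (proximal forearm,) and humerus of a person with
kinetic tremor performing a repetitive finger-to-nose task (~30 s, 3 cycles,
100 Hz). Each sensor emits a fused orientation stream; the raw accelerometer /
gyroscope / magnetometer channels and the onboard fusion filter are not
accessible. From orientation alone the package (a) identifies each sensor's
*relative* position on the chain and (b) separates the wrist's tremulous from
its voluntary angular velocity in a form suitable for real-time use.

## Angular velocity from orientation

Finite rotations do not commute, so attitude angles cannot be differentiated
directly. The angular-velocity matrix of the rotating frame is

    Omega = dR/dt · R^T   (global frame; R maps body to global),

skew-symmetric for exact R. `poisson_angular_velocity` estimates dR/dt with
second-order central differences (one-sided at the ends), skew-symmetrizes
Omega as (Omega − Omega^T)/2 to cancel the symmetric part introduced by
differencing, and reads off ω = (Ω₃₂, Ω₁₃, Ω₂₁). At 100 Hz the truncation
error is O(‖ω‖³ dt²): negligible for tremor-band content at physiological
amplitudes, ~1e-2 rad/s only for sustained rotation near 10 rad/s. A body-frame
variant (R^T · dR/dt) is available behind a flag.

The inverse operation, `integrate_angular_velocity`, composes exact per-step
axis-angle increments from midpoint velocities. Because integration and
extraction do not share a linearization, their round trip is a genuine
consistency check (RMS < 1e-2 rad/s for sub-hertz content up to 10 rad/s).

Euler decomposition defaults to intrinsic Z-Y-X (yaw-pitch-roll) — no
convention is canonical for this task — with temporal unwrapping and a warning
within 1e-3 rad of gimbal lock. Upsampling (100 Hz → 1 kHz before filtering)
is linear interpolation: the g-h filter is insensitive to sub-sample
smoothness, and linear interpolation adds no spectral content that could be
mistaken for tremor.

## Location features and classifiers

Movement of proximal segments is carried along by distal ones, and kinetic
tremor is likewise amplified toward the hand. Eighteen features summarize each
sensor's angular displacement, velocity and acceleration after per-axis
rectification (|x|, |y|, |z|), which together with symmetric axis combination
makes them insensitive to sensor orientation on the segment: per-axis path
length (displacement only), per-axis maxima (velocity/acceleration), summed
per-axis RMS, RMS of the vector norm, summed per-axis variances, the sum of
covariance eigenvalues, and the summed absolute loadings of the first
principal component. Displacement and acceleration derive from the same
Poisson velocity chain (trapezoidal integral; central difference). Variance is
always the population variance. Interpretation choices worth noting: "total
distance" is the per-axis path length Σ|Δθ| (the only magnitude-monotone
reading); the vector-norm RMS distinguishes the un-summed RMS features from
the summed ones; eigenvector sign ambiguity forces absolute values in the
principal-component loadings, and for a constant (degenerate) signal the
loadings fall back to the eigensolver's deterministic tie-break with a logged
warning.

Features are consumed as within-trial **ranks** (1 = largest, ties broken by
input order and flagged), which removes tremor-severity scale from the
classification problem entirely.

* **Ranking** (training-free): sorting sensors by any magnitude-monotone
  feature directly yields the distal-to-proximal order. Stateless — the chain
  can be re-configured without retraining.
* **Random forest**: 100 bagged trees, minimum leaf size 4, √18 candidate
  features per split, scored by out-of-bag error.
* **Decision tree**: CART with cost-complexity pruning; the subtree is the
  smallest whose stratified 10-fold cross-validation error is within one
  standard deviation of the minimum (1-SE rule); resubstitution and CV errors
  are both reported. Folds are stratified by class.

Classifier instances are (trial × sensor) rows with 18 rank predictors and the
chain ordinal as label; models are trained per sensor configuration. When a
trained model assigns two sensors the same ordinal, the higher-confidence
sensor keeps it and the other takes its next-best label, with the conflict
flagged.

## Tremor estimation

The wrist joint velocity is the difference of the distal and proximal sensors'
angular velocities, upsampled to 1 kHz. Voluntary movement lives below 2 Hz,
tremor in 3–12 Hz, so a heavily smoothed two-state tracker follows the
voluntary component only. The g-h filter uses the critically damped
single-parameter family

    g = 1 − θ²,   h = (1 − θ)²,

and its one-step prediction x_{k+1,k} is the voluntary estimate (the filtered
update is available behind a flag); the residual y_k − x_{k+1,k} is the tremor
estimate. Eliminating the state gives the exact residual difference equation
with transfer function (z−1)²/(z−θ)² — double zero at DC, double pole at θ —
evaluated as a direct-form IIR with initial conditions reproducing
x̂₀ = y₀, v̂₀ = 0. At θ ≈ 0.995 the filter passes ~98% of a 5 Hz tremor into
the residual while rejecting ~92–98% of the voluntary band. Filtering is per
axis; the norm channel applies the same filter to the Euclidean norm of the
joint velocity so every emitted channel satisfies raw = voluntary + tremor.

The **offline reference** — the gold standard a real-time method is scored
against — is a zero-phase (forward-backward) second-order Butterworth low-pass
at fc = 2 Hz; its remainder is the reference tremor. Zero-phase filtering is
inherently offline, which is exactly why it serves as reference.

**Kinematic tracking error.** With b_k = |estimate_k − reference_k|,
KTE = mean(b) + var(b) (population variance). The mean term measures response
time, the variance term smoothness. Shipped defaults θ = 0.9952 (gyroscope
pipeline) and θ = 0.9958 (orientation pipeline) are the values tuned on the
original patient recordings; they cannot be re-derived without that data, but
the GA below reproduces the tuning procedure on synthetic trials (where the
optimum lands near 0.997).

**GA tuning.** θ is tuned over [0.8, 1] — smaller values would track the
tremor itself — by a real-coded genetic algorithm: population 100, uniform
initialization, roulette selection on inverted cost, arithmetic crossover at
rate 0.8, two elites per generation, Gaussian mutation. The mutation scale
(σ = 5% of the bound width) and stopping rule (50 generations, or a best-cost
improvement below 1e-6 for 10 consecutive generations) are this package's
choices and are configurable. The cost is the summed per-axis KTE of the g-h
tremor estimate against the offline reference over all supplied trials.

## Synthetic trial generator

Patient recordings are not redistributable, so `tremorkit.synth` generates the
conditions the algorithms assume. Defaults: 30 s, 3 cycles (0.1 Hz
fundamental), 100 Hz, tremor at 5 Hz. Joint contributions are low-harmonic
sinusoids with small phase offsets (a coordinated reach; large offsets would
let a distal joint cancel a proximal one), amplified by 1.8 per joint
distally from a 0.4 rad/s humerus scale; tremor is a cycle-locked
amplitude-modulated sinusoid amplified by 2.5 per segment toward the hand
(1 rad/s there by default). The forearm is non-rigid for pronosupination: the
proximal forearm sensor receives 60% of the distal pronosupination component,
without which the two forearm sensors of the 4-sensor layout would be
indistinguishable from angular velocity. White noise (0.01 rad/s) is added to
the velocity before exact axis-angle integration into orientation; an optional
causal first-order low-pass of the quaternion stream emulates the smoothing
lag of the sensors' onboard fusion. The ground truth stores the constructed
voluntary/tremor/total series and a `gyro` channel defined as the Poisson
velocity of the lag-free orientation stream — the ideal co-located gyroscope,
so that with the lag disabled the orientation and gyroscope pipelines consume
identical inputs and their comparison isolates the lag mechanism.

`make_fixture_suite` spreads tremor severity geometrically over a 100× range
(nearly absent to severe), jitters trial amplitudes by ±30%, and derives all
randomness from one seed.

What passing on this bed shows — and does not. It shows the algorithms are
correct under their own assumptions: additive chain, distal amplification,
band-separated voluntary/tremor content, rigid segments under each sensor. It
does not establish robustness to soft-tissue artifacts, magnetic disturbance
of the fusion, non-stationary tremor frequency, sensor dropout, or tasks whose
joint coordination breaks distal amplification; the printed patient-level KTE
magnitudes are likewise not reproducible here.

## Problem sizes and numerics

Tests and the acceptance script use default-size trials (3001 samples at
100 Hz; 30001 after upsampling) and suites of 12–20 trials; the GA check uses
two trials against a 201-point grid-search oracle. Tolerances: orthonormality
1e-6 after load-time re-orthonormalization (hard failure at 1e-3), quaternion
norm drift 1e-3, timestamp jitter 1% of the nominal period, decomposition
additivity enforced at 1e-9 (the tremor channel is bitwise raw − voluntary).
Ranking ties and classifier label conflicts are resolved deterministically (
input order / confidence order) and always flagged rather than silently
broken.
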