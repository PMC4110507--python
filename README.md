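# tremorkit

Relative sensor-location identification and real-time tremor estimation for
upper-limb chains of wearable orientation sensors (MIMUs).

People with essential tremor are commonly monitored — and increasingly
assisted by tremor-suppressing neuroprostheses — through small
magnetic-inertial units strapped to the hand, forearm and humerus. These
sensors emit fused orientation streams. Two practical problems stand between
those streams and useful clinical quantities, and this package solves both:

1. **Where is each sensor on the chain?** Donning is done by patients or
   clinicians, not engineers. `tremorkit` identifies each sensor's *relative*
   position (hand → humerus) from a single ~30 s finger-to-nose trial, with a
   training-free ranking classifier: movement and kinetic tremor are amplified
   distally, so sorting sensors by any magnitude-monotone motion feature
   reproduces the chain order. Trained alternatives (random forest, pruned
   decision tree on within-trial rank features) are included.
2. **How much of the movement is tremor?** Angular velocity is extracted from
   orientation via the Poisson equation `Ω = Ṙ R⁻¹`, the wrist joint velocity
   is formed by distal-minus-proximal subtraction, and a critically damped g-h
   filter (gains `g = 1 − θ²`, `h = (1 − θ)²`, one smoothing parameter
   θ ∈ [0.8, 1] tuned by a genetic algorithm) separates the sub-2 Hz voluntary
   component from 3–12 Hz tremor in real time. Estimates are scored with the
   kinematic tracking error `KTE = mean(|b|) + var(|b|)` against an offline
   zero-phase 2 Hz low-pass reference.

Because no patient recordings ship with the package, `tremorkit.synth`
generates labelled synthetic finger-to-nose trials (additive kinematic chain,
distal amplification, amplitude-modulated tremor, optional emulation of the
sensors' onboard fusion lag) with exact ground-truth decompositions.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
import numpy as np
import tremorkit as tk

# one synthetic 3-sensor finger-to-nose trial: 30 s, 100 Hz, 5 Hz tremor
sim = tk.simulate_trial(tk.SynthConfig(seed=7))
trial = sim.recording

# 1. where is each sensor? (feature 1 = summed total angular path)
pred = tk.rank_classify(trial, feature_id=1)
print("predicted order:", pred.predicted_order)
print("accuracy:", pred.accuracy)

# 2. how much of the wrist movement is tremor?
est = tk.estimate_tremor_from_orientation(trial, theta=0.9958)
dec = est.axes["x"]                                   # wrist flexion axis
ref = tk.offline_reference(dec.raw, est.rate_hz, fc=2.0)
res = tk.kte(dec.tremor, ref.tremor)
print(f"KTE = {res.kte:.4f}  (kte1 = {res.kte1:.4f}, kte2 = {res.kte2:.4f})")

f, a = tk.amplitude_spectrum(dec.tremor, est.rate_hz)
band = (f >= 3) & (f <= 12)
print(f"tremor peak: {f[band][np.argmax(a[band])]:.2f} Hz, "
      f"amplitude {a[band].max():.3f} rad/s")
```

prints

```
predicted order: ['hand', 'forearm_distal', 'humerus']
accuracy: 1.0
KTE = 0.0592  (kte1 = 0.0578, kte2 = 0.0014)
tremor peak: 5.00 Hz, amplitude 0.317 rad/s
```

The ranking classifier places all three sensors correctly (accuracy 1.0). The
real-time tremor estimate tracks the offline reference with a tracking error
dominated by its mean (response-time) component, and its spectrum peaks at the
configured 5 Hz tremor frequency.

The same pipeline is available from the shell:

```sh
tremorkit simulate --seed 7 --n-trials 3 --out trials/
tremorkit locate --method ranking --feature 1 --trials trials/<id>.csv --out report.json
tremorkit estimate --trial trials/<id>.csv --theta 0.9958 --out decomposition.csv
tremorkit evaluate --trial trials/<id>.csv --truth trials/<id>.truth.csv --out kte.csv
```

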