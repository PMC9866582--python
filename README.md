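# pulsekit

Tools for radial-artery wrist pulse waveform analysis: simulation of the
full measurement chain of a wearable three-sensor pulse wristband,
adaptive localization of the three palpation points (Cun, Guan, Chi),
wavelet/sliding-window denoising, landmark-based reconstruction of
anomalous cycles, feature extraction, and slippery-vs-normal pulse
classification.

It is aimed at researchers prototyping pulse-waveform pipelines for
wearable pressure-sensor arrays, where raw data is a 125 Hz amplitude
series per sensor plus an optional cuff-pressure channel.

## The model

A pulse cycle of period *T* is a superposition of three component waves,

    Y(t) = y1(t) + y2(t) + y3(t),   0 <= t < T,

where

* the **main wave** y1(t) = k1(t) f1(t) is a cubic-smoothstep rise to the
  systolic peak *Ym* at *ts*, decaying to zero at *T*, modulated by a
  curvature envelope k1 that drops linearly from 1 to a constant
  *c* between the peak and the main-wave valley time *b*, then decays as
  c·exp(−((t−b)/(T−b))³);
* the **tidal wave** y2 is a smooth bump of height *Ym1* supported on
  [b, T1), peaking at *ts1*;
* the **dicrotic wave** y3 is a smooth bump of height *Ym2* supported on
  [T1, T), peaking at *ts2*.  *Ym2* = 0 encodes the **slippery pulse**
  class, whose defining trait is the absent dicrotic wave; the **normal
  pulse** has all three waves.

Every segment uses the canonical cubic with zero slope at both ends, so
cycles are continuous and start/end at zero.

Around the waveform model the package implements:

* a **sensor model** — the cubic pressure-to-voltage calibration
  u = 2.333m³ − 0.689m² + 0.171m + 0.068 (m in grams), contact pressure
  P = mg/S, the 12-bit ADC mapping y = u·4096/3.3 and a 0.5–100 Hz
  band-limit emulation;
* **adaptive pulse finding** — a 6-parameter quadratic amplitude surface
  z = a0x² + a1xy + a2y² + a3x + a4y + a5 fitted to a 5×5 wrist scan,
  then three collinear points 1.5 cm apart placed to maximize the mean
  fitted amplitude subject to a 60-count floor, with array angle
  θ = arctan((x2−x1)/(y2−y1));
* a **denoising chain** — 5-level DWT (db4, periodization),
  soft/hard-compromise shrinkage (threshold
  N = 1.43·median|CD1|·√(2 ln 500), survivors shrunk by λ = αN),
  trough-based period segmentation, then per-cycle shear
  f(n) → f(n) − n·tanθ and baseline removal y(n) = x(n) − min x(n);
* **prediction/reconstruction** — per-cycle landmarks (h1..h6, t1..t6)
  mapped back to waveform parameters from the last valid cycle, refined
  by bounded least squares on (b, ts, c), replacing cycles whose
  amplitude or period mutated;
* **features and classification** — spatio-temporal features
  Ft{ts/tf, t1:t2:t3, h1:h2:h3} and modal energies Fy{y6, y5, y4}
  (yi = ‖Yi‖/‖Y‖ for wavelet components passing the correlation filter
  r > 0.2), feeding an 8-cell comparison of {NN, SVM} × {linear, rbf} ×
  {Ft, F = Ft ∪ Fy} with a stratified 60/20/20 split.

## Worked example

```python
import pulsekit as pk

# simulate a noisy normal-pulse record and denoise it
noise = pk.NoiseSpec(baseline_amp=3.0, baseline_freq=0.2, white_sd=0.5)
trace, truth = pk.synthesize_record("normal", n_cycles=8, noise=noise, seed=42)
clean, seg = pk.denoise_pipeline(trace)
print(f"{seg.n_cycles} cycles, mean period {seg.period.mean()/clean.fs:.3f} s")

fv = pk.featurize_record(clean, seg, label="normal")
print(f"ts/tf = {fv.ts_tf:.3f}   h2/h1 = {fv.h2_h1:.3f}   h3/h1 = {fv.h3_h1:.3f}")
print(f"modal energies: y6 = {fv.y6:.3f}, y5 = {fv.y5:.3f}, y4 = {fv.y4:.3f}")

# locate the key points on a synthetic wrist scan
grid = pk.scan_grid_fixture((-20.0, 0.5, -4.0, 40.0, 1.0, 85.0), noise_sd=1.0, seed=0)
kp = pk.locate_key_points(pk.fit_surface(grid))
print(f"Guan at ({kp.p1[0]:.2f}, {kp.p1[1]:.2f}) cm, theta = {kp.theta:.3f} rad, "
      f"mean amplitude = {kp.mean_amp:.1f}")
```

prints

```
8 cycles, mean period 1.040 s
ts/tf = 0.191   h2/h1 = 0.424   h3/h1 = 0.237
modal energies: y6 = 0.931, y5 = 0.342, y4 = 0.129
Guan at (1.00, 0.20) cm, theta = 0.022 rad, mean amplitude = 98.9
```

The duration ratio ts/tf ≈ 0.19 sits in the normal band (slippery pulses
run ≈ 0.25–0.30), h3/h1 > 0 confirms a detected dicrotic wave, and the
scaling-band energy y6 dominates the modal-energy profile, as expected
for a ~1 Hz pulse sampled at 125 Hz.  The located Guan point lands on
the synthetic surface's ridge with the array nearly parallel to the arm
axis.

A command-line interface mirrors the library:
`pulsekit simulate | find-pulse | denoise | reconstruct | features |
train | compare | report` (see `pulsekit --help`).

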