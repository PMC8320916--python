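# subpix

Sub-pixel particle detection for image-based particle tracking.

In complex plasmas, colloids and granular matter, micrometer-sized particles
are imaged as small bright blobs on a dark background. Computing per-particle
velocities (particle tracking velocimetry) requires localizing each blob to a
small fraction of a pixel. `subpix` implements the full toolchain for building
and benchmarking such detectors:

- **Scene simulation** — particles as pixel-integrated bivariate Gaussians
  (the value of pixel *(x, y)* is
  ¼·[erf((x+½−μₓ)/√2σₓ) − erf((x−½−μₓ)/√2σₓ)]·[erf((y+½−μᵧ)/√2σᵧ) − erf((y−½−μᵧ)/√2σᵧ)]),
  motion streaks via a time integral over the exposure, global rescaling to
  [0, 1], additive white Gaussian noise scaled by 1/SNR with clipping,
  salt-and-pepper noise, and 8/16-bit quantization — with ground truth.
- **Preprocessing** — Hann amplitude (low-pass) filtering with
  w(r) = ½[1 − cos(2π(r − (N−1)/2)/(N−1))] for r ≤ (N−1)/2, gamma
  adjustment, and automatic thresholds by Otsu's method (maximal between-class
  variance) and intermodes smoothing (iterated 3-bin averaging to bimodality).
- **Generalized moment method** — blobs are sets of above-threshold pixels
  connected transitively under a distance-≤ r relation (r = 1: classic
  4-connected sets; r > √2 bridges pepper-noise gaps), filtered by minimum
  pixel count, extent, density and brightness density; sub-pixel centers are
  intensity-weighted centroids x_c = Σ x (I − I_base) / Σ (I − I_base), with
  I_base = I_threshold as the bias-reducing choice. Image moments supply an
  orientation angle α = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂) and a motion-streak travel
  length from the stadium model A = πρ² + 2ρl, l_m = l + 2ρ.
- **PSF refinement** — each detection gets a non-overlapping square tile
  (half the Chebyshev distance to its nearest neighbour) in which a
  generalized Gaussian p^{1−1/p}/(2σΓ(1/p))·exp(−r^p/(pσ^p)) plus constant
  background is least-squares fitted with L-BFGS-B (numeric central-difference
  gradients) on the original, unfiltered image.
- **Pipelines** — the named presets `alg01`–`alg12` combining these stages.
- **Evaluation** — mutual-nearest-neighbour matching against truth, RMSE,
  pixel-locking curves, streak angle/length errors, and velocity-error
  propagation Δv = 2·Δx·(mm/px)/dt plus the thermal speed √(k_B T/m) a setup
  must resolve.

## Worked example

```python
import subpix as sp

# 400 unit-width particles, one per 20x20 px cell, SNR = 100
scene = sp.grid_scene(400, sigma=1.0, snr=100, seed=1)
img, truth = sp.simulate_scene(scene)

# Hann filter (N=5) + moment method + generalized-Gaussian refinement
dets, meta = sp.run_pipeline(img, sp.resolve_preset("alg06", threshold=0.1))
report = sp.match_truth(sp.detections_to_frame(dets), truth)
print(f"detections: {report.n_detected} / {report.n_truth}")
print(f"position RMSE: {report.rmse:.4f} px")
print(f"velocity error at 0.020 mm/px, dt=10 ms: "
      f"{sp.velocity_uncertainty(report.rmse, 0.020, 0.010):.4f} mm/s")
```

prints

```
detections: 400 / 400
position RMSE: 0.0115 px
velocity error at 0.020 mm/px, dt=10 ms: 0.0460 mm/s
```

Every particle is recovered, the fitted centers are accurate to about 1/100
of a pixel, and for a camera at 0.020 mm/px and 100 frames/s that position
noise maps to a velocity uncertainty of about 0.05 mm/s — below the ~0.08
mm/s thermal speed of a 9.19 µm, 1.51 g/cm³ microsphere at room temperature
(`sp.thermal_speed(9.19, 1.51)`), so Brownian-scale motion is resolvable.

The same pipelines are available from the shell:

```bash
subpix synth --n-particles 400 --snr 100 --seed 1 \
    --image-out scene.png --truth-out truth.csv
subpix run --preset alg06 --image scene.png --threshold 0.1 --out det.csv
subpix eval det.csv truth.csv
```

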