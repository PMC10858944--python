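# contourscope

Computational pipeline for **lensless mesoscopic fluorescence microscopy**
of cortical activity. A thin phase mask with a "contour" point-spread
function (PSF) replaces the objective lens: every scene point is multiplexed
across the sensor as a set of thin curved lines, and the scene is recovered
by solving a regularized inverse problem. The payoff is a field of view of
tens of mm² at ~10 μm resolution from a device light enough to ride on a
freely moving animal's head — at the cost of making image formation a
computational problem.

`contourscope` implements that computation end to end on synthetic data:

* **Mask design** — contour PSF targets from Perlin noise + Canny edge
  detection; quantized phase masks (200 nm steps, 1 μm max height) via
  angular-spectrum phase retrieval.
* **Forward model** — PSF simulation over depth and field position, the
  shift-variant operator Φi = Σₖ(wₖ⊙i)∗pₖ built from a calibrated PSF grid
  (9×9 per depth in the instrument), shot/read sensor noise.
* **Reconstruction** — closed-form Wiener/Tikhonov deconvolution
  î = F⁻¹(conj(F(p))F(b)/(|F(p)|²+γ)); joint scene+background estimation
  min_{i≥0,g} ‖(Φi+g)−b‖²+(γ/2)‖i‖² with g confined to the lowest 5×5 DCT
  block, solved by monotone FISTA; digital refocusing over a calibrated
  depth range (20 μm steps).
* **Phantoms** — USAF-1951 resolution targets and a cortical sheet with
  semi-periodic orientation columns (~1.2 cycles/mm, with pinwheels), 4 Hz
  stimulus-entrained GCaMP dynamics at 20 Hz, heartbeat-band (2–3 Hz)
  artifact and shot noise.
* **Analysis** — blank-trial subtraction, ΔF/F, rigid registration,
  position tuning (1D Gaussian fits), orientation mapping (first-harmonic
  maps, RMS ROI, 0.8–2.5 cycles/mm spatial bandpass, pixel-wise
  d′ = (m₀−m₉₀)/√((σ₀²+σ₉₀²)/2), cross-validated d′-weighted linear
  decoding, pairwise map correlations vs orientation difference,
  vector-summation composite maps, sin(2θ) map comparison, shuffle nulls).

Intended users: imaging-systems researchers prototyping lensless
reconstruction pipelines, and systems neuroscientists who want a fully
synthetic, ground-truthed testbed for widefield orientation-mapping
analyses.

## Worked example

```bash
python examples/orientation_mapping_demo.py
```

generates a 96×96 cortical phantom, simulates 6 grating orientations × 10
trials plus blanks with heartbeat artifact and shot noise, runs the
orientation analysis and prints:

```
pairwise map correlation vs orientation difference:
     30 deg: r = +0.575
     60 deg: r = -0.255
     90 deg: r = -0.668
(positive at 30 deg, most negative at 90 deg — the signature of orientation columns)
recovered vs planted preferred-orientation map: r = 0.990
trial-label shuffle null: mean +0.058, max 0.957 — the actual map beats every shuffle
```

The correlation curve decreasing from +0.58 at 30° to −0.67 at 90° is the
classic fingerprint of orientation columns (maps 90° apart are
anti-correlated); r = 0.99 says the recovered preferred-orientation map
matches the planted ground truth almost perfectly in this direct-imaging
configuration. Other examples cover mask design, USAF resolution round
trips with digital refocusing, d′ decoding, and the full lensless pipeline
(`examples/end_to_end_pipeline.py`).

A thin CLI wraps the same library calls:

```bash
contourscope design-mask --shape 256 --seed 0 --out out/
contourscope phantom cortex --shape 128 --out out/
contourscope reconstruct --stack stack.tif --psf-grid grid.h5 --model fista --out out/
contourscope run --config pipeline.yaml
```

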