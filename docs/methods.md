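# Methods

`contourscope` reimplements, on synthetic data, the computational chain of a
lensless mesoscopic fluorescence microscope for cortical calcium imaging: a
phase mask with a "contour" point-spread function replaces the objective, the
sensor records multiplexed measurements, a regularized inverse problem
recovers the scene, and standard widefield calcium-imaging statistics are
computed on the reconstructed trial videos.

## Phase-mask design

The target PSF is a set of thin closed curves obtained by Canny edge
detection on gradient-lattice Perlin noise, dilated to the fabrication
linewidth (6 μm at a 1 μm fabrication pixel). Thin curves give the PSF a
broadband, high-contrast spectrum in every direction, which is what makes
the multiplexed measurements invertible.

The Canny detector is implemented in-package (Gaussian smoothing, Sobel
gradients, 4-direction non-maximum suppression, hysteresis with thresholds
expressed as fractions of the gradient-magnitude maximum, defaults 0.1/0.3).
The fraction-of-max threshold convention and the need for exact agreement
with a reference implementation in tests is why this step is not delegated
to an external edge detector with different non-maximum-suppression
conventions.

The phase profile realizing the target is recovered by error-reduction
(Gerchberg–Saxton-type) phase retrieval between the mask plane (unit
amplitude, free phase) and the sensor plane (amplitude clamped to √target),
propagating with the band-limited angular-spectrum method. Fidelity is
monitored as the normalized cross-correlation between the propagated
intensity and the target; error reduction makes it non-decreasing in
practice, and a final fidelity below a configurable floor flags
`converged=False` rather than raising. Phase is converted to resist height
via h = φλ/(2πΔn) with a configurable index contrast Δn = 0.55, then
quantized to the 200 nm lithography step and clipped at 1 μm (six levels);
at λ = 530 nm the full 2π range maps to 964 nm, so clipping is inert and
quantization moves no height by more than half a step.

## Forward model

The shift-variant operator follows the standard low-rank windowed model: the
field of view is spanned by a grid of locally calibrated PSFs (9×9 over
8 mm × 8 mm in the instrument; any grid here), and

Φ i = Σₖ (wₖ ⊙ i) ∗ pₖ

with bilinear hat windows wₖ that form an exact partition of unity over the
grid hull. The model is exact at grid nodes, continuous between them, and
degenerates to ordinary convolution when all PSFs coincide. Convolutions are
linear (aperiodic): both operands are zero-padded to the next fast FFT
length ≥ scene+kernel−1, multiplied in the frequency domain, and cropped so
forward, adjoint and Wiener paths share one bit-identical convention. The
top-left crop is exactly the adjoint of the top-left zero-pad, so Φᵀ is the
exact adjoint of Φ (verified to machine precision). A `periodic` boundary
option runs the same machinery without padding, which is the convention
under which the Wiener filter is the exact closed-form inverse.

Sensor noise: Poisson shot noise at a configurable photon count per
measurement unit, optional Gaussian read noise, and optional clipping and
quantization to 8-bit counts matching the instrument's sensor.

## Reconstruction

Two solvers:

* **Wiener/Tikhonov (closed form).** î = F⁻¹(conj(F(p))·F(b)/(|F(p)|²+γ)),
  evaluated on the padded grid. With γ = 0 and a PSF whose spectrum has
  near-zeros, a division-guard error is raised. The per-image default
  γ = 0.01·max|F(p)|².
* **FISTA with a DCT-constrained background.** The scene i ≥ 0 and an
  additive background g restricted to the lowest 5×5 block of its 2D DCT
  are estimated jointly by minimizing ‖(Φi+g)−b‖² + (γ/2)‖i‖². Because g is
  unpenalized and quadratic, it is eliminated exactly each iteration — the
  optimal g given i is the DCT-subspace projection of b−Φi — and FISTA runs
  on the reduced objective. This block-exact elimination has the same
  minimizer as the joint iteration but avoids its ill-conditioned coupled
  directions. The step is 1/L with L = 2σ₁(Φ)²+γ bounded by power
  iteration; the accept step is monotone (an objective increase keeps the
  previous iterate and restarts momentum), so the recorded objective trace
  is non-increasing by construction. Note the γ conventions: the
  unconstrained shift-invariant limit of the FISTA objective equals the
  Wiener filter evaluated at γ/2.

Identifiability: any scene perturbation δ with Φδ inside the background's
DCT subspace trades exactly against g. The constant direction is always such
a perturbation; nonnegativity and the γ‖i‖² term resolve it, but for very
small γ the selection is slow, so planted-recovery accuracy is best at
moderate γ (≈1e-4 in the tests) and with kernels whose spectrum is bounded
away from zero.

Digital refocusing reconstructs at each candidate depth (central-PSF
Wiener), scores sharpness by the variance of the Laplacian in a chosen ROI,
and returns the argmax depth; ties break to the smallest depth. Very small γ
makes the sharpness score reward amplified out-of-band noise when
deconvolving with the wrong depth's PSF; the default γ avoids this.

## Phantoms

**USAF-1951 target.** Standard three-bar geometry (bar length five times
width, gaps one width) for any set of groups and elements, with the
resolution formula linewidth = 500/2^(group+(element−1)/6) μm. Elements
below 2 px at the requested pitch are omitted with a warning. The layout
packs element blocks on a grid; it is geometrically faithful per element,
not a facsimile of the printed chart arrangement.

**Orientation-column cortex.** Complex white noise filtered by a Gaussian
annulus at the column periodicity (default 1.2 cycles/mm, bandwidth
0.3 cycles/mm); preferred orientation is arg(z)/2, which guarantees
pinwheels and the correct spatial spectrum by construction. Tuning strength
follows |z| (dipping at pinwheels) normalized so its **mean** equals the
ΔF/F amplitude parameter (default 0.03) — the parameter is the
characteristic peak ΔF/F of a tuned pixel. The baseline is a smooth random
fluorescence field at 10 units with dark vessel lines carved out; at the
default photon scale of 1000 photons per unit this corresponds to ~10⁴
photons/pixel/frame, the normal operating range of an sCMOS widefield
system at 10 ms exposure, and the regime in which single-trial
stimulus-entrained responses are visible, as they are in real widefield
GCaMP recordings.

**Trials.** Stimuli are flashed 4×/trial at 4 Hz (100 ms ON / 150 ms OFF),
imaged at 20 Hz with a 200 ms pre-onset window (24 frames/trial). Pixel
responses are tuning_amp·(1+cos 2(θ−stimulus))/2 times the ON/OFF train
convolved with a GCaMP6f-like kernel ((1−e^(−t/τr))e^(−t/τd), τr = 50 ms,
τd = 400 ms, peak-normalized, computed on a 1 ms grid and sampled at frame
times). The heartbeat artifact is a global multiplicative sinusoid at a
random 2–3 Hz frequency and random phase per trial (phase-locking to trial
onset, emulating ECG-gated acquisition, is available via
`heartbeat_locked`). With this kernel most single-sided spectral power of a
1 s trial sits in the slow onset-envelope bins below 2 Hz; the 4 Hz
entrained line dominates at and above 2 Hz, and the analysis reads exactly
that line.

What the phantom does **not** model: hemodynamic signals beyond the
heartbeat band, photobleaching, tissue scattering, eye movements, and any
non-cosine structure of real tuning curves. Passing tests therefore show
that the algorithms recover what this generative model plants, not that the
instrument performs identically on tissue.

## Analysis

Preprocessing follows the trial-based widefield convention: the mean blank
time course is subtracted per pixel from each stimulus trial, then each
trial's mean residual over the 200 ms pre-onset window is removed, making
the pre-onset mean exactly zero. **Trials are then averaged per condition
before the first-harmonic amplitude is taken.** The order matters: the
harmonic magnitude is a nonlinear statistic, and magnitudes of
noise-dominated single trials carry a Rician floor that no amount of
post-hoc averaging removes; averaging time courses first lets the
stimulus-locked signal add coherently while heartbeat (random phase) and
shot noise cancel.

Per-condition 4 Hz amplitude maps are restricted to an ROI where the
cross-condition RMS exceeds one third of its maximum, bandpassed to
0.8–2.5 cycles/mm (annular mask with raised-cosine edges of 0.1 cycles/mm;
a hard annulus is available), correlated pairwise as a function of circular
orientation difference, and combined by vector summation
z = Σₖ Rₖ e^(i2θₖ) into a preferred-orientation map (arg z/2) and tuning
magnitude (|z|/Σ|Rₖ|). Two preference maps are compared by Pearson
correlation of sin(2θ). The decoder computes per-pixel d′ maps between 0°
and 90°, per-trial decision variables DV = Σ_ROI m·d′, and an overall d′
from held-out DVs under leave-one-out cross-validation (the
smallest-variance unbiased scheme at 10 trials per condition).

**Shuffle null.** Two nulls are provided. The map-level null relabels the
six finished orientation maps; it is retained for diagnostics, but label
assignments that leave the sin(2θ)-converted composite exactly invariant
(the original labeling and its θ→90°−θ reflection) are excluded, since the
comparison statistic cannot distinguish them from unshuffled data. The
null used by the end-to-end validation relabels at the **trial** level:
orientation labels are permuted across trials, condition maps are rebuilt
from per-trial complex 4 Hz coefficients (linearity makes this exactly
equivalent to re-averaging the videos), bandpassed, composited and
compared. Trial-level relabeling pools trials of mixed orientations, so the
orientation-specific signal averages away while shared structure survives —
the appropriate question being whether a map reflects orientation columns
rather than any reproducible pattern.

## End-to-end validation

The closure study plants a 256×256 cortex phantom (31.25 μm object pixels,
8 mm field), simulates 6 orientations × 10 trials plus 10 blanks with
heartbeat artifact, forms measurements through a 3×3 shift-variant grid of
contour PSFs, adds shot noise, reconstructs every frame with FISTA, runs
the full orientation pipeline and compares the recovered preference map to
the planted one, requiring the 1500-draw trial-shuffle null maximum to fall
below the actual correlation.

The grid PSFs for this study are thin-stroke contour patterns (the design
target intensity itself) sampled on the object-plane grid with 0.5 mm
support, laterally shifted per grid node. Wave-optics propagation of the
1 μm-pitch mask, resampled to 31 μm object pixels, yields an unrealistically
diffuse kernel whose spectrum is ~0.03 in the columnar band — an artifact of
the resampling, not of the instrument, whose PSF is exactly the thin
high-contrast contour pattern. The compact support compensates for this
study's 1× sensor sampling (the instrument oversamples the object ~16× with
a 2048² sensor, recovering a comparable information budget).

Solver settings for the study: γ = 0.02, 6 FISTA iterations per frame
warm-started from a clipped Wiener reconstruction, single-precision FFTs,
one shared operator and Lipschitz estimate across all 1,680 frames. The
slightly heavier damping and early stopping act as additional
regularization at this noise level — per-frame reconstructions sit close to
the damped Wiener solution, which is where the trial-averaged harmonic
analysis is most accurate. These problem sizes keep the whole study at
roughly five minutes on one CPU core.

## Numerical conventions

* Object-plane coordinates in mm, pitches in μm, heights in nm; 0-based
  pixel indexing, origin top-left, y down.
* All randomness flows from explicit integer seeds;
  `numpy.random.default_rng` throughout. The pipeline driver derives
  per-stage seeds from one global seed via `SeedSequence`.
* Convolution padding: next fast FFT length ≥ scene+kernel−1 (exact linear
  convolution); kernels centered at (k//2, k//2).
* FISTA stops on relative objective decrease < tol on a non-restart
  iteration, or at max_iter with `converged=False`.
* Refocus ties break to the smallest depth; depth lookups between
  calibrated planes interpolate PSFs linearly.

## Known limitations

* The shift-variant model is exact only at grid nodes; between nodes it is
  the standard bilinear interpolation approximation.
* The background DCT subspace overlaps the range of Φ, so scene/background
  separation is resolved only by nonnegativity and the γ term (see
  Identifiability above); very small γ degrades planted-background
  recovery.
* The phase-retrieval stage uses error reduction with a fixed support; no
  over-relaxation or hybrid input-output variants are provided.
* Registration is rigid translation only.
* The decoder assumes two conditions (0° vs 90°), as in the source
  experimental design.
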