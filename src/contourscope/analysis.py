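"""Widefield calcium-imaging analysis.

Implements the trial-based analyses used for mesoscopic GCaMP imaging of
macaque V1:

* preprocessing — blank-trial subtraction with pre-onset re-baselining,
  ΔF/F conversion, rigid frame registration against a vascular template;
* position tuning — per-ROI condition means fitted with a 1D Gaussian over
  stimulus position;
* orientation mapping — per-pixel first-harmonic (4 Hz) response amplitude,
  RMS-based ROI selection (> 1/3 of max), spatial bandpass at the columnar
  scale (0.8–2.5 cycles/mm), pixel-wise d′ maps, a cross-validated linear
  decoder (decision variables weighted by the d′ map), pairwise map
  correlations vs orientation difference, vector-summation composite maps,
  sin(2θ) map comparison, and an orientation-label shuffle null.

The d′ conventions: per pixel

    d′(x,y) = (m₀ − m₉₀) / sqrt((σ₀² + σ₉₀²)/2),

per trial DV = Σ_{ROI} m_trial · d′_map, and the decoder discriminability
d′_DV = (mean DV₀ − mean DV₉₀)/sqrt((SD₀² + SD₉₀²)/2), computed on held-out
trials under leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

__all__ = [
    "TrialSet",
    "TuningFit",
    "OrientationStats",
    "DecoderResult",
    "OrientationMapSet",
    "subtract_blank",
    "dff",
    "register_frames",
    "position_tuning",
    "harmonic_amplitude",
    "rms_roi",
    "bandpass_spatial",
    "dprime_map",
    "decode_orientation",
    "pairwise_map_correlation",
    "composite_orientation_map",
    "compare_maps",
    "shuffle_null",
    "shuffle_null_trials",
    "harmonic_coefficient",
    "orientation_pipeline",
]

BLANK = "blank"


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class TrialSet:
    """Trial videos with condition labels.

    ``videos``: (n_trials, T, H, W); ``labels``: per-trial condition
    (orientation in degrees, position index/degrees, or ``"blank"``);
    ``onset_frame``: stimulus onset index shared by all trials.
    """

    videos: np.ndarray
    labels: list
    frame_rate: float = 20.0
    onset_frame: int = 4
    pixel_pitch_obj: float = 31.25  # μm at object plane

    def __post_init__(self):
        self.videos = np.asarray(self.videos, dtype=float)
        if self.videos.ndim != 4:
            raise ValueError("videos must be (n_trials, T, H, W)")
        if len(self.labels) != self.videos.shape[0]:
            raise ValueError("labels length must match trial count")
        self.labels = list(self.labels)

    @property
    def blank_indices(self):
        return [i for i, l in enumerate(self.labels) if l == BLANK]

    def condition_indices(self, condition):
        return [i for i, l in enumerate(self.labels) if l == condition]

    @property
    def conditions(self):
        seen = []
        for l in self.labels:
            if l != BLANK and l not in seen:
                seen.append(l)
        return seen


@dataclass
class TuningFit:
    """Per-ROI position-tuning result: Gaussian fit of response vs position."""

    roi_centers: np.ndarray  # mm, ROI center coordinates
    positions: np.ndarray  # stimulus positions (degrees of visual angle)
    responses: np.ndarray  # (n_roi, n_positions) mean responses
    params: np.ndarray  # (n_roi, 4): amplitude, center, sigma, offset
    residuals: np.ndarray
    flagged: np.ndarray  # bool per ROI: fit failed or degenerate

    @property
    def peak_positions(self):
        return self.params[:, 1]


@dataclass
class OrientationStats:
    """Per-pixel condition means and SDs feeding the d′ map."""

    m0: np.ndarray
    m90: np.ndarray
    s0: np.ndarray
    s90: np.ndarray

    @property
    def dprime(self):
        return dprime_map(self.m0, self.m90, self.s0, self.s90)


@dataclass
class DecoderResult:
    """Linear-decoder output: per-trial decision variables and overall d′."""

    dv0: np.ndarray
    dv90: np.ndarray
    dprime_dv: float
    cv_scheme: str = "leave-one-out"


@dataclass
class OrientationMapSet:
    """Bandpassed single-orientation maps and derived composite quantities."""

    single_maps: np.ndarray  # (n_orientations, H, W)
    orientations: np.ndarray  # degrees
    corr_deltas: np.ndarray = None
    corr_curve: np.ndarray = None
    pref_map: np.ndarray = None  # degrees [0, 180)
    magnitude_map: np.ndarray = None
    roi_mask: np.ndarray = None
    trial_coefs: np.ndarray = None  # per-trial complex 4 Hz maps (stim trials)
    trial_labels: np.ndarray = None


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------


def subtract_blank(trials: TrialSet, pre_onset_ms: float = 200.0) -> TrialSet:
    """Blank-trial subtraction with pre-onset re-baselining.

    The average blank time course is subtracted per pixel from every stimulus
    trial; then each trial's mean residual over the ``pre_onset_ms`` window
    before onset is removed per pixel, so the pre-onset mean of every
    corrected trial is exactly zero.  Returns a TrialSet of the stimulus
    trials only.
    """
    blanks = trials.blank_indices
    if not blanks:
        raise ValueError("blank subtraction requires at least one blank trial")
    n_pre = int(round(pre_onset_ms / 1000.0 * trials.frame_rate))
    if trials.onset_frame < n_pre:
        raise ValueError(
            f"need ≥ {pre_onset_ms} ms of pre-onset frames "
            f"(onset at frame {trials.onset_frame}, need {n_pre})"
        )
    blank_mean = trials.videos[blanks].mean(axis=0)
    stim = [i for i in range(len(trials.labels)) if i not in set(blanks)]
    corrected = trials.videos[stim] - blank_mean[None]
    pre = slice(trials.onset_frame - n_pre, trials.onset_frame)
    corrected = corrected - corrected[:, pre].mean(axis=1, keepdims=True)
    return TrialSet(
        corrected,
        [trials.labels[i] for i in stim],
        frame_rate=trials.frame_rate,
        onset_frame=trials.onset_frame,
        pixel_pitch_obj=trials.pixel_pitch_obj,
    )


def dff(video: np.ndarray, baseline_window) -> np.ndarray:
    """ΔF/F: (F − F₀)/F₀ with F₀ the per-pixel mean over ``baseline_window``.

    Pixels with nonpositive baseline are masked to NaN; the count is reported
    in a warning.
    """
    video = np.asarray(video, dtype=float)
    f0 = video[baseline_window].mean(axis=0)
    bad = f0 <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pixels have nonpositive baseline; set to NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (video - f0[None]) / f0[None]
    out[:, bad] = np.nan
    return out


def register_frames(video: np.ndarray, template: np.ndarray, upsample: int = 10,
                    pixel_pitch: float = 1.0):
    """Rigid per-frame registration against a (vascular) template.

    Translation is found by upsampled cross-correlation; frames are shifted
    back with spline interpolation.  Returns (displacements_um, corrected,
    flagged) where displacements are (n_frames, 2) in μm (y, x) and flagged
    marks frames whose correlation peak sits implausibly near the border.
    """
    video = np.asarray(video, dtype=float)
    if template.shape != video.shape[-2:]:
        raise ValueError("template shape must match frame shape")
    n = video.shape[0]
    disp = np.zeros((n, 2))
    out = np.empty_like(video)
    flagged = np.zeros(n, dtype=bool)
    lim = min(template.shape) / 2.0 - 1.0
    for i in range(n):
        shift, _, _ = phase_cross_correlation(
            template, video[i], upsample_factor=upsample, normalization=None
        )
        if np.any(np.abs(shift) >= lim):
            flagged[i] = True
        disp[i] = shift
        out[i] = ndimage.shift(video[i], shift, order=1, mode="nearest")
    return disp * pixel_pitch, out, flagged


# --------------------------------------------------------------------------
# position tuning
# --------------------------------------------------------------------------


def _gauss1d(x, a, c, s, o):
    return a * np.exp(-0.5 * ((x - c) / s) ** 2) + o


def position_tuning(
    trials: TrialSet,
    roi_size_mm: float = 0.3,
    roi_spacing_mm: float = 0.37,
    n_roi: int = 6,
    response_window_s: float = 1.0,
) -> TuningFit:
    """Gaussian position-tuning fits on a row of square ROIs.

    ``trials`` must already be blank-subtracted; labels are stimulus
    positions in degrees of visual angle.  ROIs of ``roi_size_mm`` are spaced
    ``roi_spacing_mm`` apart along the horizontal midline.  The response is
    the mean over the ROI and over [onset, onset + response_window_s); per
    condition means are fitted with a·exp(−(x−c)²/2σ²)+o.  Degenerate or
    failed fits are flagged with raw responses preserved.
    """
    positions = sorted(trials.conditions)
    if len(positions) < 3:
        raise ValueError("need at least 3 stimulus positions")
    H, W = trials.videos.shape[-2:]
    pitch_mm = trials.pixel_pitch_obj * 1e-3
    size_px = max(int(round(roi_size_mm / pitch_mm)), 1)
    spacing_px = max(int(round(roi_spacing_mm / pitch_mm)), 1)
    row = H // 2
    total = (n_roi - 1) * spacing_px
    starts_x = W // 2 - total // 2 + np.arange(n_roi) * spacing_px
    if starts_x[0] - size_px // 2 < 0 or starts_x[-1] + size_px // 2 > W:
        raise ValueError(
            f"ROI row ({n_roi} ROIs of {roi_size_mm} mm at {roi_spacing_mm} mm "
            f"spacing) does not fit a {W * pitch_mm:.2f} mm wide field"
        )
    centers_mm = (starts_x * pitch_mm)

    t0 = trials.onset_frame
    t1 = t0 + int(round(response_window_s * trials.frame_rate))
    resp = np.zeros((n_roi, len(positions)))
    for j, pos in enumerate(positions):
        idx = trials.condition_indices(pos)
        mean_video = trials.videos[idx, t0:t1].mean(axis=(0, 1))
        for r in range(n_roi):
            y0 = max(row - size_px // 2, 0)
            x0 = max(starts_x[r] - size_px // 2, 0)
            resp[r, j] = mean_video[y0 : y0 + size_px, x0 : x0 + size_px].mean()

    xs = np.asarray(positions, dtype=float)
    params = np.zeros((n_roi, 4))
    residuals = np.zeros((n_roi, len(positions)))
    flagged = np.zeros(n_roi, dtype=bool)
    span = xs.max() - xs.min()
    for r in range(n_roi):
        y = resp[r]
        ptp = y.max() - y.min()
        if ptp <= 1e-12 * max(abs(y).max(), 1.0) or ptp == 0:
            flagged[r] = True
            params[r] = [0.0, np.nan, np.nan, y.mean()]
            continue
        p0 = [ptp, xs[int(np.argmax(y))], span / 4.0, y.min()]
        try:
            popt, _ = optimize.curve_fit(
                _gauss1d, xs, y, p0=p0,
                bounds=([-np.inf, xs.min() - span, 1e-6, -np.inf],
                        [np.inf, xs.max() + span, 10 * span, np.inf]),
                maxfev=10000,
            )
            params[r] = popt
            residuals[r] = y - _gauss1d(xs, *popt)
            if abs(popt[0]) < 1e-6 * max(abs(y).max(), 1.0):
                flagged[r] = True
        except (RuntimeError, ValueError):
            flagged[r] = True
            params[r] = [np.nan] * 4
    return TuningFit(centers_mm, xs, resp, params, residuals, flagged)


# --------------------------------------------------------------------------
# orientation mapping
# --------------------------------------------------------------------------


def harmonic_coefficient(video: np.ndarray, stim_freq: float = 4.0,
                         frame_rate: float = 20.0) -> np.ndarray:
    """Per-pixel complex first-harmonic coefficient at the stimulus frequency.

    (2/N)·Σ_t x_t e^{−i2πft}; linear in the video, so the coefficient of a
    trial-averaged video equals the average of per-trial coefficients.  If
    ``stim_freq`` is not on the DFT grid of the trace length the nearest bin
    is used with a warning.
    """
    video = np.asarray(video, dtype=float)
    n = video.shape[0]
    if stim_freq >= frame_rate / 2:
        raise ValueError("stim_freq must be below Nyquist")
    if n < 2 * frame_rate / stim_freq:
        raise ValueError("need at least 2 stimulus cycles of data")
    k_exact = stim_freq * n / frame_rate
    k = int(round(k_exact))
    if abs(k - k_exact) > 1e-9:
        warnings.warn(
            f"stimulus frequency {stim_freq} Hz not on the DFT grid for "
            f"{n} frames at {frame_rate} Hz; using nearest bin {k}"
        )
    t = np.arange(n)
    phasor = np.exp(-2j * np.pi * k * t / n)
    return (2.0 / n) * np.tensordot(phasor, video, axes=(0, 0))


def harmonic_amplitude(video: np.ndarray, stim_freq: float = 4.0,
                       frame_rate: float = 20.0) -> np.ndarray:
    """Per-pixel first-harmonic amplitude at the stimulus frequency.

    (2/N)·|Σ_t x_t e^{−i2πft}| so a pure sinusoid of amplitude A returns A.
    """
    return np.abs(harmonic_coefficient(video, stim_freq, frame_rate))


def rms_roi(amplitude_maps: np.ndarray, threshold_frac: float = 1.0 / 3.0) -> np.ndarray:
    """ROI mask: pixels whose cross-condition RMS exceeds a fraction of max."""
    maps = np.asarray(amplitude_maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    rms = np.sqrt(np.mean(maps**2, axis=0))
    top = rms.max()
    if top == 0:
        raise ValueError("all-zero amplitude maps: empty ROI")
    return rms > threshold_frac * top


def bandpass_spatial(
    map2d: np.ndarray,
    low: float = 0.8,
    high: float = 2.5,
    pixel_pitch_obj: float = 31.25,
    taper: float = 0.1,
) -> np.ndarray:
    """Annular spatial bandpass in cycles/mm with raised-cosine edges.

    Keeps radial frequencies in [low, high]; each edge is tapered by a
    raised cosine of width ``taper`` cycles/mm (``taper=0`` gives the hard
    annulus).  ``map2d`` may carry leading batch axes.
    """
    arr = np.asarray(map2d, dtype=float)
    ny, nx = arr.shape[-2:]
    pitch_mm = pixel_pitch_obj * 1e-3
    nyq = 0.5 / pitch_mm
    if high >= nyq:
        raise ValueError(f"high cutoff {high} ≥ Nyquist {nyq:.2f} cycles/mm")
    fy = spfft.fftfreq(ny, d=pitch_mm)
    fx = spfft.fftfreq(nx, d=pitch_mm)
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)

    def edge_up(f, f0):
        if taper == 0:
            return (f >= f0).astype(float)
        x = np.clip((f - (f0 - taper / 2)) / taper, 0.0, 1.0)
        return 0.5 * (1 - np.cos(np.pi * x))

    filt = edge_up(fr, low) * (1.0 - edge_up(fr, high + taper))
    return np.real(spfft.ifft2(spfft.fft2(arr, axes=(-2, -1)) * filt, axes=(-2, -1)))


def dprime_map(m0, m90, s0, s90) -> np.ndarray:
    """Pixel-wise discriminability (m₀ − m₉₀)/sqrt((σ₀² + σ₉₀²)/2).

    Pixels with zero pooled SD are set to 0 (their count is logged in a
    warning when any occur).
    """
    m0, m90, s0, s90 = (np.asarray(a, dtype=float) for a in (m0, m90, s0, s90))
    if not (m0.shape == m90.shape == s0.shape == s90.shape):
        raise ValueError("all maps must share one shape")
    pooled = np.sqrt((s0**2 + s90**2) / 2.0)
    zero = pooled == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} pixels with zero pooled SD set to d'=0")
    out = np.zeros_like(m0)
    np.divide(m0 - m90, pooled, out=out, where=~zero)
    return out


def _dv(trial_map, weights, roi_mask):
    return float(np.sum(trial_map[roi_mask] * weights[roi_mask]))


def decode_orientation(
    trial_maps_0: np.ndarray,
    trial_maps_90: np.ndarray,
    roi_mask: np.ndarray | None = None,
    cv: str | None = "leave-one-out",
) -> DecoderResult:
    """Linear d′-weighted decoder of 0° vs 90° from per-trial response maps.

    With ``cv="leave-one-out"``, each trial's decision variable is computed
    with a d′ map estimated from the remaining trials, so d′_DV is built only
    from held-out DVs.  ``cv=None`` uses the population d′ map for all trials
    (used by calibration tests, not for inference).
    """
    a0 = np.asarray(trial_maps_0, dtype=float)
    a90 = np.asarray(trial_maps_90, dtype=float)
    if roi_mask is None:
        roi_mask = np.ones(a0.shape[-2:], dtype=bool)
    n0, n90 = a0.shape[0], a90.shape[0]
    if cv == "leave-one-out":
        if min(n0, n90) < 3:
            raise ValueError("leave-one-out decoding needs ≥ 3 trials per condition")
        dv0 = np.empty(n0)
        dv90 = np.empty(n90)
        for i in range(n0):
            rest = np.delete(a0, i, axis=0)
            w = dprime_map(rest.mean(0), a90.mean(0), rest.std(0, ddof=1), a90.std(0, ddof=1))
            dv0[i] = _dv(a0[i], w, roi_mask)
        for i in range(n90):
            rest = np.delete(a90, i, axis=0)
            w = dprime_map(a0.mean(0), rest.mean(0), a0.std(0, ddof=1), rest.std(0, ddof=1))
            dv90[i] = _dv(a90[i], w, roi_mask)
        scheme = "leave-one-out"
    elif cv is None:
        if min(n0, n90) < 2:
            raise ValueError("need ≥ 2 trials per condition")
        w = dprime_map(a0.mean(0), a90.mean(0), a0.std(0, ddof=1), a90.std(0, ddof=1))
        dv0 = np.array([_dv(m, w, roi_mask) for m in a0])
        dv90 = np.array([_dv(m, w, roi_mask) for m in a90])
        scheme = "population"
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    pooled = np.sqrt((dv0.std(ddof=1) ** 2 + dv90.std(ddof=1) ** 2) / 2.0)
    d = float((dv0.mean() - dv90.mean()) / pooled) if pooled > 0 else 0.0
    return DecoderResult(dv0, dv90, d, scheme)


def pairwise_map_correlation(
    maps: np.ndarray,
    orientations,
    roi_mask: np.ndarray | None = None,
):
    """Mean Pearson correlation between map pairs vs orientation difference.

    The orientation difference is circular modulo 180°:
    Δ = min(|θᵢ−θⱼ|, 180−|θᵢ−θⱼ|).  Zero-variance maps cause their pairs to
    be skipped with a warning.  Returns (unique_deltas, mean_r).
    """
    maps = np.asarray(maps, dtype=float)
    th = np.asarray(orientations, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 maps")
    if roi_mask is None:
        roi_mask = np.ones(maps.shape[-2:], dtype=bool)
    vals = {}
    for i in range(len(th)):
        for j in range(i + 1, len(th)):
            a = maps[i][roi_mask]
            b = maps[j][roi_mask]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(f"zero-variance map in pair ({i},{j}); skipped")
                continue
            d = abs(th[i] - th[j]) % 180.0
            d = min(d, 180.0 - d)
            r = float(np.corrcoef(a, b)[0, 1])
            vals.setdefault(round(d, 9), []).append(r)
    deltas = np.array(sorted(vals))
    curve = np.array([np.mean(vals[d]) for d in deltas])
    return deltas, curve


def composite_orientation_map(single_maps: np.ndarray, orientations):
    """Vector-summation composite map.

    z(x,y) = Σₖ Rₖ(x,y)·e^{i2θₖ}; preferred orientation is (arg z)/2 mod 180°
    and the tuning magnitude is |z| / Σₖ|Rₖ| (0 where the denominator is 0).
    Isotropic pixels (|z| ≈ 0) get preference 0 and are reported in the
    returned mask.  Returns (pref_map, magnitude_map, defined_mask).
    """
    maps = np.asarray(single_maps, dtype=float)
    th = np.deg2rad(np.asarray(orientations, dtype=float))
    if len(th) < 3:
        raise ValueError("need ≥ 3 orientations spanning [0, 180)")
    z = np.tensordot(np.exp(2j * th), maps, axes=(0, 0))
    denom = np.abs(maps).sum(axis=0)
    mag = np.zeros_like(denom)
    np.divide(np.abs(z), denom, out=mag, where=denom > 0)
    pref = np.mod(np.degrees(np.angle(z)) / 2.0, 180.0)
    tol = 1e-12 * max(denom.max(), 1.0)
    defined = np.abs(z) > tol
    pref = np.where(defined, pref, 0.0)
    mag = np.where(defined, mag, 0.0)
    return pref, mag, defined


def compare_maps(prefA: np.ndarray, prefB: np.ndarray,
                 roi_mask: np.ndarray | None = None) -> float:
    """Correlation of two preferred-orientation maps via sin(2θ) conversion."""
    a = np.sin(2.0 * np.deg2rad(np.asarray(prefA, dtype=float)))
    b = np.sin(2.0 * np.deg2rad(np.asarray(prefB, dtype=float)))
    if a.shape != b.shape:
        raise ValueError("maps must share one shape")
    if roi_mask is not None:
        a, b = a[roi_mask], b[roi_mask]
    a, b = a.ravel(), b.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant converted map: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ShuffleNull:
    values: np.ndarray
    min: float
    max: float
    mean: float


def shuffle_null(
    single_maps: np.ndarray,
    orientations,
    reference_pref_map: np.ndarray,
    n_shuffles: int = 1500,
    seed: int = 0,
    roi_mask: np.ndarray | None = None,
    _permutations=None,
) -> ShuffleNull:
    """Orientation-label shuffle null for the composite-map comparison.

    Each shuffle assigns every single-orientation map an orientation label
    drawn uniformly at random (with replacement), rebuilds the composite map
    and compares it to ``reference_pref_map``.  Label assignments that leave
    the sin(2θ)-converted composite exactly invariant — the original
    labeling and its reflection θ → 90° − θ — are excluded from the null,
    since the comparison statistic cannot distinguish them from the
    unshuffled data.  ``_permutations`` is a diagnostic hook accepting
    explicit label index assignments (e.g. the identity, or the exhaustive
    6! permutation set); the hook bypasses the exclusion rule.
    """
    if n_shuffles < 1 and _permutations is None:
        raise ValueError("n_shuffles must be >= 1")
    maps = np.asarray(single_maps, dtype=float)
    th = np.asarray(orientations, dtype=float)
    rng = np.random.default_rng(seed)
    if _permutations is None:
        n = len(th)
        invariant = [th, np.mod(90.0 - th, 180.0)]
        assignments = []
        while len(assignments) < n_shuffles:
            idx = rng.integers(0, n, size=n)
            if any(np.array_equal(th[idx], inv) for inv in invariant):
                continue
            assignments.append(idx)
    else:
        assignments = [np.asarray(p) for p in _permutations]
    rs = np.empty(len(assignments))
    for k, p in enumerate(assignments):
        pref, _, _ = composite_orientation_map(maps, th[p])
        rs[k] = compare_maps(pref, reference_pref_map, roi_mask)
    return ShuffleNull(rs, float(rs.min()), float(rs.max()), float(rs.mean()))


def shuffle_null_trials(
    trial_coefs: np.ndarray,
    trial_labels,
    reference_pref_map: np.ndarray,
    n_shuffles: int = 1500,
    seed: int = 0,
    roi_mask: np.ndarray | None = None,
    band=(0.8, 2.5),
    pixel_pitch_obj: float = 31.25,
) -> ShuffleNull:
    """Trial-level orientation-label shuffle null.

    Each shuffle permutes the orientation labels across the stimulus trials,
    rebuilds the per-orientation response maps (|mean of complex 4 Hz
    coefficients| per relabeled group), bandpasses them, forms the composite
    map and compares it to ``reference_pref_map``.  Because relabeled groups
    pool trials of mixed true orientations, the orientation-specific signal
    averages away while shared (non-orientation) structure survives — the
    appropriate null for asking whether a map reflects orientation columns
    rather than any reproducible spatial pattern.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    coefs = np.asarray(trial_coefs)
    labels = np.asarray(trial_labels, dtype=float)
    if len(labels) != coefs.shape[0]:
        raise ValueError("one label per trial map required")
    uniq = np.unique(labels)
    rng = np.random.default_rng(seed)
    rs = np.empty(n_shuffles)
    for k in range(n_shuffles):
        lab = rng.permutation(labels)
        single = np.stack(
            [np.abs(coefs[lab == o].mean(axis=0)) for o in uniq]
        )
        single = bandpass_spatial(single, band[0], band[1],
                                  pixel_pitch_obj=pixel_pitch_obj)
        pref, _, _ = composite_orientation_map(single, uniq)
        rs[k] = compare_maps(pref, reference_pref_map, roi_mask)
    return ShuffleNull(rs, float(rs.min()), float(rs.max()), float(rs.mean()))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def orientation_pipeline(
    trials: TrialSet,
    stim_freq: float = 4.0,
    band=(0.8, 2.5),
    threshold_frac: float = 1.0 / 3.0,
) -> OrientationMapSet:
    """Full orientation-mapping chain on a blank-containing TrialSet.

    blank subtraction → average across repeats (coherent, so stimulus-locked
    signal survives while heartbeat/shot noise cancels) → per-condition 4 Hz
    first-harmonic maps → RMS ROI → spatial bandpass → pairwise correlations
    and composite map.  Averaging the time courses before the (nonlinear)
    harmonic magnitude is essential at low single-trial SNR: magnitudes of
    noise-dominated single trials carry a Rician floor that trial averaging
    cannot remove.
    """
    corrected = subtract_blank(trials)
    conds = sorted(corrected.conditions)
    onset = corrected.onset_frame
    # complex 4 Hz coefficient per trial; linearity makes |mean coef| equal
    # to the harmonic amplitude of the trial-averaged video
    coefs = np.stack(
        [
            harmonic_coefficient(corrected.videos[i, onset:], stim_freq,
                                 corrected.frame_rate)
            for i in range(len(corrected.labels))
        ]
    )
    labels = np.asarray(corrected.labels, dtype=float)
    cond_means = np.stack(
        [np.abs(coefs[labels == c].mean(axis=0)) for c in conds]
    )
    roi = rms_roi(cond_means, threshold_frac)
    single = bandpass_spatial(
        cond_means, band[0], band[1], pixel_pitch_obj=trials.pixel_pitch_obj
    )
    deltas, curve = pairwise_map_correlation(single, conds, roi)
    pref, mag, _ = composite_orientation_map(single, conds)
    return OrientationMapSet(
        single_maps=single,
        orientations=np.asarray(conds, dtype=float),
        corr_deltas=deltas,
        corr_curve=curve,
        pref_map=pref,
        magnitude_map=mag,
        roi_mask=roi,
        trial_coefs=coefs,
        trial_labels=labels,
    )
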