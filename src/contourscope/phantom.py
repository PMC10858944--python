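"""Synthetic ground-truth scenes and trial videos.

Two phantom families make every downstream stage testable without real data:

* a fluorescent USAF-1951 three-bar resolution target (bright bars on a dark
  background), used to exercise the optical resolution chain; and
* a cortical sheet with a semi-periodic orientation-preference map
  (~1.2 cycles/mm columns with pinwheels, as in macaque V1), GCaMP responses
  entrained to a 4 Hz flashed-grating stimulus at a 20 Hz frame rate, a
  heartbeat-band (2–3 Hz) multiplicative artifact, and shot/read noise.

The orientation map is built by filtering complex Gaussian noise through an
annular spectral band centered on the column periodicity; the preferred
orientation is half the phase of the filtered field, which guarantees
pinwheel singularities and the right spatial power spectrum by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft
from scipy import ndimage

from .forward import add_sensor_noise

__all__ = [
    "CortexPhantom",
    "StimulusProtocol",
    "usaf_linewidth",
    "generate_usaf_target",
    "generate_orientation_map",
    "make_cortex_phantom",
    "gcamp_kernel",
    "stimulus_envelope",
    "generate_trial_video",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class CortexPhantom:
    """Ground-truth cortical sheet for the orientation-mapping pipeline."""

    pref_map: np.ndarray  # preferred orientation, degrees in [0, 180)
    tuning_amp: np.ndarray  # ΔF/F response amplitude per pixel
    baseline: np.ndarray  # resting fluorescence (arbitrary counts)
    vasculature: np.ndarray  # binary mask of dark vessels
    column_periodicity: float = 1.2  # cycles/mm
    pixel_pitch_obj: float = 31.25  # μm at the object plane

    def __post_init__(self):
        self.pref_map = np.asarray(self.pref_map, dtype=float)
        if self.pref_map.min() < 0 or self.pref_map.max() >= 180.0:
            raise ValueError("pref_map must lie in [0, 180)")
        if np.asarray(self.tuning_amp).min() < 0:
            raise ValueError("tuning_amp must be nonnegative")


@dataclass
class StimulusProtocol:
    """Flashed-grating trial structure.

    Six orientations, flashed 4×/trial at 4 Hz (100 ms ON / 150 ms OFF),
    imaged at 20 Hz, 10 repeats per condition plus blank fixation trials.
    A 200 ms pre-onset window precedes the stimulus in every trial.
    """

    orientations: tuple = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    stim_freq: float = 4.0  # Hz
    on_ms: float = 100.0
    off_ms: float = 150.0
    cycles_per_trial: int = 4
    frame_rate: float = 20.0  # Hz
    trials_per_condition: int = 10
    blank_trials: int = 10
    pre_onset_ms: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if abs(self.on_ms + self.off_ms - 1000.0 / self.stim_freq) > 1e-9:
            raise ValueError("on_ms + off_ms must equal one stimulus period")

    @property
    def n_pre_frames(self) -> int:
        return int(round(self.pre_onset_ms / 1000.0 * self.frame_rate))

    @property
    def n_stim_frames(self) -> int:
        return int(round(self.cycles_per_trial / self.stim_freq * self.frame_rate))

    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + self.n_stim_frames

    @property
    def onset_frame(self) -> int:
        return self.n_pre_frames


# --------------------------------------------------------------------------
# USAF-1951 target
# --------------------------------------------------------------------------


def usaf_linewidth(group: int, element: int) -> float:
    """Bar line width in μm of a USAF-1951 element.

    Resolution in line pairs/mm is 2^(group + (element−1)/6); the line width
    is half the line-pair period: 500 / 2^(group + (element−1)/6) μm.
    """
    if not 1 <= element <= 6:
        raise ValueError("element must be in [1, 6]")
    return 500.0 / 2.0 ** (group + (element - 1) / 6.0)


def generate_usaf_target(
    pixel_pitch_obj: float,
    groups=range(2, 6),
    elements=range(1, 7),
) -> np.ndarray:
    """Synthetic fluorescent USAF-1951 target: three-bar element blocks.

    For each (group, element) draws the standard geometry — three bars of
    width w and length 5w separated by w, in both horizontal and vertical
    orientation — as bright bars on a dark background.  Elements whose bar
    width falls below 2 px at the given pitch are omitted with a warning.
    The layout packs elements on a grid; it is geometrically faithful per
    element, not a facsimile of the printed chart arrangement.
    """
    blocks = []
    for g in groups:
        for e in elements:
            w_um = usaf_linewidth(g, e)
            w = w_um / pixel_pitch_obj
            if w < 2.0:
                warnings.warn(
                    f"group {g} element {e}: bar width {w_um:.2f} μm "
                    f"unresolvable at {pixel_pitch_obj} μm pitch; omitted"
                )
                continue
            wpx = int(round(w))
            L = 5 * wpx
            # horizontal bars: 3 bars stacked with gaps of one bar width
            horiz = np.zeros((5 * wpx, L), dtype=bool)
            for k in range(3):
                horiz[2 * k * wpx : (2 * k + 1) * wpx, :] = True
            vert = horiz.T
            pad = 2 * wpx
            block = np.zeros(
                (max(horiz.shape[0], vert.shape[0]) + pad,
                 horiz.shape[1] + vert.shape[1] + 3 * pad),
                dtype=bool,
            )
            block[: horiz.shape[0], pad : pad + horiz.shape[1]] = horiz
            block[: vert.shape[0], 2 * pad + horiz.shape[1] :
                  2 * pad + horiz.shape[1] + vert.shape[1]] = vert
            blocks.append(block)
    if not blocks:
        raise ValueError("no resolvable elements at this pixel pitch")

    # pack blocks into rows of bounded width
    max_w = max(b.shape[1] for b in blocks)
    row_limit = max(4 * max_w, 256)
    rows, cur, cur_w = [], [], 0
    for b in blocks:
        if cur and cur_w + b.shape[1] > row_limit:
            rows.append(cur)
            cur, cur_w = [], 0
        cur.append(b)
        cur_w += b.shape[1]
    if cur:
        rows.append(cur)
    row_imgs = []
    for r in rows:
        h = max(b.shape[0] for b in r)
        row_imgs.append(
            np.hstack([np.pad(b, ((0, h - b.shape[0]), (0, 0))) for b in r])
        )
    W = max(im.shape[1] for im in row_imgs)
    canvas = np.vstack([np.pad(im, ((0, 0), (0, W - im.shape[1]))) for im in row_imgs])
    return np.pad(canvas, 8)


# --------------------------------------------------------------------------
# orientation-column cortex
# --------------------------------------------------------------------------


def generate_orientation_map(
    shape,
    pixel_pitch_obj: float,
    periodicity: float = 1.2,
    bandwidth: float = 0.3,
    seed: int = 0,
    return_complex: bool = False,
):
    """Semi-periodic orientation-preference map with pinwheels.

    Complex white Gaussian noise is filtered by a Gaussian annulus centered
    at ``periodicity`` (cycles/mm, width ``bandwidth`` cycles/mm) in the 2D
    spectral plane; the preferred orientation is arg(z)/2 mapped to [0, 180)
    degrees.  Phase singularities of z are the orientation pinwheels.
    """
    ny, nx = (int(shape), int(shape)) if np.isscalar(shape) else map(int, shape)
    pitch_mm = pixel_pitch_obj * 1e-3
    nyq = 0.5 / pitch_mm
    if periodicity >= nyq:
        raise ValueError(f"periodicity {periodicity} ≥ Nyquist {nyq:.2f} cycles/mm")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((ny, nx)) + 1j * rng.standard_normal((ny, nx))
    fy = spfft.fftfreq(ny, d=pitch_mm)
    fx = spfft.fftfreq(nx, d=pitch_mm)
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    ring = np.exp(-0.5 * ((fr - periodicity) / bandwidth) ** 2)
    z = spfft.ifft2(spfft.fft2(z) * ring)
    pref = np.mod(np.degrees(np.angle(z)) / 2.0, 180.0)
    if return_complex:
        return pref, z
    return pref


def make_cortex_phantom(
    shape=(256, 256),
    pixel_pitch_obj: float = 31.25,
    periodicity: float = 1.2,
    dff_amp: float = 0.03,
    baseline_level: float = 10.0,
    vessel_fraction: float = 0.03,
    seed: int = 0,
) -> CortexPhantom:
    """Assemble a full cortical phantom.

    tuning_amp follows the magnitude of the column field, so tuning strength
    dips at pinwheel centers as in real maps, normalized so its mean equals
    ``dff_amp`` (the characteristic peak ΔF/F of a tuned pixel); the baseline
    is a smooth random fluorescence field with dark vasculature lines carved
    out.
    """
    pref, z = generate_orientation_map(
        shape, pixel_pitch_obj, periodicity, seed=seed, return_complex=True
    )
    mag = np.abs(z)
    tuning = dff_amp * mag / mag.mean()
    rng = np.random.default_rng(seed + 1)
    base = ndimage.gaussian_filter(rng.standard_normal(pref.shape), 12.0)
    base = baseline_level * (1.0 + 0.15 * base / max(np.abs(base).max(), 1e-12))
    vessels = ndimage.gaussian_filter(rng.standard_normal(pref.shape), 3.0)
    vmask = vessels > np.quantile(vessels, 1.0 - vessel_fraction)
    base = np.where(vmask, 0.55 * base, base)
    return CortexPhantom(
        pref_map=pref,
        tuning_amp=tuning,
        baseline=base,
        vasculature=vmask,
        column_periodicity=periodicity,
        pixel_pitch_obj=pixel_pitch_obj,
    )


# --------------------------------------------------------------------------
# GCaMP dynamics and trial videos
# --------------------------------------------------------------------------


def gcamp_kernel(dt_s: float, tau_rise: float = 0.05, tau_decay: float = 0.4):
    """GCaMP6f-like impulse response (1 − e^{−t/τr})·e^{−t/τd}, peak 1."""
    t = np.arange(0.0, 5.0 * tau_decay, dt_s)
    k = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    return k / k.max()


def stimulus_envelope(protocol: StimulusProtocol, dt_ms: float = 1.0) -> np.ndarray:
    """Per-frame response envelope: 4 Hz ON/OFF train ⊛ GCaMP kernel.

    Computed on a fine (1 ms) time base then sampled at frame times;
    normalized to peak 1 so tuning_amp is the peak ΔF/F.
    """
    dt = dt_ms * 1e-3
    n_fine = int(round(protocol.n_frames / protocol.frame_rate / dt))
    t = np.arange(n_fine) * dt
    onset = protocol.pre_onset_ms * 1e-3
    period = 1.0 / protocol.stim_freq
    on = np.zeros(n_fine)
    for c in range(protocol.cycles_per_trial):
        t0 = onset + c * period
        on[(t >= t0) & (t < t0 + protocol.on_ms * 1e-3)] = 1.0
    env = np.convolve(on, gcamp_kernel(dt))[:n_fine]
    env /= max(env.max(), 1e-12)
    frame_idx = np.round(np.arange(protocol.n_frames) / protocol.frame_rate / dt).astype(int)
    return env[np.clip(frame_idx, 0, n_fine - 1)]


def generate_trial_video(
    phantom: CortexPhantom,
    protocol: StimulusProtocol,
    condition,
    noise: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """One trial of object-plane fluorescence, (frames, y, x), float.

    ``condition`` is a stimulus orientation in degrees, or ``"blank"``.  The
    per-pixel ΔF/F response is ``tuning_amp · (1 + cos 2(θ − condition))/2``
    times the stimulus envelope; a global multiplicative heartbeat sinusoid
    (2–3 Hz) is applied on top of the baseline.  ``noise`` optionally applies
    shot/read noise and 8-bit quantization via :func:`add_sensor_noise` with
    keys heartbeat_freq, heartbeat_amp, heartbeat_locked, photon_scale,
    read_sigma; heartbeat keys alone keep the video float-valued.
    """
    noise = dict(noise or {})
    if condition == "blank":
        resp_amp = np.zeros_like(phantom.pref_map)
    else:
        cond = float(condition)
        if cond not in protocol.orientations:
            raise ValueError(f"condition {cond} not in protocol orientations")
        dtheta = np.deg2rad(phantom.pref_map - cond)
        resp_amp = phantom.tuning_amp * (1.0 + np.cos(2.0 * dtheta)) / 2.0

    env = stimulus_envelope(protocol)
    dff = resp_amp[None] * env[:, None, None]
    video = phantom.baseline[None] * (1.0 + dff)

    hb_amp = noise.get("heartbeat_amp", 0.0)
    if hb_amp > 0:
        rng = np.random.default_rng(seed)
        f_hb = noise.get("heartbeat_freq", rng.uniform(2.0, 3.0))
        # hardware heartbeat gating: trial start phase-locked to the artifact
        phase = 0.0 if noise.get("heartbeat_locked", False) else rng.uniform(0, 2 * np.pi)
        t = np.arange(protocol.n_frames) / protocol.frame_rate
        video = video * (1.0 + hb_amp * np.sin(2 * np.pi * f_hb * t + phase))[:, None, None]

    if "photon_scale" in noise:
        video = add_sensor_noise(
            video,
            photon_scale=noise["photon_scale"],
            read_sigma=noise.get("read_sigma", 0.0),
            seed=seed + 1,
            full_scale=noise.get("full_scale"),
        ).astype(float)
    return video
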