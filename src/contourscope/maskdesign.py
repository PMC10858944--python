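"""Contour phase-mask design.

The imaging system replaces the objective lens with a thin phase mask whose
point spread function (PSF) is a dense set of thin curved lines ("contours").
Such a PSF multiplexes every scene point across the sensor while retaining
contrast at all orientations of spatial frequency, which is what makes the
multiplexed measurements invertible.  The design pipeline is:

1. draw a band-limited random field (gradient-lattice Perlin noise),
2. extract its level-set geometry with Canny edge detection and thicken the
   edges to the fabrication linewidth (6 μm), giving the target PSF pattern,
3. recover a phase profile whose far-field intensity matches that pattern via
   iterative transform phase retrieval under scalar (angular-spectrum)
   diffraction, and
4. convert phase to a photoresist height map quantized to the two-photon
   lithography step (200 nm steps, 1 μm maximum height).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft
from scipy import ndimage

__all__ = [
    "NoiseField",
    "ContourPattern",
    "PhaseMask",
    "MaskDesignResult",
    "generate_perlin_noise",
    "canny_edges",
    "contour_from_noise",
    "propagate_angular_spectrum",
    "design_phase_mask",
    "phase_to_height",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class NoiseField:
    """Band-limited random field used as the seed of the contour pattern.

    values are unitless in [-1, 1]; ``feature_scale`` is the gradient-lattice
    spacing in μm and sets the characteristic size of the blobs whose level
    sets become the PSF contours.
    """

    values: np.ndarray
    pixel_pitch: float  # μm
    feature_scale: float  # μm
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1 - 1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("NoiseField values must lie in [-1, 1]")


@dataclass
class ContourPattern:
    """Binary target PSF pattern: thin closed contours at fixed stroke width."""

    mask: np.ndarray
    pixel_pitch: float = 1.0  # μm, fabrication pixel
    pattern_width: float = 6.0  # μm, stroke width of the contours

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def stroke_width_px(self) -> int:
        return int(round(self.pattern_width / self.pixel_pitch))

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


@dataclass
class PhaseMask:
    """Quantized photoresist height map realizing the contour PSF.

    Heights are in nm, constrained to integer multiples of ``height_step``
    within [0, max_height] (six fabrication levels at the defaults).
    """

    heights: np.ndarray  # nm
    pixel_pitch: float = 1.0  # μm
    height_step: float = 200.0  # nm
    max_height: float = 1000.0  # nm
    extent: tuple = (2.3, 2.3)  # mm
    design_wavelength: float = 530.0  # nm
    mask_to_sensor_distance: float = 3.5  # mm
    refractive_index_contrast: float = 0.55  # Δn, resist vs air

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        q = self.heights / self.height_step
        if not np.allclose(q, np.round(q), atol=1e-9):
            raise ValueError("heights must be integer multiples of height_step")
        if self.heights.min() < -1e-9 or self.heights.max() > self.max_height + 1e-9:
            raise ValueError("heights must lie in [0, max_height]")

    def phase(self, wavelength: float | None = None) -> np.ndarray:
        """Phase delay (radians) imparted at ``wavelength`` (nm)."""
        lam = self.design_wavelength if wavelength is None else wavelength
        return 2.0 * np.pi * self.refractive_index_contrast * self.heights / lam


@dataclass
class MaskDesignResult:
    """Phase-retrieval output: the quantized mask plus convergence diagnostics."""

    mask: PhaseMask
    phase: np.ndarray  # unquantized retrieved phase, radians in [0, 2π)
    fidelity_trace: list = field(default_factory=list)
    final_fidelity: float = np.nan
    converged: bool = True


# --------------------------------------------------------------------------
# Perlin noise
# --------------------------------------------------------------------------


def _fade(t):
    # quintic smoothstep: zero first and second derivatives at lattice nodes
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def generate_perlin_noise(
    shape,
    pixel_pitch: float,
    feature_scale: float,
    seed: int,
    _gradients: np.ndarray | None = None,
) -> NoiseField:
    """Classic gradient-lattice Perlin noise.

    Unit gradient vectors are drawn on a lattice with spacing
    ``feature_scale`` and blended with the quintic fade, then rescaled by √2
    so the output occupies (most of) [-1, 1].

    ``_gradients`` is a diagnostic hook: an explicit ``(ny, nx, 2)`` gradient
    array overriding the seeded draw (an all-zero array yields an identically
    zero field).
    """
    ny, nx = (int(shape), int(shape)) if np.isscalar(shape) else map(int, shape)
    if ny <= 0 or nx <= 0:
        raise ValueError("shape must be positive")
    if feature_scale <= 0 or pixel_pitch <= 0:
        raise ValueError("pixel_pitch and feature_scale must be positive")
    if feature_scale < 2 * pixel_pitch:
        raise ValueError("feature_scale must be at least 2× pixel_pitch")

    cell = feature_scale / pixel_pitch  # lattice spacing in pixels
    gy = int(np.ceil(ny / cell)) + 1
    gx = int(np.ceil(nx / cell)) + 1
    if _gradients is not None:
        grads = np.asarray(_gradients, dtype=float)
        if grads.shape[:2] < (gy, gx) or grads.shape[2] != 2:
            raise ValueError(f"_gradients must be at least ({gy}, {gx}, 2)")
    else:
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(gy, gx))
        grads = np.stack([np.cos(theta), np.sin(theta)], axis=-1)

    yy, xx = np.meshgrid(np.arange(ny) / cell, np.arange(nx) / cell, indexing="ij")
    iy = np.floor(yy).astype(int)
    ix = np.floor(xx).astype(int)
    fy = yy - iy
    fx = xx - ix

    def corner(dy, dx):
        g = grads[iy + dy, ix + dx]
        return g[..., 1] * (fx - dx) + g[..., 0] * (fy - dy)

    uy = _fade(fy)
    ux = _fade(fx)
    top = corner(0, 0) * (1 - ux) + corner(0, 1) * ux
    bot = corner(1, 0) * (1 - ux) + corner(1, 1) * ux
    vals = np.clip(np.sqrt(2.0) * (top * (1 - uy) + bot * uy), -1.0, 1.0)
    return NoiseField(vals, pixel_pitch, feature_scale, seed)


# --------------------------------------------------------------------------
# Canny edges → contour pattern
# --------------------------------------------------------------------------


def canny_edges(
    image: np.ndarray,
    sigma: float = 1.0,
    low_frac: float = 0.1,
    high_frac: float = 0.3,
) -> np.ndarray:
    """Canny edge detector with thresholds as fractions of the gradient max.

    Gaussian smoothing → Sobel gradients → non-maximum suppression with the
    gradient direction quantized to 4 bins → hysteresis: pixels above
    ``high_frac × max(|∇|)`` seed edges, pixels above ``low_frac × max(|∇|)``
    extend them by 8-connectivity.
    """
    if not 0 < low_frac < high_frac <= 1:
        raise ValueError("require 0 < low_frac < high_frac <= 1")
    img = ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma)
    gy = ndimage.sobel(img, axis=0)
    gx = ndimage.sobel(img, axis=1)
    mag = np.hypot(gy, gx)
    gmax = mag.max()
    if gmax == 0:
        return np.zeros(img.shape, dtype=bool)

    # quantize gradient direction to 0°, 45°, 90°, 135°
    angle = np.mod(np.rad2deg(np.arctan2(gy, gx)), 180.0)
    dbin = np.zeros(img.shape, dtype=int)
    dbin[(angle >= 22.5) & (angle < 67.5)] = 1
    dbin[(angle >= 67.5) & (angle < 112.5)] = 2
    dbin[(angle >= 112.5) & (angle < 157.5)] = 3

    pad = np.pad(mag, 1, mode="constant")
    c = pad[1:-1, 1:-1]
    neighbors = {
        0: (pad[1:-1, 2:], pad[1:-1, :-2]),  # horizontal gradient → E/W
        1: (pad[2:, 2:], pad[:-2, :-2]),  # 45°
        2: (pad[2:, 1:-1], pad[:-2, 1:-1]),  # vertical gradient → N/S
        3: (pad[2:, :-2], pad[:-2, 2:]),  # 135°
    }
    nms = np.zeros(img.shape, dtype=bool)
    for b, (n1, n2) in neighbors.items():
        sel = dbin == b
        nms |= sel & (c >= n1) & (c >= n2)
    thin = np.where(nms, mag, 0.0)

    strong = thin >= high_frac * gmax
    weak = thin >= low_frac * gmax
    labels, n = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros(img.shape, dtype=bool)
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return keep[labels]


def _disk_footprint(width_px: int) -> np.ndarray:
    """Circular footprint with diameter ``width_px`` (even widths supported)."""
    c = (width_px - 1) / 2.0
    yy, xx = np.mgrid[0:width_px, 0:width_px]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (width_px / 2.0) ** 2 * (1 + 1e-9)


def contour_from_noise(
    field: NoiseField,
    low_frac: float = 0.1,
    high_frac: float = 0.3,
    pattern_width: float = 6.0,
    sigma: float = 1.0,
) -> ContourPattern:
    """Canny edges of the noise field, dilated to the fabrication linewidth."""
    edges = canny_edges(field.values, sigma=sigma, low_frac=low_frac, high_frac=high_frac)
    if not edges.any():
        warnings.warn("constant or featureless field: returning an empty pattern")
        return ContourPattern(edges, field.pixel_pitch, pattern_width)
    width_px = int(round(pattern_width / field.pixel_pitch))
    if width_px > 1:
        edges = ndimage.binary_dilation(edges, structure=_disk_footprint(width_px))
    return ContourPattern(edges, field.pixel_pitch, pattern_width)


# --------------------------------------------------------------------------
# scalar diffraction
# --------------------------------------------------------------------------


def propagate_angular_spectrum(
    field: np.ndarray,
    distance: float,
    wavelength: float,
    pixel_pitch: float,
) -> np.ndarray:
    """Angular-spectrum propagation of a complex scalar field.

    distance in mm, wavelength in nm, pixel_pitch in μm.  Evanescent
    components (kx² + ky² > k²) are zeroed.  A warning is emitted when the
    propagation kernel is not adequately sampled (phase step between adjacent
    frequency samples exceeding π at the band edge).
    """
    field = np.asarray(field, dtype=complex)
    if distance == 0:
        return field.copy()
    lam_um = wavelength * 1e-3
    z_um = distance * 1e3
    ny, nx = field.shape
    fy = spfft.fftfreq(ny, d=pixel_pitch)
    fx = spfft.fftfreq(nx, d=pixel_pitch)
    fy2, fx2 = np.meshgrid(fy**2, fx**2, indexing="ij")
    arg = 1.0 / lam_um**2 - fy2 - fx2
    prop = arg > 0

    # band-limit check (Matsushima-style): the kernel phase must vary by < π
    # between adjacent frequency samples at the aperture band edge.
    fmax = min(0.5 / pixel_pitch, 1.0 / lam_um)
    df = max(1.0 / (ny * pixel_pitch), 1.0 / (nx * pixel_pitch))
    denom = np.sqrt(max(1.0 / lam_um**2 - fmax**2, 1e-300))
    if 2.0 * np.pi * abs(z_um) * fmax * df / denom > np.pi:
        warnings.warn(
            "angular-spectrum kernel under-sampled for this distance/pitch; "
            "expect wrap-around artifacts"
        )

    kz = np.zeros_like(arg)
    kz[prop] = 2.0 * np.pi * np.sqrt(arg[prop])
    H = np.where(prop, np.exp(1j * kz * z_um), 0.0)
    return spfft.ifft2(spfft.fft2(field) * H)


# --------------------------------------------------------------------------
# phase retrieval
# --------------------------------------------------------------------------


def phase_to_height(
    phase: np.ndarray,
    wavelength: float,
    delta_n: float = 0.55,
    height_step: float = 200.0,
    max_height: float = 1000.0,
) -> np.ndarray:
    """Convert a phase profile (radians) to a quantized resist height map (nm).

    h = φ·λ / (2π·Δn) with φ wrapped to [0, 2π), rounded to the fabrication
    step and clipped to the maximum height.
    """
    phi = np.mod(phase, 2.0 * np.pi)
    h = phi * wavelength / (2.0 * np.pi * delta_n)
    return np.clip(np.round(h / height_step) * height_step, 0.0, max_height)


def _ncc(a, b):
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(np.sum(a * b) / denom) if denom > 0 else 0.0


def design_phase_mask(
    target: ContourPattern,
    distance: float = 3.5,
    wavelength: float = 530.0,
    n_iter: int = 50,
    seed: int = 0,
    delta_n: float = 0.55,
    height_step: float = 200.0,
    max_height: float = 1000.0,
    fidelity_floor: float = 0.3,
) -> MaskDesignResult:
    """Design a quantized phase mask whose PSF matches the contour target.

    Error-reduction (Gerchberg–Saxton-type) phase retrieval between the mask
    plane (unit amplitude, free phase) and the sensor plane (amplitude clamped
    to √target, free phase), propagating with the angular spectrum method.
    Fidelity is the normalized cross-correlation between the propagated
    intensity and the target pattern; a final fidelity below
    ``fidelity_floor`` sets ``converged=False`` on the result (never raises).
    """
    if target.is_empty:
        raise ValueError("target pattern is empty")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    t = target.mask.astype(float)
    amp_t = np.sqrt(t)
    # match total power to the unit-amplitude mask plane
    amp_t *= np.sqrt(t.size / np.sum(amp_t**2))

    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=t.shape)
    trace = []
    for _ in range(n_iter):
        m = np.exp(1j * phi)
        s = propagate_angular_spectrum(m, distance, wavelength, target.pixel_pitch)
        trace.append(_ncc(np.abs(s) ** 2, t))
        s = amp_t * np.exp(1j * np.angle(s))
        back = propagate_angular_spectrum(s, -distance, wavelength, target.pixel_pitch)
        phi = np.angle(back)

    s = propagate_angular_spectrum(np.exp(1j * phi), distance, wavelength, target.pixel_pitch)
    final = _ncc(np.abs(s) ** 2, t)
    trace.append(final)

    phi = np.mod(phi, 2.0 * np.pi)
    heights = phase_to_height(phi, wavelength, delta_n, height_step, max_height)
    mask = PhaseMask(
        heights,
        pixel_pitch=target.pixel_pitch,
        height_step=height_step,
        max_height=max_height,
        extent=(
            target.mask.shape[0] * target.pixel_pitch * 1e-3,
            target.mask.shape[1] * target.pixel_pitch * 1e-3,
        ),
        design_wavelength=wavelength,
        mask_to_sensor_distance=distance,
        refractive_index_contrast=delta_n,
    )
    return MaskDesignResult(
        mask=mask,
        phase=phi,
        fidelity_trace=trace,
        final_fidelity=final,
        converged=final >= fidelity_floor,
    )
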