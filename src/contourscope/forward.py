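"""Image formation for the lensless microscope.

A scene at depth ``z`` is multiplexed onto the sensor by convolution with the
contour PSF.  Because the mask sits close to the sensor, the PSF drifts with
lateral field position, so the calibrated model is a grid of local PSFs (9×9
at 1 mm spacing over an 8 mm × 8 mm field in the instrument; any grid here).
The shift-variant operator Φ blends local convolutions with bilinear
interpolation windows that form an exact partition of unity:

    Φ i = Σ_k (w_k ⊙ i) * p_k ,   Σ_k w_k = 1 everywhere.

The operator is exact at the grid nodes and continuous in between; with all
PSFs equal it degenerates to ordinary shift-invariant convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fft import conv_same, corr_same, kernel_spectrum, padded_shape
from .maskdesign import PhaseMask, propagate_angular_spectrum

__all__ = [
    "PSFGrid",
    "MeasurementStack",
    "ShiftVariantOperator",
    "simulate_psf",
    "simulate_psf_grid",
    "psf_shift_for_offset",
    "forward_shift_invariant",
    "forward_shift_variant",
    "interpolation_windows",
    "add_sensor_noise",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class PSFGrid:
    """Calibrated or simulated PSFs indexed by depth and lateral grid position.

    ``psfs`` has shape (n_depths, grid_rows, grid_cols, py, px); every PSF is
    nonnegative and normalized to unit sum.  ``depths`` are strictly
    increasing (mm); ``grid_coords`` are the lateral node positions (mm),
    uniformly spaced (1 mm in the instrument calibration).
    """

    psfs: np.ndarray
    depths: np.ndarray
    grid_coords_y: np.ndarray = None  # mm
    grid_coords_x: np.ndarray = None  # mm
    pixel_pitch: float = 2.4  # μm, sensor pitch

    def __post_init__(self):
        self.psfs = np.asarray(self.psfs, dtype=float)
        if self.psfs.ndim != 5:
            raise ValueError("psfs must be 5D: (depth, grid_row, grid_col, y, x)")
        self.depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        if len(self.depths) != self.psfs.shape[0]:
            raise ValueError("depths length must match psfs first axis")
        if len(self.depths) > 1 and not np.all(np.diff(self.depths) > 0):
            raise ValueError("depths must be strictly increasing")
        if self.psfs.min() < 0:
            raise ValueError("PSFs must be nonnegative")
        sums = self.psfs.sum(axis=(-2, -1))
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each PSF must sum to 1 (±1e-6)")
        nr, nc = self.psfs.shape[1:3]
        if self.grid_coords_y is None:
            self.grid_coords_y = np.arange(nr, dtype=float)
        if self.grid_coords_x is None:
            self.grid_coords_x = np.arange(nc, dtype=float)
        self.grid_coords_y = np.asarray(self.grid_coords_y, dtype=float)
        self.grid_coords_x = np.asarray(self.grid_coords_x, dtype=float)
        for c in (self.grid_coords_y, self.grid_coords_x):
            if len(c) > 2 and not np.allclose(np.diff(c), np.diff(c)[0]):
                raise ValueError("grid spacing must be uniform")

    @property
    def grid_shape(self):
        return self.psfs.shape[1:3]

    def depth_index(self, depth: float) -> int:
        i = int(np.argmin(np.abs(self.depths - depth)))
        if abs(self.depths[i] - depth) > 1e-9:
            raise KeyError(f"depth {depth} mm not in grid (nearest {self.depths[i]})")
        return i

    def at_depth(self, depth: float) -> np.ndarray:
        """PSFs at ``depth``, linearly interpolated between calibrated planes."""
        d = float(depth)
        if d <= self.depths[0]:
            return self.psfs[0]
        if d >= self.depths[-1]:
            return self.psfs[-1]
        j = int(np.searchsorted(self.depths, d))
        d0, d1 = self.depths[j - 1], self.depths[j]
        t = (d - d0) / (d1 - d0)
        return (1 - t) * self.psfs[j - 1] + t * self.psfs[j]


@dataclass
class MeasurementStack:
    """Raw sensor frames: (time, y, x) integer counts at a fixed bit depth."""

    frames: np.ndarray
    bit_depth: int = 8
    exposure: float = 10.0  # ms
    frame_rate: float = 20.0  # Hz
    pixel_pitch: float = 2.4  # μm

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        top = 2**self.bit_depth - 1
        if self.frames.min() < 0 or self.frames.max() > top:
            raise ValueError(f"frame values must lie in [0, {top}]")


# --------------------------------------------------------------------------
# PSF simulation
# --------------------------------------------------------------------------


def psf_shift_for_offset(offset_mm, depth_mm: float, mask_to_sensor_mm: float):
    """Lateral PSF displacement (mm on the sensor) for a source offset.

    Shadow geometry (similar triangles): a source shifted by δ displaces the
    projected pattern by −δ · (mask-to-sensor distance / working distance).
    """
    off = np.asarray(offset_mm, dtype=float)
    return -off * mask_to_sensor_mm / depth_mm


def simulate_psf(
    mask: PhaseMask,
    depth: float,
    wavelength: float | None = None,
    source_offset=(0.0, 0.0),
) -> np.ndarray:
    """Incoherent intensity PSF of a point source seen through the mask.

    A spherical wave from a point at lateral ``source_offset`` (mm) and axial
    distance ``depth`` (mm) illuminates the mask, picks up the mask phase and
    propagates ``mask_to_sensor_distance`` to the sensor; the intensity
    |·|² is normalized to unit sum.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    lam = mask.design_wavelength if wavelength is None else wavelength
    ny, nx = mask.heights.shape
    pitch = mask.pixel_pitch  # μm
    y = (np.arange(ny) - ny / 2.0) * pitch
    x = (np.arange(nx) - nx / 2.0) * pitch
    yy, xx = np.meshgrid(y, x, indexing="ij")
    oy, ox = (np.asarray(source_offset, dtype=float) * 1e3)  # mm → μm
    z_um = depth * 1e3
    lam_um = lam * 1e-3
    r = np.sqrt((yy - oy) ** 2 + (xx - ox) ** 2 + z_um**2)
    src = np.exp(1j * 2.0 * np.pi * r / lam_um) / r
    u = src * np.exp(1j * mask.phase(lam))
    u = propagate_angular_spectrum(u, mask.mask_to_sensor_distance, lam, pitch)
    psf = np.abs(u) ** 2
    return psf / psf.sum()


def simulate_psf_grid(
    mask: PhaseMask,
    depths,
    grid_shape=(3, 3),
    grid_extent_mm: float = 0.0,
    wavelength: float | None = None,
    crop: int | None = None,
) -> PSFGrid:
    """Simulate a PSFGrid over depths and a lateral grid of source offsets.

    ``grid_extent_mm`` is the half-width of the lateral grid; 0 gives
    replicated central PSFs (a shift-invariant grid).  ``crop`` optionally
    center-crops each PSF to ``crop × crop`` pixels (renormalized).
    """
    depths = np.atleast_1d(np.asarray(depths, dtype=float))
    nr, nc = grid_shape
    oy = np.linspace(-grid_extent_mm, grid_extent_mm, nr) if nr > 1 else [0.0]
    ox = np.linspace(-grid_extent_mm, grid_extent_mm, nc) if nc > 1 else [0.0]
    out = []
    for d in depths:
        plane = []
        for yo in oy:
            row = []
            for xo in ox:
                p = simulate_psf(mask, d, wavelength, source_offset=(yo, xo))
                if crop is not None:
                    cy, cx = p.shape[0] // 2, p.shape[1] // 2
                    h = crop // 2
                    p = p[cy - h : cy - h + crop, cx - h : cx - h + crop]
                    p = p / p.sum()
                row.append(p)
            plane.append(row)
        out.append(plane)
    return PSFGrid(
        np.asarray(out),
        depths,
        grid_coords_y=np.asarray(oy, dtype=float),
        grid_coords_x=np.asarray(ox, dtype=float),
        pixel_pitch=mask.pixel_pitch,
    )


# --------------------------------------------------------------------------
# forward operators
# --------------------------------------------------------------------------


def forward_shift_invariant(scene: np.ndarray, psf: np.ndarray,
                            boundary: str = "pad") -> np.ndarray:
    """Convolution of scene with PSF, cropped to the scene size.

    ``boundary="pad"`` (default) zero-pads to avoid wraparound, giving the
    "same"-sized linear convolution; ``"periodic"`` convolves circularly on
    the scene grid (the convention under which the Wiener filter is the exact
    closed-form inverse).
    """
    scene = np.asarray(scene, dtype=float)
    psf = np.asarray(psf, dtype=float)
    if scene.min() < 0 or psf.min() < 0:
        raise ValueError("scene and psf must be nonnegative")
    if boundary == "pad":
        pshape = padded_shape(scene.shape[-2:], psf.shape)
    elif boundary == "periodic":
        pshape = scene.shape[-2:]
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    kspec = kernel_spectrum(psf, pshape)
    return conv_same(scene, kspec, pshape)


def interpolation_windows(shape, grid_shape) -> np.ndarray:
    """Bilinear blending windows for a node grid spanning the array extent.

    Returns (grid_rows·grid_cols, H, W) hat-function windows whose sum is
    exactly 1 at every pixel (partition of unity).  Nodes sit at
    ``linspace(0, N-1, n)`` along each axis.
    """
    H, W = shape
    nr, nc = grid_shape

    def hats(n, nodes):
        pos = np.arange(n, dtype=float)
        if len(nodes) == 1:
            return np.ones((1, n))
        out = np.zeros((len(nodes), n))
        for k, c in enumerate(nodes):
            left = nodes[k - 1] if k > 0 else c
            right = nodes[k + 1] if k < len(nodes) - 1 else c
            w = np.zeros(n)
            if k > 0:
                sel = (pos >= left) & (pos <= c)
                w[sel] = (pos[sel] - left) / (c - left)
            if k < len(nodes) - 1:
                sel = (pos >= c) & (pos <= right)
                w[sel] = 1.0 - (pos[sel] - c) / (right - c)
            if k == 0:
                w[pos <= c] = 1.0
            if k == len(nodes) - 1:
                w[pos >= c] = 1.0
            out[k] = w
        return out

    wy = hats(H, np.linspace(0, H - 1, nr))
    wx = hats(W, np.linspace(0, W - 1, nc))
    return (wy[:, None, :, None] * wx[None, :, None, :]).reshape(nr * nc, H, W)


class ShiftVariantOperator:
    """Precomputed Φ for a fixed scene shape, grid, and depth.

    Holds the interpolation windows and kernel spectra so repeated
    applications (FISTA iterations, video frames) cost only FFTs.
    """

    def __init__(self, grid: PSFGrid, scene_shape, depth: float, dtype=np.float64,
                 boundary: str = "pad"):
        psfs = grid.at_depth(depth)
        nr, nc, py, px = psfs.shape
        self.scene_shape = tuple(scene_shape)
        self.windows = interpolation_windows(scene_shape, (nr, nc)).astype(dtype)
        if boundary == "pad":
            self.pshape = padded_shape(self.scene_shape, (py, px))
        elif boundary == "periodic":
            self.pshape = self.scene_shape
        else:
            raise ValueError(f"unknown boundary {boundary!r}")
        self.kspecs = np.stack(
            [
                kernel_spectrum(p.astype(dtype), self.pshape, dtype=dtype)
                for p in psfs.reshape(-1, py, px)
            ]
        )
        self.dtype = dtype

    def apply(self, scene: np.ndarray) -> np.ndarray:
        """Φ scene (scene may carry leading batch axes)."""
        import scipy.fft as spfft

        scene = np.asarray(scene, dtype=self.dtype)
        acc = None
        for w, k in zip(self.windows, self.kspecs):
            buf = np.zeros(scene.shape[:-2] + self.pshape, dtype=self.dtype)
            buf[..., : self.scene_shape[0], : self.scene_shape[1]] = w * scene
            term = spfft.rfft2(buf) * k
            acc = term if acc is None else acc + term
        full = spfft.irfft2(acc, s=self.pshape)
        return full[..., : self.scene_shape[0], : self.scene_shape[1]]

    def adjoint(self, meas: np.ndarray) -> np.ndarray:
        """Φᵀ meas."""
        import scipy.fft as spfft

        meas = np.asarray(meas, dtype=self.dtype)
        buf = np.zeros(meas.shape[:-2] + self.pshape, dtype=self.dtype)
        buf[..., : self.scene_shape[0], : self.scene_shape[1]] = meas
        spec = spfft.rfft2(buf)
        out = np.zeros(meas.shape[:-2] + self.scene_shape, dtype=self.dtype)
        for w, k in zip(self.windows, self.kspecs):
            full = spfft.irfft2(spec * np.conj(k), s=self.pshape)
            out += w * full[..., : self.scene_shape[0], : self.scene_shape[1]]
        return out

    def norm_estimate(self, n_iter: int = 30, seed: int = 0) -> float:
        """Largest singular value of Φ by power iteration on ΦᵀΦ."""
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(self.scene_shape).astype(self.dtype)
        v /= np.linalg.norm(v)
        s = 0.0
        for _ in range(n_iter):
            u = self.adjoint(self.apply(v))
            s = np.linalg.norm(u)
            if s == 0:
                return 0.0
            v = u / s
        return float(np.sqrt(s))

    def dense_matrix(self) -> np.ndarray:
        """Explicit Φ as a dense matrix (tiny problems only; used by oracles)."""
        H, W = self.scene_shape
        cols = []
        for j in range(H * W):
            e = np.zeros(H * W, dtype=self.dtype)
            e[j] = 1.0
            cols.append(self.apply(e.reshape(H, W)).ravel())
        return np.asarray(cols).T


def forward_shift_variant(scene: np.ndarray, grid: PSFGrid, depth: float) -> np.ndarray:
    """Apply the shift-variant forward model Φ to a scene at ``depth``.

    The scene array is assumed to span the calibrated grid hull; depths
    outside the calibrated range raise (no extrapolation).
    """
    scene = np.asarray(scene, dtype=float)
    d = float(depth)
    if len(grid.depths) > 1 and not (grid.depths[0] - 1e-9 <= d <= grid.depths[-1] + 1e-9):
        raise ValueError(
            f"depth {d} mm outside calibrated range "
            f"[{grid.depths[0]}, {grid.depths[-1]}] mm"
        )
    op = ShiftVariantOperator(grid, scene.shape[-2:], d)
    return op.apply(scene)


# --------------------------------------------------------------------------
# sensor noise
# --------------------------------------------------------------------------


def add_sensor_noise(
    measurement: np.ndarray,
    photon_scale: float,
    read_sigma: float,
    seed: int,
    bit_depth: int = 8,
    full_scale: float | None = None,
    quantize: bool = True,
) -> np.ndarray:
    """Shot + read noise and quantization of an ideal measurement.

    Poisson(photon_scale·m)/photon_scale models shot noise at a mean photon
    count of ``photon_scale`` per unit of measurement (variance m/photon_scale
    in measurement units); Gaussian read noise of ``read_sigma`` (same units
    as m) is added, and the result is scaled by ``full_scale`` (default: max
    of the measurement → ~full range), clipped and quantized to
    ``bit_depth``-bit integer counts.  ``quantize=False`` returns the noisy
    float measurement in the original units (useful for noise diagnostics).
    """
    if photon_scale <= 0:
        raise ValueError("photon_scale must be positive")
    m = np.asarray(measurement, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(np.clip(m, 0, None) * photon_scale) / photon_scale
    if read_sigma > 0:
        noisy = noisy + rng.normal(0.0, read_sigma, size=m.shape)
    if not quantize:
        return noisy
    top = 2**bit_depth - 1
    scale = (m.max() if full_scale is None else full_scale)
    if scale <= 0:
        scale = 1.0
    counts = np.clip(np.round(noisy / scale * top), 0, top)
    return counts.astype(np.uint8 if bit_depth <= 8 else np.uint16)
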