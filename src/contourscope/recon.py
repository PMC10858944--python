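"""Scene reconstruction from multiplexed lensless measurements.

Two solvers are provided.

*Wiener* — the closed-form frequency-domain solution of the shift-invariant
Tikhonov problem,

    î = F⁻¹( conj(F(p)) ⊙ F(b) / (|F(p)|² + γ) ),

evaluated on the same zero-padded grid as the forward model so forward and
inverse paths share one convolution convention.

*FISTA* — accelerated proximal gradient descent on the joint objective

    min_{i ≥ 0, g ∈ DCT_k}  ‖(Φ i + g) − b‖² + (γ/2)‖i‖² ,

where Φ is the shift-variant operator and g is a low-frequency additive
background constrained to the lowest ``dct_keep × dct_keep`` block of its
2D DCT (5×5 by default).  The implementation is the monotone variant
(a step is only accepted if it does not increase the objective) with
momentum restarts, so the recorded objective trace is non-increasing by
construction.  Note the γ conventions: the FISTA objective carries γ/2, so
its unconstrained shift-invariant limit equals ``wiener_reconstruct`` called
with γ/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft
from scipy import ndimage

from ._fft import kernel_spectrum, padded_shape, wiener_apply
from .forward import PSFGrid, ShiftVariantOperator

__all__ = [
    "ReconConfig",
    "SceneEstimate",
    "wiener_reconstruct",
    "fista_reconstruct",
    "dct_background_project",
    "refocus",
    "default_gamma",
]


@dataclass
class ReconConfig:
    """Solver settings for :func:`fista_reconstruct`.

    gamma: Tikhonov weight γ (None → 0.01 × max|F(p)|², i.e. 0.01 for
    unit-sum PSFs).  dct_keep: size of the retained low-frequency DCT block
    of the background; 0 disables the background term.  nonneg: clip the
    scene at 0 each iteration.
    """

    gamma: float | None = None
    model: str = "shift_variant"  # or "shift_invariant"
    max_iter: int = 100
    tol: float = 1e-6
    dct_keep: int = 5
    nonneg: bool = True
    depth: float | str = "auto"
    boundary: str = "pad"

    def __post_init__(self):
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.dct_keep < 0:
            raise ValueError("dct_keep must be >= 0 (0 disables the background)")
        if self.model not in ("shift_variant", "shift_invariant"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class SceneEstimate:
    """Reconstruction result: scene î, background ĝ, and diagnostics."""

    image: np.ndarray
    background: np.ndarray
    depth: float
    objective_trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def default_gamma(psf: np.ndarray) -> float:
    """Per-image default regularization: 0.01 × max|F(p)|²."""
    return 0.01 * float(np.max(np.abs(spfft.fft2(psf)) ** 2))


def wiener_reconstruct(b: np.ndarray, psf: np.ndarray, gamma: float,
                       boundary: str = "pad") -> np.ndarray:
    """Closed-form Tikhonov/Wiener deconvolution.

    ``boundary="pad"`` applies the inverse filter on the same zero-padded
    grid as ``forward_shift_invariant``; ``"periodic"`` applies it on the
    scene grid (circular convolution model).  With γ = 0 and a PSF whose
    spectrum has (near-)zeros, a division-guard error is raised rather than
    returning amplified garbage.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    b = np.asarray(b, dtype=float)
    psf = np.asarray(psf, dtype=float)
    if not np.any(psf):
        raise ValueError("psf must be nonzero")
    if boundary == "pad":
        pshape = padded_shape(b.shape[-2:], psf.shape)
    elif boundary == "periodic":
        pshape = b.shape[-2:]
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    kspec = kernel_spectrum(psf, pshape)
    if gamma == 0 and np.min(np.abs(kspec)) < 1e-12 * np.max(np.abs(kspec)):
        raise ZeroDivisionError(
            "PSF spectrum has (near-)zeros and gamma is 0; use gamma > 0"
        )
    return wiener_apply(b, kspec, gamma, pshape)


def dct_background_project(g: np.ndarray, keep: int) -> np.ndarray:
    """Project onto the span of the lowest ``keep × keep`` 2D DCT-II modes."""
    g = np.asarray(g, dtype=float)
    if keep > min(g.shape[-2:]):
        raise ValueError("keep exceeds array extent")
    c = spfft.dctn(g, type=2, norm="ortho", axes=(-2, -1))
    mask = np.zeros(g.shape[-2:], dtype=bool)
    mask[:keep, :keep] = True
    c = np.where(mask, c, 0.0)
    return spfft.idctn(c, type=2, norm="ortho", axes=(-2, -1))


def _make_operator(b_shape, grid: PSFGrid, config: ReconConfig, depth, dtype):
    if config.model == "shift_invariant":
        # degenerate grid: use the central PSF everywhere
        psfs = grid.at_depth(depth)
        central = psfs[psfs.shape[0] // 2, psfs.shape[1] // 2]
        uniform = np.broadcast_to(central, psfs.shape)
        grid = PSFGrid(
            uniform[None] if uniform.ndim == 4 else uniform,
            [depth],
            grid_coords_y=grid.grid_coords_y,
            grid_coords_x=grid.grid_coords_x,
            pixel_pitch=grid.pixel_pitch,
        )
    return ShiftVariantOperator(grid, b_shape, depth, dtype=dtype,
                                boundary=config.boundary)


def fista_reconstruct(
    b: np.ndarray,
    grid: PSFGrid,
    config: ReconConfig | None = None,
    depth: float | None = None,
    x0: np.ndarray | None = None,
    g0: np.ndarray | None = None,
    operator: ShiftVariantOperator | None = None,
    lipschitz: float | None = None,
    dtype=np.float64,
) -> SceneEstimate:
    """Joint scene/background estimation by monotone FISTA.

    Minimizes ``‖Φi + g − b‖² + (γ/2)‖i‖²`` over ``i ≥ 0`` (if configured)
    and ``g`` in the low-frequency DCT subspace.  The step size is 1/L with L
    bounded through power iteration on Φ; momentum restarts on objective
    increase.  ``x0``/``g0`` warm-start the iteration (e.g. from the previous
    video frame); ``operator`` and ``lipschitz`` allow reuse of precomputed
    state across frames.

    ``b`` may carry a leading batch axis, in which case all frames are
    reconstructed jointly with a shared (summed) objective.
    """
    config = config or ReconConfig()
    b = np.asarray(b, dtype=dtype)
    shape = b.shape[-2:]
    d = config.depth if depth is None else depth
    if d == "auto":
        d = float(grid.depths[len(grid.depths) // 2])
    d = float(d)

    op = operator if operator is not None else _make_operator(shape, grid, config, d, dtype)
    if config.gamma is None:
        central = grid.at_depth(d)
        central = central[central.shape[0] // 2, central.shape[1] // 2]
        gamma = default_gamma(central)
    else:
        gamma = float(config.gamma)

    if lipschitz is None:
        sig = op.norm_estimate()
        lipschitz = 2.0 * sig**2 + gamma
    step = 1.0 / lipschitz

    use_bg = config.dct_keep > 0

    def bg_project(r):
        # exact minimizer of ‖g − r‖² over the low-frequency DCT subspace
        if not use_bg:
            return np.zeros_like(r)
        return dct_background_project(r, config.dct_keep).astype(dtype)

    # The background enters the objective quadratically with no penalty, so
    # it is eliminated exactly: given i, the optimal g is the DCT-subspace
    # projection of (b − Φi).  FISTA then runs on the reduced objective
    #     ‖(I − P)(Φi − b)‖² + (γ/2)‖i‖²,
    # which shares its minimizer over i with the joint problem but avoids
    # the ill-conditioned coupled directions.
    x = np.zeros(b.shape, dtype=dtype) if x0 is None else np.array(x0, dtype=dtype)

    def reduced(fx, xi):
        r = fx - b
        r = r - bg_project(r)
        return r, float(np.sum(r * r) + 0.5 * gamma * np.sum(xi * xi))

    fx = op.apply(x)
    _, obj = reduced(fx, x)
    trace = [obj]

    x_prev, fx_prev = x, fx
    t = 1.0
    y_x, fy = x, fx
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        ry, _ = reduced(fy, y_x)
        grad_x = 2.0 * op.adjoint(ry) + gamma * y_x
        x_new = y_x - step * grad_x
        if config.nonneg:
            np.clip(x_new, 0.0, None, out=x_new)

        fx_new = op.apply(x_new)
        _, obj_new = reduced(fx_new, x_new)
        if not np.isfinite(obj_new):
            raise FloatingPointError(
                f"FISTA diverged (objective became non-finite) at step size {step:g}"
            )

        restart = obj_new > obj
        if restart:
            # monotone step: keep the previous iterate, drop momentum
            x_new, fx_new, obj_new = x, fx, obj
            t = 1.0
            t_new = 1.0
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))

        beta = (t - 1.0) / t_new
        y_x = x_new + beta * (x_new - x_prev)
        # Φ is linear: Φy from stored forward passes, no extra FFTs
        fy = fx_new + beta * (fx_new - fx_prev)

        rel = (obj - obj_new) / max(obj, 1e-300)
        x_prev, fx_prev = x, fx
        x, fx, obj, t = x_new, fx_new, obj_new, t_new
        trace.append(obj)
        # restart iterations repeat the previous objective; they must not
        # satisfy the relative-decrease stopping rule
        if not restart and 0 <= rel < config.tol and it > 2:
            converged = True
            break

    g = bg_project(b - fx)
    return SceneEstimate(
        image=np.asarray(x, dtype=float),
        background=np.asarray(g, dtype=float),
        depth=d,
        objective_trace=trace,
        converged=converged,
        n_iter=it,
    )


def refocus(
    b: np.ndarray,
    psf_stack: PSFGrid,
    depths=None,
    roi=None,
    gamma: float | None = None,
):
    """Digital refocusing: reconstruct at candidate depths, pick the sharpest.

    Each depth is reconstructed with the central PSF (Wiener); sharpness is
    the variance of the Laplacian inside ``roi`` (y0, y1, x0, x1).  Returns
    ``(best_depth, {depth: image})``; ties break to the smallest depth.
    """
    b = np.asarray(b, dtype=float)
    depths = psf_stack.depths if depths is None else np.atleast_1d(depths)
    if len(depths) < 2:
        raise ValueError("refocus needs at least 2 candidate depths")
    if roi is None:
        roi = (0, b.shape[0], 0, b.shape[1])
    y0, y1, x0, x1 = roi
    if not (0 <= y0 < y1 <= b.shape[0] and 0 <= x0 < x1 <= b.shape[1]):
        raise ValueError(f"roi {roi} outside image of shape {b.shape}")

    images = {}
    scores = []
    for d in depths:
        psfs = psf_stack.at_depth(float(d))
        central = psfs[psfs.shape[0] // 2, psfs.shape[1] // 2]
        gam = default_gamma(central) if gamma is None else gamma
        img = wiener_reconstruct(b, central, gam)
        images[float(d)] = img
        lap = ndimage.laplace(img[y0:y1, x0:x1])
        scores.append(float(np.var(lap)))
    best = float(np.asarray(depths, dtype=float)[int(np.argmax(scores))])
    return best, images
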