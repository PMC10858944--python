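import numpy as np
import pytest
from scipy import ndimage

import contourscope as cs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240210)


def make_contour_kernel(support=16, seed=11, stroke=1.0, feature_scale=8.0):
    """Broadband test kernel: thin contour strokes, unit sum.

    This is the contour PSF pattern at the reconstruction grid — thin closed
    curves, which is what gives the lensless PSF its broadband spectrum.
    """
    field = cs.generate_perlin_noise(support + 16, 1.0, feature_scale, seed=seed)
    pat = cs.contour_from_noise(field, pattern_width=stroke)
    k = ndimage.gaussian_filter(pat.mask.astype(float), 0.5)
    k = k[8 : 8 + support, 8 : 8 + support]
    return k / k.sum()


@pytest.fixture(scope="session")
def contour_kernel():
    return make_contour_kernel()


@pytest.fixture(scope="session")
def pinhole_contour_kernel():
    """Well-conditioned kernel: half pinhole (delta), half contour pattern.

    The delta component bounds the spectrum away from zero everywhere, which
    planted-recovery oracles need; the contour component keeps it a
    multiplexing kernel.
    """
    k = 0.5 * make_contour_kernel()
    k[k.shape[0] // 2, k.shape[1] // 2] += 0.5
    return k


@pytest.fixture(scope="session")
def ring_kernel():
    yy, xx = np.mgrid[:9, :9]
    r = np.hypot(yy - 4, xx - 4)
    k = ((r > 2) & (r < 4)).astype(float)
    return k / k.sum()


def uniform_grid(kernel, depths=(3.0,), grid_shape=(2, 2)):
    """PSFGrid with one kernel replicated at every node (shift-invariant)."""
    nr, nc = grid_shape
    psfs = np.broadcast_to(
        kernel, (len(depths), nr, nc) + kernel.shape
    ).copy()
    return cs.PSFGrid(psfs, list(depths), pixel_pitch=31.25)
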