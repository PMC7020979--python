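"""Cubic B-spline displacement fields on integer control-point lattices.

The control-point lattice has an integer voxel stride per axis; control point
``m`` sits at voxel index ``(m - 1) * stride`` so one layer of points lies
outside each face of the volume (cubic B-spline support is 4 knots). Dense
synthesis and its exact adjoint are separable 1-D convolutions, which keeps
gradient backprojection cheap and makes the pair verifiable via the inner
product identity <Bc, v> = <c, B^T v>.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def cubic_bspline(t: np.ndarray) -> np.ndarray:
    """The cubic B-spline kernel beta3(t), support |t| < 2."""
    at = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(at)
    near = at < 1.0
    mid = (at >= 1.0) & (at < 2.0)
    out[near] = 2.0 / 3.0 - at[near] ** 2 + 0.5 * at[near] ** 3
    out[mid] = (2.0 - at[mid]) ** 3 / 6.0
    return out


class BSplineLattice:
    """Separable cubic B-spline synthesis for one scalar component."""

    def __init__(self, shape: tuple[int, int, int], stride: tuple[int, int, int]):
        self.shape = tuple(int(n) for n in shape)
        self.stride = tuple(max(1, int(s)) for s in stride)
        # control points m = 0..nc-1 at voxel index (m-1)*stride
        self.n_control = tuple(
            int(np.ceil((n - 1) / s)) + 3 for n, s in zip(self.shape, self.stride)
        )
        self._kernels = [
            cubic_bspline(np.arange(-(2 * s - 1), 2 * s) / s) for s in self.stride
        ]
        # padded work-array length per axis: control points span voxels
        # -stride .. (nc-2)*stride
        self._length = tuple(
            (nc - 1) * s + 1 for nc, s in zip(self.n_control, self.stride)
        )

    def synthesize(self, coeff: np.ndarray) -> np.ndarray:
        """Dense scalar field from control coefficients, shape == self.shape."""
        assert coeff.shape == self.n_control
        work = np.zeros(self._length)
        work[:: self.stride[0], :: self.stride[1], :: self.stride[2]] = coeff
        for axis, k in enumerate(self._kernels):
            work = ndimage.convolve1d(work, k, axis=axis, mode="constant")
        s = self.stride
        return work[
            s[0] : s[0] + self.shape[0],
            s[1] : s[1] + self.shape[1],
            s[2] : s[2] + self.shape[2],
        ]

    def adjoint(self, dense: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`synthesize` (gradient backprojection)."""
        assert dense.shape == self.shape
        s = self.stride
        work = np.zeros(self._length)
        work[
            s[0] : s[0] + self.shape[0],
            s[1] : s[1] + self.shape[1],
            s[2] : s[2] + self.shape[2],
        ] = dense
        for axis, k in enumerate(self._kernels):
            work = ndimage.convolve1d(work, k, axis=axis, mode="constant")
        return work[:: s[0], :: s[1], :: s[2]].copy()


def difference_penalty(coeff: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
    """First-difference smoothness penalty on a (...,3) coefficient lattice.

    Returns (value, gradient). ``weights`` holds one 1/spacing^2 factor per
    axis so the penalty approximates the mean squared displacement gradient.
    """
    value = 0.0
    grad = np.zeros_like(coeff)
    n = coeff[..., 0].size
    for axis in range(3):
        d = np.diff(coeff, axis=axis)
        w = weights[axis] / n
        value += w * float((d**2).sum())
        g = 2.0 * w * d
        sl_lo = [slice(None)] * 4
        sl_hi = [slice(None)] * 4
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        grad[tuple(sl_lo)] -= g
        grad[tuple(sl_hi)] += g
    return value, grad
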