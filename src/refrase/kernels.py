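"""The unit dipole response in k-space and FFT-based dipole convolution.

The field shift (in units of the source susceptibility) produced by a
susceptibility distribution chi is the convolution ``chi * d`` whose k-space
representation is the well-known kernel

    D(k) = 1/3 - k_z^2 / |k|^2,       D(0) = 0,

with the main field along z.  ``D(0) = 0`` makes the convolved field
mean-free over the grid; since phase-based field maps carry no absolute
reference, any global constant is immaterial downstream.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _fft

__all__ = ["dipole_kernel", "dipole_convolve"]


def _freq_grids(shape, voxel_size, half):
    ks = [np.fft.fftfreq(n, d=dx) for n, dx in zip(shape[:-1], voxel_size[:-1])]
    last = (np.fft.rfftfreq if half else np.fft.fftfreq)(shape[-1], d=voxel_size[-1])
    return np.meshgrid(*ks, last, indexing="ij", sparse=True)


def _half_kernel(shape, voxel_size, b0_dir):
    """Dipole kernel on the rfftn half-spectrum grid."""
    b0 = np.asarray(b0_dir, dtype=float)
    b0 = b0 / np.linalg.norm(b0)
    kx, ky, kz = _freq_grids(shape, voxel_size, half=True)
    k_par = kx * b0[0] + ky * b0[1] + kz * b0[2]
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - k_par**2 / k2
    d[0, 0, 0] = 0.0
    return d


def dipole_kernel(shape, voxel_size=(1.0, 1.0, 1.0), b0_dir=(0.0, 0.0, 1.0)):
    """k-space dipole kernel D(k) = 1/3 - (k.b0)^2/|k|^2 on an FFT grid.

    Parameters
    ----------
    shape : tuple of int
        Grid shape (3-D).
    voxel_size : tuple of float
        Voxel edge lengths; only their ratios matter.
    b0_dir : tuple of float
        Main-field direction; normalized internally.  Defaults to z.

    Returns
    -------
    ndarray
        Real kernel with D(0) = 0, values in [-2/3, 1/3], laid out in
        standard (unshifted) FFT order.
    """
    if len(shape) != 3:
        raise ValueError("dipole_kernel expects a 3-D shape")
    b0 = np.asarray(b0_dir, dtype=float)
    b0 = b0 / np.linalg.norm(b0)
    kx, ky, kz = _freq_grids(shape, voxel_size, half=False)
    k_par = kx * b0[0] + ky * b0[1] + kz * b0[2]
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - k_par**2 / k2
    d[0, 0, 0] = 0.0
    return d


def dipole_convolve(chi, voxel_size=(1.0, 1.0, 1.0), b0_dir=(0.0, 0.0, 1.0),
                    pad=True):
    """Convolve a susceptibility volume with the unit dipole kernel.

    With ``pad=True`` the volume is zero-padded by a factor two per axis
    before the FFT, which suppresses the circular wrap-around of the
    long-range r^-3 dipole tails; the result is cropped back to the input
    shape.  The output is in the same units as ``chi`` (multiply by
    :func:`refrase.units.hz_per_ppm` to obtain Hz from ppm).
    """
    chi = np.asarray(chi, dtype=float)
    if chi.ndim != 3:
        raise ValueError("dipole_convolve expects a 3-D volume")
    if pad:
        work_shape = tuple(2 * n for n in chi.shape)
        buf = np.zeros(work_shape, dtype=float)
        buf[: chi.shape[0], : chi.shape[1], : chi.shape[2]] = chi
    else:
        work_shape = chi.shape
        buf = chi
    d = _half_kernel(work_shape, voxel_size, b0_dir)
    out = _fft.irfftn(_fft.rfftn(buf) * d, s=work_shape)
    if pad:
        out = out[: chi.shape[0], : chi.shape[1], : chi.shape[2]]
    return out
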