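"""Real solid spherical harmonics r^l * Y_lm for smooth background fields.

Solid harmonics are the harmonic polynomials; truncated at order L they span
the smooth, source-free field perturbations (shim imperfections, distant
susceptibility structure) inside a region.  The basis is evaluated on a
coordinate frame with its origin at the grid centre and z along the main
field.  There are (L+1)^2 functions up to order L, indexed ``l*l + l + m``
for l = 0..L, m = -l..l.

Real harmonics follow the usual convention: for m > 0 the function is
``sqrt(2) * (-1)^m * Re(Y_lm)``, for m < 0 ``sqrt(2) * (-1)^m * Im(Y_l|m|)``,
and for m = 0 the (real) ``Y_l0``.  The radial factor r^l is in voxel units.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["n_basis", "grid_coords", "solid_harmonic_table", "evaluate_ssh_field"]


def n_basis(order: int) -> int:
    """Number of solid harmonics up to ``order`` inclusive: (L+1)^2."""
    return (order + 1) ** 2


def grid_coords(shape, origin=None):
    """Voxel coordinates (N, 3) relative to ``origin`` (default grid centre)."""
    if origin is None:
        origin = [(n - 1) / 2.0 for n in shape]
    axes = [np.arange(n, dtype=float) - o for n, o in zip(shape, origin)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def solid_harmonic_table(coords, order: int):
    """Evaluate the real solid harmonics at points ``coords`` (N, 3).

    Returns an (N, (order+1)^2) matrix, one column per basis function.
    """
    coords = np.asarray(coords, dtype=float)
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    r = np.sqrt(x * x + y * y + z * z)
    # polar/azimuth; at r = 0 the angles are arbitrary, the r^l factor (or
    # the constant l = 0 term) makes the product well defined
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.divide(z, r, out=np.zeros_like(z),
                                            where=r > 0), -1.0, 1.0))
    phi = np.arctan2(y, x)
    out = np.empty((coords.shape[0], n_basis(order)), dtype=float)
    for l in range(order + 1):
        rl = r**l
        for m in range(0, l + 1):
            ylm = sph_harm_y(l, m, theta, phi)
            idx = l * l + l + m
            if m == 0:
                out[:, idx] = rl * ylm.real
            else:
                s = np.sqrt(2.0) * (-1.0) ** m
                out[:, idx] = rl * s * ylm.real
                out[:, l * l + l - m] = rl * s * ylm.imag
    return out


def evaluate_ssh_field(shape, coeffs, origin=None):
    """Field volume of a solid-harmonic expansion with coefficients ``coeffs``.

    ``coeffs`` has length (L+1)^2 for some order L.  Evaluation accumulates
    one basis function at a time to keep peak memory at a single volume.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    order = int(np.sqrt(coeffs.size)) - 1
    if n_basis(order) != coeffs.size:
        raise ValueError("coefficient vector length must be a perfect square")
    coords = grid_coords(shape, origin)
    field = np.zeros(coords.shape[0], dtype=float)
    # evaluate per order to bound the size of the temporary table
    for l in range(order + 1):
        sel = slice(l * l, (l + 1) * (l + 1))
        if not np.any(coeffs[sel]):
            continue
        table = _single_order_table(coords, l)
        field += table @ coeffs[sel]
    return field.reshape(shape)


def _single_order_table(coords, l):
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    r = np.sqrt(x * x + y * y + z * z)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.divide(z, r, out=np.zeros_like(z),
                                            where=r > 0), -1.0, 1.0))
    phi = np.arctan2(y, x)
    out = np.empty((coords.shape[0], 2 * l + 1), dtype=float)
    rl = r**l
    for m in range(0, l + 1):
        ylm = sph_harm_y(l, m, theta, phi)
        if m == 0:
            out[:, l] = rl * ylm.real
        else:
            s = np.sqrt(2.0) * (-1.0) ** m
            out[:, l + m] = rl * s * ylm.real
            out[:, l - m] = rl * s * ylm.imag
    return out
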