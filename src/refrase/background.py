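"""Background-field estimation and extrapolation.

Fields measured inside the brain contain a dominant background from
sources outside it: shim imperfections and distant structure (smooth,
harmonic — modelled by solid spherical harmonics) and nearby external
susceptibility such as air cavities and bone (modelled by an explicit
external pseudo-susceptibility distribution convolved with the dipole
kernel).  Both models are fitted on the trusted evaluation area m_EA only,
but — being parametric — can be *evaluated* on the larger maximum support
m_max.  That extrapolation is what allows corrupted rim phase to be
restored: the background estimate exists where the data could not be
unwrapped.

The external-dipole stage minimizes

    || m_EA * (b - f0*1e-6*(chi_ext * d)) ||^2  +  lambda * || m_pen * chi_ext ||^2

by conjugate gradients on the normal equations with FFT convolutions,
where the Tikhonov term suppresses sources inside the (dilated) support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.fft as _fft
from scipy import ndimage

from .harmonics import grid_coords, n_basis, solid_harmonic_table
from .kernels import _half_kernel
from .units import hz_per_ppm

__all__ = ["SSHModel", "DipoleSourceModel", "BackgroundModel",
           "build_ssh_basis", "fit_ssh", "fit_external_dipoles",
           "dipole_background_field", "PaddedDipoleConv"]


# --------------------------------------------------------------------------
# solid spherical harmonic stage
# --------------------------------------------------------------------------

@dataclass
class SSHModel:
    """Solid-harmonic background model fitted over a domain mask.

    ``coeffs`` multiply the *raw* solid harmonics (so the model can be
    evaluated anywhere); ``ortho_transform`` maps raw to the basis that is
    orthonormal over the domain voxels (QR factor), kept for diagnostics.
    """

    order: int
    coeffs: np.ndarray
    domain: np.ndarray
    origin: tuple
    column_scale: np.ndarray
    ortho_transform: np.ndarray

    def evaluate(self, mask: np.ndarray) -> np.ndarray:
        """Evaluate the fitted expansion on ``mask`` (zeros elsewhere)."""
        shape = mask.shape
        coords = grid_coords(shape, self.origin)[mask.ravel()]
        table = solid_harmonic_table(coords, self.order)
        out = np.zeros(shape)
        out[mask] = table @ self.coeffs
        return out


def build_ssh_basis(order: int, domain: np.ndarray, origin=None):
    """Orthonormalized solid-harmonic basis over a domain mask.

    Returns ``(q, scale, r, coords_mask)`` where ``q`` (n_vox x (L+1)^2)
    has orthonormal columns over the domain voxels, obtained by column
    scaling followed by a QR factorization (numerically equivalent to
    modified Gram-Schmidt), and raw coefficients are recovered as
    ``scale * solve(r, q.T @ y)``.
    """
    domain = np.asarray(domain, dtype=bool)
    nb = n_basis(order)
    nv = int(domain.sum())
    if nv < nb:
        raise ValueError(f"domain has {nv} voxels, fewer than the {nb} basis functions")
    if origin is None:
        origin = tuple((n - 1) / 2.0 for n in domain.shape)
    coords = grid_coords(domain.shape, origin)[domain.ravel()]
    a = solid_harmonic_table(coords, order)
    scale = 1.0 / np.linalg.norm(a, axis=0)
    q, r = np.linalg.qr(a * scale)
    return q, scale, r, origin


def fit_ssh(b: np.ndarray, m_ea: np.ndarray, order: int = 5,
            m_eval: Optional[np.ndarray] = None, origin=None):
    """Least-squares solid-harmonic fit of a field on m_EA, evaluated on m_eval.

    Returns ``(model, b_ssh)`` with ``b_ssh`` the extrapolated harmonic
    field on ``m_eval`` (defaults to m_EA itself) in the same units as
    ``b``.
    """
    m_ea = np.asarray(m_ea, dtype=bool)
    q, scale, r, origin = build_ssh_basis(order, m_ea, origin)
    y = np.asarray(b, dtype=float)[m_ea]
    c_ortho = q.T @ y
    coeffs = scale * np.linalg.solve(r, c_ortho)
    model = SSHModel(order=order, coeffs=coeffs, domain=m_ea, origin=origin,
                     column_scale=scale, ortho_transform=r)
    target = m_ea if m_eval is None else np.asarray(m_eval, dtype=bool)
    return model, model.evaluate(target)


# --------------------------------------------------------------------------
# external dipole stage
# --------------------------------------------------------------------------

class PaddedDipoleConv:
    """Self-adjoint FFT dipole convolution with 2x zero padding per axis."""

    def __init__(self, shape, voxel_size=(1.0, 1.0, 1.0), b0_dir=(0, 0, 1.0),
                 pad: bool = True, dtype=np.float64):
        self.shape = tuple(shape)
        self.pad = pad
        self.dtype = np.dtype(dtype)
        work = tuple(2 * n for n in shape) if pad else self.shape
        self.work_shape = work
        self.kernel = _half_kernel(work, voxel_size, b0_dir).astype(
            np.float32 if self.dtype == np.float32 else np.float64)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        buf = np.zeros(self.work_shape, dtype=self.dtype)
        buf[: self.shape[0], : self.shape[1], : self.shape[2]] = x
        out = _fft.irfftn(_fft.rfftn(buf) * self.kernel, s=self.work_shape)
        if self.pad:
            out = out[: self.shape[0], : self.shape[1], : self.shape[2]]
        return np.asarray(out, dtype=np.float64)


@dataclass
class DipoleSourceModel:
    """External pseudo-susceptibility (ppm) explaining the residual field."""

    chi_ext: np.ndarray
    lambda_ext: float
    m_ea: np.ndarray
    m_penalty: np.ndarray
    b0: float
    converged: bool
    n_iter: int
    objective_history: np.ndarray


def fit_external_dipoles(b_residual: np.ndarray, m_ea: np.ndarray,
                         m_penalty: np.ndarray, lambda_ext: float = 1e-3,
                         b0: float = 7.0, tol: float = 1e-6,
                         max_iter: int = 300,
                         conv: Optional[PaddedDipoleConv] = None,
                         warn: bool = True) -> DipoleSourceModel:
    """Fit an external susceptibility distribution to a residual field (Hz).

    ``m_penalty`` is the source-suppression mask (the support, dilated to
    exceed m_EA by at least one voxel).  The data are normalized by the
    Larmor shift per ppm so chi_ext is in ppm and ``lambda_ext`` is
    relative to unit-scale data.  Conjugate gradients on the (symmetric
    positive semi-definite) normal equations; the quadratic objective is
    recorded per iteration and is non-increasing.
    """
    m_ea = np.asarray(m_ea, dtype=bool)
    m_pen = np.asarray(m_penalty, dtype=bool)
    if np.any(m_ea & ~m_pen):
        raise ValueError("penalty mask must contain m_EA")
    shape = m_ea.shape
    f0 = hz_per_ppm(b0)
    b_ppm = np.zeros(shape)
    b_ppm[m_ea] = np.asarray(b_residual, dtype=float)[m_ea] / f0
    if conv is None:
        conv = PaddedDipoleConv(shape)

    mea_f = m_ea.astype(float)
    mpen_f = m_pen.astype(float)

    def normal_op(x):
        v = x.reshape(shape)
        y = conv(v) * mea_f
        z = conv(y)
        z += lambda_ext * (mpen_f * v)
        return z.ravel()

    rhs = conv(b_ppm * mea_f).ravel()
    x = np.zeros(shape).ravel()
    r = rhs - normal_op(x)
    p = r.copy()
    rs = r @ r
    rhs_norm = np.sqrt(rhs @ rhs)
    history = []
    converged = rhs_norm == 0
    n_done = 0
    for it in range(max_iter):
        if converged:
            break
        ap = normal_op(p)
        alpha = rs / (p @ ap)
        x += alpha * p
        r -= alpha * ap
        rs_new = r @ r
        n_done = it + 1
        # quadratic objective 0.5 x'Ax - b'x, monotone along CG iterates
        history.append(0.5 * (x @ (rhs - r)) - rhs @ x)
        if np.sqrt(rs_new) <= tol * max(rhs_norm, 1e-30):
            converged = True
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    if not converged and warn:
        import warnings
        warnings.warn(f"external dipole fit: CG did not reach tol={tol} "
                      f"within {max_iter} iterations", RuntimeWarning)
    return DipoleSourceModel(chi_ext=x.reshape(shape), lambda_ext=lambda_ext,
                             m_ea=m_ea, m_penalty=m_pen, b0=b0,
                             converged=converged, n_iter=n_done,
                             objective_history=np.asarray(history))


def dipole_background_field(model: DipoleSourceModel, m_max: np.ndarray,
                            sigma: float = 1.0,
                            conv: Optional[PaddedDipoleConv] = None) -> np.ndarray:
    """Background field (Hz) of the fitted external sources, on m_max.

    The forward field is evaluated on the full grid, Gaussian-smoothed with
    sigma = 1 voxel to suppress edge overshoot near the fit boundary, then
    restricted to m_max.
    """
    if conv is None:
        conv = PaddedDipoleConv(model.chi_ext.shape)
    b = hz_per_ppm(model.b0) * conv(model.chi_ext)
    if sigma > 0:
        b = ndimage.gaussian_filter(b, sigma)
    out = np.zeros_like(b)
    m_max = np.asarray(m_max, dtype=bool)
    out[m_max] = b[m_max]
    return out


@dataclass
class BackgroundModel:
    """Accumulated background field over iterations (exact running sum)."""

    shape: tuple
    components: list = field(default_factory=list)  # list of (b_ssh, b_dip)

    @property
    def total(self) -> np.ndarray:
        out = np.zeros(self.shape)
        for b_ssh, b_dip in self.components:
            out = out + b_ssh + b_dip
        return out

    def add(self, b_ssh: np.ndarray, b_dip: np.ndarray):
        self.components.append((np.asarray(b_ssh), np.asarray(b_dip)))
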