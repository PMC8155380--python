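"""Phase unwrapping (spatial and temporal) and per-voxel field-map regression.

The measured phase is only known modulo 2*pi.  Spatial unwrapping restores
a continuous phase per echo wherever a Nyquist-compliant path exists (true
phase change below pi per voxel step); a quality-guided, best-path style
region-growing algorithm is used.  Because spatial unwrapping leaves one
global 2*pi*k per echo undetermined, the echoes are then aligned in time at
a central reference voxel, assuming zero phase at t = 0.  Finally the field
b (Hz) is the per-voxel least-squares slope of phase against 2*pi*TE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap_phase

__all__ = ["EchoSeries", "FieldMap", "UnwrapResult", "wrap_phase",
           "unwrap_spatial", "unwrap_1d", "unwrap_temporal", "fit_fieldmap",
           "smooth_first_echo", "reference_voxel"]


def wrap_phase(phi):
    """Wrap to the principal interval (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


@dataclass
class EchoSeries:
    """Multi-echo phase/magnitude volumes with echo times (seconds)."""

    phase: np.ndarray       # (n_echo, nx, ny, nz), radians
    magnitude: np.ndarray   # (n_echo, nx, ny, nz), >= 0
    tes: np.ndarray         # (n_echo,), seconds, strictly increasing
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.tes = np.asarray(self.tes, dtype=float)
        if self.phase.ndim != 4 or self.phase.shape != self.magnitude.shape:
            raise ValueError("phase and magnitude must be (n_echo, nx, ny, nz) and match")
        if self.tes.ndim != 1 or self.tes.size != self.phase.shape[0]:
            raise ValueError("need one echo time per echo volume")
        if self.tes.size > 1 and np.any(np.diff(self.tes) <= 0):
            raise ValueError("echo times must be strictly increasing")

    @property
    def n_echoes(self) -> int:
        return self.phase.shape[0]

    @property
    def shape(self):
        return self.phase.shape[1:]

    def complex(self, e: int) -> np.ndarray:
        return self.magnitude[e] * np.exp(1j * self.phase[e])

    def copy(self) -> "EchoSeries":
        return EchoSeries(self.phase.copy(), self.magnitude.copy(),
                          self.tes.copy(), self.voxel_size)


@dataclass
class FieldMap:
    """Scalar field-shift volume in Hz with a validity mask."""

    data: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("field map is not finite inside its mask")


@dataclass
class UnwrapResult:
    """Continuous phase plus the integer 2*pi multiples that were applied."""

    unwrapped: np.ndarray
    k: np.ndarray           # integer volume; unwrapped = wrapped + 2*pi*k
    mask: np.ndarray


def _check_connected(mask):
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = sorted(np.bincount(lab.ravel())[1:].tolist(), reverse=True)
        raise ValueError(
            f"mask has {n} disconnected components (sizes {sizes}); "
            "remove all but one before unwrapping")
    if n == 0:
        raise ValueError("mask is empty")


def unwrap_spatial(phase: np.ndarray, mask: np.ndarray,
                   quality: Optional[np.ndarray] = None) -> UnwrapResult:
    """Unwrap a wrapped 3-D phase volume inside a connected mask.

    Uses reliability-sorted region growing (the best-path family): exact up
    to a single global 2*pi*k whenever every neighbouring pair of true
    phases differs by less than pi along some spanning path.  The optional
    ``quality`` volume is accepted for interface compatibility; the
    implementation derives its own reliability ordering from local phase
    second differences, which serves the same purpose.
    """
    phase = np.asarray(phase, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    _check_connected(mask)
    ma = np.ma.array(phase, mask=~mask)
    unwrapped = np.asarray(_unwrap_phase(ma).filled(0.0), dtype=float)
    k = np.zeros(phase.shape, dtype=np.int64)
    k[mask] = np.round((unwrapped[mask] - phase[mask]) / (2.0 * np.pi)).astype(np.int64)
    # snap exactly onto wrapped + 2*pi*k so re-wrapping reproduces the input
    unwrapped = np.where(mask, phase + 2.0 * np.pi * k, 0.0)
    return UnwrapResult(unwrapped=unwrapped, k=k, mask=mask)


def unwrap_1d(phase):
    """Path unwrap of a 1-D wrapped phase profile (first sample kept)."""
    return np.unwrap(np.asarray(phase, dtype=float))


def reference_voxel(mask: np.ndarray):
    """Centre of mass of a mask, shifted to the nearest in-mask voxel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    com = np.array(ndimage.center_of_mass(mask))
    idx = np.argwhere(mask)
    best = idx[np.argmin(((idx - com) ** 2).sum(axis=1))]
    return tuple(int(i) for i in best)


def unwrap_temporal(series: EchoSeries, reference, mask: Optional[np.ndarray] = None) -> EchoSeries:
    """Align the per-echo global phase constants at a reference voxel.

    Each spatially unwrapped echo is offset by an unknown 2*pi*k_e.  With
    the model phase(0) = 0, the first echo is shifted so its reference
    phase lies in (-pi, pi], and each later echo is shifted by the multiple
    of 2*pi that brings its reference phase closest to the linear
    continuation of the previous echo (minimal-jump continuation).
    """
    ref = tuple(int(i) for i in reference)
    if mask is not None and not np.asarray(mask, bool)[ref]:
        raise ValueError(f"reference voxel {ref} lies outside the mask")
    if np.any(series.magnitude[(slice(None),) + ref] == 0):
        raise ValueError(f"reference voxel {ref} has zero magnitude in some echo")
    out = series.copy()
    two_pi = 2.0 * np.pi
    prev = None
    for e in range(series.n_echoes):
        p_ref = out.phase[e][ref]
        if prev is None:
            k = np.round((wrap_phase(p_ref) - p_ref) / two_pi)  # into (-pi, pi]
        else:
            predicted = prev * (series.tes[e] / series.tes[e - 1])
            k = np.round((predicted - p_ref) / two_pi)
        out.phase[e] = out.phase[e] + two_pi * k
        prev = out.phase[e][ref]
    return out


def fit_fieldmap(series: EchoSeries, mask: np.ndarray,
                 include_intercept: bool = False,
                 magnitude_weighted: bool = False) -> FieldMap:
    """Per-voxel least-squares field map b (Hz) from unwrapped phases.

    Without an intercept the model is phase = 2*pi*b*t (zero phase at
    t = 0, appropriate for simulated data); with an intercept a per-voxel
    phase offset is estimated as well, which requires >= 2 echoes.
    Optionally weight each echo by its magnitude.
    """
    mask = np.asarray(mask, dtype=bool)
    t = series.tes
    if include_intercept and t.size < 2:
        raise ValueError("intercept fit requires at least two echoes")
    phi = series.phase[:, mask]                    # (n_echo, n_vox)
    if magnitude_weighted:
        w = series.magnitude[:, mask]
    else:
        w = np.ones_like(phi)
    x = 2.0 * np.pi * t[:, None]
    if include_intercept:
        # weighted 2-parameter LSQ per voxel, closed form
        sw = w.sum(0)
        sx = (w * x).sum(0)
        sxx = (w * x * x).sum(0)
        sy = (w * phi).sum(0)
        sxy = (w * x * phi).sum(0)
        det = sw * sxx - sx * sx
        b = (sw * sxy - sx * sy) / det
    else:
        b = (w * x * phi).sum(0) / (w * x * x).sum(0)
    data = np.zeros(series.shape)
    data[mask] = b
    return FieldMap(data=data, mask=mask)


def smooth_first_echo(series: EchoSeries, sigma: float = 2.0) -> EchoSeries:
    """Gaussian-smooth the complex signal of the first echo only.

    Early echoes carry little phase contrast relative to their noise; a
    narrow Gaussian applied to the complex phasor (real and imaginary parts
    separately) stabilizes the field fit without touching later echoes.
    The smoothed phase is re-extracted; the magnitude is kept.
    """
    out = series.copy()
    s = series.complex(0)
    sm = (ndimage.gaussian_filter(s.real, sigma)
          + 1j * ndimage.gaussian_filter(s.imag, sigma))
    out.phase[0] = np.angle(np.where(np.abs(sm) > 0, sm, 1.0))
    return out
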