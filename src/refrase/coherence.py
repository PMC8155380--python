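"""Local phase coherence and evaluation-mask construction.

The local coherence (LC) of a phase volume is the magnitude of the mean
complex phasor over the 3x3x3 neighbourhood of each voxel,

    Q_LC[ijk] = | (1/27) * sum_{neighbourhood} exp(i * phase) |,

which is 1 for locally constant phase, drops toward 0 for steep gradients
(a per-voxel phase step g along one axis gives |1 + 2 cos g| / 3 per axis)
and for noise.  Thresholding a lightly smoothed Q_LC inside the maximum
brain support and keeping the largest connected component yields the
evaluation area m_EA — the set of voxels whose phase can be trusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["CoherenceMap", "MaskSet", "local_coherence", "smooth_coherence",
           "make_evaluation_mask"]


@dataclass
class CoherenceMap:
    """Q_LC volume in [0, 1] with the threshold/echo used to produce it."""

    q: np.ndarray
    threshold: float | None = None
    source_echo: int | None = None


@dataclass
class MaskSet:
    """Maximum support m_max and the evaluation area m_EA (m_EA subset of m_max)."""

    m_max: np.ndarray
    m_ea: np.ndarray

    def __post_init__(self):
        if np.any(self.m_ea & ~self.m_max):
            raise ValueError("m_EA must be a subset of m_max")


def local_coherence(phase: np.ndarray, mask: np.ndarray | None = None,
                    source_echo: int | None = None) -> CoherenceMap:
    """Mean-phasor magnitude over each voxel's 3x3x3 neighbourhood.

    When a ``mask`` is given the phase is only defined (and only trusted)
    inside it, so the neighbourhood sum runs over in-mask neighbours and
    is renormalized by their count; Q_LC is 0 outside the mask.  Without a
    mask the same renormalization handles the volume boundary.  Either
    way Q_LC stays in [0, 1].
    """
    phase = np.asarray(phase, dtype=float)
    if mask is None:
        valid = np.ones(phase.shape)
    else:
        valid = np.asarray(mask, dtype=float)
    z = np.exp(1j * phase) * valid
    size = 3
    # zero-padded box sums, then renormalize by the valid neighbourhood size
    re = ndimage.uniform_filter(z.real, size=size, mode="constant", cval=0.0)
    im = ndimage.uniform_filter(z.imag, size=size, mode="constant", cval=0.0)
    counts = ndimage.uniform_filter(valid, size=size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.abs(re + 1j * im) / counts
    q = np.where(counts > 0, q, 0.0) * (valid > 0)
    return CoherenceMap(q=np.clip(q, 0.0, 1.0), source_echo=source_echo)


def smooth_coherence(cmap: CoherenceMap, sigma: float = 2.0,
                     mask: np.ndarray | None = None) -> CoherenceMap:
    """Gaussian-smoothed coherence, clipped back to [0, 1].

    Smoothing suppresses the non-random noise bias of the small 27-voxel
    neighbourhood before thresholding; ``sigma = 0`` is the identity.
    With a ``mask`` the filter is renormalized over in-mask voxels so the
    undefined exterior does not drag down rim values.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return CoherenceMap(q=cmap.q.copy(), threshold=cmap.threshold,
                            source_echo=cmap.source_echo)
    if mask is None:
        q = ndimage.gaussian_filter(cmap.q, sigma)
    else:
        m = np.asarray(mask, dtype=float)
        num = ndimage.gaussian_filter(cmap.q * m, sigma)
        den = ndimage.gaussian_filter(m, sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(den > 0, num / den, 0.0) * (m > 0)
    q = np.clip(q, 0.0, 1.0)
    return CoherenceMap(q=q, threshold=cmap.threshold, source_echo=cmap.source_echo)


def make_evaluation_mask(cmap: CoherenceMap, q_min: float,
                         m_max: np.ndarray) -> MaskSet:
    """Threshold Q_LC >= q_min inside m_max and keep the largest component.

    Connectivity is 6-connected (face neighbours), the conservative choice
    for thin bridges.  Raises if no voxel survives the threshold.
    """
    m_max = np.asarray(m_max, dtype=bool)
    cand = (cmap.q >= q_min) & m_max
    if not cand.any():
        raise ValueError(f"no voxel reaches Q_LC >= {q_min} inside m_max")
    lab, n = ndimage.label(cand)  # default structure = 6-connectivity in 3-D
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        cand = lab == np.argmax(sizes)
    return MaskSet(m_max=m_max, m_ea=cand)
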