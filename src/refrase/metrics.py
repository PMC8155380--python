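"""Quantitative evaluation: mask coverage, region statistics, RMSE.

All susceptibility comparisons are reference-free — reconstructed maps and
ground truth are only defined up to a global constant — so RMSE is
computed after subtracting the mean residual over the mask.  The rim mask
isolates the voxels within a given width of the evaluation-mask surface,
where fringe-phase errors concentrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["RegionStats", "mask_difference", "region_stats", "rim_mask",
           "region_shell_mask", "rmse_offset_corrected"]


@dataclass
class RegionStats:
    mean: float      # ppm
    std: float       # ppm, sample (n-1) standard deviation
    count: int
    label: str = ""


def mask_difference(m_max: np.ndarray, m_ea: np.ndarray) -> float:
    """Relative mask voxel-count difference n_rel = |m_max - m_EA| / |m_max|."""
    m_max = np.asarray(m_max, dtype=bool)
    m_ea = np.asarray(m_ea, dtype=bool)
    n_max = int(m_max.sum())
    if n_max == 0:
        raise ValueError("m_max is empty")
    return float(np.sum(m_max ^ (m_ea & m_max)) / n_max)


def region_stats(chi: np.ndarray, region: np.ndarray, label: str = "") -> RegionStats:
    """Mean and sample standard deviation of chi over a region mask."""
    region = np.asarray(region, dtype=bool)
    vals = np.asarray(chi, dtype=float)[region]
    if vals.size == 0:
        raise ValueError("region mask is empty")
    std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return RegionStats(mean=float(vals.mean()), std=std,
                       count=int(vals.size), label=label)


def rim_mask(m_ea: np.ndarray, width: int = 6) -> np.ndarray:
    """Voxels of m_EA within ``width`` erosion steps of its surface.

    The mask is eroded ``width`` times with the 6-connected structuring
    element; the rim is the part of m_EA that erosion removed.  With
    ``width = 0`` the rim is empty; when the mask is thinner than twice
    the width the rim is the whole mask.
    """
    m_ea = np.asarray(m_ea, dtype=bool)
    if not m_ea.any():
        raise ValueError("m_EA is empty")
    if width <= 0:
        return np.zeros_like(m_ea)
    core = ndimage.binary_erosion(m_ea, ndimage.generate_binary_structure(3, 1),
                                  iterations=width)
    return m_ea & ~core


def region_shell_mask(region: np.ndarray, tissue: np.ndarray,
                      inner: int = 2, outer: int = 5) -> np.ndarray:
    """Tissue shell surrounding a region: dilation band ``inner``..``outer``.

    Used for local contrast measurements (region mean minus surrounding
    tissue mean), which are insensitive to the global reference.
    """
    st = ndimage.generate_binary_structure(3, 1)
    region = np.asarray(region, dtype=bool)
    shell = (ndimage.binary_dilation(region, st, iterations=outer)
             & ~ndimage.binary_dilation(region, st, iterations=inner))
    return shell & np.asarray(tissue, dtype=bool)


def rmse_offset_corrected(chi: np.ndarray, chi_true: np.ndarray,
                          mask: np.ndarray) -> float:
    """Root-mean-square error over a mask after removing the mean offset.

    The global constant offset between result and ground truth is
    subtracted first, since both maps are reference-less.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    resid = (np.asarray(chi, float) - np.asarray(chi_true, float))[mask]
    resid = resid - resid.mean()
    return float(np.sqrt(np.mean(resid**2)))
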