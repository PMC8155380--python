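"""Numerical head phantom: geometry, susceptibility, fields, and multi-echo signal.

The phantom is a simplified head at ultra-high field (7 T by default): a
spherical brain support ``m_max`` surrounded by a thin tissue gap and a
spherical bone shell, embedded in air.  Strong field distortions at the rim
of the brain support — the mechanism that produces erroneous phase regions
(EPRs) in vivo — come from air-filled cavities and a blood-filled bubble
placed near the inferior rim, plus a smooth random background field built
from solid spherical harmonics up to fifth order.  Three small spheres near
the centre imitate deep grey matter and serve as quantitative control
regions (R1 is the reference used throughout the evaluation).

The multi-echo gradient-echo signal is simulated per echo time t as
``S(t) = M0 * exp(-t/T2*) * exp(i * 2*pi*b*t)`` with complex Gaussian noise
added to both quadratures, and ``T2* = 1 / (1/T2 + ||grad b||)`` inside the
brain (0 elsewhere), so that steep field gradients also dephase the
magnitude as they do in real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .fieldmap import EchoSeries
from .harmonics import evaluate_ssh_field, n_basis
from .kernels import dipole_convolve
from .units import hz_per_ppm

__all__ = [
    "PhantomSpec", "LabelVolume", "GroundTruth", "InvalidSpecError",
    "LABELS", "build_geometry", "assign_susceptibility", "draw_ssh_coeffs",
    "simulate_field", "compute_t2star", "simulate_signal", "simulate_phantom",
    "true_local_field", "monte_carlo",
]

#: integer labels of the exhaustive, mutually exclusive tissue classes
LABELS = {
    "air": 0, "tissue": 1, "skull": 2, "cavity": 3, "bubble": 4,
    "R1": 5, "R2": 6, "R3": 7,
}


class InvalidSpecError(ValueError):
    """Raised when phantom geometry parameters are inconsistent."""


@dataclass
class PhantomSpec:
    """All parameters of the numerical head phantom.

    Susceptibilities are in ppm, times in seconds, lengths in voxels.
    Defaults reproduce the reference simulation conditions: a 128^3 grid,
    chi of 0.36 (air), -0.9 (skull), -0.7 (blood), -9.0 ppm (tissue) with
    control regions at tissue + 0.2 / 0.25 / 0.3 ppm, B0 = 7 T, uniform
    T2 = 80 ms, echoes at 4..52 ms, 1% complex noise, and a 5th-order
    solid-harmonic background with per-order coefficient standard
    deviations of 1, 1, 2.5e-3, 1.25e-4, 1.25e-7, 1.25e-8.
    """

    grid_shape: tuple = (128, 128, 128)
    brain_radius: float = 48.0
    skull_inner_radius: float = 50.0
    skull_outer_radius: float = 54.0
    cavity_radii: tuple = (8.0, 7.0)
    bubble_radius: float = 5.0
    region_radii: tuple = (6.0, 6.0, 6.0)
    #: absolute voxel coordinates of R1/R2/R3 centres; None -> defaults near
    #: the grid centre
    region_centers: Optional[tuple] = None
    #: absolute voxel coordinates of the cavities / bubble; None -> drawn at
    #: the inferior rim from ``rng_seed``
    cavity_centers: Optional[tuple] = None
    bubble_center: Optional[tuple] = None
    chi_air: float = 0.36
    chi_skull: float = -0.9
    chi_blood: float = -0.7
    chi_tissue: float = -9.0
    chi_R1: float = -9.0 + 0.2
    chi_R2: float = -9.0 + 0.25
    chi_R3: float = -9.0 + 0.3
    B0: float = 7.0
    T2: float = 0.080
    TEs: tuple = (0.004, 0.016, 0.028, 0.040, 0.052)
    sigma_noise: float = 0.01
    M0: float = 1.0
    ssh_order: int = 5
    ssh_coeff_std_per_order: tuple = (1.0, 1.0, 2.5e-3, 1.25e-4, 1.25e-7, 1.25e-8)
    rng_seed: int = 0

    @property
    def center(self):
        """Grid centre, the common origin of all spheres and of the SSH frame."""
        return tuple((n - 1) / 2.0 for n in self.grid_shape)

    @property
    def chi_by_label(self):
        return {
            LABELS["air"]: self.chi_air,
            LABELS["tissue"]: self.chi_tissue,
            LABELS["skull"]: self.chi_skull,
            LABELS["cavity"]: self.chi_air,
            LABELS["bubble"]: self.chi_blood,
            LABELS["R1"]: self.chi_R1,
            LABELS["R2"]: self.chi_R2,
            LABELS["R3"]: self.chi_R3,
        }

    @classmethod
    def scaled(cls, grid: int = 64, **overrides) -> "PhantomSpec":
        """A geometrically scaled-down spec (same tissue values and timing).

        All radii shrink with the grid so the phantom keeps its proportions;
        susceptibilities, field strength, echo times, noise level and the
        solid-harmonic coefficient spreads are left at their defaults.
        """
        f = grid / 128.0
        base = cls(
            grid_shape=(grid, grid, grid),
            brain_radius=48.0 * f,
            skull_inner_radius=50.0 * f,
            skull_outer_radius=54.0 * f,
            cavity_radii=(8.0 * f, 7.0 * f),
            bubble_radius=5.0 * f,
            region_radii=(6.0 * f,) * 3,
        )
        return replace(base, **overrides)

    def validate(self):
        if len(self.grid_shape) != 3 or any(n < 8 for n in self.grid_shape):
            raise InvalidSpecError("grid_shape must be a 3-D shape of >= 8 voxels per axis")
        for name in ("brain_radius", "skull_inner_radius", "skull_outer_radius",
                     "bubble_radius"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if any(r <= 0 for r in self.cavity_radii) or any(r <= 0 for r in self.region_radii):
            raise InvalidSpecError("all radii must be positive")
        if not (self.brain_radius < self.skull_inner_radius < self.skull_outer_radius):
            raise InvalidSpecError("need brain_radius < skull_inner < skull_outer")
        if len(self.TEs) < 1 or any(t <= 0 for t in self.TEs):
            raise InvalidSpecError("echo times must be positive")
        if list(self.TEs) != sorted(self.TEs):
            raise InvalidSpecError("echo times must be strictly increasing")
        if len(self.ssh_coeff_std_per_order) != self.ssh_order + 1:
            raise InvalidSpecError("need one coefficient std per SSH order 0..L")
        if any(s < 0 for s in self.ssh_coeff_std_per_order):
            raise InvalidSpecError("coefficient stds must be non-negative")


@dataclass
class LabelVolume:
    """Per-voxel tissue labels plus the geometric brain support mask."""

    labels: np.ndarray
    m_max: np.ndarray
    spec: PhantomSpec

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


@dataclass
class GroundTruth:
    """Everything the simulator knows that a measurement would not reveal."""

    chi: np.ndarray          # ppm
    b: np.ndarray            # Hz, b_ssh + b_dip
    b_ssh: np.ndarray        # Hz
    b_dip: np.ndarray        # Hz
    t2star: np.ndarray       # s, 0 outside brain
    m0: np.ndarray           # equilibrium magnetization (1 in non-air tissue)
    labels: LabelVolume
    ssh_coeffs: np.ndarray

    def phase_true(self, te: float) -> np.ndarray:
        """Unwrapped true phase 2*pi*b*t at echo time ``te`` (radians)."""
        return 2.0 * np.pi * self.b * te


def _sphere_mask(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2


def _draw_rim_position(rng, spec, radius, margin=0.5):
    """Centre for a rim structure: random direction in the inferior half,
    tangent to the brain sphere from outside (the source is external to
    m_max but its near field reaches across the rim)."""
    dist = spec.brain_radius + radius + margin
    # polar angle biased toward the -z pole (inferior), azimuth uniform
    cos_t = rng.uniform(-1.0, -0.3)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    sin_t = np.sqrt(1.0 - cos_t**2)
    d = np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return tuple(c + dist * di for c, di in zip(spec.center, d))


def build_geometry(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the phantom's spheres into an exhaustive label volume.

    The brain support ``m_max`` is the geometric brain sphere; cavities and
    the bubble straddle its inferior rim (their centres are drawn from
    ``spec.rng_seed`` when not given explicitly), the control regions R1-R3
    sit strictly inside the brain.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    center = spec.center
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 101]))

    cav_centers = spec.cavity_centers
    if cav_centers is None:
        cav_centers = tuple(_draw_rim_position(rng, spec, r) for r in spec.cavity_radii)
    bub_center = spec.bubble_center
    if bub_center is None:
        bub_center = _draw_rim_position(rng, spec, spec.bubble_radius)

    reg_centers = spec.region_centers
    if reg_centers is None:
        off = 0.30 * spec.brain_radius
        reg_centers = (
            tuple(np.add(center, (-off, 0.0, 0.0))),
            tuple(np.add(center, (off, 0.0, 0.0))),
            tuple(np.add(center, (0.0, off, 0.0))),
        )

    # -- validation of placements ------------------------------------------
    # R1-R3 must sit strictly inside the brain, clear of the skull; the rim
    # structures must be external to the brain support (they may carve into
    # the tissue gap and the bone shell, and may be clipped by the grid)
    c0 = np.asarray(center)
    for i in range(3):
        ctr = np.asarray(reg_centers[i])
        rad = spec.region_radii[i]
        if np.any(ctr - rad < 0) or np.any(ctr + rad > np.asarray(shape) - 1):
            raise InvalidSpecError(f"R{i + 1} extends outside the grid")
        if np.linalg.norm(ctr - c0) + rad > spec.skull_inner_radius:
            raise InvalidSpecError(f"R{i + 1} overlaps the skull shell")
        if np.linalg.norm(ctr - c0) + rad > spec.brain_radius:
            raise InvalidSpecError(f"R{i + 1} must lie strictly inside the brain sphere")
    for name, ctr, rad in ([("cavity", c, r) for c, r in zip(cav_centers, spec.cavity_radii)]
                           + [("bubble", bub_center, spec.bubble_radius)]):
        if np.linalg.norm(np.asarray(ctr) - c0) - rad < spec.brain_radius:
            raise InvalidSpecError(f"{name} overlaps the brain support m_max")

    labels = np.zeros(shape, dtype=np.uint8)
    head = _sphere_mask(shape, center, spec.skull_inner_radius)
    skull = _sphere_mask(shape, center, spec.skull_outer_radius) & ~head
    labels[head] = LABELS["tissue"]
    labels[skull] = LABELS["skull"]
    for c, r in zip(cav_centers, spec.cavity_radii):
        labels[_sphere_mask(shape, c, r)] = LABELS["cavity"]
    labels[_sphere_mask(shape, bub_center, spec.bubble_radius)] = LABELS["bubble"]
    for i, (c, r) in enumerate(zip(reg_centers, spec.region_radii)):
        m = _sphere_mask(shape, c, r)
        if np.any(labels[m] != LABELS["tissue"]):
            raise InvalidSpecError(f"R{i + 1} overlaps another structure")
        labels[m] = LABELS["R%d" % (i + 1)]

    m_max = _sphere_mask(shape, center, spec.brain_radius)
    n_comp = ndimage.label(m_max)[1]
    if n_comp != 1:
        raise InvalidSpecError("brain support is not a single connected component")
    resolved = replace(spec, cavity_centers=tuple(map(tuple, cav_centers)),
                       bubble_center=tuple(bub_center),
                       region_centers=tuple(map(tuple, reg_centers)))
    return LabelVolume(labels=labels, m_max=m_max, spec=resolved)


def assign_susceptibility(labels: LabelVolume, spec: Optional[PhantomSpec] = None) -> np.ndarray:
    """Per-voxel susceptibility (ppm) looked up from the label's tissue class."""
    spec = spec or labels.spec
    chi = np.zeros(labels.labels.shape, dtype=float)
    table = spec.chi_by_label
    present = np.unique(labels.labels)
    unknown = set(present.tolist()) - set(table)
    if unknown:
        raise ValueError(f"unknown labels present: {sorted(unknown)}")
    for lab in present:
        chi[labels.labels == lab] = table[int(lab)]
    return chi


def draw_ssh_coeffs(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian solid-harmonic coefficients, one std per order."""
    coeffs = np.empty(n_basis(spec.ssh_order))
    for l, std in enumerate(spec.ssh_coeff_std_per_order):
        coeffs[l * l:(l + 1) * (l + 1)] = rng.normal(0.0, std, 2 * l + 1)
    return coeffs


def simulate_field(chi: np.ndarray, ssh_coeffs, spec: PhantomSpec):
    """True field b = b_SSH + b_Dipole in Hz.

    The dipole part is the FFT convolution of the susceptibility map (ppm)
    with the unit dipole kernel, scaled by the Larmor frequency per ppm;
    the harmonic part is the solid-harmonic expansion evaluated on the grid
    (coefficients carry Hz units).
    """
    chi = np.asarray(chi, dtype=float)
    if chi.shape != tuple(spec.grid_shape):
        raise ValueError("susceptibility volume does not match spec.grid_shape")
    b_dip = hz_per_ppm(spec.B0) * dipole_convolve(chi, pad=True)
    b_ssh = evaluate_ssh_field(chi.shape, np.asarray(ssh_coeffs, float), origin=spec.center)
    return b_ssh + b_dip, b_ssh, b_dip


def compute_t2star(b: np.ndarray, spec: PhantomSpec, brain_mask: np.ndarray) -> np.ndarray:
    """Effective transverse relaxation  T2* = 1 / (1/T2 + ||grad b||).

    The gradient is the central-difference gradient of the field in
    Hz/voxel, read as a dephasing rate in 1/s; T2* is set to 0 outside the
    brain.  Monotone: steeper local field, shorter T2*, never above T2.
    """
    grads = np.gradient(np.asarray(b, dtype=float))
    gnorm = np.sqrt(sum(g * g for g in grads))
    t2star = 1.0 / (1.0 / spec.T2 + gnorm)
    t2star[~brain_mask] = 0.0
    return t2star


def simulate_signal(gt: GroundTruth, spec: PhantomSpec,
                    rng: Optional[np.random.Generator] = None,
                    add_noise: bool = True) -> EchoSeries:
    """Complex gradient-echo signal at every echo time, optionally noisy.

    Noise is complex Gaussian with standard deviation ``sigma_noise``
    (relative to M0 = 1) per quadrature, independent across voxels and
    echoes.  Voxels with T2* = 0 have no coherent signal.
    """
    if any(t < 0 for t in spec.TEs):
        raise ValueError("negative echo time")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 103]))
    shape = gt.b.shape
    n_echo = len(spec.TEs)
    mag = np.empty((n_echo,) + shape, dtype=float)
    phase = np.empty((n_echo,) + shape, dtype=float)
    alive = gt.t2star > 0
    for e, te in enumerate(spec.TEs):
        decay = np.zeros(shape)
        decay[alive] = np.exp(-te / gt.t2star[alive])
        s = gt.m0 * decay * np.exp(1j * 2.0 * np.pi * gt.b * te)
        if add_noise and spec.sigma_noise > 0:
            s = s + spec.sigma_noise * (rng.standard_normal(shape)
                                        + 1j * rng.standard_normal(shape))
        mag[e] = np.abs(s)
        phase[e] = np.angle(s)
    return EchoSeries(phase=phase, magnitude=mag, tes=np.asarray(spec.TEs, float))


def simulate_phantom(spec: PhantomSpec, add_noise: bool = True):
    """Full simulation: geometry -> chi -> field -> T2* -> signal.

    Returns ``(series, gt)``; identical specs give bit-identical results.
    """
    spec.validate()
    labels = build_geometry(spec)
    chi = assign_susceptibility(labels)
    coeff_rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 102]))
    coeffs = draw_ssh_coeffs(spec, coeff_rng)
    b, b_ssh, b_dip = simulate_field(chi, coeffs, spec)
    t2star = compute_t2star(b, spec, labels.m_max)
    m0 = np.where(labels.labels != LABELS["air"], spec.M0, 0.0)
    m0[labels.mask("cavity")] = 0.0
    gt = GroundTruth(chi=chi, b=b, b_ssh=b_ssh, b_dip=b_dip, t2star=t2star,
                     m0=m0, labels=labels, ssh_coeffs=coeffs)
    series = simulate_signal(gt, spec, add_noise=add_noise)
    return series, gt


def true_local_field(gt: GroundTruth) -> np.ndarray:
    """Ground-truth local field (Hz): dipole field of the sources inside m_max.

    This is what a perfect background removal would leave behind — the
    reference input for evaluating the susceptibility inversion in
    isolation.
    """
    spec = gt.labels.spec
    chi_int = np.where(gt.labels.m_max, gt.chi, 0.0)
    return hz_per_ppm(spec.B0) * dipole_convolve(chi_int, pad=True)


def monte_carlo(spec: PhantomSpec, n_instances: int, add_noise: bool = True):
    """Monte-Carlo set: ``n_instances`` phantoms with randomized cavity and
    bubble positions and fresh solid-harmonic coefficients.

    Child seeds are drawn from ``spec.rng_seed`` and stored in each
    instance's resolved spec (``gt.labels.spec``) for exact replay.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    master = np.random.default_rng(int(spec.rng_seed))
    seeds = master.integers(0, 2**31 - 1, size=n_instances)
    out = []
    for s in seeds:
        inst_spec = replace(spec, rng_seed=int(s), cavity_centers=None,
                            bubble_center=None)
        out.append(simulate_phantom(inst_spec, add_noise=add_noise))
    return out
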