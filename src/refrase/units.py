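"""Unit conventions shared across the package.

Field maps are stored in Hz, susceptibility in ppm.  The conversion between
the two goes through the proton Larmor frequency of the main field:
``b [Hz] = f0 * 1e-6 * (chi_ppm * d)`` with ``f0 = gamma/2pi * B0``.
"""

GAMMA_BAR_HZ_PER_T = 42.577e6
"""Proton gyromagnetic ratio over 2*pi, in Hz/T."""


def larmor_hz(b0_tesla: float) -> float:
    """Proton Larmor frequency f0 = (gamma/2pi) * B0 in Hz."""
    return GAMMA_BAR_HZ_PER_T * b0_tesla


def hz_per_ppm(b0_tesla: float) -> float:
    """Field shift in Hz produced by a susceptibility-induced shift of 1 ppm.

    At 7 T this is about 298.04 Hz/ppm.
    """
    return larmor_hz(b0_tesla) * 1e-6
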