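"""Unit conventions and conversion helpers.

Gradients are gamma-normalized throughout the package: amplitudes carry
units of Hz/m and slew rates Hz/m/s, following the public Pulseq
convention.  Conversions to engineering units (mT/m, T/m/s) assume the
proton gyromagnetic ratio.
"""

GAMMA_HZ_PER_T = 42.576e6
"""Proton gyromagnetic ratio gamma/2pi in Hz/T."""


def mtm_to_hzm(g_mt_per_m: float) -> float:
    """Convert a gradient amplitude from mT/m to gamma-normalized Hz/m."""
    return g_mt_per_m * 1e-3 * GAMMA_HZ_PER_T


def hzm_to_mtm(g_hz_per_m: float) -> float:
    """Convert a gradient amplitude from Hz/m to mT/m."""
    return g_hz_per_m / GAMMA_HZ_PER_T * 1e3


def tms_to_hzms(slew_t_per_m_s: float) -> float:
    """Convert a slew rate from T/m/s to Hz/m/s."""
    return slew_t_per_m_s * GAMMA_HZ_PER_T


def hzms_to_tms(slew_hz_per_m_s: float) -> float:
    """Convert a slew rate from Hz/m/s to T/m/s."""
    return slew_hz_per_m_s / GAMMA_HZ_PER_T
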