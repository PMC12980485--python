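"""Pinned physical constants and spectrometer conventions.

Every relaxation-rate prediction in this package traces back to the values
below.  They are collected in one table (rather than pulled from
``scipy.constants``) so that a report can state, number by number, exactly
which conventions produced a given rate — reproducing a relaxation analysis
hinges on agreeing about these.
"""

from __future__ import annotations

import math

#: Reduced Planck constant (J s).
HBAR = 1.0546e-34

#: mu_0 / 4 pi (T^2 m^3 J^-1).
MU0_OVER_4PI = 1e-7

#: Boltzmann constant (J K^-1).
K_B = 1.3807e-23

#: 1H gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_H = 2.6752e8

#: 19F gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_F = 2.5181e8

#: Proton Larmor frequency of the spectrometer (Hz).  "400 MHz instrument"
#: fixes the static field; the 19F frequency follows from the ratio of
#: gyromagnetic ratios (~376.5 MHz).
PROTON_FREQ_HZ = 400.0e6

#: Static field (T) implied by the proton frequency.
B0 = 2 * math.pi * PROTON_FREQ_HZ / GAMMA_H

#: Viscosity of water at 298 K (Pa s).
WATER_VISCOSITY_298K = 8.9e-4


def larmor_omega(gamma: float, b0: float = B0) -> float:
    """Angular Larmor frequency (rad s^-1) for a gyromagnetic ratio at field b0."""
    return gamma * b0


def constants_table() -> dict[str, float]:
    """All pinned constants as a flat dict, for report provenance blocks."""
    return {
        "hbar_J_s": HBAR,
        "mu0_over_4pi": MU0_OVER_4PI,
        "k_B_J_per_K": K_B,
        "gamma_H_rad_per_s_T": GAMMA_H,
        "gamma_F_rad_per_s_T": GAMMA_F,
        "proton_freq_Hz": PROTON_FREQ_HZ,
        "B0_T": B0,
        "water_viscosity_298K_Pa_s": WATER_VISCOSITY_298K,
    }
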