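"""Physical constants in the package's internal unit system.

Internal units are angstrom (length), femtosecond (time), atomic mass
unit (mass) and elementary charge (charge).  The derived energy unit is
``amu * A**2 / fs**2`` (exactly 1e4 kJ/mol).  All spectra are reported on
a wavenumber axis in cm^-1, converted from angular frequency by
``nu_tilde = omega / (2 * pi * c)``.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _sc

#: speed of light in cm / fs
C_CM_PER_FS: float = _sc.c * 100.0 * 1e-15

#: Boltzmann constant in amu A^2 fs^-2 K^-1
KB: float = _sc.k / (_sc.atomic_mass * 1e-20 / 1e-30)

#: internal energy unit expressed in kJ/mol (= 1e4)
ENERGY_KJMOL: float = _sc.atomic_mass * 1e-20 / 1e-30 * _sc.N_A / 1000.0

#: vacuum permittivity in e^2 fs^2 amu^-1 A^-3
EPSILON_0: float = _sc.epsilon_0 / (
    _sc.e**2 / (_sc.atomic_mass * 1e-20 / 1e-30 * 1e-10)
)


def omega_to_wavenumber(omega: np.ndarray | float) -> np.ndarray | float:
    """Angular frequency in rad/fs -> wavenumber in cm^-1."""
    return omega / (2.0 * np.pi * C_CM_PER_FS)


def wavenumber_to_omega(nu: np.ndarray | float) -> np.ndarray | float:
    """Wavenumber in cm^-1 -> angular frequency in rad/fs."""
    return nu * 2.0 * np.pi * C_CM_PER_FS


def frequency_to_wavenumber(f: np.ndarray | float) -> np.ndarray | float:
    """Ordinary frequency in cycles/fs -> wavenumber in cm^-1."""
    return f / C_CM_PER_FS
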