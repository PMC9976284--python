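"""Physical constants and unit conversions.

All factors are derived from CODATA values via :mod:`scipy.constants` at
import time, so every conversion pair composes to identity to machine
precision.  Conventions used throughout the package:

* coordinates are stored in Å externally and converted to Bohr at module
  boundaries,
* masses are stored in amu and converted to electron masses (mₑ) before
  any Hessian mass-weighting, so that mass-weighted Hessian eigenvalues
  come out in Hartree·mₑ⁻¹·Bohr⁻², and
* harmonic wavenumbers are reported in cm⁻¹ with negative sign encoding
  imaginary frequencies.
"""

from __future__ import annotations

import math

import scipy.constants as _c

# -- length ----------------------------------------------------------------
BOHR_TO_ANGSTROM: float = _c.value("Bohr radius") / _c.angstrom
ANGSTROM_TO_BOHR: float = 1.0 / BOHR_TO_ANGSTROM

# -- mass ------------------------------------------------------------------
AMU_TO_ELECTRON_MASS: float = _c.value("atomic mass constant") / _c.m_e
ELECTRON_MASS_TO_AMU: float = 1.0 / AMU_TO_ELECTRON_MASS

# -- energy ----------------------------------------------------------------
HARTREE_TO_EV: float = _c.value("Hartree energy in eV")
EV_TO_HARTREE: float = 1.0 / HARTREE_TO_EV
HARTREE_TO_JOULE: float = _c.value("Hartree energy")

# E = h c ν̃  →  1 Hartree in cm⁻¹
HARTREE_TO_WAVENUMBER: float = HARTREE_TO_JOULE / (_c.h * _c.c) / 100.0
WAVENUMBER_TO_HARTREE: float = 1.0 / HARTREE_TO_WAVENUMBER
EV_TO_WAVENUMBER: float = EV_TO_HARTREE * HARTREE_TO_WAVENUMBER
WAVENUMBER_TO_EV: float = 1.0 / EV_TO_WAVENUMBER

# hc in eV·nm; fixed at the printed CODATA value used for photon
# energy/wavelength interconversion.
HC_EV_NM: float = 1239.84198

# √(Hartree / (mₑ·Bohr²)) is an angular frequency in atomic units
# (Hartree/ħ); dividing by 2πc gives the wavenumber factor below.
_OMEGA_AU = HARTREE_TO_JOULE / _c.hbar  # 1 au of angular frequency, s⁻¹
SQRT_EIGENVALUE_TO_WAVENUMBER: float = _OMEGA_AU / (2.0 * math.pi * _c.c) / 100.0

# Boltzmann constant in Hartree/K, handy for thermal sampling.
KB_HARTREE_PER_K: float = _c.k / HARTREE_TO_JOULE


def ev_to_nm(energy_ev: float) -> float:
    """Photon energy (eV) → vacuum wavelength (nm), λ = hc/E.

    Raises
    ------
    ValueError
        If ``energy_ev`` is not strictly positive.
    """
    if energy_ev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_ev} eV")
    return HC_EV_NM / energy_ev


def nm_to_ev(wavelength_nm: float) -> float:
    """Vacuum wavelength (nm) → photon energy (eV), E = hc/λ."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm} nm")
    return HC_EV_NM / wavelength_nm


def eigenvalue_to_wavenumber(eigenvalue: float) -> float:
    """Mass-weighted Hessian eigenvalue (Hartree·mₑ⁻¹·Bohr⁻²) → cm⁻¹.

    Negative eigenvalues (imaginary frequencies) map to negative
    wavenumbers: ν̃ = sign(λ)·√|λ|·C.
    """
    return math.copysign(math.sqrt(abs(eigenvalue)), eigenvalue) * SQRT_EIGENVALUE_TO_WAVENUMBER


def wavenumber_to_eigenvalue(wavenumber: float) -> float:
    """Inverse of :func:`eigenvalue_to_wavenumber`."""
    x = wavenumber / SQRT_EIGENVALUE_TO_WAVENUMBER
    return math.copysign(x * x, wavenumber)
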