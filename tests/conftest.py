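"""Shared fixtures: analytic molecules with known spectra and closed-form
reference systems used as oracles throughout the suite."""

from __future__ import annotations

import numpy as np
import pytest

from resoraman.core import HessianMatrix, MolecularStructure
from resoraman.toy_models import make_harmonic_molecule


@pytest.fixture(scope="session")
def toy5():
    """5-atom molecule with prescribed spectrum 400–1900 cm⁻¹ (9 modes)."""
    freqs = np.linspace(400.0, 1900.0, 9)
    structure, hessian, modes = make_harmonic_molecule(5, freqs, seed=3)
    return structure, hessian, modes, freqs


@pytest.fixture(scope="session")
def toy3():
    """Small bent 3-atom molecule, 3 vibrational modes."""
    freqs = np.array([1000.0, 1500.0, 2000.0])
    structure, hessian, modes = make_harmonic_molecule(3, freqs, seed=11)
    return structure, hessian, modes, freqs


def diatomic(k: float, m1: float, m2: float, bond: float = 1.2):
    """Two atoms on the z axis with a pure-stretch Hessian of force
    constant ``k`` (Hartree/Bohr²): H = k·BᵀB with B the bond-length
    gradient, so the single vibration is ν̃ = (1/2πc)·√(k/μ)."""
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, bond]])
    structure = MolecularStructure(["X1", "X2"], coords, np.array([m1, m2]))
    u = np.array([0.0, 0.0, 1.0])
    b = np.concatenate([-u, u])  # d(bond length)/dx, unitless direction
    hessian = HessianMatrix(k * np.outer(b, b), 2)
    return structure, hessian


# MolecularStructure validates labels only through masses, which we set
# explicitly above, so the placeholder symbols X1/X2 are fine.
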