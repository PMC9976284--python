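"""Analytic fixture generators: every pipeline stage is testable with no
quantum-chemistry engine and no external data.

Three ingredients:

* molecules with Hessians synthesized spectrally from a prescribed
  frequency list, so full diagonalization must recover known answers;
* a sum-over-states (resonance-pole) polarizability with closed-form
  geometric derivatives, standing in for an electronic-structure
  calculator while remaining exactly differentiable; and
* seeded harmonic trajectories with classical thermal displacements
  along the normal coordinates, emulating uncorrelated MD snapshots.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .core import FrameSet, HessianMatrix, MolecularStructure, NormalModeSet
from .units import (
    AMU_TO_ELECTRON_MASS,
    ANGSTROM_TO_BOHR,
    BOHR_TO_ANGSTROM,
    EV_TO_WAVENUMBER,
    KB_HARTREE_PER_K,
    HARTREE_TO_EV,
    wavenumber_to_eigenvalue,
)
from .vibrations import transrot_basis

__all__ = [
    "make_harmonic_molecule",
    "pole_polarizability",
    "pole_polarizability_calculator",
    "mode_coordinate",
    "linear_coupling_toy",
    "make_synthetic_trajectory",
]

_TOY_ELEMENTS = ("C", "O", "N", "C", "H")


def make_harmonic_molecule(
    n_atoms: int,
    frequencies_cm1,
    seed: int,
) -> tuple[MolecularStructure, HessianMatrix, NormalModeSet]:
    """Molecule with a Hessian built to have exactly the given spectrum.

    A seeded non-degenerate geometry is drawn; a random mass-weighted
    orthonormal basis orthogonal to translation/rotation carries
    eigenvalues λ_k matching ``frequencies_cm1`` (negative wavenumbers
    give negative curvature); the Hessian is M^(1/2)·L·diag(λ)·Lᵀ·M^(1/2).
    Diagonalizing it recovers the input frequencies — the
    construction-by-spectrum oracle used throughout the test suite.
    """
    freqs = np.atleast_1d(np.asarray(frequencies_cm1, float))
    n_vib = 3 * n_atoms - 6
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms for a nonlinear toy molecule")
    if freqs.size != n_vib:
        raise ValueError(
            f"expected {n_vib} frequencies for {n_atoms} atoms, got {freqs.size}"
        )
    rng = np.random.default_rng(seed)
    # spread-out geometry; retry until safely non-collinear
    for _ in range(100):
        coords = rng.uniform(-1.5, 1.5, size=(n_atoms, 3))
        coords *= 1.4  # ~bond-length scale in Å
        s = np.linalg.svd(coords - coords.mean(axis=0), compute_uv=False)
        if s[1] > 0.3 * s[0] and s[2] > 1e-2 * s[0]:
            break
    labels = [_TOY_ELEMENTS[i % len(_TOY_ELEMENTS)] for i in range(n_atoms)]
    structure = MolecularStructure.from_labels(labels, coords)

    tr = transrot_basis(structure)  # (6, 3N)
    n3 = 3 * n_atoms
    rand = rng.standard_normal((n3, n3))
    rand[: tr.shape[0]] = tr
    q, _ = np.linalg.qr(rand.T)  # first 6 columns span trans/rot
    vib_basis = q[:, tr.shape[0]:]  # (3N, n_vib) mass-weighted orthonormal

    lam = np.array([wavenumber_to_eigenvalue(f) for f in freqs])
    h_mw = vib_basis @ np.diag(lam) @ vib_basis.T
    sqrt_m = np.sqrt(np.repeat(structure.masses * AMU_TO_ELECTRON_MASS, 3))
    hessian = HessianMatrix(h_mw * np.outer(sqrt_m, sqrt_m), n_atoms)

    order = np.argsort(freqs)
    cart = (vib_basis / sqrt_m[:, None]).T[order]
    m_amu3 = np.repeat(structure.masses, 3)
    red = 1.0 / np.sum((vib_basis / np.sqrt(m_amu3)[:, None]) ** 2, axis=0)[order]
    modes = NormalModeSet(freqs[order], cart.reshape(n_vib, n_atoms, 3), red)
    return structure, hessian, modes


def pole_polarizability(
    excitation_energies_ev: np.ndarray,
    transition_dipoles: np.ndarray,
    incident_ev: float,
    damping_cm1: float,
) -> np.ndarray:
    """Sum-over-states α(ω) = Σ_j μ_j⊗μ_j·[ (E_j−ħω−iΓ)⁻¹ + (E_j+ħω+iΓ)⁻¹ ].

    Energies in eV, dipoles in au, damping in cm⁻¹ (converted to eV);
    the returned tensor is complex symmetric (outer products of real
    dipoles), in au up to the 1/eV energy denominator scale.
    """
    e = np.atleast_1d(np.asarray(excitation_energies_ev, float))
    mu = np.atleast_2d(np.asarray(transition_dipoles, float))
    if np.any(e <= 0):
        raise ValueError("excitation energies must be positive")
    gamma_ev = damping_cm1 / EV_TO_WAVENUMBER
    alpha = np.zeros((3, 3), dtype=complex)
    for ej, mj in zip(e, mu):
        denom_res = ej - incident_ev - 1j * gamma_ev
        denom_nr = ej + incident_ev + 1j * gamma_ev
        alpha += np.outer(mj, mj) * (1.0 / denom_res + 1.0 / denom_nr)
    return alpha


def pole_polarizability_calculator(
    excitation_energy_fn: Callable[[MolecularStructure], np.ndarray],
    transition_dipole_fn: Callable[[MolecularStructure], np.ndarray],
):
    """Wrap geometry-dependent state functions into a calculator.

    The returned callable satisfies the polarizability-calculator
    contract ``(structure, incident_ev, damping_cm1) → 3×3 complex``.
    """

    def calculator(structure: MolecularStructure, incident_ev: float,
                   damping_cm1: float) -> np.ndarray:
        return pole_polarizability(
            excitation_energy_fn(structure),
            transition_dipole_fn(structure),
            incident_ev,
            damping_cm1,
        )

    return calculator


def mode_coordinate(
    reference: MolecularStructure,
    modes: NormalModeSet,
    mode_index: int,
    structure: MolecularStructure,
) -> float:
    """Mass-weighted normal coordinate Q_k (Bohr·√mₑ) of a displaced
    geometry relative to ``reference``: Q_k = L_kᵀ·M^(1/2)·Δx."""
    lw = modes.mass_weighted_vectors(reference.masses[modes.active_atoms])
    dx = (structure.coords - reference.coords)[modes.active_atoms] * ANGSTROM_TO_BOHR
    sqrt_m = np.sqrt(reference.masses[modes.active_atoms] * AMU_TO_ELECTRON_MASS)
    return float(lw[mode_index] @ (dx * sqrt_m[:, None]).ravel())


def linear_coupling_toy(
    reference: MolecularStructure,
    modes: NormalModeSet,
    coupled_mode: int,
    e0_ev: float = 2.49,
    coupling_ev_per_q: float = 0.02,
    dipole=(1.0, 0.3, 0.1),
):
    """Single-state toy whose excitation energy is linear in one normal
    coordinate, so that mode dominates the RR spectrum.

    Returns ``(calculator, analytic_derivative)`` where the second is a
    closed-form dα/dQ_k at the reference geometry (chain rule through the
    pole), the oracle for finite-difference convergence tests.
    """
    mu = np.asarray(dipole, float)

    def e_fn(structure: MolecularStructure) -> np.ndarray:
        q = mode_coordinate(reference, modes, coupled_mode, structure)
        return np.array([e0_ev + coupling_ev_per_q * q])

    def mu_fn(structure: MolecularStructure) -> np.ndarray:
        return mu[None, :]

    calculator = pole_polarizability_calculator(e_fn, mu_fn)

    def analytic_derivative(mode_index: int, incident_ev: float,
                            damping_cm1: float) -> np.ndarray:
        """dα/dQ at the reference geometry; zero for uncoupled modes."""
        if mode_index != coupled_mode:
            return np.zeros((3, 3), dtype=complex)
        gamma_ev = damping_cm1 / EV_TO_WAVENUMBER
        de = coupling_ev_per_q
        d_res = e0_ev - incident_ev - 1j * gamma_ev
        d_nr = e0_ev + incident_ev + 1j * gamma_ev
        return np.outer(mu, mu) * (-de / d_res**2 - de / d_nr**2)

    return calculator, analytic_derivative


def make_synthetic_trajectory(
    structure: MolecularStructure,
    modes: NormalModeSet,
    temperature_k: float,
    n_frames: int,
    stride_ps: float = 1.0,
    seed: int = 0,
    random_rotation: bool = False,
) -> FrameSet:
    """Seeded harmonic pseudo-trajectory around ``structure``.

    Each frame displaces the geometry by independent Gaussian
    mass-weighted normal coordinates with the classical equipartition
    variance ⟨Q_k²⟩ = k_BT/ω_k², mapped to Cartesian via M^(−1/2)·L_k.
    ``random_rotation`` additionally applies a uniform random rigid
    rotation per frame (exercising the mode-rotation strategy).
    """
    if temperature_k < 0:
        raise ValueError("temperature must be nonnegative")
    if np.any(modes.wavenumbers <= 0):
        raise ValueError("synthetic trajectory requires all-real mode frequencies")
    rng = np.random.default_rng(seed)
    omega_au = np.sqrt(
        np.array([wavenumber_to_eigenvalue(w) for w in modes.wavenumbers])
    )
    sigma_q = (
        np.sqrt(KB_HARTREE_PER_K * temperature_k) / omega_au
        if temperature_k > 0
        else np.zeros_like(omega_au)
    )
    lw = modes.mass_weighted_vectors(structure.masses)  # (n_modes, 3N)
    inv_sqrt_m = 1.0 / np.sqrt(
        np.repeat(structure.masses * AMU_TO_ELECTRON_MASS, 3)
    )
    frames = []
    for _ in range(n_frames):
        q = rng.standard_normal(modes.n_modes) * sigma_q
        dx = (q @ lw) * inv_sqrt_m * BOHR_TO_ANGSTROM
        coords = structure.coords + dx.reshape(-1, 3)
        if random_rotation:
            rot = _random_rotation(rng)
            com = coords.mean(axis=0)
            coords = (coords - com) @ rot.T + com
        frames.append(structure.with_coords(coords))
    times = np.arange(n_frames) * stride_ps
    return FrameSet(frames, times)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
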