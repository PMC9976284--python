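"""Harmonic vibrational analysis on trajectory snapshots.

Two of the four normal-mode strategies live here:

* **A0** — full diagonalization of the snapshot Hessian, optionally after
  Eckart projection of overall translation/rotation.  Snapshots are not
  stationary points, so imaginary frequencies (negative wavenumbers) are
  expected data, not errors.
* **PHVA** — partial Hessian vibrational analysis: only the sub-block of
  the mass-weighted Hessian over a set of *active* atoms is diagonalized;
  the environment is frozen (treated as infinitely heavy).  Freezing
  breaks translational/rotational invariance, so no Eckart projection is
  applied by default.

All mass-weighting is done in electron masses so that eigenvalues are in
Hartree·mₑ⁻¹·Bohr⁻², converting directly to cm⁻¹.
"""

from __future__ import annotations

import numpy as np

from .core import HessianMatrix, MolecularStructure, NormalModeSet
from .units import (
    AMU_TO_ELECTRON_MASS,
    SQRT_EIGENVALUE_TO_WAVENUMBER,
)

__all__ = [
    "mass_weight",
    "transrot_basis",
    "eckart_project",
    "normal_modes_a0",
    "phva_modes",
    "count_imaginary",
]

#: modes with |ν̃| below this (cm⁻¹) are treated as projected-out
#: translation/rotation residue
TRANSROT_RESIDUE_CM1 = 1.0


def mass_weight(hessian: np.ndarray, masses_amu: np.ndarray) -> np.ndarray:
    """Scale H(i,j) by 1/√(mᵢmⱼ), masses converted amu → mₑ.

    ``masses_amu`` has one entry per atom; it is expanded ×3 over the
    Cartesian components.
    """
    masses_amu = np.asarray(masses_amu, float)
    if np.any(masses_amu <= 0):
        raise ValueError("all masses must be positive")
    m_e = np.repeat(masses_amu * AMU_TO_ELECTRON_MASS, 3)
    if hessian.shape != (m_e.size, m_e.size):
        raise ValueError(
            f"Hessian shape {hessian.shape} inconsistent with {masses_amu.size} atoms"
        )
    inv_sqrt = 1.0 / np.sqrt(m_e)
    return hessian * np.outer(inv_sqrt, inv_sqrt)


def transrot_basis(structure: MolecularStructure) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors, shape (k, 3N).

    k = 6 for nonlinear molecules, 5 for linear ones (detected from the
    moment-of-inertia rank), 3 for a single atom.
    """
    coords = structure.coords  # any length unit; only directions matter
    m = structure.masses * AMU_TO_ELECTRON_MASS
    n = structure.n_atoms
    com = m @ coords / m.sum()
    disp = coords - com
    sqrtm = np.sqrt(m)

    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = sqrtm
        vecs.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        r = np.cross(np.broadcast_to(e, (n, 3)), disp) * sqrtm[:, None]
        vecs.append(r.ravel())
    basis = np.array(vecs).T  # (3N, 6)
    # rank-revealing orthonormalization drops null rotations (atoms on an axis)
    q, s, _ = np.linalg.svd(basis, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    return q[:, :rank].T


def eckart_project(mw_hessian: np.ndarray, structure: MolecularStructure) -> np.ndarray:
    """Project overall translation/rotation out of a mass-weighted Hessian.

    Returns P·H·P with P = I − Σ|v⟩⟨v| over the orthonormal trans/rot
    basis; P is symmetric and idempotent by construction.
    """
    basis = transrot_basis(structure)  # (k, 3N)
    proj = np.eye(mw_hessian.shape[0]) - basis.T @ basis
    return proj @ mw_hessian @ proj


def _modes_from_mw_hessian(
    mw: np.ndarray,
    masses_amu: np.ndarray,
    active_atoms: np.ndarray,
    drop_count: int = 0,
    drop_tol_cm1: float = TRANSROT_RESIDUE_CM1,
) -> NormalModeSet:
    """Diagonalize a mass-weighted Hessian block and package the modes.

    ``drop_count`` smallest-|ν̃| modes are removed (projected null space);
    they must sit below ``drop_tol_cm1`` in magnitude or a ValueError
    advises reviewing the projection.
    """
    evals, evecs = np.linalg.eigh(mw)
    wn = np.sign(evals) * np.sqrt(np.abs(evals)) * SQRT_EIGENVALUE_TO_WAVENUMBER

    if drop_count:
        order = np.argsort(np.abs(wn))
        null_idx = order[:drop_count]
        if np.any(np.abs(wn[null_idx]) > drop_tol_cm1):
            bad = wn[null_idx][np.abs(wn[null_idx]) > drop_tol_cm1]
            raise ValueError(
                f"projected null-space modes not numerically zero "
                f"(|ν̃| up to {np.abs(bad).max():.3f} cm⁻¹ > {drop_tol_cm1}); "
                "review the projection / soft-coordinate specs"
            )
        keep = np.setdiff1d(np.arange(wn.size), null_idx)
        wn, evecs = wn[keep], evecs[:, keep]

    order = np.argsort(wn)
    wn = wn[order]
    L = evecs[:, order]  # columns mass-weighted-orthonormal

    m_e = np.repeat(masses_amu * AMU_TO_ELECTRON_MASS, 3)
    cart = (L / np.sqrt(m_e)[:, None]).T  # (n_modes, 3N) Cartesian direction
    # reduced mass: μ_k = 1 / Σ d², with d the Cartesian vector normalized
    # so that M^(1/2) d is a unit vector (masses in amu for the amu result)
    m_amu3 = np.repeat(masses_amu, 3)
    cart_amu = L / np.sqrt(m_amu3)[:, None]
    red = 1.0 / np.sum(cart_amu**2, axis=0)
    n_act = masses_amu.size
    return NormalModeSet(wn, cart.reshape(-1, n_act, 3), red, active_atoms)


def normal_modes_a0(
    hessian: HessianMatrix,
    structure: MolecularStructure,
    project_transrot: bool = True,
) -> NormalModeSet:
    """Strategy A0: diagonalize the snapshot Hessian as-is.

    With ``project_transrot`` the six (five if linear) overall-motion
    directions are Eckart-projected out first and the resulting
    null-space modes dropped.  Imaginary frequencies are returned as
    negative wavenumbers.
    """
    mw = mass_weight(hessian.matrix, structure.masses)
    drop = 0
    if project_transrot:
        basis = transrot_basis(structure)
        proj = np.eye(mw.shape[0]) - basis.T @ basis
        mw = proj @ mw @ proj
        drop = basis.shape[0]
    return _modes_from_mw_hessian(
        mw, structure.masses, np.arange(structure.n_atoms), drop_count=drop
    )


def phva_modes(
    hessian: HessianMatrix,
    structure: MolecularStructure,
    active_atoms: np.ndarray | list[int],
    project_transrot: bool = False,
) -> NormalModeSet:
    """Partial Hessian vibrational analysis over ``active_atoms``.

    The 3Nₐ×3Nₐ sub-block of the mass-weighted Hessian is diagonalized;
    frozen atoms never move, so the returned vectors span only the active
    atoms.  With the full atom set and projection off this reproduces
    :func:`normal_modes_a0` exactly.  ``project_transrot`` (off by
    default: the frozen environment breaks overall invariance) projects
    the *active-subsystem* translations/rotations.
    """
    active = np.asarray(active_atoms, dtype=int)
    if active.size == 0:
        raise ValueError("active_atoms must be nonempty")
    if active.size != np.unique(active).size:
        raise ValueError("active_atoms contains duplicates")
    if active.min() < 0 or active.max() >= structure.n_atoms:
        raise ValueError("active_atoms index out of range")

    idx3 = (3 * active[:, None] + np.arange(3)[None, :]).ravel()
    mw_full = mass_weight(hessian.matrix, structure.masses)
    mw = mw_full[np.ix_(idx3, idx3)]
    masses = structure.masses[active]

    drop = 0
    if project_transrot:
        sub = MolecularStructure(
            [structure.labels[i] for i in active], structure.coords[active], masses
        )
        basis = transrot_basis(sub)
        proj = np.eye(mw.shape[0]) - basis.T @ basis
        mw = proj @ mw @ proj
        drop = basis.shape[0]
    return _modes_from_mw_hessian(mw, masses, active, drop_count=drop)


def count_imaginary(
    modes: NormalModeSet,
    threshold_cm1: float = -TRANSROT_RESIDUE_CM1,
) -> tuple[int, np.ndarray]:
    """Count modes with ν̃ below ``threshold_cm1``.

    The default −1 cm⁻¹ ignores numerical-zero translation/rotation
    residue.  Returns ``(count, indices)``.
    """
    idx = np.flatnonzero(modes.wavenumbers < threshold_cm1)
    return idx.size, idx
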