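"""Strategy A2: reduced-dimensionality Hessian with soft (large-amplitude)
internal coordinates projected out.

Large-amplitude torsions — methyl and ammonium rotors, hydroxyl
dihedrals — are poorly described by a harmonic expansion at a
non-stationary snapshot and are the usual source of imaginary
frequencies.  Declaring them as soft coordinates, linearizing each as a
Wilson B row, and projecting the spanned subspace out of the
mass-weighted Hessian yields 3N−6−m well-behaved modes.

The projection is the linear (infinitesimal-displacement) realization:
uᵢ = M^(−1/2)·Bᵢᵀ, orthonormalized together with the translation/rotation
vectors; P = I − Σ|uᵢ⟩⟨uᵢ|; diagonalize P·H_mw·P and drop the null space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HessianMatrix, MolecularStructure, NormalModeSet
from .vibrations import _modes_from_mw_hessian, mass_weight, transrot_basis

__all__ = [
    "SoftCoordinateSpec",
    "dihedral_value",
    "wilson_b_row",
    "soft_mode_projector",
    "reduced_modes",
]


@dataclass(frozen=True)
class SoftCoordinateSpec:
    """A declared soft internal coordinate (proper dihedral only).

    ``atoms`` is the ordered quadruple (i, j, k, l) of 0-based indices;
    the dihedral is the angle between the (i,j,k) and (j,k,l) planes.
    """

    atoms: tuple[int, int, int, int]
    label: str = ""
    kind: str = "dihedral"

    def __post_init__(self) -> None:
        if self.kind != "dihedral":
            raise ValueError(f"unsupported soft-coordinate kind: {self.kind!r}")
        if len(self.atoms) != 4 or len(set(self.atoms)) != 4:
            raise ValueError(f"dihedral needs four distinct atom indices, got {self.atoms}")

    def validate(self, n_atoms: int) -> None:
        if min(self.atoms) < 0 or max(self.atoms) >= n_atoms:
            raise ValueError(
                f"soft coordinate {self.label or self.atoms}: index out of range "
                f"for {n_atoms} atoms"
            )


def _bond_vectors(structure: MolecularStructure, spec: SoftCoordinateSpec):
    i, j, k, l = spec.atoms
    x = structure.coords
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    if np.linalg.norm(b2) < 1e-10:
        raise ValueError(f"dihedral {spec.label or spec.atoms}: inner atoms coincide")
    f = np.cross(b1, b2)
    g = np.cross(b2, b3)
    if np.linalg.norm(f) < 1e-10 or np.linalg.norm(g) < 1e-10:
        raise ValueError(
            f"dihedral {spec.label or spec.atoms}: three consecutive atoms collinear"
        )
    return b1, b2, b3, f, g


def dihedral_value(structure: MolecularStructure, spec: SoftCoordinateSpec) -> float:
    """Signed dihedral angle in (−π, π], IUPAC sign convention.

    φ = atan2(|b₂|·b₁·(b₂×b₃), (b₁×b₂)·(b₂×b₃)); cis-planar → 0,
    trans-planar → π.
    """
    b1, b2, _, f, g = _bond_vectors(structure, spec)
    y = np.linalg.norm(b2) * np.dot(b1, g)
    x = np.dot(f, g)
    phi = float(np.arctan2(y, x))
    return np.pi if phi == -np.pi else phi


def wilson_b_row(structure: MolecularStructure, spec: SoftCoordinateSpec) -> np.ndarray:
    """Analytic gradient ∂φ/∂x of the dihedral: the Wilson s-vector row.

    Returns a 3N vector (units rad/Å) that is nonzero only on the four
    atoms and is orthogonal to rigid translations and infinitesimal
    rotations (the dihedral is a pure internal coordinate).
    """
    i, j, k, l = spec.atoms
    b1, b2, b3, f, g = _bond_vectors(structure, spec)
    nb2 = np.linalg.norm(b2)
    g1 = -nb2 / (f @ f) * f            # ∂φ/∂x_i
    g4 = nb2 / (g @ g) * g             # ∂φ/∂x_l
    t = (b1 @ b2) / (nb2 * nb2)
    u = (b3 @ b2) / (nb2 * nb2)
    g2 = -(1.0 + t) * g1 + u * g4      # ∂φ/∂x_j
    g3 = t * g1 - (1.0 + u) * g4       # ∂φ/∂x_k
    row = np.zeros(3 * structure.n_atoms)
    for idx, grad in zip((i, j, k, l), (g1, g2, g3, g4)):
        row[3 * idx:3 * idx + 3] = grad
    return row


def _orthonormalize(vectors: list[np.ndarray], labels: list[str],
                    n_fixed: int, rank_tol: float = 1e-8) -> np.ndarray:
    """Modified Gram–Schmidt with re-orthogonalization and rank check.

    The first ``n_fixed`` vectors (trans/rot) are assumed independent;
    a soft vector whose residual norm drops below ``rank_tol`` of its
    original norm is linearly dependent and reported by label.
    """
    basis: list[np.ndarray] = []
    dependent: list[str] = []
    for idx, v in enumerate(vectors):
        w = v / np.linalg.norm(v)
        for _ in range(2):  # second pass tightens orthogonality
            for b in basis:
                w = w - (b @ w) * b
        res = np.linalg.norm(w)
        if res < rank_tol:
            if idx < n_fixed:
                continue  # degenerate trans/rot already handled upstream
            dependent.append(labels[idx])
            continue
        basis.append(w / res)
    if dependent:
        raise ValueError(
            "soft coordinates linearly dependent after mass-weighting: "
            + ", ".join(dependent)
        )
    return np.array(basis)


def soft_mode_projector(
    structure: MolecularStructure,
    soft_specs: list[SoftCoordinateSpec],
    project_transrot: bool = True,
) -> tuple[np.ndarray, int]:
    """Build P = I − Σ|u⟩⟨u| over mass-weighted soft + trans/rot vectors.

    Returns ``(P, k)`` with k the dimension of the removed subspace.
    """
    n3 = 3 * structure.n_atoms
    fixed: list[np.ndarray] = []
    if project_transrot:
        fixed = list(transrot_basis(structure))
    sqrt_m = np.sqrt(np.repeat(structure.masses, 3))  # amu; unit cancels
    soft = []
    labels = ["trans/rot"] * len(fixed)
    for s in soft_specs:
        s.validate(structure.n_atoms)
        soft.append(wilson_b_row(structure, s) / sqrt_m)
        labels.append(s.label or str(s.atoms))
    basis = _orthonormalize(fixed + soft, labels, n_fixed=len(fixed))
    if basis.size == 0:
        return np.eye(n3), 0
    proj = np.eye(n3) - basis.T @ basis
    return proj, basis.shape[0]


def reduced_modes(
    hessian: HessianMatrix,
    structure: MolecularStructure,
    soft_specs: list[SoftCoordinateSpec],
    project_transrot: bool = True,
) -> NormalModeSet:
    """Diagonalize the Hessian with soft coordinates projected out.

    With an empty soft set this reduces to the full analysis (strategy
    A0) with the same projection flag.  The (6 + m) null-space modes are
    dropped after a sanity check that they sit below 1 cm⁻¹.
    """
    mw = mass_weight(hessian.matrix, structure.masses)
    proj, k = soft_mode_projector(structure, soft_specs, project_transrot)
    mw_red = proj @ mw @ proj
    return _modes_from_mw_hessian(
        mw_red, structure.masses, np.arange(structure.n_atoms), drop_count=k
    )
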