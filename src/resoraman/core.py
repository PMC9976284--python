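"""Domain types shared by every pipeline stage.

The containers are deliberately thin: NumPy arrays with validated shape
and unit metadata.  Coordinates are Å, masses amu, Hessians
Hartree/Bohr², wavenumbers cm⁻¹ (negative = imaginary mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .masses import mass_of

__all__ = [
    "MolecularStructure",
    "FrameSet",
    "HessianMatrix",
    "NormalModeSet",
]


@dataclass
class MolecularStructure:
    """Element labels, Cartesian coordinates (Å) and atomic masses (amu)."""

    labels: list[str]
    coords: np.ndarray  # (N, 3) Å
    masses: np.ndarray  # (N,) amu

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.labels)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with {n} labels"
            )
        if self.masses.shape != (n,):
            raise ValueError(
                f"masses shape {self.masses.shape} inconsistent with {n} labels"
            )
        if np.any(self.masses <= 0):
            raise ValueError("all atomic masses must be positive")

    @classmethod
    def from_labels(cls, labels: list[str], coords: np.ndarray) -> "MolecularStructure":
        """Build a structure filling masses from the bundled weight table."""
        masses = np.array([mass_of(s) for s in labels])
        return cls(list(labels), np.asarray(coords, float), masses)

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        """Copy with replaced coordinates (same labels/masses)."""
        return MolecularStructure(list(self.labels), np.asarray(coords, float),
                                  self.masses.copy())

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()


@dataclass
class FrameSet:
    """Ordered trajectory frames sharing one atom ordering.

    ``timestamps`` (ps) are optional; when absent, stride-based selection
    works in frame counts.
    """

    frames: list[MolecularStructure]
    timestamps: np.ndarray | None = None
    #: solvent-shell-trimmed sets legitimately differ in environment atoms;
    #: set False to skip the label-consistency check for those
    homogeneous: bool = True

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("FrameSet requires at least one frame")
        ref = self.frames[0]
        if self.homogeneous:
            for i, f in enumerate(self.frames[1:], start=1):
                if f.labels != ref.labels:
                    raise ValueError(
                        f"frame {i} label sequence differs from frame 0"
                    )
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (len(self.frames),):
                raise ValueError("timestamps length must match frame count")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> MolecularStructure:
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms


@dataclass
class HessianMatrix:
    """3N×3N Cartesian second-derivative matrix in Hartree/Bohr²."""

    matrix: np.ndarray
    atom_count: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n3 = 3 * self.atom_count
        if self.matrix.shape != (n3, n3):
            raise ValueError(
                f"Hessian shape {self.matrix.shape}, expected ({n3}, {n3}) "
                f"for {self.atom_count} atoms"
            )
        scale = max(np.abs(self.matrix).max(), 1.0)
        asym = np.abs(self.matrix - self.matrix.T).max() / scale
        if asym > 1e-8:
            raise ValueError(
                f"Hessian asymmetric beyond tolerance (relative asymmetry {asym:.2e}); "
                "symmetrize before constructing HessianMatrix"
            )
        self.matrix = 0.5 * (self.matrix + self.matrix.T)


@dataclass
class NormalModeSet:
    """Harmonic modes: wavenumbers (cm⁻¹, negative = imaginary), Cartesian
    displacement vectors, reduced masses (amu).

    ``vectors[k]`` is the (N, 3) Cartesian displacement of mode *k*, i.e.
    M^(−1/2)·L_k with L_k the mass-weighted-orthonormal eigenvector, so
    the vectors are *mass-weighted* orthonormal, not Euclidean.
    ``active_atoms`` lists the atom indices the modes span (all atoms for
    full analyses, a subset for partial-Hessian modes).
    """

    wavenumbers: np.ndarray          # (n_modes,) cm⁻¹
    vectors: np.ndarray              # (n_modes, N, 3) Cartesian, Å-direction
    reduced_masses: np.ndarray       # (n_modes,) amu
    active_atoms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.reduced_masses = np.asarray(self.reduced_masses, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[0] != self.wavenumbers.size:
            raise ValueError("vectors must be (n_modes, N, 3) matching wavenumbers")
        if self.active_atoms is None:
            self.active_atoms = np.arange(self.vectors.shape[1])
        else:
            self.active_atoms = np.asarray(self.active_atoms, dtype=int)
        if self.wavenumbers.size > 3 * self.active_atoms.size:
            raise ValueError("more modes than 3×|active atoms|")

    @property
    def n_modes(self) -> int:
        return self.wavenumbers.size

    def mass_weighted_vectors(self, masses_amu: np.ndarray) -> np.ndarray:
        """Return L_k = M^(1/2)·(Cartesian vectors), shape (n_modes, 3N).

        ``masses_amu`` must cover the atoms the vectors span (length
        ``vectors.shape[1]``). Mass unit cancels in orthonormality checks
        as long as the vectors were built with the same convention.
        """
        w = np.sqrt(np.asarray(masses_amu, float))
        lw = self.vectors * w[None, :, None]
        lw = lw.reshape(self.n_modes, -1)
        norms = np.linalg.norm(lw, axis=1)
        return lw / norms[:, None]

    def real_mode_indices(self) -> np.ndarray:
        return np.flatnonzero(self.wavenumbers > 0)
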