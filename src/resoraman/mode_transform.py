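"""Strategy A1: rigid-body superposition of a reference structure onto
each trajectory frame and rotation of the reference normal modes into
the frame's orientation.

The idea: computing a Hessian per snapshot is expensive, but if the
chromophore is conformationally stable its modes barely change from
frame to frame — only its orientation does.  A weighted Kabsch fit gives
the proper rotation R minimizing the RMSD between reference and frame;
applying R to every atomic displacement of every reference mode yields
frame-adapted modes at zero electronic-structure cost.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import MolecularStructure, NormalModeSet

logger = logging.getLogger(__name__)

__all__ = ["SuperpositionResult", "superpose", "rotate_modes", "apply_transform"]


@dataclass
class SuperpositionResult:
    """Best-fit rigid transform: frame ≈ R·(reference − c_ref) + c_frame.

    ``rotation`` is proper orthogonal (det = +1); ``translation`` maps a
    reference point x as R·x + translation.
    """

    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,) Å
    rmsd_before: float        # Å, after optimal translation only
    rmsd_after: float         # Å, after rotation too

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, float)
        if np.abs(r.T @ r - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")
        self.rotation = r
        self.translation = np.asarray(self.translation, float)

    @property
    def angle(self) -> float:
        """Rotation angle in radians, from the trace."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _weighted_rmsd(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.sum(w[:, None] * d * d) / w.sum()))


def superpose(
    reference: MolecularStructure,
    frame: MolecularStructure,
    weights: np.ndarray | None = None,
    allow_reflection: bool = False,
) -> SuperpositionResult:
    """Weighted least-squares rigid fit of ``reference`` onto ``frame``.

    Kabsch algorithm via SVD of the weighted covariance; the reflection
    branch is disabled unless ``allow_reflection`` (det forced +1 by
    flipping the smallest singular direction).  Atom correspondence is
    by index.  Collinear inputs produce a valid solution with a warning
    (rotation about the common axis is arbitrary; the SVD tie-break
    yields the smallest-angle choice).
    """
    if reference.n_atoms != frame.n_atoms:
        raise ValueError(
            f"atom count mismatch: reference {reference.n_atoms} vs frame {frame.n_atoms}"
        )
    n = reference.n_atoms
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative, length N, not all zero")

    p = reference.coords - (w @ reference.coords) / w.sum()
    q = frame.coords - (w @ frame.coords) / w.sum()

    cov = (w[:, None] * p).T @ q  # 3×3
    u, s, vt = np.linalg.svd(cov)
    # collinearity check: covariance rank < 2 leaves the fit underdetermined
    if s[0] > 0 and s[1] / s[0] < 1e-10:
        warnings.warn(
            "superpose: (near-)collinear atom set; rotation about the axis "
            "is arbitrary (smallest-angle tie-break used)",
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if allow_reflection:
        d = 1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    if s[0] > 0 and s[1] / s[0] < 1e-10:
        rot = _smallest_angle_about_axis(rot, p)

    rmsd_before = _weighted_rmsd(p, q, w)
    rmsd_after = _weighted_rmsd(p @ rot.T, q, w)
    trans = (w @ frame.coords) / w.sum() - rot @ ((w @ reference.coords) / w.sum())
    return SuperpositionResult(rot, trans, rmsd_before, rmsd_after)


def _smallest_angle_about_axis(rot: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Resolve the collinear degeneracy by the smallest total rotation.

    For a collinear reference, any spin about the molecular axis leaves
    the fit unchanged; pick the spin angle maximizing tr(R·Rot(a, θ)),
    i.e. minimizing the overall rotation angle.
    """
    # axis of the reference line (top right-singular vector of centered coords)
    _, _, vt_p = np.linalg.svd(p)
    a = vt_p[0]
    ax = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    c1 = np.trace(rot) - a @ rot @ a
    c2 = np.trace(rot @ ax)
    theta = np.arctan2(c2, c1)
    spin = (np.cos(theta) * np.eye(3)
            + (1 - np.cos(theta)) * np.outer(a, a)
            + np.sin(theta) * ax)
    return rot @ spin


def apply_transform(structure: MolecularStructure,
                    transform: SuperpositionResult) -> MolecularStructure:
    """Apply the rigid transform to a structure's coordinates."""
    new = structure.coords @ transform.rotation.T + transform.translation
    return structure.with_coords(new)


def rotate_modes(reference_modes: NormalModeSet,
                 transform: SuperpositionResult) -> NormalModeSet:
    """Rotate every mode's per-atom displacement by the fit rotation.

    Wavenumbers and reduced masses are untouched; mass-weighted
    orthonormality is preserved because the same orthogonal matrix acts
    on every atom.  The vectors are *not* re-orthogonalized against the
    frame's translation/rotation space — this is a pure rotation of the
    reference modes into the frame's orientation.
    """
    r = transform.rotation
    vecs = np.einsum("ab,knb->kna", r, reference_modes.vectors)
    return NormalModeSet(
        reference_modes.wavenumbers.copy(),
        vecs,
        reference_modes.reduced_masses.copy(),
        reference_modes.active_atoms.copy(),
    )
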