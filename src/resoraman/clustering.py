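"""Trajectory clustering into structural families and persistence weights.

Uncorrelated MD snapshots of a flexible chromophore fall into a handful
of conformational families.  Pairwise minimized RMSD over a chosen atom
selection feeds a greedy neighbor-count (GROMOS/Daura-style) clustering;
each family contributes one representative frame to the spectroscopy
pipeline, weighted by its persistence (fraction of frames it absorbs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FrameSet, MolecularStructure
from .mode_transform import superpose

__all__ = [
    "ClusterAssignment",
    "heavy_atom_indices",
    "rmsd_matrix",
    "cluster_frames",
    "select_snapshots",
]


@dataclass
class ClusterAssignment:
    """Cluster id per frame, representative frame per cluster, and the
    persistence fraction of each cluster (sums to 1)."""

    labels: np.ndarray          # (n_frames,) cluster id
    representatives: np.ndarray  # (n_clusters,) frame index
    persistence: np.ndarray     # (n_clusters,) fractions

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.representatives = np.asarray(self.representatives, dtype=int)
        self.persistence = np.asarray(self.persistence, dtype=float)
        if abs(self.persistence.sum() - 1.0) > 1e-12:
            raise ValueError("persistence fractions must sum to 1")
        for cid, rep in enumerate(self.representatives):
            if self.labels[rep] != cid:
                raise ValueError(f"representative {rep} not in its own cluster {cid}")

    @property
    def n_clusters(self) -> int:
        return self.representatives.size


def heavy_atom_indices(structure: MolecularStructure) -> np.ndarray:
    """Indices of non-hydrogen atoms (D counted as hydrogen isotope)."""
    return np.array(
        [i for i, lab in enumerate(structure.labels) if lab not in ("H", "D")],
        dtype=int,
    )


def _subset(structure: MolecularStructure, sel: np.ndarray) -> MolecularStructure:
    return MolecularStructure(
        [structure.labels[i] for i in sel], structure.coords[sel], structure.masses[sel]
    )


def rmsd_matrix(
    frames: FrameSet,
    selection: np.ndarray | list[int] | None = None,
    superpose_first: bool = True,
) -> np.ndarray:
    """Symmetric matrix of pairwise minimized RMSD (Å) over ``selection``.

    ``selection`` defaults to heavy atoms.  With ``superpose_first`` off
    the raw (translation-only-centered, unrotated) RMSD is used.
    """
    if selection is None:
        selection = heavy_atom_indices(frames[0])
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty atom selection for RMSD")
    subs = [_subset(f, sel) for f in frames.frames]
    n = len(subs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = superpose(subs[j], subs[i])
            mat[i, j] = mat[j, i] = res.rmsd_after if superpose_first else res.rmsd_before
    return mat


def cluster_frames(rmsd: np.ndarray, cutoff: float) -> ClusterAssignment:
    """Greedy neighbor-count clustering of a distance matrix.

    Repeatedly pick the unassigned frame with the most unassigned
    neighbors within ``cutoff`` (ties broken by lowest frame index) as a
    new representative; its neighborhood becomes the cluster.  Clusters
    are numbered in discovery order (largest first under this greedy
    rule); persistence = cluster size / total frames.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    rmsd = np.asarray(rmsd, float)
    n = rmsd.shape[0]
    if rmsd.shape != (n, n) or np.abs(rmsd - rmsd.T).max() > 1e-9:
        raise ValueError("rmsd must be a square symmetric matrix")
    neighbor = rmsd <= cutoff
    np.fill_diagonal(neighbor, True)

    labels = np.full(n, -1, dtype=int)
    reps: list[int] = []
    remaining = np.ones(n, dtype=bool)
    cid = 0
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        rep = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[rep] & remaining)
        labels[members] = cid
        reps.append(rep)
        remaining[members] = False
        cid += 1
    sizes = np.bincount(labels, minlength=cid).astype(float)
    return ClusterAssignment(labels, np.array(reps), sizes / n)


def select_snapshots(
    frames: FrameSet,
    stride: float = 1.0,
    shell_cutoff: float = np.inf,
    target_atoms: np.ndarray | list[int] | None = None,
    residue_ids: np.ndarray | list[int] | None = None,
    stride_in_ps: bool = False,
) -> FrameSet:
    """Decimate a trajectory and trim the environment to a solvent shell.

    Frames are kept at every ``stride`` (frame counts, or picoseconds
    when ``stride_in_ps`` and timestamps are present).  For each kept
    frame, environment residues whose atoms are *all* farther than
    ``shell_cutoff`` Å from every target atom are removed; a residue is
    kept whenever any of its atoms is within the cutoff of any target
    atom, so molecules are never broken.  ``residue_ids`` assigns each
    atom to a residue (default: every non-target atom its own residue);
    target atoms are always kept.
    """
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    n = len(frames)
    if stride_in_ps:
        if frames.timestamps is None:
            raise ValueError("stride in ps requires timestamps")
        keep_frames = []
        next_t = frames.timestamps[0]
        for i, t in enumerate(frames.timestamps):
            if t >= next_t - 1e-12:
                keep_frames.append(i)
                next_t = t + stride
    else:
        keep_frames = list(range(0, n, int(round(stride))))

    targets = (np.arange(frames.n_atoms) if target_atoms is None
               else np.asarray(target_atoms, dtype=int))
    rid = (np.arange(frames.n_atoms) if residue_ids is None
           else np.asarray(residue_ids, dtype=int))

    out: list[MolecularStructure] = []
    for i in keep_frames:
        s = frames[i]
        if not np.isfinite(shell_cutoff):
            out.append(s)
            continue
        d = np.linalg.norm(
            s.coords[:, None, :] - s.coords[None, targets, :], axis=-1
        ).min(axis=1)
        atom_keep = np.zeros(s.n_atoms, dtype=bool)
        atom_keep[targets] = True
        for r in np.unique(rid):
            mask = rid == r
            if np.any(d[mask] <= shell_cutoff):
                atom_keep |= mask
        sel = np.flatnonzero(atom_keep)
        out.append(_subset(s, sel))
    ts = None
    if frames.timestamps is not None:
        ts = frames.timestamps[keep_frames]
    homogeneous = len({tuple(s.labels) for s in out}) == 1
    return FrameSet(out, ts, homogeneous=homogeneous)
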