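"""Readers and writers: multi-frame XYZ, plain-text Hessians, mode files,
and two-column TSV spectra.

The Hessian file format is bespoke plain text (no interchange standard
exists for Cartesian Hessians): a header line ``hessian <N> <unit-tag>``
followed by 3N rows of 3N whitespace-separated floats, in Hartree/Bohr².
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np

from .core import FrameSet, HessianMatrix, MolecularStructure, NormalModeSet
from .masses import mass_of

logger = logging.getLogger(__name__)

__all__ = [
    "read_xyz", "write_xyz", "read_hessian", "write_hessian",
    "read_modes", "write_modes", "write_spectrum_tsv", "read_spectrum_tsv",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_xyz(path: str | Path) -> FrameSet:
    """Read a (multi-frame) XYZ file into a :class:`FrameSet`.

    Masses are filled from the bundled standard-atomic-weight table.
    Raises :class:`ParseError` naming the line for a malformed atom-count
    line, and a ``KeyError``-derived message for unknown element symbols.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[MolecularStructure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from None
        if i + 2 + natoms > len(lines):
            raise ParseError(
                f"{path}: line {i + 1}: frame declares {natoms} atoms but file ends early"
            )
        labels: list[str] = []
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            ln = i + 2 + a
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {ln + 1}: expected 'symbol x y z', got {lines[ln]!r}"
                )
            labels.append(parts[0])
            coords[a] = [float(p) for p in parts[1:4]]
        try:
            masses = np.array([mass_of(s) for s in labels])
        except KeyError as e:
            raise ParseError(f"{path}: {e.args[0]}") from None
        frames.append(MolecularStructure(labels, coords, masses))
        i += 2 + natoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return FrameSet(frames)


def write_xyz(path: str | Path, frames: FrameSet | MolecularStructure,
              comment: str = "") -> None:
    """Write one structure or a whole frame set as multi-frame XYZ."""
    if isinstance(frames, MolecularStructure):
        frames = FrameSet([frames])
    with open(path, "w") as fh:
        for k, s in enumerate(frames.frames):
            fh.write(f"{s.n_atoms}\n{comment or f'frame {k}'}\n")
            for lab, xyz in zip(s.labels, s.coords):
                fh.write(f"{lab:<3s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}\n")


def read_hessian(path: str | Path, atom_count: int | None = None) -> HessianMatrix:
    """Read a plain-text Hessian file.

    Asymmetry beyond 1e-6 relative logs a warning; beyond 1e-3 raises.
    The returned matrix is symmetrized as (H + Hᵀ)/2.
    """
    lines = Path(path).read_text().split("\n")
    header = lines[0].split()
    if len(header) < 2 or header[0].lower() != "hessian":
        raise ParseError(f"{path}: line 1: expected 'hessian <N> <unit-tag>' header")
    n_file = int(header[1])
    if atom_count is not None and n_file != atom_count:
        raise ParseError(
            f"{path}: expected Hessian for {atom_count} atoms, file declares {n_file}"
        )
    n3 = 3 * n_file
    values = np.loadtxt(lines[1:], ndmin=2)
    if values.shape != (n3, n3):
        raise ParseError(
            f"{path}: expected {n3}×{n3} matrix, found {values.shape[0]}×{values.shape[1]}"
        )
    scale = max(np.abs(values).max(), 1e-300)
    asym = np.abs(values - values.T).max() / scale
    if asym > 1e-3:
        raise ParseError(
            f"{path}: Hessian asymmetry {asym:.2e} exceeds 1e-3 — refusing to symmetrize"
        )
    if asym > 1e-6:
        logger.warning("%s: Hessian asymmetry %.2e beyond 1e-6; symmetrizing", path, asym)
    sym = 0.5 * (values + values.T)
    return HessianMatrix(sym, n_file)


def write_hessian(path: str | Path, hessian: HessianMatrix,
                  unit_tag: str = "hartree_bohr2") -> None:
    with open(path, "w") as fh:
        fh.write(f"hessian {hessian.atom_count} {unit_tag}\n")
        for row in hessian.matrix:
            fh.write(" ".join(f"{v:.12e}" for v in row) + "\n")


def write_modes(path: str | Path, modes: NormalModeSet) -> None:
    """Text mode file: one block per mode, wavenumber then N×3 vector."""
    with open(path, "w") as fh:
        fh.write(f"# modes {modes.n_modes} atoms {modes.vectors.shape[1]}\n")
        fh.write("# active_atoms " + " ".join(map(str, modes.active_atoms)) + "\n")
        for k in range(modes.n_modes):
            fh.write(f"mode {k} wavenumber_cm-1 {modes.wavenumbers[k]:.8f} "
                     f"reduced_mass_amu {modes.reduced_masses[k]:.10f}\n")
            for row in modes.vectors[k]:
                fh.write(f"  {row[0]:18.12f} {row[1]:18.12f} {row[2]:18.12f}\n")


def read_modes(path: str | Path) -> NormalModeSet:
    lines = Path(path).read_text().splitlines()
    head = lines[0].split()
    n_modes, n_atoms = int(head[2]), int(head[4])
    active = np.array([int(x) for x in lines[1].split()[2:]], dtype=int)
    wavenumbers = np.empty(n_modes)
    red = np.empty(n_modes)
    vecs = np.empty((n_modes, n_atoms, 3))
    i = 2
    for k in range(n_modes):
        parts = lines[i].split()
        wavenumbers[k] = float(parts[3])
        red[k] = float(parts[5])
        for a in range(n_atoms):
            vecs[k, a] = [float(x) for x in lines[i + 1 + a].split()]
        i += 1 + n_atoms
    return NormalModeSet(wavenumbers, vecs, red, active)


def write_spectrum_tsv(path: str | Path, grid: np.ndarray, intensity: np.ndarray,
                       metadata: dict | None = None) -> None:
    """Two-column TSV (wavenumber cm⁻¹, intensity) with '#' metadata header."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# wavenumber_cm-1\tintensity\n")
        for x, y in zip(grid, intensity):
            fh.write(f"{x:.4f}\t{y:.10e}\n")


def read_spectrum_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if line.strip():
            a, b = line.split("\t")
            xs.append(float(a))
            ys.append(float(b))
    return np.array(xs), np.array(ys), meta
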