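"""Resonance-Raman intensities from complex polarizability derivatives.

In the short-time approximation the RR intensity of mode *k* is governed
by the geometric derivative ∂α(ω)/∂Q_k of the complex frequency-dependent
polarizability, evaluated at the incident frequency with an electronic
damping (lifetime) Γ folded into the frequency argument.  The derivative
is taken by central finite difference: the geometry is displaced by
±step (default 0.001, in mass-weighted atomic units Bohr·√mₑ) along each
real-frequency normal mode and the calculator is evaluated at both.

The differential Stokes cross section uses the standard frequency
factors and rotational invariants,

    I_k ∝ (ν̃₀ − ν̃_k)³ · ν̃₀ · (45·a²_k + 7·γ²_k) / ν̃_k,

optionally with a thermal occupancy factor; spectra are max-normalized,
so all constant prefactors cancel and only relative intensities matter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import MolecularStructure, NormalModeSet
from .units import (
    AMU_TO_ELECTRON_MASS,
    ANGSTROM_TO_BOHR,
    BOHR_TO_ANGSTROM,
    EV_TO_WAVENUMBER,
    KB_HARTREE_PER_K,
    HARTREE_TO_WAVENUMBER,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PolarizabilityCalculator",
    "ComplexPolarizabilityDerivativeSet",
    "RamanSpectrum",
    "displace_along_mode",
    "polarizability_derivatives",
    "raman_invariants",
    "stick_spectrum",
    "convolve_lorentzian",
    "average_spectra",
]

#: calculator contract: (structure, incident_energy_eV, damping_cm⁻¹) → 3×3
#: complex symmetric tensor in atomic units
PolarizabilityCalculator = Callable[[MolecularStructure, float, float], np.ndarray]

_SYMMETRY_RTOL = 1e-8


def _check_symmetric(alpha: np.ndarray, context: str) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=complex)
    if alpha.shape != (3, 3):
        raise ValueError(f"{context}: polarizability must be 3×3, got {alpha.shape}")
    scale = max(np.abs(alpha).max(), 1e-300)
    if np.abs(alpha - alpha.T).max() / scale > _SYMMETRY_RTOL:
        raise ValueError(
            f"{context}: antisymmetric polarizability component beyond tolerance; "
            "the invariant formulas assume a symmetric tensor"
        )
    return 0.5 * (alpha + alpha.T)


@dataclass
class ComplexPolarizabilityDerivativeSet:
    """Per-mode complex tensors dα/dQ_k (au per Bohr·√mₑ) plus provenance."""

    tensors: np.ndarray            # (n_real_modes, 3, 3) complex
    mode_indices: np.ndarray       # indices into the parent NormalModeSet
    wavenumbers: np.ndarray        # cm⁻¹ of those modes
    incident_energy_ev: float
    damping_cm1: float
    step_used: float


@dataclass
class RamanSpectrum:
    """Broadened spectrum on a wavenumber grid plus the underlying sticks."""

    grid: np.ndarray               # cm⁻¹
    intensity: np.ndarray          # arbitrary units, ≥ 0
    sticks: list[tuple[float, float]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(self.intensity < 0):
            raise ValueError("spectral intensity must be nonnegative")

    def normalized(self) -> "RamanSpectrum":
        """Scale so the maximum intensity is exactly 1."""
        peak = self.intensity.max()
        if peak == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        meta = dict(self.metadata, normalized=True)
        sticks = [(w, i / peak) for w, i in self.sticks]
        return RamanSpectrum(self.grid, self.intensity / peak, sticks, meta)


def displace_along_mode(
    structure: MolecularStructure,
    modes: NormalModeSet,
    mode_index: int,
    step: float = 0.001,
) -> tuple[MolecularStructure, MolecularStructure]:
    """Geometries displaced ±step along one normal mode.

    ``step`` is in mass-weighted atomic units (Bohr·√mₑ); the Cartesian
    displacement is step·M^(−1/2)·L_k converted to Å.  Imaginary modes
    are rejected — they carry no RR intensity and must be excluded
    upstream.
    """
    if step < 0:
        raise ValueError("step must be nonnegative")
    if modes.wavenumbers[mode_index] <= 0:
        raise ValueError(
            f"mode {mode_index} has imaginary/zero frequency "
            f"({modes.wavenumbers[mode_index]:.2f} cm⁻¹); exclude imaginary "
            "modes before computing derivatives"
        )
    lw = modes.mass_weighted_vectors(structure.masses[modes.active_atoms])
    l_k = lw[mode_index].reshape(-1, 3)  # unit mass-weighted vector
    m_e = structure.masses[modes.active_atoms] * AMU_TO_ELECTRON_MASS
    dx_bohr = l_k / np.sqrt(m_e)[:, None] * step
    dx = np.zeros_like(structure.coords)
    dx[modes.active_atoms] = dx_bohr * BOHR_TO_ANGSTROM
    return structure.with_coords(structure.coords + dx), structure.with_coords(
        structure.coords - dx
    )


def polarizability_derivatives(
    calculator: PolarizabilityCalculator,
    structure: MolecularStructure,
    modes: NormalModeSet,
    incident_ev: float,
    damping_cm1: float = 500.0,
    step: float = 0.001,
) -> ComplexPolarizabilityDerivativeSet:
    """Central-difference dα/dQ_k for every real-frequency mode.

    Imaginary modes are skipped and logged.  A calculator failure on a
    displaced geometry raises, naming the mode.
    """
    real_idx = modes.real_mode_indices()
    skipped = modes.n_modes - real_idx.size
    if skipped:
        logger.info("skipping %d imaginary/zero-frequency modes in RR evaluation",
                    skipped)
    tensors = np.empty((real_idx.size, 3, 3), dtype=complex)
    for out_i, k in enumerate(real_idx):
        plus, minus = displace_along_mode(structure, modes, int(k), step)
        try:
            a_plus = _check_symmetric(
                calculator(plus, incident_ev, damping_cm1), f"mode {k} (+)")
            a_minus = _check_symmetric(
                calculator(minus, incident_ev, damping_cm1), f"mode {k} (−)")
        except ValueError:
            raise
        except Exception as exc:
            raise RuntimeError(
                f"polarizability calculator failed on displaced geometry of mode {k}"
            ) from exc
        tensors[out_i] = (a_plus - a_minus) / (2.0 * step)
    return ComplexPolarizabilityDerivativeSet(
        tensors, real_idx, modes.wavenumbers[real_idx],
        incident_ev, damping_cm1, step,
    )


def raman_invariants(dalpha: np.ndarray) -> tuple[float, float]:
    """Rotational invariants (a², γ²) of a complex symmetric tensor.

    a² = |(d_xx + d_yy + d_zz)/3|²;
    γ² = ½[|d_xx−d_yy|² + |d_yy−d_zz|² + |d_zz−d_xx|²]
         + 3(|d_xy|² + |d_yz|² + |d_zx|²).
    """
    d = _check_symmetric(dalpha, "raman_invariants")
    a2 = abs((d[0, 0] + d[1, 1] + d[2, 2]) / 3.0) ** 2
    g2 = 0.5 * (
        abs(d[0, 0] - d[1, 1]) ** 2
        + abs(d[1, 1] - d[2, 2]) ** 2
        + abs(d[2, 2] - d[0, 0]) ** 2
    ) + 3.0 * (abs(d[0, 1]) ** 2 + abs(d[1, 2]) ** 2 + abs(d[2, 0]) ** 2)
    return float(a2), float(g2)


def stick_spectrum(
    derivatives: ComplexPolarizabilityDerivativeSet,
    incident_ev: float | None = None,
    temperature_k: float | None = None,
) -> list[tuple[float, float]]:
    """Relative Stokes RR stick intensities per real mode.

    I_k ∝ (ν̃₀−ν̃_k)³·ν̃₀·(45a²+7γ²)/ν̃_k, with an optional thermal factor
    [1 − exp(−hcν̃_k/k_BT)]⁻¹.  Modes at or above the incident energy are
    skipped with a warning (anti-Stokes scattering is not modeled).
    """
    nu0 = (incident_ev if incident_ev is not None
           else derivatives.incident_energy_ev) * EV_TO_WAVENUMBER
    sticks: list[tuple[float, float]] = []
    for tensor, nu_k in zip(derivatives.tensors, derivatives.wavenumbers):
        if nu_k >= nu0:
            logger.warning(
                "mode at %.1f cm⁻¹ at/above the incident energy %.1f cm⁻¹; skipped",
                nu_k, nu0,
            )
            continue
        a2, g2 = raman_invariants(tensor)
        intensity = (nu0 - nu_k) ** 3 * nu0 * (45.0 * a2 + 7.0 * g2) / nu_k
        if temperature_k is not None:
            if temperature_k <= 0:
                raise ValueError("temperature must be positive when given")
            x = nu_k / HARTREE_TO_WAVENUMBER / (KB_HARTREE_PER_K * temperature_k)
            intensity /= 1.0 - math.exp(-x)
        sticks.append((float(nu_k), float(intensity)))
    return sticks


def convolve_lorentzian(
    sticks: Sequence[tuple[float, float]],
    grid: np.ndarray,
    hwhm_cm1: float = 10.0,
    metadata: dict | None = None,
) -> RamanSpectrum:
    """Broaden sticks with unit-area Lorentzians of half-width γ = hwhm.

    S(ν̃) = Σ_k I_k·(1/π)·γ/((ν̃−ν̃_k)² + γ²); an isolated peak then has
    FWHM = 2·hwhm and height I_k/(πγ).
    """
    if hwhm_cm1 <= 0:
        raise ValueError(f"hwhm must be positive, got {hwhm_cm1}")
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    intensity = np.zeros_like(grid)
    g = hwhm_cm1
    for nu_k, i_k in sticks:
        intensity += i_k * (g / math.pi) / ((grid - nu_k) ** 2 + g * g)
    meta = dict(metadata or {})
    meta.setdefault("hwhm_cm1", hwhm_cm1)
    return RamanSpectrum(grid, intensity, list(sticks), meta)


def average_spectra(
    spectra: Sequence[RamanSpectrum],
    weights: Sequence[float] | None = None,
    normalize: bool = True,
) -> RamanSpectrum:
    """Persistence-weighted pointwise mean of spectra on a common grid.

    Weights not summing to 1 are renormalized with a warning; with
    ``normalize`` the result is scaled so its maximum is exactly 1.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
            raise ValueError("spectra must share a common wavenumber grid")
    w = (np.full(len(spectra), 1.0 / len(spectra)) if weights is None
         else np.asarray(weights, float))
    if w.shape != (len(spectra),) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative, one per spectrum")
    if abs(w.sum() - 1.0) > 1e-9:
        logger.warning("averaging weights sum to %.6f; renormalizing", w.sum())
    w = w / w.sum()
    intensity = np.einsum("s,sg->g", w, np.array([s.intensity for s in spectra]))
    sticks = [(nu, w_i * i) for w_i, s in zip(w, spectra) for nu, i in s.sticks]
    meta = {"weights": w.tolist()}
    out = RamanSpectrum(grid, intensity, sticks, meta)
    return out.normalized() if normalize else out
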