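"""RR intensity engine: finite-difference derivatives against the
closed-form pole model, tensor invariants, stick formula, broadening and
persistence-weighted averaging."""

import numpy as np
import pytest

from resoraman.raman import (
    RamanSpectrum,
    average_spectra,
    convolve_lorentzian,
    displace_along_mode,
    polarizability_derivatives,
    raman_invariants,
    stick_spectrum,
)
from resoraman.toy_models import (
    linear_coupling_toy,
    make_harmonic_molecule,
    mode_coordinate,
    pole_polarizability,
)
from resoraman.units import EV_TO_WAVENUMBER


@pytest.fixture(scope="module")
def toy():
    s, h, m = make_harmonic_molecule(5, np.linspace(400, 1900, 9), seed=3)
    calc, dana = linear_coupling_toy(s, m, coupled_mode=8)
    return s, m, calc, dana


def test_displacement_symmetry_and_zero_step(toy):
    s, m, _, _ = toy
    plus, minus = displace_along_mode(s, m, 5, step=0.0)
    np.testing.assert_allclose(plus.coords, s.coords)
    np.testing.assert_allclose(minus.coords, s.coords)
    plus, minus = displace_along_mode(s, m, 5, step=0.01)
    np.testing.assert_allclose((plus.coords + minus.coords) / 2, s.coords, atol=1e-12)


def test_displacement_magnitude_is_step_in_mass_weighted_units(toy):
    s, m, _, _ = toy
    step = 0.01
    plus, _ = displace_along_mode(s, m, 8, step=step)
    assert mode_coordinate(s, m, 8, plus) == pytest.approx(step, rel=1e-10)


def test_diatomic_displacement_changes_only_bond_length():
    from conftest import diatomic
    from resoraman.units import AMU_TO_ELECTRON_MASS, BOHR_TO_ANGSTROM
    from resoraman.vibrations import normal_modes_a0
    k, mass = 0.5, 12.011
    s, h = diatomic(k, mass, mass)
    modes = normal_modes_a0(h, s)
    step = 0.02
    plus, minus = displace_along_mode(s, modes, 0, step=step)
    # perpendicular coordinates untouched
    np.testing.assert_allclose(plus.coords[:, :2], s.coords[:, :2], atol=1e-14)
    # bond-length change: Δr = step·(|L1z|+|L2z|)/√m with L = (∓1,±1)/√2
    m_e = mass * AMU_TO_ELECTRON_MASS
    expected = step * 2 / np.sqrt(2 * m_e) * BOHR_TO_ANGSTROM
    d_plus = abs(plus.coords[1, 2] - plus.coords[0, 2])
    assert abs(d_plus - 1.2) == pytest.approx(expected, rel=1e-10)


def test_imaginary_mode_displacement_rejected():
    s, h, _ = make_harmonic_molecule(3, [900.0, -50.0, 1400.0], seed=2)
    from resoraman.vibrations import normal_modes_a0
    modes = normal_modes_a0(h, s)
    bad = int(np.argmin(modes.wavenumbers))
    with pytest.raises(ValueError, match="imaginary"):
        displace_along_mode(s, modes, bad)


def test_linear_calculator_derivative_exact(toy):
    """α linear in the coupled coordinate → central difference is exact."""
    s, m, _, _ = toy

    def linear_calc(structure, incident_ev, damping_cm1):
        q = mode_coordinate(s, m, 8, structure)
        return (1.0 + 2.5 * q) * np.eye(3, dtype=complex)

    d = polarizability_derivatives(linear_calc, s, m, 2.49)
    np.testing.assert_allclose(d.tensors[8], 2.5 * np.eye(3), atol=1e-9)
    np.testing.assert_allclose(d.tensors[:8], 0, atol=1e-9)


def test_pole_derivative_second_order_convergence(toy):
    """Central difference vs analytic chain-rule derivative: halving the
    step must shrink the error ~4× (second order)."""
    s, m, calc, dana = toy
    exact = dana(8, 2.49, 500.0)
    errs = []
    for step in (0.004, 0.002):
        d = polarizability_derivatives(calc, s, m, 2.49, 500.0, step)
        errs.append(np.abs(d.tensors[8] - exact).max())
    ratio = errs[0] / errs[1]
    assert ratio == pytest.approx(4.0, abs=0.2)


def test_derivatives_skip_imaginary_modes():
    s, h, _ = make_harmonic_molecule(3, [900.0, -50.0, 1400.0], seed=2)
    from resoraman.vibrations import normal_modes_a0
    modes = normal_modes_a0(h, s)
    calc = lambda st, e, g: np.eye(3, dtype=complex)
    d = polarizability_derivatives(calc, s, modes, 2.49)
    assert d.tensors.shape[0] == 2
    assert np.all(modes.wavenumbers[d.mode_indices] > 0)


def test_damping_suppresses_derivatives_monotonically(toy):
    s, m, calc, _ = toy
    norms = []
    for gamma in (250.0, 500.0, 1000.0, 2000.0):
        d = polarizability_derivatives(calc, s, m, 2.49, gamma, 0.001)
        norms.append(np.linalg.norm(d.tensors[8]))
    assert all(a > b for a, b in zip(norms, norms[1:]))


def test_invariants_isotropic_and_traceless():
    c = 2.0 - 1.0j
    a2, g2 = raman_invariants(c * np.eye(3))
    assert a2 == pytest.approx(abs(c) ** 2, rel=1e-12)
    assert g2 == pytest.approx(0.0, abs=1e-12)
    a2, g2 = raman_invariants(np.diag([1.0, -1.0, 0.0]).astype(complex))
    assert a2 == pytest.approx(0.0, abs=1e-12)
    assert g2 == pytest.approx(3.0, rel=1e-12)


def test_invariants_rotation_invariant():
    rng = np.random.default_rng(61)
    t = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
    t = 0.5 * (t + t.T)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    r = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    a2a, g2a = raman_invariants(t)
    a2b, g2b = raman_invariants(r @ t @ r.T)
    assert a2b == pytest.approx(a2a, rel=1e-10, abs=1e-10)
    assert g2b == pytest.approx(g2a, rel=1e-10, abs=1e-10)


def test_antisymmetric_tensor_rejected():
    t = np.eye(3, dtype=complex)
    t[0, 1], t[1, 0] = 0.5, -0.5
    with pytest.raises(ValueError, match="antisymmetric"):
        raman_invariants(t)


def test_stick_formula_frequency_factors():
    """Two modes with identical invariants: intensity ratio is purely the
    (ν̃₀−ν̃)³/ν̃ factor."""
    from resoraman.raman import ComplexPolarizabilityDerivativeSet
    tensors = np.array([np.eye(3), np.eye(3)], dtype=complex)
    nu0 = 20000.0 / EV_TO_WAVENUMBER  # incident at 20000 cm⁻¹, in eV
    d = ComplexPolarizabilityDerivativeSet(
        tensors, np.array([0, 1]), np.array([1000.0, 2000.0]), nu0, 500.0, 0.001)
    sticks = stick_spectrum(d)
    ratio = sticks[0][1] / sticks[1][1]
    expected = (19000.0**3 / 1000.0) / (18000.0**3 / 2000.0)
    assert ratio == pytest.approx(expected, rel=1e-12)


def test_zero_derivative_gives_zero_stick():
    from resoraman.raman import ComplexPolarizabilityDerivativeSet
    d = ComplexPolarizabilityDerivativeSet(
        np.zeros((1, 3, 3), dtype=complex), np.array([0]),
        np.array([1000.0]), 2.49, 500.0, 0.001)
    assert stick_spectrum(d)[0][1] == 0.0


def test_mode_above_incident_energy_skipped():
    from resoraman.raman import ComplexPolarizabilityDerivativeSet
    nu0_ev = 800.0 / EV_TO_WAVENUMBER
    d = ComplexPolarizabilityDerivativeSet(
        np.array([np.eye(3)], dtype=complex), np.array([0]),
        np.array([1000.0]), nu0_ev, 500.0, 0.001)
    assert stick_spectrum(d) == []


def test_intensity_peaks_at_resonance(toy):
    """Scanning the incident energy through the toy excitation maximizes
    the dominant-mode intensity at resonance."""
    s, m, calc, _ = toy
    energies = np.linspace(2.0, 3.0, 21)  # toy excitation at 2.49 eV
    peak = []
    for e in energies:
        d = polarizability_derivatives(calc, s, m, e, 500.0, 0.001)
        sticks = stick_spectrum(d)
        peak.append(max(i for _, i in sticks))
    assert abs(energies[int(np.argmax(peak))] - 2.49) <= 0.051


def test_lorentzian_height_fwhm_and_area():
    grid = np.arange(0.0, 2000.0, 0.1)
    hwhm = 10.0
    spec = convolve_lorentzian([(1000.0, 1.0)], grid, hwhm)
    peak = spec.intensity.max()
    assert peak == pytest.approx(1.0 / (np.pi * hwhm), rel=1e-6)
    # numerically measured FWHM = 2·hwhm
    above = grid[spec.intensity >= peak / 2]
    assert above[-1] - above[0] == pytest.approx(20.0, abs=0.2)
    assert np.trapezoid(spec.intensity, grid) == pytest.approx(1.0, rel=0.01)


def test_lorentzian_input_validation():
    with pytest.raises(ValueError):
        convolve_lorentzian([(1000.0, 1.0)], np.arange(10.0), hwhm_cm1=0.0)
    with pytest.raises(ValueError, match="increasing"):
        convolve_lorentzian([(1000.0, 1.0)], np.array([2.0, 1.0]), 10.0)


def _three_spectra():
    grid = np.arange(800.0, 1200.0, 1.0)
    specs = [convolve_lorentzian([(900.0 + 100 * k, 1.0 + k)], grid, 10.0)
             for k in range(3)]
    return grid, specs


def test_average_equal_weights_is_mean():
    grid, specs = _three_spectra()
    avg = average_spectra(specs, normalize=False)
    expected = np.mean([s.intensity for s in specs], axis=0)
    np.testing.assert_allclose(avg.intensity, expected, atol=1e-14)


def test_average_delta_weight_returns_first():
    grid, specs = _three_spectra()
    avg = average_spectra(specs, [1.0, 0.0, 0.0], normalize=False)
    np.testing.assert_allclose(avg.intensity, specs[0].intensity, atol=1e-14)


def test_average_weighted_sum_oracle_and_normalization():
    grid, specs = _three_spectra()
    w = [0.5, 0.3, 0.2]
    direct = sum(wi * s.intensity for wi, s in zip(w, specs))
    avg = average_spectra(specs, w, normalize=False)
    np.testing.assert_allclose(avg.intensity, direct, atol=1e-14)
    normed = average_spectra(specs, w, normalize=True)
    assert normed.intensity.max() == 1.0
    np.testing.assert_allclose(normed.intensity, direct / direct.max(), atol=1e-14)


def test_average_grid_mismatch_rejected():
    grid, specs = _three_spectra()
    other = RamanSpectrum(grid + 5.0, specs[0].intensity)
    with pytest.raises(ValueError, match="common"):
        average_spectra([specs[0], other])


def test_stick_spectrum_rotation_invariance(toy):
    """Rotating the structure (the toy dipole rides along via the mode
    coordinate) leaves stick intensities unchanged."""
    s, m, calc, _ = toy
    from resoraman.mode_transform import rotate_modes, superpose
    rng = np.random.default_rng(71)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    r = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    frame = s.with_coords(s.coords @ r.T)
    fit = superpose(s, frame)
    m_rot = rotate_modes(m, fit)
    calc_rot, _ = linear_coupling_toy(frame, m_rot, coupled_mode=8)
    d0 = polarizability_derivatives(calc, s, m, 2.49)
    d1 = polarizability_derivatives(calc_rot, frame, m_rot, 2.49)
    i0 = np.array([i for _, i in stick_spectrum(d0)])
    i1 = np.array([i for _, i in stick_spectrum(d1)])
    # relative to the dominant stick (uncoupled modes carry only
    # finite-difference noise many orders below it)
    np.testing.assert_allclose(i1 / i1.max(), i0 / i0.max(), atol=1e-8)


def test_off_resonance_ratios_converge_to_static():
    """Far below the lowest excitation the intensity ratio of two coupled
    modes approaches the static (ω = 0) limit of the same model."""
    s, h, m = make_harmonic_molecule(5, np.linspace(400, 1900, 9), seed=3)
    from resoraman.toy_models import pole_polarizability_calculator, mode_coordinate

    def e_fn(structure):
        q1 = mode_coordinate(s, m, 7, structure)
        q2 = mode_coordinate(s, m, 8, structure)
        return np.array([3.0 + 0.02 * q1, 4.0 + 0.03 * q2])

    def mu_fn(structure):
        return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])

    calc = pole_polarizability_calculator(e_fn, mu_fn)

    def invariant_ratio(incident):
        d = polarizability_derivatives(calc, s, m, incident, 1.0, 0.001)
        from resoraman.raman import raman_invariants
        act = [45 * a + 7 * g for a, g in (raman_invariants(t) for t in d.tensors)]
        return act[7] / act[8]

    static = invariant_ratio(1e-6)
    diffs = [abs(invariant_ratio(e) - static) for e in (1.0, 0.3, 0.1, 0.01)]
    assert all(a >= b for a, b in zip(diffs, diffs[1:]))
    assert diffs[-1] / static < 1e-3
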