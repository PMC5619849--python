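"""Ewald q-mapping, closed-form scattering oracles and Poisson noise."""

import numpy as np
import pytest
from scipy.stats import chisquare, poisson

import spisim as s
from spisim.constants import R_E2_A2, form_factor

from conftest import static_trajectory, uniform_pulse


def test_edge_half_period_resolution(geometry):
    """The working geometry encodes 3.6 A half-period resolution at the
    detector mid-edge."""
    assert round(s.edge_half_period_resolution(geometry), 1) == 3.6


def test_beam_centre_pixel_q_zero():
    g = s.DetectorGeometry(beam_center=(40.0, 40.0))
    qm = s.compute_qmap(g)
    j = 40 * g.n_cols + 40
    assert qm.qmag[j] == 0.0
    assert np.isinf(qm.half_period_resolution()[j])


def test_qmag_matches_trigonometric_oracle(geometry, qmap):
    """|q| at an arbitrary pixel equals the independent construction
    2 k sin(theta) from the pixel offset, distance and wavelength."""
    row, col = 17, 63
    j = row * geometry.n_cols + col
    px = geometry.pixel_size_um / 1000.0
    dx = (col - geometry.beam_center[1]) * px
    dy = (row - geometry.beam_center[0]) * px
    two_theta = np.arctan2(np.hypot(dx, dy), geometry.distance_mm)
    k = 2 * np.pi / geometry.wavelength_A
    assert np.isclose(qmap.qmag[j], 2 * k * np.sin(two_theta / 2), rtol=1e-12)


def test_qmap_geometry_invariants(geometry, qmap):
    assert np.all(qmap.solid_angle > 0)
    # |q| grows monotonically with radial pixel distance along the mid-row
    row = 40
    cols = np.arange(40, geometry.n_cols)
    js = row * geometry.n_cols + cols
    assert np.all(np.diff(qmap.qmag[js]) > 0)
    with pytest.raises(ValueError):
        s.DetectorGeometry(distance_mm=0.0)


def test_single_atom_form_factor(qmap):
    """One neutral carbon at the origin scatters |f_C(q)|^2 into every pixel,
    independent of rotation."""
    F2, S, N = s.structure_factors(
        ["C"], np.zeros((1, 3)), np.array([6.0]), qmap
    )
    assert np.allclose(F2, form_factor("C", qmap.qmag) ** 2, rtol=1e-9)
    assert np.allclose(S, 6.0 * (1 - (form_factor("C", qmap.qmag) / 6.0) ** 2))
    assert np.all(N == 0.0)


def test_two_atom_interference(qmap):
    """Two identical atoms at +-d/2 on x: |F|^2 = 4 f^2 cos^2(q_x d / 2)."""
    d = 5.0
    pos = np.array([[d / 2, 0, 0], [-d / 2, 0, 0]])
    F2, _, _ = s.structure_factors(
        ["O", "O"], pos, np.array([8.0, 8.0]), qmap
    )
    f = form_factor("O", qmap.qmag)
    expected = 4 * f**2 * np.cos(qmap.qvecs[:, 0] * d / 2) ** 2
    assert np.allclose(F2, expected, rtol=1e-9, atol=1e-9 * expected.max())


def test_stripped_atom_contributes_nothing(qmap):
    F2, S, _ = s.structure_factors(
        ["C"], np.zeros((1, 3)), np.array([0.0]), qmap
    )
    assert np.all(F2 == 0.0) and np.all(S == 0.0)


def test_unknown_element_rejected(qmap):
    with pytest.raises(KeyError):
        s.structure_factors(["Xx"], np.zeros((1, 3)), np.array([1.0]), qmap)


def test_incoherent_terms_rotation_invariant(qmap, small_structure):
    rot = s.random_rotation(3)
    z = small_structure.atomic_numbers.astype(float)
    _, S0, _ = s.structure_factors(
        small_structure.elements, small_structure.positions, z, qmap
    )
    _, S1, _ = s.structure_factors(
        small_structure.elements,
        s.apply_rotation(small_structure, rot).positions,
        z,
        qmap,
    )
    assert np.allclose(S0, S1)


def test_zero_pulse_gives_zero_pattern(qmap, small_structure, beam):
    times = np.linspace(-4.5, 4.5, 100)
    pulse = s.PulseProfile(times, np.zeros(100), 4.96, 3.0, 0.0)
    traj = static_trajectory(small_structure, times)
    pat = s.integrate_pattern(traj, pulse, beam, qmap, s.Rotation())
    assert np.all(pat.expected == 0.0)


def test_single_free_electron_thomson(qmap):
    """One trapped electron and nothing else: each pixel sees the hand
    arithmetic  fluence x r_e^2 x polarization x solid angle."""
    st = s.AtomicStructure(np.array(["H"], dtype=object), np.zeros((1, 3)))
    times = np.linspace(0.0, 1.0, 100)
    flux = 1e6
    pulse = uniform_pulse(flux, 0.0, 1.0, n=100)
    beam = s.BeamConditions(focus_fwhm=1.0, fluence_scale=1.0)
    traj = static_trajectory(
        st, times, z_bound=np.array([0.0]), n_free=1.0, n_escaped=0.0
    )
    pat = s.integrate_pattern(traj, pulse, beam, qmap, s.Rotation())
    # windowed snapshot weights integrate the uniform flux over [0, 1] fs
    expected = flux * 1.0 * R_E2_A2 * qmap.polarization * qmap.solid_angle
    assert np.allclose(pat.expected, expected, rtol=1e-6)


def test_pattern_linear_in_pulse_intensity(qmap, small_structure, beam):
    p1 = s.generate_sase_pulse(3.0, 1e11, seed=8)
    p2 = s.generate_sase_pulse(3.0, 2e11, seed=8)  # same shape, doubled
    times = p1.times
    traj = static_trajectory(small_structure, times)
    rot = s.random_rotation(1)
    a = s.integrate_pattern(traj, p1, beam, qmap, rot)
    b = s.integrate_pattern(traj, p2, beam, qmap, rot)
    assert np.allclose(b.expected, 2 * a.expected, rtol=1e-12)


def test_coherent_signal_scales_with_bound_electrons_squared():
    """Halving every bound-electron count quarters the forward coherent
    intensity — elastic scattering goes as the square of bound electrons."""
    g = s.DetectorGeometry(beam_center=(40.0, 40.0))
    qm = s.compute_qmap(g)
    j = 40 * g.n_cols + 40  # q = 0 pixel
    rng = np.random.default_rng(0)
    pos = rng.uniform(-10, 10, (50, 3))
    z = np.full(50, 6.0)
    F2_full, _, _ = s.structure_factors(["C"] * 50, pos, z, qm)
    F2_half, _, _ = s.structure_factors(["C"] * 50, pos, z / 2, qm)
    assert np.isclose(F2_half[j], F2_full[j] / 4, rtol=1e-12)


def test_friedel_symmetry_of_static_pattern(qmap, small_structure, beam):
    """An undamaged static sample obeys Friedel symmetry on the inner rings
    (flat-Ewald limit): centro-symmetric pixel pairs agree to 2%."""
    pulse = s.generate_sase_pulse(3.0, 1e11, seed=8)
    traj = static_trajectory(small_structure, pulse.times)
    pat = s.integrate_pattern(traj, pulse, beam, qmap, s.random_rotation(4))
    img = pat.expected.reshape(80, 80)
    flipped = img[::-1, ::-1]
    rows, cols = np.mgrid[0:80, 0:80]
    r = np.hypot(rows - 39.5, cols - 39.5)
    ring = (r >= 1.0) & (r < 5.0)
    rel = np.abs(img[ring] - flipped[ring]) / img[ring]
    assert np.percentile(rel, 95) < 0.02


def test_poissonize_moments_and_determinism():
    expected = np.full(6400, 4.0)
    pat = s.DiffractionPattern(expected=expected, rotation=s.Rotation())
    noisy = s.poissonize(pat, seed=5)
    again = s.poissonize(pat, seed=5)
    assert np.array_equal(noisy.counts, again.counts)
    mean = noisy.counts.mean()
    assert 3.85 < mean < 4.15
    assert 0.9 < noisy.counts.var() / mean < 1.1
    zero = s.poissonize(
        s.DiffractionPattern(expected=np.zeros(10), rotation=s.Rotation()), 1
    )
    assert np.all(zero.counts == 0)


def test_poisson_distribution_goodness_of_fit():
    """10^5 draws at lambda = 1.7 pass a chi-square test against the Poisson
    pmf."""
    lam = 1.7
    pat = s.DiffractionPattern(
        expected=np.full(100_000, lam), rotation=s.Rotation()
    )
    counts = s.poissonize(pat, seed=17).counts
    kmax = 9
    observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
    probs = poisson.pmf(np.arange(kmax), lam)
    probs = np.append(probs, 1.0 - probs.sum())
    stat, p = chisquare(observed, probs * len(counts))
    assert p > 0.01


def test_negative_expectation_rejected():
    with pytest.raises(ValueError):
        s.DiffractionPattern(expected=np.array([-1.0]), rotation=s.Rotation())


def test_pattern_archive_roundtrip(tmp_path, geometry):
    from spisim.diffraction import load_patterns, save_patterns

    rng = np.random.default_rng(0)
    counts = rng.poisson(0.1, (7, geometry.n_pixels))
    quats = np.tile([1.0, 0, 0, 0], (7, 1))
    save_patterns(tmp_path / "pat.h5", counts, quats, geometry)
    back, quats2, geo2 = load_patterns(tmp_path / "pat.h5")
    assert np.array_equal(back, counts)
    assert geo2.pixel_size_um == geometry.pixel_size_um
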