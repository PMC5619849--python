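"""EMC: rotation sampling, expand/compress geometry and EM updates."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as R

import spisim as s
from spisim.emc import (
    DiffractionVolume,
    EMCOperator,
    RotationSet,
    TOMOGRAM_FLOOR,
    em_iteration,
    expand,
    slice_volume,
)


@pytest.fixture(scope="module")
def small_geometry():
    return s.DetectorGeometry(n_rows=24, n_cols=24, pixel_size_um=2400,
                              distance_mm=130)


@pytest.fixture(scope="module")
def small_operator(small_geometry):
    return EMCOperator(small_geometry, level=2)


def _geodesic_gap(set_quats, probe_quats):
    """Max over probes of the min rotation angle to the set (|q.q'| metric)."""
    dots = np.abs(probe_quats @ set_quats.T)
    return np.arccos(np.clip(dots.max(axis=1), -1, 1)).max() * 2.0


def test_rotation_set_counts_and_uniqueness():
    """Level 1 yields the 60 rotations of the half 600-cell; higher levels
    follow the 10(5n^3+n) count with no duplicate rotations."""
    for level in (1, 2, 3):
        rs = s.sample_rotation_set(level)
        assert len(rs) == 10 * (5 * level**3 + level)
        assert np.isclose(rs.weights.sum(), 1.0)
        dots = np.abs(rs.quaternions @ rs.quaternions.T)
        np.fill_diagonal(dots, 0.0)
        # min pairwise rotation angle > 0: no q/-q duplicates either
        assert dots.max() < 1.0 - 1e-9
    with pytest.raises(ValueError):
        s.sample_rotation_set(0)


def test_rotation_refinement_shrinks_gaps():
    """The worst geodesic gap to a random probe set strictly shrinks from
    level 2 to level 4."""
    probes = R.random(2000, rng=np.random.default_rng(3)).as_quat()[:, [3, 0, 1, 2]]
    gap2 = _geodesic_gap(s.sample_rotation_set(2).quaternions, probes)
    gap4 = _geodesic_gap(s.sample_rotation_set(4).quaternions, probes)
    assert gap4 < gap2


def test_expand_constant_volume(small_geometry):
    qm = s.compute_qmap(small_geometry)
    vol = DiffractionVolume(np.full((25, 25, 25), 3.7), 0.0464)
    rs = RotationSet(np.array([[1.0, 0, 0, 0]]), np.array([1.0]), 1)
    tom = expand(vol, rs, qm)
    assert np.allclose(tom, 3.7)


def test_expand_single_voxel_support(small_operator):
    """A volume that is nonzero in one voxel produces tomograms nonzero only
    at pixels whose rotated q lands in that voxel's interpolation support."""
    op = small_operator
    n = op.n_vox
    vol = np.zeros((n, n, n))
    target = (n // 2 + 3, n // 2 - 2, n // 2 + 1)
    vol[target] = 5.0
    W = op.expand(vol)
    flat_target = np.ravel_multi_index(target, (n, n, n))
    support = np.any(op._idx8 == flat_target, axis=2)
    assert np.all(W[~support] == 0.0)
    assert W[support].max() > 0.0


def test_expand_compress_roundtrip(small_geometry):
    """Compress after expand reproduces a smooth radial volume within 5% on
    the voxels sampled by the rotation set."""
    op = EMCOperator(small_geometry, level=4)
    n = op.n_vox
    c = n // 2
    ax = np.arange(n) - c
    rr = np.sqrt((ax[:, None, None]) ** 2 + (ax[None, :, None]) ** 2
                 + (ax[None, None, :]) ** 2)
    vol = np.exp(-((rr / 6.0) ** 2)) + 0.1
    W = op.expand(vol)
    back = op.compress(W)
    sampled = (op._wsum.reshape(n, n, n) > 0.5) & (rr <= c)
    rel = np.abs(back[sampled] - vol[sampled]) / vol[sampled]
    assert np.percentile(rel, 95) < 0.05


def test_em_likelihood_dominance(small_operator):
    """A high-count pattern equal to one tomogram's expectation is assigned
    to that rotation."""
    op = small_operator
    rng = np.random.default_rng(0)
    n = op.n_vox
    from scipy.ndimage import gaussian_filter

    vol = gaussian_filter(rng.random((n, n, n)), 1.5) + 0.02
    W = np.clip(op.expand(vol), TOMOGRAM_FLOOR, None) * 500.0
    r_true = 57
    K = W[r_true][None, :]
    _, _, P = em_iteration(K, W)
    assert P[0].argmax() == r_true


def test_em_symmetry_and_degenerate_cases():
    rng = np.random.default_rng(1)
    W = rng.random((30, 50)) + 0.1
    pat = rng.poisson(3.0, 50).astype(float)
    K = np.stack([pat, pat])
    _, _, P = em_iteration(K, W)
    assert np.allclose(P[0], P[1])

    # single-rotation set: P = 1 and the updated tomogram is the mean pattern
    K3 = rng.poisson(2.0, (5, 50)).astype(float)
    W1 = rng.random((1, 50)) + 0.5
    W_new, _, P1 = em_iteration(K3, W1)
    assert np.allclose(P1, 1.0)
    assert np.allclose(W_new[0], K3.mean(axis=0))


def test_em_photon_conservation_and_monotonicity():
    """The posterior-weighted tomogram photon sum equals the mean photons
    per pattern, and repeated EM updates never decrease the likelihood."""
    rng = np.random.default_rng(2)
    W = rng.random((40, 60)) + 0.1
    K = rng.poisson(1.5, (25, 60)).astype(float)
    lls = []
    for _ in range(12):
        W_new, ll, P = em_iteration(K, W)
        denom = P.sum(axis=0)
        total = (denom * W_new.sum(axis=1)).sum() / len(K)
        assert np.isclose(total, K.sum() / len(K), rtol=1e-6)
        W = W_new
        lls.append(ll)
    assert np.all(np.diff(lls) > -1e-6 * np.abs(np.array(lls[:-1])))


def test_em_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        em_iteration(np.ones((2, 10)), np.ones((5, 11)))


def test_run_emc_identical_patterns(small_operator):
    """Identical patterns: EMC converges almost immediately and every
    tomogram of the converged volume reproduces the common pattern on the
    well-sampled pixels."""
    op = small_operator
    n = op.n_vox
    c = n // 2
    ax = np.arange(n) - c
    rr = np.sqrt((ax[:, None, None]) ** 2 + (ax[None, :, None]) ** 2
                 + (ax[None, None, :]) ** 2)
    radial = 20.0 * np.exp(-((rr / 5.0) ** 2)) + 1.0
    pattern = op.expand(radial)[0]
    K = np.tile(pattern, (8, 1))
    vol, info = s.run_emc(K, operator=op, max_iter=12, tol=1e-2, seed=0)
    # a couple of extra sweeps relax the expand/compress interpolation pair
    assert info["converged"] and info["n_iter"] <= 8
    W = op.expand(vol.data)
    good = op._w8.sum(axis=2) > 0.99  # pixels fully inside the grid
    rel = np.abs(W[good] - np.broadcast_to(pattern, W.shape)[good]) / pattern.max()
    assert np.percentile(rel, 95) < 0.05


def test_run_emc_scaling_equivariance(small_operator):
    """Scaling all patterns by c scales the reconstruction by c.  Exact only
    once orientation posteriors are unambiguous (the Poisson posteriors
    themselves sharpen with counts), so high-count structured patterns are
    used and a percent-level tolerance allowed."""
    op = small_operator
    rng = np.random.default_rng(4)
    from scipy.ndimage import gaussian_filter

    n = op.n_vox
    vol = gaussian_filter(rng.random((n, n, n)), 2.0) + 0.05
    picks = rng.integers(0, len(op.rotations), 40)
    K = op.expand(vol)[picks] * 200.0
    v1, _ = s.run_emc(K, operator=op, max_iter=8, tol=1e-6, seed=3)
    v2, _ = s.run_emc(K * 3.0, operator=op, max_iter=8, tol=1e-6, seed=3)
    # the global orientation is a gauge freedom: compare the (rotation-
    # invariant) sorted intensity distributions of the two reconstructions
    a = np.sort(v1.data.ravel())
    b = np.sort(v2.data.ravel())
    big = a > a.max() * 1e-2
    rel = np.abs(b[big] - 3.0 * a[big]) / (3.0 * a[big])
    assert np.percentile(rel, 95) < 0.02


def test_run_emc_requires_two_patterns(small_operator):
    with pytest.raises(ValueError):
        s.run_emc(np.ones((1, small_operator.n_pix)), operator=small_operator)


def test_slice_volume_matches_operator_expand(small_operator):
    """slice_volume at a rotation-set quaternion agrees with the operator's
    precomputed expand for that rotation."""
    op = small_operator
    rng = np.random.default_rng(5)
    from scipy.ndimage import gaussian_filter

    n = op.n_vox
    vol = gaussian_filter(rng.random((n, n, n)), 2.0) + 0.05
    dv = DiffractionVolume(vol, op.dq)
    r = 123
    tom_op = op.expand(vol)[r]
    tom_sl = slice_volume(dv, op.rotations.quaternions[r], op.qmap)
    inside = op._w8[r].sum(axis=1) > 0.99
    # operator caches float32 interpolation weights; agreement to ~1e-6
    assert np.allclose(tom_op[inside], tom_sl[inside], rtol=1e-5)


def test_volume_roundtrip_hdf5(tmp_path):
    from spisim.emc import load_volume, save_volume

    vol = DiffractionVolume(np.random.default_rng(0).random((9, 9, 9)), 0.02)
    save_volume(tmp_path / "v.h5", vol)
    back = load_volume(tmp_path / "v.h5")
    assert np.array_equal(back.data, vol.data)
    assert back.dq == vol.dq
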