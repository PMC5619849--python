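"""Expand-maximize-compress orientation recovery with Poisson likelihood.

EMC starts from a random positive 3-D diffraction volume on a cubic q-grid
(the reference model), repeatedly (E) expands it into tomograms — Ewald-
sphere slices at a quasi-uniform discretization of SO(3) built from the
600-cell — (M) computes the posterior rotation probabilities of every
measured pattern under a Poisson likelihood and updates the tomograms, and
(C) compresses the tomograms back into the volume, until the relative change
in voxel intensities stays below a threshold in two subsequent iterations.

The rotation discretization follows the standard 600-cell subdivision: the
level-1 set is the 60 rotations of the half 600-cell (one quaternion per
antipodal pair) and level n subdivides each tetrahedral cell barycentrically,
giving 10(5 n^3 + n) rotations with shrinking angular gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import map_coordinates
from scipy.special import logsumexp
from scipy.spatial.transform import Rotation as _R

from .diffraction import DetectorGeometry, QMap, compute_qmap

__all__ = [
    "RotationSet",
    "DiffractionVolume",
    "sample_rotation_set",
    "EMCOperator",
    "expand",
    "em_iteration",
    "run_emc",
    "slice_volume",
    "align_volumes",
    "save_volume",
    "load_volume",
]

TOMOGRAM_FLOOR = 1e-10


@dataclass
class RotationSet:
    """Quasi-uniform SO(3) sample: scalar-first quaternions plus weights."""

    quaternions: np.ndarray
    weights: np.ndarray
    level: int

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("quadrature weights must sum to 1")

    def __len__(self) -> int:
        return len(self.quaternions)

    def matrices(self) -> np.ndarray:
        q = self.quaternions
        return _R.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()


@dataclass
class DiffractionVolume:
    """Intensities on a cubic q-grid; the centre voxel maps to q = 0."""

    data: np.ndarray
    dq: float

    def __post_init__(self):
        n = self.data.shape[0]
        if self.data.shape != (n, n, n) or n % 2 == 0:
            raise ValueError("volume must be cubic with odd edge length")
        if np.any(self.data < 0):
            raise ValueError("volume intensities must be non-negative")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def centre(self) -> int:
        return self.n // 2

    def qmag_grid(self) -> np.ndarray:
        c = self.centre
        ax = (np.arange(self.n) - c) * self.dq
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        return np.sqrt(x**2 + y**2 + z**2)


def _cell600_vertices() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for i in range(4):
        for s in (1.0, -1.0):
            v = np.zeros(4)
            v[i] = s
            verts.append(v)
    for signs in product((0.5, -0.5), repeat=4):
        verts.append(np.array(signs))
    base = np.array([phi / 2.0, 0.5, 1.0 / (2.0 * phi), 0.0])
    even_perms = [p for p in permutations(range(4)) if _perm_sign(p) == 1]
    for perm in even_perms:
        for signs in product((1.0, -1.0), repeat=3):
            v = base[list(perm)].copy()
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            for s_i, j in zip(signs, nz):
                v[j] *= s_i
            verts.append(v)
    verts = np.unique(np.round(np.array(verts), 12), axis=0)
    assert verts.shape == (120, 4)
    return verts


def _perm_sign(perm) -> int:
    sign = 1
    perm = list(perm)
    for i in range(len(perm)):
        for j in range(i + 1, len(perm)):
            if perm[i] > perm[j]:
                sign = -sign
    return sign


@lru_cache(maxsize=None)
def _cell600_cells():
    verts = _cell600_vertices()
    dots = verts @ verts.T
    adj = np.isclose(dots, (1.0 + np.sqrt(5.0)) / 4.0, atol=1e-9)
    n = len(verts)
    cells = set()
    for u in range(n):
        nb = np.flatnonzero(adj[u])
        nb = nb[nb > u]
        for ii, v in enumerate(nb):
            common = [w for w in nb[ii + 1 :] if adj[v, w]]
            for jj, w in enumerate(common):
                for x in common[jj + 1 :]:
                    if adj[w, x]:
                        cells.add((u, v, w, x))
    cells = sorted(cells)
    assert len(cells) == 600
    return verts, cells


@lru_cache(maxsize=None)
def sample_rotation_set(level: int) -> RotationSet:
    """Deterministic quasi-uniform SO(3) sampling from the subdivided
    600-cell; ``level`` 1 gives the 60 base rotations, and the count grows as
    10 (5 level^3 + level)."""
    if level < 1:
        raise ValueError("refinement level must be >= 1")
    verts, cells = _cell600_cells()
    seen = {}
    for cell in cells:
        vs = verts[list(cell)]
        for comp in _compositions(level):
            p = (np.array(comp, dtype=float) @ vs) / level
            p /= np.linalg.norm(p)
            p = _canonical(p)
            seen[tuple(np.round(p, 9))] = p
    quats = np.array(sorted(seen.values(), key=tuple))
    weights = np.full(len(quats), 1.0 / len(quats))
    return RotationSet(quats, weights, level)


def _compositions(n: int):
    for i in range(n + 1):
        for j in range(n - i + 1):
            for k in range(n - i - j + 1):
                yield (i, j, k, n - i - j - k)


def _canonical(q: np.ndarray) -> np.ndarray:
    for comp in q:
        if abs(comp) > 1e-9:
            return q if comp > 0 else -q
    return q


# ------------------------------------------------------------------ operator

class EMCOperator:
    """Precomputed expand/compress machinery for one geometry + rotation set.

    Caches, per rotation, the trilinear interpolation indices and weights of
    every detector pixel's rotated Ewald q-vector on the voxel grid, so that
    expand and compress are pure gather/scatter operations.  Pixels whose
    rotated q falls outside the grid are clamped to the boundary and counted
    in ``n_clamped``.
    """

    def __init__(
        self,
        geometry: DetectorGeometry,
        level: int = 2,
        n_vox: int | None = None,
        dq: float | None = None,
        mask: np.ndarray | None = None,
    ):
        self.geometry = geometry
        self.qmap: QMap = compute_qmap(geometry)
        lam = geometry.wavelength_A
        self.dq = dq or (
            2.0 * np.pi / lam * (geometry.pixel_size_um / 1000.0)
            / geometry.distance_mm
        )
        self.n_vox = n_vox or (2 * (geometry.n_cols // 2) + 1)
        self.rotations = sample_rotation_set(level)
        self.mask = (
            np.ones(self.qmap.n_pixels, bool) if mask is None else mask.ravel()
        )
        self.live = np.flatnonzero(self.mask)
        self._precompute()

    def _precompute(self):
        n = self.n_vox
        c = n // 2
        mats = self.rotations.matrices()
        qpix = self.qmap.qvecs[self.live]  # (P, 3)
        coords = np.einsum("rij,pj->rpi", mats, qpix) / self.dq + c
        lo = np.clip(coords, 0.0, n - 1.000001)
        self.n_clamped = int(np.sum(np.any(coords != lo, axis=2)))
        base = np.floor(lo).astype(np.int32)
        frac = (lo - base).astype(np.float32)
        R, P = base.shape[:2]
        idx8 = np.empty((R, P, 8), dtype=np.int32)
        w8 = np.empty((R, P, 8), dtype=np.float32)
        k = 0
        for dx in (0, 1):
            wx = frac[..., 0] if dx else 1.0 - frac[..., 0]
            for dy in (0, 1):
                wy = frac[..., 1] if dy else 1.0 - frac[..., 1]
                for dz in (0, 1):
                    wz = frac[..., 2] if dz else 1.0 - frac[..., 2]
                    idx8[..., k] = (
                        (base[..., 0] + dx) * n + (base[..., 1] + dy)
                    ) * n + (base[..., 2] + dz)
                    w8[..., k] = wx * wy * wz
                    k += 1
        self._idx8 = idx8
        self._w8 = w8
        self._wsum = np.bincount(
            idx8.ravel(), weights=w8.ravel().astype(float), minlength=n**3
        )

    @property
    def n_pix(self) -> int:
        return len(self.live)

    def expand(self, volume: np.ndarray) -> np.ndarray:
        """Tomogram stack W_r (n_rot, n_live_pix) by trilinear interpolation."""
        flat = volume.ravel()
        out = np.zeros(self._idx8.shape[:2])
        for k in range(8):  # corner-by-corner keeps temporaries small
            out += flat[self._idx8[..., k]] * self._w8[..., k]
        return out

    def compress(self, tomograms: np.ndarray, rot_weights=None) -> np.ndarray:
        """Volume from tomograms by transpose interpolation (weighted scatter).

        ``rot_weights`` (n_rot,) weights each tomogram's contribution — in
        EMC iterations the posterior mass collected by each rotation — so
        rotations no pattern was assigned to do not dilute the model.
        """
        n = self.n_vox
        if rot_weights is None:
            weighted = tomograms
            wsum = self._wsum
        else:
            rw = np.asarray(rot_weights, dtype=float)[:, None]
            weighted = tomograms * rw
            wsum = np.zeros(n**3)
        num = np.zeros(n**3)
        for k in range(8):
            idx = self._idx8[..., k].ravel()
            w = self._w8[..., k]
            num += np.bincount(
                idx, weights=(weighted * w).ravel(), minlength=n**3
            )
            if rot_weights is not None:
                wsum += np.bincount(
                    idx, weights=(rw * w).ravel(), minlength=n**3
                )
        with np.errstate(invalid="ignore", divide="ignore"):
            vol = np.where(wsum > 1e-12, num / wsum, 0.0)
        return vol.reshape(n, n, n)


def expand(volume: DiffractionVolume, rotations: RotationSet, qmap: QMap):
    """Standalone expand: slice the volume at every rotation of the set."""
    mats = rotations.matrices()
    c = volume.centre
    out = np.empty((len(rotations), qmap.n_pixels))
    for r, m in enumerate(mats):
        coords = (qmap.qvecs @ m.T) / volume.dq + c
        out[r] = map_coordinates(
            volume.data, coords.T, order=1, mode="nearest"
        )
    return np.clip(out, 0.0, None)


def em_iteration(counts, tomograms, weights=None, floor=TOMOGRAM_FLOOR):
    """One EM step in tomogram space.

    ``counts`` is (n_patterns, n_pix) (dense or CSR), ``tomograms`` is
    (n_rot, n_pix) and strictly positive after flooring.  Returns the updated
    tomograms, the data log-likelihood and the posterior matrix P (n_patterns,
    n_rot).  The expected-data log-likelihood is non-decreasing across calls.
    """
    K = counts if sp.issparse(counts) else np.asarray(counts, dtype=float)
    W = np.clip(tomograms, floor, None)
    n_rot = W.shape[0]
    if K.shape[1] != W.shape[1]:
        raise ValueError("pattern/pixel count mismatch with tomograms")
    w_r = np.full(n_rot, 1.0 / n_rot) if weights is None else weights

    lnW = np.log(W)
    sumW = W.sum(axis=1)
    logR = (K @ lnW.T) - sumW[None, :] + np.log(w_r)[None, :]
    logR = np.asarray(logR)
    lse = logsumexp(logR, axis=1)
    P = np.exp(logR - lse[:, None])
    loglik = float(lse.sum())

    denom = P.sum(axis=0)
    numer = np.asarray(P.T @ K)
    with np.errstate(invalid="ignore", divide="ignore"):
        W_new = np.where(denom[:, None] > 1e-300, numer / denom[:, None], W)
    return W_new, loglik, P


def run_emc(
    counts,
    geometry: DetectorGeometry | None = None,
    level: int = 2,
    max_iter: int = 60,
    tol: float = 1e-3,
    seed: int = 0,
    friedel: bool = True,
    operator: EMCOperator | None = None,
):
    """Full EMC reconstruction of a diffraction volume from noisy patterns.

    Starts from a seeded random positive volume and alternates expand,
    EM update and compress (with Friedel symmetrization) until the relative
    RMS voxel-intensity change stays below ``tol`` in two consecutive
    iterations, or ``max_iter`` is reached (then the returned info carries a
    warning flag).  Returns ``(DiffractionVolume, info)``.
    """
    if operator is None:
        if geometry is None:
            raise ValueError("need a DetectorGeometry or a prebuilt EMCOperator")
        operator = EMCOperator(geometry, level=level)
    K = counts if sp.issparse(counts) else np.asarray(counts, dtype=float)
    if K.shape[0] < 2:
        raise ValueError("EMC needs at least two patterns")
    K_live = K[:, operator.live] if K.shape[1] != operator.n_pix else K
    if not sp.issparse(K_live):
        density = np.count_nonzero(K_live) / K_live.size
        if density < 0.25:  # photon-sparse patterns: CSR matmuls win
            K_live = sp.csr_matrix(K_live)

    rng = np.random.default_rng(seed)
    n = operator.n_vox
    scale = max(K_live.sum() / K_live.shape[0] / operator.n_pix, TOMOGRAM_FLOOR)
    vol = rng.uniform(0.5, 1.5, size=(n, n, n)) * scale

    logliks = []
    changes = []
    below = 0
    converged = False
    for _ in range(max_iter):
        W = operator.expand(vol)
        W_new, loglik, P = em_iteration(
            K_live, W, weights=operator.rotations.weights
        )
        vol_new = operator.compress(W_new, rot_weights=P.sum(axis=0))
        if friedel:
            vol_new = 0.5 * (vol_new + vol_new[::-1, ::-1, ::-1])
        denom = np.linalg.norm(vol) or 1.0
        change = np.linalg.norm(vol_new - vol) / denom
        vol = vol_new
        logliks.append(loglik)
        changes.append(change)
        below = below + 1 if change < tol else 0
        if below >= 2:
            converged = True
            break
    info = {
        "converged": converged,
        "n_iter": len(logliks),
        "loglik": np.array(logliks),
        "changes": np.array(changes),
        "n_clamped": operator.n_clamped,
    }
    return DiffractionVolume(np.clip(vol, 0.0, None), operator.dq), info


def slice_volume(volume: DiffractionVolume, quaternion, qmap: QMap) -> np.ndarray:
    """Tomogram of the volume at one arbitrary rotation (scalar-first quat)."""
    q = np.asarray(quaternion, dtype=float)
    m = _R.from_quat(q[[1, 2, 3, 0]]).as_matrix()
    coords = (qmap.qvecs @ m.T) / volume.dq + volume.centre
    return np.clip(
        map_coordinates(volume.data, coords.T, order=1, mode="nearest"), 0.0, None
    )


def _resample(volume: DiffractionVolume, m: np.ndarray, pts: np.ndarray):
    coords = (pts @ m.T) + volume.centre
    return map_coordinates(volume.data, coords.T, order=1, mode="nearest")


def align_volumes(
    volume: DiffractionVolume,
    reference: DiffractionVolume,
    level: int = 2,
    subsample: int = 2,
    refine: bool = True,
):
    """Rotate ``volume`` to best match ``reference``.

    Searches the level-``level`` rotation set for the rotation maximizing the
    Pearson correlation on interior voxels, optionally polishes it with a
    continuous local search (the discrete grid alone leaves a residual
    misorientation of up to half its angular gap), then resamples the full
    volume.  Returns ``(aligned DiffractionVolume, best correlation)``.
    """
    if volume.n != reference.n:
        raise ValueError("volumes must share the same grid")
    n, c = volume.n, volume.centre
    ax = np.arange(0, n, subsample) - c
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)
    interior = np.linalg.norm(pts, axis=1) <= c
    pts = pts[interior]
    ref_vals = _resample(reference, np.eye(3), pts)

    best_corr, best_m = -2.0, np.eye(3)
    for m in sample_rotation_set(level).matrices():
        vals = _resample(volume, m, pts)
        corr = _pearson(vals, ref_vals)
        if corr > best_corr:
            best_corr, best_m = corr, m

    if refine:
        from scipy.optimize import minimize

        def neg_corr(rotvec):
            m = _R.from_rotvec(rotvec).as_matrix() @ best_m
            return -_pearson(_resample(volume, m, pts), ref_vals)

        res = minimize(
            neg_corr, np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200},
        )
        if -res.fun > best_corr:
            best_corr = -res.fun
            best_m = _R.from_rotvec(res.x).as_matrix() @ best_m

    axf = np.arange(n) - c
    gx, gy, gz = np.meshgrid(axf, axf, axf, indexing="ij")
    full = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)
    data = _resample(volume, best_m, full).reshape(n, n, n)
    return DiffractionVolume(np.clip(data, 0.0, None), volume.dq), float(best_corr)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def save_volume(path, volume: DiffractionVolume) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=volume.data)
        f.attrs["dq_invA"] = volume.dq


def load_volume(path) -> DiffractionVolume:
    import h5py

    with h5py.File(path, "r") as f:
        return DiffractionVolume(f["intensities"][...], float(f.attrs["dq_invA"]))
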