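import numpy as np
import pytest

import spisim as s


@pytest.fixture(scope="session")
def small_structure():
    """500-atom pseudo-protein, the standard desk-scale damage fixture."""
    return s.generate_pseudo_protein(500, 20.0, seed=7)


@pytest.fixture(scope="session")
def beam():
    return s.BeamConditions()


@pytest.fixture(scope="session")
def geometry():
    return s.DetectorGeometry()


@pytest.fixture(scope="session")
def qmap(geometry):
    return s.compute_qmap(geometry)


def grid_structure(n_atoms, symbol="C", spacing=2.0):
    """Atoms on a cubic lattice: a cheap many-atom fixture for rate tests."""
    side = int(np.ceil(n_atoms ** (1 / 3)))
    ax = np.arange(side) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pos = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)[:n_atoms]
    pos = pos - pos.mean(axis=0)
    return s.AtomicStructure(np.full(n_atoms, symbol, dtype=object), pos)


def uniform_pulse(flux, t_start, t_end, n=101, photon_energy=4.96):
    """Pulse with constant intensity ``flux`` photons/fs on [t_start, t_end]."""
    times = np.linspace(t_start, t_end, n)
    intens = np.full(n, float(flux))
    total = np.trapezoid(intens, times)
    return s.PulseProfile(times, intens, photon_energy, t_end - t_start, total)


def static_trajectory(structure, times, z_bound=None, n_free=0.0, n_escaped=0.0):
    """Motionless trajectory over the given snapshot times (undamaged unless
    ``z_bound`` is given; charge bookkeeping must balance)."""
    S, N = len(times), len(structure)
    zb = structure.atomic_numbers.astype(float) if z_bound is None else z_bound
    return s.DamageTrajectory(
        snapshot_times=np.asarray(times, dtype=float),
        positions=np.broadcast_to(structure.positions, (S, N, 3)).copy(),
        z_bound=np.broadcast_to(zb, (S, N)).copy(),
        n_free=np.full(S, float(n_free)),
        n_escaped=np.full(S, float(n_escaped)),
        elements=np.asarray(structure.elements, dtype=object),
        dt=float(times[1] - times[0]),
    )
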