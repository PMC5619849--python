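"""Per-atom Monte-Carlo radiation-damage emulator.

This is a declared emulator of an atomistic molecular-dynamics damage code,
not a reimplementation: it reproduces the observables that feed diffraction
(per-snapshot atom positions, bound-electron counts and the trapped
free-electron count) with a minimal stochastic model:

* photoionization with probability ``sigma_ph * (z/Z) * flux * dt`` per step,
  creating an inner-shell hole (one hole per atom at a time);
* hole decay by Auger emission with an exponential per-species lifetime,
  ejecting a second electron (with ``enable_auger=False`` holes relax
  radiatively: the chain continues but no Auger electron is emitted);
* an impact-ionization proxy driven by trapped electrons, rate
  ``k_impact * n_free * z`` per atom;
* electron escape versus electrostatic trapping decided by comparing the
  ejected electron's kinetic energy to the Coulomb barrier of the current
  molecular net charge at the sample radius;
* ion motion under a mean-field radial Coulomb force from the enclosed net
  charge (spherical-symmetry approximation), integrated with velocity-Verlet.

Electrons are counts, not particles; there is no recombination.  Charge is
conserved exactly: sum(Z - z_bound) = n_free + n_escaped at every snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    COULOMB_EV_A,
    ELEMENT_DATA,
    EV_A_AMU_ACC,
    IMPACT_ELECTRON_EV,
)
from .pulse import BeamConditions, PulseProfile, fluence_series
from .sample import AtomicStructure

__all__ = [
    "AtomicRates",
    "DamageParams",
    "DamageTrajectory",
    "run_damage",
    "summarize_trajectories",
    "save_trajectory",
    "load_trajectory",
]


@dataclass
class AtomicRates:
    """Per-element rate constants used by the emulator."""

    atomic_number: int
    mass_amu: float
    sigma_ph_A2: float
    hole_lifetime_fs: float | None
    photoelectron_eV: float
    auger_eV: float | None

    @classmethod
    def for_element(cls, symbol: str) -> "AtomicRates":
        z, m, sig, tau, pe, ae = ELEMENT_DATA[symbol]
        return cls(z, m, sig, tau, pe, ae)


@dataclass
class DamageParams:
    """Knobs of the damage emulator.

    ``impact_rate_const`` (fs^-1 per trapped electron per bound electron) is
    the single calibration parameter of the secondary-ionization proxy; the
    default is chosen so that long (30 fs) pulses on a protein-sized sample
    strip carbon to roughly half its electrons, the qualitative behaviour of
    the reference damage simulations.
    """

    enable_auger: bool = True
    enable_impact: bool = True
    enable_motion: bool = True
    impact_rate_const: float = 3.0e-6
    n_snapshots: int = 100
    substeps: int | None = None  # per snapshot interval; None = automatic
    max_event_prob: float = 0.1
    softening_A: float = 1.0
    record_events: bool = False


@dataclass
class DamageTrajectory:
    """Snapshots of one stochastic damage run.

    ``positions`` has shape (n_snapshots, n_atoms, 3) in Angstrom; ``z_bound``
    (n_snapshots, n_atoms) counts bound electrons; ``n_free`` and
    ``n_escaped`` count trapped and escaped electrons per snapshot.
    """

    snapshot_times: np.ndarray
    positions: np.ndarray
    z_bound: np.ndarray
    n_free: np.ndarray
    n_escaped: np.ndarray
    elements: np.ndarray
    dt: float
    seed: int = 0
    events: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        S, N = self.z_bound.shape
        if self.positions.shape != (S, N, 3):
            raise ValueError("positions/z_bound shape mismatch")
        Zs = np.array([ELEMENT_DATA[e][0] for e in self.elements])
        if np.any(self.z_bound < 0) or np.any(self.z_bound > Zs[None, :]):
            raise ValueError("z_bound must lie in [0, Z]")
        lost = (Zs[None, :] - self.z_bound).sum(axis=1)
        if not np.allclose(lost, self.n_free + self.n_escaped):
            raise ValueError("charge conservation violated")

    @property
    def n_snapshots(self) -> int:
        return self.z_bound.shape[0]

    def displacements(self) -> np.ndarray:
        """|r(t) - r(0)| per snapshot per atom, A."""
        return np.linalg.norm(self.positions - self.positions[0], axis=2)


def _auto_substeps(max_rate: float, dt_snap: float, target: float = 0.05) -> int:
    return max(10, int(np.ceil(max_rate * dt_snap / target)))


def run_damage(
    structure: AtomicStructure,
    pulse: PulseProfile,
    beam: BeamConditions,
    params: DamageParams | None = None,
    seed: int = 0,
) -> DamageTrajectory:
    """Run one stochastic damage trajectory.

    Snapshots are taken on a uniform grid spanning the pulse's time window
    (three times the FWHM), ``params.n_snapshots`` samples.  Deterministic
    under ``seed``.
    """
    params = params or DamageParams()
    n_atoms = len(structure)
    if n_atoms == 0:
        raise ValueError("structure must contain at least one atom")

    rates = [AtomicRates.for_element(e) for e in structure.elements]
    Z = np.array([r.atomic_number for r in rates], dtype=float)
    sigma0 = np.array([r.sigma_ph_A2 for r in rates])
    tau = np.array(
        [r.hole_lifetime_fs if r.hole_lifetime_fs else np.inf for r in rates]
    )
    has_auger = np.array(
        [r.hole_lifetime_fs is not None and r.auger_eV is not None for r in rates]
    )
    pe_ev = np.array([r.photoelectron_eV for r in rates])
    au_ev = np.array([r.auger_eV if r.auger_eV else 0.0 for r in rates])
    mass = np.array([r.mass_amu for r in rates])

    snap_times = np.linspace(
        pulse.times[0], pulse.times[-1], params.n_snapshots
    )
    dt_snap = snap_times[1] - snap_times[0]
    flux_snap = np.interp(snap_times, pulse.times, fluence_series(pulse, beam))

    max_rate = sigma0.max() * fluence_series(pulse, beam).max()
    if params.substeps is None:
        substeps = _auto_substeps(max_rate, dt_snap)
    else:
        substeps = int(params.substeps)
        if max_rate * dt_snap / substeps > params.max_event_prob:
            raise ValueError(
                "time step too coarse: per-step ionization probability "
                f"{max_rate * dt_snap / substeps:.3f} exceeds "
                f"{params.max_event_prob}; use a finer grid (more substeps)"
            )
    dt = dt_snap / substeps

    rng = np.random.default_rng(seed)
    pos = structure.positions.copy()
    vel = np.zeros_like(pos)
    z = Z.copy()
    hole = np.zeros(n_atoms, dtype=bool)
    hole_decay = np.full(n_atoms, np.inf)
    hole_birth = np.zeros(n_atoms)
    n_free = 0
    n_escaped = 0
    R0 = max(structure.radius, 1.0)
    events: list = []

    S = params.n_snapshots
    snap_pos = np.empty((S, n_atoms, 3))
    snap_z = np.empty((S, n_atoms))
    snap_free = np.empty(S)
    snap_esc = np.empty(S)

    def eject(kinetic_ev: np.ndarray) -> None:
        nonlocal n_free, n_escaped
        # barrier from the net charge seen by each departing electron
        for ke in np.atleast_1d(kinetic_ev):
            barrier = COULOMB_EV_A * (n_escaped + 1) / R0
            if ke > barrier:
                n_escaped += 1
            else:
                n_free += 1

    def accel() -> np.ndarray:
        q = Z - z
        r = np.linalg.norm(pos, axis=1)
        order = np.argsort(r)
        cum = np.cumsum(q[order]) - q[order]  # ion charge strictly inside
        q_enc = np.empty(n_atoms)
        q_enc[order] = cum
        q_enc -= n_free * np.minimum(1.0, (r / R0) ** 3)
        fmag = COULOMB_EV_A * q * q_enc / (r**2 + params.softening_A**2)
        rhat = np.divide(pos, r[:, None], out=np.zeros_like(pos), where=r[:, None] > 0)
        return (fmag / mass)[:, None] * rhat * EV_A_AMU_ACC

    a = accel() if params.enable_motion else np.zeros_like(pos)

    for i_snap in range(S):
        snap_pos[i_snap] = pos
        snap_z[i_snap] = z
        snap_free[i_snap] = n_free
        snap_esc[i_snap] = n_escaped
        if i_snap == S - 1:
            break
        t0 = snap_times[i_snap]
        flux0, flux1 = flux_snap[i_snap], flux_snap[i_snap + 1]
        for k in range(substeps):
            t = t0 + k * dt
            flux = flux0 + (flux1 - flux0) * (k + 0.5) / substeps

            # photoionization (inner-shell); blocked while a hole is open
            p = sigma0 * (z / Z) * flux * dt
            p[hole] = 0.0
            hit = rng.random(n_atoms) < p
            hit &= z >= 1
            if hit.any():
                idx = np.flatnonzero(hit)
                z[idx] -= 1
                eject(pe_ev[idx])
                if params.enable_auger:
                    mk = idx[has_auger[idx]]
                    hole[mk] = True
                    hole_birth[mk] = t
                    hole_decay[mk] = t + rng.exponential(tau[mk])

            # Auger decay of open holes
            due = hole & (hole_decay <= t + dt)
            if due.any():
                idx = np.flatnonzero(due)
                if params.record_events:
                    events.extend(
                        (structure.elements[j], hole_birth[j],
                         hole_decay[j] - hole_birth[j])
                        for j in idx
                    )
                ok = idx[z[idx] >= 1]
                z[ok] -= 1
                eject(au_ev[ok])
                hole[idx] = False
                hole_decay[idx] = np.inf

            # impact-ionization proxy by trapped electrons
            if params.enable_impact and n_free > 0:
                p = params.impact_rate_const * n_free * z * dt
                hit = (rng.random(n_atoms) < p) & (z >= 1)
                if hit.any():
                    idx = np.flatnonzero(hit)
                    z[idx] -= 1
                    eject(np.full(len(idx), IMPACT_ELECTRON_EV))

            # Coulomb-expansion ion motion, velocity-Verlet
            if params.enable_motion:
                vel += 0.5 * dt * a
                pos += dt * vel
                a = accel()
                vel += 0.5 * dt * a

    return DamageTrajectory(
        snapshot_times=snap_times,
        positions=snap_pos,
        z_bound=snap_z,
        n_free=snap_free,
        n_escaped=snap_esc,
        elements=np.asarray(structure.elements, dtype=object),
        dt=float(dt_snap),
        seed=seed,
        events=events,
    )


def summarize_trajectories(trajectories, rms: bool = False) -> dict:
    """Per-species mean bound electrons and mean displacement versus time.

    Averages over all atoms of each species and over trajectories — the
    quantities usually plotted for damage runs.  ``rms=True`` switches the
    displacement average from mean |dr| to the root-mean-square.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    t0 = trajectories[0].snapshot_times
    for tr in trajectories[1:]:
        if tr.z_bound.shape != trajectories[0].z_bound.shape or not np.allclose(
            tr.snapshot_times, t0
        ):
            raise ValueError("trajectories have mismatched snapshot grids")

    elements = trajectories[0].elements
    out = {"times": t0, "species": {}}
    for sym in sorted(set(elements)):
        mask = elements == sym
        zs = np.stack([tr.z_bound[:, mask] for tr in trajectories])
        ds = np.stack([tr.displacements()[:, mask] for tr in trajectories])
        disp = np.sqrt((ds**2).mean(axis=(0, 2))) if rms else ds.mean(axis=(0, 2))
        out["species"][sym] = {
            "mean_z_bound": zs.mean(axis=(0, 2)),
            "mean_displacement": disp,
        }
    all_d = np.stack([tr.displacements() for tr in trajectories])
    all_z = np.stack([tr.z_bound for tr in trajectories])
    out["mean_displacement"] = (
        np.sqrt((all_d**2).mean(axis=(0, 2))) if rms else all_d.mean(axis=(0, 2))
    )
    out["mean_z_bound"] = all_z.mean(axis=(0, 2))
    out["mean_n_free"] = np.stack([tr.n_free for tr in trajectories]).mean(axis=0)
    return out


def save_trajectory(path, traj: DamageTrajectory) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=traj.positions)
        f.create_dataset("z_bound", data=traj.z_bound)
        f.create_dataset("n_free", data=traj.n_free)
        f.create_dataset("n_escaped", data=traj.n_escaped)
        f.create_dataset("snapshot_times", data=traj.snapshot_times)
        f.create_dataset(
            "elements", data=np.array([str(e) for e in traj.elements], dtype="S4")
        )
        f.attrs["seed"] = traj.seed
        f.attrs["dt_fs"] = traj.dt


def load_trajectory(path) -> DamageTrajectory:
    import h5py

    with h5py.File(path, "r") as f:
        return DamageTrajectory(
            snapshot_times=f["snapshot_times"][...],
            positions=f["positions"][...],
            z_bound=f["z_bound"][...],
            n_free=f["n_free"][...],
            n_escaped=f["n_escaped"][...],
            elements=np.array(
                [s.decode() for s in f["elements"][...]], dtype=object
            ),
            dt=float(f.attrs["dt_fs"]),
            seed=int(f.attrs["seed"]),
        )
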