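"""Atomic structures, synthetic pseudo-proteins and rigid rotations.

Structures carry only element symbols and centred coordinates: the damage
emulator supplies all dynamics, so occupancies and B factors are ignored, and
alternate locations keep conformer A only.  Coordinates are recentred on the
centroid at load time so random rigid rotations act about the sample centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as _R

from .constants import atomic_number

__all__ = [
    "AtomicStructure",
    "Rotation",
    "read_pdb",
    "write_pdb",
    "generate_pseudo_protein",
    "random_rotation",
    "apply_rotation",
]


@dataclass
class AtomicStructure:
    """Element symbols and centroid-centred coordinates (Angstrom)."""

    elements: np.ndarray
    positions: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if len(self.elements) != len(self.positions):
            raise ValueError("elements/positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        # resolve symbols eagerly so unknown elements fail at load time
        self.atomic_numbers = np.array(
            [atomic_number(e) for e in self.elements], dtype=int
        )

    def __len__(self) -> int:
        return len(self.elements)

    def recentred(self) -> "AtomicStructure":
        return AtomicStructure(
            self.elements, self.positions - self.positions.mean(axis=0),
            label=self.label,
        )

    @property
    def radius(self) -> float:
        """Largest centre-to-atom distance, A."""
        return float(np.linalg.norm(self.positions, axis=1).max())


@dataclass
class Rotation:
    """Rigid rotation stored as a scalar-first unit quaternion.

    q and -q denote the same rotation; the stored representative has a
    non-negative scalar part.
    """

    quaternion: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float)
        if q.shape != (4,):
            raise ValueError("quaternion must be a 4-vector")
        n = np.linalg.norm(q)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("quaternion must be unit-norm")
        q = q / n
        if q[0] < 0:
            q = -q
        self.quaternion = q

    def as_matrix(self) -> np.ndarray:
        w, x, y, z = self.quaternion
        return _R.from_quat([x, y, z, w]).as_matrix()

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "Rotation":
        x, y, z, w = _R.from_matrix(m).as_quat()
        return cls(np.array([w, x, y, z]))

    def angle(self) -> float:
        """Rotation angle in radians, in [0, pi]."""
        return 2.0 * np.arccos(np.clip(abs(self.quaternion[0]), -1.0, 1.0))


def read_pdb(path, drop_hydrogens: bool = False) -> AtomicStructure:
    """Read all ATOM/HETATM records of a PDB file as a centred structure.

    Hydrogens are kept when present unless ``drop_hydrogens``; alternate
    locations keep conformer A.  An empty or atom-less file raises a parse
    error naming the file.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc

    elements, positions = [], []
    if len(st) > 0:
        for chain in st[0]:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("\x00", "", "A"):
                        continue
                    sym = atom.element.name
                    if drop_hydrogens and sym == "H":
                        continue
                    elements.append(sym)
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not elements:
        raise ValueError(f"parse error: no ATOM/HETATM records found in {path}")
    return AtomicStructure(
        np.array(elements, dtype=object), np.array(positions), label=st.name
    ).recentred()


def write_pdb(structure: AtomicStructure, path) -> None:
    """Write a minimal valid PDB file (one chain, one pseudo-residue per atom)."""
    import gemmi

    st = gemmi.Structure()
    st.name = structure.label or "synthetic"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (sym, pos) in enumerate(zip(structure.elements, structure.positions)):
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = sym
        atom.element = gemmi.Element(sym)
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# protein-like non-hydrogen stoichiometry with an Fe/S metal-site flavour
DEFAULT_COMPOSITION = {"C": 0.55, "N": 0.15, "O": 0.25, "S": 0.04, "Fe": 0.01}


def generate_pseudo_protein(
    n_atoms: int,
    radius: float,
    composition: dict | None = None,
    seed: int = 0,
    min_dist: float = 1.0,
    max_tries: int = 200,
) -> AtomicStructure:
    """Uniform random atom cloud in a sphere with protein-like stoichiometry.

    Atoms are placed uniformly in a sphere of the given radius with a minimum
    pair distance (default 1 A) enforced by rejection; element counts match
    the composition fractions to rounding.  Deterministic under ``seed``.
    """
    if n_atoms <= 0:
        raise ValueError("n_atoms must be positive")
    if radius <= 0:
        raise ValueError("radius must be positive")
    composition = dict(composition or DEFAULT_COMPOSITION)
    total = sum(composition.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"composition fractions must sum to 1, got {total}")

    # largest-remainder apportionment of element counts
    symbols = sorted(composition)
    raw = np.array([composition[s] * n_atoms for s in symbols])
    counts = np.floor(raw).astype(int)
    rem = n_atoms - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1

    rng = np.random.default_rng(seed)

    def _pack(sampling_radius):
        accepted = np.empty((0, 3))
        for _ in range(max_tries):
            need = n_atoms - len(accepted)
            if need == 0:
                break
            cand = rng.standard_normal((4 * need, 3))
            cand *= (
                sampling_radius
                * rng.random(len(cand))[:, None] ** (1.0 / 3.0)
                / np.linalg.norm(cand, axis=1)[:, None]
            )
            if len(accepted):
                tree = cKDTree(accepted)
                cand = cand[tree.query(cand, k=1)[0] >= min_dist]
            # greedy thinning of the batch itself
            for p in cand:
                if len(accepted) == n_atoms:
                    break
                if len(accepted) == 0 or np.min(
                    np.linalg.norm(accepted - p, axis=1)
                ) >= min_dist:
                    accepted = np.vstack([accepted, p])
        if len(accepted) < n_atoms:
            raise ValueError(
                f"cannot pack {n_atoms} atoms with min distance {min_dist} A in "
                f"a {radius} A sphere (placed {len(accepted)})"
            )
        return accepted

    # recentring on the centroid can push edge atoms slightly outside the
    # requested radius; shrink the sampling sphere until the centred cloud fits
    sampling_radius = radius
    for _ in range(20):
        pos = _pack(sampling_radius)
        pos -= pos.mean(axis=0)
        overshoot = np.linalg.norm(pos, axis=1).max() - radius
        if overshoot <= 0:
            break
        sampling_radius -= overshoot + 1e-3
    else:
        raise ValueError("could not fit centred cloud inside the requested radius")

    elements = np.concatenate(
        [np.full(c, s, dtype=object) for s, c in zip(symbols, counts)]
    )
    rng.shuffle(elements)
    return AtomicStructure(elements, pos, label="pseudo-protein")


def random_rotation(rng) -> Rotation:
    """Uniform random rotation on SO(3) (Shoemake subgroup construction)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    q = np.array(
        [
            b * np.cos(2 * np.pi * u3),
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
        ]
    )
    return Rotation(q)


def apply_rotation(structure: AtomicStructure, rotation: Rotation) -> AtomicStructure:
    """Rotate every atom about the sample centre; distances are preserved."""
    m = rotation.as_matrix()
    return AtomicStructure(
        structure.elements, structure.positions @ m.T, label=structure.label
    )
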