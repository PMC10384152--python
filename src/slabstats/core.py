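"""Domain types: atoms, topology, frames and trajectories.

A :class:`Topology` is the static description of a configuration — atom
names, elements, residues, role labels, bonds and the 12 backbone torsion
quadruples of each surfactant. A :class:`Frame` holds positions (nm) at one
time (ps); a :class:`Trajectory` is an ordered sequence of frames sharing
one topology.

Role labels tie analysis code to chemistry without hard-coding any atom
numbering: ``N1`` (quaternary ammonium nitrogen), ``C16`` (carboxylate
carbon), ``C4`` (first tail carbon bonded to N1), ``C15`` (terminal tail
methyl), ``O_carboxyl`` (the two head-group oxygens), ``OW``/``HW`` (water).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .box import PeriodicBox
from .exceptions import ArgumentError, RoleError, StructuralError, TopologyError

#: Recognised role labels.
ROLES = ("N1", "C16", "C4", "C15", "O_carboxyl", "OW", "HW")

#: Roles that must be unique within a surfactant residue.
UNIQUE_ROLES = ("N1", "C16", "C4", "C15")

#: Residue names treated as water when inferring bonds.
WATER_RESNAMES = ("SOL", "WAT", "HOH", "TIP3", "SPC")


@dataclass
class AtomRecord:
    """One atom: naming, residue membership and optional role label."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    role: str | None = None

    def __post_init__(self):
        if self.role is not None and self.role not in ROLES:
            raise ArgumentError(f"unknown role label {self.role!r}")


class Topology:
    """Atoms plus connectivity and per-residue torsion definitions.

    Parameters
    ----------
    atoms : list of AtomRecord
    bonds : list of (i, j) atom-index pairs, optional
    dihedrals : mapping residue_index -> list of 12 atom-index quadruples,
        ordered head-to-tail, optional
    """

    def __init__(self, atoms, bonds=None, dihedrals=None):
        self.atoms: list[AtomRecord] = list(atoms)
        self.bonds: list[tuple[int, int]] = [tuple(b) for b in (bonds or [])]
        self.dihedrals: dict[int, list[tuple[int, int, int, int]]] = {
            int(k): [tuple(q) for q in v] for k, v in (dihedrals or {}).items()
        }
        self._check_unique_roles()

    # -- basic views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_indices(self) -> list[int]:
        seen = dict.fromkeys(a.residue_index for a in self.atoms)
        return list(seen)

    def atoms_in_residue(self, residue_index: int) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.residue_index == residue_index],
            dtype=int,
        )

    def atoms_by_residue(self) -> dict[int, list[int]]:
        """Residue index -> atom indices, in one pass over the atoms."""
        out: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_index, []).append(i)
        return out

    def indices_with_role(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ArgumentError(f"unknown role label {role!r}")
        return np.array([i for i, a in enumerate(self.atoms) if a.role == role], dtype=int)

    def require_role(self, role: str) -> np.ndarray:
        idx = self.indices_with_role(role)
        if idx.size == 0:
            raise RoleError(f"no atoms labeled with role {role!r}")
        return idx

    def indices_with_name(self, name: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.name == name], dtype=int)

    def residues_with_role(self, role: str) -> list[int]:
        seen = dict.fromkeys(self.atoms[i].residue_index for i in self.indices_with_role(role))
        return list(seen)

    # -- roles -------------------------------------------------------------

    def _check_unique_roles(self):
        per_res: dict[tuple[int, str], int] = {}
        for a in self.atoms:
            if a.role in UNIQUE_ROLES:
                key = (a.residue_index, a.role)
                per_res[key] = per_res.get(key, 0) + 1
                if per_res[key] > 1:
                    raise TopologyError(
                        f"role {a.role!r} appears more than once in residue "
                        f"{a.residue_index}"
                    )

    def apply_role_map(self, role_map: dict) -> None:
        """Assign roles from ``{resname: {atom_name: role}}`` (or a flat
        ``{atom_name: role}`` applied to every residue)."""
        flat = not any(isinstance(v, dict) for v in role_map.values())
        for a in self.atoms:
            sub = role_map if flat else role_map.get(a.residue_name, {})
            role = sub.get(a.name)
            if role is not None:
                if role not in ROLES:
                    raise ArgumentError(f"unknown role label {role!r}")
                a.role = role
        self._check_unique_roles()

    # -- connectivity ------------------------------------------------------

    def bonded_to(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def donor_hydrogen_map(self) -> dict[int, list[int]]:
        """Map heavy donor atom index -> bonded hydrogen indices.

        Every hydrogen must be bonded to exactly one heavy atom.
        """
        adj: dict[int, list[int]] = {}
        for a, b in self.bonds:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        out: dict[int, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            if atom.element != "H":
                continue
            heavies = [j for j in adj.get(i, []) if self.atoms[j].element != "H"]
            if len(heavies) != 1:
                raise TopologyError(
                    f"hydrogen atom {i} ({atom.name}) has {len(heavies)} bonded "
                    "heavy atoms; expected exactly one donor"
                )
            out.setdefault(heavies[0], []).append(i)
        return out

    def surfactant_dihedrals(self) -> dict[int, list[tuple[int, int, int, int]]]:
        """Validated 12-torsion table per surfactant residue."""
        if not self.dihedrals:
            raise TopologyError("topology defines no dihedral quadruples")
        bond_set = {frozenset(b) for b in self.bonds}
        for res, quads in self.dihedrals.items():
            if len(quads) != 12:
                raise TopologyError(
                    f"residue {res} exposes {len(quads)} dihedrals, expected 12"
                )
            for q in quads:
                if len(set(q)) != 4:
                    raise TopologyError(f"dihedral {q} has repeated atoms")
                for i in q:
                    if self.atoms[i].residue_index != res:
                        raise TopologyError(
                            f"dihedral {q} references atom {i} outside residue {res}"
                        )
                if bond_set:
                    for a, b in zip(q, q[1:]):
                        if frozenset((a, b)) not in bond_set:
                            raise TopologyError(
                                f"dihedral {q}: atoms {a}-{b} are not bonded"
                            )
        return self.dihedrals

    def infer_water_bonds(self) -> None:
        """Add O-H bonds for water residues (by residue name) if absent."""
        existing = {frozenset(b) for b in self.bonds}
        for res, idx in self.atoms_by_residue().items():
            if self.atoms[idx[0]].residue_name not in WATER_RESNAMES:
                continue
            oxy = [i for i in idx if self.atoms[i].element == "O"]
            hyd = [i for i in idx if self.atoms[i].element == "H"]
            if len(oxy) == 1:
                for h in hyd:
                    if frozenset((oxy[0], h)) not in existing:
                        self.bonds.append((oxy[0], h))


@dataclass
class Frame:
    """Positions (nm) of all atoms at one instant."""

    positions: np.ndarray
    box: PeriodicBox
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.time < 0:
            raise ArgumentError("frame time must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


class Trajectory:
    """Ordered frames over one topology with strictly increasing times.

    ``metadata`` is a free-form dict; synthetic generators use it to attach
    their realized ground truth (planted torsion states, drawn tilts, ...).
    """

    def __init__(self, topology: Topology, frames, metadata: dict | None = None):
        self.topology = topology
        self.metadata = dict(metadata or {})
        self.frames: list[Frame] = list(frames)
        if not self.frames:
            raise ArgumentError("trajectory needs at least one frame")
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != topology.n_atoms:
                raise StructuralError(
                    f"frame {k} has {fr.n_atoms} positions for a topology of "
                    f"{topology.n_atoms} atoms"
                )
        times = [fr.time for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ArgumentError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k) -> Frame:
        return self.frames[k]

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def dt(self) -> float:
        """Nominal frame spacing in ps (from the first two frames; 1.0 for a
        single-frame trajectory)."""
        if len(self.frames) < 2:
            return 1.0
        return self.frames[1].time - self.frames[0].time

    @classmethod
    def from_frame(cls, topology: Topology, frame: Frame) -> "Trajectory":
        return cls(topology, [frame])
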