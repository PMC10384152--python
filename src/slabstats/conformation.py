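"""Chain conformation statistics: gauche defects, tilt angles, tail lengths.

A backbone torsion is *gauche* when it deviates from the anti (trans, 180
degree) conformation by more than 60 degrees of circular distance; exactly
60 degrees (torsion 120 or 240) is still trans, reading the defining
inequality strictly. Tilt angles are measured against the outward normal of
the molecule's leaflet (+z above the water slab midplane, -z below), so 0
degrees points to the vapor phase, 90 degrees lies in the interface plane
and 180 degrees points into the water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory
from .exceptions import GeometryError, RoleError, TopologyError
from .geometry import dihedral_angles


def classify_gauche(angle_deg: float) -> bool:
    """True iff the torsion (degrees, [0, 360)) is a gauche defect."""
    a = np.mod(np.asarray(angle_deg, dtype=float), 360.0)
    return np.abs(a - 180.0) > 60.0


@dataclass
class GaucheProfile:
    """Per-torsion gauche fractions (head torsion 1 ... tail torsion 12)."""

    p_gauche: np.ndarray
    counts: np.ndarray  # (12, 2): gauche / trans tallies

    def to_text(self) -> str:
        lines = ["# dihedral p_gauche n_gauche n_trans"]
        for k in range(12):
            lines.append(
                f"{k + 1} {self.p_gauche[k]:.6f} "
                f"{int(self.counts[k, 0])} {int(self.counts[k, 1])}")
        return "\n".join(lines) + "\n"


def gauche_profile(trajectory: Trajectory) -> GaucheProfile:
    """Fraction of gauche states per torsion over all molecules and frames."""
    quads_by_res = trajectory.topology.surfactant_dihedrals()
    quads = np.array([quads_by_res[res] for res in sorted(quads_by_res)])
    if quads.size == 0:
        raise TopologyError("no surfactant dihedrals defined")
    gauche_counts = np.zeros(12)
    total = 0
    for fr in trajectory:
        p = fr.positions
        ang = dihedral_angles(p[quads[..., 0]], p[quads[..., 1]],
                              p[quads[..., 2]], p[quads[..., 3]])
        gauche_counts += classify_gauche(ang).sum(axis=0)
        total += quads.shape[0]
    p_gauche = gauche_counts / total
    counts = np.stack([gauche_counts, total - gauche_counts], axis=1)
    return GaucheProfile(p_gauche, counts)


@dataclass
class TiltReport:
    """Per-molecule, per-frame tilt angles (degrees) vs the outward normal.

    ``a_tail`` uses the C4->C15 vector, ``a_whole`` C16->C15 and ``a_polar``
    C16->C4. Arrays are (frames, molecules); means are pooled arithmetic
    averages in degrees.
    """

    a_tail: np.ndarray
    a_whole: np.ndarray
    a_polar: np.ndarray
    leaflet_id: np.ndarray

    @property
    def mean_a_tail(self) -> float:
        return float(self.a_tail.mean())

    @property
    def mean_a_whole(self) -> float:
        return float(self.a_whole.mean())

    @property
    def mean_a_polar(self) -> float:
        return float(self.a_polar.mean())


def _role_atom_per_molecule(topology, role, molecules):
    idx = topology.indices_with_role(role)
    by_res = {topology.atoms[i].residue_index: i for i in idx}
    try:
        return np.array([by_res[m] for m in molecules], dtype=int)
    except KeyError as exc:
        raise RoleError(f"molecule {exc} lacks an atom with role {role!r}")


def leaflet_assignment(trajectory: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(molecule residue ids, leaflet sign per molecule) frozen from the
    first frame: +1 above the water-slab center of mass, -1 below. Without
    labeled waters the box midplane is the divider."""
    top = trajectory.topology
    molecules = top.residues_with_role("N1")
    if not molecules:
        raise RoleError("no surfactant molecules (role N1) labeled")
    heads = _role_atom_per_molecule(top, "N1", molecules)
    fr = trajectory[0]
    waters = top.indices_with_role("OW")
    z_mid = fr.positions[waters][:, 2].mean() if waters.size else fr.box.lz / 2.0
    sign = np.where(fr.positions[heads][:, 2] >= z_mid, 1.0, -1.0)
    return np.array(molecules), sign


def tilt_angles(trajectory: Trajectory) -> TiltReport:
    """Tilt of tail (C4->C15), whole molecule (C16->C15) and polar head
    (C16->C4) against each molecule's outward leaflet normal."""
    top = trajectory.topology
    molecules, leaflet = leaflet_assignment(trajectory)
    c4 = _role_atom_per_molecule(top, "C4", molecules)
    c15 = _role_atom_per_molecule(top, "C15", molecules)
    c16 = _role_atom_per_molecule(top, "C16", molecules)

    def angles(vec: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(vec, axis=-1)
        if np.any(norms < 1e-9):
            raise GeometryError("zero-length tilt-defining vector")
        cosang = vec[..., 2] * leaflet / norms
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    a_tail, a_whole, a_polar = [], [], []
    for fr in trajectory:
        p = fr.positions
        a_tail.append(angles(p[c15] - p[c4]))
        a_whole.append(angles(p[c15] - p[c16]))
        a_polar.append(angles(p[c4] - p[c16]))
    return TiltReport(np.array(a_tail), np.array(a_whole), np.array(a_polar),
                      leaflet)


@dataclass
class ChainLengthResult:
    """Histogram of per-molecule, per-frame tail end-to-end lengths (nm)."""

    lengths: np.ndarray  # (frames, molecules)
    bin_centers: np.ndarray
    histogram: np.ndarray
    bin_width: float

    @property
    def mean(self) -> float:
        return float(self.lengths.mean())


def chain_length_distribution(trajectory: Trajectory,
                              bin_width: float = 0.01) -> ChainLengthResult:
    """Euclidean C4-C15 distance histogram over molecules and frames.

    The chain span is measured without minimum-image wrapping: molecules are
    assumed whole, and a 12-carbon tail (max ~1.4 nm) cannot legitimately
    span half a periodic edge of the studied boxes.
    """
    top = trajectory.topology
    molecules = top.residues_with_role("C4")
    if not molecules:
        raise RoleError("no molecules with labeled tail endpoints")
    c4 = _role_atom_per_molecule(top, "C4", molecules)
    c15 = _role_atom_per_molecule(top, "C15", molecules)
    lengths = np.array([
        np.linalg.norm(fr.positions[c15] - fr.positions[c4], axis=1)
        for fr in trajectory
    ])
    lo = 0.0
    hi = float(lengths.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist, _ = np.histogram(lengths.ravel(), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ChainLengthResult(lengths, centers, hist, bin_width)
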