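"""Synthetic monolayer, water-slab and H-bond time-series generators.

Every downstream statistic in the package has a generator here that plants
its ground truth: a tanh-profile water slab of known 10-90 width, surfactant
chains with per-torsion gauche probabilities and a prescribed tilt of the
tail axis, waters planted at exact H-bond geometries, and two-state
(telegraph) bond kinetics with a closed-form autocorrelation.

The default composition mirrors the studied systems: an 8 x 8 x 24 nm box
with a central 8 x 8 x 8 nm water slab at liquid-water number density
(~33.4 nm^-3, i.e. ~17k waters) and equal surfactant counts on the two
leaflets. Chains are built from idealized internal coordinates (C-C
0.153 nm, tetrahedral backbone angles, torsions trans 180 deg or gauche
+/-60 deg); the statistics under test are geometric, so no energetics are
involved.

All randomness flows through one ``numpy`` generator seeded from the spec:
identical spec and seed give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .box import PeriodicBox
from .core import AtomRecord, Frame, Topology, Trajectory
from .exceptions import ArgumentError, CapacityError, GeometryError
from .geometry import place_atom, random_rotation, rotation_aligning

# Rigid 3-site water geometry (nm / degrees).
WATER_OH = 0.09572
WATER_HOH = 104.52

# Idealized surfactant internal coordinates (nm / degrees).
CC_BOND = 0.153
CN_BOND = 0.147
CO_BOND = 0.125
TETRAHEDRAL = 109.4712206
CARBOXYL_OCO_HALF = 117.0

#: Default per-torsion gauche probabilities, head (1) to tail (12): high for
#: the two head torsions, a deep minimum at torsion 3, then a shallow
#: alkyl-chain plateau rising slightly at the terminal torsion.
DEFAULT_GAUCHE_PROB = (0.5, 0.6, 0.08, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.15)

#: Names of the 12 torsion quadruples, head CCNC first, terminal CCCC last.
DIHEDRAL_NAME_QUADS = (
    ("C16", "C3", "N1", "C4"),
    ("C3", "N1", "C4", "C5"),
    ("N1", "C4", "C5", "C6"),
    ("C4", "C5", "C6", "C7"),
    ("C5", "C6", "C7", "C8"),
    ("C6", "C7", "C8", "C9"),
    ("C7", "C8", "C9", "C10"),
    ("C8", "C9", "C10", "C11"),
    ("C9", "C10", "C11", "C12"),
    ("C10", "C11", "C12", "C13"),
    ("C11", "C12", "C13", "C14"),
    ("C12", "C13", "C14", "C15"),
)

#: Surfactant heavy atoms in residue order. N-methyls C1/C2, head CH2 C3,
#: carboxylate C16 with O1/O2, tail C4..C15.
NDB_ATOM_NAMES = (
    ["N1", "C1", "C2", "C3", "C16", "O1", "O2"]
    + [f"C{k}" for k in range(4, 16)]
)

NDB_BOND_NAME_PAIRS = (
    [("N1", "C1"), ("N1", "C2"), ("N1", "C3"), ("N1", "C4"),
     ("C3", "C16"), ("C16", "O1"), ("C16", "O2")]
    + [(f"C{k}", f"C{k + 1}") for k in range(4, 15)]
)

NDB_ROLE_MAP = {
    "N1": "N1", "C16": "C16", "C4": "C4", "C15": "C15",
    "O1": "O_carboxyl", "O2": "O_carboxyl",
}

WATER_ROLE_MAP = {"OW": "OW", "HW1": "HW", "HW2": "HW"}


def default_annotation() -> dict:
    """Sidecar annotation matching the synthetic surfactant template."""
    return {
        "roles": {"NDB": dict(NDB_ROLE_MAP), "SOL": dict(WATER_ROLE_MAP)},
        "bonds": {
            "NDB": [list(p) for p in NDB_BOND_NAME_PAIRS],
            "SOL": [["OW", "HW1"], ["OW", "HW2"]],
        },
        "dihedrals": {"NDB": [list(q) for q in DIHEDRAL_NAME_QUADS]},
    }


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class MonolayerSpec:
    """Recipe for a synthetic monolayer/water-slab system.

    ``gauche_prob`` holds the 12 per-torsion gauche probabilities head to
    tail; ``tilt_mean``/``tilt_sd`` (degrees) set the Normal distribution of
    the angle between the C4->C15 tail axis and the outward leaflet normal;
    ``interface_width_w`` is the tanh parameter w of the water density
    profile (10-90 width = 2*atanh(0.8)*w ~ 2.1972 w).
    """

    box: PeriodicBox = field(default_factory=lambda: PeriodicBox(8.0, 8.0, 24.0))
    n_surfactant_per_leaflet: int = 32
    tilt_mean: float = 30.0
    tilt_sd: float = 10.0
    gauche_prob: tuple = DEFAULT_GAUCHE_PROB
    bond_length: float = CC_BOND
    water_slab_halfwidth: float = 4.0
    interface_width_w: float = 0.2
    water_number_density: float = 33.4
    seed: int = 0
    n_frames: int = 1
    dt: float = 1.0
    include_water: bool = True
    jitter_frac: float = 0.1
    torsion_jitter_sd: float = 0.0

    def __post_init__(self):
        if self.n_surfactant_per_leaflet < 0:
            raise ArgumentError("surfactant count must be non-negative")
        if len(self.gauche_prob) != 12:
            raise ArgumentError("gauche_prob must hold 12 probabilities")
        if any(not (0.0 <= p <= 1.0) for p in self.gauche_prob):
            raise ArgumentError("gauche probabilities must lie in [0, 1]")
        for name in ("bond_length", "water_slab_halfwidth", "interface_width_w",
                     "water_number_density", "dt"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be positive")
        if self.tilt_sd < 0 or self.torsion_jitter_sd < 0:
            raise ArgumentError("standard deviations must be non-negative")
        if self.n_frames < 1:
            raise ArgumentError("n_frames must be at least 1")

    @property
    def z_lo(self) -> float:
        return self.box.lz / 2.0 - self.water_slab_halfwidth

    @property
    def z_hi(self) -> float:
        return self.box.lz / 2.0 + self.water_slab_halfwidth

    def to_dict(self) -> dict:
        d = asdict(self)
        d["box"] = {"lx": self.box.lx, "ly": self.box.ly, "lz": self.box.lz,
                    "periodic_z": self.box.periodic_z}
        d["gauche_prob"] = list(self.gauche_prob)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MonolayerSpec":
        d = dict(d)
        if "box" in d and isinstance(d["box"], dict):
            d["box"] = PeriodicBox(**d["box"])
        if "gauche_prob" in d:
            d["gauche_prob"] = tuple(d["gauche_prob"])
        return cls(**d)


@dataclass
class TelegraphSpec:
    """Two-state Markov (telegraph) H-bond kinetics sampled at interval dt.

    ``k_off`` is the bound->free rate, ``k_on`` the free->bound rate, both in
    ps^-1. The stationary bound fraction is p = k_on/(k_on + k_off) and the
    intermittent autocorrelation is C(t) = p + (1-p) exp(-(k_on+k_off) t).
    """

    k_off: float
    k_on: float
    n_pairs: int = 1000
    dt: float = 0.1
    n_steps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.k_off <= 0 or self.k_on <= 0:
            raise ArgumentError("telegraph rates must be positive")
        if self.dt <= 0:
            raise ArgumentError("dt must be positive")
        if self.n_pairs < 1 or self.n_steps < 2:
            raise ArgumentError("need at least 1 pair and 2 steps")

    @property
    def rate_sum(self) -> float:
        return self.k_on + self.k_off

    @property
    def p_bound(self) -> float:
        return self.k_on / self.rate_sum


def telegraph_correlation(spec: TelegraphSpec, lags_ps: np.ndarray) -> np.ndarray:
    """Closed-form intermittent autocorrelation of the telegraph process."""
    t = np.asarray(lags_ps, dtype=float)
    p = spec.p_bound
    return p + (1.0 - p) * np.exp(-spec.rate_sum * t)


# ---------------------------------------------------------------------------
# Water slab
# ---------------------------------------------------------------------------

def water_slab_profile(spec: MonolayerSpec, z: np.ndarray) -> np.ndarray:
    """Target water number density rho(z) =
    rho0/2 [tanh((z - z_lo)/w) - tanh((z - z_hi)/w)]."""
    z = np.asarray(z, dtype=float)
    w = spec.interface_width_w
    return 0.5 * spec.water_number_density * (
        np.tanh((z - spec.z_lo) / w) - np.tanh((z - spec.z_hi) / w)
    )


def _water_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2, 3) offsets of the two hydrogens for random rigid orientations."""
    half = np.radians(WATER_HOH / 2.0)
    base = np.array(
        [
            [np.sin(half), 0.0, np.cos(half)],
            [-np.sin(half), 0.0, np.cos(half)],
        ]
    ) * WATER_OH
    out = np.empty((n, 2, 3))
    for i in range(n):
        out[i] = base @ random_rotation(rng).T
    return out


def _sample_slab_z(spec: MonolayerSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample z coordinates against the tanh profile."""
    out = np.empty(0)
    lz = spec.box.lz
    rho0 = spec.water_number_density
    while out.size < n:
        cand = rng.uniform(0.0, lz, size=2 * n)
        keep = rng.uniform(0.0, 1.0, size=cand.size) < (
            water_slab_profile(spec, cand) / rho0
        )
        out = np.concatenate([out, cand[keep]])
    return out[:n]


def _expected_water_count(spec: MonolayerSpec) -> int:
    z = np.linspace(0.0, spec.box.lz, 4001)
    line_density = np.trapezoid(water_slab_profile(spec, z), z)
    return int(round(line_density * spec.box.cross_section))


def _water_positions(spec, n, rng, include_hydrogens=True) -> np.ndarray:
    pos_o = np.empty((n, 3))
    pos_o[:, 0] = rng.uniform(0.0, spec.box.lx, size=n)
    pos_o[:, 1] = rng.uniform(0.0, spec.box.ly, size=n)
    pos_o[:, 2] = _sample_slab_z(spec, n, rng)
    if not include_hydrogens:
        return pos_o.reshape(n, 1, 3)
    hh = _water_orientations(n, rng)
    return np.concatenate([pos_o[:, None, :], pos_o[:, None, :] + hh], axis=1)


def _water_topology(n: int, include_hydrogens: bool, first_residue: int = 0):
    atoms, bonds = [], []
    names = ["OW", "HW1", "HW2"] if include_hydrogens else ["OW"]
    for m in range(n):
        base = len(atoms)
        res = first_residue + m
        for name in names:
            atoms.append(AtomRecord(name, name[0], res, "SOL",
                                    role="OW" if name == "OW" else "HW"))
        if include_hydrogens:
            bonds += [(base, base + 1), (base, base + 2)]
    return atoms, bonds


def build_water_slab(spec: MonolayerSpec, include_hydrogens: bool = True,
                     rng: np.random.Generator | None = None):
    """Build one water-slab configuration; returns ``(Topology, Frame)``.

    Oxygen z coordinates are rejection-sampled against the tanh profile so
    the binned density matches the target within counting noise; hydrogens
    are attached at the rigid 3-site geometry with uniformly random
    orientation.
    """
    if spec.z_lo < 0 or spec.z_hi > spec.box.lz:
        raise GeometryError("water slab is wider than the box")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = _expected_water_count(spec)
    coords = _water_positions(spec, n, rng, include_hydrogens)
    atoms, bonds = _water_topology(n, include_hydrogens)
    topology = Topology(atoms, bonds=bonds)
    return topology, Frame(coords.reshape(-1, 3), spec.box, 0.0)


def build_water_slab_trajectory(spec: MonolayerSpec, n_frames: int,
                                include_hydrogens: bool = True):
    """Independent slab snapshots sharing one topology: ``(Topology,
    Trajectory)``.

    Frames are fresh rejection-sampled configurations (no dynamics), the
    natural input for frame-averaged profiles.
    """
    if spec.z_lo < 0 or spec.z_hi > spec.box.lz:
        raise GeometryError("water slab is wider than the box")
    if n_frames < 1:
        raise ArgumentError("n_frames must be at least 1")
    rng = np.random.default_rng(spec.seed)
    n = _expected_water_count(spec)
    atoms, bonds = _water_topology(n, include_hydrogens)
    topology = Topology(atoms, bonds=bonds)
    frames = [
        Frame(_water_positions(spec, n, rng, include_hydrogens).reshape(-1, 3),
              spec.box, float(t) * spec.dt)
        for t in range(n_frames)
    ]
    return topology, Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# Surfactant chain construction
# ---------------------------------------------------------------------------

def _tetrahedral_directions():
    """Unit vectors: +z plus three directions at the tetrahedral angle."""
    theta = np.radians(TETRAHEDRAL)
    dirs = [np.array([0.0, 0.0, 1.0])]
    for az in (0.0, 120.0, 240.0):
        a = np.radians(az)
        dirs.append(np.array(
            [np.sin(theta) * np.cos(a), np.sin(theta) * np.sin(a), np.cos(theta)]
        ))
    return dirs


_TET_DIRS = _tetrahedral_directions()


def build_ndb_chain(torsions_deg: np.ndarray, bond_cc: float = CC_BOND) -> dict:
    """Build one surfactant molecule from its 12 torsions.

    Returns ``{atom_name: position}`` in a local frame with N1 at the origin
    and the N1->C4 bond along +z. Torsion k of the result equals
    ``torsions_deg[k]`` exactly (trans = 180).
    """
    t = np.asarray(torsions_deg, dtype=float)
    if t.shape != (12,):
        raise ArgumentError("expected 12 torsion angles")
    pos: dict[str, np.ndarray] = {}
    pos["N1"] = np.zeros(3)
    pos["C4"] = CN_BOND * _TET_DIRS[0]
    pos["C3"] = CN_BOND * _TET_DIRS[1]
    pos["C1"] = CN_BOND * _TET_DIRS[2]
    pos["C2"] = CN_BOND * _TET_DIRS[3]
    # Head group: carboxylate carbon via torsion 1 (C16-C3-N1-C4 == C4-N1-C3-C16).
    pos["C16"] = place_atom(pos["C4"], pos["N1"], pos["C3"],
                            bond_cc, TETRAHEDRAL, t[0])
    # Planar carboxylate: two oxygens at fixed torsions about C3-C16.
    pos["O1"] = place_atom(pos["N1"], pos["C3"], pos["C16"],
                           CO_BOND, CARBOXYL_OCO_HALF, 90.0)
    pos["O2"] = place_atom(pos["N1"], pos["C3"], pos["C16"],
                           CO_BOND, CARBOXYL_OCO_HALF, 270.0)
    # Tail: C5 via torsion 2, C6 via torsion 3, then CCCC torsions 4..12.
    pos["C5"] = place_atom(pos["C3"], pos["N1"], pos["C4"],
                           bond_cc, TETRAHEDRAL, t[1])
    pos["C6"] = place_atom(pos["N1"], pos["C4"], pos["C5"],
                           bond_cc, TETRAHEDRAL, t[2])
    for k in range(3, 12):
        a, b, c, d = DIHEDRAL_NAME_QUADS[k]
        pos[d] = place_atom(pos[a], pos[b], pos[c], bond_cc, TETRAHEDRAL, t[k])
    return pos


def all_trans_tail_length(n_carbons: int = 12, bond: float = CC_BOND) -> float:
    """Exact end-to-end length of an all-trans zigzag of ``n_carbons`` atoms.

    Each bond advances bond*sin(theta/2) along the zigzag axis. With an even
    bond count both endpoints lie on the axis and the length is the familiar
    (n-1)*bond*sin(theta/2); with an odd bond count (e.g. the 11 C-C bonds
    of a C12 tail) the endpoints sit on opposite sides of the axis and the
    exact length carries a transverse term bond*cos(theta/2):
    sqrt(axial^2 + (bond*cos(theta/2))^2).
    """
    half = np.radians(TETRAHEDRAL) / 2.0
    n_bonds = n_carbons - 1
    axial = n_bonds * bond * np.sin(half)
    if n_bonds % 2 == 0:
        return float(axial)
    return float(np.hypot(axial, bond * np.cos(half)))


def sample_torsions(spec: MonolayerSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw 12 torsions: trans 180 or gauche +/-60 (fair coin) per the
    per-torsion probabilities, plus optional Gaussian jitter."""
    p = np.asarray(spec.gauche_prob)
    gauche = rng.uniform(size=12) < p
    sign = np.where(rng.uniform(size=12) < 0.5, 1.0, -1.0)
    t = np.where(gauche, 180.0 + sign * 120.0, 180.0)
    if spec.torsion_jitter_sd > 0:
        t = t + rng.normal(0.0, spec.torsion_jitter_sd, size=12)
    return np.mod(t, 360.0)


_CHAIN_ORDER = list(NDB_ATOM_NAMES)
_NONBONDED_MASK = None


def _nonbonded_pairs():
    """Index pairs of the template separated by more than two bonds."""
    global _NONBONDED_MASK
    if _NONBONDED_MASK is not None:
        return _NONBONDED_MASK
    n = len(_CHAIN_ORDER)
    name_to_i = {nm: i for i, nm in enumerate(_CHAIN_ORDER)}
    adj = np.zeros((n, n), dtype=bool)
    for a, b in NDB_BOND_NAME_PAIRS:
        adj[name_to_i[a], name_to_i[b]] = adj[name_to_i[b], name_to_i[a]] = True
    two = adj @ adj
    close = adj | two | np.eye(n, dtype=bool)
    ii, jj = np.where(~close)
    keep = ii < jj
    _NONBONDED_MASK = (ii[keep], jj[keep])
    return _NONBONDED_MASK


def _has_overlap(coords: np.ndarray, cutoff: float = 0.15) -> bool:
    ii, jj = _nonbonded_pairs()
    d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    return bool(np.any(d < cutoff))


def _build_molecule(spec: MonolayerSpec, rng: np.random.Generator,
                    upper: bool) -> tuple[np.ndarray, float, np.ndarray, int]:
    """Build, tilt and orient one molecule.

    Returns (coords in template order relative to N1, drawn tilt angle in
    degrees, accepted torsions, number of rejected self-overlapping draws).
    Rejection depletes clash-prone torsion combinations (syn-pentane-like
    folds of the head over the tail), so the accepted torsions — not the
    nominal probabilities — are the generator's planted ground truth.
    """
    n_rejected = 0
    for _ in range(100):
        t = sample_torsions(spec, rng)
        pos = build_ndb_chain(t, spec.bond_length)
        coords = np.stack([pos[nm] for nm in _CHAIN_ORDER])
        if not _has_overlap(coords):
            break
        n_rejected += 1
    else:
        raise GeometryError("could not build a non-overlapping chain in 100 draws")
    tilt = abs(rng.normal(spec.tilt_mean, spec.tilt_sd)) if spec.tilt_sd > 0 \
        else float(spec.tilt_mean)
    tilt = min(tilt, 180.0 - 1e-9)
    azimuth = rng.uniform(0.0, 2.0 * np.pi)
    outward_z = 1.0 if upper else -1.0
    target = np.array([
        np.sin(np.radians(tilt)) * np.cos(azimuth),
        np.sin(np.radians(tilt)) * np.sin(azimuth),
        outward_z * np.cos(np.radians(tilt)),
    ])
    i4, i15 = _CHAIN_ORDER.index("C4"), _CHAIN_ORDER.index("C15")
    axis = coords[i15] - coords[i4]
    R = rotation_aligning(axis, target)
    coords = coords @ R.T
    return coords - coords[_CHAIN_ORDER.index("N1")], tilt, t, n_rejected


def _lattice_sites(spec: MonolayerSpec, rng: np.random.Generator,
                   min_spacing: float = 0.3) -> np.ndarray:
    """Jittered square-lattice head sites for one leaflet, shape (n, 2)."""
    n = spec.n_surfactant_per_leaflet
    m = int(np.ceil(np.sqrt(n)))
    spacing = min(spec.box.lx, spec.box.ly) / m
    if spacing < min_spacing:
        raise CapacityError(
            f"{n} surfactants need lattice spacing {spacing:.3f} nm < "
            f"{min_spacing} nm on a {spec.box.lx} x {spec.box.ly} nm leaflet"
        )
    gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    sites = (np.stack([gx.ravel(), gy.ravel()], axis=1) + 0.5) * spacing
    sites = sites[:n].astype(float)
    sites += rng.uniform(-spec.jitter_frac, spec.jitter_frac, size=sites.shape) * spacing
    return sites


def build_monolayer(spec: MonolayerSpec):
    """Build the full two-leaflet system; returns ``(Topology, Trajectory)``.

    Heads (N1) sit on jittered square lattices at the two interface planes
    (z_lo and z_hi); tails extend away from the water phase with the drawn
    tilt. Frames beyond the first are independent conformational redraws at
    the same head sites — snapshots for statistics, not dynamics.
    """
    rng = np.random.default_rng(spec.seed)
    n_per = spec.n_surfactant_per_leaflet

    sites_hi = _lattice_sites(spec, rng) if n_per else np.empty((0, 2))
    sites_lo = _lattice_sites(spec, rng) if n_per else np.empty((0, 2))

    n_water = _expected_water_count(spec) if spec.include_water else 0

    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    dihedrals: dict[int, list[tuple[int, int, int, int]]] = {}
    name_to_local = {nm: i for i, nm in enumerate(_CHAIN_ORDER)}
    n_mol = 2 * n_per
    for mol in range(n_mol):
        base = len(atoms)
        for nm in _CHAIN_ORDER:
            atoms.append(AtomRecord(
                nm, "N" if nm.startswith("N") else nm[0], mol, "NDB",
                role=NDB_ROLE_MAP.get(nm)))
        for a, b in NDB_BOND_NAME_PAIRS:
            bonds.append((base + name_to_local[a], base + name_to_local[b]))
        dihedrals[mol] = [
            tuple(base + name_to_local[nm] for nm in quad)
            for quad in DIHEDRAL_NAME_QUADS
        ]
    w_atoms, w_bonds = _water_topology(n_water, True, first_residue=n_mol)
    offset = len(atoms)
    atoms += w_atoms
    bonds += [(a + offset, b + offset) for a, b in w_bonds]
    topology = Topology(atoms, bonds=bonds, dihedrals=dihedrals)

    n_chain = len(_CHAIN_ORDER)
    frames = []
    gauche_true = np.zeros(12)
    tilt_draws = []
    n_rejected_draws = 0
    n_accepted_draws = 0
    for fidx in range(spec.n_frames):
        coords = np.empty((len(atoms), 3))
        for leaflet, (sites, z_plane, upper) in enumerate(
            ((sites_hi, spec.z_hi, True), (sites_lo, spec.z_lo, False))
        ):
            for m, (sx, sy) in enumerate(sites):
                mol = leaflet * n_per + m
                local, tilt, torsions, n_rej = _build_molecule(spec, rng, upper)
                coords[mol * n_chain:(mol + 1) * n_chain] = local + np.array(
                    [sx, sy, z_plane])
                gauche_true += np.abs(np.mod(torsions, 360.0) - 180.0) > 60.0
                tilt_draws.append(tilt)
                n_rejected_draws += n_rej
                n_accepted_draws += 1
        if n_water:
            w = _water_positions(spec, n_water, rng, include_hydrogens=True)
            coords[offset:] = w.reshape(-1, 3)
        frames.append(Frame(coords, spec.box, fidx * spec.dt))
    metadata = {
        "gauche_true_counts": gauche_true,
        "tilt_true_deg": np.array(tilt_draws),
        "n_chain_draws_accepted": n_accepted_draws,
        "n_chain_draws_rejected": n_rejected_draws,
    }
    return topology, Trajectory(topology, frames, metadata=metadata)


def single_ndb_system(torsions_deg, box: PeriodicBox | None = None,
                      origin=(4.0, 4.0, 12.0)):
    """One surfactant at the given torsions: ``(Topology, Frame)``.

    Convenient for planting exact conformations in tests; the molecule is
    placed with N1 at ``origin`` in its construction frame (N1->C4 along +z).
    """
    box = box or PeriodicBox(8.0, 8.0, 24.0)
    pos = build_ndb_chain(np.asarray(torsions_deg, dtype=float))
    coords = np.stack([pos[nm] for nm in _CHAIN_ORDER]) + np.asarray(
        origin, dtype=float)
    name_to_local = {nm: i for i, nm in enumerate(_CHAIN_ORDER)}
    atoms = [AtomRecord(nm, "N" if nm.startswith("N") else nm[0], 0, "NDB",
                        role=NDB_ROLE_MAP.get(nm)) for nm in _CHAIN_ORDER]
    bonds = [(name_to_local[a], name_to_local[b]) for a, b in NDB_BOND_NAME_PAIRS]
    dihedrals = {0: [tuple(name_to_local[nm] for nm in quad)
                     for quad in DIHEDRAL_NAME_QUADS]}
    return Topology(atoms, bonds=bonds, dihedrals=dihedrals), Frame(
        coords, box, 0.0)


# ---------------------------------------------------------------------------
# Planted H-bond geometry
# ---------------------------------------------------------------------------

def plant_hbond_partner(acceptor_pos, direction, r: float, theta_deg: float,
                        angle_mode: str = "HDA",
                        rng: np.random.Generator | None = None):
    """Plant a donor water at an exact H-bond geometry around an acceptor.

    The water oxygen (donor) is placed at distance ``r`` from
    ``acceptor_pos`` along ``direction``; one hydrogen is positioned so the
    criterion angle of the requested ``angle_mode`` equals ``theta_deg``
    exactly (HDA: angle at the donor between D->H and D->A; DHA: angle at
    the hydrogen between H->D and H->A). The second hydrogen completes the
    rigid water geometry pointing away from the acceptor.

    Returns ``(water_positions (3, 3) for [OW, HW1, HW2], acceptor_pos)``.
    """
    if r <= 0:
        raise ArgumentError("donor-acceptor distance must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    acceptor = np.asarray(acceptor_pos, dtype=float)
    d_hat = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d_hat)
    if norm < 1e-12:
        raise ArgumentError("direction must be non-zero")
    d_hat = d_hat / norm
    donor = acceptor + r * d_hat
    to_acc = -d_hat  # unit vector donor -> acceptor

    # Orthonormal in-plane direction for the off-axis component.
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, to_acc)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(to_acc, ref)
    perp /= np.linalg.norm(perp)

    if angle_mode == "HDA":
        alpha = np.radians(theta_deg)  # angle at donor
    elif angle_mode == "DHA":
        # Triangle D-H-A with |DH| = OH, |DA| = r, vertex angle at H = theta.
        theta = np.radians(theta_deg)
        s = WATER_OH * np.sin(theta) / r
        if abs(s) > 1.0:
            raise ArgumentError("requested DHA angle is geometrically impossible")
        angle_at_a = np.arcsin(s)
        alpha = np.pi - theta - angle_at_a
        if alpha <= 0:
            # the triangle closes only if D-A is long enough to subtend theta
            raise ArgumentError("requested DHA angle is geometrically impossible")
    else:
        raise ArgumentError(f"unknown angle mode {angle_mode!r}")
    h1 = donor + WATER_OH * (np.cos(alpha) * to_acc + np.sin(alpha) * perp)

    # Second hydrogen: HOH angle from the first, azimuth pointing away.
    oh1 = (h1 - donor) / WATER_OH
    axis = np.cross(oh1, to_acc)
    if np.linalg.norm(axis) < 1e-9:
        axis = perp
    from .geometry import rotation_about_axis
    R = rotation_about_axis(axis, -WATER_HOH)
    h2 = donor + WATER_OH * (R @ oh1)
    return np.stack([donor, h1, h2]), acceptor


def planted_water_system(waters: list[np.ndarray], acceptors: list[np.ndarray],
                         box: PeriodicBox):
    """Assemble planted waters plus bare carboxylate-like acceptor oxygens
    into a (Topology, Frame) pair for detector truth-table tests."""
    atoms, bonds, coords = [], [], []
    for m, w in enumerate(waters):
        base = len(atoms)
        for nm, role in (("OW", "OW"), ("HW1", "HW"), ("HW2", "HW")):
            atoms.append(AtomRecord(nm, nm[0], m, "SOL", role=role))
        bonds += [(base, base + 1), (base, base + 2)]
        coords.extend(np.asarray(w).reshape(3, 3))
    res0 = len(waters)
    for k, a in enumerate(acceptors):
        atoms.append(AtomRecord("O1", "O", res0 + k, "ACC", role="O_carboxyl"))
        coords.append(np.asarray(a, dtype=float))
    topology = Topology(atoms, bonds=bonds)
    return topology, Frame(np.array(coords), box, 0.0)


# ---------------------------------------------------------------------------
# Telegraph kinetics
# ---------------------------------------------------------------------------

def simulate_telegraph(spec: TelegraphSpec):
    """Sample ``n_pairs`` independent telegraph chains at interval dt.

    Transition probabilities are the exact two-state propagator over dt, so
    the sampled chain is the continuous-time process observed stroboscopically
    and its autocorrelation matches :func:`telegraph_correlation` exactly in
    expectation. Returns an :class:`~slabstats.hbond.HBondTimeSeries`.
    """
    from .hbond import HBondTimeSeries

    k = spec.rate_sum
    p = spec.p_bound
    if spec.dt >= 1.0 / k:
        warnings.warn(
            "telegraph sampling interval dt >= 1/(k_on+k_off): the decay is "
            "undersampled", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    decay = np.exp(-k * spec.dt)
    p_stay_bound = p + (1.0 - p) * decay
    p_gain = p * (1.0 - decay)
    h = np.empty((spec.n_pairs, spec.n_steps), dtype=np.int8)
    state = (rng.uniform(size=spec.n_pairs) < p).astype(np.int8)
    h[:, 0] = state
    for t in range(1, spec.n_steps):
        u = rng.uniform(size=spec.n_pairs)
        stay = (state == 1) & (u < p_stay_bound)
        gain = (state == 0) & (u < p_gain)
        state = (stay | gain).astype(np.int8)
        h[:, t] = state
    pair_ids = [(i, i) for i in range(spec.n_pairs)]
    return HBondTimeSeries(pair_ids=pair_ids, h=h, dt=spec.dt)
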