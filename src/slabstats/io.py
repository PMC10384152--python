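"""Readers and writers: GRO (nm, fixed width), XYZ (Angstrom) and the
YAML/JSON topology-annotation sidecar (roles, bonds, dihedrals by atom name).

GRO is parsed by fixed column offsets, the only robust way to read files
whose name fields run together. Velocities, when present, are ignored.
Multi-frame GRO and XYZ sources yield a :class:`~slabstats.core.Trajectory`.
"""

from __future__ import annotations

import io as _io
import json
import re
from pathlib import Path

import numpy as np
import yaml

from .box import PeriodicBox
from .core import AtomRecord, Frame, Topology, Trajectory
from .exceptions import ParseError, StructuralError

_ANGSTROM = 0.1  # nm
_TIME_RE = re.compile(r"t\s*=\s*([0-9eE+.\-]+)")


def guess_element(name: str) -> str:
    """Element from an atom name: first alphabetic character (MW-style
    two-letter elements are out of scope for H/C/N/O systems)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _open_text(source):
    if hasattr(source, "read"):
        return _io.StringIO(source.read())
    text = str(source)
    if "\n" in text or not Path(text).exists():
        if "\n" not in text:
            raise ParseError(f"no such file: {text}")
        return _io.StringIO(text)
    return open(text)


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _parse_gro_frame(lines, start_line):
    """Parse one GRO block from an iterator; returns (records, positions,
    box, time) or None at EOF."""
    title = next(lines, None)
    if title is None:
        return None
    lineno = start_line
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else None
    count_line = next(lines, None)
    if count_line is None:
        raise StructuralError("GRO source ends after title line")
    lineno += 1
    try:
        n_atoms = int(count_line.strip())
    except ValueError:
        raise ParseError(f"unreadable atom count {count_line.strip()!r}", lineno)
    records, positions = [], []
    for k in range(n_atoms):
        line = next(lines, None)
        lineno += 1
        if line is None or len(line.rstrip("\n")) < 44:
            raise StructuralError(
                f"header promises {n_atoms} atoms but atom line {k + 1} is "
                "missing or truncated"
            )
        try:
            res_id = int(line[0:5])
            res_name = line[5:10].strip()
            atom_name = line[10:15].strip()
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except ValueError as exc:
            raise ParseError(f"malformed fixed-width atom line: {exc}", lineno)
        records.append((res_id, res_name, atom_name))
        positions.append((x, y, z))
    box_line = next(lines, None)
    lineno += 1
    if box_line is None:
        raise StructuralError("GRO frame is missing its final box line")
    fields = box_line.split()
    if len(fields) < 3:
        raise ParseError("box line must hold at least three lengths", lineno)
    box = tuple(float(v) for v in fields[:3])
    return records, np.array(positions).reshape(-1, 3), box, time, lineno


def read_gro(source, periodic_z: bool = False):
    """Read a GRO configuration or multi-frame trajectory.

    Returns ``(topology, Frame)`` for single-frame sources and
    ``(topology, Trajectory)`` otherwise. Positions are nm as stored.
    """
    fh = _open_text(source)
    try:
        lines = iter(fh.readlines())
    finally:
        fh.close()

    frames = []
    first_records = None
    lineno = 0
    default_time = 0.0
    while True:
        lineno += 1
        parsed = _parse_gro_frame(lines, lineno)
        if parsed is None:
            break
        records, positions, (lx, ly, lz), time, lineno = parsed
        if first_records is None:
            first_records = records
        elif records != first_records:
            raise StructuralError("frames in a multi-frame GRO differ in atoms")
        if time is None:
            time = default_time
        default_time = time + 1.0
        frames.append(Frame(positions, PeriodicBox(lx, ly, lz, periodic_z), time))
    if not frames:
        raise StructuralError("GRO source holds no frames")

    atoms = []
    res_map: dict[tuple[int, str], int] = {}
    for res_id, res_name, atom_name in first_records:
        key = (res_id, res_name)
        res_index = res_map.setdefault(key, len(res_map))
        atoms.append(
            AtomRecord(atom_name, guess_element(atom_name), res_index, res_name)
        )
    topology = Topology(atoms)
    if len(frames) == 1:
        return topology, frames[0]
    return topology, Trajectory(topology, frames)


def write_gro(topology: Topology, frame_or_traj, path=None, title="slabstats") -> str:
    """Write GRO text (3-decimal positions); returns the text, and writes it
    to ``path`` when given. Accepts a Frame or a Trajectory."""
    frames = (
        list(frame_or_traj)
        if isinstance(frame_or_traj, Trajectory)
        else [frame_or_traj]
    )
    chunks = []
    for fr in frames:
        if fr.n_atoms != topology.n_atoms:
            raise StructuralError(
                f"frame has {fr.n_atoms} positions for {topology.n_atoms} atoms"
            )
        out = [f"{title}, t= {fr.time:.4f}", f"{topology.n_atoms:5d}"]
        for i, (a, p) in enumerate(zip(topology.atoms, fr.positions)):
            res_id = (a.residue_index + 1) % 100000
            out.append(
                f"{res_id:5d}{a.residue_name:<5.5s}{a.name:>5.5s}"
                f"{(i + 1) % 100000:5d}{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}"
            )
        out.append(f"{fr.box.lx:10.5f}{fr.box.ly:10.5f}{fr.box.lz:10.5f}")
        chunks.append("\n".join(out))
    text = "\n".join(chunks) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# XYZ (Angstrom on disk, nm in memory)
# ---------------------------------------------------------------------------

def read_xyz(source, box: PeriodicBox | None = None):
    """Read (multi-frame) XYZ; coordinates are converted Angstrom -> nm.

    XYZ carries no cell, so ``box`` must be supplied for periodic analyses;
    a generous non-periodic bounding box is derived when omitted.
    """
    fh = _open_text(source)
    try:
        raw = fh.read().splitlines()
    finally:
        fh.close()
    frames_data = []
    elements = None
    i = 0
    lineno = 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            lineno += 1
            continue
        try:
            n = int(raw[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {raw[i]!r}", lineno + 1)
        comment = raw[i + 1] if i + 1 < len(raw) else ""
        m = _TIME_RE.search(comment)
        time = float(m.group(1)) if m else None
        block = raw[i + 2 : i + 2 + n]
        if len(block) < n:
            raise StructuralError(f"XYZ frame promises {n} atoms, found {len(block)}")
        els, pos = [], []
        for k, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError("XYZ atom line needs 'element x y z'", lineno + 3 + k)
            els.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise StructuralError("XYZ frames differ in atoms")
        frames_data.append((np.array(pos) * _ANGSTROM, time))
        i += 2 + n
        lineno = i
    if not frames_data:
        raise StructuralError("XYZ source holds no frames")
    if box is None:
        span = np.concatenate([p for p, _ in frames_data]).max(axis=0) + 1.0
        box = PeriodicBox(*np.maximum(span, 1.0))
    atoms = [AtomRecord(e, e.upper(), i, "MOL") for i, e in enumerate(elements)]
    topology = Topology(atoms)
    frames = []
    for k, (pos, time) in enumerate(frames_data):
        frames.append(Frame(pos, box, float(k) if time is None else time))
    if len(frames) == 1:
        return topology, frames[0]
    return topology, Trajectory(topology, frames)


def write_xyz(topology: Topology, frame_or_traj, path=None, comment="slabstats") -> str:
    """Write XYZ text with coordinates converted nm -> Angstrom."""
    frames = (
        list(frame_or_traj)
        if isinstance(frame_or_traj, Trajectory)
        else [frame_or_traj]
    )
    out = []
    for fr in frames:
        if fr.n_atoms != topology.n_atoms:
            raise StructuralError("frame/topology atom count mismatch")
        out.append(str(topology.n_atoms))
        out.append(f"{comment}, t= {fr.time:.4f}")
        for a, p in zip(topology.atoms, fr.positions):
            x, y, z = p / _ANGSTROM
            out.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Topology-annotation sidecar
# ---------------------------------------------------------------------------

def load_annotation(source) -> dict:
    """Load a YAML/JSON sidecar with ``roles``, ``bonds`` and ``dihedrals``
    keyed by residue name and atom name."""
    fh = _open_text(source)
    try:
        text = fh.read()
    finally:
        fh.close()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError("annotation sidecar must be a mapping")
    return data


def dump_annotation(annotation: dict, path=None) -> str:
    text = yaml.safe_dump(annotation, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def apply_annotation(topology: Topology, annotation: dict) -> None:
    """Apply a sidecar to a topology: role labels, per-residue bonds and the
    ordered dihedral quadruples, all resolved by atom name within residues."""
    roles = annotation.get("roles", {})
    if roles:
        topology.apply_role_map(roles)

    def _name_index(res_idx, name, res_atoms):
        for i in res_atoms:
            if topology.atoms[i].name == name:
                return i
        raise StructuralError(
            f"annotation names atom {name!r} absent from residue {res_idx}"
        )

    by_res = topology.atoms_by_residue()

    bonds = annotation.get("bonds", {})
    existing = {frozenset(b) for b in topology.bonds}
    for res, idx in by_res.items():
        res_name = topology.atoms[idx[0]].residue_name
        for a, b in bonds.get(res_name, []):
            pair = (_name_index(res, a, idx), _name_index(res, b, idx))
            if frozenset(pair) not in existing:
                topology.bonds.append(pair)
                existing.add(frozenset(pair))

    dihedrals = annotation.get("dihedrals", {})
    for res, idx in by_res.items():
        res_name = topology.atoms[idx[0]].residue_name
        quads = dihedrals.get(res_name)
        if quads:
            topology.dihedrals[res] = [
                tuple(_name_index(res, nm, idx) for nm in quad) for quad in quads
            ]
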