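"""Gaussian cube export for volumetric grids (SDF occupancies, RDG fields).

Cube files are bohr-based with z as the fastest-varying data axis; values
are written six per line. Only orthogonal uniform grids are supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .exceptions import ArgumentError
from .rdg import BOHR_PER_NM, atomic_number


def write_cube(path, data: np.ndarray, origin_bohr, spacing_bohr: float,
               elements=(), coords_bohr=None, comment: str = "slabstats grid"):
    """Write a 3-D array as a Gaussian cube file.

    ``origin_bohr`` and ``spacing_bohr`` define the grid; optional atoms are
    written with nuclear charge equal to the atomic number.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ArgumentError("cube data must be a 3-D array")
    origin = np.asarray(origin_bohr, dtype=float).reshape(3)
    coords = (np.asarray(coords_bohr, dtype=float).reshape(-1, 3)
              if coords_bohr is not None else np.empty((0, 3)))
    if len(elements) != len(coords):
        raise ArgumentError("elements and coordinates differ in length")

    lines = [comment, "slabstats cube export"]
    lines.append(f"{len(coords):5d} {origin[0]:12.6f} {origin[1]:12.6f} "
                 f"{origin[2]:12.6f}")
    for ax in range(3):
        step = [0.0, 0.0, 0.0]
        step[ax] = spacing_bohr
        lines.append(f"{data.shape[ax]:5d} {step[0]:12.6f} {step[1]:12.6f} "
                     f"{step[2]:12.6f}")
    for el, xyz in zip(elements, coords):
        z = atomic_number(el)
        lines.append(f"{z:5d} {float(z):12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} "
                     f"{xyz[2]:12.6f}")
    flat = data.reshape(data.shape[0] * data.shape[1], data.shape[2])
    for row in flat:
        for s in range(0, len(row), 6):
            lines.append("".join(f"{v:13.5E}" for v in row[s:s + 6]))
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text


def write_cube_nm(path, data, origin_nm, spacing_nm, elements=(),
                  coords_nm=None, comment="slabstats grid"):
    """Convenience wrapper converting an nm-based grid (e.g. an SDF) to bohr."""
    origin = np.asarray(origin_nm, dtype=float) * BOHR_PER_NM
    coords = (np.asarray(coords_nm, dtype=float) * BOHR_PER_NM
              if coords_nm is not None else None)
    return write_cube(path, data, origin, spacing_nm * BOHR_PER_NM,
                      elements, coords, comment)
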