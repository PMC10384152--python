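"""Orthorhombic periodic box and minimum-image geometry.

The slab geometry used throughout the package is periodic in x and y and, by
default, *not* periodic in z: the simulation cell is a tall box whose z axis
is normal to the two air-water interfaces, so z-images are vacuum and carry
no physics. All lengths are nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ArgumentError


@dataclass(frozen=True)
class PeriodicBox:
    """Orthorhombic cell with per-axis periodicity.

    Parameters
    ----------
    lx, ly, lz : float
        Edge lengths in nm; must be positive.
    periodic_z : bool
        Whether the z axis wraps. Off by default (slab geometry).
    """

    lx: float
    ly: float
    lz: float
    periodic_z: bool = False

    def __post_init__(self):
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ArgumentError(
                f"box lengths must be positive, got ({self.lx}, {self.ly}, {self.lz})"
            )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def periodic(self) -> np.ndarray:
        """Boolean mask of periodic axes (x, y always periodic)."""
        return np.array([True, True, self.periodic_z])

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz

    @property
    def cross_section(self) -> float:
        """Interface area lx*ly in nm^2."""
        return self.lx * self.ly

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Map displacement vector(s) ``d`` to the nearest periodic image.

        Each periodic component of the result lies in [-L/2, L/2]; the
        non-periodic z component (if any) is returned unchanged.
        """
        d = np.asarray(d, dtype=float)
        L = self.lengths
        shift = np.round(d / L) * L
        if not self.periodic_z:
            shift[..., 2] = 0.0
        return d - shift

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap absolute positions into [0, L) on periodic axes."""
        pos = np.asarray(pos, dtype=float).copy()
        L = self.lengths
        for ax in range(3):
            if self.periodic[ax]:
                pos[..., ax] = np.mod(pos[..., ax], L[ax])
        return pos

    def min_periodic_halfspan(self) -> float:
        """Half the shortest periodic edge (upper bound for pair cutoffs)."""
        spans = [self.lx, self.ly] + ([self.lz] if self.periodic_z else [])
        return min(spans) / 2.0


def minimum_image_vector(p: np.ndarray, q: np.ndarray, box: PeriodicBox) -> np.ndarray:
    """Displacement q - p mapped to the nearest periodic image of ``box``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return box.minimum_image(q - p)
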