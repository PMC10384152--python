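"""Shared fixtures and independent oracles used across the suite."""

from itertools import product

import numpy as np
import pytest

from slabstats.box import PeriodicBox
from slabstats.core import AtomRecord, Frame, Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20231207)


def _image_shifts(box: PeriodicBox) -> np.ndarray:
    z_shifts = (-1, 0, 1) if box.periodic_z else (0,)
    return np.array(list(product((-1, 0, 1), (-1, 0, 1), z_shifts)), dtype=float)


def brute_force_min_image(p, q, box: PeriodicBox) -> np.ndarray:
    """27-image oracle: the displacement to the closest explicit periodic
    copy of q (9 images when z is non-periodic)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q + _image_shifts(box) * box.lengths - p
    return d[np.argmin(np.linalg.norm(d, axis=1))]


def brute_force_distance(p, q, box: PeriodicBox) -> float:
    return float(np.linalg.norm(brute_force_min_image(p, q, box)))


def gas_trajectory(rng, n_atoms, box: PeriodicBox, n_frames=1,
                   role=None) -> tuple[Topology, Trajectory]:
    """Uniform ideal-gas configuration(s) of identical atoms."""
    atoms = [AtomRecord("AR", "C", i, "GAS", role=role) for i in range(n_atoms)]
    top = Topology(atoms)
    frames = [
        Frame(rng.uniform(0.0, 1.0, size=(n_atoms, 3)) * box.lengths, box,
              float(t))
        for t in range(n_frames)
    ]
    return top, Trajectory(top, frames)
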