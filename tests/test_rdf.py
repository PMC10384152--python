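"""RDF normalization, valley detection and coordination numbers against
brute-force and constructed oracles."""

import numpy as np
import pytest

from slabstats.box import PeriodicBox
from slabstats.core import AtomRecord, Frame, Topology, Trajectory
from slabstats.exceptions import ArgumentError, NoValleyError
from slabstats.rdf import (RDFResult, compute_rdf, coordination_number,
                           find_first_valley)

from conftest import brute_force_distance, gas_trajectory


def _point_trajectory(points, box):
    atoms = [AtomRecord("X", "C", i, "PTS") for i in range(len(points))]
    top = Topology(atoms)
    return top, Trajectory(top, [Frame(np.asarray(points, float), box, 0.0)])


class TestComputeRdf:
    def test_single_pair_delta_configuration(self):
        box = PeriodicBox(6, 6, 6, periodic_z=True)
        d = 0.517
        top, traj = _point_trajectory([[1, 1, 1], [1 + d, 1, 1]], box)
        rdf = compute_rdf(traj, [0], [1], r_max=1.0, bin_width=0.01)
        nz = np.nonzero(rdf.raw_histogram)[0]
        assert len(nz) == 1
        assert abs(rdf.bin_centers[nz[0]] - d) <= 0.005

    def test_ideal_gas_plateau_near_one(self, rng):
        box = PeriodicBox(4, 4, 4, periodic_z=True)
        top, traj = gas_trajectory(rng, 1500, box, n_frames=2)
        rdf = compute_rdf(traj, np.arange(150), np.arange(1500), r_max=1.2,
                          bin_width=0.01)
        plateau = rdf.g[rdf.bin_centers > 0.3].mean()
        assert 0.95 < plateau < 1.05

    def test_histogram_conservation(self, rng):
        """Binned counts sum to the exact number of pairs within r_max."""
        box = PeriodicBox(3, 3, 3, periodic_z=True)
        top, traj = gas_trajectory(rng, 80, box)
        r_max = 1.2
        rdf = compute_rdf(traj, np.arange(40), np.arange(80), r_max=r_max,
                          bin_width=0.02)
        pos = traj[0].positions
        n_direct = sum(
            1
            for i in range(40)
            for j in range(80)
            if i != j and brute_force_distance(pos[i], pos[j], box) < r_max
        )
        assert int(rdf.raw_histogram.sum()) == n_direct

    def test_histogram_matches_27_image_brute_force(self, rng):
        box = PeriodicBox(2.5, 2.5, 2.5, periodic_z=True)
        top, traj = gas_trajectory(rng, 200, box)
        bw = 0.02
        rdf = compute_rdf(traj, np.arange(200), np.arange(200), r_max=1.2,
                          bin_width=bw)
        pos = traj[0].positions
        edges = np.arange(0.0, 1.2 + bw / 2, bw)
        dists = [
            brute_force_distance(pos[i], pos[j], box)
            for i in range(200)
            for j in range(200)
            if i != j
        ]
        oracle = np.histogram(dists, bins=edges)[0]
        assert np.array_equal(rdf.raw_histogram.astype(int), oracle)

    def test_slab_bulk_window_normalization(self, rng):
        """A z-confined uniform gas normalizes to ~1 with a matching bulk
        window even though the global density is lower."""
        box = PeriodicBox(4, 4, 12)
        n = 3000
        pos = rng.uniform(0, 1, size=(n, 3)) * [4, 4, 4]
        pos[:, 2] += 4.0  # occupy z in [4, 8)
        top, traj = _point_trajectory(pos, box)
        rdf = compute_rdf(traj, np.arange(300), np.arange(n), r_max=1.0,
                          bin_width=0.02, bulk_region_z=(5.0, 7.0))
        plateau = rdf.g[(rdf.bin_centers > 0.3) & (rdf.bin_centers < 0.6)].mean()
        assert 0.9 < plateau < 1.1

    def test_argument_validation(self, rng):
        box = PeriodicBox(4, 4, 4, periodic_z=True)
        top, traj = gas_trajectory(rng, 10, box)
        with pytest.raises(ArgumentError):
            compute_rdf(traj, [], [0], r_max=1.0)
        with pytest.raises(ArgumentError):
            compute_rdf(traj, [0], [1], r_max=3.0)  # > half box edge


def _synthetic_rdf(g, bin_width=0.01):
    centers = (np.arange(len(g)) + 0.5) * bin_width
    return RDFResult(centers, np.asarray(g, float), bin_width, 1, 1, 1.0, 1,
                     np.zeros(len(g)))


class TestFirstValley:
    def test_single_peak_and_valley_curve(self):
        g = np.ones(40)
        g[5:16] += np.array([0.5, 1.2, 2.0, 2.6, 3.0, 2.6, 2.0, 1.2, 0.6,
                             0.25, 0.05])
        g[16] = 0.4  # explicit minimum at bin 16
        g[17:24] += np.linspace(0.0, 0.4, 7)
        rdf = _synthetic_rdf(g)
        r = find_first_valley(rdf)
        assert abs(r - rdf.bin_centers[16]) <= 2 * rdf.bin_width

    def test_flat_gas_has_no_valley(self):
        rdf = _synthetic_rdf(np.ones(60))
        with pytest.raises(NoValleyError):
            find_first_valley(rdf)

    def test_noisy_two_shell_curve_recovered_within_one_bin(self, rng):
        bw = 0.01
        r = (np.arange(120) + 0.5) * bw
        clean = (1.0 + 2.5 * np.exp(-((r - 0.30) / 0.04) ** 2)
                 - 0.6 * np.exp(-((r - 0.45) / 0.05) ** 2)
                 + 0.8 * np.exp(-((r - 0.62) / 0.05) ** 2))
        true_valley = r[np.argmin(clean[25:55]) + 25]
        noisy = clean + rng.normal(0, 0.02, size=len(r))
        rdf = _synthetic_rdf(noisy, bw)
        found = find_first_valley(rdf)
        assert abs(found - true_valley) <= 2 * bw


class TestCoordinationNumber:
    def test_planted_shell_counts_k_neighbors(self, rng):
        box = PeriodicBox(6, 6, 6, periodic_z=True)
        k = 6
        center = np.array([3.0, 3.0, 3.0])
        dirs = rng.normal(size=(k, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = np.vstack([center, center + 0.3 * dirs])
        top, traj = _point_trajectory(pts, box)
        rdf = compute_rdf(traj, [0], np.arange(1, k + 1), r_max=1.0,
                          bin_width=0.01)
        n = coordination_number(rdf, 0.5)
        assert n == pytest.approx(k, abs=0.3)

    def test_zero_targets_inside_valley(self):
        box = PeriodicBox(6, 6, 6, periodic_z=True)
        top, traj = _point_trajectory([[3, 3, 3], [3, 3, 5.0]], box)
        rdf = compute_rdf(traj, [0], [1], r_max=1.0, bin_width=0.01)
        assert coordination_number(rdf, 0.5) == 0.0

    def test_uniform_gas_matches_direct_counting(self, rng):
        box = PeriodicBox(4, 4, 4, periodic_z=True)
        n = 1200
        top, traj = gas_trajectory(rng, n, box)
        rdf = compute_rdf(traj, np.arange(200), np.arange(n), r_max=1.0,
                          bin_width=0.01)
        r_v = 0.8
        n_est = coordination_number(rdf, r_v)
        pos = traj[0].positions
        d = box.minimum_image(pos[None, :1200, :] - pos[:200, None, :])
        dist = np.linalg.norm(d, axis=-1)
        direct = ((dist < r_v).sum() - 200) / 200  # exclude self pairs
        assert n_est == pytest.approx(direct, rel=0.03)

    def test_uniform_gas_matches_shell_volume_formula(self, rng):
        box = PeriodicBox(4, 4, 4, periodic_z=True)
        n = 4000
        top, traj = gas_trajectory(rng, n, box, n_frames=2)
        rdf = compute_rdf(traj, np.arange(300), np.arange(n), r_max=1.0,
                          bin_width=0.01)
        r_v = 0.8
        expected = 4.0 / 3.0 * np.pi * r_v**3 * n / box.volume
        assert coordination_number(rdf, r_v) == pytest.approx(expected,
                                                              rel=0.02)

    def test_limit_outside_range_rejected(self, rng):
        box = PeriodicBox(4, 4, 4, periodic_z=True)
        top, traj = gas_trajectory(rng, 50, box)
        rdf = compute_rdf(traj, np.arange(10), np.arange(50), r_max=1.0,
                          bin_width=0.01)
        with pytest.raises(ArgumentError):
            coordination_number(rdf, 1.5)
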