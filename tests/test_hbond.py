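"""Hydrogen-bond detection (vs brute force), correlation functions and
lifetime fits."""

import numpy as np
import pytest

from slabstats.box import PeriodicBox
from slabstats.exceptions import ArgumentError
from slabstats.core import Trajectory
from slabstats.hbond import (HBondCriterion, HBondTimeSeries,
                             correlation_lifetime, detect_hbonds,
                             fit_multiexponential, hbond_count_per_head,
                             hbond_lifetime, intermittent_acf)
from slabstats.synth import (TelegraphSpec, plant_hbond_partner,
                             planted_water_system, simulate_telegraph,
                             _water_orientations)

from conftest import brute_force_min_image

BOX = PeriodicBox(5.0, 5.0, 5.0, periodic_z=True)


def _random_water_box(rng, n_waters, box=BOX):
    """Random rigid waters plus two bare acceptor oxygens."""
    oxy = rng.uniform(0, 1, size=(n_waters, 3)) * box.lengths
    hh = _water_orientations(n_waters, rng)
    waters = [np.vstack([o, o + h]) for o, h in zip(oxy, hh)]
    acceptors = [rng.uniform(0, 1, size=3) * box.lengths for _ in range(2)]
    return planted_water_system(waters, acceptors, box)


def brute_force_detect(frame, topology, criterion):
    """Pure-python O(N^2) oracle over every donor, hydrogen and acceptor."""
    donors = topology.indices_with_role("OW")
    accept = np.concatenate([topology.indices_with_role("OW"),
                             topology.indices_with_role("O_carboxyl")])
    dh = topology.donor_hydrogen_map()
    pos = frame.positions
    found = set()
    for d in donors:
        for a in accept:
            if d == a:
                continue
            da = brute_force_min_image(pos[d], pos[a], frame.box)
            if np.linalg.norm(da) > criterion.r_cut + 1e-9:
                continue
            for h in dh.get(int(d), []):
                hv = brute_force_min_image(pos[d], pos[h], frame.box)
                if criterion.angle_mode == "HDA":
                    cosv = (hv @ da) / (np.linalg.norm(hv) * np.linalg.norm(da))
                    ang = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
                    ok = ang <= criterion.angle_cut + 1e-7
                else:
                    hd = -hv
                    ha = da - hv
                    cosv = (hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                    ang = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
                    ok = ang >= criterion.angle_cut - 1e-7
                if ok:
                    found.add((int(d), int(a)))
                    break
    return found


class TestDetectHbonds:
    def _detect(self, top, frame, criterion):
        donors = top.indices_with_role("OW")
        acceptors = np.concatenate([donors,
                                    top.indices_with_role("O_carboxyl")])
        return detect_hbonds(frame, donors, top.donor_hydrogen_map(),
                             acceptors, criterion, topology=top)

    def test_planted_linear_bond_detected(self):
        acc = np.array([2.5, 2.5, 2.5])
        water, _ = plant_hbond_partner(acc, [1, 0, 0], 0.28, 0.0, "HDA")
        top, frame = planted_water_system([water], [acc], BOX)
        bonds = self._detect(top, frame, HBondCriterion())
        assert (0, 3) in bonds

    def test_pair_beyond_cutoff_silent(self):
        acc = np.array([2.5, 2.5, 2.5])
        water, _ = plant_hbond_partner(acc, [1, 0, 0], 0.36, 0.0, "HDA")
        top, frame = planted_water_system([water], [acc], BOX)
        assert self._detect(top, frame, HBondCriterion()) == []

    def test_boundary_distance_is_bonded(self):
        """Exactly r = r_cut counts as bonded (closed decision)."""
        acc = np.array([2.5, 2.5, 2.5])
        water, _ = plant_hbond_partner(acc, [0, 1, 0], 0.35, 30.0, "HDA")
        top, frame = planted_water_system([water], [acc], BOX)
        assert self._detect(top, frame, HBondCriterion()) == [(0, 3)]

    def test_angle_beyond_cut_silent(self):
        acc = np.array([2.5, 2.5, 2.5])
        water, _ = plant_hbond_partner(acc, [0, 0, 1], 0.30, 45.0, "HDA")
        top, frame = planted_water_system([water], [acc], BOX)
        assert self._detect(top, frame, HBondCriterion()) == []

    @pytest.mark.parametrize("mode", ["HDA", "DHA"])
    def test_matches_brute_force_on_random_boxes(self, rng, mode):
        criterion = HBondCriterion(angle_mode=mode)
        for _ in range(25):
            top, frame = _random_water_box(rng, 30)
            got = set(self._detect(top, frame, criterion))
            assert got == brute_force_detect(frame, top, criterion)

    def test_n1_excluded_from_both_sides(self):
        from slabstats.synth import single_ndb_system
        from slabstats.core import AtomRecord, Topology, Frame
        top, frame = single_ndb_system(np.full(12, 180.0))
        n1 = top.indices_with_role("N1")
        # ask for bonds donor=water planted right at N1 distance
        water, _ = plant_hbond_partner(frame.positions[n1[0]], [1, 0, 0],
                                       0.30, 0.0)
        atoms = list(top.atoms) + [
            AtomRecord("OW", "O", 1, "SOL", role="OW"),
            AtomRecord("HW1", "H", 1, "SOL", role="HW"),
            AtomRecord("HW2", "H", 1, "SOL", role="HW")]
        bonds = list(top.bonds) + [(len(top.atoms), len(top.atoms) + 1),
                                   (len(top.atoms), len(top.atoms) + 2)]
        top2 = Topology(atoms, bonds=bonds)
        frame2 = Frame(np.vstack([frame.positions, water]), frame.box)
        donors = top2.indices_with_role("OW")
        got = detect_hbonds(frame2, donors, top2.donor_hydrogen_map(),
                            n1, HBondCriterion(), topology=top2)
        assert got == []


class TestCountPerHead:
    def test_exact_planted_counts(self, rng):
        """Four heads, each with a known number of satisfying waters."""
        counts = [3, 1, 0, 2]
        acceptors = [np.array([1.0 + 2.0 * k, 2.5, 2.5]) for k in range(4)]
        box = PeriodicBox(8.0, 8.0, 5.0)
        waters = []
        for acc, k in zip(acceptors, counts):
            for j in range(k):
                direction = np.array([np.cos(2 * np.pi * j / 3 + 0.3),
                                      np.sin(2 * np.pi * j / 3 + 0.3), 0.4])
                w, _ = plant_hbond_partner(acc, direction, 0.29, 5.0, "HDA")
                waters.append(w)
        top, frame = planted_water_system(waters, acceptors, box)
        traj = Trajectory(top, [frame])
        mean, sd = hbond_count_per_head(traj)
        assert mean == pytest.approx(np.mean(counts))
        assert sd == 0.0

    def test_no_waters_gives_zero(self):
        acceptors = [np.array([2.5, 2.5, 2.5])]
        top, frame = planted_water_system([], acceptors, BOX)
        traj = Trajectory(top, [frame])
        assert hbond_count_per_head(traj) == (0.0, 0.0)


class TestIntermittentAcf:
    def test_constant_occupancy_gives_unity(self):
        series = HBondTimeSeries([(0, 0)], np.ones((1, 50), dtype=np.int8),
                                 dt=0.5)
        acf = intermittent_acf(series, max_lag=20)
        assert np.allclose(acf.C, 1.0)
        assert acf.lags[1] == 0.5

    def test_alternating_pattern(self):
        h = np.tile([1, 0], 25).reshape(1, 50)
        series = HBondTimeSeries([(0, 0)], h, dt=1.0)
        acf = intermittent_acf(series, max_lag=10)
        assert np.allclose(acf.C[::2], 1.0)
        assert np.allclose(acf.C[1::2], 0.0)

    def test_all_zero_occupancy_rejected(self):
        series = HBondTimeSeries([(0, 0)], np.zeros((1, 50), dtype=np.int8),
                                 dt=1.0)
        with pytest.raises(ArgumentError):
            intermittent_acf(series, max_lag=10)

    def test_max_lag_validation(self):
        series = HBondTimeSeries([(0, 0)], np.ones((1, 10), dtype=np.int8),
                                 dt=1.0)
        with pytest.raises(ArgumentError):
            intermittent_acf(series, max_lag=10)


class TestMultiExponentialFit:
    def test_single_term_self_fit(self):
        t = np.arange(0, 40, 0.2)
        C = np.exp(-t / 5.0)
        ((a, b),) = fit_multiexponential(C, t, 1)
        assert a == pytest.approx(1.0, abs=1e-6)
        assert b == pytest.approx(5.0, rel=0.01)

    def test_two_term_recovery(self):
        t = np.arange(0, 60, 0.1)
        C = 0.5 * np.exp(-t / 2.0) + 0.5 * np.exp(-t / 10.0)
        terms = fit_multiexponential(C, t, 2)
        (a1, b1), (a2, b2) = terms
        assert a1 == pytest.approx(0.5, rel=0.02)
        assert b1 == pytest.approx(2.0, rel=0.02)
        assert a2 == pytest.approx(0.5, rel=0.02)
        assert b2 == pytest.approx(10.0, rel=0.02)

    def test_weights_sum_to_one(self):
        t = np.arange(0, 30, 0.1)
        C = 0.7 * np.exp(-t / 1.5) + 0.3 * np.exp(-t / 8.0)
        terms = fit_multiexponential(C, t, 3)
        assert sum(a for a, _ in terms) == pytest.approx(1.0, abs=1e-6)
        assert all(b > 0 for _, b in terms)

    def test_too_many_terms_rejected(self):
        with pytest.raises(ArgumentError):
            fit_multiexponential(np.ones(10), np.arange(10.0), 4)


class TestLifetime:
    def test_single_term_closed_form(self):
        assert hbond_lifetime([(1.0, 5.0)]) == pytest.approx(5.0)

    def test_two_term_closed_form(self):
        assert hbond_lifetime([(0.5, 2.0), (0.5, 10.0)]) == pytest.approx(6.0)

    def test_telegraph_lifetime_within_ten_percent(self):
        spec = TelegraphSpec(k_off=0.28, k_on=0.12, n_pairs=4000, dt=0.1,
                             n_steps=1500, seed=21)
        series = simulate_telegraph(spec)
        acf = intermittent_acf(series, max_lag=1100)
        life = correlation_lifetime(acf, n_terms=2)
        expected = 1.0 / spec.rate_sum
        assert life.tau == pytest.approx(expected, rel=0.10)
        assert life.plateau == pytest.approx(spec.p_bound, abs=0.03)

    def test_faster_kinetics_give_smaller_lifetime(self):
        taus = []
        for k in (0.4, 0.2, 0.1):
            spec = TelegraphSpec(k_off=0.7 * k, k_on=0.3 * k, n_pairs=2000,
                                 dt=0.1, n_steps=1200, seed=22)
            series = simulate_telegraph(spec)
            acf = intermittent_acf(series, max_lag=900)
            taus.append(correlation_lifetime(acf, n_terms=2).tau)
        assert taus[0] < taus[1] < taus[2]
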